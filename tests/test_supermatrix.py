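"""Alignment, trimming, composition test, concatenation and coverage."""

import numpy as np
import pytest

from orthomat.io_formats import MultipleAlignment, SeqRecord, Supermatrix
from orthomat.supermatrix import (
    TrimParams,
    composition_test,
    concatenate,
    coverage_filter,
    coverage_report,
    progressive_align,
    split_supermatrix,
    trim_columns,
)
from orthomat.ortholog_inference import OrthologGroup


class TestProgressiveAlign:
    def test_identical_sequences_align_gap_free(self):
        recs = [SeqRecord(f"T{i}|g", "MKVLWAAGHE") for i in range(4)]
        aln = progressive_align(recs)
        assert aln.length == 10
        assert all("-" not in s for s in aln.rows.values())

    def test_two_sequences_reduce_to_pairwise(self):
        recs = [SeqRecord("A|g", "MKVLW"), SeqRecord("B|g", "MKW")]
        aln = progressive_align(recs)
        assert len(aln) == 2 and aln.length >= 5

    def test_three_sequence_indel_case(self):
        recs = [
            SeqRecord("A|g", "MKVL"),
            SeqRecord("B|g", "MKL"),
            SeqRecord("C|g", "MKVL"),
        ]
        aln = progressive_align(recs)
        assert aln.rows["A|g"] == "MKVL"
        assert aln.rows["C|g"] == "MKVL"
        assert aln.rows["B|g"] == "MK-L"

    def test_single_sequence_returned_unchanged(self):
        aln = progressive_align([SeqRecord("A|g", "MKV")])
        assert aln.rows == {"A|g": "MKV"}

    def test_column_count_at_least_longest_input(self, rng):
        from orthomat.io_formats import AMINO_ACIDS

        recs = [
            SeqRecord(
                f"T{i}|g",
                "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(20, 40))),
            )
            for i in range(5)
        ]
        aln = progressive_align(recs)
        assert aln.length >= max(len(r.residues) for r in recs)


class TestCompositionTest:
    def test_identical_rows_have_zero_statistic(self):
        aln = MultipleAlignment({f"r{i}": "MKVLWAAGHE" for i in range(4)})
        result = composition_test(aln)
        assert all(v == pytest.approx(0.0) for v in result.chi2.values())
        assert not result.flagged

    def test_two_symbol_formula_check(self):
        """Counts (8,2) against pooled (0.5,0.5) at n=10 give chi2 = 3.6."""
        aln = MultipleAlignment({"r1": "A" * 8 + "W" * 2, "r2": "A" * 2 + "W" * 8})
        result = composition_test(aln)
        assert result.chi2["r1"] == pytest.approx(3.6)
        assert result.chi2["r2"] == pytest.approx(3.6)
        from scipy.stats import chi2 as chi2_dist

        assert result.p["r1"] == pytest.approx(chi2_dist.sf(3.6, 1))

    def test_gap_only_row_excluded(self):
        aln = MultipleAlignment({"r1": "MKV", "r2": "---"})
        result = composition_test(aln)
        assert "r2" not in result.chi2


class TestTrimColumns:
    def test_gap_free_identical_rows_keep_everything(self):
        aln = MultipleAlignment({f"r{i}": "MKVLWAAGHE" for i in range(4)})
        trimmed, mask = trim_columns(aln, TrimParams(gt=0.4, st=0.01, w=3))
        assert trimmed.length == 10 and mask == list(range(10))

    def test_gappy_column_removed_at_threshold(self):
        rows = {"r1": "MAV", "r2": "M-V", "r3": "M-V", "r4": "M-V"}
        trimmed, mask = trim_columns(
            MultipleAlignment(rows), TrimParams(gt=0.4, st=0.0, w=0)
        )
        assert mask == [0, 2]  # middle column non-gap fraction 0.25 < 0.4

    def test_windowed_rule_matches_naive_oracle(self, rng):
        """Windowed keep-set equals a direct loop evaluation of the rule."""
        from orthomat.supermatrix import _AA_TO_IDX, _PAIR_SIM

        aas = list("MKVLW")
        rows = {}
        for r in range(4):
            chars = [
                "-" if rng.random() < 0.3 else aas[rng.integers(len(aas))]
                for _ in range(10)
            ]
            rows[f"r{r}"] = "".join(chars)
        aln = MultipleAlignment(rows)
        params = TrimParams(gt=0.4, st=0.2, w=1)
        try:
            _, mask = trim_columns(aln, params)
        except ValueError:
            mask = []
        # naive oracle
        L = aln.length
        nongap, sim = [], []
        for j in range(L):
            col = [s[j] for s in rows.values()]
            present = [c for c in col if c in _AA_TO_IDX]
            nongap.append(len(present) / len(col))
            pairs = [
                _PAIR_SIM[_AA_TO_IDX[a], _AA_TO_IDX[b]]
                for i, a in enumerate(present)
                for b in present[i + 1 :]
            ]
            sim.append(float(np.mean(pairs)) if pairs else 0.0)
        expected = []
        for j in range(L):
            lo, hi = max(0, j - 1), min(L, j + 2)
            ng = np.mean(nongap[lo:hi])
            sm = np.mean(sim[lo:hi])
            if ng >= params.gt and sm >= params.st:
                expected.append(j)
        assert mask == expected

    def test_trimming_is_idempotent(self, rng):
        from orthomat.io_formats import AMINO_ACIDS

        rows = {
            f"r{i}": "".join(
                "-" if rng.random() < 0.2 else AMINO_ACIDS[rng.integers(20)]
                for _ in range(40)
            )
            for i in range(5)
        }
        params = TrimParams()
        trimmed, mask = trim_columns(MultipleAlignment(rows), params)
        again, mask2 = trim_columns(trimmed, params)
        assert again.rows == trimmed.rows
        assert mask2 == list(range(trimmed.length))

    def test_all_columns_removed_names_gene(self):
        aln = MultipleAlignment({"r1": "M---", "r2": "-M--", "r3": "--M-", "r4": "---M"})
        with pytest.raises(ValueError, match="geneX"):
            trim_columns(aln, TrimParams(gt=0.9, st=0.5, w=0), gene="geneX")


class TestConcatenate:
    def _alns(self):
        return {
            "geneB": MultipleAlignment({"t1": "MKV", "t2": "MKL"}),
            "geneA": MultipleAlignment({"t1": "WAAGHED", "t3": "WAAGHED"}),
        }

    def test_partitions_tile_in_lexicographic_order(self):
        sm = concatenate(self._alns(), ["t1", "t2", "t3"])
        assert sm.partitions == [("geneA", 1, 7), ("geneB", 8, 10)]
        assert sm.alignment.length == 10

    def test_absent_taxon_gap_filled(self):
        sm = concatenate(self._alns(), ["t1", "t2", "t3"])
        assert sm.alignment.rows["t2"][:7] == "-------"
        assert sm.alignment.rows["t3"][7:] == "---"

    def test_split_is_inverse(self):
        alns = self._alns()
        sm = concatenate(alns, ["t1", "t2", "t3"])
        back = split_supermatrix(sm)
        for gene, aln in alns.items():
            for taxon, seq in aln.rows.items():
                assert back[gene].rows[taxon] == seq

    def test_nongap_bookkeeping(self, rng):
        """Per-taxon residue count equals the sum over present genes."""
        from orthomat.io_formats import AMINO_ACIDS

        taxa = [f"t{i}" for i in range(4)]
        alns, expected = {}, {t: 0 for t in taxa}
        for g in range(6):
            L = int(rng.integers(3, 12))
            rows = {}
            for t in taxa:
                if rng.random() < 0.7:
                    rows[t] = "".join(rng.choice(list(AMINO_ACIDS), size=L))
                    expected[t] += L
            if len(rows) >= 2:
                alns[f"g{g}"] = MultipleAlignment(rows)
        sm = concatenate(alns, taxa)
        for t in taxa:
            got = sum(ch != "-" for ch in sm.alignment.rows[t])
            assert got == expected[t]

    def test_duplicate_gene_names_rejected(self):
        aln = MultipleAlignment({"t1": "MK"})
        with pytest.raises(ValueError, match="duplicate"):
            concatenate([("g", aln), ("g", aln)], ["t1"])


class TestCoverageFilter:
    def _group(self, taxa):
        members = {t: [f"{t}|g"] for t in taxa}
        return OrthologGroup(name="og", members=members, seed=(f"{taxa[0]}|g", f"{taxa[1]}|g"))

    def test_full_sampling_kept(self):
        g = self._group(
            ["Chlorokybus", "Klebsormidium", "Nitella", "Coleochaete",
             "Chaetosphaeridium", "Penium", "Spirogyra", "Mesostigma"]
        )
        assert coverage_filter([g]) == [g]

    def test_or_set_lineage_satisfied_by_either_taxon(self):
        g = self._group(
            ["Chlorokybus", "Klebsormidium", "Nitella", "Chaetosphaeridium", "Spirogyra"]
        )
        assert coverage_filter([g]) == [g]

    def test_missing_whole_lineage_rejected(self):
        g = self._group(
            ["Chlorokybus", "Klebsormidium", "Nitella", "Coleochaete"]
        )  # no Zygnematales representative
        assert coverage_filter([g]) == []

    def test_unknown_taxon_raises(self):
        g = self._group(["Chlorokybus", "Wrongia"])
        with pytest.raises(ValueError, match="Wrongia"):
            coverage_filter([g])


class TestCoverageReport:
    def test_percent_arithmetic(self):
        aln = MultipleAlignment(
            {"t1": "MKVMKV", "t2": "MKV---", "t3": "---MKV"}
        )
        sm = Supermatrix(aln, [("g1", 1, 3), ("g2", 4, 6)])
        rep = coverage_report(sm, ["t2", "t3"])
        assert rep.genes_present == {"t1": 2, "t2": 1, "t3": 1}
        assert rep.percent["t2"] == 50.0
        assert rep.mean_focal_per_gene == 1.0
        assert rep.missing_fraction == pytest.approx(6 / 18)
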