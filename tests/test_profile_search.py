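"""Position-specific profile construction and top-hit retrieval."""

import math

import numpy as np
import pytest

from orthomat.io_formats import AMINO_ACIDS, MultipleAlignment, Proteome, SeqRecord
from orthomat.profile_search import (
    SCORE_FLOOR,
    build_profile,
    score_sequence,
    search_top_hit,
)

A = AMINO_ACIDS.index("A")
W = AMINO_ACIDS.index("W")


class TestBuildProfile:
    def test_conserved_column_limit_small_pseudocount(self):
        aln = MultipleAlignment({f"r{i}": "A" for i in range(4)})
        p = build_profile(aln, pseudocount=1e-9)
        bg_a = (4 + 1) / (4 + 20)
        assert p.scores[0][A] == pytest.approx(math.log2(1 / bg_a), abs=1e-6)
        assert p.scores[0][W] == SCORE_FLOOR

    def test_uniform_column_is_uninformative(self):
        aln = MultipleAlignment({f"r{i}": aa for i, aa in enumerate(AMINO_ACIDS)})
        p = build_profile(aln, pseudocount=1.0)
        assert np.allclose(p.scores[0], 0.0, atol=1e-12)

    def test_toy_alignment_matches_direct_formula(self):
        """Three-column toy profile vs an independent evaluation of
        log2(((count + pc*bg)/(n_eff + pc))/bg) with Laplace background."""
        aln = MultipleAlignment({"r1": "AKV", "r2": "AKV", "r3": "ARV", "r4": "A-V"})
        p = build_profile(aln, pseudocount=1.0)
        glob = {"A": 4, "K": 2, "R": 1, "V": 4}
        total = 11

        def bg(aa):
            return (glob.get(aa, 0) + 1) / (total + 20)

        def expected(count, n_eff, aa):
            return math.log2(((count + bg(aa)) / (n_eff + 1)) / bg(aa))

        K, R, V = (AMINO_ACIDS.index(x) for x in "KRV")
        assert p.scores[0][A] == pytest.approx(expected(4, 4, "A"))
        assert p.scores[1][K] == pytest.approx(expected(2, 3, "K"))
        assert p.scores[1][R] == pytest.approx(expected(1, 3, "R"))
        assert p.scores[1][W] == pytest.approx(expected(0, 3, "W"))
        assert p.scores[2][V] == pytest.approx(expected(4, 4, "V"))

    def test_majority_gap_columns_excluded(self):
        aln = MultipleAlignment({"r1": "A-V", "r2": "A-V", "r3": "A-V", "r4": "AWV"})
        p = build_profile(aln)
        assert p.columns == [0, 2]

    def test_all_gap_alignment_rejected(self):
        aln = MultipleAlignment({"r1": "--", "r2": "--"})
        with pytest.raises(ValueError):
            build_profile(aln)


class TestSearchTopHit:
    def _profile(self):
        rows = {f"r{i}": "MKVLWAAGHEDERTKY" for i in range(3)}
        return build_profile(MultipleAlignment(rows))

    def test_core_member_retrieves_itself(self):
        profile = self._profile()
        unigenes = Proteome(
            "T",
            [
                SeqRecord("T|u1", "MKVLWAAGHEDERTKY"),
                SeqRecord("T|u2", "PPPPPPPPPP"),
            ],
        )
        assert search_top_hit(profile, unigenes, min_score=5.0) == "T|u1"

    def test_partial_profile_coverage_allowed(self):
        profile = self._profile()
        assert score_sequence(profile, "AAGHED") > 0  # internal window only

    def test_threshold_returns_none(self):
        profile = self._profile()
        unigenes = Proteome("T", [SeqRecord("T|u1", "PPP")])
        assert search_top_hit(profile, unigenes, min_score=50.0) is None

    def test_empty_unigene_set_returns_none(self):
        profile = self._profile()
        assert search_top_hit(profile, Proteome("T", []), min_score=1.0) is None

    def test_tie_breaks_to_smallest_id(self):
        profile = self._profile()
        unigenes = Proteome(
            "T",
            [
                SeqRecord("T|zz", "MKVLWAAGHEDERTKY"),
                SeqRecord("T|aa", "MKVLWAAGHEDERTKY"),
            ],
        )
        assert search_top_hit(profile, unigenes, min_score=1.0) == "T|aa"

    def test_retrieval_matches_truth_on_clean_study(self):
        """Without duplications the top hit is the true ortholog >=98%."""
        from orthomat.synthetic_study import (
            REFERENCE_TAXA,
            SimulationConfig,
            generate_study,
        )
        from orthomat.supermatrix import progressive_align

        cfg = SimulationConfig(
            n_genes=20,
            gene_length=120,
            dup_rate=0.0,
            loss_rate=0.0,
            occupancy_profile={},
            biased_fraction=0.0,
            incongruent_fraction=0.0,
            seed=17,
        )
        truth, per_taxon, alns = generate_study(cfg)
        trans_taxa = [t for t in per_taxon if t not in REFERENCE_TAXA]
        unigenes = {
            t: Proteome(t, sorted(per_taxon[t], key=lambda r: r.id))
            for t in trans_taxa
        }
        checked, correct = 0, 0
        for gene, aln in alns.items():
            ref_rows = {
                rid: seq for rid, seq in aln.rows.items()
                if rid.split("|")[0] in REFERENCE_TAXA
            }
            profile = build_profile(MultipleAlignment(ref_rows))
            for taxon in trans_taxa:
                hit = search_top_hit(profile, unigenes[taxon], min_score=15.0)
                checked += 1
                if hit == f"{taxon}|{gene}":
                    correct += 1
        assert checked == 20 * 8
        assert correct / checked >= 0.98


def test_at_most_one_hit_per_taxon_by_construction():
    """The search returns a single id or None — never multiple hits."""
    rows = {f"r{i}": "MKVLWAAGHE" for i in range(3)}
    profile = build_profile(MultipleAlignment(rows))
    unigenes = Proteome("T", [SeqRecord(f"T|u{i}", "MKVLWAAGHE") for i in range(5)])
    hit = search_top_hit(profile, unigenes, min_score=1.0)
    assert isinstance(hit, str)
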