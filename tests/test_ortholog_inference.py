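"""RBH seeding, in-paralog clustering, TC extension and the tree filter."""

import itertools

import numpy as np
import pytest

from orthomat.io_formats import Proteome, SeqRecord, read_newick
from orthomat.ortholog_inference import (
    CladeConstraint,
    OrthologGroup,
    build_core_orthologs,
    cluster_inparalogs,
    pairwise_score,
    phylogenetic_filter,
    reciprocal_best_hits,
)
from orthomat.synthetic_study import evolve_sequences
from orthomat.ml_engine import lg_model


class TestPairwiseScore:
    def test_textbook_smith_waterman_instance(self):
        hit = pairwise_score(
            SeqRecord("A|q", "HEAGAWGHEE"),
            SeqRecord("B|s", "PAWHEAE"),
            matrix="BLOSUM50",
            gap_open=8,
            gap_extend=8,
        )
        assert hit.score == 28.0

    def test_self_alignment_equals_diagonal_sum(self):
        from Bio.Align import substitution_matrices

        b62 = substitution_matrices.load("BLOSUM62")
        seq = "MKVLWAAGHE"
        hit = pairwise_score(SeqRecord("A|q", seq), SeqRecord("A|q", seq))
        assert hit.score == sum(float(b62[c, c]) for c in seq)

    def test_no_positive_local_alignment_scores_zero(self):
        hit = pairwise_score(SeqRecord("A|q", "AAAA"), SeqRecord("B|s", "WWWW"))
        assert hit.score == 0.0

    def test_unknown_residue_rejected_but_x_allowed(self):
        with pytest.raises(ValueError, match="unknown residue"):
            pairwise_score(SeqRecord("A|q", "MKB"), SeqRecord("B|s", "MKV"))
        assert pairwise_score(SeqRecord("A|q", "MXV"), SeqRecord("B|s", "MKV")).score > 0


class _FakeEngine:
    """Score table injected in place of the alignment engine."""

    def __init__(self, table):
        self.table = table

    def score(self, a, b):
        if a.id == b.id:
            return self.table.get((a.id, b.id), 100.0)
        return self.table.get((a.id, b.id), self.table.get((b.id, a.id), 0.0))


def _proteome(taxon, n):
    return Proteome(taxon, [SeqRecord(f"{taxon}|g{i}", "MKVL") for i in range(n)])


class TestReciprocalBestHits:
    def test_single_pair_seed(self):
        A, B = _proteome("A", 1), _proteome("B", 1)
        engine = _FakeEngine({("A|g0", "B|g0"): 50.0})
        assert reciprocal_best_hits(A, B, engine, 40.0) == [("A|g0", "B|g0")]

    def test_reciprocity_violation_blocks_seed(self):
        A, B = _proteome("A", 2), _proteome("B", 1)
        engine = _FakeEngine({("A|g0", "B|g0"): 50.0, ("A|g1", "B|g0"): 60.0})
        seeds = reciprocal_best_hits(A, B, engine, 40.0)
        assert seeds == [("A|g1", "B|g0")]

    def test_matches_brute_force_on_random_matrices(self, rng):
        """Seeds equal exhaustive enumeration of mutual unique argmax pairs."""
        for trial in range(20):
            A, B = _proteome("A", 5), _proteome("B", 5)
            table = {
                (a.id, b.id): float(rng.integers(0, 200))
                for a in A for b in B
            }
            engine = _FakeEngine(table)
            got = reciprocal_best_hits(A, B, engine, 40.0)
            expected = []
            for a in A:
                arow = {b.id: table[(a.id, b.id)] for b in B}
                abest = max(arow.values())
                atop = [k for k, v in arow.items() if v == abest]
                if len(atop) != 1 or abest < 40.0:
                    continue
                b_id = atop[0]
                bcol = {x.id: table[(x.id, b_id)] for x in A}
                bbest = max(bcol.values())
                btop = [k for k, v in bcol.items() if v == bbest]
                if len(btop) == 1 and btop[0] == a.id:
                    expected.append((a.id, b_id))
            assert got == sorted(expected)

    def test_invariant_under_record_order(self, rng):
        A, B = _proteome("A", 4), _proteome("B", 4)
        table = {(a.id, b.id): float(rng.integers(0, 99)) for a in A for b in B}
        engine = _FakeEngine(table)
        ref = reciprocal_best_hits(A, B, engine, 10.0)
        A2 = Proteome("A", list(reversed(A.records)))
        B2 = Proteome("B", list(reversed(B.records)))
        assert reciprocal_best_hits(A2, B2, engine, 10.0) == ref


class TestInparalogClustering:
    def test_seed_only_group(self):
        A, B = _proteome("A", 1), _proteome("B", 1)
        engine = _FakeEngine({("A|g0", "B|g0"): 50.0})
        grp = cluster_inparalogs(("A|g0", "B|g0"), A, B, engine)
        assert grp.members == {"A": ["A|g0"], "B": ["B|g0"]}
        assert grp.confidences["A|g0"] == 1.0

    def test_recent_duplicate_joins_group(self):
        A, B = _proteome("A", 2), _proteome("B", 1)
        engine = _FakeEngine(
            {
                ("A|g0", "B|g0"): 50.0,
                ("A|g1", "B|g0"): 20.0,
                ("A|g0", "A|g1"): 90.0,  # close duplicate of the seed
                ("A|g0", "A|g0"): 100.0,
            }
        )
        grp = cluster_inparalogs(("A|g0", "B|g0"), A, B, engine)
        assert sorted(grp.members["A"]) == ["A|g0", "A|g1"]
        assert grp.confidences["A|g1"] == pytest.approx((90 - 50) / (100 - 50))

    def test_simulated_postspeciation_duplication_recovered(self):
        """An in-paralog evolved after the split joins its seed's group."""
        model = lg_model()
        hits = 0
        for seed in range(100):
            tree = read_newick("((A1:0.03,A2:0.03):0.25,B:0.28);")
            aln = evolve_sequences(tree, 150, model, seed=seed)
            A = Proteome("A", [SeqRecord("A|g1", aln.rows["A1"]),
                               SeqRecord("A|g1.p1", aln.rows["A2"])])
            B = Proteome("B", [SeqRecord("B|g1", aln.rows["B"])])
            seeds = reciprocal_best_hits(A, B, score_cutoff=40.0)
            if not seeds:
                continue
            grp = cluster_inparalogs(seeds[0], A, B)
            if sorted(grp.members["A"]) == ["A|g1", "A|g1.p1"]:
                hits += 1
        assert hits >= 95


class TestCoreOrthologs:
    def _pairwise(self, taxa, gene="g0"):
        groups = []
        for ta, tb in itertools.combinations(taxa, 2):
            sa, sb = f"{ta}|{gene}", f"{tb}|{gene}"
            groups.append(
                OrthologGroup(
                    name=f"{sa}--{sb}",
                    members={ta: [sa], tb: [sb]},
                    seed=(sa, sb),
                    provenance="pairwise",
                    confidences={sa: 1.0, sb: 1.0},
                )
            )
        return groups

    def test_consistent_triangle_forms_one_group(self):
        core, discarded = build_core_orthologs(self._pairwise("ABC"), list("ABC"))
        assert len(core) == 1 and discarded == 0
        assert core[0].members == {"A": ["A|g0"], "B": ["B|g0"], "C": ["C|g0"]}

    def test_component_missing_a_taxon_is_discarded(self):
        groups = self._pairwise("AB")  # no C anywhere
        core, discarded = build_core_orthologs(groups, list("ABC"))
        assert core == [] and discarded == 1


class TestPhylogeneticFilter:
    CONSTRAINTS = [CladeConstraint("land plants", frozenset({"lp1", "lp2"}))]

    def _group(self, taxa):
        return OrthologGroup(
            name="og1",
            members={t: [f"{t}|g"] for t in taxa},
            seed=(f"{taxa[0]}|g", f"{taxa[1]}|g"),
        )

    def test_monophyletic_ingroup_keeps(self):
        tree = read_newick("((lp1:1,lp2:1):1,alga1:1,alga2:1);")
        keep, reason = phylogenetic_filter(
            self._group(["lp1", "lp2", "alga1", "alga2"]), tree, self.CONSTRAINTS
        )
        assert keep and reason is None

    def test_broken_monophyly_rejects_with_reason(self):
        tree = read_newick("((lp1:1,alga1:1):1,lp2:1,alga2:1);")
        keep, reason = phylogenetic_filter(
            self._group(["lp1", "lp2", "alga1", "alga2"]), tree, self.CONSTRAINTS
        )
        assert not keep and reason == "land plants"

    def test_leaf_set_mismatch_raises(self):
        tree = read_newick("((lp1:1,lp2:1):1,other:1,alga2:1);")
        with pytest.raises(ValueError):
            phylogenetic_filter(
                self._group(["lp1", "lp2", "alga2", "alga1"]), tree, self.CONSTRAINTS
            )

    def test_swapped_paralogs_detected_on_simulations(self):
        """Groups with a paralog breaking reference monophyly are rejected."""
        from orthomat.ml_engine import nni_search, wag_model

        constraints = [CladeConstraint("ingroup", frozenset({"P1", "P2", "P3"}))]
        n_bad_rejected = 0
        n_clean_kept = 0
        for seed in range(20):
            clean = read_newick(
                "(((P1:0.1,P2:0.1):0.08,P3:0.15):0.2,(O1:0.15,O2:0.15):0.1);"
            )
            bad = read_newick(
                "(((P1:0.1,O1:0.1):0.08,P3:0.15):0.2,(P2:0.15,O2:0.15):0.1);"
            )
            for topo, is_bad in ((clean, False), (bad, True)):
                aln = evolve_sequences(topo, 400, wag_model(), seed=seed)
                tree = nni_search(None, aln, wag_model()).tree
                group = self._group(["P1", "P2", "P3", "O1", "O2"])
                keep, _ = phylogenetic_filter(group, tree, constraints)
                if is_bad and not keep:
                    n_bad_rejected += 1
                if not is_bad and keep:
                    n_clean_kept += 1
        assert n_bad_rejected >= 18
        assert n_clean_kept >= 18
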