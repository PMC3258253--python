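"""Likelihood engine: oracle agreement, optimization, search, bootstrap, AIC."""

import numpy as np
import pytest

from orthomat.io_formats import AMINO_ACIDS, MultipleAlignment, read_newick
from orthomat.ml_engine import (
    TreeLikelihood,
    aic_model_select,
    bootstrap,
    lg_model,
    nni_search,
    optimize_branch_lengths,
    poisson_model,
    tree_loglik,
    wag_model,
)
from orthomat.synthetic_study import evolve_sequences
from orthomat.tree import random_binary_tree
from tests.conftest import brute_force_loglik

MODELS = [poisson_model(), wag_model(), lg_model(), poisson_model(0.7), wag_model(1.3), lg_model(2.5)]


@pytest.mark.parametrize("model", MODELS, ids=lambda m: f"{m.name}-a{m.gamma_alpha}")
def test_pruning_matches_exhaustive_enumeration(model, toy_alignment, quartet_newick):
    """Felsenstein pruning equals the brute-force expm oracle to 1e-8."""
    tree = read_newick(quartet_newick)
    got = tree_loglik(tree, toy_alignment, model).lnl
    expect = brute_force_loglik(tree, toy_alignment, model)
    assert got == pytest.approx(expect, abs=1e-8)


@pytest.mark.parametrize("model", [poisson_model(), wag_model(), lg_model(0.5)])
def test_transition_matrices_are_stochastic(model):
    for t in (0.01, 0.1, 1.0, 10.0):
        P = model.transition_matrices(t)
        assert np.allclose(P.sum(axis=2), 1.0, atol=1e-10)
        assert np.all(P >= 0)
    P0 = model.transition_matrices(0.0)
    for k in range(P0.shape[0]):
        assert np.allclose(P0[k], np.eye(20), atol=1e-10)


def test_discrete_gamma_rates_average_to_one():
    for alpha in (0.05, 0.5, 1.0, 7.0):
        rates = poisson_model(alpha).category_rates()
        assert rates.mean() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(rates) > 0)


def test_two_taxon_identity_closed_form():
    """Two-leaf Poisson site likelihood equals bg*(1/20+(19/20)e^(-20t/19))."""
    t = 0.1
    aln = MultipleAlignment({"A": "W", "B": "W"})
    tree = read_newick(f"(A:{t / 2},B:{t / 2});")
    got = tree_loglik(tree, aln, poisson_model()).lnl
    expect = np.log(0.05 * (1 / 20 + (19 / 20) * np.exp(-(20 / 19) * t)))
    assert got == pytest.approx(expect, abs=1e-10)


def test_zero_distance_gives_equilibrium_frequency():
    aln = MultipleAlignment({"A": "W", "B": "W"})
    tree = read_newick("(A:0.0,B:0.0);")
    got = tree_loglik(tree, aln, wag_model()).lnl
    w = wag_model().frequencies[AMINO_ACIDS.index("W")]
    assert got == pytest.approx(np.log(w), abs=1e-8)


def test_likelihood_invariant_under_rerooting(toy_alignment):
    """Pulley principle: splitting an edge differently leaves lnL unchanged."""
    t1 = read_newick("((A:0.1,B:0.2):0.15,C:0.3,D:0.05);")
    t2 = read_newick("((C:0.3,(A:0.1,B:0.2):0.15):0.025,D:0.025);")
    m = lg_model(0.8)
    assert tree_loglik(t1, toy_alignment, m).lnl == pytest.approx(
        tree_loglik(t2, toy_alignment, m).lnl, abs=1e-9
    )


class TestBranchOptimization:
    def test_lnl_never_decreases(self, toy_alignment, quartet_newick):
        engine = TreeLikelihood(read_newick(quartet_newick), toy_alignment, wag_model())
        before = engine.loglik()
        after = engine.optimize_branch_lengths()
        assert after >= before

    def test_identical_sequences_drive_lengths_to_clamp(self):
        aln = MultipleAlignment({n: "MKVLWAAGHE" * 3 for n in "ABCD"})
        res = optimize_branch_lengths(
            read_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);"), aln, poisson_model()
        )
        assert all(e.length <= 1e-6 for e in res.tree.edges())

    def test_branch_length_recovery_on_long_alignment(self):
        true = read_newick("((A:0.20,B:0.10):0.15,C:0.30,D:0.08);")
        aln = evolve_sequences(true, 50000, poisson_model(), seed=11)
        res = optimize_branch_lengths(true.copy(), aln, poisson_model())
        got = {frozenset(_split(e, res.tree)): e.length for e in res.tree.edges()}
        for edge in true.edges():
            key = frozenset(_split(edge, true))
            assert got[key] == pytest.approx(edge.length, rel=0.05)


def _split(edge, tree):
    names = frozenset(l.name for l in _leaves_below(edge))
    total = frozenset(tree.leaf_names())
    anchor = min(total)
    return names if anchor not in names else total - names


def _leaves_below(node):
    if node.is_leaf:
        return [node]
    out = []
    for c in node.children:
        out.extend(_leaves_below(c))
    return out


class TestNNISearch:
    def test_four_taxon_search_matches_exhaustive(self):
        """NNI result equals the best of all three unrooted quartets."""
        true = read_newick("((A:0.2,B:0.2):0.2,(C:0.2,D:0.2):0.0);").unroot()
        aln = evolve_sequences(
            read_newick("((A:0.2,B:0.2):0.2,C:0.2,D:0.2);"), 500, poisson_model(), seed=3
        )
        best = nni_search(None, aln, poisson_model())
        topos = [
            "((A:0.1,B:0.1):0.1,C:0.1,D:0.1);",
            "((A:0.1,C:0.1):0.1,B:0.1,D:0.1);",
            "((A:0.1,D:0.1):0.1,B:0.1,C:0.1);",
        ]
        scores = [
            optimize_branch_lengths(read_newick(t), aln, poisson_model()).lnl
            for t in topos
        ]
        assert best.lnl == pytest.approx(max(scores), abs=1e-3)

    def test_true_topology_is_local_optimum(self):
        tree = read_newick("((A:0.15,B:0.15):0.1,(C:0.15,D:0.15):0.1,E:0.2);")
        aln = evolve_sequences(tree, 3000, poisson_model(), seed=5)
        res = nni_search(tree.copy(), aln, poisson_model())
        assert res.tree.symmetric_difference(tree) == 0

    def test_eight_taxon_topology_recovery(self, rng):
        hits = 0
        for seed in range(3):
            local = np.random.default_rng(seed)
            true = random_binary_tree(
                [f"T{i}" for i in range(8)], local, lambda: 0.08 + local.exponential(0.1)
            )
            aln = evolve_sequences(true, 2000, lg_model(), seed=seed + 100)
            res = nni_search(None, aln, lg_model())
            hits += res.tree.symmetric_difference(true) == 0
        assert hits == 3


class TestBootstrap:
    def _data(self):
        tree = read_newick(
            "((A:0.2,B:0.2):0.15,(C:0.2,D:0.2):0.15,(E:0.2,F:0.2):0.15);"
        )
        return tree, evolve_sequences(tree, 5000, poisson_model(), seed=9)

    def test_strong_signal_gives_full_support(self):
        tree, aln = self._data()
        annotated, support = bootstrap(aln, poisson_model(), 10, seed=1)
        for split in tree.bipartitions():
            assert support[split] >= 95.0

    def test_single_replicate_supports_are_degenerate(self):
        _, aln = self._data()
        _, support = bootstrap(aln, poisson_model(), 1, seed=4)
        assert set(support.values()) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self):
        _, aln = self._data()
        _, s1 = bootstrap(aln, poisson_model(), 5, seed=42)
        _, s2 = bootstrap(aln, poisson_model(), 5, seed=42)
        assert s1 == s2


class TestModelSelection:
    def test_wag_gamma_recovered(self):
        tree = read_newick("((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2,E:0.4);")
        aln = evolve_sequences(tree, 2000, wag_model(0.5), seed=21)
        best, scores = aic_model_select(
            aln, [poisson_model(), wag_model(), wag_model(1.0)]
        )
        assert best.name.startswith("WAG") and best.gamma_alpha is not None

    def test_aic_difference_is_twice_parameter_difference(self):
        m1, m2 = poisson_model(), poisson_model()
        assert 2 * (m1.n_free_parameters - m2.n_free_parameters) == 0
        mg = poisson_model(1.0)
        assert mg.n_free_parameters - m1.n_free_parameters == 1

    def test_identical_candidates_tie_to_first(self):
        tree = read_newick("((A:0.2,B:0.2):0.1,C:0.2,D:0.2);")
        aln = evolve_sequences(tree, 300, wag_model(), seed=2)
        best, _ = aic_model_select(aln, [wag_model(), wag_model()])
        assert best.name == "WAG"
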