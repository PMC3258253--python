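"""Tree search, bootstrap support and AIC model choice.

The search strategy is NNI hill-climbing from a neighbour-joining start
tree (distances: Poisson-corrected p-distances).  Bootstrap support is
computed by resampling alignment columns with replacement, repeating the
search from the maximum-likelihood tree, and counting bipartitions.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from ..io_formats import MultipleAlignment, read_newick
from ..tree import PhyloTree
from .likelihood import (
    MIN_BRANCH,
    MISSING_CODE,
    LikelihoodResult,
    TreeLikelihood,
    encode_alignment,
)
from .models import SubstitutionModel


# ---------------------------------------------------------------------- #
# distance start tree
# ---------------------------------------------------------------------- #
def pairwise_distances(aln: MultipleAlignment, taxa: Optional[list[str]] = None) -> tuple[np.ndarray, list[str]]:
    """Poisson-corrected p-distances, ignoring missing positions."""
    taxa = sorted(aln.rows) if taxa is None else taxa
    codes = encode_alignment(aln, taxa)
    n = len(taxa)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] != MISSING_CODE) & (codes[j] != MISSING_CODE)
            if ok.sum() == 0:
                p = 0.75  # no shared sites: fall back to a large distance
            else:
                p = float((codes[i][ok] != codes[j][ok]).mean())
            p = min(p, 0.94)  # keep the correction finite
            d = -19.0 / 20.0 * np.log(1.0 - 20.0 / 19.0 * p)
            dist[i, j] = dist[j, i] = max(d, 0.0)
    return dist, taxa


def nj_tree(aln: MultipleAlignment) -> PhyloTree:
    """Neighbour-joining start tree on corrected distances."""
    dist, taxa = pairwise_distances(aln)
    if len(taxa) < 2:
        raise ValueError("need at least two sequences")
    if len(taxa) == 2:
        return read_newick(f"({taxa[0]}:{dist[0, 1] / 2:.6f},{taxa[1]}:{dist[0, 1] / 2:.6f});")
    if len(taxa) == 3:
        a, b, c = taxa
        return read_newick(f"({a}:0.1,{b}:0.1,{c}:0.1);")
    dm = DistanceMatrix(dist, ids=taxa)
    newick = str(_skbio_nj(dm))
    tree = read_newick(newick)
    for node in tree.edges():
        node.length = max(node.length, MIN_BRANCH)
    return tree.unroot()


# ---------------------------------------------------------------------- #
# public operations
# ---------------------------------------------------------------------- #
def tree_loglik(
    tree: PhyloTree, aln: MultipleAlignment, model: SubstitutionModel
) -> LikelihoodResult:
    """Log-likelihood of a fixed tree (no optimization)."""
    engine = TreeLikelihood(tree, aln, model)
    return engine.result()


def optimize_branch_lengths(
    tree: PhyloTree, aln: MultipleAlignment, model: SubstitutionModel
) -> LikelihoodResult:
    engine = TreeLikelihood(tree, aln, model)
    engine.optimize_branch_lengths()
    return engine.result()


def nni_search(
    start: Optional[PhyloTree],
    aln: MultipleAlignment,
    model: SubstitutionModel,
    tol: float = 1e-4,
) -> LikelihoodResult:
    """NNI hill-climbing ML search; ``start=None`` uses the NJ tree."""
    if start is None:
        start = nj_tree(aln)
    engine = TreeLikelihood(start, aln, model)
    engine.nni_search(tol=tol)
    return engine.result()


def optimize_gamma_alpha(
    tree: PhyloTree,
    aln: MultipleAlignment,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (0.02, 100.0),
) -> SubstitutionModel:
    """Brent-optimize the gamma shape on a fixed tree (branch lengths fixed)."""
    if model.gamma_alpha is None:
        return model

    def neg(log_a: float) -> float:
        m = model.with_gamma(float(np.exp(log_a)), model.n_categories)
        return -TreeLikelihood(tree, aln, m).loglik()

    res = minimize_scalar(
        neg,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return model.with_gamma(float(np.exp(res.x)), model.n_categories)


def bootstrap(
    aln: MultipleAlignment,
    model: SubstitutionModel,
    n_reps: int,
    seed: int,
    best_tree: Optional[PhyloTree] = None,
) -> tuple[PhyloTree, dict[frozenset, float]]:
    """Site-resampling bootstrap support mapped onto the best tree.

    Each replicate redraws pattern weights by a multinomial over the
    original columns and reruns the NNI search starting from the ML tree.
    Returns the best tree with integer percent supports on internal nodes
    and the full bipartition->percent table.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if best_tree is None:
        best_tree = nni_search(None, aln, model).tree
    rng = np.random.default_rng(seed)
    engine = TreeLikelihood(best_tree, aln, model)
    base_weights = engine.weights.copy()
    probs = base_weights / base_weights.sum()
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        engine_rep = TreeLikelihood(best_tree, aln, model)
        engine_rep.weights = rng.multinomial(engine.n_sites, probs).astype(float)
        engine_rep.nni_search(bl_sweeps=3)
        for split in engine_rep.tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    support = {split: 100.0 * c / n_reps for split, c in counts.items()}
    annotated = best_tree.copy()
    all_leaves = frozenset(annotated.leaf_names())
    anchor = min(all_leaves)
    below = {}
    for node in annotated.postorder():
        if node.is_leaf:
            below[node] = frozenset([node.name])
            continue
        below[node] = frozenset().union(*(below[c] for c in node.children))
        if node is annotated.root:
            continue
        side = below[node]
        if anchor in side:
            side = all_leaves - side
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        node.support = round(support.get(side, 0.0))
    return annotated, support


def aic_model_select(
    aln: MultipleAlignment,
    candidates: Sequence[SubstitutionModel],
    alpha_init: float = 1.0,
) -> tuple[SubstitutionModel, dict[str, float]]:
    """Pick the AIC-best model on a fixed NJ tree with optimized branches.

    AIC = 2k - 2 lnL with k the model's free parameters (+G adds one,
    +F adds 19).  Ties (and equal lnL) resolve to the earliest candidate.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    start = nj_tree(aln)
    scores: dict[str, float] = {}
    best: tuple[float, int, SubstitutionModel] | None = None
    for order, model in enumerate(candidates):
        fitted = model
        engine = TreeLikelihood(start, aln, fitted)
        lnl = engine.optimize_branch_lengths()
        if fitted.gamma_alpha is not None:
            fitted = optimize_gamma_alpha(engine.tree, aln, fitted)
            engine = TreeLikelihood(engine.tree, aln, fitted)
            lnl = engine.optimize_branch_lengths()
        aic = 2.0 * fitted.n_free_parameters - 2.0 * lnl
        scores[model.name] = aic
        if best is None or aic < best[0] - 1e-9:
            best = (aic, order, fitted)
    return best[2], scores
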