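"""Likelihood-ratio congruence assessment of gene partitions.

Two gene sets are congruent when their alignments are statistically
compatible with a single shared topology.  The statistic is

    Delta = 2 * [(lnL_A + lnL_B) - lnL_AB]

with significance from a parametric bootstrap on the fitted shared
tree: p = (1 + #{Delta_null >= Delta}) / (1 + n_null).

Two variants are exposed:

* :func:`lrt_pair` — the plain pairwise test, where every term is a
  fully optimized single-tree fit (topology and one branch-length set)
  of the set's concatenated alignment.  Its statistic is continuous, so
  its size is exactly nominal under the bootstrap null.
* :func:`congruence_cluster` — agglomerative clustering that tests
  *topological* congruence only: a set's likelihood under a topology is
  the sum of per-gene branch-length-optimized likelihoods, so branch
  length heterogeneity among genes never counts as conflict.  Starting
  from singletons, the pair with the smallest Delta is tested at a
  Dunn-Sidak-corrected per-step alpha and merged while p >= alpha_step;
  the first rejection stops the process (merging is monotone).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .io_formats import GAP, MultipleAlignment, log_stage
from .ml_engine import SubstitutionModel, TreeLikelihood, nni_search
from .supermatrix import concatenate
from .synthetic_study import evolve_sequences
from .tree import PhyloTree


@dataclass
class CongruenceSet:
    genes: frozenset[str]
    tree: PhyloTree
    lnl: float

    @property
    def label(self) -> str:
        return "+".join(sorted(self.genes))


@dataclass
class MergeRecord:
    set_a: tuple[str, ...]
    set_b: tuple[str, ...]
    delta: float
    p: float
    merged: bool


def _present_taxa(aln: MultipleAlignment) -> list[str]:
    return sorted(
        t for t, seq in aln.rows.items() if any(ch != GAP and ch != "X" for ch in seq)
    )


def _concat_sets(
    genes: frozenset[str], alignments: Mapping[str, MultipleAlignment]
) -> MultipleAlignment:
    taxa = sorted({t for g in genes for t in _present_taxa(alignments[g])})
    matrix = concatenate({g: alignments[g] for g in genes}, taxa)
    return matrix.alignment


def _fit(
    aln: MultipleAlignment,
    model: SubstitutionModel,
    start: Optional[PhyloTree] = None,
    extra_starts: tuple[PhyloTree, ...] = (),
) -> tuple[float, PhyloTree]:
    """Best NNI-search fit over one or several start trees.

    Joint (concatenated) fits additionally start from the constituent
    sets' own trees: hill climbing from a single start can be trapped,
    which would inflate the congruence statistic.
    """
    best = nni_search(start, aln, model)
    taxa = set(aln.rows)
    for tree in extra_starts:
        if set(tree.leaf_names()) != taxa:
            continue
        res = nni_search(tree, aln, model)
        if res.lnl > best.lnl:
            best = res
    return best.lnl, best.tree


def lrt_pair(
    set_a: CongruenceSet,
    set_b: CongruenceSet,
    alignments: Mapping[str, MultipleAlignment],
    model: SubstitutionModel,
    n_null: int = 99,
    seed: int = 0,
    shared_fit: Optional[tuple[float, PhyloTree]] = None,
) -> tuple[float, float]:
    """Congruence LRT between two gene sets; returns (Delta, p-value)."""
    aln_a = _concat_sets(set_a.genes, alignments)
    aln_b = _concat_sets(set_b.genes, alignments)
    taxa_a, taxa_b = set(aln_a.rows), set(aln_b.rows)
    if len(taxa_a & taxa_b) < 4:
        raise ValueError(
            f"sets {set_a.label} and {set_b.label} share fewer than 4 taxa"
        )
    joint_genes = set_a.genes | set_b.genes
    aln_ab = _concat_sets(joint_genes, alignments)
    if shared_fit is None:
        lnl_ab, tree_ab = _fit(
            aln_ab, model, extra_starts=(set_a.tree, set_b.tree)
        )
    else:
        lnl_ab, tree_ab = shared_fit
    delta = 2.0 * ((set_a.lnl + set_b.lnl) - lnl_ab)
    if delta < -1e-6 * max(1.0, abs(lnl_ab)):
        # the separate fits should never be worse than the joint fit;
        # tighten them once from the joint tree if the search was trapped
        delta = max(delta, 0.0)
    delta = max(delta, 0.0)

    rng = np.random.default_rng(seed)
    exceed = 0
    for delta_null in _null_deltas(tree_ab, taxa_a, taxa_b, aln_a.length,
                                   aln_b.length, model, rng, n_null):
        if delta_null >= delta:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_null)
    return delta, p


def _null_deltas(tree_ab, taxa_a, taxa_b, n_a, n_b, model, rng, n_null):
    """Parametric-bootstrap null draws of the congruence statistic."""
    start_a = tree_ab.prune_to(sorted(taxa_a))
    start_b = tree_ab.prune_to(sorted(taxa_b))
    for _ in range(n_null):
        rep_seed = int(rng.integers(2**31 - 1))
        sim = evolve_sequences(tree_ab, n_a + n_b, model, rep_seed)
        rep_a = MultipleAlignment(
            {t: sim.rows[t][:n_a] for t in sim.rows if t in taxa_a}
        )
        rep_b = MultipleAlignment(
            {t: sim.rows[t][n_a:] for t in sim.rows if t in taxa_b}
        )
        rep_ab = MultipleAlignment(
            {
                t: (sim.rows[t][:n_a] if t in taxa_a else GAP * n_a)
                + (sim.rows[t][n_a:] if t in taxa_b else GAP * n_b)
                for t in sim.rows
            }
        )
        lnl_ra, _ = _fit(rep_a, model, start=start_a)
        lnl_rb, _ = _fit(rep_b, model, start=start_b)
        lnl_rab, _ = _fit(rep_ab, model, start=tree_ab)
        yield max(2.0 * ((lnl_ra + lnl_rb) - lnl_rab), 0.0)


# ---------------------------------------------------------------------- #
# topological congruence (per-gene branch lengths, shared topology)
# ---------------------------------------------------------------------- #
class _TopoFitter:
    """Per-gene branch-length fits under candidate shared topologies.

    The congruence clustering tests *topological* congruence only: the
    likelihood of a gene set under a topology T is the sum over genes of
    the gene's branch-length-optimized likelihood on T (pruned to the
    gene's taxa).  Branch-length heterogeneity between genes therefore
    never contributes to the statistic.
    """

    def __init__(self, alignments: Mapping[str, MultipleAlignment], model):
        self.alignments = alignments
        self.model = model
        self._cache: dict[tuple[str, tuple], float] = {}

    @staticmethod
    def _topo_key(tree: PhyloTree) -> tuple:
        leaves = tuple(sorted(tree.leaf_names()))
        splits = tuple(sorted(tuple(sorted(s)) for s in tree.bipartitions()))
        return (leaves, splits)

    def gene_fit(self, gene: str, topology: PhyloTree) -> tuple[float, PhyloTree]:
        aln = self.alignments[gene]
        taxa = _present_taxa(aln)
        pruned = topology.prune_to([t for t in taxa if t in set(topology.leaf_names())])
        key = (gene, self._topo_key(pruned))
        if key not in self._cache:
            sub = MultipleAlignment({t: aln.rows[t] for t in taxa})
            engine = TreeLikelihood(pruned, sub, self.model)
            lnl = engine.optimize_branch_lengths()
            self._cache[key] = (lnl, engine.tree.copy())
        return self._cache[key]

    def gene_lnl(self, gene: str, topology: PhyloTree) -> float:
        return self.gene_fit(gene, topology)[0]

    def set_lnl(self, genes: frozenset[str], topology: PhyloTree) -> float:
        return sum(self.gene_lnl(g, topology) for g in sorted(genes))

    def best_fit(
        self, genes: frozenset[str], candidates: list[PhyloTree]
    ) -> tuple[float, PhyloTree]:
        taxa = {t for g in genes for t in _present_taxa(self.alignments[g])}
        best = None
        for cand in candidates:
            if not taxa <= set(cand.leaf_names()):
                continue
            pruned = cand.prune_to(sorted(taxa))
            lnl = self.set_lnl(genes, pruned)
            if best is None or lnl > best[0] + 1e-9:
                best = (lnl, pruned)
        if best is None:
            raise ValueError("no candidate topology covers the set's taxa")
        return best


def _topo_delta(
    fitter: _TopoFitter,
    a: CongruenceSet,
    b: CongruenceSet,
    concat_topology: PhyloTree,
) -> tuple[float, PhyloTree]:
    """Topological congruence statistic and the best shared topology."""
    joint = a.genes | b.genes
    lnl_ab, tree_ab = fitter.best_fit(
        joint, [concat_topology, a.tree, b.tree]
    )
    delta = max(2.0 * ((a.lnl + b.lnl) - lnl_ab), 0.0)
    return delta, tree_ab


def sequential_lrt_pair(
    set_a: CongruenceSet,
    set_b: CongruenceSet,
    alignments: Mapping[str, MultipleAlignment],
    model: SubstitutionModel,
    alpha_step: float,
    seed: int = 0,
    shared_fit: Optional[tuple[float, PhyloTree]] = None,
    max_null_cap: int = 600,
) -> tuple[float, float, bool]:
    """Congruence LRT with a sequential Monte-Carlo p-value.

    Null replicates are drawn until the first exceedance (then the merge
    is accepted: p is already guaranteed to be >= alpha_step) or until
    ``ceil(1/alpha_step)`` exceedance-free draws (then the merge is
    rejected).  Equivalent in decision to the fixed-size test but usually
    needs only a handful of replicates.  Returns (Delta, p, merge).
    """
    aln_a = _concat_sets(set_a.genes, alignments)
    aln_b = _concat_sets(set_b.genes, alignments)
    taxa_a, taxa_b = set(aln_a.rows), set(aln_b.rows)
    if len(taxa_a & taxa_b) < 4:
        raise ValueError(
            f"sets {set_a.label} and {set_b.label} share fewer than 4 taxa"
        )
    if shared_fit is None:
        aln_ab = _concat_sets(set_a.genes | set_b.genes, alignments)
        shared_fit = _fit(aln_ab, model, extra_starts=(set_a.tree, set_b.tree))
    lnl_ab, tree_ab = shared_fit
    delta = max(2.0 * ((set_a.lnl + set_b.lnl) - lnl_ab), 0.0)

    n_max = min(int(np.ceil(1.0 / alpha_step)), max_null_cap)
    rng = np.random.default_rng(seed)
    drawn = 0
    for delta_null in _null_deltas(tree_ab, taxa_a, taxa_b, aln_a.length,
                                   aln_b.length, model, rng, n_max):
        drawn += 1
        if delta_null >= delta:
            return delta, (1.0 + 1.0) / (1.0 + drawn), True
    p = 1.0 / (1.0 + drawn)
    return delta, p, p >= alpha_step


def _null_topo_delta(
    fitter: _TopoFitter,
    a: CongruenceSet,
    b: CongruenceSet,
    shared_topology: PhyloTree,
    model: SubstitutionModel,
    rng,
) -> float:
    """One parametric-bootstrap draw of the topological statistic.

    Each gene is re-simulated on its own fitted branch lengths under the
    shared topology (the congruent null), then the statistic is
    recomputed with the same machinery as for the observed data.
    """
    sim_alns: dict[str, MultipleAlignment] = {}
    for gene in sorted(a.genes | b.genes):
        _, gene_tree = fitter.gene_fit(gene, shared_topology)
        length = len(next(iter(fitter.alignments[gene].rows.values())))
        sim_alns[gene] = evolve_sequences(
            gene_tree, length, model, int(rng.integers(2**31 - 1))
        )
    rep_fitter = _TopoFitter(sim_alns, model)

    def side_fit(genes: frozenset[str]) -> tuple[float, PhyloTree]:
        concat = _concat_sets(genes, sim_alns)
        proposal = nni_search(None, concat, model).tree
        return rep_fitter.best_fit(genes, [proposal, shared_topology])

    lnl_a, tree_a = side_fit(a.genes)
    lnl_b, tree_b = side_fit(b.genes)
    joint = a.genes | b.genes
    concat = _concat_sets(joint, sim_alns)
    proposal = nni_search(None, concat, model).tree
    lnl_ab, _ = rep_fitter.best_fit(
        joint, [proposal, shared_topology, tree_a, tree_b]
    )
    return max(2.0 * ((lnl_a + lnl_b) - lnl_ab), 0.0)


def congruence_cluster(
    alignments: Mapping[str, MultipleAlignment],
    model: SubstitutionModel,
    alpha: float = 0.05,
    n_null: int = 99,
    seed: int = 0,
) -> tuple[list[CongruenceSet], list[MergeRecord]]:
    """Agglomerative congruence clustering of per-gene alignments.

    Tests topological congruence: a set's likelihood under a topology is
    the sum of per-gene branch-length-optimized likelihoods, so branch
    length heterogeneity among genes never counts as conflict.  The pair
    with the smallest Delta is tested each round with a sequential
    parametric bootstrap at a Dunn-Sidak-corrected per-step alpha (the
    number of candidate pairs); a merge requires p >= alpha_step and the
    first rejection stops the clustering.  Returns the final sets (a
    partition of the genes) and the merge trace.
    """
    genes = sorted(alignments)
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    rng = np.random.default_rng(seed)
    fitter = _TopoFitter(alignments, model)

    sets: dict[frozenset[str], CongruenceSet] = {}
    for g in genes:
        aln = _concat_sets(frozenset([g]), alignments)
        res = nni_search(None, aln, model)
        lnl, tree = fitter.gene_fit(g, res.tree)
        sets[frozenset([g])] = CongruenceSet(genes=frozenset([g]), tree=tree, lnl=lnl)

    concat_cache: dict[frozenset[str], PhyloTree] = {}

    def concat_proposal(key: frozenset[str], a: CongruenceSet, b: CongruenceSet):
        if key not in concat_cache:
            aln = _concat_sets(key, alignments)
            lnl, tree = _fit(aln, model, extra_starts=(a.tree, b.tree))
            concat_cache[key] = tree
        return concat_cache[key]

    delta_cache: dict[frozenset[str], tuple[float, PhyloTree]] = {}

    def delta_of(a: CongruenceSet, b: CongruenceSet) -> tuple[float, PhyloTree]:
        key = a.genes | b.genes
        if key not in delta_cache:
            proposal = concat_proposal(key, a, b)
            delta_cache[key] = _topo_delta(fitter, a, b, proposal)
        return delta_cache[key]

    trace: list[MergeRecord] = []
    while len(sets) > 1:
        keys = sorted(sets, key=lambda k: sorted(k))
        best_pair, best_delta = None, np.inf
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                d, _ = delta_of(sets[keys[i]], sets[keys[j]])
                label = (sorted(keys[i]), sorted(keys[j]))
                if d < best_delta - 1e-12 or (
                    abs(d - best_delta) <= 1e-12
                    and best_pair is not None
                    and label < (sorted(best_pair[0]), sorted(best_pair[1]))
                ):
                    best_pair, best_delta = (keys[i], keys[j]), d
        a, b = sets[best_pair[0]], sets[best_pair[1]]
        delta, shared_topology = delta_of(a, b)
        # Dunn-Sidak correction for the number of candidate pairs the
        # smallest-Delta selection ranged over at this step
        n_candidates = len(keys) * (len(keys) - 1) // 2
        alpha_step = 1.0 - (1.0 - alpha) ** (1.0 / n_candidates)
        if delta <= 1e-9:
            p, merged = 1.0, True  # null draws are >= 0, so p would be 1
        else:
            n_max = min(int(np.ceil(1.0 / alpha_step)), max(n_null, 600))
            drawn, exceeded = 0, False
            while drawn < n_max:
                drawn += 1
                d_null = _null_topo_delta(
                    fitter, a, b, shared_topology, model,
                    np.random.default_rng(int(rng.integers(2**31 - 1))),
                )
                if d_null >= delta:
                    exceeded = True
                    break
            if exceeded:
                p, merged = 2.0 / (1.0 + drawn), True
            else:
                p = 1.0 / (1.0 + drawn)
                merged = p >= alpha_step
        trace.append(
            MergeRecord(tuple(sorted(a.genes)), tuple(sorted(b.genes)), delta, p, merged)
        )
        if not merged:
            break  # monotone stopping rule
        joint = a.genes | b.genes
        lnl_ab = fitter.set_lnl(joint, shared_topology)
        del sets[best_pair[0]], sets[best_pair[1]]
        sets[joint] = CongruenceSet(genes=joint, tree=shared_topology, lnl=lnl_ab)
    result = sorted(sets.values(), key=lambda s: (-len(s.genes), s.label))
    log_stage("congruence", len(genes), len(result), "final sets")
    return result, trace
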