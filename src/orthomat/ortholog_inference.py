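"""Core ortholog construction from reference proteomes.

The pipeline seeds ortholog groups with reciprocal best hits (RBH)
between every pair of reference proteomes under Smith-Waterman local
alignment scores, adds within-species in-paralogs that score closer to
their own seed than the seeds score to each other, extends pairwise
groups across all reference taxa by transitive closure over shared seed
sequences, and finally validates each group with a phylogenetic filter:
the group's ML gene tree must be compatible with required well-known
clades (by default, monophyly of the land plants and of the chlorophyte
outgroups).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import AMINO_ACIDS, Proteome, SeqRecord, UNKNOWN, log_stage, split_id
from .tree import PhyloTree

_VALID = set(AMINO_ACIDS + UNKNOWN)

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0
DEFAULT_SCORE_CUTOFF = 40.0


@dataclass(frozen=True)
class HitScore:
    query_id: str
    subject_id: str
    score: float


@dataclass
class OrthologGroup:
    name: str
    members: dict[str, list[str]]          # taxon -> sequence ids
    seed: tuple[str, str]
    provenance: str = "core"               # "core" | "extended"
    confidences: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for taxon, ids in self.members.items():
            for seq_id in ids:
                if split_id(seq_id)[0] != taxon:
                    raise ValueError(
                        f"member {seq_id!r} filed under taxon {taxon!r}"
                    )

    def all_ids(self) -> list[str]:
        return [i for ids in self.members.values() for i in ids]

    def representative(self, taxon: str) -> str:
        """Highest-confidence member for ``taxon`` (ties: smallest id)."""
        ids = self.members[taxon]
        return sorted(ids, key=lambda i: (-self.confidences.get(i, 1.0), i))[0]


@dataclass
class CladeConstraint:
    """A required-monophyletic set of taxa."""

    name: str
    ingroup: frozenset[str]

    def __post_init__(self):
        self.ingroup = frozenset(self.ingroup)
        if len(self.ingroup) < 2:
            raise ValueError(f"constraint {self.name!r} needs >=2 taxa")


# ---------------------------------------------------------------------- #
# similarity engine
# ---------------------------------------------------------------------- #
class SimilarityEngine:
    """Smith-Waterman local alignment scores with a cache.

    Scores use the given substitution matrix with affine gaps (the
    opening position costs ``gap_open``, each further position
    ``gap_extend``).  ``X`` scores 0 against everything, and scores are
    floored at 0 (the empty local alignment).
    """

    def __init__(
        self,
        matrix: str = "BLOSUM62",
        gap_open: float = DEFAULT_GAP_OPEN,
        gap_extend: float = DEFAULT_GAP_EXTEND,
    ):
        mat = substitution_matrices.load(matrix).copy()
        if UNKNOWN in mat.alphabet:
            for aa in mat.alphabet:
                mat[UNKNOWN, aa] = 0.0
                mat[aa, UNKNOWN] = 0.0
        self.matrix_name = matrix
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = mat
        self._aligner.open_gap_score = -float(gap_open)
        self._aligner.extend_gap_score = -float(gap_extend)
        self._diag = {aa: float(mat[aa, aa]) for aa in AMINO_ACIDS + UNKNOWN}
        self._cache: dict[tuple[str, str], float] = {}

    def score_records(self, a: SeqRecord, b: SeqRecord) -> HitScore:
        return HitScore(a.id, b.id, self.score(a, b))

    def score(self, a: SeqRecord, b: SeqRecord) -> float:
        key = (a.id, b.id) if a.id <= b.id else (b.id, a.id)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        for rec in (a, b):
            bad = set(rec.residues) - _VALID
            if bad:
                raise ValueError(
                    f"unknown residue {sorted(bad)} in {rec.id!r} (only X is allowed)"
                )
        if a.id == b.id:
            value = sum(self._diag[ch] for ch in a.residues)
        else:
            value = max(0.0, float(self._aligner.score(a.residues, b.residues)))
        self._cache[key] = value
        return value


def pairwise_score(
    a: SeqRecord,
    b: SeqRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> HitScore:
    """One-off Smith-Waterman score between two ungapped records."""
    return SimilarityEngine(matrix, gap_open, gap_extend).score_records(a, b)


# ---------------------------------------------------------------------- #
# Inparanoid-style seeding and clustering
# ---------------------------------------------------------------------- #
def reciprocal_best_hits(
    A: Proteome,
    B: Proteome,
    engine: Optional[SimilarityEngine] = None,
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> list[tuple[str, str]]:
    """Seed pairs: mutual unique best hits scoring at least ``score_cutoff``.

    A sequence has no best hit when its top score is exactly tied between
    several partners (uniqueness is required); candidate subjects are
    scanned in lexicographic id order so the outcome is independent of
    record order.
    """
    if not A.records or not B.records:
        raise ValueError("both proteomes must be non-empty")
    engine = engine or SimilarityEngine()

    def best_map(queries: Proteome, subjects: Proteome) -> dict[str, Optional[str]]:
        best: dict[str, Optional[str]] = {}
        for q in queries:
            top_score, top_id, tied = -1.0, None, False
            for s in sorted(subjects, key=lambda r: r.id):
                sc = engine.score(q, s)
                if sc > top_score:
                    top_score, top_id, tied = sc, s.id, False
                elif sc == top_score:
                    tied = True
            best[q.id] = top_id if (top_score >= score_cutoff and not tied) else None
        return best

    a_best = best_map(A, B)
    b_best = best_map(B, A)
    seeds = [
        (a_id, b_id)
        for a_id, b_id in sorted(a_best.items())
        if b_id is not None and b_best.get(b_id) == a_id
    ]
    return seeds


def cluster_inparalogs(
    seed: tuple[str, str],
    A: Proteome,
    B: Proteome,
    engine: Optional[SimilarityEngine] = None,
    confidence_cutoff: float = 0.05,
    name: Optional[str] = None,
) -> OrthologGroup:
    """Grow a seed pair into a two-taxon group with in-paralogs.

    A same-species sequence joins when it scores at least as high against
    its seed as the two seeds score against each other; its confidence is
    the score excess normalized by the seed self-score excess, clamped to
    [0, 1].  Members below ``confidence_cutoff`` are dropped; seeds have
    confidence 1.
    """
    engine = engine or SimilarityEngine()
    seed_a, seed_b = seed
    rec_a, rec_b = A.get(seed_a), B.get(seed_b)
    seed_score = engine.score(rec_a, rec_b)

    members: dict[str, list[str]] = {A.taxon: [seed_a], B.taxon: [seed_b]}
    confidences = {seed_a: 1.0, seed_b: 1.0}
    for proteome, seed_rec in ((A, rec_a), (B, rec_b)):
        self_score = engine.score(seed_rec, seed_rec)
        for cand in proteome:
            if cand.id == seed_rec.id:
                continue
            sc = engine.score(cand, seed_rec)
            if sc < seed_score:
                continue
            denom = self_score - seed_score
            conf = 1.0 if denom <= 0 else (sc - seed_score) / denom
            conf = min(max(conf, 0.0), 1.0)
            if conf >= confidence_cutoff:
                members[proteome.taxon].append(cand.id)
                confidences[cand.id] = conf
    return OrthologGroup(
        name=name or f"{seed_a}--{seed_b}",
        members=members,
        seed=seed,
        provenance="pairwise",
        confidences=confidences,
    )


def build_core_orthologs(
    pairwise_groups: Iterable[OrthologGroup],
    reference_taxa: Sequence[str],
) -> tuple[list[OrthologGroup], int]:
    """Transitive-closure extension across taxa ("TC").

    Seed sequences form graph nodes; each pairwise group links its two
    seeds.  A connected component becomes a core group iff it covers
    every reference taxon; incomplete components are discarded and
    counted.  Returns (core groups, n_discarded).
    """
    pairwise_groups = list(pairwise_groups)
    adjacency: dict[str, set[str]] = {}
    by_seed: dict[str, list[OrthologGroup]] = {}
    for grp in pairwise_groups:
        a, b = grp.seed
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
        by_seed.setdefault(a, []).append(grp)
        by_seed.setdefault(b, []).append(grp)

    seen: set[str] = set()
    components: list[list[str]] = []
    for start in sorted(adjacency):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.append(node)
            for nxt in adjacency[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        components.append(sorted(comp))

    reference_taxa = list(reference_taxa)
    core: list[OrthologGroup] = []
    n_discarded = 0
    for comp in components:
        taxa_covered = {split_id(s)[0] for s in comp}
        if not set(reference_taxa) <= taxa_covered:
            n_discarded += 1
            continue
        members: dict[str, list[str]] = {t: [] for t in reference_taxa}
        confidences: dict[str, float] = {}
        for seed_id in comp:
            for grp in by_seed[seed_id]:
                for taxon, ids in grp.members.items():
                    for i in ids:
                        if i not in confidences:
                            members[taxon].append(i)
                        confidences[i] = max(
                            confidences.get(i, 0.0), grp.confidences.get(i, 0.0)
                        )
        for taxon in members:
            members[taxon].sort()
        seed_pair = min(
            (tuple(sorted((g.seed))) for s in comp for g in by_seed[s])
        )
        core.append(
            OrthologGroup(
                name=f"og{len(core) + 1:04d}",
                members=members,
                seed=seed_pair,
                provenance="core",
                confidences=confidences,
            )
        )
    log_stage("core-orthologs", len(components), len(core), f"{n_discarded} discarded")
    return core, n_discarded


# ---------------------------------------------------------------------- #
# phylogenetic filter
# ---------------------------------------------------------------------- #
def phylogenetic_filter(
    group: OrthologGroup,
    tree: PhyloTree,
    constraints: Sequence[CladeConstraint],
) -> tuple[bool, Optional[str]]:
    """Keep a group iff its gene tree satisfies every clade constraint.

    ``tree`` is the group's ML tree with one leaf per taxon (leaves are
    taxon names).  Constraint taxa absent from the tree are pruned from
    the constraint; monophyly is tested on the unrooted topology.
    Returns (keep, first violated constraint name or None).
    """
    leaf_taxa = set(tree.leaf_names())
    group_taxa = {t for t, ids in group.members.items() if ids}
    if not leaf_taxa <= group_taxa:
        raise ValueError(
            f"tree leaves {sorted(leaf_taxa - group_taxa)} not in group {group.name}"
        )
    for constraint in constraints:
        present = constraint.ingroup & leaf_taxa
        if len(present) < 2:
            continue
        if not tree.has_clade(present):
            return False, constraint.name
    return True, None
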