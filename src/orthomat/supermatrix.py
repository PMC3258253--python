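"""Alignment, filtering, trimming and concatenation of the gene matrix.

Covers the stretch of the pipeline between ortholog extension and tree
inference: progressive multiple alignment of each gene, the lineage
coverage filter, the per-taxon amino-acid composition chi-square test,
gap/similarity column trimming, concatenation into a partitioned
supermatrix, and the per-taxon missing-data report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2 as chi2_dist

from .io_formats import (
    AMINO_ACIDS,
    GAP,
    UNKNOWN,
    MultipleAlignment,
    SeqRecord,
    Supermatrix,
    log_stage,
)
from .ortholog_inference import OrthologGroup

_AA_TO_IDX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# taxon -> major charophyte lineage, and the lineages a gene must cover:
# one representative for every required lineage (an OR over its taxa)
DEFAULT_LINEAGE_MAP = {
    "Chlorokybus": "Chlorokybales",
    "Mesostigma": "Mesostigmatales",
    "Klebsormidium": "Klebsormidiales",
    "Nitella": "Charales",
    "Coleochaete": "Coleochaetales",
    "Chaetosphaeridium": "Coleochaetales",
    "Penium": "Zygnematales",
    "Spirogyra": "Zygnematales",
}
DEFAULT_REQUIRED_LINEAGES = (
    "Chlorokybales",
    "Klebsormidiales",
    "Charales",
    "Coleochaetales",
    "Zygnematales",
)


# ---------------------------------------------------------------------- #
# progressive alignment
# ---------------------------------------------------------------------- #
def _similarity_distance(records: Sequence[SeqRecord]) -> np.ndarray:
    """1 - normalized global alignment score, for the guide tree."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    mat = substitution_matrices.load("BLOSUM62")
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    n = len(records)
    self_scores = [
        sum(float(mat[ch, ch]) if ch in AMINO_ACIDS else 0.0 for ch in r.residues)
        for r in records
    ]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = float(
                aligner.score(
                    records[i].residues.replace(UNKNOWN, "A"),
                    records[j].residues.replace(UNKNOWN, "A"),
                )
            )
            norm = min(self_scores[i], self_scores[j])
            d = 1.0 - max(s, 0.0) / norm if norm > 0 else 1.0
            dist[i, j] = dist[j, i] = max(d, 0.0)
    return dist


_B62 = substitution_matrices.load("BLOSUM62")
_B62_AA = np.array([[float(_B62[a, b]) for b in AMINO_ACIDS] for a in AMINO_ACIDS])
_GAP_PENALTY = 4.0  # linear, per profile column


def _profile_matrix(rows: Mapping[str, str]) -> tuple[np.ndarray, np.ndarray]:
    """Residue frequency profile (L, 20) and per-column occupancy (L,)."""
    length = len(next(iter(rows.values())))
    freq = np.zeros((length, 20))
    occ = np.zeros(length)
    for seq in rows.values():
        for j, ch in enumerate(seq):
            if ch in _AA_TO_IDX:
                freq[j, _AA_TO_IDX[ch]] += 1
                occ[j] += 1
    nz = occ > 0
    freq[nz] /= occ[nz, None]
    occ /= len(rows)
    return freq, occ


def _merge_alignments(
    left: Mapping[str, str], right: Mapping[str, str]
) -> dict[str, str]:
    """Profile-profile global alignment (Needleman-Wunsch, linear gaps)."""
    f1, o1 = _profile_matrix(left)
    f2, o2 = _profile_matrix(right)
    L1, L2 = f1.shape[0], f2.shape[0]
    S = (f1 @ _B62_AA @ f2.T) * np.outer(o1, o2)
    g = _GAP_PENALTY
    M = np.empty((L1 + 1, L2 + 1))
    M[0, :] = -g * np.arange(L2 + 1)
    M[:, 0] = -g * np.arange(L1 + 1)
    idx = np.arange(L2 + 1)
    for i in range(1, L1 + 1):
        cand = np.empty(L2 + 1)
        cand[0] = M[i - 1, 0] - g
        np.maximum(M[i - 1, :-1] + S[i - 1], M[i - 1, 1:] - g, out=cand[1:])
        M[i] = np.maximum.accumulate(cand + g * idx) - g * idx
    # traceback (prefer diagonal, then up, then left — deterministic)
    path = []
    i, j = L1, L2
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(M[i, j], M[i - 1, j - 1] + S[i - 1, j - 1]):
            path.append(("D", i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(M[i, j], M[i - 1, j] - g):
            path.append(("U", i - 1, None))
            i -= 1
        else:
            path.append(("L", None, j - 1))
            j -= 1
    path.reverse()
    merged: dict[str, list[str]] = {name: [] for name in (*left, *right)}
    for move, pi, pj in path:
        for name, seq in left.items():
            merged[name].append(seq[pi] if move in ("D", "U") else GAP)
        for name, seq in right.items():
            merged[name].append(seq[pj] if move in ("D", "L") else GAP)
    return {name: "".join(chars) for name, chars in merged.items()}


def progressive_align(records: Sequence[SeqRecord]) -> MultipleAlignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    Pairwise normalized-similarity distances give the guide tree
    (average linkage); sub-alignments are merged by profile-profile
    Needleman-Wunsch.  Deterministic for a fixed input order.
    """
    if not records:
        raise ValueError("no sequences to align")
    for rec in records:
        if GAP in rec.residues:
            raise ValueError(f"input sequence {rec.id!r} already contains gaps")
    if len(records) == 1:
        log_stage("align", 1, 1, "single sequence returned unchanged")
        return MultipleAlignment({records[0].id: records[0].residues})
    if len(records) == 2:
        merged = _merge_alignments(
            {records[0].id: records[0].residues}, {records[1].id: records[1].residues}
        )
        return MultipleAlignment(merged)
    dist = _similarity_distance(records)
    tree = linkage(squareform(dist, checks=False), method="average")
    clusters: dict[int, dict[str, str]] = {
        i: {rec.id: rec.residues} for i, rec in enumerate(records)
    }
    nxt = len(records)
    for a, b, _, _ in tree:
        clusters[nxt] = _merge_alignments(clusters.pop(int(a)), clusters.pop(int(b)))
        nxt += 1
    return MultipleAlignment(clusters[nxt - 1])


# ---------------------------------------------------------------------- #
# coverage filter
# ---------------------------------------------------------------------- #
def coverage_filter(
    groups: Sequence[OrthologGroup],
    lineage_map: Mapping[str, str] = DEFAULT_LINEAGE_MAP,
    required_lineages: Sequence[str] = DEFAULT_REQUIRED_LINEAGES,
    reference_taxa: Sequence[str] = (),
) -> list[OrthologGroup]:
    """Keep groups with at least one member in every required lineage.

    ``lineage_map`` assigns each transcriptome taxon to its major
    lineage; taxa listed in ``reference_taxa`` are exempt from the rule.
    An unknown member taxon raises.
    """
    known = set(lineage_map) | set(reference_taxa)
    kept = []
    for group in groups:
        present_lineages = set()
        for taxon, ids in group.members.items():
            if not ids:
                continue
            if taxon not in known:
                raise ValueError(f"unknown taxon {taxon!r} in group {group.name}")
            if taxon in lineage_map:
                present_lineages.add(lineage_map[taxon])
        if all(lin in present_lineages for lin in required_lineages):
            kept.append(group)
    log_stage("coverage-filter", len(groups), len(kept))
    return kept


# ---------------------------------------------------------------------- #
# composition bias test
# ---------------------------------------------------------------------- #
@dataclass
class CompositionTestResult:
    chi2: dict[str, float]
    p: dict[str, float]
    flagged_rows: set[str]
    alpha: float

    @property
    def flagged(self) -> bool:
        """Gene-level flag: any row deviates at ``alpha``."""
        return bool(self.flagged_rows)


def composition_test(aln: MultipleAlignment, alpha: float = 0.05) -> CompositionTestResult:
    """Chi-square test of each row's residue composition against the pool.

    Expected frequencies are pooled over all rows (gaps and X excluded);
    each row's statistic is
    ``sum_a (n_a - n pi_a)^2 / (n pi_a)`` over residues with pi_a > 0,
    with df = (number of pooled residues) - 1.  Rows with no counted
    residues are excluded with a warning.
    """
    counts = {}
    for name, seq in aln.rows.items():
        c = np.zeros(20)
        for ch in seq:
            if ch in _AA_TO_IDX:
                c[_AA_TO_IDX[ch]] += 1
        counts[name] = c
    pooled = np.sum(list(counts.values()), axis=0)
    if pooled.sum() == 0:
        raise ValueError("alignment has no countable residues")
    pi = pooled / pooled.sum()
    support = pi > 0
    df = int(support.sum()) - 1
    chi2_by_row: dict[str, float] = {}
    p_by_row: dict[str, float] = {}
    flagged: set[str] = set()
    for name, c in counts.items():
        n = c.sum()
        if n == 0:
            log_stage("composition-test", 1, 0, f"row {name} has no residues")
            continue
        expected = n * pi[support]
        stat = float(((c[support] - expected) ** 2 / expected).sum())
        p = float(chi2_dist.sf(stat, df))
        chi2_by_row[name] = stat
        p_by_row[name] = p
        if p < alpha:
            flagged.add(name)
    return CompositionTestResult(chi2=chi2_by_row, p=p_by_row, flagged_rows=flagged, alpha=alpha)


# ---------------------------------------------------------------------- #
# trimming
# ---------------------------------------------------------------------- #
@dataclass
class TrimParams:
    """Column-trimming thresholds: gap threshold ``gt``, similarity
    threshold ``st``, window half-width ``w`` (columns)."""

    gt: float = 0.4
    st: float = 0.01
    w: int = 3

    def __post_init__(self):
        if not (0 <= self.gt <= 1 and 0 <= self.st <= 1 and self.w >= 0):
            raise ValueError("invalid trimming parameters")


_B62_DIAG = np.array([float(_B62[a, a]) for a in AMINO_ACIDS])
# pair similarity in [0, 1]: positive scores normalized by the geometric
# mean of the diagonal entries
_PAIR_SIM = np.maximum(_B62_AA, 0.0) / np.sqrt(np.outer(_B62_DIAG, _B62_DIAG))


def _window_average(values: np.ndarray, w: int) -> np.ndarray:
    if w == 0:
        return values
    n = values.size
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    for i in range(n):
        lo, hi = max(0, i - w), min(n, i + w + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def trim_columns(
    aln: MultipleAlignment, params: TrimParams, gene: str = "?"
) -> tuple[MultipleAlignment, list[int]]:
    """Remove poorly aligned columns.

    Per column, the non-gap fraction (X counts as a gap) and the mean
    pairwise residue similarity (normalized substitution-matrix score)
    are window-averaged over ``[i-w, i+w]``; a column is kept iff both
    windowed values meet their thresholds.  Returns the trimmed alignment
    and the kept-column mask (strictly increasing 0-based indices).
    """
    n_rows = len(aln)
    codes = np.full((n_rows, aln.length), -1, dtype=np.int64)
    for r, seq in enumerate(aln.rows.values()):
        for j, ch in enumerate(seq):
            if ch in _AA_TO_IDX:
                codes[r, j] = _AA_TO_IDX[ch]
    nongap_fraction = (codes >= 0).mean(axis=0)
    similarity = np.zeros(aln.length)
    for j in range(aln.length):
        present = codes[codes[:, j] >= 0, j]
        if present.size < 2:
            similarity[j] = 0.0
            continue
        sims = _PAIR_SIM[np.ix_(present, present)]
        iu = np.triu_indices(present.size, k=1)
        similarity[j] = float(sims[iu].mean())
    keep = (_window_average(nongap_fraction, params.w) >= params.gt) & (
        _window_average(similarity, params.w) >= params.st
    )
    mask = [int(i) for i in np.nonzero(keep)[0]]
    if not mask:
        raise ValueError(f"trimming removed every column of gene {gene}")
    return aln.subset_columns(mask), mask


# ---------------------------------------------------------------------- #
# concatenation and missing-data report
# ---------------------------------------------------------------------- #
def concatenate(
    alignments: Mapping[str, MultipleAlignment] | Iterable[tuple[str, MultipleAlignment]],
    taxa: Sequence[str],
) -> Supermatrix:
    """Concatenate per-gene alignments (rows keyed by taxon) into a
    supermatrix, gap-filling absent taxa; genes in lexicographic order."""
    if isinstance(alignments, Mapping):
        items = list(alignments.items())
    else:
        items = list(alignments)
    names = [g for g, _ in items]
    if len(set(names)) != len(names):
        dupes = sorted({g for g in names if names.count(g) > 1})
        raise ValueError(f"duplicate gene names: {dupes}")
    items.sort(key=lambda kv: kv[0])
    taxa = list(taxa)
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    cursor = 1
    for gene, aln in items:
        unknown_rows = set(aln.rows) - set(taxa)
        if unknown_rows:
            raise ValueError(f"gene {gene}: rows {sorted(unknown_rows)} not in taxa")
        for t in taxa:
            chunks[t].append(aln.rows.get(t, GAP * aln.length))
        partitions.append((gene, cursor, cursor + aln.length - 1))
        cursor += aln.length
    rows = {t: "".join(parts) for t, parts in chunks.items()}
    return Supermatrix(MultipleAlignment(rows), partitions)


def split_supermatrix(matrix: Supermatrix) -> dict[str, MultipleAlignment]:
    """Inverse of :func:`concatenate`: per-gene alignments, all-taxa rows."""
    out = {}
    for gene, start, end in matrix.partitions:
        out[gene] = MultipleAlignment(
            {t: seq[start - 1 : end] for t, seq in matrix.alignment.rows.items()}
        )
    return out


@dataclass
class CoverageReport:
    genes_present: dict[str, int]
    percent: dict[str, float]
    total_genes: int
    mean_focal_per_gene: float
    missing_fraction: float

    def as_table(self) -> list[tuple[str, int, float]]:
        return [
            (taxon, self.genes_present[taxon], self.percent[taxon])
            for taxon in self.genes_present
        ]


def coverage_report(matrix: Supermatrix, focal_taxa: Sequence[str]) -> CoverageReport:
    """Per-taxon gene presence and the global missing-data fraction.

    A gene counts as present for a taxon when its partition holds at
    least one residue (gaps and X are missing).
    """
    total = len(matrix.partitions)
    present: dict[str, set[str]] = {t: set() for t in matrix.alignment.rows}
    for gene, start, end in matrix.partitions:
        for taxon, seq in matrix.alignment.rows.items():
            chunk = seq[start - 1 : end]
            if any(ch not in (GAP, UNKNOWN) for ch in chunk):
                present[taxon].add(gene)
    genes_present = {t: len(s) for t, s in present.items()}
    percent = {t: 100.0 * n / total for t, n in genes_present.items()}
    focal = [t for t in focal_taxa if t in present]
    per_gene_focal = [
        sum(1 for t in focal if gene in present[t]) for gene, _, _ in matrix.partitions
    ]
    mean_focal = float(np.mean(per_gene_focal)) if per_gene_focal else 0.0
    all_chars = "".join(matrix.alignment.rows.values())
    missing = sum(1 for ch in all_chars if ch in (GAP, UNKNOWN))
    return CoverageReport(
        genes_present=genes_present,
        percent=percent,
        total_genes=total,
        mean_focal_per_gene=mean_focal,
        missing_fraction=missing / len(all_chars),
    )
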