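"""Top-hit profile search of transcriptome unigene sets.

Each core ortholog group is summarized as a position-specific log-odds
profile built from its alignment.  Every unigene is scored by its best
ungapped local match to the profile (maximal-scoring diagonal run,
partial profile coverage allowed), and only the single top-scoring
unigene per taxon is extracted — one putative ortholog per transcriptome,
suitable for direct inclusion in a phylogenetic analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import AMINO_ACIDS, GAP, MultipleAlignment, Proteome

logger = logging.getLogger("orthomat")

SCORE_FLOOR = -10.0  # bits; cap for log-odds of unobserved residues
DEFAULT_MIN_SCORE = 30.0  # bits; comfortably above the best random match
# in a transcriptome-sized search space, far below any true ortholog hit
_AA_TO_IDX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class ColumnProfile:
    """Per-column log2-odds scores over the 20 residues.

    ``scores`` has shape (length, 20); ``columns`` maps profile columns
    back to source-alignment columns (those with <= 50% gaps).
    """

    scores: np.ndarray
    background: np.ndarray
    columns: list[int]

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def build_profile(core_alignment: MultipleAlignment, pseudocount: float = 1.0) -> ColumnProfile:
    """Log-odds profile from a core alignment.

    Background frequencies are the alignment-wide residue frequencies
    with one Laplace pseudocount per residue.  Column scores are
    ``log2(((count_a + pc * bg_a) / (n_eff + pc)) / bg_a)`` where n_eff
    counts the column's non-gap, non-X residues; columns with more than
    50% gaps are excluded.
    """
    counts_by_col = []
    global_counts = np.zeros(20)
    n_rows = len(core_alignment)
    kept_columns = []
    for j in range(core_alignment.length):
        col = core_alignment.column(j)
        counts = np.zeros(20)
        for ch in col:
            if ch in _AA_TO_IDX:
                counts[_AA_TO_IDX[ch]] += 1
        global_counts += counts
        gap_fraction = col.count(GAP) / n_rows
        if gap_fraction <= 0.5:
            kept_columns.append(j)
            counts_by_col.append(counts)
    if not kept_columns:
        raise ValueError("alignment has no usable (<=50% gap) columns")
    background = (global_counts + 1.0) / (global_counts.sum() + 20.0)
    scores = np.empty((len(kept_columns), 20))
    for i, counts in enumerate(counts_by_col):
        n_eff = counts.sum()
        with np.errstate(divide="ignore"):
            odds = (counts + pseudocount * background) / (n_eff + pseudocount) / background
            scores[i] = np.log2(odds)
    np.maximum(scores, SCORE_FLOOR, out=scores)
    return ColumnProfile(scores=scores, background=background, columns=kept_columns)


def score_sequences(profile: ColumnProfile, sequences: list[str]) -> np.ndarray:
    """Best ungapped local profile match per sequence.

    A Kadane scan along every profile/sequence diagonal, vectorized over
    all sequences at once (shorter sequences are padded with a sentinel
    that cannot extend a match).  ``X`` contributes 0; the empty match
    scores 0.
    """
    if not sequences:
        return np.zeros(0)
    coded = [
        [_AA_TO_IDX.get(ch, 20) for ch in seq if ch != GAP] for seq in sequences
    ]
    width = max((len(c) for c in coded), default=0)
    if width == 0:
        return np.zeros(len(sequences))
    PAD = 21
    codes = np.full((len(coded), width), PAD, dtype=np.int64)
    for r, c in enumerate(coded):
        codes[r, : len(c)] = c
    # column 20 = X (neutral), column 21 = padding (impossible)
    col_scores = np.hstack(
        [
            profile.scores,
            np.zeros((profile.length, 1)),
            np.full((profile.length, 1), -1e9),
        ]
    )
    best = np.zeros(len(coded))
    running = np.zeros_like(codes, dtype=float)
    shifted = np.empty_like(running)
    for i in range(profile.length):
        row = col_scores[i][codes]
        shifted[:, 0] = 0.0
        np.maximum(running[:, :-1], 0.0, out=shifted[:, 1:])
        running = row + shifted
        np.maximum(best, running.max(axis=1), out=best)
    return best


def score_sequence(profile: ColumnProfile, residues: str) -> float:
    """Best ungapped local profile match of one sequence."""
    return float(score_sequences(profile, [residues])[0])


def search_top_hit(
    profile: ColumnProfile,
    unigenes: Proteome,
    min_score: float = DEFAULT_MIN_SCORE,
) -> Optional[str]:
    """Single best unigene id, or None below ``min_score`` / on empty input.

    Ties resolve to the lexicographically smallest id, so at most one
    putative ortholog is ever returned per taxon.
    """
    if not unigenes.records:
        logger.info("[hamstr] empty unigene set for %s", unigenes.taxon)
        return None
    records = sorted(unigenes, key=lambda r: r.id)
    scores = score_sequences(profile, [r.residues for r in records])
    best = int(np.argmax(scores))  # argmax takes the first (smallest id) on ties
    if scores[best] >= min_score:
        return records[best].id
    return None
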