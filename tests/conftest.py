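"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.linalg import expm

from orthomat.io_formats import AMINO_ACIDS, MultipleAlignment
from orthomat.tree import PhyloTree


def brute_force_loglik(tree: PhyloTree, aln: MultipleAlignment, model) -> float:
    """Exhaustive likelihood oracle: matrix exponentials (scipy expm) and
    naive recursion over all internal-state assignments via dense vectors.

    Independent of the pruning engine: no shared code paths beyond the
    rate matrix definition.
    """
    taxa = sorted(aln.rows)
    pi = model.frequencies
    rates = model.category_rates()
    Q = model.rate_matrix()
    tr = tree.copy().unroot()

    def partial(node, rate, col):
        if node.is_leaf:
            v = np.zeros(20)
            ch = col[taxa.index(node.name)]
            if ch in ("-", "X"):
                return np.ones(20)
            v[AMINO_ACIDS.index(ch)] = 1.0
            return v
        out = np.ones(20)
        for child in node.children:
            P = expm(Q * child.length * rate)
            out = out * (P @ partial(child, rate, col))
        return out

    lnl = 0.0
    for i in range(aln.length):
        col = [aln.rows[t][i] for t in taxa]
        site = np.mean([pi @ partial(tr.root, r, col) for r in rates])
        lnl += math.log(site)
    return lnl


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_alignment():
    return MultipleAlignment(
        {"A": "MKV-W", "B": "MRVLW", "C": "LKXLW", "D": "MKVLF"}
    )


@pytest.fixture
def quartet_newick():
    return "((A:0.1,B:0.2):0.15,C:0.3,D:0.05);"
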