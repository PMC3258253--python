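"""Felsenstein-pruning likelihood core with branch and topology optimization.

The engine compresses alignment columns into site patterns, computes
conditional likelihoods bottom-up (with per-node scaling against
underflow), and exposes:

* ``loglik`` — the log-likelihood of a fixed tree;
* ``optimize_branch_lengths`` — coordinate ascent, one Brent line search
  per edge using up/down partial caches so each evaluation is O(patterns);
* ``nni_search`` — nearest-neighbour-interchange hill climbing, scoring
  both rearrangements of every internal edge with re-optimization of the
  central branch only, then fully re-optimizing after each accepted move.

Gaps and ``X`` are missing data: their conditional likelihood is 1 for
every state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from ..io_formats import GAP, UNKNOWN, MultipleAlignment
from ..tree import Node, PhyloTree
from .models import AA_INDEX, N_STATES, SubstitutionModel

MIN_BRANCH = 1e-8
MAX_BRANCH = 20.0
MISSING_CODE = N_STATES


def encode_alignment(aln: MultipleAlignment, taxa: list[str]) -> np.ndarray:
    """Integer codes (len(taxa), n_sites); gap/X become MISSING_CODE."""
    table = np.full(128, -1, dtype=np.int8)
    for aa, i in AA_INDEX.items():
        table[ord(aa)] = i
    table[ord(GAP)] = MISSING_CODE
    table[ord(UNKNOWN)] = MISSING_CODE
    rows = []
    for taxon in taxa:
        if taxon not in aln.rows:
            raise ValueError(f"taxon {taxon!r} missing from alignment")
        codes = table[np.frombuffer(aln.rows[taxon].encode(), dtype=np.uint8)]
        rows.append(codes)
    return np.asarray(rows, dtype=np.int64)


@dataclass
class LikelihoodResult:
    lnl: float
    per_site: np.ndarray
    tree: PhyloTree


class TreeLikelihood:
    """Likelihood machine bound to one alignment/model and a mutable tree."""

    def __init__(
        self,
        tree: PhyloTree,
        aln: MultipleAlignment,
        model: SubstitutionModel,
        weights: np.ndarray | None = None,
    ):
        self.tree = tree.copy().unroot()
        self.model = model
        self.taxa = sorted(self.tree.leaf_names())
        codes = encode_alignment(aln, self.taxa)
        patterns, self._site_to_pattern, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self._patterns = patterns  # (n_taxa, n_patterns)
        self.n_sites = codes.shape[1]
        self.weights = counts.astype(float) if weights is None else np.asarray(weights, float)
        self._taxon_row = {t: i for i, t in enumerate(self.taxa)}
        ncat = len(model.category_rates())
        self._ncat = ncat
        self._npat = patterns.shape[1]
        # leaf partials (shared across categories): (n_patterns, 20)
        self._leaf_partial: dict[str, np.ndarray] = {}
        for taxon, row in self._taxon_row.items():
            part = np.zeros((self._npat, N_STATES))
            codes_t = patterns[row]
            obs = codes_t < N_STATES
            part[np.arange(self._npat)[obs], codes_t[obs]] = 1.0
            part[~obs, :] = 1.0
            self._leaf_partial[taxon] = part
        # caches keyed by node object id
        self._D: dict[int, np.ndarray] = {}   # (cat, pat, 20) below-node partial
        self._M: dict[int, np.ndarray] = {}   # message through the parent edge
        self._ls: dict[int, np.ndarray] = {}  # cumulative log-scalers, (pat,)

    # ------------------------------------------------------------------ #
    # down pass
    # ------------------------------------------------------------------ #
    def _compute_down(self) -> None:
        self._D.clear()
        self._M.clear()
        self._ls.clear()
        n_internal = 0
        for node in self.tree.postorder():
            if node.is_leaf:
                D = np.broadcast_to(
                    self._leaf_partial[node.name], (self._ncat, self._npat, N_STATES)
                )
                ls = np.zeros(self._npat)
            else:
                D = self._M[id(node.children[0])].copy()
                ls = self._ls[id(node.children[0])].copy()
                for child in node.children[1:]:
                    D *= self._M[id(child)]
                    ls += self._ls[id(child)]
                n_internal += 1
                # rescale periodically; partials shrink by a bounded factor
                # per level, so every third internal node is ample at desk
                # scale while halving the reduction cost
                if n_internal % 3 == 0 or node is self.tree.root:
                    scale = D.max(axis=(0, 2))
                    nz = scale > 0
                    D[:, nz, :] /= scale[None, nz, None]
                    ls[nz] += np.log(scale[nz])
            self._D[id(node)] = D
            self._ls[id(node)] = ls
            if node is not self.tree.root:
                P = self.model.transition_matrices(node.length)
                self._M[id(node)] = np.matmul(D, P.transpose(0, 2, 1))

    def _root_site_loglik(self) -> np.ndarray:
        D = self._D[id(self.tree.root)]
        site_l = (D @ self.model.frequencies).mean(axis=0)
        return np.log(np.maximum(site_l, 1e-300)) + self._ls[id(self.tree.root)]

    def loglik(self) -> float:
        self._compute_down()
        return float(self.weights @ self._root_site_loglik())

    def per_site_loglik(self) -> np.ndarray:
        self._compute_down()
        return self._root_site_loglik()[self._site_to_pattern]

    # ------------------------------------------------------------------ #
    # edge machinery
    # ------------------------------------------------------------------ #
    def _edge_loglik_fn(self, U, ls_const, D):
        """lnL as a function of the focal branch length.

        Works in the model's eigenbasis: with P(t) = R exp(L t) V the site
        likelihood U . P(t) D reduces to ((U R) * (D V^T)) . exp(lam t r),
        so each Brent evaluation is a single small contraction.
        """
        eigval, right, left = self.model._eigensystem()
        rates = self.model.category_rates()
        W = np.matmul(U, right) * np.matmul(D, left.T)  # (cat, pat, 20)
        W_flat = np.ascontiguousarray(W.transpose(1, 0, 2).reshape(self._npat, -1))

        def fn(t: float) -> float:
            e = np.exp(eigval[None, :] * (t * rates)[:, None])  # (cat, 20)
            site_l = W_flat @ e.ravel()
            site_l /= self._ncat
            return float(self.weights @ (np.log(np.maximum(site_l, 1e-300)) + ls_const))

        return fn

    def _optimize_edge(self, fn, t0: float) -> tuple[float, float]:
        res = minimize_scalar(
            lambda t: -fn(t),
            bounds=(MIN_BRANCH, MAX_BRANCH),
            method="bounded",
            options={"xatol": 1e-6, "maxiter": 60},
        )
        t_new, lnl_new = float(res.x), float(-res.fun)
        lnl0 = fn(t0)
        if lnl_new < lnl0:  # guard: bounded Brent can stall on flat surfaces
            return t0, lnl0
        return t_new, lnl_new

    def optimize_branch_lengths(
        self, max_sweeps: int = 20, tol: float = 1e-6
    ) -> float:
        """Coordinate-ascent branch optimization; returns the final lnL.

        Each sweep refreshes the down partials, then walks the tree in
        preorder maintaining up partials, Brent-optimizing each branch in
        turn.  Stops when a sweep improves lnL by less than ``tol``
        (relative) or lnL would decrease (stale-cache numerics).
        """
        pi = self.model.frequencies
        current = self.loglik()
        for _ in range(max_sweeps):
            previous_lengths = {id(n): n.length for n in self.tree.edges()}
            self._compute_down()
            U_cache: dict[int, np.ndarray] = {}
            ls_up: dict[int, np.ndarray] = {}
            for node in self.tree.preorder():
                if node is self.tree.root:
                    continue
                parent = node.parent
                if parent is self.tree.root:
                    U = np.broadcast_to(
                        pi, (self._ncat, self._npat, N_STATES)
                    ).copy()
                    ls = np.zeros(self._npat)
                else:
                    P = self.model.transition_matrices(parent.length)
                    U = np.matmul(U_cache[id(parent)], P)
                    ls = ls_up[id(parent)].copy()
                for sib in parent.children:
                    if sib is node:
                        continue
                    U = U * self._M[id(sib)]
                    ls = ls + self._ls[id(sib)]
                scale = U.max(axis=(0, 2))
                nz = scale > 0
                U[:, nz, :] /= scale[None, nz, None]
                ls[nz] += np.log(scale[nz])
                U_cache[id(node)] = U
                ls_up[id(node)] = ls
                fn = self._edge_loglik_fn(U, ls + self._ls[id(node)], self._D[id(node)])
                t_new, _ = self._optimize_edge(fn, node.length)
                node.length = t_new
                P = self.model.transition_matrices(t_new)
                self._M[id(node)] = np.matmul(
                    self._D[id(node)], P.transpose(0, 2, 1)
                )
            new = self.loglik()
            if new < current:  # never let a sweep lower the likelihood
                for n in self.tree.edges():
                    n.length = previous_lengths[id(n)]
                self._compute_down()
                break
            if new - current <= tol * max(1.0, abs(current)):
                current = new
                break
            current = new
        return current

    # ------------------------------------------------------------------ #
    # NNI search
    # ------------------------------------------------------------------ #
    def _nni_candidates(self):
        """Internal edges eligible for NNI: internal non-root child nodes."""
        return [
            n
            for n in self.tree.postorder()
            if n is not self.tree.root and not n.is_leaf
        ]

    def _score_nnis(self):
        """Score both rearrangements of every internal edge.

        Returns (current_lnl, moves) where each move is
        (delta, edge_node, child_index, sibling_node, new_length).
        """
        pi = self.model.frequencies
        self._compute_down()
        current = float(self.weights @ self._root_site_loglik())
        # up partials for every node (message from the parent side,
        # including the equilibrium prior folded in at the root)
        U_cache: dict[int, np.ndarray] = {}
        ls_up: dict[int, np.ndarray] = {}
        for node in self.tree.preorder():
            if node is self.tree.root:
                continue
            parent = node.parent
            if parent is self.tree.root:
                U = np.broadcast_to(pi, (self._ncat, self._npat, N_STATES)).copy()
                ls = np.zeros(self._npat)
            else:
                P = self.model.transition_matrices(parent.length)
                U = np.matmul(U_cache[id(parent)], P)
                ls = ls_up[id(parent)].copy()
            for sib in parent.children:
                if sib is not node:
                    U = U * self._M[id(sib)]
                    ls = ls + self._ls[id(sib)]
            scale = U.max(axis=(0, 2))
            nz = scale > 0
            U[:, nz, :] /= scale[None, nz, None]
            ls[nz] += np.log(scale[nz])
            U_cache[id(node)] = U
            ls_up[id(node)] = ls

        moves = []
        for v in self._nni_candidates():
            if len(v.children) != 2:
                continue
            p = v.parent
            siblings = [s for s in p.children if s is not v]
            if p is self.tree.root:
                if len(siblings) != 2:
                    continue
                above = np.broadcast_to(
                    pi, (self._ncat, self._npat, N_STATES)
                )
                ls_above = np.zeros(self._npat)
                swap_units = siblings  # either root sibling can cross the edge
            else:
                P = self.model.transition_matrices(p.length)
                above = np.matmul(U_cache[id(p)], P)
                ls_above = ls_up[id(p)]
                swap_units = siblings  # single sibling
            c1, c2 = v.children
            for sib in swap_units:
                other_units = [s for s in siblings if s is not sib]
                U_base = above
                ls_base = ls_above
                for o in other_units:
                    U_base = U_base * self._M[id(o)]
                    ls_base = ls_base + self._ls[id(o)]
                for ci, (inner, outer) in enumerate(((c1, c2), (c2, c1))):
                    # move `inner` to the parent side, `sib` under v
                    U_alt = U_base * self._M[id(inner)]
                    D_alt = self._M[id(sib)] * self._M[id(outer)]
                    ls_alt = (
                        ls_base
                        + self._ls[id(inner)]
                        + self._ls[id(sib)]
                        + self._ls[id(outer)]
                    )
                    fn = self._edge_loglik_fn(U_alt, ls_alt, D_alt)
                    t_new, lnl_new = self._optimize_edge(fn, v.length)
                    moves.append((lnl_new - current, v, ci, sib, t_new))
        return current, moves

    def _apply_nni(self, v: Node, child_index: int, sib: Node, new_length: float):
        p = v.parent
        child = v.children[child_index]
        v.children[child_index] = sib
        p.children[p.children.index(sib)] = child
        sib.parent, child.parent = v, p
        v.length = max(new_length, MIN_BRANCH)

    def nni_search(
        self, tol: float = 1e-4, max_rounds: int = 100, bl_sweeps: int = 20
    ) -> float:
        """Hill-climb over NNI moves; returns the final lnL.

        ``bl_sweeps`` caps branch-length sweeps between moves (bootstrap
        replicates use a small cap, rapid-bootstrap style).
        """
        current = self.optimize_branch_lengths(max_sweeps=bl_sweeps)
        if len(self.taxa) < 4:
            return current
        for _ in range(max_rounds):
            _, moves = self._score_nnis()
            if not moves:
                break
            best = max(moves, key=lambda m: m[0])
            if best[0] <= tol:
                break
            self._apply_nni(best[1], best[2], best[3], best[4])
            current = self.optimize_branch_lengths(max_sweeps=bl_sweeps)
        return current

    # ------------------------------------------------------------------ #
    def result(self) -> LikelihoodResult:
        lnl = self.loglik()
        per_site = self._root_site_loglik()[self._site_to_pattern]
        return LikelihoodResult(lnl=lnl, per_site=per_site, tree=self.tree.copy())
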