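"""Amino-acid substitution models (Poisson, WAG, LG) with +G and +F options.

A model is a reversible 20-state GTR-style process: symmetric
exchangeabilities S and equilibrium frequencies pi give the generator
Q_ij = S_ij * pi_j (i != j), with rows summing to zero and the mean rate
-sum_i pi_i Q_ii normalized to 1 so branch lengths are in expected
substitutions per site.  Rate heterogeneity uses Yang's discrete gamma
with equal-probability categories whose rates are the category means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ..io_formats import AMINO_ACIDS

N_STATES = 20
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _load_table(name: str) -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("orthomat.data").joinpath(f"{name}.txt").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    exch = np.zeros((N_STATES, N_STATES))
    for i, line in enumerate(lines[:-1], start=1):
        vals = [float(x) for x in line.split()]
        exch[i, : len(vals)] = vals
    exch = exch + exch.T
    freqs = np.array([float(x) for x in lines[-1].split()])
    return exch, freqs / freqs.sum()


@dataclass
class SubstitutionModel:
    """Reversible amino-acid model, optionally with discrete-gamma rates."""

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    gamma_alpha: Optional[float] = None
    n_categories: int = 4
    _eigen: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.exchangeabilities.shape != (N_STATES, N_STATES):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma shape must be positive")
        self._eigen = None

    # ------------------------------------------------------------------ #
    def rate_matrix(self) -> np.ndarray:
        """Generator Q with zero row sums and unit mean rate."""
        pi = self.frequencies
        Q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        return Q / mu

    def _eigensystem(self):
        if self._eigen is None:
            pi = self.frequencies
            Q = self.rate_matrix()
            sqrt_pi = np.sqrt(pi)
            # similarity transform to a symmetric matrix for a stable eigh
            B = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
            B = (B + B.T) / 2.0
            eigval, eigvec = np.linalg.eigh(B)
            right = eigvec / sqrt_pi[:, None]      # rows scaled: U = D^-1 V
            left = eigvec.T * sqrt_pi[None, :]     # V^T D
            self._eigen = (eigval, right, left)
        return self._eigen

    def category_rates(self) -> np.ndarray:
        """Discrete-gamma category rates (mean of each equal-probability bin).

        Without +G this is the single rate 1.0.
        """
        if self.gamma_alpha is None:
            return np.array([1.0])
        a = self.gamma_alpha
        k = self.n_categories
        cuts = gamma_dist.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
        bounds = np.concatenate([[0.0], cuts, [np.inf]])
        upper = gammainc(a + 1.0, np.where(np.isinf(bounds[1:]), 1e12, bounds[1:]) * a)
        lower = gammainc(a + 1.0, bounds[:-1] * a)
        rates = k * (upper - lower)
        return rates / rates.mean()

    def transition_matrices(self, t: float) -> np.ndarray:
        """P(t * r_c) for each rate category; shape (n_cat, 20, 20)."""
        if t < 0:
            raise ValueError("negative branch length")
        eigval, right, left = self._eigensystem()
        rates = self.category_rates()
        expo = np.exp(eigval[None, :] * (t * rates)[:, None])  # (cat, 20)
        P = np.einsum("ik,ck,kj->cij", right, expo, left)
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    # ------------------------------------------------------------------ #
    def with_gamma(self, alpha: float, n_categories: int = 4) -> "SubstitutionModel":
        return SubstitutionModel(
            name=self.name.split("+")[0] + "+G",
            exchangeabilities=self.exchangeabilities,
            frequencies=self.frequencies,
            gamma_alpha=alpha,
            n_categories=n_categories,
        )

    def with_frequencies(self, frequencies: np.ndarray) -> "SubstitutionModel":
        """Empirical-frequency (+F) variant of this model."""
        freqs = np.asarray(frequencies, dtype=float)
        freqs = freqs / freqs.sum()
        return SubstitutionModel(
            name=self.name + "+F",
            exchangeabilities=self.exchangeabilities,
            frequencies=freqs,
            gamma_alpha=self.gamma_alpha,
            n_categories=self.n_categories,
        )

    @property
    def n_free_parameters(self) -> int:
        """Parameters counted for AIC: +G adds 1, +F adds 19."""
        k = 0
        if self.gamma_alpha is not None:
            k += 1
        if self.name.endswith("+F") or "+F+" in self.name:
            k += 19
        return k


def poisson_model(
    gamma_alpha: Optional[float] = None, frequencies: Optional[np.ndarray] = None
) -> SubstitutionModel:
    """Uniform exchangeabilities and (by default) uniform frequencies."""
    exch = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(exch, 0.0)
    freqs = np.full(N_STATES, 1.0 / N_STATES) if frequencies is None else frequencies
    return SubstitutionModel("Poisson", exch, np.asarray(freqs, float), gamma_alpha)


def wag_model(gamma_alpha: Optional[float] = None) -> SubstitutionModel:
    exch, freqs = _load_table("wag")
    return SubstitutionModel("WAG", exch, freqs, gamma_alpha)


def lg_model(gamma_alpha: Optional[float] = None) -> SubstitutionModel:
    exch, freqs = _load_table("lg")
    return SubstitutionModel("LG", exch, freqs, gamma_alpha)


def get_model(spec: str, empirical_frequencies: Optional[np.ndarray] = None,
              gamma_alpha: float = 1.0) -> SubstitutionModel:
    """Build a model from a string such as ``"LG+G+F"`` or ``"WAG"``."""
    parts = spec.upper().split("+")
    base = {"POISSON": poisson_model, "WAG": wag_model, "LG": lg_model}.get(parts[0])
    if base is None:
        raise ValueError(f"unknown model {parts[0]!r}")
    model = base()
    if "G" in parts[1:]:
        model = model.with_gamma(gamma_alpha)
    if "F" in parts[1:]:
        if empirical_frequencies is None:
            raise ValueError("+F requires empirical frequencies")
        model = model.with_frequencies(empirical_frequencies)
    return model
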