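"""Reversible 20-state amino-acid substitution models.

A model is specified by symmetric exchangeabilities ``S`` and equilibrium
frequencies ``pi``.  The instantaneous rate matrix is ``Q[i, j] = S[i, j] *
pi[j]`` off the diagonal, with the diagonal set so rows sum to zero, and the
whole matrix rescaled so that one unit of branch length corresponds to one
expected substitution per site at equilibrium.  Transition matrices
``P(t) = expm(Q t)`` are computed from the symmetric eigendecomposition of
``diag(sqrt(pi)) Q diag(1/sqrt(pi))``, which is exact for reversible models
and lets a single decomposition serve every branch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._wag_data import PAML_ORDER, WAG_FREQUENCIES, WAG_LOWER_TRIANGLE

#: Canonical state order used throughout the package: one-letter codes in
#: alphabetical order, so that argmax tie-breaking is alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _expand_lower_triangle(values: np.ndarray, n: int = 20) -> np.ndarray:
    """Expand a column-major lower triangle into a symmetric matrix."""
    m = np.zeros((n, n))
    k = 0
    for j in range(n - 1):
        for i in range(j + 1, n):
            m[i, j] = values[k]
            k += 1
    return m + m.T


@dataclass(frozen=True)
class SubstitutionModel:
    """Time-reversible amino-acid substitution model.

    Parameters
    ----------
    name : str
        Model identifier ("WAG", "poisson", ...).
    exchangeabilities : (20, 20) ndarray
        Symmetric non-negative rates, states in :data:`AMINO_ACIDS` order.
    frequencies : (20,) ndarray
        Equilibrium frequencies, non-negative, summing to 1.
    """

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    _eig: tuple = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (20, 20) or not np.allclose(s, s.T):
            raise ValueError("exchangeabilities must be a symmetric 20x20 matrix")
        if pi.shape != (20,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("frequencies must be 20 non-negative values summing to 1")
        object.__setattr__(self, "exchangeabilities", s)
        object.__setattr__(self, "frequencies", pi / pi.sum())
        # symmetric eigendecomposition cached for transition matrices
        q = self.rate_matrix
        sq = np.sqrt(self.frequencies)
        b = (q * sq[:, None]) / sq[None, :]
        w, v = np.linalg.eigh((b + b.T) / 2.0)
        object.__setattr__(self, "_eig", (w, v, sq))

    @property
    def rate_matrix(self) -> np.ndarray:
        """Scaled rate matrix Q (rows sum to 0; mean rate 1 at equilibrium)."""
        pi = self.frequencies
        q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(q)))
        return q / mu

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t); rows sum to 1."""
        if t < 0 or not np.isfinite(t):
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        w, v, sq = self._eig
        p = (v * np.exp(w * t)) @ v.T
        p = p / sq[:, None] * sq[None, :]
        return np.clip(p, 0.0, None)


def wag_model() -> SubstitutionModel:
    """The WAG empirical model, reordered to alphabetical one-letter codes."""
    tri = np.array(WAG_LOWER_TRIANGLE.split(), dtype=float)
    pi_paml = np.array(WAG_FREQUENCIES.split(), dtype=float)
    s_paml = _expand_lower_triangle(tri)
    order = [PAML_ORDER.index(aa) for aa in AMINO_ACIDS]
    s = s_paml[np.ix_(order, order)]
    pi = pi_paml[order]
    return SubstitutionModel("WAG", s, pi / pi.sum())


def poisson_model() -> SubstitutionModel:
    """Uniform-rate, uniform-frequency (Poisson / JC-like) model."""
    s = np.ones((20, 20)) - np.eye(20)
    pi = np.full(20, 1 / 20)
    return SubstitutionModel("poisson", s, pi)


_REGISTRY = {"WAG": wag_model, "poisson": poisson_model}


def get_model(name: str) -> SubstitutionModel:
    """Look up a model by name (case-insensitive); default registry: WAG, poisson."""
    for key, factory in _REGISTRY.items():
        if key.lower() == name.lower():
            return factory()
    raise KeyError(f"unknown substitution model {name!r}; available: {sorted(_REGISTRY)}")
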