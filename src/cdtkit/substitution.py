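"""HKY + discrete-Gamma nucleotide substitution model.

One model object serves both directions of the pipeline: forward simulation
of sequences down a genealogy and Felsenstein pruning of the likelihood up
it.  The rate matrix is normalized to one expected substitution per site per
unit time, so branch lengths are in substitutions/site.  Among-site rate
variation uses the standard discrete-Gamma approximation (equal-probability
bins, mean-of-bin rates; 4 categories by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.stats import gamma as gamma_dist

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: transitions are A<->G and C<->T
_TRANSITION = np.zeros((4, 4), dtype=bool)
_TRANSITION[0, 2] = _TRANSITION[2, 0] = True
_TRANSITION[1, 3] = _TRANSITION[3, 1] = True


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean-of-bin rates for the equal-probability discrete-Gamma model.

    The bin mean uses the closed-form identity
    ``E[X; X in (a,b)] = F_{alpha+1}(b) - F_{alpha+1}(a)`` (scale chosen so
    the overall mean is 1), so the returned rates average exactly to 1.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_categories
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1.0 / shape)
    upper = gamma_dist.cdf(edges, a=shape + 1, scale=1.0 / shape)
    rates = k * np.diff(upper)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """HKY85 with optional discrete-Gamma rate heterogeneity.

    ``gamma_shape=None`` disables rate variation (single unit-rate class).
    """

    kappa: float = 2.0
    base_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    gamma_shape: float | None = None
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.base_frequencies = np.asarray(self.base_frequencies, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.base_frequencies.shape != (4,):
            raise ValueError("base_frequencies must have length 4")
        if np.any(self.base_frequencies <= 0) or np.any(self.base_frequencies >= 1):
            raise ValueError("base frequencies must lie in (0,1)")
        if abs(self.base_frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    @cached_property
    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        """Normalized HKY generator Q (rows sum to zero, mean rate 1)."""
        pi = self.base_frequencies
        q = np.where(_TRANSITION, self.kappa, 1.0) * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    @cached_property
    def _eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of Q via the reversible symmetrization."""
        pi = self.base_frequencies
        sq = np.sqrt(pi)
        sym = self.rate_matrix * sq[:, None] / sq[None, :]
        sym = 0.5 * (sym + sym.T)
        lam, u = np.linalg.eigh(sym)
        right = u / sq[:, None]
        left = u.T * sq[None, :]
        return lam, right, left

    def transition_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """P(t) for an array of branch lengths; output shape ``lengths.shape + (4, 4)``."""
        lam, right, left = self._eigensystem
        t = np.asarray(lengths, dtype=float)
        el = np.exp(np.multiply.outer(t, lam))
        p = np.einsum("ik,...k,kj->...ij", right, el, left)
        return np.clip(p, 0.0, None)

    def empirical(self, counts: np.ndarray) -> "SubstitutionModel":
        """Copy of the model with frequencies set from observed base counts."""
        freqs = np.asarray(counts, dtype=float) + 1.0
        return SubstitutionModel(
            kappa=self.kappa,
            base_frequencies=freqs / freqs.sum(),
            gamma_shape=self.gamma_shape,
            n_categories=self.n_categories,
        )
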