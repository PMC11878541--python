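"""Amino-acid substitution models and discrete-gamma rate heterogeneity.

The default model is the 20-state symmetric equal-rates chain with uniform
stationary frequencies (the protein analogue of Jukes–Cantor). A general
time-reversible model can be supplied through an exchangeability matrix and
stationary frequencies; transition probabilities come from the spectral
decomposition of the rate matrix, scaled so one unit of branch length is
one expected substitution per site.

Across-site rate variation uses the standard discrete-gamma construction:
a mean-one Gamma(alpha, alpha) density cut into ``k`` equal-probability
categories, each represented by its conditional mean, so the category mix
has mean exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alphabet import N_STATES


class SubstitutionModel:
    """Time-reversible amino-acid substitution model.

    Parameters
    ----------
    exchangeabilities:
        Symmetric non-negative matrix of relative rates (diagonal ignored);
        ``None`` means all-equal (the symmetric equal-rates model).
    freqs:
        Stationary frequencies; ``None`` means uniform.

    The generator Q is built as ``Q_ij = s_ij * pi_j`` and rescaled so the
    expected substitution rate at stationarity is 1, i.e. branch lengths
    are in expected substitutions per site.
    """

    def __init__(self, exchangeabilities: np.ndarray | None = None,
                 freqs: np.ndarray | None = None):
        n = N_STATES
        if freqs is None:
            freqs = np.full(n, 1.0 / n)
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (n,) or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("freqs must be a length-20 probability vector")
        if exchangeabilities is None:
            s = np.ones((n, n))
        else:
            s = np.asarray(exchangeabilities, dtype=float)
            if s.shape != (n, n) or not np.allclose(s, s.T):
                raise ValueError("exchangeabilities must be a symmetric 20x20 matrix")
            if (s < 0).any():
                raise ValueError("exchangeabilities must be non-negative")
        q = s * freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(freqs * np.diag(q)).sum()
        if mu <= 0:
            raise ValueError("degenerate model: zero total rate")
        q /= mu
        self.freqs = freqs
        self.q = q
        # symmetrized eigendecomposition: B = D^1/2 Q D^-1/2 is symmetric
        d_sqrt = np.sqrt(freqs)
        b = (d_sqrt[:, None] * q) / d_sqrt[None, :]
        lam, u = np.linalg.eigh((b + b.T) / 2.0)
        self._lam = lam
        self._left = u / d_sqrt[:, None] * 1.0  # D^-1/2 U
        self._right = (u * d_sqrt[:, None]).T  # U^T D^1/2

    def transition_matrices(self, t: np.ndarray | float) -> np.ndarray:
        """P(t) for one or many branch lengths; shape ``t.shape + (20, 20)``."""
        t_arr = np.asarray(t, dtype=float)
        if (t_arr < 0).any():
            raise ValueError("branch lengths must be non-negative")
        e = np.exp(np.multiply.outer(t_arr, self._lam))  # t.shape + (20,)
        p = np.einsum("ij,...j,jk->...ik", self._left, e, self._right)
        np.clip(p, 0.0, 1.0, out=p)
        return p


@dataclass
class GammaRateModel:
    """Discrete-gamma site-rate model with equal-weight categories.

    ``rates`` are the conditional means of a mean-one Gamma(alpha, alpha)
    distribution within each of ``k`` equal-probability slices, so
    ``sum(weights * rates) == 1`` exactly.
    """

    alpha: float
    k: int
    rates: np.ndarray = field(default=None)  # type: ignore[assignment]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("gamma shape alpha must be positive")
        if self.k < 1:
            raise ValueError("need at least one rate category")
        if self.rates is None:
            self.rates = discretize_gamma(self.alpha, self.k)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.weights is None:
            self.weights = np.full(self.k, 1.0 / self.k)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("category weights must sum to 1")
        if not np.isclose(float(self.weights @ self.rates), 1.0, atol=1e-6):
            raise ValueError("category mixture must have mean 1")


def discretize_gamma(alpha: float, k: int) -> np.ndarray:
    """Equal-probability category means of a mean-one gamma distribution.

    With boundaries at the i/k quantiles of Gamma(alpha, rate=alpha), the
    conditional mean of slice i is ``k * (I(alpha+1, a*q_i) - I(alpha+1,
    a*q_{i-1}))`` where I is the regularized lower incomplete gamma.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if k == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1.0, alpha * bounds), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * bounds)])
    return k * (upper - lower)
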