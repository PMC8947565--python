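"""Bernstein-polynomial density estimators on the unit interval.

Two estimators share the Bernstein basis ``b_k(m, x) = C(m, k) x^k (1-x)^(m-k)``:

* the Vitale estimator, a plug-in smoother of the empirical CDF,
  ``f1(x) = m * sum_k [F_n((k+1)/m) - F_n(k/m)] b_k(m-1, x)``
  — equivalently a mixture of Beta(k+1, m-k) densities with weights given
  by empirical-CDF increments;
* Guan's estimator, a mixture of the scaled basis ``B_mi = (m+1) b_i(m, .)``
  with simplex weights fitted by maximum likelihood via EM.

Both are genuine densities on [0, 1] (no boundary mass leakage), which is
what makes them attractive compared to kernel smoothing near the edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.stats import binom

from .exceptions import DegeneracyError, InvalidInputError

__all__ = [
    "UnitSample",
    "VitaleEstimate",
    "GuanEstimate",
    "empirical_cdf",
    "bernstein_basis",
    "basis_matrix",
    "fit_vitale",
    "evaluate_vitale",
    "fit_guan",
    "evaluate_guan",
    "guan_log_likelihood",
]


@dataclass(frozen=True)
class UnitSample:
    """An i.i.d. univariate sample with all values in [0, 1]."""

    values: np.ndarray
    _sorted: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise InvalidInputError("sample must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("sample contains non-finite values")
        if np.any(v < 0.0) or np.any(v > 1.0):
            raise InvalidInputError("sample values must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "_sorted", np.sort(v))
        if np.any(v == 0.0):
            warnings.warn(
                "observations exactly at 0 contribute to F_n(0) and remove "
                "mass from the Vitale weights",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.values.size


def empirical_cdf(sample: UnitSample, t) -> np.ndarray | float:
    """Right-continuous empirical distribution function F_n(t) = #{X_i <= t}/n."""
    t_arr = np.asarray(t, dtype=float)
    out = np.searchsorted(sample._sorted, t_arr, side="right") / sample.n
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def bernstein_basis(m: int, k, x) -> np.ndarray | float:
    """Bernstein basis polynomial ``b_k(m, x) = C(m, k) x^k (1-x)^(m-k)``.

    Computed through the binomial pmf (log-space binomial coefficients),
    stable for degrees well beyond the m <= 300 search range.
    """
    if m < 0:
        raise InvalidInputError("degree m must be >= 0")
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or np.any(k_arr > m):
        raise InvalidInputError(f"basis index k must lie in 0..{m}")
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0.0) or np.any(x_arr > 1.0):
        raise InvalidInputError("x must lie in [0, 1]")
    out = binom.pmf(k_arr, m, x_arr)
    if np.isscalar(k) and np.isscalar(x):
        return float(out)
    return out


def basis_matrix(m: int, x) -> np.ndarray:
    """All basis rows at once: shape (m+1, len(x)), row k = b_k(m, x).

    Uses the degree recurrence
    ``b_k(m, x) = (1-x) b_k(m-1, x) + x b_{k-1}(m-1, x)``,
    which is stable (all terms nonnegative) and cheaper than m+1
    independent pmf evaluations.
    """
    *_, B = _basis_rows_upto(m, x)
    return B


def _basis_rows_upto(m_max: int, x) -> Iterator[np.ndarray]:
    """Yield the basis matrix of every degree 0..m_max in turn."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if m_max < 0:
        raise InvalidInputError("degree must be >= 0")
    B = np.ones((1, x.size))
    yield B
    onemx = 1.0 - x
    for m in range(1, m_max + 1):
        nxt = np.zeros((m + 1, x.size))
        nxt[:m] = onemx * B
        nxt[1:] += x * B
        B = nxt
        yield B


@dataclass(frozen=True)
class VitaleEstimate:
    """Vitale's Bernstein density estimator of degree m.

    ``weights[k] = F_n((k+1)/m) - F_n(k/m)``; they are nonnegative and sum
    to ``1 - F_n(0)`` (exactly 1 when no observation sits at 0).
    """

    m: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if self.m < 1 or w.size != self.m:
            raise InvalidInputError("weights must have length m >= 1")
        if np.any(w < 0.0):
            raise InvalidInputError("Vitale weights must be nonnegative")
        object.__setattr__(self, "weights", w)

    def __call__(self, x):
        return evaluate_vitale(self, x)


def fit_vitale(sample: UnitSample, m: int) -> VitaleEstimate:
    """Fit the Vitale estimator: empirical-CDF increments on the grid k/m."""
    if m < 1:
        raise InvalidInputError("Vitale degree m must be >= 1")
    edges = np.arange(m + 1) / m
    cdf = np.searchsorted(sample._sorted, edges, side="right") / sample.n
    return VitaleEstimate(m=m, weights=np.diff(cdf))


def evaluate_vitale(est: VitaleEstimate, x) -> np.ndarray | float:
    """Evaluate ``m * sum_k w_k b_k(m-1, x)`` for x in [0, 1]."""
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x_arr < 0.0) or np.any(x_arr > 1.0):
        raise InvalidInputError("x must lie in [0, 1]")
    B = basis_matrix(est.m - 1, x_arr)
    out = est.m * (est.weights @ B)
    return float(out[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else out


@dataclass(frozen=True)
class GuanEstimate:
    """Bernstein mixture with simplex weights p over (m+1) basis densities."""

    m: int
    p: np.ndarray
    n_iter: int = 0
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if self.m < 0 or p.size != self.m + 1:
            raise InvalidInputError("p must have length m + 1")
        if np.any(p < 0.0) or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidInputError("p must lie on the probability simplex")
        object.__setattr__(self, "p", p)

    def __call__(self, x):
        return evaluate_guan(self, x)


def _scaled_basis(m: int, x: np.ndarray) -> np.ndarray:
    """B_mi(x) = (m+1) b_i(m, x): (m+1) densities on [0, 1], rows over i."""
    return (m + 1) * basis_matrix(m, x)


def guan_log_likelihood(p: np.ndarray, B: np.ndarray) -> float:
    """Observed-data log-likelihood sum_j log sum_i p_i B_mi(x_j)."""
    dens = p @ B
    if np.any(dens <= 0.0):
        raise DegeneracyError("mixture density is zero at a data point")
    return float(np.sum(np.log(dens)))


def fit_guan(
    sample: UnitSample,
    m: int,
    p0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GuanEstimate:
    """Fit Guan's Bernstein mixture of degree m by EM.

    The fixed-point update is
    ``p_i <- (1/n) sum_j p_i B_mi(x_j) / sum_k p_k B_mk(x_j)``,
    a genuine EM step for the (m+1)-component mixture, so the observed
    log-likelihood never decreases.  Iteration stops when the max-abs
    change in p drops below *tol* or after *max_iter* sweeps.
    """
    if m < 0:
        raise InvalidInputError("Guan degree m must be >= 0")
    if p0 is None:
        p = np.full(m + 1, 1.0 / (m + 1))
    else:
        p = np.asarray(p0, dtype=float)
        if p.size != m + 1 or np.any(p < 0.0) or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidInputError("p0 must lie on the simplex of dimension m+1")
    if m == 0:
        return GuanEstimate(m=0, p=np.array([1.0]), n_iter=0, log_likelihood=0.0)

    B = _scaled_basis(m, sample.values)  # (m+1, n)
    it = 0
    for it in range(1, max_iter + 1):
        dens = p @ B
        if np.any(dens <= 0.0):
            raise DegeneracyError(
                "mixture density vanished at a data point during EM"
            )
        p_new = p * np.mean(B / dens, axis=1)
        delta = np.max(np.abs(p_new - p))
        p = p_new
        if delta < tol:
            break
    # renormalize away accumulated rounding
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return GuanEstimate(m=m, p=p, n_iter=it, log_likelihood=guan_log_likelihood(p, B))


def evaluate_guan(est: GuanEstimate, x) -> np.ndarray | float:
    """Evaluate ``sum_i p_i (m+1) b_i(m, x)`` for x in [0, 1]."""
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x_arr < 0.0) or np.any(x_arr > 1.0):
        raise InvalidInputError("x must lie in [0, 1]")
    out = est.p @ _scaled_basis(est.m, x_arr)
    return float(out[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else out
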