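"""Univariate finite Gaussian mixtures fitted by EM, with gap-statistic
selection of the number of components.

The mixture ``g(x | theta) = sum_k pi_k N(mu_k, sigma_k)(x)`` is the
parametric component of the shrinkage estimator.  EM alternates posterior
responsibilities (E-step) with weighted moment updates (M-step) until the
max-abs parameter change falls below a threshold; the observed-data
log-likelihood is non-decreasing along the way.

Two numerical floors keep EM alive on degenerate inputs: a variance floor
(components cannot collapse onto a point mass) and a density floor inside
the responsibility denominators (no 0/0 in far tails).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.vq import kmeans2

from .exceptions import EmptyComponentError, InvalidInputError

__all__ = [
    "GMMParams",
    "gmm_density",
    "gmm_log_likelihood",
    "e_step",
    "m_step",
    "fit_gmm_em",
    "select_K_gap",
]

#: smallest admissible component variance (data are typically on [0, 1])
VARIANCE_FLOOR = 1e-6
#: floor inside responsibility denominators
DENSITY_FLOOR = 1e-300

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class GMMParams:
    """Parameters theta = (pi, mu, sigma) of a K-component Gaussian mixture."""

    pi: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if not (pi.size == mu.size == sigma.size and pi.size >= 1):
            raise InvalidInputError("pi, mu, sigma must share a positive length")
        if np.any(pi < 0.0) or abs(pi.sum() - 1.0) > 1e-8:
            raise InvalidInputError("pi must lie on the probability simplex")
        if np.any(sigma <= 0.0):
            raise InvalidInputError("all sigma must be positive")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def K(self) -> int:
        return self.pi.size

    def __call__(self, x):
        return gmm_density(self, x)


def _component_densities(params: GMMParams, x: np.ndarray) -> np.ndarray:
    """Matrix (n, K): pi_k N(mu_k, sigma_k)(x_i)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = (x[:, None] - params.mu[None, :]) / params.sigma[None, :]
    dens = np.exp(-0.5 * z * z) / (params.sigma[None, :] * _SQRT2PI)
    return params.pi[None, :] * dens


def gmm_density(params: GMMParams, x) -> np.ndarray | float:
    """Mixture density ``sum_k pi_k N(mu_k, sigma_k)(x)``."""
    out = _component_densities(params, x).sum(axis=1)
    return float(out[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else out


def gmm_log_likelihood(params: GMMParams, x) -> float:
    dens = _component_densities(params, x).sum(axis=1)
    return float(np.sum(np.log(np.maximum(dens, DENSITY_FLOOR))))


def e_step(params: GMMParams, x) -> np.ndarray:
    """Posterior responsibilities tau (n, K); each row sums to 1."""
    comp = _component_densities(params, x)
    denom = np.maximum(comp.sum(axis=1, keepdims=True), DENSITY_FLOOR)
    return comp / denom


def m_step(tau: np.ndarray, x, variance_floor: float = VARIANCE_FLOOR) -> GMMParams:
    """Weighted-moment updates: pi_j = mean tau_ij; mu_j, sigma_j^2 the
    tau-weighted mean and (biased) variance."""
    tau = np.asarray(tau, dtype=float)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if tau.ndim != 2 or tau.shape[0] != x.size:
        raise InvalidInputError("tau must be an (n, K) matrix aligned with x")
    nk = tau.sum(axis=0)
    if np.any(nk <= 0.0):
        raise EmptyComponentError("a mixture component has zero responsibility")
    pi = nk / x.size
    mu = (tau * x[:, None]).sum(axis=0) / nk
    var = (tau * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
    sigma = np.sqrt(np.maximum(var, variance_floor))
    return GMMParams(pi=pi, mu=mu, sigma=sigma)


def _init_params(x: np.ndarray, K: int, rng: np.random.Generator) -> GMMParams:
    """k-means seeding of the means, equal weights, pooled spread."""
    pooled = max(float(np.std(x)), np.sqrt(VARIANCE_FLOOR))
    if K == 1:
        mu = np.array([float(np.mean(x))])
    else:
        seed = int(rng.integers(2**31 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            centers, _ = kmeans2(x, K, minit="++", seed=seed)
        centers = np.sort(centers)
        # collapse duplicated centers onto distinct quantiles
        if np.unique(np.round(centers, 12)).size < K:
            centers = np.quantile(x, (np.arange(K) + 0.5) / K)
        mu = centers
    return GMMParams(pi=np.full(K, 1.0 / K), mu=mu, sigma=np.full(K, pooled))


def _em_loop(
    params: GMMParams, values: np.ndarray, tol: float, max_iter: int
) -> GMMParams:
    for _ in range(max_iter):
        tau = e_step(params, values)
        new = m_step(tau, values)
        delta = max(
            np.max(np.abs(new.pi - params.pi)),
            np.max(np.abs(new.mu - params.mu)),
            np.max(np.abs(new.sigma - params.sigma)),
        )
        params = new
        if delta < tol:
            break
    return params


def fit_gmm_em(
    x,
    K: int,
    init: GMMParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | np.random.Generator | None = 0,
    n_init: int = 5,
) -> GMMParams:
    """Fit a K-component Gaussian mixture by EM.

    Parameters
    ----------
    x : array-like or UnitSample
        Observations (any real scale).
    K : int
        Number of components; requires ``n >= K``.
    init : GMMParams, optional
        Starting parameters; when given, a single EM run starts there.
        Default is deterministic k-means seeding.
    tol : float
        Stop when the max-abs change across (pi, mu, sigma) drops below it.
    max_iter : int
        Iteration cap per restart.
    seed : int or Generator
        Drives the k-means seeding only.
    n_init : int
        Number of seeded restarts for K > 1; the run with the best final
        log-likelihood wins (EM for mixtures is multimodal, restarts are
        the standard defence).
    """
    values = getattr(x, "values", x)
    values = np.atleast_1d(np.asarray(values, dtype=float))
    n = values.size
    if K < 1:
        raise InvalidInputError("K must be >= 1")
    if n < K:
        raise InvalidInputError(f"need at least K={K} observations, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if init is not None:
        if init.K != K:
            raise InvalidInputError("init has wrong number of components")
        return _em_loop(init, values, tol, max_iter)
    restarts = 1 if K == 1 else max(1, n_init)
    best, best_ll = None, -np.inf
    for _ in range(restarts):
        params = _em_loop(_init_params(values, K, rng), values, tol, max_iter)
        ll = gmm_log_likelihood(params, values)
        if ll > best_ll:
            best, best_ll = params, ll
    return best


def _within_dispersion(x: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Within-cluster sum of squares around cluster means."""
    w = 0.0
    for j in range(k):
        xj = x[labels == j]
        if xj.size:
            w += float(np.sum((xj - xj.mean()) ** 2))
    return w


def _kmeans_w(x: np.ndarray, k: int, rng: np.random.Generator) -> float:
    if k == 1:
        return float(np.sum((x - x.mean()) ** 2))
    seed = int(rng.integers(2**31 - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, labels = kmeans2(x, k, minit="++", seed=seed)
    return _within_dispersion(x, labels, k)


def select_K_gap(
    x,
    K_max: int = 10,
    B: int = 50,
    seed: int | np.random.Generator | None = 0,
) -> int:
    """Choose the number of mixture components by the gap statistic.

    ``Gap(k) = mean_b log W*_kb - log W_k`` compares the log within-cluster
    dispersion of a k-means clustering of the data against B uniform
    reference sets drawn on the data range.  Returns the smallest k with
    ``Gap(k) >= Gap(k+1) - s_{k+1}`` where s is the reference spread
    inflated by sqrt(1 + 1/B); falls back to K_max when no k qualifies.
    """
    values = getattr(x, "values", x)
    values = np.atleast_1d(np.asarray(values, dtype=float))
    n = values.size
    if K_max < 1 or B < 1:
        raise InvalidInputError("K_max and B must be >= 1")
    if n == 1:
        return 1
    if n < K_max:
        warnings.warn(f"n={n} < K_max={K_max}; reducing K_max to n", stacklevel=2)
        K_max = n
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    eps = DENSITY_FLOOR  # guard for zero dispersion (constant samples)
    lo, hi = float(values.min()), float(values.max())
    refs = rng.uniform(lo, hi, size=(B, n))

    gap = np.empty(K_max + 1)
    s = np.empty(K_max + 1)
    for k in range(1, K_max + 1):
        log_w = np.log(max(_kmeans_w(values, k, rng), eps))
        log_wref = np.array(
            [np.log(max(_kmeans_w(refs[b], k, rng), eps)) for b in range(B)]
        )
        gap[k] = float(log_wref.mean() - log_w)
        s[k] = float(log_wref.std(ddof=0) * np.sqrt(1.0 + 1.0 / B))

    for k in range(1, K_max):
        if gap[k] >= gap[k + 1] - s[k + 1]:
            return k
    return K_max
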