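"""Standard Gaussian kernel density estimator (the boundary-biased comparator).

No boundary correction is applied on purpose: near the edges of a compact
support the kernel spills mass outside [0, 1], which is the phenomenon the
shrinkage estimator is designed to avoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bernstein import UnitSample
from .exceptions import InvalidInputError

__all__ = ["KernelEstimate", "evaluate_kernel"]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class KernelEstimate:
    """Gaussian KDE: sample plus bandwidth h > 0."""

    sample: UnitSample
    h: float

    def __post_init__(self) -> None:
        if not self.h > 0.0:
            raise InvalidInputError("bandwidth h must be positive")

    def __call__(self, x):
        return evaluate_kernel(self, x)


def evaluate_kernel(est: KernelEstimate, x) -> np.ndarray | float:
    """``(1 / (n h)) sum_i phi((x - X_i) / h)`` with phi the standard
    normal density; defined for any real x."""
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    z = (x_arr[:, None] - est.sample.values[None, :]) / est.h
    out = np.exp(-0.5 * z * z).sum(axis=1) / (est.sample.n * est.h * _SQRT2PI)
    return float(out[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else out
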