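"""Support transformations between a native sample scale and the unit interval.

Bernstein-polynomial estimators live on [0, 1], so data on a general
support are first mapped there:

* interval [a, b]      ->  y = (x - a) / (b - a)
* real line            ->  y = 1/2 + arctan(x) / pi
* positive half-line   ->  y = x / (1 + x)

``transform_density`` pushes a density through the same map (change of
variables), so that estimation errors can be computed on the unit scale
where all estimators coexist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .exceptions import BoundaryError, InvalidInputError

__all__ = [
    "SupportSpec",
    "interval",
    "real_line",
    "positive_half_line",
    "unit_interval",
    "to_unit",
    "from_unit",
    "transform_density",
    "unit_jacobian",
    "data_driven_bounds",
]

Kind = Literal["interval", "real_line", "positive_half_line"]


@dataclass(frozen=True)
class SupportSpec:
    """Declared support of a sample: ``interval(a, b)``, the real line,
    or the positive half-line."""

    kind: Kind
    a: float = 0.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("interval", "real_line", "positive_half_line"):
            raise InvalidInputError(f"unknown support kind {self.kind!r}")
        if self.kind == "interval" and not self.a < self.b:
            raise InvalidInputError(
                f"interval support requires a < b, got a={self.a}, b={self.b}"
            )


def interval(a: float, b: float) -> SupportSpec:
    return SupportSpec("interval", float(a), float(b))


def unit_interval() -> SupportSpec:
    return SupportSpec("interval", 0.0, 1.0)


def real_line() -> SupportSpec:
    return SupportSpec("real_line")


def positive_half_line() -> SupportSpec:
    return SupportSpec("positive_half_line")


def to_unit(values, spec: SupportSpec) -> np.ndarray:
    """Map native-scale values into [0, 1] according to *spec*.

    Raises :class:`InvalidInputError` (naming the first offending index)
    when a value lies outside the declared support.
    """
    x = np.asarray(values, dtype=float)
    if spec.kind == "interval":
        bad = np.flatnonzero((x < spec.a) | (x > spec.b))
        if bad.size:
            raise InvalidInputError(
                f"value {x.flat[bad[0]]} at index {bad[0]} outside "
                f"declared support [{spec.a}, {spec.b}]"
            )
        return (x - spec.a) / (spec.b - spec.a)
    if spec.kind == "real_line":
        return 0.5 + np.arctan(x) / np.pi
    # positive half-line
    bad = np.flatnonzero(x < 0)
    if bad.size:
        raise InvalidInputError(
            f"value {x.flat[bad[0]]} at index {bad[0]} outside the "
            "positive half-line"
        )
    return x / (1.0 + x)


def from_unit(values, spec: SupportSpec) -> np.ndarray:
    """Exact inverse of :func:`to_unit`.

    For the two unbounded supports the unit values must lie strictly
    inside (0, 1); the boundary points map to infinity.
    """
    y = np.asarray(values, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise InvalidInputError("unit-scale values must lie in [0, 1]")
    if spec.kind == "interval":
        return spec.a + (spec.b - spec.a) * y
    if np.any(y <= 0) or np.any(y >= 1):
        raise BoundaryError(
            "0 and 1 have no finite preimage under an unbounded support map"
        )
    if spec.kind == "real_line":
        return np.tan(np.pi * (y - 0.5))
    return y / (1.0 - y)


def transform_density(
    pdf: Callable[[np.ndarray], np.ndarray], spec: SupportSpec
) -> Callable[[np.ndarray], np.ndarray]:
    """Push a native-scale density through the support map.

    Returns ``f_Y(y) = f_X(T^-1(y)) * |dT^-1/dy|``, a density on (0, 1).
    Jacobian factors: interval ``b - a``; real line ``pi (1 + x^2)`` with
    ``x = tan(pi (y - 1/2))``; half-line ``(1 - y)^-2``.
    """
    if spec.kind == "interval":
        width = spec.b - spec.a

        def f_unit(y):
            y = np.asarray(y, dtype=float)
            return pdf(spec.a + width * y) * width

    elif spec.kind == "real_line":

        def f_unit(y):
            y = np.asarray(y, dtype=float)
            x = np.tan(np.pi * (y - 0.5))
            return pdf(x) * np.pi * (1.0 + x * x)

    else:  # positive half-line

        def f_unit(y):
            y = np.asarray(y, dtype=float)
            onemy = 1.0 - y
            x = y / onemy
            return pdf(x) / (onemy * onemy)

    return f_unit


def unit_jacobian(values, spec: SupportSpec) -> np.ndarray:
    """``|dT^-1/dy|`` at unit-scale points y: the factor by which the
    support map stretches the native axis.

    interval: ``b - a``; real line: ``pi (1 + tan^2(pi (y - 1/2)))``;
    half-line: ``(1 - y)^-2``.  Useful for moving integrals between the
    unit and native scales.
    """
    y = np.asarray(values, dtype=float)
    if spec.kind == "interval":
        return np.full_like(y, spec.b - spec.a)
    if spec.kind == "real_line":
        t = np.tan(np.pi * (y - 0.5))
        return np.pi * (1.0 + t * t)
    onemy = 1.0 - y
    return 1.0 / (onemy * onemy)


def data_driven_bounds(values, n: int | None = None) -> tuple[float, float]:
    """Enclosing interval (a, b) for data with unknown finite support.

    The tails left outside are of order 1/n: the sample range is extended
    by ``range / n`` on each side.  A constant sample is widened by a
    fixed fraction of its magnitude (with a warning).
    """
    x = np.asarray(values, dtype=float)
    if n is None:
        n = x.size
    if n < 2:
        raise InvalidInputError("data_driven_bounds requires n >= 2")
    lo, hi = float(np.min(x)), float(np.max(x))
    span = hi - lo
    if span == 0.0:
        warnings.warn(
            "constant sample: widening bounds by 10% of |x| (or 1.0 if x == 0)",
            stacklevel=2,
        )
        pad = 0.1 * abs(lo) if lo != 0.0 else 1.0
        return lo - pad, hi + pad
    pad = span / n
    return lo - pad, hi + pad
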