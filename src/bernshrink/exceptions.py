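"""Exception hierarchy.

``InvalidInputError`` covers contract violations a caller can fix;
``DegeneracyError`` covers numerical breakdowns (zero mixture densities,
empty mixture components) that survive the built-in floors.
"""


class BernshrinkError(Exception):
    """Base class for all package errors."""


class InvalidInputError(BernshrinkError, ValueError):
    """An argument violates a documented precondition."""


class BoundaryError(InvalidInputError):
    """An evaluation point sits on a boundary where the quantity diverges."""


class DegeneracyError(BernshrinkError, ArithmeticError):
    """A numerical degeneracy (zero density, collapsed component)."""


class EmptyComponentError(DegeneracyError):
    """A mixture component received zero total responsibility."""
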