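"""Exception hierarchy for rodsphere."""


class RodSphereError(Exception):
    """Base class for all rodsphere errors."""


class InvalidGeometryError(RodSphereError, ValueError):
    """Degenerate or inconsistent geometric input (e.g. coincident rod ends)."""


class OverlapError(RodSphereError, ValueError):
    """The rod penetrates the sphere; the integrated potential diverges.

    Carries the minimum rod-to-center distance when available.
    """

    def __init__(self, msg, min_distance=None, radius=None):
        super().__init__(msg)
        self.min_distance = min_distance
        self.radius = radius


class DomainError(RodSphereError, ValueError):
    """Scalar argument outside the mathematical domain (e.g. r <= 0)."""


class BranchError(RodSphereError, ValueError):
    """A branch-specific primitive was called outside its branch (h vs a)."""


class UnsupportedOperationError(RodSphereError, ValueError):
    """Operation undefined for the given inputs (e.g. torque on an infinite rod)."""


class PrecisionError(RodSphereError, ArithmeticError):
    """A closed-form evaluation stayed non-finite even in extended precision."""


class OracleError(RodSphereError, RuntimeError):
    """The numerical-quadrature reference failed to converge."""
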