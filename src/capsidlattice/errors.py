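"""Exception hierarchy for capsidlattice."""


class CapsidError(Exception):
    """Base class for all capsidlattice errors."""


class InvalidStepError(CapsidError, ValueError):
    """Raised for a degenerate or malformed hexagonal-lattice step."""


class NotATNumberError(CapsidError, ValueError):
    """Raised when an integer is not a valid triangulation number.

    A triangulation number must be representable as h^2 + h*k + k^2
    for non-negative integers (h, k) != (0, 0).
    """


class NoCenteredHexamerError(CapsidError, ValueError):
    """Raised when a centered-hexamer construction is requested for a
    T-number that is not divisible by three (no hexamer can sit on a
    global 3-fold axis)."""


class StructureError(CapsidError, RuntimeError):
    """Raised when a polyhedron or lattice fails an internal structural
    invariant (wrong site counts, malformed scaffold)."""


class ClassificationMismatchError(CapsidError, RuntimeError):
    """Raised when the exact lattice predicates and the floating-point
    geometric route disagree about a capsomer's symmetry class."""
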