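"""Exception types raised by cordmorph."""


class CordMorphError(Exception):
    """Base class for all package errors."""


class ValidationError(CordMorphError):
    """An input object violates a structural invariant."""


class DegenerateInputError(CordMorphError):
    """Input too small or empty for the requested computation."""


class UndefinedShapeError(CordMorphError):
    """A shape descriptor is undefined for this pixel set (e.g. collinear)."""
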