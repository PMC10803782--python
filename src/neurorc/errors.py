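"""Exception hierarchy shared across the package."""


class NeurorcError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NeurorcError, ValueError):
    """Input file or matrix does not have the expected layout."""


class ValidationError(NeurorcError, ValueError):
    """Data violates a structural invariant (non-finite entries, negative weights, ...)."""


class ParameterError(NeurorcError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class DegenerateInputError(NeurorcError, ValueError):
    """Operation undefined on this input (all-zero matrix, zero spectral radius, ...)."""


class DegenerateLabelError(NeurorcError, ValueError):
    """Classification targets contain fewer than two classes."""


class DivergenceError(NeurorcError, RuntimeError):
    """Reservoir state left the finite/bounded range during simulation."""


class ShapeError(NeurorcError, ValueError):
    """Array dimensions do not match between coupled arguments."""


class UnknownLabelError(NeurorcError, KeyError):
    """A requested partition label does not exist."""
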