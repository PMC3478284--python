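"""Exception hierarchy shared across the package."""


class CytoploidError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CytoploidError, ValueError):
    """Invalid input data or parameters."""


class AmbiguityError(CytoploidError):
    """A histogram carries no usable mode structure (e.g. flat)."""


class ResolutionError(CytoploidError, ValueError):
    """A requested object cannot be represented at the given pixel scale."""


class UnresolvedCytotypeError(CytoploidError):
    """The G1 peak is not close to any allowed ploidy multiplier."""


class UnknownPresetError(CytoploidError, KeyError):
    """Requested synthetic preset does not exist."""
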