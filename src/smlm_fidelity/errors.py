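"""Exception hierarchy."""


class SmlmFidelityError(Exception):
    """Base class for package errors."""


class ParameterError(SmlmFidelityError, ValueError):
    """An argument is out of its valid range."""


class FormatError(SmlmFidelityError, ValueError):
    """An input file has the wrong format (e.g. multi-channel TIFF)."""


class DegenerateInputError(SmlmFidelityError, ValueError):
    """Input is formally valid but carries no usable information
    (constant image, all-zero density, empty foreground)."""


class TessellationError(SmlmFidelityError, ValueError):
    """The Voronoi tessellation of the emitter set is ill-posed."""


class LookupError_(SmlmFidelityError, KeyError):
    """A requested (n, kappa, d) cell is absent from a sweep table."""
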