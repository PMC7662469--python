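"""Exception hierarchy shared across the package."""


class SoyspecError(Exception):
    """Base class for all package errors."""


class FormatError(SoyspecError):
    """Malformed input file (bad headers, missing cells, wrong dialect)."""


class GridError(SoyspecError):
    """Wavelength grids are incompatible between two objects."""


class ParameterError(SoyspecError):
    """Invalid parameter combination passed to an operation."""


class DegenerateInputError(SoyspecError):
    """Input is structurally valid but numerically degenerate
    (all-zero spectrum, constant trait, zero class residual variance)."""


class ConfigError(SoyspecError):
    """Invalid run or generator configuration."""


class DataError(SoyspecError):
    """Data fails a semantic requirement (too few samples, missing trait,
    mass-balance violation)."""
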