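"""Exception types shared across the pipeline."""


class AznanoError(Exception):
    """Base class for all package errors."""


class FormatError(AznanoError):
    """A localization file is missing a required column or attribute."""


class ParseError(AznanoError):
    """A cell in a localization file could not be parsed as a number."""


class ParameterError(AznanoError):
    """An operation was called with invalid parameters."""


class EmptyInputError(AznanoError):
    """An operation that requires data received an empty input."""


class DegenerateGeometryError(AznanoError):
    """Fewer than three non-collinear points, or an otherwise degenerate shape."""


class InsufficientDataError(AznanoError):
    """Not enough observations to compute the requested statistic."""


class UnderdeterminedError(ParameterError):
    """Too few control-point pairs to fit the requested transform."""


class NormalizationError(AznanoError):
    """Normalization against a zero or missing control group."""


class BoundsError(AznanoError):
    """A sampling window exits the image bounds."""
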