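"""Exception types shared across the package."""


class MaldiScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(MaldiScreenError):
    """Invalid simulation or processing configuration."""


class SpectrumValidationError(MaldiScreenError):
    """A spectrum violates its structural invariants (axis order, lengths, finiteness)."""


class ParseError(MaldiScreenError):
    """A file could not be parsed; the message names the offending location."""


class PlateMapError(MaldiScreenError):
    """Plate-map table is malformed (unknown role, duplicate key, missing column)."""


class MissingControlError(PlateMapError):
    """A compound set lacks the positive or negative control it needs for QC."""


class FitError(MaldiScreenError):
    """Curve fitting failed; carries diagnostics in the message."""


class ParameterError(MaldiScreenError, ValueError):
    """Invalid analysis parameter (even smoothing window, too-small morphology window...)."""
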