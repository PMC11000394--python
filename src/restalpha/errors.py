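"""Exception hierarchy for the restalpha pipeline."""


class RestAlphaError(Exception):
    """Base class for all package errors."""


class ParameterError(RestAlphaError, ValueError):
    """A caller-supplied parameter violates a precondition."""


class FormatError(RestAlphaError, ValueError):
    """A file does not conform to the expected on-disk format."""


class UnsupportedLayoutError(FormatError):
    """The file is syntactically valid but uses a layout we do not handle."""


class RangeError(RestAlphaError, ValueError):
    """A signal exceeds the declared physical range (no silent clipping)."""


class MontageError(RestAlphaError, KeyError):
    """A required electrode is missing from the montage or recording."""


class QualityError(RestAlphaError, RuntimeError):
    """Data quality is insufficient for the requested operation."""


class DegenerateDataError(RestAlphaError, ValueError):
    """The data are degenerate for the requested statistic (e.g. constant)."""
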