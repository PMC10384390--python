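"""Exception hierarchy shared across the package."""


class MRScanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRScanError):
    """A configuration problem: missing column mapping, missing sample sizes, ..."""


class InputError(MRScanError):
    """Malformed or empty input data."""


class ParameterError(MRScanError, ValueError):
    """An out-of-range or nonsensical parameter value."""


class InsufficientInstrumentsError(MRScanError):
    """Too few retained instruments for the requested method."""
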