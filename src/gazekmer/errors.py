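"""Exception hierarchy shared across the package."""


class GazeKmerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GazeKmerError):
    """A column mapping, AOI scheme or run configuration is invalid."""


class DataError(GazeKmerError):
    """Input data violates a structural precondition (order, type, missing fields)."""


class DegenerateDataError(DataError):
    """Data admits no defined statistic (e.g. zero variance where a ratio needs it)."""


class FitError(GazeKmerError):
    """A model fit is impossible on the given series."""
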