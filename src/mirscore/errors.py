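"""Exception hierarchy.

All package errors derive from :class:`MirscoreError` so callers can catch
one base class; subclasses distinguish bad inputs from bad configuration
from data that is simply insufficient for the requested statistic.
"""


class MirscoreError(Exception):
    """Base class for all errors raised by mirscore."""


class InputValidationError(MirscoreError, ValueError):
    """Malformed input data (bad Ct values, duplicate replicates, ...)."""


class ConfigurationError(MirscoreError, ValueError):
    """Inconsistent configuration (missing calibrator/normalizer, unknown marker, ...)."""


class MissingDataError(MirscoreError, ValueError):
    """A required group of measurements is empty after applying the censoring policy."""


class InsufficientDataError(MirscoreError, ValueError):
    """Too few observations for the requested statistic (e.g. n < 3 for Pearson r)."""


class DegenerateDataError(MirscoreError, ValueError):
    """Zero-variance or single-class data where the statistic is undefined."""
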