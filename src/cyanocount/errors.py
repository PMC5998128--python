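"""Exception and warning types shared across the pipeline."""


class CyanocountError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CyanocountError):
    """Unsupported or malformed image/file format."""


class ContractError(CyanocountError):
    """An operation was called with arguments violating its contract."""


class DegenerateImageError(CyanocountError):
    """The image admits no foreground/background split (e.g. constant)."""


class CalibrationError(CyanocountError):
    """Unit-cell-area calibration could not be performed."""


class GenerationError(CyanocountError):
    """A synthetic scene could not be realised under its constraints."""


class CompactnessWarning(UserWarning):
    """Compactness exceeded its theoretical bound of 1 (discretization)."""


class LowSampleWarning(UserWarning):
    """A statistic was estimated from fewer samples than recommended."""


class UndefinedMetricWarning(UserWarning):
    """A classification metric had a zero denominator and is undefined."""
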