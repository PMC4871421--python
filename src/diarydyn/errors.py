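"""Exception hierarchy for diarydyn.

All package errors derive from :class:`DiaryDynError` so callers can catch
one base class; the pipeline additionally distinguishes validation problems
(bad input data) from analysis exclusions (data that cannot support the
requested model).
"""


class DiaryDynError(Exception):
    """Base class for all diarydyn errors."""


class FormatError(DiaryDynError):
    """Input file is not parseable in the expected dialect."""


class ValidationError(DiaryDynError):
    """Input parsed but violates a data contract (range, duplicates...)."""


class ParameterError(DiaryDynError):
    """An argument is outside its admissible range."""


class DegenerateSeriesError(DiaryDynError):
    """A series is constant (or otherwise carries no usable variation)."""


class LengthError(DiaryDynError):
    """A series is too short for the requested operation."""


class RankError(DiaryDynError):
    """Design matrix is rank deficient (collinear or constant series)."""


class ImputationError(DiaryDynError):
    """Missing-value imputation is infeasible for this dataset."""


class NoStationaryWindowError(DiaryDynError):
    """No analysis window satisfying the stationarity gate exists."""


class StabilityError(DiaryDynError):
    """Operation requires a stable VAR but the model is not stable."""


class NoValidModelError(DiaryDynError):
    """No VAR order up to p_max passes the diagnostic checks."""


class UnsupportedDimensionError(DiaryDynError):
    """Operation is only defined for bivariate (K=2) systems."""


class ConfigError(DiaryDynError):
    """A synthetic-scenario or pipeline configuration is inconsistent."""


class BootstrapError(DiaryDynError):
    """Too many bootstrap replicates failed re-estimation."""
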