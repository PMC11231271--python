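"""Exception hierarchy for the carbonsplit pipeline.

Every stage raises a subclass of :class:`CarbonSplitError`, so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class CarbonSplitError(Exception):
    """Base class for all carbonsplit errors."""


class ConfigError(CarbonSplitError):
    """Invalid configuration (bad value, overlapping periods, windows out of range)."""


class SchemaError(CarbonSplitError):
    """An input table is missing a required column or has the wrong layout."""


class IntegrityError(CarbonSplitError):
    """An input table violates a structural invariant (duplicate or unordered dates)."""


class AlignmentError(CarbonSplitError):
    """Two inputs that must share a date range do not overlap or are misaligned."""


class SpatialSelectionError(CarbonSplitError):
    """A bounding box selects no grid cells."""


class InsufficientDataError(CarbonSplitError):
    """Too few rows to fit a model or compute a statistic."""


class DegenerateInputError(CarbonSplitError):
    """Zero-variance or otherwise degenerate input to a fit."""


class FeatureError(CarbonSplitError):
    """A requested feature is not part of the fitted model."""


class MissingBaselineError(CarbonSplitError):
    """A calendar month required for baseline comparison has no baseline data."""


class StageError(CarbonSplitError):
    """A pipeline stage failed; carries the stage name and underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
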