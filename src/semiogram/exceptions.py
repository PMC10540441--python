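"""Exception hierarchy for gait-analysis failures.

Every data-dependent failure raises a :class:`GaitError` subclass so callers
(and the CLI) can separate bad input from programming errors.
"""


class GaitError(ValueError):
    """Base class for all gait-analysis data errors."""


class IncompleteSensorSetError(GaitError):
    """A required sensor site (left_foot, right_foot, lower_back) is missing."""


class UnorderedSamplesError(GaitError):
    """Timestamps in an input file are not strictly increasing."""


class CorruptStreamError(GaitError):
    """More than the tolerated fraction of samples is non-finite."""


class InsufficientGaitError(GaitError):
    """Too few gait events detected to analyse the trial."""


class NoUTurnError(GaitError):
    """No half-revolution of the trunk found in the recording."""


class DegenerateSegmentationError(GaitError):
    """The U-turn/stride segmentation leaves no usable walking data."""


class DegenerateSignalError(GaitError):
    """A signal is identically zero or otherwise unusable for a parameter."""


class InsufficientDataError(GaitError):
    """Not enough strides/values/subjects for the requested statistic."""
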