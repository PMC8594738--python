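"""Exception hierarchy for the gait-phase pipeline.

Each stage family raises a distinct subclass so callers (and the CLI's exit
codes) can tell a malformed file from a bad filter spec from a degenerate
dataset.
"""


class GaitFuseError(Exception):
    """Base class for all package errors."""


class ChannelError(GaitFuseError):
    """A named channel is missing, duplicated, or unknown."""


class SamplingError(GaitFuseError):
    """Timestamps are absent, empty, or not uniform within tolerance."""


class AlignmentError(GaitFuseError):
    """Multi-rate streams cannot be reconciled (non-integer rate ratio,
    gross length mismatch between feature and angle streams, ...)."""


class FilterSpecError(GaitFuseError):
    """Filter specification is invalid for the given sampling rate."""


class ConfigError(GaitFuseError):
    """A configuration value is out of its legal range."""


class DataError(GaitFuseError):
    """Model input/label data are malformed (shape, length, class codes)."""


class SplitError(GaitFuseError):
    """Dataset too small or fractions invalid for the requested split."""
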