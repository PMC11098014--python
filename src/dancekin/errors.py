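"""Exception hierarchy.

Every error raised by dancekin derives from :class:`DancekinError`, so callers
(and the CLI) can distinguish configuration, data, and computation failures.
"""


class DancekinError(Exception):
    """Base class for all dancekin errors."""


class ConfigError(DancekinError):
    """Invalid configuration (bad smoothing window, bad split fraction, ...)."""


class LayoutError(ConfigError):
    """A required joint role is missing from the skeleton layout."""


class DataError(DancekinError):
    """Input data is malformed (non-finite values, schema mismatch, ...)."""


class LengthError(DataError):
    """A sequence or series is too short for the requested computation."""


class AlignmentError(DataError):
    """Arrays that must share a frame range do not."""


class SplitError(DataError):
    """The dataset cannot be split as requested (e.g. no advanced sequences)."""


class LabelError(DataError):
    """A label falls outside the known vocabulary."""


class SchemaError(DataError):
    """Feature keys or class vocabularies do not match."""


class FeatureError(DancekinError):
    """A feature computation failed; the message names the feature."""


class OracleDomainError(DancekinError):
    """A motion spec lies outside the validity domain of the analytic oracles."""
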