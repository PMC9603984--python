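"""Exception hierarchy for the orgaswell pipeline.

Every stage raises a subclass of :class:`OrgaswellError`, so callers (and the
CLI) can catch one type and still report which stage and which records failed.
"""


class OrgaswellError(Exception):
    """Base class for all orgaswell errors."""


class ConfigurationError(OrgaswellError):
    """An invalid configuration field; the message names the field."""


class InvalidBoxError(OrgaswellError):
    """A bounding box with zero or negative extent."""


class DataError(OrgaswellError):
    """Malformed input records (duplicates, missing columns, out-of-range)."""


class UnfittableTrackError(OrgaswellError):
    """A track with fewer than two distinct-frame observations."""


class DegeneratePlateError(OrgaswellError):
    """A plate whose reference wells have zero IQR; names the plate."""


class InsufficientWellsError(OrgaswellError):
    """Fewer eligible wells than required for plate normalization."""


class LayoutError(OrgaswellError):
    """A well referenced by the data has no layout entry."""


class TraceError(OrgaswellError):
    """A trace too short or ill-formed for the requested computation."""
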