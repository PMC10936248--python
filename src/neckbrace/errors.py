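"""Exception hierarchy shared by all neckbrace modules.

``NeckbraceError`` is the common base so callers (and the CLI) can map any
library failure to a data-error exit code with a single except clause.
"""


class NeckbraceError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(NeckbraceError):
    """Arguments violate a documented precondition (non-finite, empty, ...)."""


class SchemaError(NeckbraceError):
    """A file or record is missing required columns/labels or has bad shape."""


class DegenerateGeometryError(NeckbraceError):
    """Geometry too degenerate to proceed (collinear markers, coplanar cloud)."""


class DegenerateFitError(NeckbraceError):
    """A regression problem is rank deficient (e.g. constant sensor voltage)."""


class SynchronizationError(NeckbraceError):
    """Trigger edges missing or streams cannot be aligned."""


class SegmentationError(NeckbraceError):
    """Movement-cycle segmentation preconditions violated."""


class GenerationError(NeckbraceError):
    """The synthetic generator cannot realise the requested session."""


class ConfigError(NeckbraceError):
    """Configuration file invalid or internally inconsistent."""
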