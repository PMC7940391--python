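"""Exception hierarchy for parcstd.

All package-specific errors derive from :class:`ParcstdError` so callers can
catch one base class; the CLI maps them onto exit codes.
"""


class ParcstdError(Exception):
    """Base class for all parcstd errors."""


class FormatError(ParcstdError):
    """A file could not be read as the expected on-disk format."""


class InvalidLabelError(ParcstdError):
    """Voxel values cannot be interpreted as integer region labels."""


class DimensionalityError(ParcstdError):
    """An image does not have the required 3-D single-volume layout."""


class CapacityError(ParcstdError):
    """A label exceeds the capacity of the chosen on-disk integer type."""


class GridMismatchError(ParcstdError):
    """Two volumes do not share one voxel grid (shape and affine)."""


class ParameterError(ParcstdError):
    """An operation parameter is out of its valid range."""


class DegenerateParameterError(ParameterError):
    """Parameters produce a degenerate (e.g. empty) geometric object."""


class NamingConventionError(ParcstdError):
    """A filename does not follow the atlas naming convention."""


class MetadataError(ParcstdError):
    """An atlas metadata document violates the sidecar schema."""


class ConsistencyError(ParcstdError):
    """Cross-object consistency violated (e.g. unknown label referenced)."""
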