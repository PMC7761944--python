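"""Exception hierarchy.

Errors are grouped so the CLI can map them onto distinct exit codes:
configuration problems, bad input data, geometric failures and
topological failures are told apart by their base class.
"""


class ToothWearError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ToothWearError):
    """Missing/invalid configuration: unknown technique, missing label, bad key."""


class InvalidInputError(ToothWearError):
    """Input data violates a precondition (empty mesh, bad indices, ...)."""


class MeshFormatError(InvalidInputError):
    """File is unreadable or not a supported mesh format."""


class InvalidSpecError(InvalidInputError):
    """A synthetic-data spec is out of its valid range."""


class DegenerateInputError(InvalidInputError):
    """Geometrically degenerate input (collinear landmarks, <3 pairs, ...)."""


class GeometryError(ToothWearError):
    """A geometric operation failed (self-intersecting cap polygon, ...)."""


class EmptyPartError(GeometryError):
    """Slicing removed the whole mesh."""


class CannotIsolateError(GeometryError):
    """The changed region cannot be isolated by admissible slicing planes."""


class PlacementError(GeometryError):
    """A synthetic element (retainer wire) could not be placed on the surface."""


class TopologyError(ToothWearError):
    """Mesh connectivity violates a requirement (non-manifold edge, open part)."""


class NoCorrespondenceError(ToothWearError):
    """Every ICP correspondence was rejected (e.g. all on overhangs)."""


class GenerationError(ToothWearError):
    """The synthetic generator could not produce valid geometry."""
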