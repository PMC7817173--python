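"""Exception hierarchy shared across clonedyn modules."""


class CloneDynError(Exception):
    """Base class for all clonedyn errors."""


class InvalidInputError(CloneDynError, ValueError):
    """An argument violates a documented precondition."""


class EmptySelectionError(CloneDynError, ValueError):
    """A filter or selection matched zero records where at least one is required."""


class InsufficientReplicatesError(CloneDynError, ValueError):
    """Too few replicates (animals) to run the requested statistical test."""


class DegenerateGeometryError(CloneDynError, ValueError):
    """Geometry input is degenerate (collinear, duplicate, or too few points)."""


class ValidationError(CloneDynError, ValueError):
    """A table failed schema validation; message names the row and column."""


class LatticeBoundaryError(CloneDynError, RuntimeError):
    """A simulated clone reached the lattice boundary; the run was halted."""
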