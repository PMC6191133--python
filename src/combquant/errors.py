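"""Exception hierarchy for comb-frame quantification."""


class CombQuantError(Exception):
    """Base class for all package errors."""


class InvalidImageError(CombQuantError):
    """Raised when a raster does not satisfy the expected shape/dtype contract."""


class InvalidGeometryError(CombQuantError):
    """Raised for degenerate or self-intersecting polygons."""


class InvalidAnnotationError(CombQuantError):
    """Raised when an annotation document violates its schema or label set."""


class InvalidSpecError(CombQuantError):
    """Raised when a synthetic scene specification violates its invariants."""


class InsufficientDetectionsError(CombQuantError):
    """Raised when an operation needs at least two detected cell centres."""


class DegenerateSampleError(CombQuantError):
    """Raised when a paired sample has no non-zero differences."""


class UndefinedCorrelationError(CombQuantError):
    """Raised when a correlation is requested on zero-variance data."""
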