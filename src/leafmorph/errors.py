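"""Exception hierarchy for leafmorph.

Error messages mirror the contract strings used throughout the docs
("empty segmentation", "ambiguous boundary", ...), so callers can match on
type rather than parse text.
"""


class LeafMorphError(Exception):
    """Base class for all leafmorph errors."""


class EmptySegmentationError(LeafMorphError):
    """Binarisation produced zero foreground pixels."""


class SegmentationFailureError(LeafMorphError):
    """Foreground is implausible (e.g. touches all four image borders)."""


class AmbiguousBoundaryError(LeafMorphError):
    """Boundary tracing requires exactly one foreground component."""


class InvalidCentroidError(LeafMorphError):
    """A signature was requested with a centroid outside the foreground."""


class InsufficientMaximaError(LeafMorphError):
    """Fewer than two local maxima; vertex-fan construction impossible."""


class DegenerateFanError(LeafMorphError):
    """All vertex angles equal (regular polygon); no pole structure."""


class PoleSelectionError(LeafMorphError):
    """North/south pole selection failed (a region is empty)."""


class VeinUndetectableError(LeafMorphError):
    """No mid-vein pixels found in either pole window."""


class IncompleteCCGError(LeafMorphError):
    """A CCG ray missed the contour segment.

    ``missing`` holds the interval angles (degrees) with no boundary point.
    """

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"incomplete CCG: no boundary point at angles {self.missing}")


class DegenerateToothError(LeafMorphError):
    """Tooth peak and valleys are collinear; measurements undefined."""


class InvalidSpecError(LeafMorphError):
    """Synthetic leaf specification is geometrically infeasible."""


class EvaluationError(LeafMorphError):
    """Classification evaluation inputs are inconsistent."""
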