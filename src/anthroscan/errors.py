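"""Exception hierarchy for the scan-processing pipeline.

Every stage raises a subclass of :class:`ScanError` so callers (and the CLI)
can attach site/stage context and map failures to exit codes uniformly.
"""


class ScanError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ScanError):
    """Unreadable file or unsupported mesh format."""


class EmptyMeshError(ScanError):
    """Mesh has too little geometry to process (< 4 vertices or faces)."""


class UnitInferenceError(ScanError):
    """Bounding-box height is outside every plausible stature band."""


class AlignmentError(ScanError):
    """Degenerate geometry: principal axes are not defined."""


class DegeneratePolygonError(ScanError):
    """A section loop has fewer than 3 non-collinear points."""


class LandmarkError(ScanError):
    """Base class for landmark-detection failures."""


class MissingLimbError(LandmarkError):
    """One body side has no vertices in the foot region."""


class LegsNotSeparableError(LandmarkError):
    """No transverse band with two disjoint leg loops (fused thighs)."""


class ArmsNotSeparableError(LandmarkError):
    """Arm loop never separates from the torso loop (arm pressed to trunk)."""


class ShoulderNotFoundError(LandmarkError):
    """Empty shoulder search cylinder above an armpit, even after widening."""


class SegmentationError(ScanError):
    """Body partition failed (wrong leg component count, empty arm, ...)."""


class AxisUndefinedError(ScanError):
    """Limb segment is not elongated enough to define a principal axis."""


class SiteNotFoundError(ScanError):
    """No section plane in the requested band intersects the segment."""


class MeasurementError(ScanError):
    """A measurement-set invariant was violated."""


class SampleSizeError(ScanError):
    """Too few paired observations for the requested statistic."""


class RegressionError(ScanError):
    """Zero predictor variance: ordinary least squares is undefined."""


class SpecError(ScanError):
    """Invalid synthetic avatar specification."""


class DegradationError(ScanError):
    """Requested degradation would disconnect the mesh."""
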