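"""End-to-end scan processing: load → repair → landmarks → measurements."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .landmarks import LandmarkSet, detect_landmarks
from .measure import MeasurementSet, measure_all
from .meshes import (
    RepairReport,
    TriMesh,
    canonicalize,
    fill_holes,
    load_mesh,
    repair,
)
from .segmentation import BodySegments, segment_body


@dataclass
class PipelineResult:
    """Everything one scan produces."""

    mesh: TriMesh
    landmarks: LandmarkSet
    segments: BodySegments
    measurements: MeasurementSet
    repair_report: RepairReport
    fill_report: RepairReport


def process_scan(source, units: str = "auto", rules=None,
                 perimeter_mode: str = "hull") -> PipelineResult:
    """Run the full measurement pipeline on a mesh file or :class:`TriMesh`.

    The stages mirror how a scan moves through the system: canonical
    alignment, face cleanup, hole filling, landmark detection, body
    segmentation, and the eleven circumference measurements.
    """
    if isinstance(source, (str, Path)):
        mesh = load_mesh(source, units=units)
    else:
        mesh = source
    mesh = canonicalize(mesh)
    mesh, repair_report = repair(mesh)
    mesh, fill_report = fill_holes(mesh)
    lm = detect_landmarks(mesh)
    segments = segment_body(mesh, lm)
    measurements = measure_all(mesh, rules=rules, lm=lm, segments=segments,
                               perimeter_mode=perimeter_mode)
    return PipelineResult(
        mesh=mesh, landmarks=lm, segments=segments,
        measurements=measurements, repair_report=repair_report,
        fill_report=fill_report,
    )
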