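"""Partition a scan into left/right arms, left/right legs and center body.

Legs are everything below the horizontal plane through the crotch landmark,
split left/right by the sign of each connected patch's centroid x.  Each arm
is cut off by the plane spanned by the shoulder-to-armpit segment and the
anterior-posterior axis: arm faces lie lateral to that plane and connect to
the distal arm tip.  Everything else — trunk, neck, head — is "center".

Faces are never split: a face straddling a cut plane is assigned by its
centroid, which keeps the partition an exact disjoint cover of the face set
at the cost of one-face-width boundary jitter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import SegmentationError
from .landmarks import LandmarkSet
from .meshes import TriMesh, face_components, save_mesh

SEGMENT_NAMES = ("arm_left", "arm_right", "leg_left", "leg_right", "center")

#: a leg patch whose centroid is closer than this to the sagittal plane
#: cannot be assigned a side
_SIDE_TOL = 0.5  # cm


@dataclass
class BodySegments:
    """Disjoint face-index partition of a scan, plus the cut planes used."""

    arm_left: np.ndarray
    arm_right: np.ndarray
    leg_left: np.ndarray
    leg_right: np.ndarray
    center: np.ndarray
    cut_planes: dict  # name -> (origin, unit normal)
    n_faces: int

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in SEGMENT_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in SEGMENT_NAMES}

    def labels(self) -> np.ndarray:
        """Per-face segment label array."""
        out = np.empty(self.n_faces, dtype=object)
        for name, idx in self.as_dict().items():
            out[idx] = name
        return out

    def validate(self) -> None:
        parts = [getattr(self, name) for name in SEGMENT_NAMES]
        total = np.concatenate(parts)
        if len(total) != self.n_faces or len(np.unique(total)) != self.n_faces:
            raise SegmentationError("segments are not a disjoint cover of "
                                    "the face set")

    def to_label_csv(self, path) -> None:
        labels = self.labels()
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["face_index", "label"])
            for i, lab in enumerate(labels):
                w.writerow([i, lab])

    def export_objs(self, mesh: TriMesh, out_dir) -> list:
        """Write one OBJ per segment; returns the paths written."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, idx in self.as_dict().items():
            sub = mesh.to_trimesh().submesh([idx], append=True)
            p = out_dir / f"segment_{name}.obj"
            save_mesh(TriMesh.from_trimesh(sub, mesh.frame), p)
            paths.append(p)
        return paths


def _arm_cut_plane(lm: LandmarkSet, side: str):
    """Plane through the shoulder–armpit segment spanning the y axis,
    with the normal pointing laterally (toward that side's arm)."""
    sh = getattr(lm, "shoulder_" + side)
    ap = getattr(lm, "armpit_" + side)
    normal = np.cross(sh - ap, np.array([0.0, 1.0, 0.0]))
    nn = np.linalg.norm(normal)
    if nn < 1e-9:
        raise SegmentationError(f"degenerate shoulder–armpit axis on the "
                                f"{side} side")
    normal = normal / nn
    sign = 1.0 if side == "left" else -1.0
    if normal[0] * sign < 0:
        normal = -normal
    return ap.astype(float), normal


def segment_body(mesh: TriMesh, lm: LandmarkSet) -> BodySegments:
    """Partition the faces of a canonical watertight scan.

    Raises :class:`SegmentationError` when the legs below the crotch plane
    do not resolve into a left and a right group, or when an arm cut yields
    no faces.
    """
    tm = mesh.to_trimesh()
    cent = mesh.face_centroids()
    n_faces = len(mesh.faces)
    z_crotch = float(lm.crotch[2])

    taken = np.zeros(n_faces, dtype=bool)
    segments = {}

    # ---- legs: connected patches below the crotch plane, by centroid side
    below = cent[:, 2] < z_crotch - 1e-9
    comps = face_components(tm, np.flatnonzero(below))
    sides = {"leg_left": [], "leg_right": []}
    for comp in comps:
        cx = cent[comp, 0].mean()
        if abs(cx) < _SIDE_TOL:
            # patches straddling the sagittal plane just below the crotch
            # cut are trunk remnants, not legs; they stay in "center"
            continue
        sides["leg_left" if cx > 0 else "leg_right"].append(comp)
    for name, patches in sides.items():
        if not patches:
            raise SegmentationError(
                f"expected leg components on both sides below the crotch "
                f"plane; {name} is empty")
        idx = np.concatenate(patches)
        segments[name] = np.sort(idx)
        taken[idx] = True

    # ---- arms: lateral of the shoulder–armpit plane, connected to the tip
    planes = {
        "crotch": (np.array([0.0, 0.0, z_crotch]), np.array([0.0, 0.0, 1.0])),
    }
    for side in ("left", "right"):
        origin, normal = _arm_cut_plane(lm, side)
        planes["arm_" + side] = (origin, normal)
        planes["armpit_level_" + side] = (
            getattr(lm, "armpit_" + side).astype(float),
            np.array([0.0, 0.0, 1.0]),
        )
        lateral = ((cent - origin) @ normal > 0) & ~taken
        cand = np.flatnonzero(lateral)
        if cand.size == 0:
            raise SegmentationError(f"no faces lateral of the {side} arm "
                                    f"cut plane")
        comps = face_components(tm, cand)
        sign = 1.0 if side == "left" else -1.0
        # the arm is the patch containing the distal tip: the hand is the
        # most lateral point of an A-pose body, which keeps trunk slivers
        # caught by the tilted cut plane out of the arm
        reach = [(cent[c, 0] * sign).max() for c in comps]
        arm = comps[int(np.argmax(reach))]
        segments["arm_" + side] = np.sort(arm)
        taken[arm] = True

    segments["center"] = np.flatnonzero(~taken)
    if segments["center"].size == 0:
        raise SegmentationError("center segment is empty")

    out = BodySegments(
        arm_left=segments["arm_left"], arm_right=segments["arm_right"],
        leg_left=segments["leg_left"], leg_right=segments["leg_right"],
        center=segments["center"], cut_planes=planes, n_faces=n_faces,
    )
    out.validate()
    return out
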