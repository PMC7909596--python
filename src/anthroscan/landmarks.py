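"""Anatomical landmark detection on a canonical, watertight scan.

Seven surface landmarks anchor segmentation and measurement: the crotch,
and the left/right armpits, shoulders and feet.  Only superficial geometry
is available from an optical scan, so every detector works from transverse
cross-sections or vertex extrema:

* **feet** — lowest vertex on each side of the sagittal plane;
* **crotch** — the height where the two leg contours of a transverse
  section merge into a single central body contour, refined by bisection;
* **armpits** — per side, the highest section showing an arm contour
  strictly separate from (disjoint with) the torso contour, refined by
  bisection;
* **shoulders** — highest vertex in a vertical search cylinder above each
  armpit.

All tie-breaks are deterministic, so identical meshes give bit-identical
landmark sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point

from .errors import (
    ArmsNotSeparableError,
    LandmarkError,
    LegsNotSeparableError,
    MissingLimbError,
    ShoulderNotFoundError,
)
from .meshes import TriMesh, plane_to_world, section_polygons, world_to_plane

#: search bands as fractions of body height
CROTCH_BAND = (0.25, 0.60)
ARMPIT_BAND = (0.55, 0.90)
COARSE_STEP = 0.5  # cm
REFINE_TOL = 0.1   # cm (1 mm bisection refinement)
SHOULDER_RADIUS = 3.0  # cm

#: minimum clearance between leg contours for the legs to count as separable
LEG_CLEARANCE = 0.2  # cm

#: contours smaller than this cannot be limb cross-sections; filters the
#: spurious fragments a plane produces when grazing a noisy near-horizontal
#: surface patch
MIN_LIMB_AREA = 10.0  # cm^2

# deterministic sub-resolution offset keeping probe planes off the exact
# vertex rings / caps of structured meshes
_PROBE_EPS = 1.2345e-4


@dataclass
class LandmarkSet:
    """The seven anatomical landmarks, canonical-frame cm coordinates."""

    crotch: np.ndarray
    armpit_left: np.ndarray
    armpit_right: np.ndarray
    shoulder_left: np.ndarray
    shoulder_right: np.ndarray
    foot_left: np.ndarray
    foot_right: np.ndarray

    def as_dict(self) -> dict:
        return {k: np.asarray(v, dtype=float)
                for k, v in self.__dict__.items()}

    def to_json(self) -> str:
        return json.dumps({k: list(map(float, v))
                           for k, v in self.as_dict().items()}, indent=2)

    def validate(self) -> None:
        for side in ("left", "right"):
            foot = self.__dict__["foot_" + side]
            ap = self.__dict__["armpit_" + side]
            sh = self.__dict__["shoulder_" + side]
            if not (foot[2] <= self.crotch[2] < ap[2] <= sh[2]):
                raise LandmarkError(
                    f"vertical ordering violated on {side} side: "
                    f"foot {foot[2]:.1f} <= crotch {self.crotch[2]:.1f} < "
                    f"armpit {ap[2]:.1f} <= shoulder {sh[2]:.1f} fails"
                )
            sign = 1.0 if side == "left" else -1.0
            for name, p in (("armpit", ap), ("shoulder", sh), ("foot", foot)):
                if p[0] * sign <= 0:
                    raise LandmarkError(
                        f"{name}_{side} is on the wrong side (x={p[0]:.1f})")


class _Loop:
    """One closed contour of a transverse section, with world geometry."""

    __slots__ = ("poly", "world", "centroid", "area")

    def __init__(self, poly, to_3d):
        self.poly = poly
        pts2d = np.asarray(poly.exterior.coords)[:-1]
        self.world = plane_to_world(pts2d, to_3d)
        c = poly.centroid
        self.centroid = plane_to_world(np.array([[c.x, c.y]]), to_3d)[0]
        self.area = poly.area


def _slices(mesh: TriMesh, heights):
    """Transverse section loops at the given z heights (None = plane missed)."""
    res = section_polygons(mesh, (0.0, 0.0, 0.0), (0.0, 0.0, 1.0), heights)
    out = []
    for entry in res:
        if entry is None:
            out.append(None)
            continue
        polys, to_3d = entry
        out.append(([_Loop(p, to_3d) for p in polys], to_3d))
    return out

def _slice_one(mesh: TriMesh, z: float):
    return _slices(mesh, [z])[0]


def _central_loop(loops, to_3d, z):
    """The torso-column loop: hull contains the point (0, y_centroid, z)."""
    total = sum(lp.area for lp in loops)
    if total <= 0:
        return None
    y_ref = sum(lp.area * lp.centroid[1] for lp in loops) / total
    target = Point(world_to_plane((0.0, y_ref, z), to_3d))
    best = None
    for lp in loops:
        if lp.poly.convex_hull.covers(target):
            if best is None or lp.area > best.area:
                best = lp
    return best


def _check_canonical(mesh: TriMesh) -> None:
    if mesh.frame != "canonical":
        raise LandmarkError("landmark detection requires a canonical mesh; "
                            "call canonicalize() first")


# ---------------------------------------------------------------------------
# individual detectors
# ---------------------------------------------------------------------------

def detect_feet(mesh: TriMesh):
    """Lowest vertex on each side of the sagittal plane x = 0.

    Ties are broken by smallest ``|x|`` then lexicographic (x, y).
    Returns ``(left, right)``.
    """
    _check_canonical(mesh)
    V = mesh.vertices
    zmin, H = V[:, 2].min(), mesh.height
    out = {}
    for side, mask in (("left", V[:, 0] > 0), ("right", V[:, 0] < 0)):
        Vs = V[mask]
        low = Vs[Vs[:, 2] < zmin + 0.10 * H]
        if len(low) == 0:
            raise MissingLimbError(f"no vertices below 10% height on the "
                                   f"{side} side")
        z0 = low[:, 2].min()
        cand = low[np.abs(low[:, 2] - z0) < 1e-9]
        order = np.lexsort((cand[:, 1], cand[:, 0], np.abs(cand[:, 0])))
        out[side] = cand[order[0]].copy()
    return out["left"], out["right"]


def detect_crotch(mesh: TriMesh) -> np.ndarray:
    """Leg-merge transition height, bisection-refined to 1 mm.

    The crotch is the lowest height z* whose transverse section contains a
    single central contour while the section just below shows two separate
    leg contours; the returned point is the midpoint between the two leg
    contours lifted to z*.
    """
    _check_canonical(mesh)
    z0 = mesh.bounds[0, 2]
    H = mesh.height
    lo_band = z0 + CROTCH_BAND[0] * H
    hi_band = z0 + CROTCH_BAND[1] * H
    heights = np.arange(lo_band, hi_band, COARSE_STEP) + _PROBE_EPS
    slices = _slices(mesh, heights)

    def central_at(i):
        if slices[i] is None:
            return None
        loops, to_3d = slices[i]
        return _central_loop(loops, to_3d, heights[i])

    first = None
    for i in range(len(heights)):
        if central_at(i) is not None:
            first = i
            break
    if first is None or first == 0:
        raise LegsNotSeparableError(
            "no transverse band with two separate leg contours found; "
            "legs may be fused or the scan band is empty"
        )
    # sanity of the two-loop side of the bracket
    loops, _ = slices[first - 1]
    legs = _two_leg_loops(loops)
    if legs is None or legs[0].poly.distance(legs[1].poly) <= LEG_CLEARANCE:
        raise LegsNotSeparableError("leg contours below the crotch touch or "
                                    "overlap; legs are not separable")

    lo, hi = heights[first - 1], heights[first]
    legs_lo = legs
    while hi - lo > REFINE_TOL:
        mid = 0.5 * (lo + hi) + _PROBE_EPS * 0.1
        entry = _slice_one(mesh, mid)
        central = None
        if entry is not None:
            loops, to_3d = entry
            central = _central_loop(loops, to_3d, mid)
        if central is not None:
            hi = mid
        else:
            lo = mid
            if entry is not None:
                cand = _two_leg_loops(entry[0])
                if cand is not None:
                    legs_lo = cand
    mid_xy = 0.5 * (legs_lo[0].centroid + legs_lo[1].centroid)
    return np.array([mid_xy[0], mid_xy[1], hi])


def _two_leg_loops(loops):
    """Largest substantial contour on each side of the sagittal plane."""
    left = right = None
    for lp in loops:
        if lp.area < MIN_LIMB_AREA:
            continue
        if lp.centroid[0] > 0.5:
            if left is None or lp.area > left.area:
                left = lp
        elif lp.centroid[0] < -0.5:
            if right is None or lp.area > right.area:
                right = lp
    if left is None or right is None:
        return None
    return left, right


def _arm_loop(loops, to_3d, z, sign):
    """The separate arm contour on one side, if any: lateral of the torso
    contour and strictly disjoint from it."""
    central = _central_loop(loops, to_3d, z)
    if central is None:
        return None
    torso_max = np.abs(central.world[:, 0]).max()
    best = None
    for lp in loops:
        if lp is central or lp.centroid[0] * sign <= 0:
            continue
        if lp.area < MIN_LIMB_AREA:
            continue
        # limb sections are near-convex; planes grazing noisy flat caps emit
        # large but wavy ring-band fragments with low solidity
        hull_area = lp.poly.convex_hull.area
        if hull_area <= 0 or lp.area / hull_area < 0.6:
            continue
        if abs(lp.centroid[0]) <= torso_max - 1.0:
            continue
        if not lp.poly.disjoint(central.poly):
            continue
        if best is None or lp.area > best.area:
            best = lp
    return best


def detect_armpits(mesh: TriMesh):
    """Per side, the highest transverse section with a separate arm contour.

    Bisection-refined to 1 mm; the returned point is the medial-most contour
    point of the arm loop just below the merge height.
    Returns ``(left, right)``.
    """
    _check_canonical(mesh)
    z0 = mesh.bounds[0, 2]
    H = mesh.height
    lo_band = z0 + ARMPIT_BAND[0] * H
    hi_band = z0 + ARMPIT_BAND[1] * H
    heights = np.arange(hi_band, lo_band, -COARSE_STEP) + _PROBE_EPS
    slices = _slices(mesh, heights)

    def present(i, sign):
        if i >= len(heights) or slices[i] is None:
            return False
        loops, to_3d = slices[i]
        return _arm_loop(loops, to_3d, heights[i], sign) is not None

    out = {}
    for side, sign in (("left", 1.0), ("right", -1.0)):
        first = None
        for i in range(len(heights)):
            # the arm must persist over ~1 cm of height: fragments from a
            # plane grazing noisy near-horizontal geometry do not
            if (present(i, sign) and present(i + 1, sign)
                    and present(i + 2, sign)):
                first = i
                break
        if first is None:
            raise ArmsNotSeparableError(
                f"{side} arm never separates from the torso in the scan band")
        loops, to_3d = slices[first]
        arm = _arm_loop(loops, to_3d, heights[first], sign)
        lo = heights[first]
        hi = heights[first - 1] if first > 0 else hi_band
        while hi - lo > REFINE_TOL:
            mid = 0.5 * (lo + hi) + _PROBE_EPS * 0.1
            entry = _slice_one(mesh, mid)
            cand = None
            if entry is not None:
                cand = _arm_loop(entry[0], entry[1], mid, sign)
            if cand is not None:
                lo, arm = mid, cand
            else:
                hi = mid
        medial = arm.world[np.argmin(np.abs(arm.world[:, 0]))]
        out[side] = medial.copy()
    return out["left"], out["right"]


def detect_shoulders(mesh: TriMesh, armpits):
    """Highest vertex in a search cylinder above each armpit.

    The cylinder radius is widened once (doubled) before failing.  Ties are
    broken by horizontal proximity to the armpit, then lexicographically.
    Returns ``(left, right)``.
    """
    _check_canonical(mesh)
    V = mesh.vertices
    out = []
    for ap in armpits:
        found = None
        for r in (SHOULDER_RADIUS, 2.0 * SHOULDER_RADIUS):
            d2 = (V[:, 0] - ap[0]) ** 2 + (V[:, 1] - ap[1]) ** 2
            cand = V[d2 <= r * r]
            if len(cand):
                z1 = cand[:, 2].max()
                top = cand[np.abs(cand[:, 2] - z1) < 1e-9]
                prox = ((top[:, 0] - ap[0]) ** 2 + (top[:, 1] - ap[1]) ** 2)
                order = np.lexsort((top[:, 1], top[:, 0], prox))
                found = top[order[0]].copy()
                break
        if found is None:
            raise ShoulderNotFoundError(
                f"no vertices within {2 * SHOULDER_RADIUS:.0f} cm of the "
                f"armpit column at ({ap[0]:.1f}, {ap[1]:.1f})")
        out.append(found)
    return out[0], out[1]


def detect_landmarks(mesh: TriMesh) -> LandmarkSet:
    """Run all detectors and validate the landmark-set invariants."""
    foot_l, foot_r = detect_feet(mesh)
    crotch = detect_crotch(mesh)
    ap_l, ap_r = detect_armpits(mesh)
    sh_l, sh_r = detect_shoulders(mesh, (ap_l, ap_r))
    lm = LandmarkSet(
        crotch=crotch,
        armpit_left=ap_l, armpit_right=ap_r,
        shoulder_left=sh_l, shoulder_right=sh_r,
        foot_left=foot_l, foot_right=foot_r,
    )
    lm.validate()
    return lm
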