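"""Locate the eleven circumference sites and compute tape-analog values.

Trunk sites (chest, waist, hip) are measured on transverse sections of the
center body, swept over a band normalized on the crotch-to-armpit span;
limb sites are measured in planes perpendicular to the limb's principal
axis, which in an A-pose scan sits at roughly 45 degrees to the vertical
for the arms.  A site rule is either

* ``extremum`` — sweep planes over the band and keep the one whose contour
  hull perimeter is minimal (waist, ankles) or maximal (chest, hip, calves);
* ``fixed_fraction`` — slice exactly at a normalized position along the
  segment axis (upper arms, thighs).

Palpation-based site definitions (intercostal spaces, the ilium border,
the patella) are unobservable on surface scans; the default bands and
fractions below are this package's geometric conventions for them and are
fully configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point

from .errors import (
    AxisUndefinedError,
    MeasurementError,
    SiteNotFoundError,
)
from .landmarks import LandmarkSet, detect_landmarks
from .meshes import TriMesh, section_polygons, world_to_plane, plane_to_world
from .segmentation import BodySegments, segment_body

#: sweep spacing for extremum rules, cm
SWEEP_STEP = 0.2

# deterministic offset keeping planes off exact vertex rings
_PROBE_EPS = 1.2345e-4


@dataclass
class SiteRule:
    """How one named circumference site is located."""

    site: str
    segment: str            # center | arm_left | arm_right | leg_left | leg_right
    mode: str               # "extremum" | "fixed_fraction"
    band: tuple = (0.0, 1.0)
    objective: str | None = None   # "min" | "max" for extremum rules
    fraction: float | None = None  # for fixed_fraction rules

    def validate(self) -> None:
        lo, hi = self.band
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"{self.site}: band must satisfy 0 <= lo < hi <= 1")
        if self.mode == "extremum":
            if self.objective not in ("min", "max"):
                raise ValueError(f"{self.site}: extremum rule needs objective "
                                 "'min' or 'max'")
        elif self.mode == "fixed_fraction":
            if self.fraction is None or not (lo <= self.fraction <= hi):
                raise ValueError(f"{self.site}: fraction must lie in the band")
        else:
            raise ValueError(f"{self.site}: unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        return {
            "site": self.site, "segment": self.segment, "mode": self.mode,
            "band": list(self.band), "objective": self.objective,
            "fraction": self.fraction,
        }


def default_rules() -> list:
    """The package's standard digital site conventions."""
    rules = [
        SiteRule("chest", "center", "extremum", (0.70, 1.00), "max"),
        SiteRule("waist", "center", "extremum", (0.35, 0.70), "min"),
        SiteRule("hip", "center", "extremum", (0.00, 0.35), "max"),
    ]
    for side in ("left", "right"):
        rules += [
            SiteRule(f"upper_arm_{side}", f"arm_{side}", "fixed_fraction",
                     (0.0, 1.0), fraction=0.25),
            SiteRule(f"thigh_{side}", f"leg_{side}", "fixed_fraction",
                     (0.0, 1.0), fraction=0.25),
            SiteRule(f"calf_{side}", f"leg_{side}", "extremum",
                     (0.55, 0.80), "max"),
            SiteRule(f"ankle_{side}", f"leg_{side}", "extremum",
                     (0.85, 0.95), "min"),
        ]
    for r in rules:
        r.validate()
    return rules


def rules_from_config(obj) -> list:
    """Build site rules from a parsed YAML/JSON mapping or list."""
    items = obj.get("sites", obj) if isinstance(obj, dict) else obj
    rules = []
    for item in items:
        rule = SiteRule(
            site=item["site"], segment=item["segment"], mode=item["mode"],
            band=tuple(item.get("band", (0.0, 1.0))),
            objective=item.get("objective"),
            fraction=item.get("fraction"),
        )
        rule.validate()
        rules.append(rule)
    return rules


@dataclass
class LimbAxis:
    """Principal elongation axis of a limb segment, pointing distal."""

    anchor: np.ndarray
    direction: np.ndarray


@dataclass
class SiteRecord:
    """The winning plane and contour behind one measurement."""

    site: str
    plane_origin: np.ndarray
    plane_normal: np.ndarray
    loop: np.ndarray  # (k, 3) world points of the measured contour
    value: float


@dataclass
class MeasurementSet:
    """The eleven named circumferences of one scan, cm."""

    values: dict
    records: dict = field(repr=False, default_factory=dict)

    def __getitem__(self, site: str) -> float:
        return self.values[site]

    def validate(self) -> None:
        for site, v in self.values.items():
            if not np.isfinite(v) or v <= 0:
                raise MeasurementError(f"{site}: non-positive circumference {v}")
        for side in ("left", "right"):
            a = self.values.get(f"ankle_{side}")
            c = self.values.get(f"calf_{side}")
            t = self.values.get(f"thigh_{side}")
            if None not in (a, c, t) and not (a < c < t):
                raise MeasurementError(
                    f"{side} leg ordering violated: ankle {a:.1f} < calf "
                    f"{c:.1f} < thigh {t:.1f} fails")

    def to_json(self) -> str:
        return json.dumps({k: float(v) for k, v in self.values.items()},
                          indent=2)


# ---------------------------------------------------------------------------
# axes and site location
# ---------------------------------------------------------------------------

def limb_axis(mesh: TriMesh, segment_faces: np.ndarray,
              proximal: np.ndarray) -> LimbAxis:
    """Dominant principal direction of a limb's vertex cloud.

    The direction is oriented away from the proximal landmark (distal
    positive).  A segment whose principal extent is less than twice its
    second extent has no well-defined axis.
    """
    vid = np.unique(mesh.faces[segment_faces])
    V = mesh.vertices[vid]
    X = V - V.mean(axis=0)
    w, Q = np.linalg.eigh((X.T @ X) / len(X))
    extents = np.ptp(X @ Q, axis=0)
    order = np.argsort(extents)[::-1]
    if extents[order[0]] < 2.0 * extents[order[1]]:
        raise AxisUndefinedError(
            f"segment is not elongated (extents {extents[order[0]]:.1f} vs "
            f"{extents[order[1]]:.1f} cm)")
    d = Q[:, order[0]]
    if (V.mean(axis=0) - np.asarray(proximal)) @ d < 0:
        d = -d
    return LimbAxis(anchor=np.asarray(proximal, dtype=float), direction=d)


def _hull_perimeter(poly) -> float:
    return float(poly.convex_hull.exterior.length)


def _raw_perimeter(poly) -> float:
    return float(poly.exterior.length)


def _pick_loop(polys, to_3d, point_world):
    """The contour whose convex hull contains the reference point."""
    target = Point(world_to_plane(point_world, to_3d))
    best = None
    for poly in polys:
        if poly.convex_hull.covers(target):
            if best is None or poly.area > best.area:
                best = poly
    return best


def _loop_world(poly, to_3d) -> np.ndarray:
    pts = np.asarray(poly.exterior.coords)[:-1]
    return plane_to_world(pts, to_3d)


def locate_site(mesh: TriMesh, segments: BodySegments, lm: LandmarkSet,
                rule: SiteRule, axis: LimbAxis | None = None,
                perimeter_mode: str = "hull",
                step: float = SWEEP_STEP) -> SiteRecord:
    """Find the section plane a rule selects and measure its contour.

    Trunk rules sweep transverse planes over the band normalized on the
    crotch-to-armpit span; limb rules sweep planes perpendicular to the limb
    axis over the band normalized on the proximal-to-distal extent.  The
    measured contour is the one containing the segment's local centroid.
    Extremum ties break toward the lower plane offset (lower z for the
    trunk; for limbs the sweep runs proximal to distal, so toward proximal —
    ties only arise on exact plateaus).
    """
    measure_fn = _hull_perimeter if perimeter_mode == "hull" else _raw_perimeter
    lo, hi = rule.band

    if rule.segment == "center":
        z0 = float(lm.crotch[2])
        z1 = 0.5 * (lm.armpit_left[2] + lm.armpit_right[2])
        span = z1 - z0
        origin = np.zeros(3)
        normal = np.array([0.0, 0.0, 1.0])
        offs = _band_offsets(z0 + lo * span, z0 + hi * span, rule, step)
        cent = mesh.face_centroids()[segments["center"]]
        ref_xy = cent[:, :2].mean(axis=0)

        def ref_point(h):
            return np.array([ref_xy[0], ref_xy[1], h])

    else:
        if axis is None:
            proximal = _proximal_landmark(lm, rule.segment)
            axis = limb_axis(mesh, segments[rule.segment], proximal)
        _check_axis(axis, rule.segment)
        origin = axis.anchor
        normal = axis.direction
        vid = np.unique(mesh.faces[segments[rule.segment]])
        V = mesh.vertices[vid]
        s = (V - origin) @ normal
        s0, s1 = float(s.min()), float(s.max())
        span = s1 - s0
        offs = _band_offsets(s0 + lo * span, s0 + hi * span, rule, step)
        order = np.argsort(s)
        s_sorted, V_sorted = s[order], V[order]

        def ref_point(h):
            i0 = np.searchsorted(s_sorted, h - 1.0)
            i1 = np.searchsorted(s_sorted, h + 1.0)
            if i1 - i0 < 8:  # thin slab: widen to the nearest vertices
                k = np.argsort(np.abs(s_sorted - h))[:32]
                local = V_sorted[k]
            else:
                local = V_sorted[i0:i1]
            m = local.mean(axis=0)
            return m + (h - (m - origin) @ normal) * normal

    results = section_polygons(mesh, origin, normal, offs)
    best = None  # (value, off, poly, to_3d)
    for off, entry in zip(offs, results):
        if entry is None:
            continue
        polys, to_3d = entry
        poly = _pick_loop(polys, to_3d, ref_point(off))
        if poly is None:
            continue
        value = measure_fn(poly)
        if best is None:
            best = (value, off, poly, to_3d)
        elif rule.mode == "extremum":
            if rule.objective == "min" and value < best[0]:
                best = (value, off, poly, to_3d)
            elif rule.objective == "max" and value > best[0]:
                best = (value, off, poly, to_3d)
    if best is None:
        raise SiteNotFoundError(
            f"{rule.site}: no section in band {rule.band} intersects "
            f"segment {rule.segment}")
    value, off, poly, to_3d = best
    return SiteRecord(
        site=rule.site,
        plane_origin=origin + off * normal,
        plane_normal=normal.copy(),
        loop=_loop_world(poly, to_3d),
        value=value,
    )


def _band_offsets(lo, hi, rule: SiteRule, step: float) -> np.ndarray:
    if rule.mode == "fixed_fraction":
        span = hi - lo
        b0, b1 = rule.band
        # fraction is normalized on the same scale as the band
        h = lo + (rule.fraction - b0) / (b1 - b0) * span
        return np.array([h + _PROBE_EPS])
    n = max(2, int(np.floor((hi - lo) / step)) + 1)
    return np.linspace(lo, hi, n) + _PROBE_EPS


def _proximal_landmark(lm: LandmarkSet, segment: str) -> np.ndarray:
    if segment.startswith("arm_"):
        return getattr(lm, "shoulder_" + segment[4:])
    if segment.startswith("leg_"):
        return lm.crotch
    raise ValueError(f"segment {segment!r} has no proximal landmark")


def _check_axis(axis: LimbAxis, segment: str) -> None:
    d = axis.direction
    if segment.startswith("leg_") and d[2] >= 0:
        raise AxisUndefinedError(f"{segment}: leg axis does not point down")
    if segment.startswith("arm_"):
        ang = np.degrees(np.arccos(np.clip(-d[2], -1.0, 1.0)))
        if not (10.0 < ang < 80.0):
            raise AxisUndefinedError(
                f"{segment}: arm axis at {ang:.0f} deg from vertical is "
                "outside the A-pose range (10-80 deg)")


def measure_all(mesh: TriMesh, rules: list | None = None,
                lm: LandmarkSet | None = None,
                segments: BodySegments | None = None,
                perimeter_mode: str = "hull",
                step: float = SWEEP_STEP) -> MeasurementSet:
    """Compute all circumferences of a canonical watertight scan.

    Landmarks and segments are detected when not supplied.  Deterministic
    for fixed input and rules; any stage error propagates with the site
    name attached.
    """
    rules = rules if rules is not None else default_rules()
    lm = lm or detect_landmarks(mesh)
    segments = segments or segment_body(mesh, lm)

    axes = {}
    values, records = {}, {}
    for rule in rules:
        rule.validate()
        axis = None
        if rule.segment != "center":
            if rule.segment not in axes:
                proximal = _proximal_landmark(lm, rule.segment)
                axes[rule.segment] = limb_axis(
                    mesh, segments[rule.segment], proximal)
            axis = axes[rule.segment]
        try:
            rec = locate_site(mesh, segments, lm, rule, axis=axis,
                              perimeter_mode=perimeter_mode, step=step)
        except SiteNotFoundError:
            raise
        except Exception as exc:
            raise type(exc)(f"{rule.site}: {exc}") from exc
        values[rule.site] = rec.value
        records[rule.site] = rec
    ms = MeasurementSet(values=values, records=records)
    ms.validate()
    return ms
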