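"""Parametric A-pose avatar generator with exact ground-truth circumferences.

Real optical body scans are not redistributable, so the package carries a
phantom generator that emulates the capture pose of turntable scanners: a
standing adult with two separated legs, a trunk, a head, and two arms held
in a downward V at roughly 45 degrees from vertical.  Every body part is a
generalized cylinder (stacked polygonal rings); radius profiles are
piecewise linear with *plateaus at the eleven measurement sites*, so the
circumference implied at each site is known in closed form:

* limbs use circular rings — circumference ``2 n r sin(pi / n)`` for ring
  resolution ``n``;
* the trunk uses elliptical rings (hips are wider than deep) — the ground
  truth is the exact perimeter of the generated ring polygon.

The generator also provides scanner-artifact injection (armpit/crotch holes
and Gaussian vertex noise) and randomized specs for recovery experiments.
All randomness is driven by an explicit seed; a fixed spec always produces a
bit-identical mesh.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import trimesh

from .errors import DegradationError, SpecError
from .meshes import TriMesh, face_components

SITES = (
    "chest",
    "waist",
    "hip",
    "upper_arm_left",
    "upper_arm_right",
    "thigh_left",
    "thigh_right",
    "calf_left",
    "calf_right",
    "ankle_left",
    "ankle_right",
)


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass
class AvatarSpec:
    """Geometry of one synthetic A-pose body.

    Heights are z-positions in cm (sole at 0); radii are cm.  The trunk
    cross-section is an ellipse with semi-axes ``(aspect * r, r / aspect)``.
    ``arm_gap = 0`` models arms pressed against the trunk (they become part
    of the trunk silhouette, the failure mode of scans of subjects with
    obesity); ``leg_gap = 0`` makes the inner thigh walls touch.
    """

    stature: float = 175.0
    crotch_height: float = 80.0
    armpit_height: float = 140.0
    shoulder_height: float = 150.0

    # trunk (site radii are the plateau values)
    torso_base_radius: float = 15.2
    hip_radius: float = 16.0
    waist_radius: float = 12.5
    chest_radius: float = 15.5
    torso_armpit_radius: float = 14.8
    torso_top_radius: float = 14.0
    torso_aspect: float = 1.25

    # legs
    thigh_radius: float = 8.5
    knee_radius: float = 5.8
    calf_radius: float = 6.0
    ankle_radius: float = 4.0
    heel_radius: float = 4.6
    leg_gap: float = 4.0

    # arms
    upper_arm_radius: float = 4.7
    wrist_radius: float = 3.2
    arm_angle_deg: float = 45.0
    arm_drop: float = 42.0  # vertical drop from armpit height to the distal cap
    arm_gap: float = 1.0

    # head / neck
    neck_radius: float = 5.5
    head_radius: float = 8.5

    ring_resolution: int = 96
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.crotch_height < self.armpit_height
                <= self.shoulder_height < self.stature):
            raise SpecError(
                "need 0 < crotch < armpit <= shoulder < stature, got "
                f"{self.crotch_height}, {self.armpit_height}, "
                f"{self.shoulder_height}, {self.stature}"
            )
        radii = (
            self.torso_base_radius, self.hip_radius, self.waist_radius,
            self.chest_radius, self.torso_armpit_radius, self.torso_top_radius,
            self.thigh_radius, self.knee_radius, self.calf_radius,
            self.ankle_radius, self.heel_radius, self.upper_arm_radius,
            self.wrist_radius, self.neck_radius, self.head_radius,
        )
        if any(r <= 0 for r in radii):
            raise SpecError("all radii must be positive")
        if self.ring_resolution < 12 or self.ring_resolution % 2:
            raise SpecError("ring_resolution must be even and >= 12")
        if not (10.0 < self.arm_angle_deg < 80.0):
            raise SpecError(
                "arm_angle_deg must be in (10, 80): outside this the arms "
                "either fuse with the trunk or become unreachable by the "
                "armpit search"
            )
        if self.leg_gap < 0 or self.arm_gap < 0:
            raise SpecError("gaps must be >= 0")
        if self.waist_radius >= min(self.hip_radius, self.chest_radius):
            raise SpecError("waist must be narrower than hip and chest")
        if not (self.ankle_radius < self.calf_radius < self.thigh_radius):
            raise SpecError("need ankle < calf < thigh")
        # the arm axis must clear the trunk before reaching the sole
        if self.arm_drop <= 0 or self.arm_drop >= self.armpit_height:
            raise SpecError("arm_drop out of range")

    # -- derived geometry --------------------------------------------------
    @property
    def leg_offset(self) -> float:
        return self.leg_gap / 2.0 + self.thigh_radius

    def torso_profile(self):
        """(z, radius) breakpoints; plateaus at hip / waist / chest sites."""
        zc, za, zs = self.crotch_height, self.armpit_height, self.shoulder_height
        span = za - zc
        pts = [
            (zc, self.torso_base_radius),
            (zc + 0.05 * span, self.hip_radius),
            (zc + 0.15 * span, self.hip_radius),
            (zc + 0.45 * span, self.waist_radius),
            (zc + 0.60 * span, self.waist_radius),
            (zc + 0.80 * span, self.chest_radius),
            (zc + 0.90 * span, self.chest_radius),
            (za, self.torso_armpit_radius),
        ]
        if zs > za:
            pts.append((zs, self.torso_top_radius))
        return pts

    def leg_profile(self):
        """(t, radius) with t normalized 0 at crotch, 1 at the sole."""
        return [
            (0.00, self.thigh_radius),
            (0.35, self.thigh_radius),
            (0.50, self.knee_radius),
            (0.60, self.calf_radius),
            (0.70, self.calf_radius),
            (0.875, self.ankle_radius),
            (0.925, self.ankle_radius),
            (0.97, self.heel_radius),
            (1.00, self.heel_radius),
        ]

    def torso_semi_x(self, z: float) -> float:
        pts = self.torso_profile()
        zs = [p[0] for p in pts]
        rs = [p[1] for p in pts]
        return self.torso_aspect * float(np.interp(z, zs, rs))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "AvatarSpec":
        return cls(**d)


@dataclass
class GroundTruth:
    """Analytic truth implied by an :class:`AvatarSpec`."""

    circumferences: dict  # site -> cm
    landmarks: dict       # name -> (3,) array
    segment_areas: dict   # segment -> cm^2
    spec: AvatarSpec = field(repr=False, default=None)

    def to_json(self) -> str:
        return json.dumps(
            {
                "circumferences": self.circumferences,
                "landmarks": {k: list(map(float, v))
                              for k, v in self.landmarks.items()},
                "segment_areas": self.segment_areas,
            },
            indent=2,
        )


def ring_circumference(radius: float, n: int) -> float:
    """Perimeter of a regular n-gon inscribed in a circle of ``radius``."""
    return 2.0 * n * radius * np.sin(np.pi / n)


def ellipse_ring_circumference(radius: float, aspect: float, n: int) -> float:
    """Perimeter of the generator's elliptical trunk ring polygon."""
    phi = 2.0 * np.pi * np.arange(n) / n
    pts = np.column_stack([aspect * radius * np.cos(phi),
                           radius / aspect * np.sin(phi)])
    return float(np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0),
                                axis=1).sum())


# ---------------------------------------------------------------------------
# mesh assembly helpers
# ---------------------------------------------------------------------------

def _refine_stations(breaks, max_step=4.0):
    """Insert stations so no span exceeds ``max_step``; keeps breakpoints."""
    out = [breaks[0]]
    for a, b in zip(breaks[:-1], breaks[1:]):
        k = max(1, int(np.ceil(abs(b - a) / max_step)))
        out.extend(np.linspace(a, b, k + 1)[1:])
    return np.asarray(out)


def _grid_faces(rows: int, cols: int, closed: bool = True):
    """Triangulate a (rows x cols) vertex grid, columns wrapping around."""
    faces = []
    for i in range(rows - 1):
        for j in range(cols):
            j2 = (j + 1) % cols
            if not closed and j2 == 0:
                continue
            a = i * cols + j
            b = i * cols + j2
            c = (i + 1) * cols + j2
            d = (i + 1) * cols + j
            faces.append([a, b, c])
            faces.append([a, c, d])
    return faces


def _cap_disk(rim_ids, rim_pts, next_vid, fractions=(2.0 / 3.0, 1.0 / 3.0)):
    """Triangulated disk closing a planar rim, with concentric inner rings.

    Concentric rings keep cap triangles comparable in size to the tube
    facets so local operations (hole carving, noise) behave like they do on
    the rest of the surface.  Returns ``(new_vertices, faces)``.
    """
    n = len(rim_ids)
    center = rim_pts.mean(axis=0)
    ring_ids = [list(rim_ids)]
    new_pts = []
    vid = next_vid
    for f in fractions:
        pts = center + f * (rim_pts - center)
        ring_ids.append(list(range(vid, vid + n)))
        new_pts.append(pts)
        vid += n
    cid = vid
    faces = []
    for ra, rb in zip(ring_ids[:-1], ring_ids[1:]):
        for j in range(n):
            j2 = (j + 1) % n
            faces.append([ra[j], ra[j2], rb[j2]])
            faces.append([ra[j], rb[j2], rb[j]])
    inner = ring_ids[-1]
    for j in range(n):
        faces.append([inner[j], inner[(j + 1) % n], cid])
    new_pts = np.vstack(new_pts + [center[None, :]])
    return new_pts, faces


def _finalize_part(verts, faces):
    """Make winding consistent and outward for one closed part."""
    tm = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces, dtype=np.int64),
                         process=False)
    trimesh.repair.fix_normals(tm)
    if tm.volume < 0:  # pragma: no cover - fix_normals orients outward
        tm.invert()
    return np.asarray(tm.vertices), np.asarray(tm.faces, dtype=np.int64)


def _vertical_tube(x0, y0, z_breaks, r_of_z, n, su=1.0, sv=1.0):
    """Closed vertical generalized cylinder with elliptical scaling."""
    stations = _refine_stations(z_breaks)
    phi = 2.0 * np.pi * np.arange(n) / n
    cu, sV = np.cos(phi), np.sin(phi)
    verts = []
    for z in stations:
        r = r_of_z(z)
        ring = np.column_stack([x0 + su * r * cu, y0 + sv * r * sV,
                                np.full(n, z)])
        verts.append(ring)
    verts = np.vstack(verts)
    faces = _grid_faces(len(stations), n)
    vb = np.arange(n)
    vt = (len(stations) - 1) * n + np.arange(n)
    pts_b, faces_b = _cap_disk(list(vb), verts[vb], len(verts))
    verts = np.vstack([verts, pts_b])
    pts_t, faces_t = _cap_disk(list(vt), verts[vt], len(verts))
    verts = np.vstack([verts, pts_t])
    return _finalize_part(verts, faces + faces_b + faces_t)


def _arm_tube(spec: AvatarSpec, side: int):
    """Tilted circular arm cylinder, clipped flat at shoulder height.

    ``side`` is +1 for the subject's left (x > 0).  The axis passes through
    ``(side * x_A, 0, armpit_height)`` with direction ``(side sin, 0, -cos)``
    of the arm angle; the lateral offset ``x_A`` is chosen so the arm surface
    is exactly tangent to the trunk at the armpit height and diverges below.
    """
    th = np.radians(spec.arm_angle_deg)
    a = spec.upper_arm_radius
    za, zs = spec.armpit_height, spec.shoulder_height
    n = spec.ring_resolution
    x_a = spec.torso_semi_x(za) + a / np.cos(th)

    d = np.array([np.sin(th), 0.0, -np.cos(th)])
    u = np.array([np.cos(th), 0.0, np.sin(th)])
    v = np.array([0.0, 1.0, 0.0])
    A = np.array([x_a, 0.0, za])

    s_dist = spec.arm_drop / np.cos(th)
    # radius profile along the axis: plateau over the upper arm, taper to wrist
    s_taper0 = 0.35 * s_dist
    breaks_s = [-(zs - za + a * np.sin(th)) / np.cos(th) - 1.0,
                s_taper0, s_dist - 0.12 * s_dist, s_dist]
    radii = [a, a, spec.wrist_radius, spec.wrist_radius + 0.2]

    def a_of_s(s):
        return float(np.interp(s, breaks_s, radii))

    phi = 2.0 * np.pi * np.arange(n) / n
    cphi, sphi = np.cos(phi), np.sin(phi)
    # per-column start station: the solution of z(s, phi) = shoulder height
    s_start = (za - zs + a * np.sin(th) * cphi) / np.cos(th)
    # row spacing tied to physical length (~3 cm), not ring resolution
    rows = max(24, int(np.ceil((s_dist - s_start.min()) / 3.0)))
    verts = []
    for i in range(rows + 1):
        t = i / rows
        s_i = s_start + t * (s_dist - s_start)
        r_i = np.array([a_of_s(s) for s in s_i])
        pts = (A[None, :] + s_i[:, None] * d[None, :]
               + r_i[:, None] * (cphi[:, None] * u[None, :]
                                 + sphi[:, None] * v[None, :]))
        verts.append(pts)
    verts = np.vstack(verts)
    faces = _grid_faces(rows + 1, n)
    top = np.arange(n)
    bot = rows * n + np.arange(n)
    pts_t, faces_t = _cap_disk(list(top), verts[top], len(verts))
    verts = np.vstack([verts, pts_t])
    pts_b, faces_b = _cap_disk(list(bot), verts[bot], len(verts))
    verts = np.vstack([verts, pts_b])
    faces = np.asarray(faces + faces_t + faces_b, dtype=np.int64)
    if side < 0:
        verts = verts * np.array([-1.0, 1.0, 1.0])
        faces = faces[:, ::-1]
    return _finalize_part(verts, faces)


def _foot_box(spec: AvatarSpec, side: int):
    """Subdivided box foot: toes anterior (-y), sole at z = 0."""
    w, length, h = 9.0, 24.0, 3.0
    box = trimesh.creation.box(extents=(w, length, h))
    box = box.subdivide().subdivide()
    v = np.asarray(box.vertices) + np.array(
        [side * spec.leg_offset, -(length / 2.0 - 6.0), h / 2.0]
    )
    return _finalize_part(v, np.asarray(box.faces))


# ---------------------------------------------------------------------------
# avatar assembly
# ---------------------------------------------------------------------------

def make_avatar(spec: AvatarSpec | None = None):
    """Build a watertight canonical avatar and its analytic ground truth.

    Returns ``(mesh, truth)``.  The mesh is the disjoint union of closed body
    parts (trunk, head, legs, feet, arms) that abut or interpenetrate — like
    a real scan it has zero boundary edges.  Deterministic for a fixed spec.
    """
    spec = spec or AvatarSpec()
    spec.validate()
    n = spec.ring_resolution
    zc, za, zs = spec.crotch_height, spec.armpit_height, spec.shoulder_height

    parts = {}

    tp = spec.torso_profile()
    tz = [p[0] for p in tp]
    tr = [p[1] for p in tp]
    parts["torso"] = _vertical_tube(
        0.0, 0.0, tz, lambda z: float(np.interp(z, tz, tr)), n,
        su=spec.torso_aspect, sv=1.0 / spec.torso_aspect,
    )

    head_z = [zs, zs + 0.15 * (spec.stature - zs), zs + 0.35 * (spec.stature - zs),
              zs + 0.85 * (spec.stature - zs), spec.stature]
    head_r = [spec.neck_radius, spec.neck_radius, spec.head_radius,
              spec.head_radius, 0.6 * spec.head_radius]
    parts["head"] = _vertical_tube(
        0.0, 0.0, head_z, lambda z: float(np.interp(z, head_z, head_r)), n
    )

    lp = spec.leg_profile()
    lt = [p[0] for p in lp]
    lr = [p[1] for p in lp]

    def leg_r(z):
        return float(np.interp((zc - z) / zc, lt, lr))

    for side, name in ((1, "leg_left"), (-1, "leg_right")):
        parts[name] = _vertical_tube(side * spec.leg_offset, 0.0,
                                     [0.0, zc], leg_r, n)
        fv, ff = _foot_box(spec, side)
        parts["foot" + name[3:]] = (fv, ff)

    if spec.arm_gap > 0:
        for side, name in ((1, "arm_left"), (-1, "arm_right")):
            parts[name] = _arm_tube(spec, side)

    # assemble with per-part face bookkeeping
    all_v, all_f, labels = [], [], []
    off = 0
    for name, (v, f) in parts.items():
        all_v.append(v)
        all_f.append(np.asarray(f) + off)
        labels.extend([name] * len(f))
        off += len(v)
    V = np.vstack(all_v)
    F = np.vstack(all_f)
    labels = np.asarray(labels)
    mesh = TriMesh(V, F, frame="raw")

    # ground-truth landmarks in build coordinates
    bx_a = spec.torso_semi_x(za)
    bx_s = spec.torso_semi_x(zs)
    lm = {
        "crotch": np.array([0.0, 0.0, zc]),
        "armpit_left": np.array([bx_a, 0.0, za]),
        "armpit_right": np.array([-bx_a, 0.0, za]),
        "shoulder_left": np.array([bx_s, 0.0, zs]),
        "shoulder_right": np.array([-bx_s, 0.0, zs]),
        "foot_left": np.array([spec.leg_offset, 0.0, 0.0]),
        "foot_right": np.array([-spec.leg_offset, 0.0, 0.0]),
    }

    segment_areas = _ground_truth_areas(mesh, labels, lm, spec)

    # The build frame is canonical by construction (+z up, soles at z = 0,
    # anterior -y); recentre the footprint so x = y = 0 like canonicalize()
    # does, using the same area-weighted centroid.
    wts = mesh.face_areas()
    cxy = (wts @ mesh.face_centroids()[:, :2]) / wts.sum()
    shift = np.array([cxy[0], cxy[1], 0.0])
    V = V - shift
    mesh = TriMesh(V, F, frame="canonical")
    lm = {k: p - shift for k, p in lm.items()}

    circ = {
        "chest": ellipse_ring_circumference(spec.chest_radius,
                                            spec.torso_aspect, n),
        "waist": ellipse_ring_circumference(spec.waist_radius,
                                            spec.torso_aspect, n),
        "hip": ellipse_ring_circumference(spec.hip_radius,
                                          spec.torso_aspect, n),
    }
    for side in ("left", "right"):
        circ["upper_arm_" + side] = ring_circumference(spec.upper_arm_radius, n)
        circ["thigh_" + side] = ring_circumference(spec.thigh_radius, n)
        circ["calf_" + side] = ring_circumference(spec.calf_radius, n)
        circ["ankle_" + side] = ring_circumference(spec.ankle_radius, n)

    return mesh, GroundTruth(circ, lm, segment_areas, spec)


def _ground_truth_areas(mesh: TriMesh, labels, lm, spec: AvatarSpec) -> dict:
    """Per-segment surface areas implied by the analytic cut planes.

    Legs are the closed leg and foot parts on each side; arms are the arm
    parts lateral of the shoulder-armpit cut plane (their medial portion
    hidden inside the trunk counts as center, exactly as the segmentation
    contract assigns it); everything else is center.
    """
    cent = mesh.face_centroids()
    areas = mesh.face_areas()
    seg = np.full(len(labels), "center", dtype=object)
    for side in ("left", "right"):
        seg[(labels == "leg_" + side) | (labels == "foot_" + side)] = \
            "leg_" + side
    for side, sgn in (("left", 1), ("right", -1)):
        sh, ap = lm["shoulder_" + side], lm["armpit_" + side]
        nrm = np.cross(sh - ap, [0.0, 1.0, 0.0])
        if nrm[0] * sgn < 0:
            nrm = -nrm
        is_arm = (labels == "arm_" + side) & ((cent - ap) @ nrm > 0)
        seg[is_arm] = "arm_" + side
    return {name: float(areas[seg == name].sum())
            for name in ("arm_left", "arm_right", "leg_left", "leg_right",
                         "center")}


# ---------------------------------------------------------------------------
# degradation
# ---------------------------------------------------------------------------

def _hole_anchors(mesh: TriMesh, hole_radius: float):
    """Crotch/armpit-region anchor points for hole carving.

    Uses landmark detection when it succeeds (holes sit exactly where real
    turntable scans lose coverage); falls back to the typical height
    fractions of an adult body otherwise.  Armpit anchors are dropped a bit
    below the merge height onto the trunk wall so one hole carves one
    surface sheet.
    """
    try:
        from .landmarks import detect_landmarks

        lm = detect_landmarks(mesh)
        # drop below the merge height so the carving ball clears the
        # diverging arm and cuts a single sheet of the trunk wall
        drop = hole_radius + 5.0
        return [
            lm.crotch + np.array([0.0, 0.0, 0.8 * hole_radius]),
            lm.armpit_left + np.array([0.0, 0.0, -drop]),
            lm.armpit_right + np.array([0.0, 0.0, -drop]),
        ]
    except Exception:
        b = mesh.bounds
        H = b[1, 2] - b[0, 2]
        return [np.array([0.0, 0.0, b[0, 2] + 0.46 * H + 0.8 * hole_radius])]


def degrade_mesh(mesh: TriMesh, holes: int = 2, hole_radius: float = 2.5,
                 noise_sd: float = 0.0, seed: int = 0,
                 anchors=None) -> TriMesh:
    """Inject scanner artifacts: surface holes and Gaussian vertex noise.

    Hole centres are biased to the crotch and armpit regions (the classic
    self-occluded areas of turntable scans); beyond those, centres fall on
    random surface vertices.  A face is removed when any of its vertices
    lies within ``hole_radius`` of a centre.  Deterministic per seed.
    ``anchors`` overrides the biased centres (e.g. with generator ground
    truth).
    """
    if holes == 0 and noise_sd == 0:
        return mesh.copy()
    rng = np.random.default_rng(seed)
    V = mesh.vertices.copy()
    F = mesh.faces.copy()

    if holes:
        if anchors is None:
            anchors = _hole_anchors(mesh, hole_radius)
        anchors = [np.asarray(a, dtype=np.float64) for a in anchors]
        tm = mesh.to_trimesh()
        n_before = len(face_components(tm, np.arange(len(F))))
        centers = []
        for i in range(holes):
            if i < len(anchors):
                c = anchors[i] + rng.normal(0.0, 0.2, 3)
            else:
                c = V[int(rng.integers(len(V)))]
            centers.append(c)
        hit = np.zeros(len(V), dtype=bool)
        for c in centers:
            hit |= np.linalg.norm(V - c, axis=1) <= hole_radius
        keep = ~hit[F].any(axis=1)
        F2 = F[keep]
        if len(F2) == 0:
            raise DegradationError("hole radius removes every face")
        tm2 = TriMesh(V, F2, mesh.frame).to_trimesh()
        n_after = len(face_components(tm2, np.arange(len(F2))))
        if n_after != n_before:
            raise DegradationError(
                f"hole radius {hole_radius} disconnects the mesh "
                f"({n_before} -> {n_after} components)"
            )
        F = F2

    if noise_sd > 0:
        V = V + rng.normal(0.0, noise_sd, V.shape)

    return TriMesh(V, F, mesh.frame)


# ---------------------------------------------------------------------------
# randomized specs and cohorts
# ---------------------------------------------------------------------------

def random_spec(rng: np.random.Generator, ring_resolution: int = 96) -> AvatarSpec:
    """Draw a plausible adult spec; all site-ordering constraints hold."""
    stature = rng.uniform(158.0, 192.0)
    s = stature / 175.0
    waist = rng.uniform(11.0, 13.8)
    thigh = rng.uniform(7.6, 9.6)
    calf = rng.uniform(5.2, min(7.0, thigh - 1.2))
    ankle = rng.uniform(3.4, min(4.4, calf - 1.0))
    arm = rng.uniform(4.2, 5.3)
    spec = AvatarSpec(
        stature=stature,
        crotch_height=rng.uniform(0.44, 0.48) * stature,
        armpit_height=rng.uniform(0.78, 0.81) * stature,
        shoulder_height=rng.uniform(0.845, 0.865) * stature,
        hip_radius=waist + rng.uniform(2.6, 4.4),
        waist_radius=waist,
        chest_radius=waist + rng.uniform(2.2, 3.6),
        thigh_radius=thigh,
        knee_radius=calf - 0.3,
        calf_radius=calf,
        ankle_radius=ankle,
        heel_radius=ankle + 0.6,
        upper_arm_radius=arm,
        wrist_radius=arm - rng.uniform(1.2, 1.6),
        arm_angle_deg=rng.uniform(38.0, 52.0),
        arm_drop=rng.uniform(0.22, 0.26) * stature,
        leg_gap=rng.uniform(3.0, 6.0),
        ring_resolution=ring_resolution,
    )
    spec.torso_base_radius = spec.hip_radius - 0.8
    spec.torso_armpit_radius = spec.chest_radius - rng.uniform(0.5, 1.2)
    spec.torso_top_radius = spec.torso_armpit_radius - 0.8
    spec.validate()
    return spec


def make_cohort(n: int, seed: int = 0, tape_sd: float = 0.3,
                ring_resolution: int = 96):
    """Ground-truth circumference table for ``n`` random subjects.

    Returns ``(specs, table)`` where ``table`` has one row per (subject,
    site) with the exact circumference and a tape-like reading with
    measurement noise of SD ``tape_sd`` cm.  No meshes are built here; use
    :func:`make_avatar` per spec when surface geometry is needed.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    specs, rows = [], []
    for i in range(n):
        spec = random_spec(rng, ring_resolution=ring_resolution)
        specs.append(spec)
        nr = spec.ring_resolution
        truth = {
            "chest": ellipse_ring_circumference(spec.chest_radius,
                                                spec.torso_aspect, nr),
            "waist": ellipse_ring_circumference(spec.waist_radius,
                                                spec.torso_aspect, nr),
            "hip": ellipse_ring_circumference(spec.hip_radius,
                                              spec.torso_aspect, nr),
        }
        for side in ("left", "right"):
            truth["upper_arm_" + side] = ring_circumference(
                spec.upper_arm_radius, nr)
            truth["thigh_" + side] = ring_circumference(spec.thigh_radius, nr)
            truth["calf_" + side] = ring_circumference(spec.calf_radius, nr)
            truth["ankle_" + side] = ring_circumference(spec.ankle_radius, nr)
        for site in SITES:
            rows.append({
                "scan_id": f"subject_{i:03d}",
                "site": site,
                "truth_cm": truth[site],
                "ca_cm": truth[site] + rng.normal(0.0, tape_sd),
            })
    return specs, pd.DataFrame(rows)
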