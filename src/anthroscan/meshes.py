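"""Triangular-mesh data model and geometric primitives.

A body scan is a triangular surface mesh: a list of 3D vertices and a list of
vertex-index triples ("faces").  This module provides

* :class:`TriMesh` — the in-memory container, tagged with its reference frame;
* file I/O for OBJ / PLY / STL with unit normalization to centimetres;
* :func:`canonicalize` — principal-axis alignment into the canonical body
  frame (+z up, z = 0 at the lowest vertex, subject's left at +x);
* :func:`repair` / :func:`fill_holes` — face-level cleanup and watertighting;
* :func:`cross_section` / :func:`perimeter` — planar sectioning and the
  tape-measure analog (convex-hull perimeter of a section loop).

All lengths are centimetres throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError

from .errors import (
    AlignmentError,
    DegeneratePolygonError,
    EmptyMeshError,
    FormatError,
    UnitInferenceError,
)

#: faces with area below this (cm^2) are treated as degenerate
DEGENERATE_AREA = 1e-6

#: points within this distance (cm) of a section plane count as on-plane
PLANE_TOL = 1e-6

#: plausible adult stature band (cm) used for unit auto-inference
STATURE_BAND = (120.0, 220.0)

_SUPPORTED_SUFFIXES = {".obj", ".ply", ".stl"}


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class TriMesh:
    """A triangular surface mesh in cm units.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    frame : ``"raw"`` or ``"canonical"``
    """

    vertices: np.ndarray
    faces: np.ndarray
    frame: str = "raw"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    # -- basic geometry ----------------------------------------------------
    @property
    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    @property
    def height(self) -> float:
        b = self.bounds
        return float(b[1, 2] - b[0, 2])

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), self.frame)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, frame: str = "raw") -> "TriMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), frame)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_areas(self) -> np.ndarray:
        v = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )


@dataclass
class CrossSection:
    """Closed intersection contours of one plane with the surface."""

    plane_origin: np.ndarray
    plane_normal: np.ndarray
    loops: list  # list of (k, 3) arrays; closure implicit (first != last)
    perimeters: list  # per-loop hull-mode perimeter, cm

    @property
    def n_loops(self) -> int:
        return len(self.loops)


@dataclass
class RepairReport:
    """Bookkeeping for repair / hole-filling passes."""

    n_degenerate_removed: int = 0
    n_duplicates_removed: int = 0
    n_holes_filled: int = 0
    n_boundary_edges_before: int = 0
    n_boundary_edges_after: int = 0
    n_holes_unfilled: int = 0
    watertight: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_UNIT_FACTORS = {"mm": 0.1, "cm": 1.0, "m": 100.0}


def _infer_unit_factor(height: float) -> float:
    lo, hi = STATURE_BAND
    candidates = [f for f in (0.1, 1.0, 100.0) if lo <= height * f <= hi]
    if len(candidates) != 1:
        raise UnitInferenceError(
            f"cannot infer units from bounding-box height {height:g}; "
            "pass units explicitly (mm/cm/m)"
        )
    return candidates[0]


def load_mesh(path, units: str = "auto") -> TriMesh:
    """Load an OBJ/PLY/STL scan and return a raw-frame :class:`TriMesh` in cm.

    ``units='auto'`` infers the scale factor by mapping the bounding-box
    height into the plausible adult stature band 120–220 cm; ambiguous
    heights raise :class:`UnitInferenceError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported mesh format: {path.suffix!r}")
    try:
        tm = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"could not read {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or tm.vertices.shape[0] == 0:
        raise EmptyMeshError(f"{path} contains no mesh geometry")
    # STL stores one vertex triple per facet: weld exact duplicates so the
    # surface has shared edges and sections form closed loops.
    tm.merge_vertices()
    if len(tm.vertices) < 4 or len(tm.faces) < 4:
        raise EmptyMeshError(
            f"{path}: need >= 4 vertices and faces, got "
            f"{len(tm.vertices)} vertices / {len(tm.faces)} faces"
        )
    mesh = TriMesh.from_trimesh(tm, frame="raw")
    if units == "auto":
        factor = _infer_unit_factor(float(tm.extents.max()))
    else:
        try:
            factor = _UNIT_FACTORS[units]
        except KeyError:
            raise FormatError(f"unknown units {units!r}") from None
    if factor != 1.0:
        mesh.vertices = mesh.vertices * factor
    return mesh


def save_mesh(mesh: TriMesh, path) -> None:
    """Write a mesh as OBJ (ASCII), PLY (binary little-endian) or STL (binary)."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported mesh format: {path.suffix!r}")
    mesh.to_trimesh().export(str(path))


# ---------------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------------

def _deterministic_sign(vec: np.ndarray) -> np.ndarray:
    """Flip a vector so its largest-magnitude component is positive."""
    i = int(np.argmax(np.abs(vec)))
    return -vec if vec[i] < 0 else vec


def _end_component_count(tm: trimesh.Trimesh, proj: np.ndarray, band) -> int:
    """Number of connected face patches whose vertices all project into band."""
    lo, hi = band
    vmask = (proj >= lo) & (proj <= hi)
    fmask = vmask[tm.faces].all(axis=1)
    idx = np.flatnonzero(fmask)
    if idx.size == 0:
        return 0
    return _face_component_count(tm, idx)


def _face_component_count(tm: trimesh.Trimesh, face_idx: np.ndarray) -> int:
    return len(face_components(tm, face_idx))


def face_components(tm: trimesh.Trimesh, face_idx: np.ndarray) -> list:
    """Connected components (lists of face indices) within a face subset.

    Adjacency is shared-edge adjacency of the full mesh restricted to the
    subset; faces of distinct closed shells are never merged.
    """
    face_idx = np.asarray(face_idx, dtype=np.int64)
    if face_idx.size == 0:
        return []
    pos = -np.ones(len(tm.faces), dtype=np.int64)
    pos[face_idx] = np.arange(face_idx.size)
    adj = tm.face_adjacency
    if len(adj):
        a, b = pos[adj[:, 0]], pos[adj[:, 1]]
        keep = (a >= 0) & (b >= 0)
        a, b = a[keep], b[keep]
    else:  # pragma: no cover - degenerate soup
        a = b = np.empty(0, dtype=np.int64)
    n = face_idx.size
    graph = coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    return [face_idx[labels == k] for k in range(n_comp)]


def _canonical_rotation(mesh: TriMesh):
    """Rotation (columns = canonical x, y, z in input coordinates).

    Moments are surface-area weighted over face centroids, so the frame does
    not depend on how densely a scanner happens to sample each body part.
    """
    V = mesh.vertices
    if len(V) < 4 or len(mesh.faces) < 4:
        raise AlignmentError("too few vertices for alignment")
    cent = mesh.face_centroids()
    wts = mesh.face_areas()
    total = wts.sum()
    if total <= 0:
        raise AlignmentError("degenerate geometry: zero surface area")
    mu = (wts @ cent) / total
    X = cent - mu
    cov = (X * wts[:, None]).T @ X / total
    w, Q = np.linalg.eigh(cov)  # ascending eigenvalues
    if w[1] < 1e-10 * max(w[2], 1.0):
        raise AlignmentError("degenerate geometry: points are collinear/coplanar")
    z = _deterministic_sign(Q[:, 2])
    y = _deterministic_sign(Q[:, 0])

    # z sign: the body end with more separate parts (two legs/feet) is down.
    tm = mesh.to_trimesh()
    proj = (V - mu) @ z
    lo, hi = proj.min(), proj.max()
    h = hi - lo
    n_bot = _end_component_count(tm, proj, (lo, lo + 0.10 * h))
    n_top = _end_component_count(tm, proj, (hi - 0.10 * h, hi))
    if n_top > n_bot:
        z = -z
    elif n_top == n_bot:
        pz = X @ z
        if float(wts @ (pz - (wts @ pz) / total) ** 3) < 0:
            z = -z

    # y sign: anterior is -y; protruding feet make the y distribution
    # negatively skewed, which pins the heading deterministically.
    py = X @ y
    skew_y = float(wts @ (py - (wts @ py) / total) ** 3)
    if skew_y > 0:
        y = -y
    x = np.cross(y, z)  # right-handed (x, y, z); +x is the subject's left
    return np.column_stack([x, y, z])


def canonical_transform(mesh: TriMesh):
    """Rigid transform into the canonical frame: ``(R, shift)``.

    Apply as ``v @ R - shift``.  The footprint centroid (area-weighted) goes
    to x = y = 0 and the lowest vertex to z = 0.
    """
    R = _canonical_rotation(mesh)
    cent = mesh.face_centroids() @ R
    wts = mesh.face_areas()
    cx, cy = (wts @ cent[:, :2]) / wts.sum()
    zmin = (mesh.vertices @ R)[:, 2].min()
    return R, np.array([cx, cy, zmin])


def canonicalize(mesh: TriMesh) -> TriMesh:
    """Rigidly align a scan into the canonical body frame.

    Longest principal extent to +z with the leg end down, z = 0 at the lowest
    vertex, footprint centroid at x = y = 0, anterior toward -y so the
    subject's left is +x.  Idempotent up to floating point; scale preserving.
    """
    R, shift = canonical_transform(mesh)
    return TriMesh(mesh.vertices @ R - shift, mesh.faces.copy(),
                   frame="canonical")


# ---------------------------------------------------------------------------
# repair
# ---------------------------------------------------------------------------

def _boundary_edge_count(faces: np.ndarray) -> int:
    if len(faces) == 0:
        return 0
    edges = np.sort(
        np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int((counts == 1).sum())


def repair(mesh: TriMesh):
    """Drop degenerate and duplicate faces; vertices are left untouched.

    Returns ``(mesh, report)``.  Idempotent: repairing a repaired mesh is a
    no-op with all counts zero.
    """
    faces = mesh.faces
    report = RepairReport(n_boundary_edges_before=_boundary_edge_count(faces))

    # faces with a repeated vertex index or below the area threshold
    v = mesh.vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
    )
    repeated = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    degen = repeated | (areas < DEGENERATE_AREA)
    report.n_degenerate_removed = int(degen.sum())
    faces = faces[~degen]

    # duplicates: same unordered index triple, first occurrence kept
    key = np.sort(faces, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    keep = np.zeros(len(faces), dtype=bool)
    keep[first] = True
    report.n_duplicates_removed = int((~keep).sum())
    faces = faces[keep]

    out = TriMesh(mesh.vertices.copy(), faces, mesh.frame)
    report.n_boundary_edges_after = _boundary_edge_count(faces)
    report.watertight = report.n_boundary_edges_after == 0 and len(faces) > 0
    return out, report


# ---------------------------------------------------------------------------
# hole filling
# ---------------------------------------------------------------------------

def _boundary_loops(faces: np.ndarray):
    """Directed boundary loops (vertex index cycles) of a mesh with boundary.

    Returns ``(loops, n_tangled)`` where tangled loops (non-manifold boundary
    vertices) are skipped rather than fatal.
    """
    if len(faces) == 0:
        return [], 0
    directed = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    bmask = counts[inv] == 1
    bedges = directed[bmask]
    if len(bedges) == 0:
        return [], 0
    nxt = {}
    tangled_verts = set()
    for a, b in bedges:
        if a in nxt:
            tangled_verts.add(int(a))
        nxt[int(a)] = int(b)
    loops = []
    n_tangled = 0
    visited = set()
    # deterministic start order
    for a in sorted(nxt):
        if a in visited:
            continue
        loop = [a]
        visited.add(a)
        cur = nxt[a]
        ok = True
        while cur != a:
            if cur in visited or cur not in nxt or cur in tangled_verts:
                ok = False
                break
            loop.append(cur)
            visited.add(cur)
            cur = nxt[cur]
        if ok and len(loop) >= 3 and not (set(loop) & tangled_verts):
            loops.append(loop)
        else:
            n_tangled += 1
    return loops, n_tangled


def fill_holes(mesh: TriMesh):
    """Patch every boundary loop so the surface becomes watertight.

    Each hole is triangulated as a fan around one inserted centre vertex,
    placed at the umbrella-smoothing fixed point (the boundary-ring mean)
    and lifted along the boundary-ring vertex normals so the patch continues
    the local surface curvature rather than capping the hole flat.
    Original vertices are never moved.  Unrecoverable (non-manifold) boundary
    tangles are counted in the report instead of raising.
    """
    faces = mesh.faces.copy()
    report = RepairReport(n_boundary_edges_before=_boundary_edge_count(faces))
    loops, n_tangled = _boundary_loops(faces)
    report.n_holes_unfilled = n_tangled
    if not loops:
        report.n_boundary_edges_after = report.n_boundary_edges_before
        report.watertight = report.n_boundary_edges_after == 0
        return mesh.copy(), report

    tm = mesh.to_trimesh()
    vnormals = np.asarray(tm.vertex_normals)
    verts = mesh.vertices.copy()
    new_vertices = []
    new_faces = []
    for loop in loops:
        loop = np.asarray(loop, dtype=np.int64)
        if len(loop) == 3:
            # single missing triangle: close it directly (reverse winding)
            new_faces.append([loop[2], loop[1], loop[0]])
        else:
            ring = verts[loop]
            # umbrella fixed point of the one interior vertex: the ring mean
            c0 = ring.mean(axis=0)
            n_i = vnormals[loop]
            n_hat = n_i.mean(axis=0)
            norm = np.linalg.norm(n_hat)
            if norm > 1e-12:
                n_hat = n_hat / norm
                # first-order curvature continuation: lift the centre to
                # where the boundary tangent planes agree on average
                denom = max(float(np.mean(n_i @ n_hat)), 0.1)
                h = float(np.mean(np.einsum("ij,ij->i", ring - c0, n_i))) / denom
                c = c0 + h * n_hat
            else:  # pragma: no cover - pathological normals
                c = c0
            ci = len(verts) + len(new_vertices)
            new_vertices.append(c)
            # boundary edge a->b belongs to an existing face; patch traverses b->a
            for a, b in zip(loop, np.roll(loop, -1)):
                new_faces.append([b, a, ci])
        report.n_holes_filled += 1
    if new_vertices:
        verts = np.vstack([verts, np.asarray(new_vertices)])
    faces = np.vstack([faces, np.asarray(new_faces, dtype=np.int64)])
    out = TriMesh(verts, faces, mesh.frame)
    report.n_boundary_edges_after = _boundary_edge_count(faces)
    report.watertight = report.n_boundary_edges_after == 0
    return out, report


# ---------------------------------------------------------------------------
# sectioning and perimeters
# ---------------------------------------------------------------------------

def _order_loops(loops):
    """Deterministic loop ordering/start: lexicographically smallest point."""
    out = []
    for pts in loops:
        pts = np.asarray(pts, dtype=np.float64)
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        start = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))[0]
        out.append(np.roll(pts, -start, axis=0))
    out.sort(key=lambda p: tuple(p[0]))
    return out


def cross_section(mesh: TriMesh, plane_origin, plane_normal,
                  mode: str = "hull") -> CrossSection:
    """Intersect the surface with a plane.

    Returns the closed intersection contours (one loop per body part crossed)
    with per-loop perimeters computed by :func:`perimeter` in ``mode``.
    A plane that misses the mesh yields an empty section, not an error.
    """
    origin = np.asarray(plane_origin, dtype=np.float64)
    normal = np.asarray(plane_normal, dtype=np.float64)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise ValueError("plane normal must be non-zero")
    normal = normal / norm
    path = mesh.to_trimesh().section(plane_origin=origin, plane_normal=normal)
    if path is None:
        return CrossSection(origin, normal, [], [])
    loops = _order_loops(path.discrete)
    loops = [lp for lp in loops if len(lp) >= 3]
    perims = [perimeter(lp, mode=mode) for lp in loops]
    return CrossSection(origin, normal, loops, perims)


def _project_to_plane(points: np.ndarray) -> np.ndarray:
    """Project near-coplanar 3D points to 2D coordinates in their own plane."""
    pts = np.asarray(points, dtype=np.float64)
    c = pts.mean(axis=0)
    X = pts - c
    # plane basis from the two dominant directions
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    return X @ vt[:2].T


def perimeter(loop, mode: str = "hull") -> float:
    """Tape-analog length of a closed planar loop, cm.

    ``raw`` sums consecutive edge lengths of the contour itself; ``hull``
    (default) is the perimeter of the loop's planar convex hull — the length
    a flexible tape takes, bridging concavities.  ``hull <= raw`` always.
    """
    pts = np.asarray(loop, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise DegeneratePolygonError("need at least 3 points")
    if pts.shape[1] == 3:
        flat = _project_to_plane(pts)
    else:
        flat = pts - pts.mean(axis=0)
    if mode == "raw":
        closed = np.vstack([flat, flat[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
    if mode != "hull":
        raise ValueError(f"unknown perimeter mode {mode!r}")
    try:
        hull = ConvexHull(flat)
    except QhullError as exc:
        raise DegeneratePolygonError(f"degenerate loop: {exc}") from exc
    # for 2D inputs, ConvexHull.area is the hull perimeter
    return float(hull.area)


def section_polygons(mesh: TriMesh, plane_origin, plane_normal, heights):
    """Batch parallel sections, as shapely polygons in plane coordinates.

    Returns a list (one entry per height, ``None`` where the plane misses the
    mesh) of ``(polygons, to_3D)`` with ``polygons`` the closed shapely
    polygons of that section and ``to_3D`` the 4x4 plane-to-world transform.
    Used by the landmark and measurement sweeps.
    """
    from shapely.geometry import MultiPolygon, Polygon

    tm = mesh.to_trimesh()
    heights = np.asarray(heights, dtype=np.float64)
    paths = tm.section_multiplane(
        plane_origin=np.asarray(plane_origin, dtype=np.float64),
        plane_normal=np.asarray(plane_normal, dtype=np.float64),
        heights=heights,
    )
    out = []
    for p in paths:
        if p is None:
            out.append(None)
            continue
        polys = []
        for loop in p.discrete:
            if len(loop) < 4:  # closing point included
                continue
            poly = Polygon(loop)
            if not poly.is_valid:
                # noisy contours can self-intersect; keep the dominant lobe
                fixed = poly.buffer(0)
                if isinstance(fixed, MultiPolygon):
                    fixed = max(fixed.geoms, key=lambda g: g.area)
                if not fixed.is_empty:
                    poly = fixed
            if poly.area > 0:
                polys.append(poly)
        if not polys:
            out.append(None)
            continue
        out.append((polys, np.asarray(p.metadata["to_3D"])))
    return out


def world_to_plane(point, to_3D: np.ndarray) -> np.ndarray:
    """Map a world point into the 2D coordinates of a section plane."""
    inv = np.linalg.inv(to_3D)
    p = inv @ np.append(np.asarray(point, dtype=np.float64), 1.0)
    return p[:2]


def plane_to_world(points2d: np.ndarray, to_3D: np.ndarray) -> np.ndarray:
    """Lift 2D section-plane coordinates back into world coordinates."""
    pts = np.asarray(points2d, dtype=np.float64)
    h = np.column_stack([pts, np.zeros(len(pts)), np.ones(len(pts))])
    return (to_3D @ h.T).T[:, :3]
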