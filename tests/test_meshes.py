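"""Mesh I/O, canonicalization, repair, hole filling and sectioning."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from anthroscan import (
    TriMesh,
    canonicalize,
    cross_section,
    fill_holes,
    load_mesh,
    perimeter,
    repair,
    save_mesh,
)
from anthroscan.errors import (
    DegeneratePolygonError,
    EmptyMeshError,
    FormatError,
    UnitInferenceError,
)
from anthroscan.meshes import _boundary_edge_count


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_load_cube_roundtrip_all_formats(cube, tmp_path):
    for ext in ("obj", "ply", "stl"):
        path = tmp_path / f"cube.{ext}"
        save_mesh(cube, path)
        back = load_mesh(path, units="cm")
        assert len(back.faces) == 12
        # identical vertex sets up to ordering and float round-trip
        a = np.array(sorted(map(tuple, np.round(cube.vertices, 4))))
        b = np.array(sorted(map(tuple, np.round(back.vertices, 4))))
        np.testing.assert_allclose(a, b, atol=1e-4)


def test_ply_binary_roundtrip_precision(small_avatar, tmp_path):
    mesh, _ = small_avatar
    path = tmp_path / "avatar.ply"
    save_mesh(mesh, path)
    back = load_mesh(path, units="cm")
    # loading welds exactly-coincident vertices, so compare nearest points
    from scipy.spatial import cKDTree

    d1, _ = cKDTree(back.vertices).query(mesh.vertices)
    d2, _ = cKDTree(mesh.vertices).query(back.vertices)
    assert max(d1.max(), d2.max()) <= 1e-4


def test_unit_auto_inference(cube, tmp_path):
    tall = TriMesh(cube.vertices * 1750.0, cube.faces)
    path = tmp_path / "tall.obj"
    save_mesh(tall, path)
    mesh = load_mesh(path, units="auto")
    assert mesh.height == pytest.approx(175.0, abs=1e-6)


def test_unit_inference_ambiguous_height_errors(cube, tmp_path):
    path = tmp_path / "cube.obj"
    save_mesh(cube, path)  # height 1: outside every stature band
    with pytest.raises(UnitInferenceError):
        load_mesh(path, units="auto")


def test_load_errors(tmp_path):
    with pytest.raises(FormatError):
        load_mesh(tmp_path / "missing.obj")
    bad = tmp_path / "scan.xyz"
    bad.write_text("not a mesh")
    with pytest.raises(FormatError):
        load_mesh(bad)
    empty = tmp_path / "empty.obj"
    empty.write_text("# empty file\n")
    with pytest.raises(EmptyMeshError):
        load_mesh(empty)


# ---------------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------------

def test_canonicalize_restores_rotated_avatar(avatar):
    mesh, _ = avatar
    reference = canonicalize(mesh)
    angle = np.radians(30.0)
    R = np.array([[1, 0, 0],
                  [0, np.cos(angle), -np.sin(angle)],
                  [0, np.sin(angle), np.cos(angle)]])
    moved = TriMesh(mesh.vertices @ R.T + np.array([40.0, -12.0, 7.0]),
                    mesh.faces)
    restored = canonicalize(moved)
    assert np.abs(restored.vertices - reference.vertices).max() < 0.1


def test_canonicalize_idempotent(avatar):
    mesh, _ = avatar
    once = canonicalize(mesh)
    twice = canonicalize(once)
    assert np.abs(twice.vertices - once.vertices).max() < 1e-8
    assert once.frame == "canonical"


def test_canonicalize_preserves_scale(avatar):
    mesh, _ = avatar
    base = canonicalize(mesh)
    doubled = canonicalize(TriMesh(mesh.vertices * 2.0, mesh.faces))
    assert doubled.height == pytest.approx(2.0 * base.height, rel=1e-9)
    # scale equivariance: canonicalize(s*mesh) = s*canonicalize(mesh)
    assert np.abs(doubled.vertices - 2.0 * base.vertices).max() < 1e-6


def test_canonicalize_degenerate_geometry_errors():
    line = np.column_stack([np.linspace(0, 1, 8), np.zeros(8), np.zeros(8)])
    flat = TriMesh(np.vstack([line, line + [0, 1e-14, 0]]),
                   [[0, 1, 8], [1, 9, 8], [2, 3, 10], [3, 11, 10]])
    from anthroscan.errors import AlignmentError
    with pytest.raises(AlignmentError):
        canonicalize(flat)


# ---------------------------------------------------------------------------
# repair
# ---------------------------------------------------------------------------

def test_repair_removes_duplicate_face(cube):
    dup = TriMesh(cube.vertices, np.vstack([cube.faces, cube.faces[3:4]]))
    out, rep = repair(dup)
    assert len(out.faces) == 12
    assert rep.n_duplicates_removed == 1
    assert rep.watertight


def test_repair_removes_degenerate_faces(cube):
    v = np.vstack([cube.vertices, cube.vertices[:1] + 1e-9])
    faces = np.vstack([cube.faces, [[0, 1, 1]], [[0, 1, 8]]])
    out, rep = repair(TriMesh(v, faces))
    assert rep.n_degenerate_removed == 2  # repeated index + near-zero area
    assert len(out.faces) == 12


def test_repair_clean_mesh_is_noop_and_idempotent(cube):
    out, rep = repair(cube)
    assert rep.n_degenerate_removed == rep.n_duplicates_removed == 0
    np.testing.assert_array_equal(out.faces, cube.faces)
    again, rep2 = repair(out)
    np.testing.assert_array_equal(again.faces, out.faces)
    assert rep2.n_degenerate_removed == rep2.n_duplicates_removed == 0


def test_repair_keeps_vertices_untouched(cube):
    out, _ = repair(TriMesh(cube.vertices, np.vstack([cube.faces,
                                                      [[0, 0, 1]]])))
    np.testing.assert_array_equal(out.vertices, cube.vertices)


# ---------------------------------------------------------------------------
# hole filling
# ---------------------------------------------------------------------------

def test_fill_single_missing_triangle_restores_icosphere():
    ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    full_area = ico.area
    holed = TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces)[1:])
    filled, rep = fill_holes(holed)
    assert rep.n_holes_filled == 1
    assert rep.n_boundary_edges_after == 0
    assert abs(filled.to_trimesh().area - full_area) / full_area < 0.01


def test_fill_avatar_holes(avatar):
    from anthroscan import degrade_mesh

    mesh, _ = avatar
    holed = degrade_mesh(mesh, holes=2, hole_radius=2.5, seed=3)
    filled, rep = fill_holes(holed)
    assert rep.n_holes_filled == 2
    assert rep.n_boundary_edges_after == 0
    assert filled.to_trimesh().is_watertight
    # original vertices unmoved
    n = len(holed.vertices)
    np.testing.assert_array_equal(filled.vertices[:n], holed.vertices)


def test_fill_watertight_is_noop(cube):
    out, rep = fill_holes(cube)
    assert rep.n_holes_filled == 0
    np.testing.assert_array_equal(out.faces, cube.faces)


def test_fill_patch_follows_curvature():
    # carve a multi-face hole in a sphere: the inserted centre vertex should
    # sit near the spherical surface, not on the flat ring plane
    ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    v, f = np.asarray(ico.vertices), np.asarray(ico.faces)
    top = np.argmax(v[:, 2])
    keep = ~(f == top).any(axis=1)
    filled, rep = fill_holes(TriMesh(v, f[keep]))
    assert rep.n_holes_filled == 1
    centre = filled.vertices[-1]
    assert np.linalg.norm(centre) > 9.9  # flat fan would sit at ~9.8


# ---------------------------------------------------------------------------
# sectioning and perimeters
# ---------------------------------------------------------------------------

def test_cube_section_is_unit_square(cube):
    cs = cross_section(cube, (0.5, 0.5, 0.5), (0, 0, 1))
    assert cs.n_loops == 1
    assert cs.perimeters[0] == pytest.approx(4.0, abs=1e-9)


def test_cylinder_section_matches_ngon_closed_form():
    cyl = trimesh.creation.cylinder(radius=10.0, height=50.0, sections=360)
    mesh = TriMesh(np.asarray(cyl.vertices), np.asarray(cyl.faces))
    cs = cross_section(mesh, (0, 0, 0), (0, 0, 1))
    expected = 2 * 360 * 10.0 * np.sin(np.pi / 360)
    assert cs.n_loops == 1
    assert cs.perimeters[0] == pytest.approx(expected, rel=1e-9)


def test_cylinder_section_converges_to_circle():
    perims = []
    for n in (36, 360):
        cyl = trimesh.creation.cylinder(radius=10.0, height=50.0, sections=n)
        mesh = TriMesh(np.asarray(cyl.vertices), np.asarray(cyl.faces))
        perims.append(cross_section(mesh, (0, 0, 0), (0, 0, 1)).perimeters[0])
    assert perims[0] < perims[1] < 2 * np.pi * 10.0


def test_two_leg_slice_has_two_loops(avatar):
    mesh, gt = avatar
    z = gt.landmarks["crotch"][2] - 10.0
    cs = cross_section(mesh, (0, 0, z), (0, 0, 1))
    assert cs.n_loops == 2


def test_missing_plane_gives_empty_section(cube):
    cs = cross_section(cube, (0, 0, 99.0), (0, 0, 1))
    assert cs.n_loops == 0


def test_perimeter_square_both_modes():
    sq = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], float)
    assert perimeter(sq, "hull") == pytest.approx(40.0)
    assert perimeter(sq, "raw") == pytest.approx(40.0)


def _gift_wrap_perimeter(pts2d: np.ndarray) -> float:
    """Independent O(n^2) planar convex-hull (gift wrapping) oracle."""
    pts = np.unique(np.round(pts2d, 12), axis=0)
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % len(pts)
        for j in range(len(pts)):
            if j == cur:
                continue
            cross = np.cross(pts[cand] - pts[cur], pts[j] - pts[cur])
            if cross < 0 or (cross == 0 and
                             np.linalg.norm(pts[j] - pts[cur]) >
                             np.linalg.norm(pts[cand] - pts[cur])):
                cand = j
        if cand == start:
            break
        hull.append(cand)
        if len(hull) > len(pts):  # pragma: no cover - safety
            raise RuntimeError("gift wrapping failed")
    ring = pts[hull + [start]]
    return float(np.linalg.norm(np.diff(ring, axis=0), axis=1).sum())


def test_star_hull_perimeter_matches_gift_wrap_oracle():
    ang = np.linspace(0, 2 * np.pi, 10, endpoint=False) - np.pi / 2
    radii = np.where(np.arange(10) % 2 == 0, 10.0, 4.0)
    star2d = np.column_stack([radii * np.cos(ang), radii * np.sin(ang)])
    star3d = np.column_stack([star2d, np.zeros(10)])
    hull = perimeter(star3d, "hull")
    raw = perimeter(star3d, "raw")
    assert hull < raw
    assert hull == pytest.approx(_gift_wrap_perimeter(star2d), rel=1e-9)


def test_collinear_loop_errors():
    pts = np.column_stack([np.arange(5.0), np.arange(5.0), np.zeros(5)])
    with pytest.raises(DegeneratePolygonError):
        perimeter(pts, "hull")
    with pytest.raises(DegeneratePolygonError):
        perimeter(pts[:2], "raw")


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10 ** 6))
def test_hull_never_exceeds_raw_perimeter(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(4, 40))
    ang = np.sort(rng.uniform(0, 2 * np.pi, k))
    r = rng.uniform(1.0, 20.0, k)
    pts = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(k)])
    if np.linalg.matrix_rank(pts[:, :2] - pts[:, :2].mean(0)) < 2:
        return
    assert perimeter(pts, "hull") <= perimeter(pts, "raw") + 1e-9


def test_convex_loop_hull_equals_raw():
    ang = np.linspace(0, 2 * np.pi, 50, endpoint=False)
    pts = np.column_stack([7 * np.cos(ang), 5 * np.sin(ang), np.zeros(50)])
    assert perimeter(pts, "hull") == pytest.approx(perimeter(pts, "raw"),
                                                   rel=1e-9)


def test_boundary_edges_bookkeeping(cube):
    assert _boundary_edge_count(cube.faces) == 0
    assert _boundary_edge_count(cube.faces[1:]) == 3
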