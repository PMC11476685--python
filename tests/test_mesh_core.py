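"""Mesh data model, STL/PLY round trips and geometric primitives."""

import io
import struct

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from guidefit.mesh_core import (
    MeshError,
    Plane,
    StlParseError,
    SurfaceQuery,
    TriangleMesh,
    closest_point_on_triangle,
    principal_axis,
    proximal_split_plane,
    read_ply,
    read_stl,
    signed_distance_point,
    split_by_plane,
    write_ply,
    write_stl,
)
from guidefit.synthetic_phantom import GuideRegionSpec, generate_guide_base

from conftest import icosphere, random_bumpy_sphere


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------


ASCII_ONE_FACET = """solid one
facet normal 0 0 1
  outer loop
    vertex 0 0 0
    vertex 1 0 0
    vertex 0 1 0
  endloop
endfacet
endsolid one
"""


def _write_binary_stl(path, facets):
    """Raw binary STL writer used as an independent byte-level oracle."""
    with open(path, "wb") as fh:
        fh.write(b"\0" * 80)
        fh.write(struct.pack("<I", len(facets)))
        for tri in facets:
            fh.write(struct.pack("<3f", 0, 0, 0))
            for v in tri:
                fh.write(struct.pack("<3f", *v))
            fh.write(struct.pack("<H", 0))


def _cube_facets():
    """12 facets of the unit cube, 36 corner records, 8 unique vertices."""
    import trimesh

    box = trimesh.creation.box(extents=(1, 1, 1))
    return box.vertices[box.faces]


def test_read_ascii_single_facet(tmp_path):
    p = tmp_path / "one.stl"
    p.write_text(ASCII_ONE_FACET)
    m = read_stl(p)
    assert m.n_vertices == 3 and m.n_faces == 1
    assert {tuple(v) for v in m.vertices} == {(0, 0, 0), (1, 0, 0), (0, 1, 0)}


def test_read_binary_cube_welds_exactly(tmp_path):
    p = tmp_path / "cube.stl"
    _write_binary_stl(p, _cube_facets())
    m = read_stl(p)
    assert m.n_vertices == 8 and m.n_faces == 12
    assert m.is_closed_oriented()


def test_read_errors(tmp_path):
    empty = tmp_path / "empty.stl"
    empty.write_bytes(b"")
    with pytest.raises(StlParseError):
        read_stl(empty)
    bad = tmp_path / "bad.stl"
    bad.write_bytes(b"\0" * 80 + struct.pack("<I", 5) + b"\0" * 50)  # claims 5 facets
    with pytest.raises(StlParseError, match="byte offset 80"):
        read_stl(bad)


@pytest.mark.parametrize("mode", ["binary", "ascii"])
def test_stl_round_trip_cube(tmp_path, mode):
    import trimesh

    box = trimesh.creation.box(extents=(1, 1, 1))
    m = TriangleMesh(box.vertices.copy(), box.faces.copy())
    path = tmp_path / f"cube_{mode}.stl"
    write_stl(m, path, mode)
    r = read_stl(path)
    assert r.n_vertices == 8 and r.n_faces == 12
    assert sorted(map(tuple, r.vertices.tolist())) == sorted(map(tuple, m.vertices.tolist()))


def test_stl_round_trip_phantom_topology(tmp_path, phantom):
    *_, mesh = phantom
    path = tmp_path / "phantom.stl"
    write_stl(mesh, path, "ascii")
    r = read_stl(path)
    assert r.n_faces == mesh.n_faces
    assert r.n_vertices == mesh.n_vertices
    assert r.is_closed_oriented()


def test_write_empty_mesh_rejected(tmp_path):
    m = TriangleMesh(np.zeros((3, 3)), np.empty((0, 3), dtype=int))
    with pytest.raises(MeshError):
        write_stl(m, tmp_path / "x.stl")


def test_ply_round_trip_scalars(tmp_path):
    m = icosphere(5.0, 1)
    m.per_vertex_scalars["signed_distance_mm"] = np.linspace(-0.3, 0.7, m.n_vertices)
    path = tmp_path / "m.ply"
    write_ply(m, path)
    r = read_ply(path)
    assert np.array_equal(r.vertices, m.vertices)
    assert np.array_equal(r.faces, m.faces)
    assert np.array_equal(
        r.per_vertex_scalars["signed_distance_mm"], m.per_vertex_scalars["signed_distance_mm"]
    )


# ---------------------------------------------------------------------------
# Closest point on triangle
# ---------------------------------------------------------------------------


def _closest_point_oracle(p, tri, grid=60):
    """Brute-force oracle: dense barycentric grid then a constrained local
    polish of min |p - q(u, v)| over the simplex u, v >= 0, u + v <= 1."""
    from scipy.optimize import minimize

    u = np.linspace(0, 1, grid)
    U, V = np.meshgrid(u, u)
    mask = U + V <= 1.0 + 1e-15
    U, V = U[mask], V[mask]
    q = (1 - U - V)[:, None] * tri[0] + U[:, None] * tri[1] + V[:, None] * tri[2]
    d2 = ((q - p) ** 2).sum(axis=1)
    k = int(np.argmin(d2))

    def f(x):
        qq = (1 - x[0] - x[1]) * tri[0] + x[0] * tri[1] + x[1] * tri[2]
        return float(((qq - p) ** 2).sum())

    res = minimize(
        f, [U[k], V[k]], method="SLSQP",
        bounds=[(0, 1), (0, 1)],
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x[0] - x[1]}],
        options={"ftol": 1e-16, "maxiter": 200},
    )
    # SLSQP may end a hair outside the simplex; project back before evaluating
    x = np.clip(res.x, 0.0, 1.0)
    if x.sum() > 1.0:
        x = x / x.sum()
    return np.sqrt(min(f(x), d2[k]))


def test_closest_point_vertex_identity():
    tri = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0]])
    q, d, tag = closest_point_on_triangle(tri[0], tri)
    assert d == 0.0 and np.array_equal(q, tri[0]) and tag.startswith("vertex")


def test_closest_point_perpendicular_foot():
    tri = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0]])
    q, d, tag = closest_point_on_triangle([0.5, 0.5, 1.0], tri)
    assert tag == "face"
    np.testing.assert_allclose(q, [0.5, 0.5, 0.0], atol=1e-12)
    assert d == pytest.approx(1.0, abs=1e-12)


def test_closest_point_degenerate_triangle_rejected():
    tri = np.array([[0.0, 0, 0], [1, 1, 1], [2, 2, 2]])
    with pytest.raises(MeshError):
        closest_point_on_triangle([0, 0, 1], tri)


def test_closest_point_matches_barycentric_oracle():
    rng = np.random.default_rng(42)
    for _ in range(300):
        tri = rng.normal(scale=3.0, size=(3, 3))
        if np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0])) < 1e-3:
            continue
        p = rng.normal(scale=4.0, size=3)
        q, d, _ = closest_point_on_triangle(p, tri)
        # postconditions
        assert d <= np.linalg.norm(tri - p, axis=1).min() + 1e-12
        assert d == pytest.approx(np.linalg.norm(p - q), abs=1e-12)
        assert d == pytest.approx(_closest_point_oracle(p, tri), abs=1e-9)


# ---------------------------------------------------------------------------
# Signed distance
# ---------------------------------------------------------------------------


def _tessellation_sag(mesh, radius):
    """Max inradius deficit of a sphere tessellation: how far the faces sag
    below the ideal sphere."""
    tri = mesh.triangles()
    centroids = tri.mean(axis=1)
    return radius - np.linalg.norm(centroids, axis=1).min()


def test_signed_distance_sphere_limits():
    m = icosphere(10.0, 3)
    sq = SurfaceQuery(m)
    sag = _tessellation_sag(m, 10.0)
    assert sag < 0.2
    inside = signed_distance_point([0.0, 0, 0], m, sq)
    assert inside == pytest.approx(-10.0, abs=sag + 1e-9)
    out_dir = np.array([1.0, 1, 1]) / np.sqrt(3)
    outside = signed_distance_point(20.0 * out_dir, m, sq)
    assert outside == pytest.approx(10.0, abs=sag + 1e-9)


def test_signed_distance_zero_on_vertices():
    m = icosphere(10.0, 2)
    sq = SurfaceQuery(m)
    assert np.all(sq.signed_distance(m.vertices) == 0.0)


def test_sphere_limit_converges_with_subdivision():
    r = 10.0
    errs = []
    for sub in (1, 2, 3):
        m = icosphere(r, sub)
        sag = _tessellation_sag(m, r)
        d = signed_distance_point([0.0, 0, 0], m, SurfaceQuery(m))
        errs.append(abs(d + r))
        assert abs(d + r) <= sag + 1e-12
    assert errs[2] < errs[0]


def test_accelerated_equals_exhaustive_bitwise():
    rng = np.random.default_rng(7)
    for _ in range(5):
        m = random_bumpy_sphere(rng)
        assert m.n_faces <= 500
        sq = SurfaceQuery(m)
        pts = rng.normal(scale=8.0, size=(200, 3))
        a = sq.signed_distance(pts)
        b = sq.signed_distance_exhaustive(pts)
        assert np.array_equal(a, b)


def test_signed_distance_rigid_invariance():
    rng = np.random.default_rng(11)
    m = random_bumpy_sphere(rng)
    pts = rng.normal(scale=8.0, size=(50, 3))
    d0 = SurfaceQuery(m).signed_distance(pts)
    R = Rotation.random(random_state=1).as_matrix()
    t = np.array([3.0, -7.0, 11.0])
    m2 = m.with_vertices(m.vertices @ R.T + t)
    d1 = SurfaceQuery(m2).signed_distance(pts @ R.T + t)
    np.testing.assert_allclose(d1, d0, atol=1e-9)


def test_signed_distance_scaling():
    rng = np.random.default_rng(13)
    m = random_bumpy_sphere(rng)
    pts = rng.normal(scale=8.0, size=(50, 3))
    d0 = SurfaceQuery(m).signed_distance(pts)
    s = 2.75
    d1 = SurfaceQuery(m.with_vertices(m.vertices * s)).signed_distance(pts * s)
    np.testing.assert_allclose(d1, s * d0, rtol=1e-9, atol=1e-12)


def test_open_target_rejected():
    m = icosphere(10.0, 1)
    open_mesh = TriangleMesh(m.vertices, m.faces[:-2], name="open")
    with pytest.raises(MeshError):
        SurfaceQuery(open_mesh)
    inverted = TriangleMesh(m.vertices, m.faces[:, ::-1], name="inverted")
    with pytest.raises(MeshError):
        SurfaceQuery(inverted)


# ---------------------------------------------------------------------------
# Principal axis and plane splitting
# ---------------------------------------------------------------------------


def _cylinder(radius=10.0, height=200.0):
    import trimesh

    c = trimesh.creation.cylinder(radius=radius, height=height, sections=48)
    return TriangleMesh(c.vertices.copy(), c.faces.copy(), name="cyl")


def test_principal_axis_cylinder():
    axis, degenerate = principal_axis(_cylinder())
    assert not degenerate
    np.testing.assert_allclose(np.abs(axis), [0, 0, 1], atol=1e-9)
    assert axis[2] > 0  # sign convention


def test_principal_axis_rotated_cylinder():
    m = _cylinder()
    R = Rotation.from_euler("xy", [35, -20], degrees=True).as_matrix()
    axis, _ = principal_axis(m.with_vertices(m.vertices @ R.T))
    expected = R @ np.array([0, 0, 1.0])
    if expected[2] < 0:
        expected = -expected
    np.testing.assert_allclose(axis, expected, atol=1e-6)


def test_principal_axis_degeneracy_and_collinear():
    assert principal_axis(icosphere(10.0, 2)).degenerate
    line = TriangleMesh(np.outer(np.arange(5.0), [1, 1, 1]), [[0, 1, 2]])
    with pytest.raises(MeshError):
        principal_axis(line)


def test_split_cube_areas():
    import trimesh

    box = trimesh.creation.box(extents=(1, 1, 1))  # centred at origin
    m = TriangleMesh(box.vertices.copy(), box.faces.copy())
    pos, neg = split_by_plane(m, Plane.make((0, 0, 0), (0, 0, 1)))
    assert pos.area() == pytest.approx(3.0, rel=1e-12)
    assert neg.area() == pytest.approx(3.0, rel=1e-12)


def test_split_missing_plane_warns():
    import trimesh

    box = trimesh.creation.box(extents=(1, 1, 1))
    m = TriangleMesh(box.vertices.copy(), box.faces.copy())
    with pytest.warns(UserWarning, match="misses"):
        pos, neg = split_by_plane(m, Plane.make((0, 0, -10.0), (0, 0, 1)))
    assert pos.n_faces == m.n_faces and neg.n_faces == 0


def test_split_area_conservation_random_planes():
    rng = np.random.default_rng(5)
    m = random_bumpy_sphere(rng)
    total = m.area()
    for _ in range(10):
        n = rng.normal(size=3)
        plane = Plane.make(rng.normal(scale=3.0, size=3), n)
        pos, neg = split_by_plane(m, plane)
        assert pos.area() + neg.area() == pytest.approx(total, rel=1e-6)


def test_proximal_split_plane_position(phantom):
    params, _, _, bone = phantom
    guide = generate_guide_base(bone, GuideRegionSpec(axial_extent=20.0))
    plane = proximal_split_plane(bone, guide)
    coord = guide.vertices @ plane.normal
    origin_coord = plane.origin @ plane.normal
    assert origin_coord == pytest.approx(coord.min() - 0.5, abs=1e-9)
    # normal points distally: guide entirely on the positive side
    assert (plane.signed_side(guide.vertices) > 0).all()


def test_proximal_split_plane_translation_equivariance(phantom):
    *_, bone = phantom
    guide = generate_guide_base(bone, GuideRegionSpec(axial_extent=20.0))
    p0 = proximal_split_plane(bone, guide)
    t = np.array([5.0, -3.0, 12.0])
    p1 = proximal_split_plane(bone.translated(t), guide.translated(t))
    np.testing.assert_allclose(p1.normal, p0.normal, atol=1e-9)
    assert p1.origin @ p1.normal == pytest.approx((p0.origin + t) @ p0.normal, abs=1e-6)


def test_validate_rejects_bad_meshes():
    with pytest.raises(MeshError):
        TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 1]]).validate()
    with pytest.raises(MeshError):
        TriangleMesh([[0, 0, 0], [1, 0, 0], [np.inf, 1, 0]], [[0, 1, 2]]).validate()
    with pytest.raises(MeshError):
        TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 3]]).validate()
    with pytest.raises(MeshError):  # zero-area face
        TriangleMesh([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1, 2]]).validate()
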