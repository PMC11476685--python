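"""Triangle-mesh data model and geometric primitives.

Meshes are indexed triangle surfaces with coordinates in millimetres, the
native unit of the STL models this package analyses (bone models and guide
bases).  The central primitive is the signed point-to-surface distance: the
magnitude is the closest-point distance to the triangle soup, and the sign is
taken from the angle-weighted pseudonormal at the closest feature
(Baerentzen & Aanaes), which gives a provably correct inside/outside
classification for closed, consistently outward-oriented meshes.  Negative
values mean the query point lies inside the target surface — the convention
under which a guide "overlapping" the bone has negative distance.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TriangleMesh",
    "Plane",
    "SurfaceQuery",
    "MeshError",
    "StlParseError",
    "OrientationError",
    "read_stl",
    "write_stl",
    "write_ply",
    "read_ply",
    "closest_point_on_triangle",
    "closest_points_on_triangles",
    "signed_distance_point",
    "principal_axis",
    "PrincipalAxis",
    "split_by_plane",
    "proximal_split_plane",
    "FEATURE_FACE",
    "FEATURE_VERTEX",
    "FEATURE_EDGE",
]

_AREA_TOL = 1e-12  # mm^2; faces below this are considered degenerate

# feature tags for closest-point queries
FEATURE_FACE = 0
FEATURE_VERTEX = (1, 2, 3)  # vertex a, b, c
FEATURE_EDGE = (4, 5, 6)  # edge (a,b), (b,c), (c,a)


class MeshError(ValueError):
    """Invalid mesh data."""


class StlParseError(MeshError):
    """Malformed STL file."""


class OrientationError(MeshError):
    """Mesh is not closed / consistently outward-oriented where required."""


@dataclass
class TriangleMesh:
    """Indexed triangle surface in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Vertex indices, counter-clockwise when seen from outside for
        outward-oriented surfaces.
    name : str
    per_vertex_scalars : dict[str, (n,) float array]
        Optional named scalar attributes (e.g. ``"signed_distance_mm"``).
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""
    per_vertex_scalars: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- basic queries -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        cr = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for closed outward meshes."""
        t = self.triangles()
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`MeshError` on failure."""
        if self.n_faces == 0:
            raise MeshError(f"mesh {self.name!r} has no faces")
        if not np.isfinite(self.vertices).all():
            raise MeshError(f"mesh {self.name!r} has non-finite coordinates")
        if self.n_faces and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise MeshError(f"mesh {self.name!r} has out-of-range face indices")
        f = self.faces
        if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
            raise MeshError(f"mesh {self.name!r} has faces repeating a vertex")
        if (self.face_areas() <= _AREA_TOL).any():
            raise MeshError(f"mesh {self.name!r} has zero-area faces (tol {_AREA_TOL} mm^2)")
        for key, vals in self.per_vertex_scalars.items():
            if len(vals) != self.n_vertices:
                raise MeshError(f"scalar {key!r} length {len(vals)} != n_vertices")

    def is_closed_oriented(self) -> bool:
        """True iff every edge is shared by exactly two faces traversed in
        opposite directions and the enclosed signed volume is positive."""
        e = self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
        lo = e.min(axis=1).astype(np.int64)
        hi = e.max(axis=1).astype(np.int64)
        forward = e[:, 0] < e[:, 1]
        key = lo * (self.n_vertices + 1) + hi
        order = np.argsort(key, kind="stable")
        key_s = key[order]
        fwd_s = forward[order]
        boundaries = np.flatnonzero(np.diff(key_s)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(key_s)]))
        if ((ends - starts) != 2).any():
            return False
        if not np.all(fwd_s[starts] != fwd_s[starts + 1]):
            return False
        return self.signed_volume() > 0

    def require_closed_oriented(self) -> None:
        if not self.is_closed_oriented():
            raise OrientationError(
                f"mesh {self.name!r} is not a closed, outward-oriented surface; "
                "signed distance to it is undefined"
            )

    # -- convenience ---------------------------------------------------

    def with_vertices(self, vertices: np.ndarray, name: str | None = None) -> "TriangleMesh":
        return TriangleMesh(
            np.asarray(vertices, dtype=np.float64),
            self.faces.copy(),
            name if name is not None else self.name,
            dict(self.per_vertex_scalars),
        )

    def translated(self, t) -> "TriangleMesh":
        return self.with_vertices(self.vertices + np.asarray(t, dtype=np.float64))

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(), self.name, dict(self.per_vertex_scalars)
        )


class Plane(NamedTuple):
    """Oriented plane: points ``x`` with ``dot(x - origin, normal) > 0`` lie on
    the positive side."""

    origin: np.ndarray
    normal: np.ndarray

    @staticmethod
    def make(origin, normal) -> "Plane":
        origin = np.asarray(origin, dtype=np.float64).reshape(3)
        normal = np.asarray(normal, dtype=np.float64).reshape(3)
        nrm = np.linalg.norm(normal)
        if not np.isfinite(nrm) or nrm == 0:
            raise ValueError("plane normal must be non-zero and finite")
        if abs(nrm - 1.0) > 1e-9:
            normal = normal / nrm
        return Plane(origin, normal)

    def signed_side(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) - self.origin) @ self.normal


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------

_BINARY_FACET = np.dtype(
    [("normal", "<f4", (3,)), ("v", "<f4", (3, 3)), ("attr", "<u2")]
)


def _weld_exact(raw_vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge bit-identical vertices; returns (unique_vertices, inverse).

    Exact-bit welding (no epsilon) preserves the property that a guide contact
    surface copied from a bone keeps exactly the bone's coordinates.
    """
    v = np.ascontiguousarray(raw_vertices, dtype=np.float64)
    view = v.view([("x", np.float64), ("y", np.float64), ("z", np.float64)]).reshape(-1)
    _, first, inverse = np.unique(view, return_index=True, return_inverse=True)
    return v[first], inverse


def _from_facet_soup(raw: np.ndarray, name: str) -> TriangleMesh:
    verts, inverse = _weld_exact(raw.reshape(-1, 3))
    faces = inverse.reshape(-1, 3)
    degenerate = (
        (faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2]) | (faces[:, 0] == faces[:, 2])
    )
    if degenerate.any():
        warnings.warn(
            f"dropping {int(degenerate.sum())} degenerate facet(s) while reading {name!r}",
            stacklevel=3,
        )
        faces = faces[~degenerate]
    mesh = TriangleMesh(verts, faces, name=name)
    if mesh.n_faces == 0:
        raise StlParseError(f"{name}: no non-degenerate facets")
    return mesh


def _looks_ascii(data: bytes) -> bool:
    if not data[:6].lower().startswith(b"solid"):
        return False
    # binary files may also start with "solid": require a facet keyword early on
    return b"facet" in data[:1024].lower() or data.strip().lower().endswith(b"endsolid")


def read_stl(path) -> TriangleMesh:
    """Read an ASCII or binary STL file into an exactly-welded indexed mesh.

    Duplicated facet corners are merged only when bit-identical; winding is
    preserved from the file.  Binary files with a facet count inconsistent
    with the file size raise :class:`StlParseError` naming the byte offset.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) == 0:
        raise StlParseError(f"{path}: empty file (0 bytes)")
    if _looks_ascii(data):
        import trimesh.exchange.stl as _stl
        import io

        try:
            kw = _stl.load_stl(io.BytesIO(data))
        except Exception as exc:  # trimesh raises various types on bad input
            raise StlParseError(f"{path}: malformed ASCII STL ({exc})") from exc
        faces = np.asarray(kw["faces"])
        verts = np.asarray(kw["vertices"], dtype=np.float64)
        if len(faces) == 0:
            raise StlParseError(f"{path}: empty solid")
        return _from_facet_soup(verts[faces.reshape(-1)], path.name)
    # binary
    if len(data) < 84:
        raise StlParseError(
            f"{path}: binary STL truncated before facet count at byte offset 80 "
            f"(file is {len(data)} bytes)"
        )
    (count,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * count
    if len(data) != expected:
        raise StlParseError(
            f"{path}: facet count {count} at byte offset 80 implies {expected} bytes, "
            f"file has {len(data)}"
        )
    if count == 0:
        raise StlParseError(f"{path}: empty solid (0 facets)")
    rec = np.frombuffer(data, dtype=_BINARY_FACET, count=count, offset=84)
    return _from_facet_soup(rec["v"].astype(np.float64), path.name)


def write_stl(mesh: TriangleMesh, path, mode: str = "binary") -> None:
    """Write ``mesh`` as STL.  ``mode`` is ``"binary"`` (80-byte header,
    uint32 count, 50-byte facet records) or ``"ascii"``.

    STL stores facet corners as float32; coordinates representable in float32
    (including everything previously read from an STL) round-trip exactly.
    """
    if mode not in ("binary", "ascii"):
        raise ValueError(f"mode must be 'binary' or 'ascii', got {mode!r}")
    mesh.validate()
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    path = Path(path)
    file_type = "stl" if mode == "binary" else "stl_ascii"
    out = tm.export(file_type=file_type)
    if isinstance(out, str):
        out = out.encode()
    path.write_bytes(out)


# ---------------------------------------------------------------------------
# PLY I/O (binary little-endian, with optional per-vertex double scalars)
# ---------------------------------------------------------------------------


def write_ply(mesh: TriangleMesh, path) -> None:
    """Write a binary little-endian PLY with double-precision coordinates and
    every entry of ``per_vertex_scalars`` as a double vertex property.

    Double precision is used so attached distance scalars round-trip
    bit-for-bit (float32 would quantise sub-micrometre distances).
    """
    path = Path(path)
    scalars = {k: np.asarray(v, dtype=np.float64) for k, v in mesh.per_vertex_scalars.items()}
    for k, v in scalars.items():
        if len(v) != mesh.n_vertices:
            raise MeshError(f"scalar {k!r} length {len(v)} != n_vertices {mesh.n_vertices}")
    header = ["ply", "format binary_little_endian 1.0"]
    header.append(f"element vertex {mesh.n_vertices}")
    for axis in "xyz":
        header.append(f"property double {axis}")
    for k in scalars:
        header.append(f"property double {k}")
    header.append(f"element face {mesh.n_faces}")
    header.append("property list uchar int vertex_indices")
    header.append("end_header")
    vdtype = np.dtype(
        [("x", "<f8"), ("y", "<f8"), ("z", "<f8")] + [(k, "<f8") for k in scalars]
    )
    vrec = np.empty(mesh.n_vertices, dtype=vdtype)
    vrec["x"], vrec["y"], vrec["z"] = mesh.vertices.T
    for k, v in scalars.items():
        vrec[k] = v
    fdtype = np.dtype([("n", "u1"), ("idx", "<i4", (3,))])
    frec = np.empty(mesh.n_faces, dtype=fdtype)
    frec["n"] = 3
    frec["idx"] = mesh.faces.astype(np.int32)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(vrec.tobytes())
        fh.write(frec.tobytes())


def read_ply(path) -> TriangleMesh:
    """Read a binary little-endian PLY written by :func:`write_ply`."""
    path = Path(path)
    data = path.read_bytes()
    end = data.find(b"end_header\n")
    if end < 0:
        raise MeshError(f"{path}: missing PLY end_header")
    header = data[:end].decode("ascii").splitlines()
    body = data[end + len(b"end_header\n"):]
    if header[0] != "ply" or "binary_little_endian" not in header[1]:
        raise MeshError(f"{path}: not a binary little-endian PLY")
    n_vert = n_face = 0
    vprops: list[str] = []
    current = None
    for line in header[2:]:
        parts = line.split()
        if parts[0] == "element":
            current = parts[1]
            if current == "vertex":
                n_vert = int(parts[2])
            elif current == "face":
                n_face = int(parts[2])
        elif parts[0] == "property" and current == "vertex":
            if parts[1] != "double":
                raise MeshError(f"{path}: unsupported vertex property type {parts[1]}")
            vprops.append(parts[2])
    vdtype = np.dtype([(p, "<f8") for p in vprops])
    vrec = np.frombuffer(body, dtype=vdtype, count=n_vert)
    fdtype = np.dtype([("n", "u1"), ("idx", "<i4", (3,))])
    frec = np.frombuffer(body, dtype=fdtype, count=n_face, offset=n_vert * vdtype.itemsize)
    verts = np.column_stack([vrec["x"], vrec["y"], vrec["z"]])
    scalars = {p: np.array(vrec[p]) for p in vprops if p not in ("x", "y", "z")}
    return TriangleMesh(verts, frec["idx"].astype(np.int64), name=path.name,
                        per_vertex_scalars=scalars)


# ---------------------------------------------------------------------------
# Closest point on triangle (Ericson, vectorised)
# ---------------------------------------------------------------------------


def _dot(u, v):
    return np.einsum("ij,ij->i", u, v)


def closest_points_on_triangles(p, a, b, c):
    """Vectorised closest point on triangles.

    All inputs are (n, 3).  Returns ``(q, d2, feature)`` where ``q`` is the
    closest point on each (closed) triangle, ``d2`` the squared distance and
    ``feature`` the tag of the supporting feature (see module constants).

    Every arithmetic step is elementwise, so results are bit-identical no
    matter how the input pairs are batched — the property that lets the
    pruned spatial query reproduce exhaustive search exactly.
    """
    p = np.asarray(p, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    n = len(p)
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = _dot(ab, ap)
    d2_ = _dot(ac, ap)
    bp = p - b
    d3 = _dot(ab, bp)
    d4 = _dot(ac, bp)
    cp = p - c
    d5 = _dot(ab, cp)
    d6 = _dot(ac, cp)
    vc = d1 * d4 - d3 * d2_
    vb = d5 * d2_ - d1 * d6
    va = d3 * d6 - d5 * d4

    q = np.empty_like(p)
    feature = np.empty(n, dtype=np.int8)
    remaining = np.ones(n, dtype=bool)

    def take(mask):
        m = mask & remaining
        remaining[m] = False
        return m

    m = take((d1 <= 0) & (d2_ <= 0))  # vertex a
    q[m] = a[m]
    feature[m] = 1
    m = take((d3 >= 0) & (d4 <= d3))  # vertex b
    q[m] = b[m]
    feature[m] = 2
    m = take((d6 >= 0) & (d5 <= d6))  # vertex c
    q[m] = c[m]
    feature[m] = 3
    m = take((vc <= 0) & (d1 >= 0) & (d3 <= 0))  # edge ab
    t = d1[m] / (d1[m] - d3[m])
    q[m] = a[m] + ab[m] * t[:, None]
    feature[m] = 4
    m = take((vb <= 0) & (d2_ >= 0) & (d6 <= 0))  # edge ca (a->c direction)
    t = d2_[m] / (d2_[m] - d6[m])
    q[m] = a[m] + ac[m] * t[:, None]
    feature[m] = 6
    m = take((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0))  # edge bc
    t = (d4[m] - d3[m]) / ((d4[m] - d3[m]) + (d5[m] - d6[m]))
    q[m] = b[m] + (c[m] - b[m]) * t[:, None]
    feature[m] = 5
    m = remaining  # face interior
    denom = 1.0 / (va[m] + vb[m] + vc[m])
    v = (vb[m] * denom)[:, None]
    w = (vc[m] * denom)[:, None]
    q[m] = a[m] + ab[m] * v + ac[m] * w
    feature[m] = 0

    diff = p - q
    d2 = _dot(diff, diff)
    return q, d2, feature


def closest_point_on_triangle(p, tri):
    """Closest point on one triangle.

    Returns ``(point, distance_mm, feature)`` with ``feature`` one of
    ``"face"``, ``"edge_0|1|2"`` (edges ab, bc, ca) or ``"vertex_0|1|2"``.
    """
    tri = np.asarray(tri, dtype=np.float64).reshape(3, 3)
    area2 = np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
    if not area2 > 2 * _AREA_TOL:
        raise MeshError("degenerate triangle")
    p = np.asarray(p, dtype=np.float64).reshape(1, 3)
    q, d2, feat = closest_points_on_triangles(p, tri[None, 0], tri[None, 1], tri[None, 2])
    code = int(feat[0])
    if code == 0:
        tag = "face"
    elif code in FEATURE_VERTEX:
        tag = f"vertex_{code - 1}"
    else:
        tag = f"edge_{code - 4}"
    return q[0], float(np.sqrt(d2[0])), tag


# ---------------------------------------------------------------------------
# Signed distance with angle-weighted pseudonormals
# ---------------------------------------------------------------------------


class SurfaceQuery:
    """Acceleration index for exact signed-distance queries against a closed,
    outward-oriented mesh.

    Candidate faces are pruned with a nearest-vertex upper bound and a
    bounding-sphere lower bound per face (kd-trees over vertices and face
    centroids); the candidate set provably contains every face attaining the
    minimum distance, so results — including ties, which are broken by lowest
    face index — are identical to exhaustive search over all faces.
    """

    def __init__(self, mesh: TriangleMesh, require_closed: bool = True):
        mesh.validate()
        if require_closed:
            mesh.require_closed_oriented()
        self.mesh = mesh
        V, F = mesh.vertices, mesh.faces
        tri = V[F]
        self._a = np.ascontiguousarray(tri[:, 0])
        self._b = np.ascontiguousarray(tri[:, 1])
        self._c = np.ascontiguousarray(tri[:, 2])
        fn = np.cross(self._b - self._a, self._c - self._a)
        fn_unit = fn / np.linalg.norm(fn, axis=1, keepdims=True)
        self._face_normal = fn_unit
        # edge pseudonormals: sum of the two incident unit face normals
        e = F[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
        ekey = np.sort(e, axis=1)
        uniq, inv = np.unique(ekey, axis=0, return_inverse=True)
        self._face_edge_id = inv.reshape(-1, 3)
        edge_n = np.zeros((len(uniq), 3))
        np.add.at(edge_n, inv, np.repeat(fn_unit, 3, axis=0))
        self._edge_normal = edge_n
        # vertex pseudonormals: incident-angle-weighted unit face normals
        vert_n = np.zeros_like(V)
        for k, (i, j) in enumerate(((1, 2), (2, 0), (0, 1))):
            u = tri[:, i] - tri[:, k]
            w = tri[:, j] - tri[:, k]
            cosang = np.einsum("ij,ij->i", u, w) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
            )
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            np.add.at(vert_n, F[:, k], fn_unit * ang[:, None])
        self._vertex_normal = vert_n
        # pruning structures
        self._centroid = tri.mean(axis=1)
        self._face_radius = np.linalg.norm(tri - self._centroid[:, None, :], axis=2).max(axis=1)
        self._rmax = float(self._face_radius.max())
        self._vtx_tree = cKDTree(V)
        self._ctr_tree = cKDTree(self._centroid)
        scale = float(np.abs(V).max()) + 1.0
        self._slack = 1e-9 * scale

    # -- internals -----------------------------------------------------

    def _signed_from_pairs(self, points, point_idx, face_idx):
        """Resolve winner per point among candidate (point, face) pairs and
        return signed distances.  Tie-break: smallest distance, then smallest
        face index — identical in pruned and exhaustive paths."""
        q, d2, feat = closest_points_on_triangles(
            points[point_idx], self._a[face_idx], self._b[face_idx], self._c[face_idx]
        )
        order = np.lexsort((face_idx, d2, point_idx))
        pi = point_idx[order]
        first = np.concatenate(([True], pi[1:] != pi[:-1]))
        sel = order[first]
        win_p = point_idx[sel]
        win_f = face_idx[sel]
        win_q = q[sel]
        win_feat = feat[sel]
        d = np.sqrt(d2[sel])
        normal = np.empty((len(sel), 3))
        mf = win_feat == 0
        normal[mf] = self._face_normal[win_f[mf]]
        for code, slot in zip(FEATURE_VERTEX, (0, 1, 2)):
            m = win_feat == code
            normal[m] = self._vertex_normal[self.mesh.faces[win_f[m], slot]]
        for code, slot in zip(FEATURE_EDGE, (0, 1, 2)):
            m = win_feat == code
            normal[m] = self._edge_normal[self._face_edge_id[win_f[m], slot]]
        side = np.einsum("ij,ij->i", points[win_p] - win_q, normal)
        signed = np.where(d == 0.0, 0.0, np.where(side < 0.0, -d, d))
        out = np.empty(len(points))
        out[win_p] = signed
        return out

    def signed_distance(self, points) -> np.ndarray:
        """Signed distances (mm) of query points: negative inside the mesh."""
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        if len(points) == 0:
            return np.empty(0)
        u, _ = self._vtx_tree.query(points)
        r = u + self._rmax + self._slack
        lists = self._ctr_tree.query_ball_point(points, r)
        counts = np.fromiter((len(l) for l in lists), dtype=np.int64, count=len(points))
        face_idx = np.concatenate([np.asarray(l, dtype=np.int64) for l in lists])
        point_idx = np.repeat(np.arange(len(points)), counts)
        # second prune: bounding-sphere lower bound must not exceed the bound
        lb = (
            np.linalg.norm(points[point_idx] - self._centroid[face_idx], axis=1)
            - self._face_radius[face_idx]
        )
        keep = lb <= u[point_idx] + self._slack
        return self._signed_from_pairs(points, point_idx[keep], face_idx[keep])

    def signed_distance_exhaustive(self, points, chunk: int = 2_000_000) -> np.ndarray:
        """Reference path: test every face for every point (oracle for tests)."""
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        m = len(self._a)
        out = np.empty(len(points))
        step = max(1, chunk // m)
        for s in range(0, len(points), step):
            pts = points[s : s + step]
            point_idx = np.repeat(np.arange(len(pts)), m)
            face_idx = np.tile(np.arange(m), len(pts))
            out[s : s + len(pts)] = self._signed_from_pairs(pts, point_idx, face_idx)
        return out


def signed_distance_point(p, mesh: TriangleMesh, accel: SurfaceQuery | None = None) -> float:
    """Signed distance (mm) from one point to a closed outward-oriented mesh;
    negative inside, positive outside, 0 on the surface."""
    if accel is None:
        accel = SurfaceQuery(mesh)
    elif accel.mesh is not mesh:
        raise ValueError("accel index was built on a different mesh")
    return float(accel.signed_distance(np.asarray(p, dtype=np.float64).reshape(1, 3))[0])


def angle_weighted_vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Unit angle-weighted pseudonormals at every vertex (Baerentzen & Aanaes).

    Each incident face contributes its unit normal weighted by the face's
    interior angle at the vertex.
    """
    V, F = mesh.vertices, mesh.faces
    tri = V[F]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    fn_unit = fn / np.linalg.norm(fn, axis=1, keepdims=True)
    out = np.zeros_like(V)
    for k, (i, j) in enumerate(((1, 2), (2, 0), (0, 1))):
        u = tri[:, i] - tri[:, k]
        w = tri[:, j] - tri[:, k]
        cosang = np.einsum("ij,ij->i", u, w) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(out, F[:, k], fn_unit * ang[:, None])
    nrm = np.linalg.norm(out, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return out / nrm


# ---------------------------------------------------------------------------
# Principal axis / plane splitting
# ---------------------------------------------------------------------------


class PrincipalAxis(NamedTuple):
    axis: np.ndarray
    degenerate: bool


def principal_axis(mesh: TriangleMesh, degeneracy_rtol: float = 0.01) -> PrincipalAxis:
    """Long axis of a mesh: unit eigenvector of the vertex covariance with the
    largest eigenvalue.

    The sign is fixed to have positive z component (ties resolved by +y then
    +x) so results are reproducible; the axis is used only through planes, for
    which the sign is irrelevant.  ``degenerate`` is True when the top two
    eigenvalues differ by less than ``degeneracy_rtol`` relatively (no
    well-defined long axis, e.g. a sphere).
    """
    V = mesh.vertices
    if len(V) < 3:
        raise MeshError("principal axis needs at least 3 vertices")
    cov = np.cov(V.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 1e-12 * max(evals[2], 1e-300):
        raise MeshError("vertices are collinear; principal axis undefined")
    axis = evecs[:, 2]
    for comp in (2, 1, 0):
        if axis[comp] != 0.0:
            if axis[comp] < 0:
                axis = -axis
            break
    degenerate = (evals[2] - evals[1]) < degeneracy_rtol * evals[2]
    return PrincipalAxis(axis, bool(degenerate))


def _clip_triangle(pts, s):
    """Clip one triangle against s >= 0.  Returns (poly_pos, poly_neg) as lists
    of 3-D points; intersection points are computed once and shared so the two
    sides partition the triangle's area exactly."""
    pos: list[np.ndarray] = []
    neg: list[np.ndarray] = []
    for i in range(3):
        j = (i + 1) % 3
        pi, pj = pts[i], pts[j]
        si, sj = s[i], s[j]
        if si >= 0:
            pos.append(pi)
        if si <= 0:
            neg.append(pi)
        if (si > 0 and sj < 0) or (si < 0 and sj > 0):
            t = si / (si - sj)
            x = pi + t * (pj - pi)
            pos.append(x)
            neg.append(x)
    return pos, neg


def _fan(poly):
    return [(poly[0], poly[k], poly[k + 1]) for k in range(1, len(poly) - 1)]


def split_by_plane(mesh: TriangleMesh, plane: Plane) -> tuple[TriangleMesh, TriangleMesh]:
    """Split a mesh by a plane into (positive-side, negative-side) open meshes.

    Faces wholly on one side are assigned by centroid side; crossing faces are
    cut along the intersection segment.  The cut is NOT capped: outputs are
    open surfaces intended only as distance *sources* (their total area equals
    the input area).  If the plane misses the mesh, one output is empty and a
    warning is issued.
    """
    s = plane.signed_side(mesh.vertices)
    sv = s[mesh.faces]
    has_pos = (sv > 0).any(axis=1)
    has_neg = (sv < 0).any(axis=1)
    crossing = has_pos & has_neg
    centroid_side = sv.sum(axis=1) >= 0

    tri_pos: list = []
    tri_neg: list = []
    tris = mesh.triangles()
    keep_pos = ~crossing & centroid_side
    keep_neg = ~crossing & ~centroid_side
    tri_pos.extend(tris[keep_pos])
    tri_neg.extend(tris[keep_neg])
    for fi in np.flatnonzero(crossing):
        pos, neg = _clip_triangle(tris[fi], sv[fi])
        if len(pos) >= 3:
            tri_pos.extend(_fan(pos))
        if len(neg) >= 3:
            tri_neg.extend(_fan(neg))

    def build(tris_list, suffix):
        if not tris_list:
            return TriangleMesh(np.empty((0, 3)), np.empty((0, 3), dtype=np.int64),
                                name=f"{mesh.name}{suffix}")
        soup = np.asarray(tris_list, dtype=np.float64).reshape(-1, 3)
        verts, inverse = _weld_exact(soup)
        faces = inverse.reshape(-1, 3)
        ok = ~(
            (faces[:, 0] == faces[:, 1])
            | (faces[:, 1] == faces[:, 2])
            | (faces[:, 0] == faces[:, 2])
        )
        return TriangleMesh(verts, faces[ok], name=f"{mesh.name}{suffix}")

    out_pos = build(tri_pos, "/pos")
    out_neg = build(tri_neg, "/neg")
    if out_pos.n_faces == 0 or out_neg.n_faces == 0:
        warnings.warn("split plane misses the mesh; one side is empty", stacklevel=2)
    return out_pos, out_neg


def proximal_split_plane(
    bone: TriangleMesh, guide: TriangleMesh, offset_mm: float = 0.5
) -> Plane:
    """Plane perpendicular to the bone's long axis, ``offset_mm`` below the
    proximal (axially lowest) edge of the guide base.

    The normal is the bone's principal axis oriented distally, i.e. toward
    the guide's centroid, so the guide footprint lies wholly on the positive
    (distal) side.
    """
    axis, degenerate = principal_axis(bone)
    if degenerate:
        raise MeshError("bone principal axis is degenerate; split plane undefined")
    bc = bone.centroid()
    if np.dot(axis, guide.centroid() - bc) < 0:
        axis = -axis
    coord = guide.vertices @ axis
    cut = float(coord.min()) - offset_mm
    origin = bc + (cut - float(bc @ axis)) * axis
    bone_min = float((bone.vertices @ axis).min())
    if cut < bone_min:
        warnings.warn(
            "guide covers the full bone length; proximal side will be empty", stacklevel=2
        )
    return Plane.make(origin, axis)
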