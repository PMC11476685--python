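"""Synthetic radius/guide phantoms: every input of the study without patient data.

The phantom is an implicit surface of a distal-radius-like bone: an elliptical
tube along z whose radius flares smoothly over the distal segment, carries a
Gaussian styloid lobe on the distal rim, and is bent ("malunited") about an
in-plane axis over the same segment.  The field is approximately a signed
distance near the surface (positive inside, zero on the surface), which makes
two things easy: root-finding the surface analytically, and converting a
field-level perturbation amplitude into a surface displacement in mm.

Rater variability is modelled as a smooth zero-mean Gaussian random field
added to the implicit field before isosurface extraction, so each synthetic
"rater" produces an independently tessellated mesh — as real raters do when
they segment independently.  Resolution degradation reslices the native
volume to a larger thickness along the slice axis and re-extracts the
surface, reproducing the reference-versus-lower-resolution workflow.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .mesh_core import (
    MeshError,
    Plane,
    TriangleMesh,
    angle_weighted_vertex_normals,
    principal_axis,
    read_stl,
    write_stl,
)
from .volume_reslice import SliceSpec, VoxelVolume, extract_isosurface, resample_slice_axis

__all__ = [
    "BonePhantomParams",
    "RaterPerturbParams",
    "GuideRegionSpec",
    "BoneField",
    "bone_field",
    "generate_reference_bone",
    "generate_guide_base",
    "perturb_as_rater",
    "rater_perturbation_grid",
    "degrade_by_reslice",
    "StudyArtifacts",
    "generate_study",
    "save_study",
    "load_study",
    "derive_seed",
]


@dataclass(frozen=True)
class BonePhantomParams:
    """Geometry of one synthetic malunited distal radius.

    Defaults approximate an adult distal radius: ~120 mm modelled length,
    9 mm shaft radius flaring 1.8x over the distal 25 mm, a 6 mm styloid
    lobe, and a 15-degree dorsal/volar malunion tilt of the distal segment.
    ``seed`` drives small smooth cross-section irregularities so phantoms
    differ per participant.
    """

    seed: int = 0
    length: float = 120.0
    shaft_radius: float = 9.0
    distal_flare_scale: float = 1.8
    flare_extent: float = 25.0
    styloid_amplitude: float = 6.0
    malunion_tilt_deg: float = 15.0
    cross_section_eccentricity: float = 0.35
    irregularity_mm: float = 0.4
    field_grid_spacing: tuple = (0.39, 0.39, 0.625)

    def validate(self) -> None:
        if not (self.length > self.flare_extent > 0):
            raise ValueError("need length > flare_extent > 0")
        if self.shaft_radius <= 0:
            raise ValueError("shaft_radius must be positive")
        if not (0 <= self.cross_section_eccentricity < 1):
            raise ValueError("eccentricity must be in [0, 1)")
        if any(s <= 0 for s in self.field_grid_spacing):
            raise ValueError("grid spacing must be positive")


@dataclass(frozen=True)
class RaterPerturbParams:
    """Smooth zero-mean surface perturbation emulating one rater's segmentation.

    ``sigma`` is the standard deviation of the induced surface displacement in
    mm; ``correlation_length`` the spatial scale of the squared-exponential
    kernel.  The default sigma is a calibration chosen so that the synthetic
    inter-rater absolute average distance error lands in the few-hundredths-
    of-a-millimetre range observed between experienced human raters.
    """

    sigma: float = 0.04
    correlation_length: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")


@dataclass(frozen=True)
class GuideRegionSpec:
    """Where the guide base sits on the bone: an axial window centred at a
    fraction of the bone length from the distal end, and an azimuthal window
    around the volar aspect."""

    axial_center_fraction: float = 0.15
    axial_extent: float = 35.0
    angular_center_deg: float = 0.0
    angular_extent_deg: float = 120.0
    base_thickness: float = 3.0

    def validate(self) -> None:
        if self.axial_extent <= 0 or self.base_thickness <= 0:
            raise ValueError("extents must be positive")
        if not (0 < self.angular_extent_deg < 360):
            raise ValueError("angular extent must be in (0, 360)")


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


class BoneField:
    """Implicit bone surface: field > 0 inside, = 0 on the surface.

    Callable on an (n, 3) array of points in mm.  ``sample()`` evaluates the
    field on the native voxel grid (deterministic for given parameters).
    """

    _STYLOID_Z_WIDTH = 6.0  # mm, axial extent of the styloid lobe
    _STYLOID_ANG_WIDTH = 0.5  # rad, azimuthal extent
    _STYLOID_AZIMUTH = np.pi / 2  # lobe sits off the volar aspect

    def __init__(self, params: BonePhantomParams):
        params.validate()
        self.params = params
        rng = np.random.default_rng(params.seed)
        # smooth per-participant cross-section irregularity: low-order sine
        # modes in azimuth (sin(m*theta) vanishes at theta=0, keeping the
        # volar half-width exactly at shaft_radius mid-shaft)
        self._irr_coeff = rng.normal(0.0, params.irregularity_mm, size=3)
        # scanner slice positions are arbitrary relative to the anatomy: a
        # per-phantom sub-slice phase of the sampling grid, so slice-grid
        # alignment effects average out over a cohort
        self._grid_phase = float(rng.uniform(0.0, 1.0))
        self._volume: VoxelVolume | None = None

    # -- field ---------------------------------------------------------

    def __call__(self, points) -> np.ndarray:
        p = self.params
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        z_h = p.length - p.flare_extent
        # inverse bend: rotate the distal segment back about the y axis
        blend = _smoothstep((z - z_h) / p.flare_extent)
        ang = np.radians(p.malunion_tilt_deg) * blend
        ca, sa = np.cos(ang), np.sin(ang)
        xb = ca * x + sa * (z - z_h)
        zb = -sa * x + ca * (z - z_h) + z_h
        yb = y
        rho = np.hypot(xb, yb)
        theta = np.arctan2(yb, xb)
        ecc = p.cross_section_eccentricity
        ell = 1.0 / np.sqrt(np.cos(theta) ** 2 + (np.sin(theta) / (1.0 - ecc)) ** 2)
        flare = 1.0 + (p.distal_flare_scale - 1.0) * _smoothstep((zb - z_h) / p.flare_extent)
        axial_mod = np.sin(np.pi * np.clip(zb, 0.0, p.length) / p.length)
        irr = axial_mod * sum(
            c * np.sin((m + 1) * theta) for m, c in enumerate(self._irr_coeff)
        )
        radius = p.shaft_radius * ell * flare + irr
        # rounded superellipse end caps; the styloid is a Gaussian azimuthal
        # lobe that extends the *distal* cap axially — a process protruding
        # along the long axis, the bone feature most sensitive to slice
        # thickness
        dth = np.arctan2(
            np.sin(theta - self._STYLOID_AZIMUTH), np.cos(theta - self._STYLOID_AZIMUTH)
        )
        lobe = np.exp(-((dth / self._STYLOID_ANG_WIDTH) ** 2))
        cz = p.length / 2.0
        ch_distal = cz + p.styloid_amplitude * lobe
        ch = np.where(zb >= cz, ch_distal, cz)
        u = (zb - cz) / ch
        s = 1.0 - u**4
        g = np.sign(s) * np.sqrt(np.abs(s))
        return radius * g - rho

    # -- grid ----------------------------------------------------------

    def grid_bounds(self, margin: float = 3.0):
        p = self.params
        cross = (
            p.shaft_radius * p.distal_flare_scale
            + p.styloid_amplitude
            + 4.0 * p.irregularity_mm
        )
        a = np.radians(p.malunion_tilt_deg)
        rmax = cross + p.flare_extent * np.sin(a) + margin
        # the tilted distal cap and the axial styloid lobe reach past z = length
        z_top = (
            p.length + p.styloid_amplitude
            + p.flare_extent * (1.0 / np.cos(a) - 1.0) + cross * np.tan(a) + margin
        )
        return (-rmax, rmax), (-rmax, rmax), (-margin, z_top)

    def sample(self, margin: float = 3.0) -> VoxelVolume:
        """Field values on the native voxel grid (cached)."""
        if self._volume is not None:
            return self._volume
        (x0, x1), (y0, y1), (z0, z1) = self.grid_bounds(margin)
        dx, dy, dz = self.params.field_grid_spacing
        xs = x0 + dx * np.arange(int(np.ceil((x1 - x0) / dx)) + 1)
        ys = y0 + dy * np.arange(int(np.ceil((y1 - y0) / dy)) + 1)
        z0 -= self._grid_phase * dz
        zs = z0 + dz * np.arange(int(np.ceil((z1 - z0) / dz)) + 1)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        vals = self(np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]))
        self._volume = VoxelVolume(
            vals.reshape(X.shape), (dx, dy, dz), (xs[0], ys[0], zs[0])
        )
        return self._volume

    def surface_radius(self, theta: float, z: float, bracket=None) -> float:
        """Radial coordinate of the zero level set along the ray (theta, z),
        found by bisection on the analytic field (oracle for tests)."""
        from scipy.optimize import brentq

        p = self.params
        lo, hi = bracket or (1e-6, p.shaft_radius * p.distal_flare_scale * 3 + 20)

        def f(r):
            pt = np.array([[r * np.cos(theta), r * np.sin(theta), z]])
            return float(self(pt)[0])

        return float(brentq(f, lo, hi, xtol=1e-9))


def bone_field(params: BonePhantomParams) -> BoneField:
    """Construct the implicit bone field for one participant."""
    return BoneField(params)


def generate_reference_bone(params: BonePhantomParams) -> tuple[VoxelVolume, TriangleMesh]:
    """Native-resolution volume and reference surface mesh for one phantom."""
    fld = bone_field(params)
    vol = fld.sample()
    mesh = extract_isosurface(vol, 0.0)
    mesh.name = f"bone(seed={params.seed})"
    return vol, mesh


# ---------------------------------------------------------------------------
# Guide base construction
# ---------------------------------------------------------------------------


def _bone_frame(bone: TriangleMesh):
    """(axis pointing distally, in-plane reference e1, e2, centroid).

    Distal = the flared end: the end whose vertices lie farther from the
    axis on average.
    """
    axis, _ = principal_axis(bone)
    center = bone.centroid()
    t = (bone.vertices - center) @ axis
    radial = bone.vertices - center - t[:, None] * axis
    r = np.linalg.norm(radial, axis=1)
    span = t.max() - t.min()
    hi = t > t.max() - 0.15 * span
    lo = t < t.min() + 0.15 * span
    if r[lo].mean() > r[hi].mean():
        axis = -axis
        t = -t
    e1 = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(e1, axis)) > 0.9:
        e1 = np.array([0.0, 1.0, 0.0])
    e1 = e1 - np.dot(e1, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return axis, e1, e2, center


def generate_guide_base(
    bone: TriangleMesh, region: GuideRegionSpec | None = None
) -> TriangleMesh:
    """Guide base whose contact surface is an exact copy of a bone patch.

    The contact surface is the subset of bone faces whose centroids fall in
    the axial/angular window of ``region`` — vertex coordinates copied
    bit-for-bit, so every contact vertex has signed distance exactly 0 to the
    source bone.  The outer surface is the patch displaced ``base_thickness``
    along outward angle-weighted vertex normals, and side walls stitch the
    two into a closed, outward-oriented mesh.
    """
    region = region or GuideRegionSpec()
    region.validate()
    axis, e1, e2, center = _bone_frame(bone)
    V, F = bone.vertices, bone.faces
    t = (V - center) @ axis
    fc = V[F].mean(axis=1)
    tc = (fc - center) @ axis
    length = t.max() - t.min()
    t_center = t.max() - region.axial_center_fraction * length
    in_axial = np.abs(tc - t_center) <= region.axial_extent / 2.0
    phi = np.arctan2((fc - center) @ e2, (fc - center) @ e1)
    phi0 = np.radians(region.angular_center_deg)
    dphi = np.arctan2(np.sin(phi - phi0), np.cos(phi - phi0))
    in_ang = np.abs(dphi) <= np.radians(region.angular_extent_deg) / 2.0
    patch = np.flatnonzero(in_axial & in_ang)
    if len(patch) == 0:
        raise MeshError("guide region selects no bone faces")

    pf = F[patch]
    used = np.unique(pf)
    remap = np.full(bone.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    contact_faces = remap[pf]
    n_patch_verts = len(used)
    normals = angle_weighted_vertex_normals(bone)[used]
    contact_verts = V[used]  # bit-exact copy
    outer_verts = contact_verts + region.base_thickness * normals

    # boundary: directed edges of the patch appearing exactly once
    e = contact_faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    key = np.sort(e, axis=1)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = e[counts[inv] == 1]

    off = n_patch_verts
    faces = []
    faces.append(contact_faces[:, ::-1])  # contact points toward the bone
    faces.append(contact_faces + off)  # outer keeps bone winding (outward)
    walls = []
    for a, b in boundary:
        walls.append((b + off, a + off, a))
        walls.append((b + off, a, b))
    faces.append(np.asarray(walls, dtype=np.int64).reshape(-1, 3))
    guide = TriangleMesh(
        np.vstack([contact_verts, outer_verts]),
        np.vstack(faces),
        name=f"guide({bone.name})",
    )
    if guide.signed_volume() < 0:
        guide = TriangleMesh(guide.vertices, guide.faces[:, ::-1], name=guide.name)
    return guide


# ---------------------------------------------------------------------------
# Rater perturbation and resolution degradation
# ---------------------------------------------------------------------------


def rater_perturbation_grid(fld: BoneField, params: RaterPerturbParams) -> VoxelVolume:
    """The smooth zero-mean perturbation (mm) on the native grid.

    White noise smoothed by a separable squared-exponential (Gaussian) kernel
    of scale ``correlation_length``, centred and scaled to unit variance, then
    multiplied by ``sigma``.  Because the bone field has ~unit gradient near
    the surface, the induced surface displacement has std ~= sigma.
    """
    params.validate()
    base = fld.sample()
    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal(base.values.shape)
    # white noise convolved with a Gaussian of std l/sqrt(2) has a
    # squared-exponential covariance exp(-r^2 / (2 l^2))
    sig_vox = [params.correlation_length / np.sqrt(2.0) / s for s in base.spacing]
    smooth = ndimage.gaussian_filter(noise, sig_vox, mode="wrap")
    # centre and scale over the near-surface shell: with a correlation length
    # comparable to the bone, regional variance of the smoothed field differs
    # noticeably from the global one, and the displacement amplitude is only
    # meaningful where the surface actually lies
    shell = np.abs(base.values) < 2.0 * max(base.spacing)
    smooth -= smooth[shell].mean()
    smooth /= smooth[shell].std()
    return VoxelVolume(params.sigma * smooth, base.spacing, base.origin)


def perturb_as_rater(fld: BoneField, params: RaterPerturbParams) -> TriangleMesh:
    """One rater's surface: isosurface of field + smooth random perturbation."""
    params.validate()
    base = fld.sample()
    if params.sigma == 0:
        mesh = extract_isosurface(base, 0.0)
    else:
        pert = rater_perturbation_grid(fld, params)
        vol = VoxelVolume(base.values + pert.values, base.spacing, base.origin)
        mesh = extract_isosurface(vol, 0.0)
    mesh.name = f"rater(seed={params.seed})"
    return mesh


def degrade_by_reslice(volume: VoxelVolume, spec: SliceSpec) -> TriangleMesh:
    """Lower-resolution surface: reslice the native volume to the requested
    thickness, then extract the isosurface from the degraded stack."""
    resliced = resample_slice_axis(volume, spec)
    mesh = extract_isosurface(resliced, 0.0)
    mesh.name = f"degraded(t={spec.slice_thickness})"
    return mesh


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------


def derive_seed(master_seed: int, participant: int = 0, rater: int = 0, t_index: int = 0) -> int:
    """Deterministic per-artifact seed: master*10^6 + participant*10^4 +
    rater*10^2 + thickness index (participants/raters/thicknesses 1-based;
    0 marks "not applicable")."""
    return int(master_seed) * 10**6 + participant * 10**4 + rater * 10**2 + t_index


@dataclass
class StudyArtifacts:
    """Every mesh of a synthetic cohort, addressable by (participant, rater)
    or (participant, thickness)."""

    master_seed: int
    participants: list
    raters: list
    thicknesses: list
    bone_params: dict = dc_field(default_factory=dict)  # p -> BonePhantomParams
    native_volumes: dict = dc_field(default_factory=dict)  # p -> VoxelVolume
    true_bones: dict = dc_field(default_factory=dict)  # p -> TriangleMesh
    rater_bones: dict = dc_field(default_factory=dict)  # (p, r) -> TriangleMesh
    rater_guides: dict = dc_field(default_factory=dict)  # (p, r) -> TriangleMesh
    degraded_bones: dict = dc_field(default_factory=dict)  # (p, t) -> TriangleMesh
    degraded_guides: dict = dc_field(default_factory=dict)  # (p, t) -> TriangleMesh

    # accessors used by the study-analysis layer
    def rater_radius(self, p, r) -> TriangleMesh:
        return self.rater_bones[(p, r)]

    def rater_guide(self, p, r) -> TriangleMesh:
        return self.rater_guides[(p, r)]

    def degraded_radius(self, p, t) -> TriangleMesh:
        return self.degraded_bones[(p, t)]

    def degraded_guide(self, p, t) -> TriangleMesh:
        return self.degraded_guides[(p, t)]


def generate_study(
    n_participants: int,
    n_raters: int,
    thickness_list,
    master_seed: int = 0,
    bone_template: BonePhantomParams | None = None,
    rater_template: RaterPerturbParams | None = None,
    region: GuideRegionSpec | None = None,
    interpolation_order: int = 3,
) -> StudyArtifacts:
    """Generate the full synthetic cohort.

    Per participant: one bone field; ``n_raters`` independently perturbed
    reference bones, each with a fitted guide; and per slice thickness one
    degraded bone with a fitted guide.  Everything is deterministic from
    ``master_seed`` via :func:`derive_seed`.
    """
    if n_participants < 1 or n_raters < 2:
        raise ValueError("need n_participants >= 1 and n_raters >= 2")
    bone_template = bone_template or BonePhantomParams()
    rater_template = rater_template or RaterPerturbParams()
    region = region or GuideRegionSpec()
    thicknesses = [float(t) for t in thickness_list]
    arts = StudyArtifacts(
        master_seed=master_seed,
        participants=list(range(1, n_participants + 1)),
        raters=list(range(1, n_raters + 1)),
        thicknesses=thicknesses,
    )
    for p in arts.participants:
        seed = derive_seed(master_seed, p)
        # anatomical size variation across the cohort (+/- 7% bone length)
        length = bone_template.length * float(np.random.default_rng(seed).uniform(0.93, 1.07))
        params = dataclasses.replace(bone_template, seed=seed, length=length)
        fld = bone_field(params)
        vol = fld.sample()
        arts.bone_params[p] = params
        arts.native_volumes[p] = vol
        truth = extract_isosurface(vol, 0.0)
        truth.name = f"p{p}/reference"
        arts.true_bones[p] = truth
        for r in arts.raters:
            rp = dataclasses.replace(rater_template, seed=derive_seed(master_seed, p, rater=r))
            mesh = perturb_as_rater(fld, rp)
            mesh.name = f"p{p}/rater{r}"
            arts.rater_bones[(p, r)] = mesh
            guide = generate_guide_base(mesh, region)
            guide.name = f"p{p}/rater{r}/guide"
            arts.rater_guides[(p, r)] = guide
        for ti, t in enumerate(thicknesses, start=1):
            mesh = degrade_by_reslice(vol, SliceSpec(t, interpolation_order))
            mesh.name = f"p{p}/t{t}"
            arts.degraded_bones[(p, t)] = mesh
            guide = generate_guide_base(mesh, region)
            guide.name = f"p{p}/t{t}/guide"
            arts.degraded_guides[(p, t)] = guide
    return arts


def save_study(arts: StudyArtifacts, out_dir) -> Path:
    """Write every mesh as binary STL plus a JSON manifest recording seeds and
    file paths; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "master_seed": arts.master_seed,
        "participants": arts.participants,
        "raters": arts.raters,
        "thicknesses": arts.thicknesses,
        "bone_params": {
            str(p): dataclasses.asdict(bp) for p, bp in arts.bone_params.items()
        },
        "files": {},
    }

    def put(kind, key, mesh):
        rel = f"{kind}_{'_'.join(str(k) for k in key)}.stl"
        write_stl(mesh, out / rel, "binary")
        manifest["files"][f"{kind}:{':'.join(str(k) for k in key)}"] = rel

    for p in arts.participants:
        put("reference", (p,), arts.true_bones[p])
        for r in arts.raters:
            put("rater_bone", (p, r), arts.rater_bones[(p, r)])
            put("rater_guide", (p, r), arts.rater_guides[(p, r)])
        for t in arts.thicknesses:
            put("degraded_bone", (p, t), arts.degraded_bones[(p, t)])
            put("degraded_guide", (p, t), arts.degraded_guides[(p, t)])
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_study(manifest_path) -> StudyArtifacts:
    """Load a cohort previously written by :func:`save_study`."""
    path = Path(manifest_path)
    if path.is_dir():
        path = path / "manifest.json"
    man = json.loads(path.read_text())
    base = path.parent
    arts = StudyArtifacts(
        master_seed=man["master_seed"],
        participants=man["participants"],
        raters=man["raters"],
        thicknesses=man["thicknesses"],
    )
    missing = []
    for key, rel in man["files"].items():
        f = base / rel
        if not f.exists():
            missing.append(rel)
            continue
        kind, *parts = key.split(":")
        mesh = read_stl(f)
        if kind == "reference":
            arts.true_bones[int(parts[0])] = mesh
        elif kind == "rater_bone":
            arts.rater_bones[(int(parts[0]), int(parts[1]))] = mesh
        elif kind == "rater_guide":
            arts.rater_guides[(int(parts[0]), int(parts[1]))] = mesh
        elif kind == "degraded_bone":
            arts.degraded_bones[(int(parts[0]), float(parts[1]))] = mesh
        elif kind == "degraded_guide":
            arts.degraded_guides[(int(parts[0]), float(parts[1]))] = mesh
    if missing:
        raise FileNotFoundError(
            f"manifest {path} names {len(missing)} missing file(s): {missing[:5]}"
        )
    return arts
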