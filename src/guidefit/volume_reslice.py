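"""Scalar-volume model of CT data and slice-axis resampling.

A :class:`VoxelVolume` is a 3-D scalar grid with anisotropic spacing, the
stand-in for a CT stack: the first two axes are the in-plane pixel grid and
the third axis (``k``) is the slice axis.  Reslicing to a larger slice
thickness interpolates along ``k`` only — the in-plane pixel size never
changes — with an interpolating spline of order 1 (linear) or 3 (cubic), the
latter mirroring bicubic reslicing of clinical images.  Surfaces are
recovered from volumes by marching cubes at an iso-level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import make_interp_spline

from .mesh_core import TriangleMesh, _weld_exact

__all__ = [
    "VoxelVolume",
    "SliceSpec",
    "resample_slice_axis",
    "threshold_segment",
    "extract_isosurface",
    "read_nifti",
    "write_nifti",
]


@dataclass(frozen=True)
class VoxelVolume:
    """Scalar 3-D grid indexed (i, j, k); k is the slice axis.

    ``spacing`` is (dx, dy, dz) in mm and ``origin`` the physical position of
    the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    def validate(self) -> None:
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("volume must be 3-D with at least 2 samples per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if not np.isfinite(self.values).all():
            raise ValueError("volume values must be finite")

    @property
    def slice_positions(self) -> np.ndarray:
        """Physical z of each slice (mm)."""
        return self.origin[2] + self.spacing[2] * np.arange(self.values.shape[2])


@dataclass(frozen=True)
class SliceSpec:
    """Target slice thickness (mm) and interpolation spline order (1 or 3)."""

    slice_thickness: float
    interpolation_order: int = 3

    def validate(self, native_thickness: float | None = None) -> None:
        if self.interpolation_order not in (1, 3):
            raise ValueError("interpolation order must be 1 or 3")
        if self.slice_thickness <= 0:
            raise ValueError("slice thickness must be positive")
        if native_thickness is not None and self.slice_thickness < native_thickness - 1e-12:
            raise ValueError(
                f"slice thickness {self.slice_thickness} mm is below the native "
                f"{native_thickness} mm; only degradation is supported"
            )


def resample_slice_axis(vol: VoxelVolume, spec: SliceSpec, z_offset: float = 0.0) -> VoxelVolume:
    """Reslice a volume to a new slice thickness along the k axis only.

    New slice positions are ``z0 + z_offset + m * t`` for every m keeping the
    position within the native z range (no extrapolation).  Values come from
    an interpolating spline of the requested order along k at each fixed
    (i, j); in-plane sampling is untouched.  New slices that coincide with a
    native slice position (within 1e-9 of the native thickness) copy the
    native slice verbatim, so resampling at the native thickness is exactly
    the identity.
    """
    vol.validate()
    dz = vol.spacing[2]
    spec.validate(native_thickness=dz)
    nz = vol.values.shape[2]
    if nz < spec.interpolation_order + 1:
        raise ValueError(
            f"need at least {spec.interpolation_order + 1} slices for order "
            f"{spec.interpolation_order} interpolation, have {nz}"
        )
    t = spec.slice_thickness
    z = vol.slice_positions
    z0, z_last = z[0] + z_offset, z[-1]
    if z0 > z_last:
        raise ValueError("z_offset pushes the first new slice past the volume")
    n_new = int(np.floor((z_last - z0) / t + 1e-9)) + 1
    z_new = z0 + t * np.arange(n_new)

    # snap knot-coincident positions so those slices are copied exactly
    rel = (z_new - z[0]) / dz
    nearest = np.rint(rel).astype(int)
    on_knot = (np.abs(rel - nearest) < 1e-9) & (nearest >= 0) & (nearest < nz)

    out = np.empty(vol.values.shape[:2] + (n_new,), dtype=np.float64)
    if on_knot.any():
        out[:, :, on_knot] = vol.values[:, :, nearest[on_knot]]
    todo = ~on_knot
    if todo.any():
        flat = vol.values.reshape(-1, nz).T  # (nz, nx*ny)
        spl = make_interp_spline(z, flat, k=spec.interpolation_order, axis=0)
        vals = spl(z_new[todo])  # (n_todo, nx*ny)
        out[:, :, todo] = vals.T.reshape(vol.values.shape[:2] + (int(todo.sum()),))
    return VoxelVolume(out, (vol.spacing[0], vol.spacing[1], t),
                       (vol.origin[0], vol.origin[1], z0))


def threshold_segment(vol: VoxelVolume, level: float) -> VoxelVolume:
    """Binary segmentation: voxel = 1 where value >= level, else 0."""
    if not np.isfinite(level):
        raise ValueError("threshold level must be finite")
    return replace(vol, values=(vol.values >= level).astype(np.float64))


def extract_isosurface(vol: VoxelVolume, iso: float) -> TriangleMesh:
    """Marching-cubes isosurface of a volume, in physical millimetres.

    The output is closed and outward-oriented (positive signed volume,
    consistent winding) whenever the iso-region does not touch the grid
    boundary; a touching region yields an open mesh and a warning.
    """
    from skimage import measure

    vol.validate()
    vmin, vmax = float(vol.values.min()), float(vol.values.max())
    if not (vmin < iso < vmax):
        raise ValueError(
            f"iso level {iso} is outside the open value range ({vmin}, {vmax})"
        )
    verts, faces, _, _ = measure.marching_cubes(vol.values, level=iso, spacing=vol.spacing)
    verts = verts + np.asarray(vol.origin)
    verts, inverse = _weld_exact(verts)
    faces = inverse[faces]
    ok = ~(
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    mesh = TriangleMesh(verts, faces[ok], name="isosurface")
    if mesh.signed_volume() < 0:
        mesh = TriangleMesh(verts, mesh.faces[:, ::-1], name=mesh.name)
    touches = (
        (vol.values[0] >= iso).any()
        or (vol.values[-1] >= iso).any()
        or (vol.values[:, 0] >= iso).any()
        or (vol.values[:, -1] >= iso).any()
        or (vol.values[:, :, 0] >= iso).any()
        or (vol.values[:, :, -1] >= iso).any()
    )
    if touches:
        import warnings

        warnings.warn("iso-region touches the grid boundary; surface is open", stacklevel=2)
    return mesh


def write_nifti(vol: VoxelVolume, path) -> None:
    """Write a volume as NIfTI-1; spacing goes to pixdim, origin to the affine."""
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.values, affine), str(path))


def read_nifti(path) -> VoxelVolume:
    """Read a NIfTI-1 volume; the third spatial axis is the slice axis."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VoxelVolume(data, spacing, origin)
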