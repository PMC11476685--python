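"""Surface-discrepancy metrics between meshes.

All comparisons are one-directional: signed distances from every vertex of a
*source* mesh (the model under test) to the surface of a closed, outward-
oriented *target* mesh (the reference).  Two summary statistics are used:

* **negative HDF** — the most negative signed distance (the deepest
  penetration of the source into the reference; the raw minimum is returned
  even when positive, so averages across comparisons keep their sign), and
* **absolute ADE** — the mean absolute signed distance over source vertices.

No registration is performed anywhere: reference and test models share one
coordinate frame by construction (the CT frame for real data, the phantom
frame for synthetic data), and aligning them would mask the very discrepancy
being measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .mesh_core import (
    Plane,
    SurfaceQuery,
    TriangleMesh,
    proximal_split_plane,
)

__all__ = [
    "SignedDistanceField",
    "ComparisonMetrics",
    "RadiusComparison",
    "signed_distance_field",
    "negative_hausdorff",
    "absolute_ade",
    "metrics_from_field",
    "compare_guide_to_radius",
    "compare_radius_to_radius",
    "attach_distance_scalars",
]

SCALAR_NAME = "signed_distance_mm"


@dataclass(frozen=True)
class SignedDistanceField:
    """Per-source-vertex signed distances (mm) to a target surface."""

    source_id: str
    target_id: str
    distances: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "distances", np.asarray(self.distances, dtype=np.float64))
        if self.distances.size and not np.isfinite(self.distances).all():
            raise ValueError("signed distances must be finite")


@dataclass(frozen=True)
class ComparisonMetrics:
    """Summary of one source-to-target comparison."""

    negative_hdf: float
    abs_ade: float
    max_distance: float
    n_vertices: int


class RadiusComparison(NamedTuple):
    """Whole / distal / proximal metrics of a radius-to-radius comparison."""

    whole: ComparisonMetrics
    distal: ComparisonMetrics
    proximal: ComparisonMetrics


def signed_distance_field(
    source: TriangleMesh,
    target: TriangleMesh,
    target_index: SurfaceQuery | None = None,
) -> SignedDistanceField:
    """Signed distance of every source vertex to the target surface.

    ``target_index`` may be passed to reuse a prebuilt :class:`SurfaceQuery`
    when many sources are compared to one reference.
    """
    if target_index is None:
        target_index = SurfaceQuery(target)
    elif target_index.mesh is not target:
        raise ValueError("target_index was built on a different mesh")
    d = target_index.signed_distance(source.vertices)
    return SignedDistanceField(source.name, target.name, d)


def _require_nonempty(field: SignedDistanceField):
    if field.distances.size == 0:
        raise ValueError("empty signed-distance field")


def negative_hausdorff(field: SignedDistanceField) -> float:
    """Most negative signed distance (mm).  May be >= 0 when the source never
    penetrates the target; the raw minimum is returned unclamped."""
    _require_nonempty(field)
    return float(field.distances.min())


def absolute_ade(field: SignedDistanceField) -> float:
    """Mean absolute signed distance (mm) over source vertices."""
    _require_nonempty(field)
    return float(np.abs(field.distances).mean())


def metrics_from_field(field: SignedDistanceField) -> ComparisonMetrics:
    _require_nonempty(field)
    d = field.distances
    return ComparisonMetrics(
        negative_hdf=float(d.min()),
        abs_ade=float(np.abs(d).mean()),
        max_distance=float(d.max()),
        n_vertices=int(d.size),
    )


def compare_guide_to_radius(
    guide: TriangleMesh,
    radius_reference: TriangleMesh,
    target_index: SurfaceQuery | None = None,
    contact_only: bool = False,
) -> ComparisonMetrics:
    """Guide-to-radius discrepancy in the guide's designed position.

    By default all guide vertices are used (contact surface, outer surface
    and walls); outer-surface vertices only enlarge ``max_distance`` and never
    affect the negative extremum of a well-fitting guide.  With
    ``contact_only`` the field is restricted to vertices lying closest to the
    bone, i.e. the half of the vertex set with the smaller distances.
    """
    field = signed_distance_field(guide, radius_reference, target_index)
    if contact_only:
        d = np.sort(field.distances)[: max(1, field.distances.size // 2)]
        field = SignedDistanceField(field.source_id, field.target_id, d)
    return metrics_from_field(field)


def compare_radius_to_radius(
    model: TriangleMesh,
    reference: TriangleMesh,
    guide_for_split: TriangleMesh | None = None,
    target_index: SurfaceQuery | None = None,
    split_plane: Plane | None = None,
) -> RadiusComparison:
    """Radius-to-radius metrics for the whole bone and its distal/proximal
    parts.

    The split plane is perpendicular to the reference's long axis, directly
    below the proximal edge of ``guide_for_split``; part metrics restrict the
    per-vertex field by plane side (vertices are never re-meshed — metrics
    are vertex-wise).  Distal is the positive side of the plane.
    """
    field = signed_distance_field(model, reference, target_index)
    whole = metrics_from_field(field)
    if split_plane is None:
        if guide_for_split is None:
            raise ValueError("need guide_for_split (or split_plane) for part metrics")
        split_plane = proximal_split_plane(reference, guide_for_split)
    side = split_plane.signed_side(model.vertices)
    parts = []
    for mask in (side > 0, side <= 0):
        sub = SignedDistanceField(field.source_id, field.target_id, field.distances[mask])
        parts.append(metrics_from_field(sub))
    return RadiusComparison(whole, parts[0], parts[1])


def attach_distance_scalars(mesh: TriangleMesh, field: SignedDistanceField) -> TriangleMesh:
    """Copy of ``mesh`` carrying the field as the per-vertex scalar
    ``"signed_distance_mm"`` (writable to PLY for distance-coloured views)."""
    if field.distances.size != mesh.n_vertices:
        raise ValueError(
            f"field length {field.distances.size} != mesh vertex count {mesh.n_vertices}"
        )
    out = mesh.copy()
    out.per_vertex_scalars[SCALAR_NAME] = field.distances.copy()
    return out
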