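"""Shared fixtures: scaled-down phantoms and cohorts.

The phantom used throughout the suite is a shortened bone (70 mm) sampled on
a 0.78 x 0.78 x 0.625 mm grid — half the in-plane resolution of the full
defaults — so a whole cohort generates in seconds while keeping the native
slice thickness (0.625 mm) that the degradation analysis reslices from.
"""

import numpy as np
import pytest
import trimesh

from guidefit.mesh_core import SurfaceQuery, TriangleMesh
from guidefit.synthetic_phantom import (
    BonePhantomParams,
    bone_field,
    generate_reference_bone,
    generate_study,
)

SMALL = dict(length=70.0, field_grid_spacing=(0.78, 0.78, 0.625))


def small_params(seed=0, **kw):
    return BonePhantomParams(seed=seed, **{**SMALL, **kw})


def icosphere(radius=10.0, subdivisions=3, name="icosphere") -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(ico.vertices.copy(), ico.faces.copy(), name=name)


@pytest.fixture(scope="session")
def phantom():
    """(params, field, native volume, reference mesh) of one small phantom."""
    params = small_params(seed=3)
    fld = bone_field(params)
    vol, mesh = generate_reference_bone(params)
    return params, fld, vol, mesh


@pytest.fixture(scope="session")
def phantom_index(phantom):
    _, _, _, mesh = phantom
    return SurfaceQuery(mesh)


@pytest.fixture(scope="session")
def study_small():
    """A 4-participant, 3-rater cohort with two degraded thicknesses."""
    return generate_study(4, 3, [1.0, 2.5], master_seed=7,
                          bone_template=small_params())


def random_bumpy_sphere(rng, subdivisions=2, radius=10.0) -> TriangleMesh:
    """Closed random test mesh: icosphere with smooth radial bumps."""
    m = icosphere(radius, subdivisions)
    v = m.vertices
    u = v / np.linalg.norm(v, axis=1, keepdims=True)
    bump = np.ones(len(v))
    for _ in range(3):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        bump += rng.uniform(0.02, 0.12) * np.cos(3.0 * (u @ d) + rng.uniform(0, 2 * np.pi))
    return TriangleMesh(v * bump[:, None], m.faces, name="bumpy")
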