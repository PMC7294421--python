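"""Shared fixtures: small canonical meshes and module-scoped synthetic scenes."""

from __future__ import annotations

import numpy as np
import pytest

from woundmetrics.camera import CameraSpec
from woundmetrics.mesh import TriangleMesh
from woundmetrics.synthetic import SyntheticWoundSpec, make_scene, make_wound


def unit_cube_mesh() -> TriangleMesh:
    """Closed unit cube [0,1]^3 as 12 consistently outward-oriented triangles."""
    v = np.array(
        [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
    )
    f = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # x = 0 (outward -x)
            [4, 6, 7], [4, 7, 5],  # x = 1
            [0, 4, 5], [0, 5, 1],  # y = 0
            [2, 3, 7], [2, 7, 6],  # y = 1
            [0, 2, 6], [0, 6, 4],  # z = 0
            [1, 5, 7], [1, 7, 3],  # z = 1
        ]
    )
    return TriangleMesh(v, f)


@pytest.fixture
def cube():
    return unit_cube_mesh()


@pytest.fixture(scope="session")
def cap_wound():
    """Noise-free tilted spherical-cap wound (R=2 cm, h=1 cm, tilt 25 deg)."""
    spec = SyntheticWoundSpec(shape="spherical_cap", sphere_radius=0.02, depth=0.01,
                              resolution=30, tilt_deg=25.0)
    return make_wound(spec)


@pytest.fixture(scope="session")
def cap_scene(cap_wound):
    """Rendered scene of the cap wound at the measurement-grade pixel pitch."""
    mesh, gt = cap_wound
    cam = CameraSpec(image_size=2048)
    return make_scene(mesh, gt, camera=cam, seed=1)


def random_view_mesh(rng: np.random.Generator, n_faces: int) -> TriangleMesh:
    """Triangle soup in general position inside the camera view at ~0.3 m."""
    centers = rng.uniform(-0.06, 0.06, size=(n_faces, 3)) * np.array([1, 1, 0.5])
    tris = centers[:, None, :] + rng.uniform(-0.02, 0.02, size=(n_faces, 3, 3))
    v = tris.reshape(-1, 3)
    f = np.arange(3 * n_faces).reshape(-1, 3)
    return TriangleMesh(v, f)
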