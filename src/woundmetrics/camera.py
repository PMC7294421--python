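"""Top-view pinhole camera: pose from spherical coordinates and projection.

The scanner acquisition protocol holds the camera roughly 30 cm above the
wound with its near plane parallel to the skin, so the canonical render view
is azimuth 0, elevation 0, distance 0.3 m: the camera sits on the world +z
axis looking down at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CameraSpec:
    """Viewpoint and image geometry for the top-view render.

    azimuth/elevation (degrees) place the camera on a sphere of radius
    ``distance`` (meters) around the world origin, looking at the origin.
    ``fov_deg`` is the vertical field of view; the image is square
    (``image_size`` pixels).  Azimuth 0 / elevation 0 puts the camera at
    (0, 0, distance).
    """

    azimuth_deg: float = 0.0
    elevation_deg: float = 0.0
    distance: float = 0.3
    fov_deg: float = 60.0
    image_size: int = 512
    near: float = 0.01
    far: float = 10.0

    def __post_init__(self) -> None:
        if not (self.distance > self.near > 0):
            raise ValueError("camera requires distance > near > 0")
        if self.far <= self.near:
            raise ValueError("camera requires far > near")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")

    @property
    def position(self) -> np.ndarray:
        az = np.deg2rad(self.azimuth_deg)
        el = np.deg2rad(self.elevation_deg)
        return self.distance * np.array(
            [np.cos(el) * np.sin(az), np.sin(el), np.cos(el) * np.cos(az)]
        )


def camera_pose(spec: CameraSpec) -> tuple[np.ndarray, np.ndarray]:
    """World -> camera rigid transform (R, t): x_cam = R @ x_world + t.

    Camera axes follow the computer-vision convention: +x right, +y down in
    the image, +z forward along the viewing direction, so the camera-space z
    coordinate of a point is its depth in meters (the world origin maps to
    depth ``spec.distance``).
    """
    pos = spec.position
    forward = -pos / np.linalg.norm(pos)
    up = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(forward, up)) > 1.0 - 1e-9:  # looking along world y
        up = np.array([0.0, 0.0, 1.0])
    right = np.cross(forward, up)
    right /= np.linalg.norm(right)
    down = np.cross(forward, right)
    R = np.stack([right, down, forward])
    t = -R @ pos
    return R, t


def projection_matrix(spec: CameraSpec) -> np.ndarray:
    """4x4 matrix mapping homogeneous camera coordinates to pixel coordinates.

    After division by the homogeneous coordinate (the camera depth), rows 0/1
    give continuous pixel coordinates with origin at the top-left image
    corner, x right, y down, and the pixel (i, j) center at (j+0.5, i+0.5).
    """
    S = spec.image_size
    f = (S / 2.0) / np.tan(np.deg2rad(spec.fov_deg) / 2.0)  # focal length, px
    c = S / 2.0
    return np.array(
        [
            [f, 0.0, c, 0.0],
            [0.0, f, c, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
        ]
    )


def world_to_screen_matrix(spec: CameraSpec) -> np.ndarray:
    """4x4 homogeneous world -> screen transform (projection o pose)."""
    R, t = camera_pose(spec)
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = t
    return projection_matrix(spec) @ M


def project_points(points, spec: CameraSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Perspective-project world points to pixel coordinates.

    Returns ``(pixels, depths, in_front)``: (n, 2) continuous pixel
    coordinates (x=column, y=row; pixel centers at half-integers), (n,)
    camera-space depths in meters, and a boolean flag per point that is False
    where the point lies behind the near plane (such points are flagged,
    never silently dropped; their pixel coordinates are not meaningful).
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    R, t = camera_pose(spec)
    cam = points @ R.T + t
    depth = cam[:, 2]
    in_front = depth > spec.near
    S = spec.image_size
    f = (S / 2.0) / np.tan(np.deg2rad(spec.fov_deg) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        px = f * cam[:, 0] / depth + S / 2.0
        py = f * cam[:, 1] / depth + S / 2.0
    return np.stack([px, py], axis=1), depth, in_front
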