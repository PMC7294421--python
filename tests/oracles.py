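"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: rasterization coverage
is recomputed per pixel against every face with barycentric coordinates and
ray/plane depths, and the minimum bounding rectangle is found by a dense
angle sweep.
"""

from __future__ import annotations

import numpy as np

from woundmetrics.camera import CameraSpec, camera_pose, project_points
from woundmetrics.mesh import TriangleMesh


def heron_area(p0, p1, p2) -> float:
    a = np.linalg.norm(np.asarray(p1) - p0)
    b = np.linalg.norm(np.asarray(p2) - p1)
    c = np.linalg.norm(np.asarray(p0) - p2)
    s = (a + b + c) / 2.0
    return float(np.sqrt(max(s * (s - a) * (s - b) * (s - c), 0.0)))


def brute_force_hits(
    mesh: TriangleMesh, spec: CameraSpec, faces_per_pixel: int, center: bool = True
):
    """All (row, col, face) hits by testing every pixel center against every
    projected face, with depths from exact ray/plane intersection in camera
    space; truncated to the nearest ``faces_per_pixel`` per pixel.

    Returns (hit set, per-pixel sorted depth lists dict).
    """
    verts = mesh.vertices - (mesh.vertices.mean(axis=0) if center else 0.0)
    pix, depth, in_front = project_points(verts, spec)
    R, t = camera_pose(spec)
    cam = verts @ R.T + t
    S = spec.image_size

    per_pixel: dict[tuple[int, int], list[tuple[float, int]]] = {}
    for fid, (i0, i1, i2) in enumerate(mesh.faces):
        if not (in_front[i0] and in_front[i1] and in_front[i2]):
            continue
        a, b, c = pix[i0], pix[i1], pix[i2]
        M = np.array([[b[0] - a[0], c[0] - a[0]], [b[1] - a[1], c[1] - a[1]]])
        det = np.linalg.det(M)
        if det == 0.0:
            continue
        Minv = np.linalg.inv(M)
        xmin = max(int(np.floor(min(a[0], b[0], c[0]))), 0)
        xmax = min(int(np.ceil(max(a[0], b[0], c[0]))), S - 1)
        ymin = max(int(np.floor(min(a[1], b[1], c[1]))), 0)
        ymax = min(int(np.ceil(max(a[1], b[1], c[1]))), S - 1)
        # camera-space plane of the face for exact depth along each pixel ray
        n_plane = np.cross(cam[i1] - cam[i0], cam[i2] - cam[i0])
        d_plane = float(n_plane @ cam[i0])
        f = (S / 2.0) / np.tan(np.deg2rad(spec.fov_deg) / 2.0)
        for row in range(ymin, ymax + 1):
            for col in range(xmin, xmax + 1):
                p = np.array([col + 0.5, row + 0.5])
                lam = Minv @ (p - a)
                u, v = lam
                w = 1.0 - u - v
                if u < 0 or v < 0 or w < 0:
                    continue
                ray = np.array([(p[0] - S / 2.0) / f, (p[1] - S / 2.0) / f, 1.0])
                denom = float(n_plane @ ray)
                if denom == 0.0:
                    continue
                z = d_plane / denom
                per_pixel.setdefault((row, col), []).append((z, fid))

    hits = set()
    depths = {}
    for key, lst in per_pixel.items():
        lst.sort()
        kept = lst[:faces_per_pixel]
        depths[key] = [z for z, _ in kept]
        for _, fid in kept:
            hits.add((key[0], key[1], fid))
    return hits, depths


def assert_depth_layers_sorted(depths: np.ndarray) -> None:
    """Along the layer axis, finite depths are non-decreasing and sentinel
    (inf) entries trail; inf - inf gaps are the sentinel tail."""
    with np.errstate(invalid="ignore"):
        diffs = np.diff(depths, axis=-1)
    tail = np.isnan(diffs)  # inf - inf: both entries are sentinels
    assert (tail | (diffs >= 0)).all()
    if tail.any():
        assert np.isinf(depths[..., 1:][tail]).all()


def column_volume_oracle(triangles: np.ndarray, pitch: float, z0: float = 0.0) -> float:
    """Voxel-column integration of the volume between a height-field surface
    and the plane z = z0.

    ``triangles`` is (m, 3, 3); the surface must be single-valued over xy
    (true for non-overhanging depressions).  A regular xy grid of spacing
    ``pitch`` samples the surface height by barycentric interpolation on
    whichever triangle contains each grid point; columns above the surface
    and below z0 contribute (z0 - z) * pitch^2.
    """
    triangles = np.asarray(triangles, dtype=np.float64)
    lo = triangles.reshape(-1, 3).min(axis=0)
    hi = triangles.reshape(-1, 3).max(axis=0)
    xs = np.arange(lo[0] + pitch / 2, hi[0], pitch)
    ys = np.arange(lo[1] + pitch / 2, hi[1], pitch)
    height = np.full((len(xs), len(ys)), np.nan)
    for tri in triangles:
        a, b, c = tri
        M = np.array([[b[0] - a[0], c[0] - a[0]], [b[1] - a[1], c[1] - a[1]]])
        det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
        if det == 0.0:
            continue
        ix = np.nonzero((xs >= tri[:, 0].min()) & (xs <= tri[:, 0].max()))[0]
        iy = np.nonzero((ys >= tri[:, 1].min()) & (ys <= tri[:, 1].max()))[0]
        if not len(ix) or not len(iy):
            continue
        gx, gy = np.meshgrid(xs[ix], ys[iy], indexing="ij")
        px = gx - a[0]
        py = gy - a[1]
        u = (M[1, 1] * px - M[0, 1] * py) / det
        v = (-M[1, 0] * px + M[0, 0] * py) / det
        inside = (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12)
        z = a[2] + u * (b[2] - a[2]) + v * (c[2] - a[2])
        sub = height[np.ix_(ix, iy)]
        sub[inside] = z[inside]
        height[np.ix_(ix, iy)] = sub
    depth = z0 - height
    depth = depth[np.isfinite(depth)]
    return float(np.clip(depth, 0.0, None).sum() * pitch**2)


def min_rect_sweep(xy: np.ndarray, n_angles: int = 3600) -> tuple[float, float]:
    """Minimum-area enclosing rectangle by dense rotation sweep."""
    xy = np.asarray(xy, dtype=np.float64)
    best = None
    for a in np.linspace(0.0, np.pi / 2, n_angles, endpoint=False):
        c, s = np.cos(a), np.sin(a)
        rot = xy @ np.array([[c, -s], [s, c]])
        w = rot[:, 0].max() - rot[:, 0].min()
        h = rot[:, 1].max() - rot[:, 1].min()
        if best is None or w * h < best[0]:
            best = (w * h, w, h)
    _, w, h = best
    return (max(w, h), min(w, h))
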