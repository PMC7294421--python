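"""Synthetic wound scenes with closed-form ground truth.

Real pressure-injury scans come with no analytic truth, so every stage of
the pipeline is validated on generated meshes: a circular skin plate holding
a depression whose depth, surface area, volume and axes are known exactly.

Shapes
------
``spherical_cap``   cap of a sphere (radius R, depth h) opening upward:
                    opening radius a = sqrt(h (2R - h)), depth = h,
                    lateral area = 2 pi R h, volume = pi h^2 (3R - h) / 3,
                    axes = 2a.  With h > R the cap is deeper than a
                    hemisphere and the rim overhangs the widest section —
                    the occlusion case that motivates multiple depth layers.
``ellipsoidal_pit`` lower half-ellipsoid (semi-axes ax, ay, az): depth = az,
                    volume = (2/3) pi ax ay az, axes = 2 max/2 min(ax, ay);
                    surface area by high-order quadrature (no closed form).
``flat_disk``       flat "wound" of radius a: depth 0, volume 0, area pi a^2.
``convex_bump``     spherical cap mirrored upward, emulating a wound pushed
                    above its rim by bone (heel/hip): volume ground truth is
                    flagged invalid.

The mesh is a single fan/ring triangulation: pole -> cap rings -> rim ring
(exactly on the rim plane) -> plate rings growing geometrically outward, so
interior/boundary face labels are exact by construction and the depression
boundary is one closed edge loop.  Optional rigid tilt and along-normal
vertex noise emulate scanner pose and measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .camera import CameraSpec
from .matching import PointCorrespondences, apply_homography, warp_mask
from .mesh import TriangleMesh, apply_rotation
from .raster import FaceIndexBuffer, rasterize
from .region import WoundRegion

Shape = Literal["spherical_cap", "ellipsoidal_pit", "flat_disk", "convex_bump"]


@dataclass
class SyntheticWoundSpec:
    """Parameters of a generated wound (lengths in meters).

    ``resolution`` is the number of depression rings between pole and rim
    (ring vertex counts follow ring circumference, so it also sets the edge
    length).  ``rim_ring_width`` is the radial width of the first plate ring
    outside the rim; by default one fifth of the mesh edge length, so the
    labeled wound margin converges onto the true rim under refinement.
    """

    shape: Shape = "spherical_cap"
    sphere_radius: float = 0.02   # R, for cap/bump
    depth: float = 0.01           # h, for cap/bump
    semi_axes: tuple[float, float, float] = (0.02, 0.012, 0.008)  # ellipsoid ax, ay, az
    disk_radius: float = 0.0173   # flat_disk opening radius
    plate_radius: float = 0.05    # "half-width" of the surrounding skin patch
    resolution: int = 30
    rim_ring_width: float | None = None
    tilt_deg: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution < 16:
            raise ValueError("resolution must be >= 16")
        if self.shape in ("spherical_cap", "convex_bump"):
            if not (0 < self.depth < 2 * self.sphere_radius):
                raise ValueError("cap depth must satisfy 0 < h < 2R")
            if self.opening_radius() >= self.plate_radius:
                raise ValueError("plate must enclose the wound opening")
        if self.shape == "ellipsoidal_pit" and max(self.semi_axes[:2]) >= self.plate_radius:
            raise ValueError("plate must enclose the wound opening")
        if self.shape == "flat_disk" and self.disk_radius >= self.plate_radius:
            raise ValueError("plate must enclose the wound opening")

    def opening_radius(self) -> float:
        if self.shape in ("spherical_cap", "convex_bump"):
            R, h = self.sphere_radius, self.depth
            return float(np.sqrt(h * (2 * R - h)))
        if self.shape == "ellipsoidal_pit":
            return float(max(self.semi_axes[:2]))
        return float(self.disk_radius)


@dataclass
class GroundTruth:
    """Analytic truth for a generated wound (meters; pre-tilt plane given
    in the tilted frame)."""

    depth: float
    area: float
    volume: float
    major_axis: float
    minor_axis: float
    interior_faces: np.ndarray
    boundary_faces: np.ndarray
    plane_normal: np.ndarray
    plane_offset: float
    volume_valid: bool = True

    def region(self, mesh: TriangleMesh) -> WoundRegion:
        return WoundRegion.from_faces(mesh, self.interior_faces, self.boundary_faces)


def _half_ellipsoid_area(ax: float, ay: float, az: float, n: int = 400) -> float:
    """Lateral area of the lower half-ellipsoid by Gauss-Legendre quadrature."""
    # parametrize x = ax sin(phi) cos(t), y = ay sin(phi) sin(t), z = -az cos(phi)
    phi_nodes, phi_w = np.polynomial.legendre.leggauss(n)
    t_nodes, t_w = np.polynomial.legendre.leggauss(n)
    phi = (phi_nodes + 1) * (np.pi / 4)          # [0, pi/2]
    t = (t_nodes + 1) * np.pi                    # [0, 2 pi]
    P, T = np.meshgrid(phi, t, indexing="ij")
    sp, cp, st, ct = np.sin(P), np.cos(P), np.sin(T), np.cos(T)
    # |r_phi x r_t|
    E = np.sqrt(
        (ay * az * sp**2 * ct) ** 2 + (ax * az * sp**2 * st) ** 2 + (ax * ay * sp * cp) ** 2
    )
    w = np.outer(phi_w, t_w) * (np.pi / 4) * np.pi
    return float((E * w).sum())


def _ring_profile(spec: SyntheticWoundSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Radial/vertical profile of the depression rings (r_i, z_i) for
    i = 0..resolution (0 = pole, resolution = rim at z = 0), plus the
    z sign multiplier (+1 bump, -1 depression handled via z values)."""
    n = spec.resolution
    if spec.shape in ("spherical_cap", "convex_bump"):
        R, h = spec.sphere_radius, spec.depth
        phi_max = np.arccos(np.clip((R - h) / R, -1.0, 1.0))
        phi = np.linspace(0.0, phi_max, n + 1)
        r = R * np.sin(phi)
        z = (R - h) - R * np.cos(phi)
        if spec.shape == "convex_bump":
            z = -z
        return r, z, phi_max
    if spec.shape == "ellipsoidal_pit":
        axx, ayy, azz = spec.semi_axes
        phi = np.linspace(0.0, np.pi / 2, n + 1)
        # radial profile on the unit circle; per-vertex scaling by (ax, ay)
        r = np.sin(phi)  # unit; scaled per angle below
        z = -azz * np.cos(phi)
        return r, z, np.pi / 2
    # flat disk
    r = np.linspace(0.0, spec.disk_radius, n + 1)
    return r, np.zeros(n + 1), 0.0


def _bridge_rings(
    inner_idx: np.ndarray, inner_ang: np.ndarray, outer_idx: np.ndarray, outer_ang: np.ndarray
) -> list[tuple[int, int, int]]:
    """Triangulate the band between two concentric vertex rings (possibly of
    different counts) by an angular merge sweep; counter-clockwise from +z."""
    na, nb = len(inner_idx), len(outer_idx)
    ai = np.concatenate([inner_ang, [inner_ang[0] + 2 * np.pi]])
    ao = np.concatenate([outer_ang, [outer_ang[0] + 2 * np.pi]])
    faces = []
    i = j = 0
    while i < na or j < nb:
        if j >= nb or (i < na and ai[i + 1] <= ao[j + 1]):
            faces.append((inner_idx[i], outer_idx[j % nb], inner_idx[(i + 1) % na]))
            i += 1
        else:
            faces.append((inner_idx[i % na], outer_idx[j % nb], outer_idx[(j + 1) % nb]))
            j += 1
    return faces


def make_wound(spec: SyntheticWoundSpec) -> tuple[TriangleMesh, GroundTruth]:
    """Generate a wound mesh and its analytic ground truth.

    The depression is meshed geodesic-style: the vertex count of each ring
    is proportional to its circumference, so triangles have near-uniform
    edge length (a sub-pixel sliver face could never be recovered from the
    face-index buffer, and scanner meshes have roughly uniform faces too).
    Deterministic for a fixed spec (seed drives only the vertex noise).
    Faces are counter-clockwise seen from above (+z normals).
    """
    n = spec.resolution
    r_prof, z_prof, phi_max = _ring_profile(spec)

    ellip = spec.shape == "ellipsoidal_pit"
    axx, ayy = (spec.semi_axes[0], spec.semi_axes[1]) if ellip else (1.0, 1.0)

    # target edge length = depression arc length / resolution
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(r_prof * max(axx, ayy) if ellip else r_prof),
                                                    np.diff(z_prof)))])
    edge = max(arc[-1] / n, 1e-6)

    def ring_count(circumference: float) -> int:
        return max(8, int(np.ceil(circumference / edge)))

    rings_xy: list[np.ndarray] = []   # (m_i, 2) per ring
    rings_z: list[float] = []
    for i in range(1, n + 1):
        if ellip:
            ca, cb = axx * r_prof[i], ayy * r_prof[i]
            # Ramanujan approximation of the ellipse circumference
            hh = ((ca - cb) / (ca + cb)) ** 2 if (ca + cb) > 0 else 0.0
            circ = np.pi * (ca + cb) * (1 + 3 * hh / (10 + np.sqrt(4 - 3 * hh)))
        else:
            ca = cb = r_prof[i]
            circ = 2 * np.pi * r_prof[i]
        m_i = ring_count(circ)
        theta = 2 * np.pi * np.arange(m_i) / m_i
        rings_xy.append(np.column_stack([ca * np.cos(theta), cb * np.sin(theta)]))
        rings_z.append(z_prof[i])
    n_cap_rings = len(rings_xy)

    # plate rings: from the rim outward, widths growing geometrically
    r0 = spec.opening_radius()
    plate_r: list[float] = []
    dr = spec.rim_ring_width if spec.rim_ring_width is not None else edge / 5.0
    r = r0
    while True:
        r = r + dr
        if r >= spec.plate_radius - 1e-9:
            plate_r.append(spec.plate_radius)
            break
        plate_r.append(r)
        dr *= 1.35
    rim_xy = rings_xy[-1]
    for rr in plate_r:
        t = (rr - r0) / (spec.plate_radius - r0)
        m_i = ring_count(2 * np.pi * rr)
        theta = 2 * np.pi * np.arange(m_i) / m_i
        circle = np.column_stack([rr * np.cos(theta), rr * np.sin(theta)])
        if ellip:
            # blend the elliptical rim outline into the outer circle
            rim_like = np.column_stack(
                [(rr / r0) * axx * np.cos(theta) * (r0 / max(axx, ayy)),
                 (rr / r0) * ayy * np.sin(theta) * (r0 / max(axx, ayy))]
            )
            rings_xy.append((1 - t) * rim_like + t * circle)
        else:
            rings_xy.append(circle)
        rings_z.append(0.0)

    # assemble vertices: pole first, then rings in order
    verts = [np.array([[0.0, 0.0, z_prof[0]]])]
    ring_start = [None]
    offset = 1
    for xy, z in zip(rings_xy, rings_z):
        ring_start.append(offset)
        verts.append(np.column_stack([xy, np.full(len(xy), z)]))
        offset += len(xy)
    vertices = np.vstack(verts)

    def ring_indices(i: int) -> tuple[np.ndarray, np.ndarray]:
        xy = rings_xy[i - 1]
        idx = ring_start[i] + np.arange(len(xy))
        ang = np.mod(np.arctan2(xy[:, 1], xy[:, 0]), 2 * np.pi)
        # rings are built with ascending angles starting at 0
        return idx, ang

    faces: list[tuple[int, int, int]] = []
    face_ring: list[int] = []  # outer ring index of each face
    idx1, _ = ring_indices(1)
    for k in range(len(idx1)):  # pole fan
        faces.append((0, idx1[k], idx1[(k + 1) % len(idx1)]))
        face_ring.append(1)
    for i in range(1, len(rings_xy)):
        ii, ia = ring_indices(i)
        oi, oa = ring_indices(i + 1)
        band = _bridge_rings(ii, ia, oi, oa)
        faces.extend(band)
        face_ring.extend([i + 1] * len(band))
    faces_arr = np.asarray(faces, dtype=np.int64)
    face_ring_arr = np.asarray(face_ring)

    # labels: depression faces (outer ring <= rim ring) are interior;
    # the first plate ring of faces is the wound boundary
    interior_faces = np.nonzero(face_ring_arr <= n_cap_rings)[0]
    boundary_faces = np.nonzero(face_ring_arr == n_cap_rings + 1)[0]

    mesh = TriangleMesh(vertices, faces_arr)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        normals = mesh.vertex_normals()
        mesh = TriangleMesh(
            mesh.vertices + spec.noise_sigma * rng.standard_normal((mesh.n_vertices, 1)) * normals,
            mesh.faces,
        )

    plane_normal = np.array([0.0, 0.0, 1.0])
    plane_offset = 0.0
    if spec.tilt_deg != 0.0:
        tilt = np.deg2rad(spec.tilt_deg)
        Rx = np.array(
            [[1, 0, 0], [0, np.cos(tilt), -np.sin(tilt)], [0, np.sin(tilt), np.cos(tilt)]]
        )
        mesh = apply_rotation(mesh, Rx)
        plane_normal = Rx @ plane_normal  # offset stays 0: plane passes through origin

    if spec.shape in ("spherical_cap", "convex_bump"):
        R_, h = spec.sphere_radius, spec.depth
        a = spec.opening_radius()
        gt = GroundTruth(
            depth=h,
            area=2 * np.pi * R_ * h,
            volume=np.pi * h**2 * (3 * R_ - h) / 3.0,
            major_axis=2 * a,
            minor_axis=2 * a,
            interior_faces=interior_faces,
            boundary_faces=boundary_faces,
            plane_normal=plane_normal,
            plane_offset=plane_offset,
            volume_valid=spec.shape == "spherical_cap",
        )
    elif spec.shape == "ellipsoidal_pit":
        axx_, ayy_, azz_ = spec.semi_axes
        gt = GroundTruth(
            depth=azz_,
            area=_half_ellipsoid_area(axx_, ayy_, azz_),
            volume=2.0 / 3.0 * np.pi * axx_ * ayy_ * azz_,
            major_axis=2 * max(axx_, ayy_),
            minor_axis=2 * min(axx_, ayy_),
            interior_faces=interior_faces,
            boundary_faces=boundary_faces,
            plane_normal=plane_normal,
            plane_offset=plane_offset,
        )
    else:  # flat_disk
        gt = GroundTruth(
            depth=0.0,
            area=np.pi * spec.disk_radius**2,
            volume=0.0,
            major_axis=2 * spec.disk_radius,
            minor_axis=2 * spec.disk_radius,
            interior_faces=interior_faces,
            boundary_faces=boundary_faces,
            plane_normal=plane_normal,
            plane_offset=plane_offset,
        )
    return mesh, gt


@dataclass
class SyntheticScene:
    """A full matching-block test scene derived from a generated wound."""

    mesh: TriangleMesh
    ground_truth: GroundTruth
    buffer: FaceIndexBuffer
    topview_mask: np.ndarray
    photo_mask: np.ndarray
    correspondences: PointCorrespondences
    true_homography: np.ndarray  # photo -> top view
    camera: CameraSpec = field(default_factory=CameraSpec)


def _random_homography(image_size: int, rng: np.random.Generator,
                       max_shift_frac: float = 0.12) -> np.ndarray:
    """Bounded random homography (top view -> photo) built by jittering the
    image corners; stands in for the unknown photograph viewpoint."""
    from .matching import fit_projective

    S = image_size
    corners = np.array([[0.0, 0.0], [S, 0.0], [S, S], [0.0, S]])
    jitter = rng.uniform(-max_shift_frac * S, max_shift_frac * S, size=(4, 2))
    shift = rng.uniform(-0.05 * S, 0.05 * S, size=2)
    corr = PointCorrespondences(corners, corners + jitter + shift)
    H, _ = fit_projective(corr)
    return H


def make_scene(
    mesh: TriangleMesh,
    gt: GroundTruth,
    camera: CameraSpec | None = None,
    faces_per_pixel: int = 5,
    n_correspondences: int = 8,
    identity_distortion: bool = False,
    seed: int = 0,
) -> SyntheticScene:
    """Render a wound and fabricate the matching-block inputs.

    The exact top-view wound mask marks pixels where any depth layer holds a
    labeled wound face.  A bounded random homography distorts it into the
    "photograph" mask, and exact correspondences sampled on a grid over the
    wound footprint are emitted together with the true homography
    (photo -> top view) for oracle checks.
    """
    camera = camera or CameraSpec()
    rng = np.random.default_rng(seed)
    render = rasterize(mesh, camera, faces_per_pixel=faces_per_pixel)
    buffer = render.buffer

    wound_faces = np.union1d(gt.interior_faces, gt.boundary_faces)
    lut = np.zeros(mesh.n_faces + 1, dtype=bool)
    lut[wound_faces] = True
    ids = buffer.face_ids
    topview_mask = lut[np.where(ids >= 0, ids, mesh.n_faces)].any(axis=2)

    S = camera.image_size
    if identity_distortion:
        H_true = np.eye(3)
    else:
        H_top_to_photo = _random_homography(S, rng)
        H_true = np.linalg.inv(H_top_to_photo)
        H_true /= H_true[2, 2]
    photo_mask = warp_mask(topview_mask, np.linalg.inv(H_true), S)

    rr, cc = np.nonzero(topview_mask)
    pad = max(4, S // 32)
    r0, r1 = max(rr.min() - pad, 0), min(rr.max() + pad, S - 1)
    c0, c1 = max(cc.min() - pad, 0), min(cc.max() + pad, S - 1)
    g = int(np.ceil(np.sqrt(n_correspondences)))
    gy, gx = np.meshgrid(np.linspace(r0, r1, g), np.linspace(c0, c1, g), indexing="ij")
    top_pts = np.column_stack([gx.ravel(), gy.ravel()])[:n_correspondences]
    photo_pts = apply_homography(np.linalg.inv(H_true), top_pts)
    corr = PointCorrespondences(photo_pts, top_pts)

    return SyntheticScene(mesh, gt, buffer, topview_mask, photo_mask, corr, H_true, replace(camera))
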