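"""Measurement block: rim-plane fit, alignment, and the wound's depth,
area, volume and major/minor axes with validity checking.

The wound rim is assumed to lie on a plane (the healthy-skin surface).
RANSAC fits that plane to the boundary vertices, the mesh is rotated so the
plane is horizontal, and then:

* depth  = max |z - z0| over interior vertices (meters below the rim plane);
* area   = sum of interior triangle areas (true 3D surface area);
* the rim is closed by the 2D convex hull of the boundary vertices' xy
  coordinates, lifted to the plane and fan-triangulated from its centroid;
* axes   = sides of the minimum-area oriented rectangle of that hull;
* volume = |sum of signed tetrahedra| from the hull centroid over the closed
  surface (wound triangles + closing triangles).

A volume is only meaningful when the wound is a depression below its rim
(concave); wounds over bone (heel, hip) can bulge above the rim plane, in
which case the tetrahedron sum counts spurious sub-volumes and the result is
flagged invalid rather than reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .mesh import (
    TriangleMesh,
    apply_rotation,
    rotation_aligning_normal,
    signed_tetra_volume,
    triangle_areas,
)
from .region import WoundRegion, region_vertices_3d

log = logging.getLogger(__name__)


@dataclass
class MeasurementConfig:
    """Tunable parameters of the measurement block (all lengths in meters)."""

    ransac_threshold: float = 1e-3   # 1 mm inlier distance for the rim plane
    ransac_iters: int = 1000
    ransac_seed: int = 0
    concavity_height_tol: float | None = None  # default: ransac_threshold
    concavity_frac_tol: float = 0.05  # fraction of interior vertices allowed above plane
    axis_aligned_box: bool = False   # measure axes on the axis-aligned box instead
    include_boundary_area: bool = False  # add boundary triangles to the area sum


@dataclass
class PlaneModel:
    """Plane {p : normal . p = offset} with unit normal; ``inliers`` indexes
    the point array the plane was fitted to."""

    normal: np.ndarray
    offset: float
    inliers: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=np.float64)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            self.normal = self.normal / n
        self.inliers = np.asarray(self.inliers, dtype=np.int64)

    def signed_distance(self, points) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.normal - self.offset


@dataclass
class WoundMeasurements:
    """Wound measurements in clinical units (cm / cm^2 / cm^3)."""

    depth_cm: float
    area_cm2: float
    major_axis_cm: float
    minor_axis_cm: float
    volume_cm3: float | None
    volume_valid: bool
    warnings: list[str] = field(default_factory=list)
    plane: PlaneModel | None = None

    def to_dict(self) -> dict:
        d = {
            "depth": {"value": self.depth_cm, "unit": "cm"},
            "area": {"value": self.area_cm2, "unit": "cm^2"},
            "major_axis": {"value": self.major_axis_cm, "unit": "cm"},
            "minor_axis": {"value": self.minor_axis_cm, "unit": "cm"},
            "volume": {
                "value": self.volume_cm3 if self.volume_valid else None,
                "unit": "cm^3",
                "valid": self.volume_valid,
            },
            "warnings": list(self.warnings),
        }
        if self.plane is not None:
            d["rim_plane"] = {
                "normal": self.plane.normal.tolist(),
                "offset_m": float(self.plane.offset),
                "inlier_count": int(len(self.plane.inliers)),
                "threshold_m": float(self.plane.threshold),
            }
        return d


def _lsq_plane(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares plane through points (SVD of centered cloud)."""
    c = points.mean(axis=0)
    _, sv, Vt = np.linalg.svd(points - c, full_matrices=False)
    n = Vt[-1]
    return n, float(n @ c)


def ransac_plane(
    points,
    threshold: float = 1e-3,
    max_iters: int = 1000,
    seed: int = 0,
    orient: np.ndarray | None = None,
) -> PlaneModel:
    """RANSAC plane fit: sample 3 points, count inliers within ``threshold``,
    keep the consensus-maximizing model, then iterate least-squares refits on
    the enlarged consensus set until it stabilizes.

    ``orient``: optional direction the plane normal should point along —
    the body-outward direction (e.g. the mean normal of the skin faces
    around the rim), so that "below the plane" means "into the body".
    Orienting from the skin rather than from the wound interior is what
    lets a wound bulging above its rim be detected as convex instead of
    being silently flipped into a depression.  Default: normal toward +z.
    Deterministic for a fixed seed.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    n_pts = len(points)
    if n_pts < 3:
        raise ValueError("plane fit needs at least 3 points")
    rng = np.random.default_rng(seed)

    best_count = 0
    best_inliers: np.ndarray | None = None
    if n_pts == 3:
        best_inliers = np.arange(3)
    else:
        for _ in range(max_iters):
            i, j, k = rng.choice(n_pts, size=3, replace=False)
            normal = np.cross(points[j] - points[i], points[k] - points[i])
            norm = np.linalg.norm(normal)
            if norm < 1e-15:
                continue
            normal = normal / norm
            d = points @ normal - normal @ points[i]
            inliers = np.abs(d) <= threshold
            count = int(inliers.sum())
            if count > best_count:
                best_count = count
                best_inliers = np.nonzero(inliers)[0]
        if best_inliers is None:
            raise ValueError("RANSAC found no valid plane (all samples collinear)")

    # refit on the consensus set, re-collect inliers, repeat until stable
    inlier_idx = best_inliers
    for _ in range(10):
        normal, offset = _lsq_plane(points[inlier_idx])
        new_idx = np.nonzero(np.abs(points @ normal - offset) <= threshold)[0]
        if len(new_idx) < 3:
            new_idx = inlier_idx  # keep the minimal consensus rather than degenerate
            break
        if np.array_equal(new_idx, inlier_idx):
            inlier_idx = new_idx
            break
        inlier_idx = new_idx
    normal, offset = _lsq_plane(points[inlier_idx])

    if orient is not None:
        flip = float(np.asarray(orient) @ normal) < 0
    else:
        flip = normal[2] < 0
    if flip:
        normal, offset = -normal, -offset
    return PlaneModel(normal, offset, inlier_idx, threshold)


def align_to_plane(mesh: TriangleMesh, plane: PlaneModel) -> tuple[TriangleMesh, PlaneModel]:
    """Rotate mesh so the rim plane's normal becomes +z; the plane becomes
    z = z0 with z0 equal to the (unchanged) plane offset."""
    R = rotation_aligning_normal(plane.normal)
    aligned = apply_rotation(mesh, R)
    new_plane = PlaneModel(np.array([0.0, 0.0, 1.0]), plane.offset, plane.inliers, plane.threshold)
    return aligned, new_plane


def compute_depth(interior_points, z0: float) -> tuple[float, np.ndarray]:
    """Wound depth = max |z0 - z| over interior points (aligned frame).

    Returns (depth in meters, per-vertex depths z0 - z; positive below the
    rim plane).  Empty interior yields depth 0 (a warning is logged).
    """
    interior_points = np.asarray(interior_points, dtype=np.float64).reshape(-1, 3)
    if len(interior_points) == 0:
        log.warning("compute_depth: empty wound interior; depth = 0")
        return 0.0, np.zeros(0)
    per_vertex = z0 - interior_points[:, 2]
    return float(np.max(np.abs(per_vertex))), per_vertex


def compute_area(region: WoundRegion, mesh: TriangleMesh, include_boundary: bool = False) -> float:
    """Wound surface area (m^2): sum of interior triangle areas (optionally
    including boundary triangles)."""
    fids = region.interior_faces
    if include_boundary:
        fids = np.union1d(fids, region.boundary_faces)
    if fids.size == 0:
        return 0.0
    return float(triangle_areas(mesh, fids).sum())


def close_top_surface(
    boundary_points, z0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Close the wound with the convex hull of the rim's xy coordinates.

    The hull polygon is lifted to the rim plane z = z0 and fan-triangulated
    from its area centroid.  Returns ``(closing_vertices, closing_faces,
    center)`` where vertex 0 of the closing mesh is the center; triangles are
    counter-clockwise in xy (normal +z, outward for the wound void below).
    """
    pts = np.asarray(boundary_points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("closing the top surface needs >= 3 boundary points")
    xy = pts[:, :2]
    try:
        hull = ConvexHull(xy)
    except QhullError as exc:
        raise ValueError("boundary points are collinear in xy; cannot close surface") from exc
    poly = xy[hull.vertices]  # counter-clockwise

    # area centroid of the hull polygon (shoelace)
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    center = np.array([cx, cy, z0])

    m = len(poly)
    verts = np.vstack([center, np.column_stack([poly, np.full(m, z0)])])
    faces = np.array([[0, 1 + i, 1 + (i + 1) % m] for i in range(m)], dtype=np.int64)
    return verts, faces, center


def min_area_rectangle(xy: np.ndarray) -> tuple[float, float]:
    """Side lengths (major >= minor) of the minimum-area oriented rectangle
    enclosing 2D points (rotating-calipers over convex-hull edge directions)."""
    xy = np.asarray(xy, dtype=np.float64).reshape(-1, 2)
    hull = ConvexHull(xy)
    poly = xy[hull.vertices]
    edges = np.roll(poly, -1, axis=0) - poly
    angles = np.unique(np.mod(np.arctan2(edges[:, 1], edges[:, 0]), np.pi / 2.0))
    best = None
    for a in angles:
        c, s = np.cos(a), np.sin(a)
        rot = poly @ np.array([[c, -s], [s, c]])
        w = rot[:, 0].max() - rot[:, 0].min()
        h = rot[:, 1].max() - rot[:, 1].min()
        if best is None or w * h < best[0]:
            best = (w * h, w, h)
    _, w, h = best
    return (max(w, h), min(w, h))


def compute_axes(boundary_points, axis_aligned: bool = False) -> tuple[float, float]:
    """Major/minor axes (meters): sides of the minimum-area oriented
    bounding rectangle of the rim hull in the aligned xy plane (or of the
    axis-aligned box when ``axis_aligned``)."""
    pts = np.asarray(boundary_points, dtype=np.float64).reshape(-1, 3)
    xy = pts[:, :2]
    if axis_aligned:
        w = float(xy[:, 0].max() - xy[:, 0].min())
        h = float(xy[:, 1].max() - xy[:, 1].min())
        return (max(w, h), min(w, h))
    major, minor = min_area_rectangle(xy)
    if major <= 0:
        raise ValueError("degenerate (zero-area) rim hull")
    return (float(major), float(minor))


def compute_volume(
    mesh: TriangleMesh,
    region: WoundRegion,
    closing_vertices: np.ndarray,
    closing_faces: np.ndarray,
    center: np.ndarray,
) -> float:
    """Wound volume (m^3): |sum of signed tetrahedra| from the closing-
    surface center over wound triangles plus closing triangles.

    Wound faces are counter-clockwise from above (normals up, into the
    void), so they are reversed to orient the closed surface consistently
    outward; the lid triangles already point +z.
    """
    wound_fids = np.union1d(region.interior_faces, region.boundary_faces)
    tw = mesh.triangles(wound_fids)[:, ::-1, :] - center  # reversed: outward (down)
    tl = closing_vertices[closing_faces] - center
    tris = np.concatenate([tw, tl])
    vols = np.einsum("ij,ij->i", tris[:, 0], np.cross(tris[:, 1], tris[:, 2])) / 6.0
    return float(abs(vols.sum()))


def validate_concavity(
    interior_points,
    z0: float,
    height_tol: float,
    frac_tol: float = 0.05,
) -> tuple[bool, dict]:
    """Check that the wound interior lies below the rim plane.

    Fails when more than ``frac_tol`` of interior vertices sit more than
    ``height_tol`` above z0 — the signature of a wound bulging over bone,
    for which the tetrahedron volume counts spurious sub-volumes.
    """
    pts = np.asarray(interior_points, dtype=np.float64).reshape(-1, 3)
    if len(pts) == 0:
        return True, {"fraction_above": 0.0, "n_interior": 0}
    above = pts[:, 2] > z0 + height_tol
    frac = float(above.mean())
    return frac <= frac_tol, {"fraction_above": frac, "n_interior": int(len(pts)),
                              "height_tol_m": float(height_tol)}


def measure_wound(
    mesh: TriangleMesh,
    region: WoundRegion,
    config: MeasurementConfig | None = None,
) -> WoundMeasurements:
    """Full measurement block: rim-plane RANSAC -> alignment -> depth, area,
    hull closure, axes, volume, concavity validation.  Input mesh is in
    meters; the report is in cm / cm^2 / cm^3."""
    cfg = config or MeasurementConfig()
    warnings_: list[str] = []

    boundary_pts, interior_pts = region_vertices_3d(region, mesh)
    if len(boundary_pts) < 3:
        raise ValueError("measurement requires >= 3 wound boundary vertices")

    # body-outward direction = mean normal of the skin faces around the rim
    outward = mesh.face_normals()[region.boundary_faces].mean(axis=0)
    if np.linalg.norm(outward) < 1e-9:
        outward = None
    plane = ransac_plane(
        boundary_pts,
        threshold=cfg.ransac_threshold,
        max_iters=cfg.ransac_iters,
        seed=cfg.ransac_seed,
        orient=outward,
    )
    aligned, aplane = align_to_plane(mesh, plane)
    z0 = aplane.offset
    bnd_a, int_a = region_vertices_3d(region, aligned)

    depth_m, _ = compute_depth(int_a, z0)
    if len(int_a) == 0:
        warnings_.append("empty wound interior: depth/area/volume are zero or undefined")
    area_m2 = compute_area(region, aligned, include_boundary=cfg.include_boundary_area)

    closing_v, closing_f, center = close_top_surface(bnd_a, z0)
    major_m, minor_m = compute_axes(bnd_a, axis_aligned=cfg.axis_aligned_box)

    height_tol = cfg.concavity_height_tol if cfg.concavity_height_tol is not None else cfg.ransac_threshold
    concave_ok, diag = validate_concavity(int_a, z0, height_tol, cfg.concavity_frac_tol)

    rim_dev = float(np.max(np.abs(bnd_a[:, 2] - z0))) if len(bnd_a) else 0.0
    rim_ok = rim_dev <= 10.0 * cfg.ransac_threshold
    if not rim_ok:
        warnings_.append(
            f"wound rim deviates {rim_dev * 100:.2f} cm from the fitted plane; "
            "the closing surface may not cap the wound"
        )

    volume_valid = bool(concave_ok and rim_ok)
    volume_m3 = compute_volume(aligned, region, closing_v, closing_f, center)
    if not concave_ok:
        warnings_.append(
            f"wound surface is not concave ({diag['fraction_above'] * 100:.1f}% of interior "
            "vertices above the rim plane): depth and volume are unreliable"
        )

    return WoundMeasurements(
        depth_cm=depth_m * 100.0,
        area_cm2=area_m2 * 1e4,
        major_axis_cm=major_m * 100.0,
        minor_axis_cm=minor_m * 100.0,
        volume_cm3=volume_m3 * 1e6,
        volume_valid=volume_valid,
        warnings=warnings_,
        plane=plane,
    )
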