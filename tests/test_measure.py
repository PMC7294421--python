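"""Measurement block: plane fit, alignment, depth/area/volume/axes."""

import numpy as np
import pytest

from woundmetrics.measure import (
    MeasurementConfig,
    align_to_plane,
    close_top_surface,
    compute_area,
    compute_axes,
    compute_depth,
    compute_volume,
    measure_wound,
    ransac_plane,
    validate_concavity,
)
from woundmetrics.mesh import TriangleMesh, apply_rotation, rotation_aligning_normal
from woundmetrics.region import WoundRegion, region_vertices_3d
from woundmetrics.synthetic import SyntheticWoundSpec, make_wound

from .oracles import min_rect_sweep


def plane_outlier_instance(seed=0):
    """70 points exactly on a tilted plane + 30 outliers kept >= 3 mm away."""
    rng = np.random.default_rng(seed)
    normal = np.array([0.2, -0.1, 1.0])
    normal /= np.linalg.norm(normal)
    d = 0.05
    basis = np.linalg.svd(normal[None, :])[2][1:]
    inliers = d * normal + rng.uniform(-0.05, 0.05, size=(70, 2)) @ basis
    outliers = []
    while len(outliers) < 30:
        p = rng.uniform(-0.06, 0.12, size=3)
        if abs(p @ normal - d) > 0.003:
            outliers.append(p)
    pts = np.vstack([inliers, np.asarray(outliers)])
    return pts, normal, d


class TestRansacPlane:
    def test_exact_horizontal_plane(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-1, 1, (100, 2)), np.full(100, 0.1)])
        plane = ransac_plane(pts, threshold=1e-3, seed=0)
        np.testing.assert_allclose(np.abs(plane.normal), [0, 0, 1], atol=1e-9)
        assert plane.offset * np.sign(plane.normal[2]) == pytest.approx(0.1, abs=1e-9)
        assert len(plane.inliers) == 100

    def test_three_points_exact_plane(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 1]], dtype=float)
        plane = ransac_plane(pts, threshold=1e-3, seed=0)
        np.testing.assert_allclose(plane.signed_distance(pts), 0, atol=1e-12)

    def test_seventy_thirty_instance_recovers_plane(self):
        pts, normal, _ = plane_outlier_instance()
        plane = ransac_plane(pts, threshold=1e-3, max_iters=1000, seed=0)
        assert set(range(70)).issubset(set(plane.inliers.tolist()))
        angle = np.degrees(np.arccos(np.clip(abs(plane.normal @ normal), -1, 1)))
        assert angle < 0.5

    def test_deterministic_given_seed(self):
        pts, _, _ = plane_outlier_instance(seed=5)
        a = ransac_plane(pts, seed=42)
        b = ransac_plane(pts, seed=42)
        np.testing.assert_array_equal(a.normal, b.normal)
        np.testing.assert_array_equal(a.inliers, b.inliers)

    def test_orientation_follows_reference_direction(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(-1, 1, (50, 2)), np.zeros(50)])
        up = ransac_plane(pts, seed=0, orient=np.array([0, 0, 1.0]))
        down = ransac_plane(pts, seed=0, orient=np.array([0, 0, -1.0]))
        np.testing.assert_allclose(up.normal, -down.normal, atol=1e-12)

    def test_collinear_points_rejected(self):
        t = np.linspace(0, 1, 10)
        pts = np.column_stack([t, 2 * t, -t])
        with pytest.raises(ValueError):
            ransac_plane(pts, seed=0)


class TestAlignment:
    def test_already_aligned_plane_is_fixed_point(self):
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.uniform(-1, 1, (30, 2)), np.full(30, 0.2)])
        mesh = TriangleMesh(pts[:3], [[0, 1, 2]])
        plane = ransac_plane(pts, seed=0)
        aligned, aplane = align_to_plane(mesh, plane)
        np.testing.assert_allclose(aligned.vertices, mesh.vertices, atol=1e-12)
        np.testing.assert_allclose(aplane.normal, [0, 0, 1], atol=1e-12)

    def test_tilted_wound_boundary_flattens(self):
        mesh, gt = make_wound(SyntheticWoundSpec(resolution=20, tilt_deg=25.0))
        region = gt.region(mesh)
        bnd, _ = region_vertices_3d(region, mesh)
        plane = ransac_plane(bnd, threshold=1e-3, seed=0)
        aligned, aplane = align_to_plane(mesh, plane)
        bnd_a, _ = region_vertices_3d(region, aligned)
        assert np.ptp(bnd_a[:, 2]) < 1e-3

    def test_alignment_preserves_area(self):
        from woundmetrics.mesh import triangle_areas

        mesh, gt = make_wound(SyntheticWoundSpec(resolution=16, tilt_deg=40.0))
        bnd, _ = region_vertices_3d(gt.region(mesh), mesh)
        plane = ransac_plane(bnd, seed=0)
        aligned, _ = align_to_plane(mesh, plane)
        assert triangle_areas(aligned).sum() == pytest.approx(
            triangle_areas(mesh).sum(), rel=1e-9
        )


class TestDepth:
    def test_interior_on_plane_gives_zero(self):
        pts = np.column_stack([np.arange(5), np.arange(5), np.full(5, 0.3)])
        depth, per_vertex = compute_depth(pts, z0=0.3)
        assert depth == 0.0
        np.testing.assert_array_equal(per_vertex, 0)

    def test_point_above_plane_counts_absolute(self):
        pts = np.array([[0, 0, 0.305], [0, 0, 0.299]])
        depth, _ = compute_depth(pts, z0=0.3)
        assert depth == pytest.approx(0.005)

    def test_empty_interior_warns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            depth, _ = compute_depth(np.zeros((0, 3)), z0=0.0)
        assert depth == 0.0


class TestArea:
    def test_unit_right_triangle(self):
        mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        region = WoundRegion.from_faces(mesh, interior_faces=[0], boundary_faces=[])
        assert compute_area(region, mesh) == pytest.approx(0.5)

    def test_invariant_under_rotation(self):
        mesh, gt = make_wound(SyntheticWoundSpec(resolution=16))
        region = gt.region(mesh)
        a0 = compute_area(region, mesh)
        R = rotation_aligning_normal(np.array([1.0, -1.0, 1.0]) / np.sqrt(3))
        assert compute_area(region, apply_rotation(mesh, R)) == pytest.approx(a0, rel=1e-9)

    def test_boundary_inclusion_flag(self):
        mesh = TriangleMesh(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], [[0, 1, 2], [1, 3, 2]]
        )
        region = WoundRegion.from_faces(mesh, interior_faces=[0], boundary_faces=[1])
        assert compute_area(region, mesh, include_boundary=True) == pytest.approx(1.0)
        assert compute_area(region, mesh, include_boundary=False) == pytest.approx(0.5)


class TestCloseTopSurface:
    def test_square_boundary_gives_four_fan_triangles(self):
        pts = np.array([[0, 0, 0.1], [1, 0, 0.1], [1, 1, 0.1], [0, 1, 0.1]])
        verts, faces, center = close_top_surface(pts, z0=0.1)
        assert len(faces) == 4
        np.testing.assert_allclose(center, [0.5, 0.5, 0.1], atol=1e-12)
        assert (verts[:, 2] == 0.1).all()

    def test_circular_rim_hull_perimeter(self):
        a = 0.017
        t = 2 * np.pi * np.arange(100) / 100
        pts = np.column_stack([a * np.cos(t), a * np.sin(t), np.zeros(100)])
        verts, faces, _ = close_top_surface(pts, z0=0.0)
        poly = verts[1:, :2]
        per = np.linalg.norm(np.roll(poly, -1, axis=0) - poly, axis=1).sum()
        assert per == pytest.approx(2 * np.pi * a, rel=0.005)

    def test_hull_contains_every_boundary_point(self):
        from matplotlib.path import Path as MplPath

        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.normal(0, 0.01, (40, 2)), np.zeros(40)])
        verts, _, _ = close_top_surface(pts, z0=0.0)
        hull_poly = MplPath(verts[1:, :2])
        assert hull_poly.contains_points(pts[:, :2], radius=1e-12).all()

    def test_collinear_boundary_rejected(self):
        t = np.linspace(0, 1, 8)
        pts = np.column_stack([t, 2 * t, np.zeros(8)])
        with pytest.raises(ValueError, match="collinear"):
            close_top_surface(pts, z0=0.0)


class TestAxes:
    def _rect_points(self, w=0.03, h=0.01, angle=0.0):
        t = np.linspace(0, 1, 25)
        edge_x = np.concatenate([t * w, np.full(25, w), t[::-1] * w, np.zeros(25)])
        edge_y = np.concatenate([np.zeros(25), t * h, np.full(25, h), t[::-1] * h])
        xy = np.column_stack([edge_x, edge_y])
        c, s = np.cos(angle), np.sin(angle)
        xy = xy @ np.array([[c, s], [-s, c]])
        return np.column_stack([xy, np.zeros(len(xy))])

    def test_axis_aligned_rectangle(self):
        major, minor = compute_axes(self._rect_points())
        assert major == pytest.approx(0.03, abs=1e-9)
        assert minor == pytest.approx(0.01, abs=1e-9)

    def test_rotated_rectangle_same_axes(self):
        major, minor = compute_axes(self._rect_points(angle=np.deg2rad(30)))
        assert major == pytest.approx(0.03, abs=1e-9)
        assert minor == pytest.approx(0.01, abs=1e-9)

    def test_circle_axes_are_diameter(self):
        a = 0.0173
        t = 2 * np.pi * np.arange(200) / 200
        pts = np.column_stack([a * np.cos(t), a * np.sin(t), np.zeros(200)])
        major, minor = compute_axes(pts)
        assert major == pytest.approx(2 * a, rel=0.002)
        assert minor == pytest.approx(2 * a, rel=0.002)

    def test_matches_dense_sweep_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            xy = rng.normal(0, 0.01, size=(30, 2))
            pts = np.column_stack([xy, np.zeros(30)])
            major, minor = compute_axes(pts)
            o_major, o_minor = min_rect_sweep(xy)
            # the sweep oracle is a lower-resolution search: calipers must not be worse
            assert major * minor <= o_major * o_minor + 1e-12
            assert major == pytest.approx(o_major, rel=1e-3)
            assert minor == pytest.approx(o_minor, rel=1e-3)

    def test_major_at_least_minor_and_bounded_by_diameter(self):
        rng = np.random.default_rng(5)
        xy = rng.normal(0, 0.01, size=(40, 2))
        pts = np.column_stack([xy, np.zeros(40)])
        major, minor = compute_axes(pts)
        assert major >= minor
        from scipy.spatial.distance import pdist

        diameter = pdist(xy).max()
        assert minor <= diameter + 1e-12
        assert major >= diameter / np.sqrt(2) - 1e-12

    def test_axis_aligned_flag(self):
        pts = self._rect_points(angle=np.deg2rad(45))
        major, _ = compute_axes(pts, axis_aligned=True)
        assert major == pytest.approx((0.03 + 0.01) / np.sqrt(2), rel=1e-6)


class TestVolume:
    def test_open_box_closed_by_lid(self, cube):
        """Unit cube with the z=1 lid removed, closed again by the hull lid."""
        open_faces = cube.faces[:10]  # drop the two z=1 triangles
        mesh = TriangleMesh(cube.vertices, open_faces)
        # wound convention: faces counter-clockwise from above -> flip the
        # outward-oriented box so normals point up/inward
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
        region = WoundRegion.from_faces(mesh, interior_faces=np.arange(2, 10),
                                        boundary_faces=np.arange(2))
        top = np.array([[0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float)
        verts, faces, center = close_top_surface(top, z0=1.0)
        vol = compute_volume(mesh, region, verts, faces, center)
        assert vol == pytest.approx(1.0, rel=1e-12)

    def test_cap_volume_near_analytic(self):
        mesh, gt = make_wound(SyntheticWoundSpec(resolution=40))
        region = gt.region(mesh)
        bnd, _ = region_vertices_3d(region, mesh)
        verts, faces, center = close_top_surface(bnd, z0=0.0)
        vol = compute_volume(mesh, region, verts, faces, center)
        assert vol == pytest.approx(gt.volume, rel=0.02)

    def test_volume_independent_of_fan_center(self):
        """Origin invariance of the closed surface: moving the tetrahedron
        apex off the lid centroid must not change the total."""
        mesh, gt = make_wound(SyntheticWoundSpec(resolution=20))
        region = gt.region(mesh)
        bnd, _ = region_vertices_3d(region, mesh)
        verts, faces, center = close_top_surface(bnd, z0=0.0)
        v0 = compute_volume(mesh, region, verts, faces, center)
        v1 = compute_volume(mesh, region, verts, faces, center + [0.3, -0.2, 0.5])
        assert v1 == pytest.approx(v0, rel=1e-6)


class TestConcavity:
    def test_all_below_plane_is_valid(self):
        pts = np.column_stack([np.zeros((20, 2)), -np.linspace(0.001, 0.01, 20)])
        ok, diag = validate_concavity(pts, z0=0.0, height_tol=1e-3)
        assert ok and diag["fraction_above"] == 0.0

    def test_bump_above_plane_is_invalid(self):
        pts = np.column_stack([np.zeros((20, 2)), np.linspace(0.002, 0.01, 20)])
        ok, diag = validate_concavity(pts, z0=0.0, height_tol=1e-3)
        assert not ok and diag["fraction_above"] == 1.0

    def test_small_jitter_fraction_tolerated(self):
        rng = np.random.default_rng(6)
        z = -rng.uniform(0.002, 0.01, 200)
        z[:6] = 0.002  # 3% slightly above
        pts = np.column_stack([np.zeros((200, 2)), z])
        ok, _ = validate_concavity(pts, z0=0.0, height_tol=1e-3, frac_tol=0.05)
        assert ok


class TestMeasureWound:
    def test_cap_measurements_near_analytic(self, cap_wound):
        mesh, gt = cap_wound
        m = measure_wound(mesh, gt.region(mesh))
        assert m.depth_cm == pytest.approx(gt.depth * 100, rel=0.02)
        assert m.area_cm2 == pytest.approx(gt.area * 1e4, rel=0.02)
        assert m.volume_cm3 == pytest.approx(gt.volume * 1e6, rel=0.02)
        assert m.major_axis_cm == pytest.approx(gt.major_axis * 100, rel=0.02)
        assert m.volume_valid

    def test_flat_disk_limits(self):
        mesh, gt = make_wound(SyntheticWoundSpec(shape="flat_disk", resolution=20))
        m = measure_wound(mesh, gt.region(mesh))
        assert m.depth_cm == pytest.approx(0.0, abs=1e-9)
        assert m.volume_cm3 == pytest.approx(0.0, abs=1e-6)
        assert m.area_cm2 == pytest.approx(np.pi * (gt.major_axis / 2 * 100) ** 2, rel=0.01)

    def test_convex_bump_flagged_invalid_but_reported(self):
        mesh, gt = make_wound(SyntheticWoundSpec(shape="convex_bump", resolution=20))
        m = measure_wound(mesh, gt.region(mesh))
        assert not m.volume_valid
        assert m.depth_cm > 0 and m.area_cm2 > 0
        assert any("concave" in w for w in m.warnings)
        assert m.to_dict()["volume"]["value"] is None

    def test_scale_equivariance(self):
        mesh, gt = make_wound(SyntheticWoundSpec(resolution=16))
        region = gt.region(mesh)
        base = measure_wound(mesh, region)
        s = 2.5
        scaled = measure_wound(TriangleMesh(mesh.vertices * s, mesh.faces), region)
        assert scaled.depth_cm == pytest.approx(s * base.depth_cm, rel=1e-6)
        assert scaled.major_axis_cm == pytest.approx(s * base.major_axis_cm, rel=1e-6)
        assert scaled.minor_axis_cm == pytest.approx(s * base.minor_axis_cm, rel=1e-6)
        assert scaled.area_cm2 == pytest.approx(s**2 * base.area_cm2, rel=1e-6)
        assert scaled.volume_cm3 == pytest.approx(s**3 * base.volume_cm3, rel=1e-6)

    def test_report_dict_has_units_and_plane(self, cap_wound):
        mesh, gt = cap_wound
        d = measure_wound(mesh, gt.region(mesh)).to_dict()
        assert d["depth"]["unit"] == "cm"
        assert d["volume"]["unit"] == "cm^3"
        assert d["rim_plane"]["inlier_count"] >= 3
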