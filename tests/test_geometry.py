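"""Contour morphometry: areas, centroids, densification and stack metrics."""

import numpy as np
import pytest
from shapely.geometry import Polygon as ShapelyPolygon

from tendonmetrics.geometry import (
    Contour,
    ContourStack,
    ContourError,
    compute_metrics,
    densify_stack,
    polygon_area_centroid,
    read_contours_csv,
    read_contours_json,
    write_contours_csv,
    write_contours_json,
)
from tendonmetrics.synthetic import apply_pose, random_rigid_pose

from conftest import circle_contour, cylinder_stack


class TestPolygonAreaCentroid:
    def test_unit_square_offset_plane(self):
        sq = Contour(
            vertices=np.array(
                [[0, 0, 5], [1, 0, 5], [1, 1, 5], [0, 1, 5]], dtype=float
            ),
            slice_index=0,
        )
        area, centroid = polygon_area_centroid(sq)
        assert area == pytest.approx(1.0, abs=1e-12)
        assert centroid == pytest.approx([0.5, 0.5, 5.0], abs=1e-12)

    def test_winding_direction_irrelevant(self):
        verts = np.array([[0, 0, 5], [1, 0, 5], [1, 1, 5], [0, 1, 5]], dtype=float)
        fwd = polygon_area_centroid(Contour(vertices=verts, slice_index=0))
        rev = polygon_area_centroid(Contour(vertices=verts[::-1], slice_index=0))
        assert fwd[0] == pytest.approx(rev[0], abs=1e-12)
        np.testing.assert_allclose(fwd[1], rev[1], atol=1e-12)

    def test_64gon_against_monte_carlo_oracle(self, rng):
        """Area of a regular 64-gon (r = 3 mm): shoelace vs a 10^6-point
        Monte-Carlo point-in-polygon integration, and within 0.5% of the
        circle area it approximates."""
        from shapely import contains_xy

        contour = circle_contour(3.0, 0.0, 0, n=64)
        area, _ = polygon_area_centroid(contour)
        poly = ShapelyPolygon(contour.vertices[:, :2])
        pts = rng.uniform(-3.2, 3.2, size=(1_000_000, 2))
        mc_area = contains_xy(poly, pts[:, 0], pts[:, 1]).mean() * 6.4**2
        assert area == pytest.approx(mc_area, rel=5e-3)
        assert area == pytest.approx(np.pi * 9.0, rel=5e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_shapely_on_star_polygons(self, seed):
        """Random star-shaped polygons in a rotated plane: area and centroid
        agree with shapely computed in the original 2D frame."""
        rng = np.random.default_rng(seed)
        theta = np.sort(rng.uniform(0, 2 * np.pi, 24))
        radii = rng.uniform(2.0, 5.0, 24)
        xy = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
        ref = ShapelyPolygon(xy)
        verts3d = np.column_stack([xy, np.zeros(24)])
        pose = random_rigid_pose(seed + 100)
        contour = Contour(vertices=apply_pose(verts3d, pose), slice_index=0)
        area, centroid = polygon_area_centroid(contour)
        assert area == pytest.approx(ref.area, rel=1e-9)
        expected_centroid = apply_pose(
            np.array([[ref.centroid.x, ref.centroid.y, 0.0]]), pose
        )[0]
        np.testing.assert_allclose(centroid, expected_centroid, atol=1e-9)

    def test_degenerate_polygon_names_slice(self):
        line = Contour(
            vertices=np.array(
                [[0, 0, 0], [1, 0, 0], [2, 0, 0], [1.0, 1e-10, 0]], dtype=float
            ),
            slice_index=7,
        )
        with pytest.raises(ContourError, match="slice 7"):
            polygon_area_centroid(line)


class TestContourValidation:
    def test_too_few_vertices(self):
        with pytest.raises(ContourError, match=">= 3"):
            Contour(vertices=np.array([[0, 0, 0], [1, 0, 0]], float), slice_index=0)

    def test_non_coplanar_rejected(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0.1], [0, 1, 0]], dtype=float
        )
        with pytest.raises(ContourError, match="plane"):
            Contour(vertices=verts, slice_index=0)

    def test_self_intersecting_rejected(self):
        bowtie = np.array(
            [[0, 0, 0], [1, 1, 0], [1, 0, 0], [0, 1, 0]], dtype=float
        )
        with pytest.raises(ContourError, match="self-intersecting"):
            Contour(vertices=bowtie, slice_index=0)

    def test_non_monotone_stack_rejected(self):
        c0 = circle_contour(3.0, 0.0, 1)
        c1 = circle_contour(3.0, 5.0, 0)
        with pytest.raises(ContourError, match="strictly increase"):
            ContourStack(contours=[c0, c1])


class TestDensify:
    def test_constant_cross_section(self):
        stack = ContourStack(
            contours=[circle_contour(3.0, 0.0, 0), circle_contour(3.0, 10.0, 1)]
        )
        dense = densify_stack(stack, 1.0)
        assert len(dense) == 11
        areas = dense.areas()
        np.testing.assert_allclose(areas, areas[0], rtol=1e-12)
        assert dense.provenance == "dense"
        assert dense.slice_spacing == pytest.approx(1.0)

    def test_linear_taper_midpoint_radius(self):
        stack = ContourStack(
            contours=[circle_contour(2.0, 0.0, 0), circle_contour(4.0, 10.0, 1)]
        )
        dense = densify_stack(stack, 5.0)
        mid = dense.contours[1]
        radii = np.linalg.norm(
            mid.vertices - mid.vertices.mean(axis=0), axis=1
        )
        assert radii.mean() == pytest.approx(3.0, abs=1e-6)

    def test_original_contours_reproduced_at_stations(self):
        stack = cylinder_stack(3.0, 10.0, 3)
        dense = densify_stack(stack, 1.0)
        # stations at 0 and 10 mm coincide with sparse slices: areas match
        # the resampled originals exactly
        assert dense.areas()[0] == pytest.approx(stack.areas()[0], rel=1e-9)
        assert dense.areas()[-1] == pytest.approx(stack.areas()[-1], rel=1e-9)

    def test_frustum_volume_against_analytic_oracle(self):
        r0, r1, h = 4.0, 2.0, 40.0
        stack = ContourStack(
            contours=[circle_contour(r0, 0.0, 0), circle_contour(r1, h, 1)]
        )
        metrics = compute_metrics(densify_stack(stack, 0.27))
        analytic = np.pi * h / 3.0 * (r0**2 + r0 * r1 + r1**2)
        assert metrics.volume == pytest.approx(analytic, rel=5e-3)

    def test_refinement_converges(self):
        stack = ContourStack(
            contours=[circle_contour(4.0, 0.0, 0), circle_contour(2.0, 40.0, 1)]
        )
        v_coarse = compute_metrics(densify_stack(stack, 0.54)).volume
        v_fine = compute_metrics(densify_stack(stack, 0.27)).volume
        assert abs(v_fine - v_coarse) / v_fine < 1e-3

    def test_needs_two_contours(self):
        stack = ContourStack(contours=[circle_contour(3.0, 0.0, 0)])
        with pytest.raises(ContourError, match=">= 2"):
            densify_stack(stack, 1.0)


class TestMetrics:
    def test_straight_cylinder_closed_form(self):
        dense = densify_stack(cylinder_stack(3.0, 40.0, 7), 0.27)
        m = compute_metrics(dense)
        assert m.volume == pytest.approx(360.0 * np.pi, rel=2e-3)
        assert m.length == pytest.approx(40.0, abs=0.01)
        assert m.average_csa == pytest.approx(9.0 * np.pi, rel=2e-3)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_rigid_motion_invariance(self, seed):
        stack = cylinder_stack(3.0, 40.0, 7)
        base = compute_metrics(densify_stack(stack, 0.27))
        pose = random_rigid_pose(seed)
        moved = ContourStack(
            contours=[
                type(c)(vertices=apply_pose(c.vertices, pose), slice_index=c.slice_index)
                for c in stack.contours
            ]
        )
        m = compute_metrics(densify_stack(moved, 0.27))
        assert m.volume == pytest.approx(base.volume, rel=1e-6)
        assert m.length == pytest.approx(base.length, rel=1e-6)
        np.testing.assert_allclose(
            m.csa_profile.csa, base.csa_profile.csa, rtol=1e-6
        )

    def test_average_csa_consistency(self):
        m = compute_metrics(densify_stack(cylinder_stack(3.0, 40.0, 5), 0.5))
        assert m.average_csa * m.length == pytest.approx(m.volume, rel=1e-12)

    def test_curved_centroid_path_length(self):
        """Centroid path on a circular arc (R = 100 mm, arc length 40 mm):
        the centroid-chain length approximates the analytic arc length."""
        from tendonmetrics.synthetic import TendonPhantomSpec, make_tendon_phantom

        spec = TendonPhantomSpec(
            length=40.0,
            distal_radius=3.0,
            proximal_radius=3.0,
            ellipticity=1.0,
            centroid_path=("arc", 100.0),
            n_sparse_slices=8,
            n_vertices=96,
        )
        sparse, _ = make_tendon_phantom(spec)
        m = compute_metrics(densify_stack(sparse, 0.27))
        assert m.length == pytest.approx(40.0, rel=1e-3)

    def test_profile_endpoints_and_affine_taper(self):
        """A stack whose slice areas vary affinely along the length yields a
        CSA profile affine in percent length, with endpoint areas matching
        the end slices."""
        h = 50.0
        zs = np.linspace(0.0, h, 8)
        a0, a1 = 80.0, 50.0  # mm^2, tendon-scale mild taper
        radii = np.sqrt((a0 + (a1 - a0) * zs / h) / np.pi)
        stack = ContourStack(
            contours=[circle_contour(r, z, i) for i, (r, z) in enumerate(zip(radii, zs))]
        )
        m = compute_metrics(densify_stack(stack, 0.27))
        prof = m.csa_profile.csa
        areas = stack.areas()
        assert prof[0] == pytest.approx(areas[0], rel=1e-3)
        assert prof[-1] == pytest.approx(areas[-1], rel=1e-3)
        affine = np.linspace(prof[0], prof[-1], 101)
        assert np.max(np.abs(prof - affine) / affine) < 5e-3

    def test_metrics_need_two_slices(self):
        stack = ContourStack(contours=[circle_contour(3.0, 0.0, 0)])
        with pytest.raises(ContourError):
            compute_metrics(stack)


class TestInterchange:
    def test_csv_round_trip_bit_exact(self, tmp_path, rng):
        stack = cylinder_stack(3.123456789, 17.5, 4, n_vertices=16)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_contours_csv(stack, p1)
        again = read_contours_csv(p1)
        write_contours_csv(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        for c0, c1 in zip(stack.contours, again.contours):
            np.testing.assert_array_equal(c0.vertices, c1.vertices)

    def test_json_round_trip(self, tmp_path):
        stack = cylinder_stack(2.5, 12.0, 3, n_vertices=12)
        path = tmp_path / "stack.json"
        write_contours_json(stack, path)
        again = read_contours_json(path)
        for c0, c1 in zip(stack.contours, again.contours):
            np.testing.assert_array_equal(c0.vertices, c1.vertices)
        assert again.provenance == "sparse"

    def test_csv_missing_columns(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b\n1,2\n")
        with pytest.raises(ContourError, match="columns"):
            read_contours_csv(bad)
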