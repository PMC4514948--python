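"""Plane fitting, contour slicing, tubercle corners, landmarks and the
3-D / 2-D axial measurements, checked against closed forms, generator truth
and dense brute-force landmark searches."""

import numpy as np
import pytest
import trimesh

import syndesmo3d as s3
from syndesmo3d import geometry as geo
from syndesmo3d import segmentation as seg

from conftest import random_rotation


def _rotate_surfaces(surfaces, rot, shift):
    out = {}
    for name, surf in surfaces.items():
        mesh = surf.mesh.copy()
        mesh.vertices = mesh.vertices @ rot.T + shift
        out[name] = seg.BoneSurface(mesh, label=name)
    return out


class TestPlafondPlane:
    def test_flat_phantom_normal_is_proximal_axis(self, male_mesh):
        surfaces, truth = male_mesh
        plane = geo.fit_plafond_plane(surfaces["tibia"],
                                      truth.articular_seed)
        assert abs(plane.normal @ np.array([0, 0, 1.0])) > 1 - 1e-6
        assert plane.normal[2] > 0  # oriented proximally
        assert abs(plane.signed_distance(truth.plane_x[0])[0]) < 1e-9

    def test_tilted_phantom_normal_recovered(self):
        spec = s3.make_preset_spec("male", seed=4,
                                   plafond_tilt_deg=(5.0, 3.0))
        surfaces, _, truth = s3.generate_phantom(spec, with_volume=False)
        plane = geo.fit_plafond_plane(surfaces["tibia"],
                                      truth.articular_seed)
        cosang = abs(plane.normal @ truth.plane_x[1])
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 0.5

    def test_voxel_path_plane_close_to_truth(self, male_voxel):
        _, volume, truth = male_voxel
        labeled = seg.segment_volume(volume, truth.seeds)
        tibia = next(s for s in labeled if s.label == "tibia")
        plane = geo.fit_plafond_plane(tibia, truth.articular_seed)
        offset = abs((plane.point - truth.plane_x[0]) @ truth.plane_x[1])
        assert offset < 0.5 * max(volume.spacing)

    def test_far_seed_rejected(self, male_mesh):
        surfaces, _ = male_mesh
        with pytest.raises(geo.GeometryError, match="seed"):
            geo.fit_plafond_plane(surfaces["tibia"],
                                  np.array([0.0, 0.0, -40.0]))


class TestSliceContours:
    def test_sphere_section_is_great_circle(self):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
        surf = seg.BoneSurface(mesh, label="sphere")
        plane = geo.AnatomicPlane(np.zeros(3), np.array([0, 0, 1.0]))
        contours = geo.slice_contours([surf], plane)
        assert len(contours) == 1
        radii = np.linalg.norm(contours[0].points, axis=1)
        assert np.allclose(radii, 10.0, rtol=0.01)

    def test_tangent_plane_graze_filtered(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        surf = seg.BoneSurface(mesh, label="sphere")
        plane = geo.AnatomicPlane(np.array([0, 0, 4.999]),
                                  np.array([0, 0, 1.0]))
        contours = geo.slice_contours([surf], plane)  # area < 1 mm^2
        assert contours == []

    def test_plane_missing_everything_returns_empty(self, male_mesh):
        surfaces, _ = male_mesh
        plane = geo.AnatomicPlane(np.array([0, 0, 500.0]),
                                  np.array([0, 0, 1.0]))
        assert geo.slice_contours(surfaces, plane) == []

    def test_phantom_plane_y_contours(self, male_mesh):
        surfaces, truth = male_mesh
        plane = geo.AnatomicPlane(*truth.plane_y)
        contours = geo.slice_contours(surfaces, plane, truth.frame)
        labels = sorted(c.label for c in contours)
        assert labels == ["fibula", "tibia"]
        tibia_c = next(c for c in contours if c.label == "tibia")
        fib_c = next(c for c in contours if c.label == "fibula")
        # fibula section of a circular shaft: convex circle of radius 6
        center = fib_c.points.mean(axis=0)
        assert np.allclose(np.linalg.norm(fib_c.points - center, axis=1),
                           6.0, atol=0.01)
        # tibia has the concave incisura notch
        inc = geo._find_incisura(tibia_c)
        assert inc is not None
        assert inc.depth == pytest.approx(
            truth.spec.ifd_true_mm, abs=0.01)


class TestTubercleCorner:
    def _rect_with_notch(self):
        # rectangle [0,20]x[0,10] with a rectangular notch cut into the
        # right (lateral) edge between y=3 and y=7, 4 mm deep
        pts = np.array([
            [0, 0], [20, 0], [20, 3], [16, 3], [16, 7], [20, 7],
            [20, 10], [0, 10]], dtype=float)
        frame = geo.PlaneFrame(np.zeros(3), np.array([1.0, 0, 0]),
                               np.array([0, 1.0, 0]))
        return geo.Contour(pts, frame)

    def test_rectangular_notch_corner_is_exact_vertex(self):
        contour = self._rect_with_notch()
        ant = geo.tubercle_corner(contour, "anterior")
        post = geo.tubercle_corner(contour, "posterior")
        assert np.allclose(ant, [20, 7])
        assert np.allclose(post, [20, 3])

    def test_phantom_anterior_corner_matches_truth_point_A(self, male_mesh):
        surfaces, truth = male_mesh
        plane = geo.AnatomicPlane(*truth.plane_y)
        contours = geo.slice_contours(surfaces, plane, truth.frame)
        tibia_c = next(c for c in contours if c.label == "tibia")
        corner = geo.tubercle_corner(tibia_c, "anterior")
        a_2d = tibia_c.frame.to_2d(truth.points["A"])[0]
        assert np.linalg.norm(corner - a_2d) < 0.3

    def test_mirrored_contour_swaps_nothing_but_x(self):
        contour = self._rect_with_notch()
        mirrored = geo.Contour(contour.points * np.array([-1.0, 1.0]),
                               contour.frame)
        ant = geo.tubercle_corner(contour, "anterior")
        ant_m = geo.tubercle_corner(mirrored, "anterior")
        assert np.allclose(ant_m, ant * np.array([-1.0, 1.0]))

    def test_no_concavity_raises(self):
        frame = geo.PlaneFrame(np.zeros(3), np.array([1.0, 0, 0]),
                               np.array([0, 1.0, 0]))
        square = geo.Contour(np.array([[0, 0], [10, 0], [10, 10], [0, 10.0]]),
                             frame)
        with pytest.raises(geo.GeometryError, match="incisura"):
            geo.tubercle_corner(square, "anterior")


class TestPointAandPlaneY:
    def test_male_level_matches_reference_plane_height(self, male_mesh):
        surfaces, truth = male_mesh
        plane_x = geo.fit_plafond_plane(surfaces["tibia"],
                                        truth.articular_seed)
        point_a, z_star = geo.locate_point_A(surfaces["tibia"], plane_x,
                                             truth.frame)
        assert z_star == pytest.approx(12.1, abs=0.625)

    def test_female_level_matches_reference_plane_height(self, female_mesh):
        surfaces, truth = female_mesh
        plane_x = geo.fit_plafond_plane(surfaces["tibia"],
                                        truth.articular_seed)
        _, z_star = geo.locate_point_A(surfaces["tibia"], plane_x,
                                       truth.frame)
        assert z_star == pytest.approx(7.8, abs=0.625)

    def test_fine_scan_agrees_with_default_step(self, male_mesh):
        """Brute force at 0.1 mm steps finds the same maximizing level to
        within one default step."""
        surfaces, truth = male_mesh
        plane_x = geo.fit_plafond_plane(surfaces["tibia"],
                                        truth.articular_seed)
        _, z_default = geo.locate_point_A(surfaces["tibia"], plane_x,
                                          truth.frame, step_mm=0.625)
        _, z_fine = geo.locate_point_A(surfaces["tibia"], plane_x,
                                       truth.frame, step_mm=0.1)
        assert abs(z_default - z_fine) <= 0.625

    def test_plane_y_through_A_and_xy_invariance(self, male_mesh, rng):
        surfaces, truth = male_mesh
        plane_x = geo.AnatomicPlane(*truth.plane_x)
        a = truth.points["A"]
        plane_y, xy = geo.build_plane_Y(plane_x, a)
        assert xy == pytest.approx(truth.spec.xy_true_mm, abs=1e-9)
        assert np.allclose(plane_y.normal, plane_x.normal)
        # rigid motion leaves XY unchanged
        rot = random_rotation(rng)
        shift = rng.normal(scale=40.0, size=3)
        plane_x_r = geo.AnatomicPlane(rot @ plane_x.point + shift,
                                      rot @ plane_x.normal)
        _, xy_r = geo.build_plane_Y(plane_x_r, rot @ a + shift)
        assert xy_r == pytest.approx(xy, abs=1e-9)

    def test_point_A_on_plane_x_gives_zero_xy(self):
        plane_x = geo.AnatomicPlane(np.zeros(3), np.array([0, 0, 1.0]))
        _, xy = geo.build_plane_Y(plane_x, np.array([3.0, 4.0, 0.0]))
        assert xy == 0.0

    def test_point_A_below_plane_x_raises(self):
        plane_x = geo.AnatomicPlane(np.zeros(3), np.array([0, 0, 1.0]))
        with pytest.raises(geo.GeometryError):
            geo.build_plane_Y(plane_x, np.array([0.0, 0.0, -1.0]))


class TestLandmarks:
    def _plane_y_contours(self, surfaces, truth):
        plane = geo.AnatomicPlane(*truth.plane_y)
        contours = geo.slice_contours(surfaces, plane, truth.frame)
        tibia_c = next(c for c in contours if c.label == "tibia")
        fib_c = next(c for c in contours if c.label == "fibula")
        return tibia_c, fib_c

    def test_nearest_point_to_circle_lies_on_center_ray(self):
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        center = np.array([10.0, -2.0])
        circle = center + 4.0 * np.column_stack([np.cos(theta),
                                                 np.sin(theta)])
        a = np.array([1.0, 3.0])
        b, dist = geo._nearest_on_polyline(a, circle)
        direction = (b - a) / np.linalg.norm(b - a)
        to_center = (center - a) / np.linalg.norm(center - a)
        # a 256-gon approximates the circle to ~r*(pi/256)^2
        assert np.allclose(direction, to_center, atol=2e-2)
        assert dist == pytest.approx(np.linalg.norm(center - a) - 4.0,
                                     abs=1e-3)

    def test_male_gaps_match_reference_means(self, male_mesh):
        surfaces, truth = male_mesh
        tibia_c, fib_c = self._plane_y_contours(surfaces, truth)
        lm = geo.locate_landmarks(tibia_c, fib_c, truth.points["A"])
        assert np.linalg.norm(lm.A - lm.B) == pytest.approx(2.8, abs=0.3)
        assert np.linalg.norm(lm.C - lm.D) == pytest.approx(3.6, abs=0.3)

    def test_landmarks_match_dense_brute_force(self, male_mesh):
        """B, D, E from the implementation match an exhaustive search over
        the contours resampled at 0.01 mm within 0.05 mm."""
        surfaces, truth = male_mesh
        tibia_c, fib_c = self._plane_y_contours(surfaces, truth)
        lm = geo.locate_landmarks(tibia_c, fib_c, truth.points["A"])

        def densify(pts, step=0.01):
            out = []
            for i in range(len(pts)):
                a, b = pts[i], pts[(i + 1) % len(pts)]
                n = max(1, int(np.ceil(np.linalg.norm(b - a) / step)))
                t = np.arange(n) / n
                out.append(a + t[:, None] * (b - a))
            return np.vstack(out)

        dense_fib = densify(fib_c.points)
        chart = tibia_c.frame
        a2 = chart.to_2d(lm.A)[0]
        c2 = chart.to_2d(lm.C)[0]
        b_brute = dense_fib[np.argmin(np.linalg.norm(dense_fib - a2,
                                                     axis=1))]
        d_brute = dense_fib[np.argmin(np.linalg.norm(dense_fib - c2,
                                                     axis=1))]
        assert np.linalg.norm(chart.to_2d(lm.B)[0] - b_brute) < 0.05
        assert np.linalg.norm(chart.to_2d(lm.D)[0] - d_brute) < 0.05
        inc = geo._find_incisura(tibia_c)
        dense_arc = densify(tibia_c.points[inc.arc], 0.01)
        ac = (c2 - a2) / np.linalg.norm(c2 - a2)
        dev = ac[0] * (dense_arc - a2)[:, 1] - ac[1] * (dense_arc - a2)[:, 0]
        side = 1.0 if np.max(dev) >= -np.min(dev) else -1.0  # medial side
        e_brute = dense_arc[np.argmax(side * dev)]
        assert np.linalg.norm(chart.to_2d(lm.E)[0] - e_brute) < 0.05

    def test_missing_fibula_raises(self, male_mesh):
        surfaces, truth = male_mesh
        tibia_c, _ = self._plane_y_contours(surfaces, truth)
        with pytest.raises(geo.GeometryError, match="fibula"):
            geo.locate_landmarks(tibia_c, None, truth.points["A"])


class TestMeasure3D:
    def test_collinear_landmarks_give_zero_ifd(self):
        lm = geo.LandmarkSet(
            A=np.array([0.0, 0, 0]), B=np.array([1.0, 0, 0]),
            C=np.array([2.0, 0, 0]), D=np.array([3.0, 0, 0]),
            E=np.array([1.5, 0, 0]))
        plane = geo.AnatomicPlane(np.zeros(3), np.array([0, 0, 1.0]))
        rec = geo.measure_3d(lm, plane, plane)
        assert rec.ifd == 0.0

    def test_male_mesh_path_recovers_truth(self, male_measured, male_mesh):
        record, _, _, _ = male_measured
        _, truth = male_mesh
        t = truth.params["3-D"]
        assert record.xy == pytest.approx(t["XY"], abs=0.3)
        assert record.tcs_a == pytest.approx(t["TCS_A"], abs=0.3)
        assert record.tcs_p == pytest.approx(t["TCS_P"], abs=0.3)
        assert record.ifd == pytest.approx(t["IFD"], abs=0.3)

    def test_record_rejects_negative_values(self):
        with pytest.raises(ValueError):
            geo.MeasurementRecord(modality="3-D", tcs_a=-0.5)


class TestPointF:
    def test_male_incisura_height(self, male_mesh):
        surfaces, truth = male_mesh
        plane_x = geo.AnatomicPlane(*truth.plane_x)
        plane_y = geo.AnatomicPlane(*truth.plane_y)
        f, height = geo.locate_point_F(surfaces["tibia"], plane_x, plane_y,
                                       truth.frame)
        assert height == pytest.approx(35.1, abs=1.0)

    def test_female_incisura_height(self, female_mesh):
        surfaces, truth = female_mesh
        plane_x = geo.AnatomicPlane(*truth.plane_x)
        plane_y = geo.AnatomicPlane(*truth.plane_y)
        _, height = geo.locate_point_F(surfaces["tibia"], plane_x, plane_y,
                                       truth.frame)
        assert height == pytest.approx(33.7, abs=1.0)

    def test_height_error_scales_with_section_step(self, male_mesh):
        surfaces, truth = male_mesh
        plane_x = geo.AnatomicPlane(*truth.plane_x)
        plane_y = geo.AnatomicPlane(*truth.plane_y)
        errs = {}
        for step in (0.25, 0.5, 1.0):
            _, h = geo.locate_point_F(surfaces["tibia"], plane_x, plane_y,
                                      truth.frame, step_mm=step)
            errs[step] = abs(h - truth.spec.ifh_true_mm)
        # worst-case bound is one step; doubling the step doubles it
        for step, err in errs.items():
            assert err <= step + 1e-9


class TestAxial2D:
    def test_male_2d_matches_reference_means(self, male_voxel):
        _, volume, truth = male_voxel
        plane_y = geo.AnatomicPlane(*truth.plane_y)
        rec = geo.measure_axial_2d(volume, plane_y, truth.seeds,
                                   truth.frame)
        vox = 2 * max(volume.spacing)
        assert rec.tcs_a == pytest.approx(2.8, abs=vox)
        assert rec.tcs_p == pytest.approx(3.6, abs=vox)
        assert rec.ifd == pytest.approx(5.1, abs=vox)

    def test_2d_agrees_with_3d_on_zero_noise_phantom(self, male_voxel):
        surfaces, volume, truth = male_voxel
        rec3, _, _, plane_y = s3.measure_surfaces(
            surfaces, truth.articular_seed, frame=truth.frame)
        rec2 = geo.measure_axial_2d(volume, plane_y, truth.seeds,
                                    truth.frame)
        for name in ("tcs_a", "tcs_p", "ifd"):
            assert abs(getattr(rec3, name)
                       - getattr(rec2, name)) < max(volume.spacing)

    def test_section_at_slice_center_equals_axial_slice(self):
        rng = np.random.default_rng(3)
        values = rng.normal(200, 50, (12, 13, 14))
        vol = seg.VoxelVolume(values, (0.625,) * 3, (0.0, 0.0, 0.0))
        k = 6
        plane = geo.AnatomicPlane(np.array([0, 0, k * 0.625]),
                                  np.array([0, 0, 1.0]))
        image, chart, px = geo.resample_plane(vol, plane)
        # the voxel-center samples of the oblique section reproduce the
        # axial slice exactly
        uv = chart.to_2d(np.array([0.0, 0.0, k * 0.625]))[0]
        i0 = int(round(-uv[0] / px)) if uv[0] <= 0 else 0
        i0 = int(round((0.0 - (chart.origin @ chart.u)) / px))
        j0 = int(round((0.0 - (chart.origin @ chart.v)) / px))
        sub = image[i0:i0 + 12, j0:j0 + 13]
        assert np.allclose(sub, values[:, :, k], atol=1e-9)

    def test_plane_outside_volume_raises(self, male_voxel):
        _, volume, truth = male_voxel
        plane = geo.AnatomicPlane(np.array([0, 0, 500.0]),
                                  np.array([0, 0, 1.0]))
        with pytest.raises(geo.GeometryError, match="outside"):
            geo.measure_axial_2d(volume, plane, truth.seeds, truth.frame)


class TestInvariances:
    def test_rigid_motion_invariance_mesh_path(self, male_mesh, rng):
        surfaces, truth = male_mesh
        base, _, _, _ = s3.measure_surfaces(surfaces, truth.articular_seed,
                                            frame=truth.frame)
        rot = random_rotation(rng)
        shift = rng.normal(scale=30.0, size=3)
        moved = _rotate_surfaces(surfaces, rot, shift)
        rec, _, _, _ = s3.measure_surfaces(
            moved, rot @ truth.articular_seed + shift,
            frame=rot @ truth.frame)
        for name in ("xy", "tcs_a", "tcs_p", "ifd", "ifh"):
            assert getattr(rec, name) == pytest.approx(
                getattr(base, name), abs=1e-6), name

    def test_scale_equivariance(self, male_mesh):
        """Scaling the geometry by s scales every parameter by s (the
        detection thresholds and search grid scale along)."""
        surfaces, truth = male_mesh
        s = 1.15
        scaled = {}
        for name, surf in surfaces.items():
            mesh = surf.mesh.copy()
            mesh.vertices = mesh.vertices * s
            scaled[name] = seg.BoneSurface(mesh, label=name)
        plane_x = geo.fit_plafond_plane(scaled["tibia"],
                                        truth.articular_seed * s)
        a, _ = geo.locate_point_A(scaled["tibia"], plane_x, truth.frame,
                                  window_mm=(4.0 * s, 20.0 * s),
                                  step_mm=0.625 * s)
        plane_y, xy = geo.build_plane_Y(plane_x, a)
        contours = geo.slice_contours(list(scaled.values()), plane_y,
                                      truth.frame)
        tibia_c = next(c for c in contours if c.label == "tibia")
        fib_c = next(c for c in contours if c.label == "fibula")
        lm = geo.locate_landmarks(tibia_c, fib_c, a)
        rec = geo.measure_3d(lm, plane_x, plane_y)
        base, _, _, _ = s3.measure_surfaces(surfaces, truth.articular_seed,
                                            frame=truth.frame)
        assert rec.xy == pytest.approx(base.xy * s, abs=1e-6)
        assert rec.tcs_a == pytest.approx(base.tcs_a * s, abs=1e-6)
        assert rec.tcs_p == pytest.approx(base.tcs_p * s, abs=1e-6)
        assert rec.ifd == pytest.approx(base.ifd * s, abs=1e-6)
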