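"""Straightened-ROI geometry: spline, arc-length sampling, frames, resampling."""

import numpy as np
import pytest

from tavrisk.roi import (LandmarkSet, ROIConfig, ROIVolume, VolumeGrid,
                         extract_roi, fit_centerline, resample_slice,
                         sample_centerline, slice_frame)
from tavrisk.synthetic import render_phantom_volume


def line_landmarks():
    t = np.linspace(0, 1, 5)
    return LandmarkSet(np.stack([10 + 40 * t, 20 + 10 * t, 5 + 50 * t], axis=1))


class TestCenterline:
    def test_interpolation_passes_through_landmarks(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.uniform(2, 8, (5, 3)), axis=0) + 10
        lms = LandmarkSet(pts)
        curve = fit_centerline(lms, smoothing=0.0)
        assert curve.max_landmark_deviation() < 1e-6

    def test_collinear_points_give_straight_segment(self):
        curve = fit_centerline(line_landmarks(), smoothing=0.0)
        u = np.linspace(0, 1, 100)
        pts = curve.point(u)
        d = pts - pts[0]
        direction = d[-1] / np.linalg.norm(d[-1])
        cross = np.linalg.norm(np.cross(d[1:], direction), axis=1)
        assert cross.max() < 1e-8

    def test_default_smoothing_respects_deviation_budget(self):
        rng = np.random.default_rng(1)
        pts = np.stack([np.linspace(5, 55, 5),
                        30 + rng.normal(0, 2, 5),
                        np.linspace(10, 50, 5)], axis=1)
        curve = fit_centerline(LandmarkSet(pts))
        assert curve.max_landmark_deviation() <= 2.0

    def test_circular_arc_matches_analytic_geometry(self):
        """Interpolating points on a circle stays close to the true arc."""
        ang = np.linspace(0, np.pi / 2, 5)
        R = 30.0
        pts = np.stack([R * np.cos(ang), R * np.sin(ang), np.zeros(5)], axis=1)
        curve = fit_centerline(LandmarkSet(pts), smoothing=0.0)
        u = np.linspace(0, 1, 200)
        radii = np.linalg.norm(curve.point(u)[:, :2], axis=1)
        assert np.max(np.abs(radii - R)) < 0.05

    def test_duplicate_landmarks_rejected(self):
        pts = line_landmarks().points.copy()
        with pytest.raises(ValueError, match="distinct"):
            LandmarkSet(np.vstack([pts[:4], pts[3]]))


class TestSampleCenterline:
    def test_straight_segment_spacing(self):
        pts = np.stack([np.full(5, 30.0), np.full(5, 30.0),
                        np.linspace(0, 63, 5)], axis=1)
        curve = fit_centerline(LandmarkSet(pts), smoothing=0.0)
        centers, tangents = sample_centerline(curve, 64)
        gaps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        np.testing.assert_allclose(gaps, 1.0, atol=1e-6)
        np.testing.assert_allclose(
            tangents, np.broadcast_to(tangents[0], tangents.shape), atol=1e-9)

    def test_arclength_uniform_on_helix(self):
        t = np.linspace(0, 1, 5)
        pts = np.stack([20 * np.cos(3 * t) + 32, 20 * np.sin(3 * t) + 32,
                        10 + 45 * t], axis=1)
        curve = fit_centerline(LandmarkSet(pts), smoothing=0.0)
        centers, _ = sample_centerline(curve, 64)
        gaps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        # uniform to 0.1% against the dense-polyline arc length
        assert gaps.std() / gaps.mean() < 1e-3

    def test_too_few_samples_rejected(self):
        curve = fit_centerline(line_landmarks(), smoothing=0.0)
        with pytest.raises(ValueError):
            sample_centerline(curve, 1)


class TestSliceFrame:
    def test_perpendicular_sagittal_projects_to_itself(self):
        u, v = slice_frame(np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(u, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(v, [0, 1, 0], atol=1e-12)

    def test_orthonormal_right_handed(self):
        rng = np.random.default_rng(2)
        s = np.array([1.0, 0.0, 0.0])
        for _ in range(50):
            t = rng.normal(size=3)
            t /= np.linalg.norm(t)
            if abs(t @ s) > 1 - 1e-3:
                continue
            u, v = slice_frame(t, s)
            for a, b in ((u, t), (v, t), (u, v)):
                assert abs(a @ b) < 1e-10
            np.testing.assert_allclose(np.cross(u, v), t, atol=1e-10)

    def test_45_degree_gram_schmidt(self):
        t = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        s = np.array([1.0, 0.0, 0.0])
        u, _ = slice_frame(t, s)
        expected = s - (s @ t) * t
        np.testing.assert_allclose(u, expected / np.linalg.norm(expected),
                                   atol=1e-12)

    def test_parallel_tangent_falls_back_to_axial(self, caplog):
        u, v = slice_frame(np.array([1.0, 0.0, 0.0]),
                           np.array([1.0, 0.0, 0.0]))
        assert abs(u @ np.array([1.0, 0.0, 0.0])) < 1e-10
        assert np.linalg.norm(np.cross(u, v) - np.array([1.0, 0.0, 0.0])) < 1e-10


class TestResampleSlice:
    def test_constant_volume_gives_constant_slice(self):
        vol = VolumeGrid.from_spacing(np.full((20, 20, 20), 77.0), (1, 1, 1))
        sl, n_out = resample_slice(vol, np.array([9.5, 9.5, 9.5]),
                                   (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),
                                   size=8, in_plane_spacing=1.0)
        np.testing.assert_allclose(sl, 77.0)
        assert n_out == 0

    def test_axial_identity_resampling(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(16, 16, 16))
        vol = VolumeGrid.from_spacing(data, (1, 1, 1))
        center = np.array([7.5, 7.5, 4.0])
        sl, _ = resample_slice(vol, center,
                               (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),
                               size=16, in_plane_spacing=1.0)
        np.testing.assert_allclose(sl, data[:, :, 4], atol=1e-12)

    def test_linear_ramp_matches_plane_equation(self):
        """I(x,y,z) = x is reproduced exactly by trilinear interpolation."""
        x = np.arange(24)
        data = np.broadcast_to(x[:, None, None], (24, 24, 24)).astype(float)
        vol = VolumeGrid.from_spacing(data, (1, 1, 1))
        rng = np.random.default_rng(4)
        t = rng.normal(size=3)
        t /= np.linalg.norm(t)
        u, v = slice_frame(t, np.array([1.0, 0.0, 0.0]))
        center = np.array([11.5, 11.5, 11.5])
        sl, n_out = resample_slice(vol, center, (u, v), size=8,
                                   in_plane_spacing=0.7)
        offs = (np.arange(8) - 3.5) * 0.7
        expected = (center[0] + offs[:, None] * u[0] + offs[None, :] * v[0])
        inside = np.ones_like(sl, bool)
        np.testing.assert_allclose(sl[inside], expected[inside], atol=1e-6)

    def test_out_of_volume_filled_with_air(self):
        vol = VolumeGrid.from_spacing(np.zeros((10, 10, 10)), (1, 1, 1))
        sl, n_out = resample_slice(vol, np.array([0.0, 0.0, 5.0]),
                                   (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),
                                   size=10, in_plane_spacing=2.0)
        assert n_out > 0
        assert sl.min() == -1000.0


class TestExtractROI:
    def test_output_shape_and_provenance(self):
        spec = {"kind": "straight", "start": (31.5, 31.5, 8.0),
                "end": (31.5, 31.5, 55.0)}
        vol, lms = render_phantom_volume(spec, tube_radius=6.0,
                                         shape=(64, 64, 64))
        roi = extract_roi(vol, lms)
        assert roi.intensities.shape == (64, 64, 64)
        assert "config_hash" in roi.provenance
        assert roi.slice_spacing_mm == pytest.approx(47.0 / 63, rel=1e-3)

    def test_landmarks_outside_volume_rejected(self):
        vol = VolumeGrid.from_spacing(np.zeros((32, 32, 32)), (1, 1, 1))
        lms = LandmarkSet(np.stack([np.linspace(5, 80, 5)] * 3, axis=1))
        with pytest.raises(ValueError, match="bounding box"):
            extract_roi(vol, lms)

    def test_straight_cylinder_straightens_to_centred_disks(self):
        spec = {"kind": "straight", "start": (31.5, 31.5, 8.0),
                "end": (31.5, 31.5, 55.0)}
        vol, lms = render_phantom_volume(spec, tube_radius=6.0,
                                         shape=(64, 64, 64))
        roi = extract_roi(vol, lms)
        for k in range(0, 64, 7):
            sl = roi.intensities[:, :, k]
            inside = sl > 100
            com = np.array(np.nonzero(inside)).mean(axis=1)
            np.testing.assert_allclose(com, [31.5, 31.5], atol=1.0)
            # radius constancy: area of the disk ~ pi r^2
            assert inside.sum() == pytest.approx(np.pi * 36, rel=0.15)

    def test_curved_tube_core_recovered(self):
        """On an arc phantom the straightened block keeps the bright core at
        the slice centers for at least 95% of slices."""
        arc = {"kind": "arc", "center": (32.0, 32.0, 10.0), "radius": 22.0,
               "angle": 1.2, "u": (1.0, 0.0, 0.0), "v": (0.0, 0.6, 0.8)}
        vol, lms = render_phantom_volume(arc, tube_radius=5.0,
                                         shape=(64, 64, 64))
        roi = extract_roi(vol, lms)
        core_hits = sum(
            roi.intensities[30:34, 30:34, k].mean() > 250 for k in range(64))
        assert core_hits >= 61  # >= 95% of 64 slices

    def test_nifti_round_trip_preserves_data_and_provenance(self, tmp_path):
        spec = {"kind": "straight", "start": (31.5, 31.5, 8.0),
                "end": (31.5, 31.5, 55.0)}
        vol, lms = render_phantom_volume(spec, tube_radius=6.0,
                                         shape=(64, 64, 64))
        roi = extract_roi(vol, lms)
        path = tmp_path / "roi.nii.gz"
        roi.to_nifti(path)
        back = ROIVolume.from_nifti(path)
        np.testing.assert_allclose(back.intensities, roi.intensities,
                                   atol=1e-2)
        assert back.provenance["config_hash"] == roi.provenance["config_hash"]

    def test_wrong_roi_shape_rejected(self):
        with pytest.raises(ValueError, match="64"):
            ROIVolume(np.zeros((32, 64, 64)), 1.0, 1.0)


def test_landmark_json_round_trip():
    lms = line_landmarks()
    back = LandmarkSet.from_json(lms.to_json())
    np.testing.assert_allclose(back.points, lms.points)
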