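"""Velocity decoding, PC-MRA, segmentation, reslicing, flow and WSS."""

import math

import numpy as np
import pytest

from proudflow import hemodynamics as hemo, phantom
from proudflow.cs import ImageSeries
from proudflow.hemodynamics import FlowCurve


def _series_from_phantom(ph, n_frames):
    phases = (np.arange(n_frames) + 0.5) / n_frames
    segs = np.stack(
        [phantom.segment_volumes_at_phase(ph, p) for p in phases], axis=0
    )
    return ImageSeries(
        data=segs,
        voxel_size_mm=ph.voxel_size_mm,
        frame_duration_s=ph.cycle_s / n_frames,
    )


class TestDecodeVelocity:
    def test_equal_phases_zero_velocity(self):
        data = np.ones((2, 4, 4, 4, 2), dtype=complex)
        s = ImageSeries(data=data, voxel_size_mm=1.0, frame_duration_s=0.1)
        v = hemo.decode_velocity(s, 150.0)
        assert np.all(v.velocity == 0)

    def test_pi_phase_gives_venc(self):
        data = np.ones((1, 4, 2, 2, 2), dtype=complex)
        data[:, 1] = np.exp(1j * (math.pi - 1e-9))
        s = ImageSeries(data=data, voxel_size_mm=1.0, frame_duration_s=0.1)
        v = hemo.decode_velocity(s, 150.0)
        assert v.velocity[0, 0] == pytest.approx(150.0, rel=1e-6)

    def test_round_trip_with_encoder(self, small_phantom):
        ph = small_phantom
        s = _series_from_phantom(ph, 3)
        v = hemo.decode_velocity(s, ph.venc)
        for i, p in enumerate((np.arange(3) + 0.5) / 3):
            truth = phantom.velocity_field_at_phase(ph, p)
            assert np.allclose(v.velocity[i], truth, atol=1e-9)


class TestPcMra:
    def test_zero_velocity_zero_volume(self):
        v = hemo.VelocitySeries(
            velocity=np.zeros((3, 3, 4, 4, 2)),
            magnitude=np.ones((3, 4, 4, 2)),
            voxel_size_mm=1.0,
            frame_duration_s=0.1,
            venc=150.0,
        )
        assert np.all(hemo.pc_mra(v) == 0)

    def test_constant_values(self):
        vel = np.zeros((3, 3, 4, 4, 2))
        vel[:, 0] = 3.0
        v = hemo.VelocitySeries(
            velocity=vel,
            magnitude=2 * np.ones((3, 4, 4, 2)),
            voxel_size_mm=1.0,
            frame_duration_s=0.1,
            venc=150.0,
        )
        assert np.allclose(hemo.pc_mra(v), 6.0)

    def test_matches_bruteforce_on_phantom(self, small_phantom):
        s = _series_from_phantom(small_phantom, 4)
        v = hemo.decode_velocity(s, small_phantom.venc)
        mra = hemo.pc_mra(v)
        brute = np.zeros(small_phantom.shape)
        for t in range(4):
            brute += v.magnitude[t] * np.sqrt((v.velocity[t] ** 2).sum(axis=0))
        brute /= 4
        assert np.allclose(mra, brute, atol=1e-12)
        tube = phantom.tube_mask(small_phantom)
        assert mra[tube].mean() > 10 * mra[~tube].mean()


class TestSegmentVessel:
    def test_two_level_volume_exact(self, small_phantom):
        tube = phantom.tube_mask(small_phantom)
        vol = np.where(tube, 5.0, 0.1)
        assert np.array_equal(hemo.segment_vessel(vol), tube)

    def test_constant_volume_errors(self):
        with pytest.raises(ValueError, match="constant"):
            hemo.segment_vessel(np.ones((8, 8, 4)))

    def test_phantom_pcmra_dice(self, small_phantom):
        s = _series_from_phantom(small_phantom, 8)
        v = hemo.decode_velocity(s, small_phantom.venc)
        mask = hemo.segment_vessel(hemo.pc_mra(v))
        tube = phantom.tube_mask(small_phantom)
        dice = 2 * (mask & tube).sum() / (mask.sum() + tube.sum())
        assert dice > 0.9


class TestReslice:
    def _uniform_axial_series(self, speed=80.0, shape=(16, 16, 8)):
        vel = np.zeros((2, 3) + shape)
        vel[:, 2] = speed
        return hemo.VelocitySeries(
            velocity=vel,
            magnitude=np.ones((2,) + shape),
            voxel_size_mm=2.0,
            frame_duration_s=0.5,
            venc=150.0,
        )

    def test_axis_aligned_identity_extraction(self, small_phantom):
        s = _series_from_phantom(small_phantom, 2)
        v = hemo.decode_velocity(s, small_phantom.venc)
        nx, ny, nz = small_phantom.shape
        res = hemo.reslice_plane(
            v, origin=(0, 0, 0), normal=(0, 0, 1),
            resolution_mm=small_phantom.voxel_size_mm, size=(nx, ny),
        )
        # plane through slice centre nz/2 (z = 0 is between voxels nz/2-1, nz/2)
        direct = 0.5 * (v.velocity[:, 2, :, :, nz // 2 - 1] + v.velocity[:, 2, :, :, nz // 2])
        assert np.allclose(np.abs(res["v_through"]), np.abs(direct), atol=1e-9)

    def test_tilted_plane_cosine_projection(self):
        v = self._uniform_axial_series()
        for theta in (0.0, 0.3, 0.6):
            n = (math.sin(theta), 0.0, math.cos(theta))
            res = hemo.reslice_plane(v, (0, 0, 0), n, resolution_mm=2.0, size=(4, 4))
            assert res["v_through"][0, 2, 2] == pytest.approx(
                80.0 * math.cos(theta), rel=1e-9
            )

    def test_plane_outside_volume_errors(self):
        v = self._uniform_axial_series()
        with pytest.raises(ValueError, match="outside"):
            hemo.reslice_plane(v, (0, 0, 500.0), (0, 0, 1), 2.0, (4, 4))

    def test_phantom_cross_section_flow(self):
        ph = phantom.FlowPhantomConfig(shape=(64, 64, 16))
        s = _series_from_phantom(ph, 6)
        v = hemo.decode_velocity(s, ph.venc)
        res = hemo.reslice_plane(
            v, (0, 0, 0), (0, 0, 1), resolution_mm=ph.voxel_size_mm, size=(64, 64)
        )
        roi = np.ones((64, 64), dtype=bool)
        curve = hemo.roi_flow_curve(res, roi)
        truth = phantom.GroundTruth(ph)
        expect = truth.flow((np.arange(6) + 0.5) / 6)
        sel = expect > 0.1 * expect.max()
        assert np.allclose(curve.flow[sel], expect[sel], rtol=0.03)


class TestFlowMetrics:
    def test_uniform_velocity_flow(self):
        resliced = {
            "v_through": np.full((3, 2, 2), 100.0),
            "pixel_area_cm2": 1.0,
            "frame_times": np.array([0.1, 0.2, 0.3]),
            "cycle_s": 0.3,
        }
        curve = hemo.roi_flow_curve(resliced, np.ones((2, 2), bool))
        assert np.allclose(curve.flow, 400.0)  # 100 cm/s over 4 cm^2

    def test_empty_roi_errors(self):
        resliced = {
            "v_through": np.zeros((2, 2, 2)),
            "pixel_area_cm2": 1.0,
            "frame_times": np.array([0.1, 0.2]),
            "cycle_s": 0.2,
        }
        with pytest.raises(ValueError, match="empty ROI"):
            hemo.roi_flow_curve(resliced, np.zeros((2, 2), bool))

    def test_constant_flow_stroke_volume(self):
        curve = FlowCurve(
            flow=np.full(10, 25.0), times=(np.arange(10) + 0.5) / 10, cycle_s=1.0
        )
        assert hemo.stroke_volume(curve) == pytest.approx(25.0)

    def test_single_frame_peak(self):
        curve = FlowCurve(flow=[42.0], times=[0.5], cycle_s=1.0)
        assert hemo.peak_flow(curve) == 42.0
        assert hemo.stroke_volume(curve) == pytest.approx(42.0)


class TestPchipResample:
    def test_identity_on_same_grid(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0, 100, 12)
        t = (np.arange(12) + 0.5) / 12
        curve = FlowCurve(flow=f, times=t, cycle_s=1.0)
        out = hemo.pchip_resample(curve, 12)
        assert np.allclose(out.flow, f, atol=1e-12)

    def test_monotone_no_overshoot(self):
        f = np.array([0.0, 1.0, 2.0, 10.0, 50.0, 60.0, 61.0, 30.0, 5.0, 0.0])
        t = (np.arange(10) + 0.5) / 10
        curve = FlowCurve(flow=f, times=t, cycle_s=1.0)
        out = hemo.pchip_resample(curve, 100)
        inner = out.flow[(out.times > t[0]) & (out.times < t[6])]
        assert inner.max() <= 61.0 + 1e-9
        assert out.flow.min() >= f.min() - 1e-9

    def test_linear_reproduced_exactly(self):
        # exact wherever the interpolation stencil sees only linear data,
        # i.e. away from the segments adjacent to the cyclic wrap
        t = (np.arange(8) + 0.5) / 8
        f = 3.0 + 5.0 * t
        curve = FlowCurve(flow=f, times=t, cycle_s=1.0)
        out = hemo.pchip_resample(curve, 40)
        interior = (out.times >= t[1]) & (out.times <= t[-2])
        assert np.allclose(out.flow[interior], 3.0 + 5.0 * out.times[interior],
                           atol=1e-10)


class TestWSS:
    def test_zero_velocity_zero_wss(self, small_phantom):
        mask = phantom.tube_mask(small_phantom)
        field = hemo.compute_wss(
            np.zeros((3,) + small_phantom.shape), mask, small_phantom.voxel_size_mm
        )
        assert np.all(field.vectors == 0)

    def test_poiseuille_wall_shear(self):
        """Steady Poiseuille flow: |WSS| = mu * 2 v_max / R at the wall."""
        ph = phantom.FlowPhantomConfig(shape=(64, 64, 16), v_max=100.0)
        r = ph.radial_grid_mm()
        prof = np.clip(1 - (r / ph.tube_radius_mm) ** 2, 0, None)
        vel = np.zeros((3,) + ph.shape)
        vel[2] = 100.0 * prof
        mask = phantom.tube_mask(ph)
        mu = 3.2e-3
        field = hemo.compute_wss(vel, mask, ph.voxel_size_mm, mu=mu)
        truth = mu * 2.0 * 1.0 / (ph.tube_radius_mm * 1e-3)  # 100 cm/s = 1 m/s
        assert field.magnitudes().mean() == pytest.approx(truth, rel=0.10)

    def test_tangency_invariant(self):
        ph = phantom.FlowPhantomConfig(shape=(32, 32, 8), v_max=100.0)
        vel = phantom.velocity_field_at_phase(ph, ph.systole_fraction / 2)
        mask = phantom.tube_mask(ph)
        field = hemo.compute_wss(vel, mask, ph.voxel_size_mm)
        mags = field.magnitudes()
        nz = mags > 1e-12
        dots = np.abs(np.sum(field.vectors[nz] * field.normals[nz], axis=1)) / mags[nz]
        assert dots.max() < 1e-6

    def test_invalid_viscosity(self, small_phantom):
        with pytest.raises(ValueError, match="viscosity"):
            hemo.compute_wss(
                np.zeros((3,) + small_phantom.shape),
                phantom.tube_mask(small_phantom),
                2.5,
                mu=0.0,
            )
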