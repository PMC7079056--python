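"""Temporal-TV compressed-sensing reconstruction."""

import numpy as np
import pytest

from proudflow import cs, phantom
from proudflow.phantom import SenseOperator


def _tv_bruteforce(series):
    nf = series.shape[0]
    tot = 0.0
    for t in range(nf):
        d = series[(t + 1) % nf] - series[t]
        for val in np.ravel(d):
            tot += abs(val)
    return tot


class TestTemporalTV:
    def test_constant_series_is_zero(self):
        s = np.ones((5, 3, 3, 2), dtype=complex)
        assert cs.temporal_tv(s) == 0.0

    def test_two_frame_single_voxel(self):
        s = np.zeros((2, 2, 2, 1))
        s[1, 0, 0, 0] = 3.0
        # |3| counted on both cyclic edges
        assert cs.temporal_tv(s) == pytest.approx(6.0)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(6, 3, 2, 2)) + 1j * rng.normal(size=(6, 3, 2, 2))
        assert cs.temporal_tv(s) == pytest.approx(_tv_bruteforce(s), rel=1e-12)


class TestTVProx:
    def test_matches_reference_dual_solver(self):
        rng = np.random.default_rng(1)
        b = rng.normal(size=(40, 8)) + 1j * rng.normal(size=(40, 8))
        w = 0.3
        x = cs.tv_prox_cyclic(b, w, n_iter=3000)
        # reference: plain numpy projected-gradient dual iteration
        u = np.zeros_like(b)
        for _ in range(3000):
            u = u + 0.25 * cs._cyclic_diff(b - cs._cyclic_diff_adj(u))
            mag = np.abs(u)
            over = mag > w
            u[over] *= w / mag[over]
        ref = b - cs._cyclic_diff_adj(u)
        assert np.allclose(x, ref, atol=1e-12)

    def test_optimality_condition(self):
        """The prox output satisfies the subgradient optimality of the TV
        objective: objective at x is below any probed perturbation."""
        rng = np.random.default_rng(2)
        b = rng.normal(size=(10, 6))
        w = 0.5
        x = cs.tv_prox_cyclic(b, w, n_iter=5000)

        def obj(z):
            return 0.5 * np.sum(np.abs(z - b) ** 2) + w * np.sum(
                np.abs(np.roll(z, -1, -1) - z)
            )

        f0 = obj(x)
        for _ in range(30):
            assert f0 <= obj(x + 1e-4 * rng.normal(size=x.shape)) + 1e-12

    def test_large_weight_flattens(self):
        rng = np.random.default_rng(3)
        b = rng.normal(size=(5, 7))
        x = cs.tv_prox_cyclic(b, 1e6, n_iter=4000)
        assert np.allclose(x, b.mean(axis=-1, keepdims=True), atol=1e-6)


@pytest.fixture(scope="module")
def tiny_recon_setup(small_phantom, small_smaps):
    ph = small_phantom
    nf = 4
    phases = (np.arange(nf) + 0.5) / nf
    segs = np.stack(
        [phantom.segment_volumes_at_phase(ph, p) for p in phases], axis=0
    )
    return ph, segs, nf


class TestPicsReconstruct:
    def test_fully_sampled_noiseless_identity(self, tiny_recon_setup, small_smaps):
        ph, segs, nf = tiny_recon_setup
        masks = np.ones(ph.shape[1:] + (nf, 4), dtype=bool)
        y = phantom.synthesize_kspace(segs, small_smaps, masks, noise_sd=0)
        masks_r = np.moveaxis(masks, (0, 1), (2, 3))  # (nf, nseg, ny, nz)
        series = cs.pics_reconstruct(
            (y, masks_r),
            smaps=small_smaps,
            config=cs.CSConfig(lam=0.0, iterations=5, dtype="complex128"),
        )
        err = np.linalg.norm(series.data - segs) / np.linalg.norm(segs)
        assert err < 1e-6

    def test_objective_monotone_and_beats_zero_filled(self, small_dataset):
        cfg, kt = small_dataset
        from proudflow import pipeline

        series = cs.pics_reconstruct(kt, config=cfg.cs_config, n_frames=8)
        zf = cs.zero_filled_recon(kt, n_frames=8)
        for trace in series.meta["objective_trace"].values():
            assert all(b <= a + 1e-9 * abs(a) for a, b in zip(trace, trace[1:]))
        tm = pipeline.truth_magnitude(cfg.phantom, 8)
        assert pipeline._nrmse(series.magnitude(), tm) < pipeline._nrmse(
            zf.magnitude(), tm
        )

    def test_huge_lambda_gives_static_series(self, tiny_recon_setup, small_smaps):
        ph, segs, nf = tiny_recon_setup
        rng = np.random.default_rng(0)
        masks = rng.random(ph.shape[1:] + (nf, 4)) < 0.5
        y = phantom.synthesize_kspace(segs, small_smaps, masks, noise_sd=0)
        masks_r = np.moveaxis(masks, (0, 1), (2, 3))
        series = cs.pics_reconstruct(
            (y, masks_r),
            smaps=small_smaps,
            config=cs.CSConfig(lam=1e6, iterations=10, prox_iterations=200),
            segments=[0],
        )
        m = series.data[:, 0]
        var = np.abs(m - m.mean(axis=0, keepdims=True)).max()
        assert var / np.abs(m).max() < 1e-3

    def test_empty_frame_mask_warns(self, tiny_recon_setup, small_smaps):
        ph, segs, nf = tiny_recon_setup
        masks = np.ones(ph.shape[1:] + (nf, 4), dtype=bool)
        masks[:, :, 2, :] = False  # frame 2 never sampled
        y = phantom.synthesize_kspace(segs, small_smaps, masks, noise_sd=0)
        masks_r = np.moveaxis(masks, (0, 1), (2, 3))
        with pytest.warns(UserWarning, match="empty frame mask"):
            cs.pics_reconstruct(
                (y, masks_r),
                smaps=small_smaps,
                config=cs.CSConfig(lam=0.01, iterations=2),
                segments=[0],
            )


class TestZeroFilled:
    def test_full_mask_single_coil_exact(self):
        ph = phantom.FlowPhantomConfig(shape=(16, 16, 4), tube_radius_mm=8.0, n_coils=1)
        segs = phantom.segment_volumes_at_phase(ph, 0.1)[None]  # one frame
        smaps = phantom.coil_maps(1, ph.shape)
        masks = np.ones(ph.shape[1:] + (1, 4), dtype=bool)
        y = phantom.synthesize_kspace(segs, smaps, masks, noise_sd=0)
        zf = cs.zero_filled_recon(
            (y, np.moveaxis(masks, (0, 1), (2, 3))), smaps=smaps
        )
        assert np.allclose(zf.data, segs, atol=1e-10)


class TestLCurve:
    def _tiny(self):
        ph = phantom.FlowPhantomConfig(
            shape=(16, 16, 4), tube_radius_mm=8.0, n_coils=2, seed=5
        )
        smaps = phantom.coil_maps(2, ph.shape, seed=5)
        nf = 4
        phases = (np.arange(nf) + 0.5) / nf
        segs = np.stack(
            [phantom.segment_volumes_at_phase(ph, p) for p in phases], axis=0
        )
        rng = np.random.default_rng(6)
        masks = rng.random(ph.shape[1:] + (nf, 4)) < 0.4
        y = phantom.synthesize_kspace(segs, smaps, masks, noise_sd=0.01, seed=6)
        return (y, np.moveaxis(masks, (0, 1), (2, 3))), smaps

    def test_single_unregularized_point(self):
        data, smaps = self._tiny()
        table = cs.lcurve_sweep(data, [0.0], [3], smaps=smaps, segments=[0])
        assert len(table) == 1 and table["lambda"].iloc[0] == 0.0

    def test_printed_lambda_range_table(self):
        data, smaps = self._tiny()
        lams = [0.0001, 0.001, 0.01, 0.1, 0.5]
        table = cs.lcurve_sweep(data, lams, [3], smaps=smaps, segments=[0])
        assert len(table) == 5
        assert np.all(np.isfinite(table[["data_norm", "tv_norm"]].to_numpy()))

    def test_determinism(self):
        data, smaps = self._tiny()
        t1 = cs.lcurve_sweep(data, [0.001, 0.1], [2], smaps=smaps, segments=[0])
        t2 = cs.lcurve_sweep(data, [0.001, 0.1], [2], smaps=smaps, segments=[0])
        assert t1.equals(t2)
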