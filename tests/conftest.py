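"""Shared fixtures: small phantoms for unit tests, the default-scale study
reconstructions (computed once per session) for the recovery checks."""

from __future__ import annotations

import numpy as np
import pytest

from proudflow import binning, cs, phantom, pipeline, trajectory


@pytest.fixture(scope="session")
def small_phantom() -> phantom.FlowPhantomConfig:
    """Desk-size pulsatile phantom for fast unit tests."""
    return phantom.FlowPhantomConfig(
        shape=(32, 32, 8), tube_radius_mm=12.5, n_coils=3, noise_sd=0.01, seed=7
    )


@pytest.fixture(scope="session")
def small_smaps(small_phantom):
    return phantom.coil_maps(small_phantom.n_coils, small_phantom.shape, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_phantom):
    """Continuously acquired dataset on the small phantom (R ~ 4 at 8 frames)."""
    cfg = pipeline.StudyConfig(
        phantom=small_phantom,
        frame_counts=(8,),
        nominal_frames=8,
        target_R=4.0,
        seed=7,
        cs_config=cs.CSConfig(iterations=10),
    )
    return cfg, pipeline.build_dataset(cfg)


def _metrics(series, zf, ph, n_frames):
    tm = pipeline.truth_magnitude(ph, n_frames)
    q = pipeline.quantify_series(series, ph)
    return {
        "nrmse_cs": pipeline._nrmse(series.magnitude(), tm),
        "nrmse_zf": pipeline._nrmse(zf.magnitude(), tm),
        "peak_flow_error_pct": q["peak_flow_error_pct"],
        "stroke_volume_error_pct": q["stroke_volume_error_pct"],
    }


@pytest.fixture(scope="session")
def study_recons():
    """Default-phantom study: one acquisition, CS at 12/24/40 frames.

    24 frames corresponds to the nominal acceleration 8 and 40 frames to 13;
    metrics are NRMSE against the ground-truth magnitude and flow errors
    against the analytic flow curve.
    """
    cfg = pipeline.StudyConfig(seed=1)
    kt = pipeline.build_dataset(cfg)
    _, ny, nz = cfg.phantom.shape
    out = {"config": cfg, "n_groups": kt.n_groups, "dataset": kt}
    for nf in (12, 24, 40):
        series = cs.pics_reconstruct(kt, config=cfg.cs_config, n_frames=nf)
        zf = cs.zero_filled_recon(kt, n_frames=nf)
        m = _metrics(series, zf, cfg.phantom, nf)
        m["R_proud"] = trajectory.acceleration_factor(ny, nz, nf, kt.n_groups)
        m["R_nominal"] = int(round(m["R_proud"]))
        out[nf] = m
    return out
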