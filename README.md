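# proudflow

Accelerated 4D flow MRI at desk scale: pseudo-spiral golden-angle Cartesian
sampling with retrospective cardiac binning, compressed-sensing and k-t PCA
reconstruction, and hemodynamic quantification — exercised end-to-end on a
synthetic pulsatile-flow phantom with closed-form ground truth.

## The problem

4D flow MRI measures a time-resolved 3-component velocity field over the
cardiac cycle, but a fully sampled acquisition is far too slow, and
conventional k-t accelerations lock the number of cardiac frames at scan
time.  The sampling scheme implemented here orders the phase-encode points
(ky, kz) along quadratic spiral arms on the Cartesian grid,

    r_n = φ_n²,   φ_n = n · 2πT/N + ∅,   n = 0…N   (N = 75, T = 3),

rotating consecutive arms by the golden angle (≈ 137.51°) and scanning
continuously without ECG triggering while recording R-peak times.  Profiles
are sorted into cardiac frames *retrospectively*, so the same scan can be
reconstructed at 12, 24, 40, … frames; heart-rate variability randomises the
k-t filling, which is what a compressed-sensing reconstruction wants.  The
nominal acceleration of such a scan is

    R = Nky · Nkz · Ncard · (π/4) / N_acquired

(the π/4 is the elliptical k-space shutter), so rebinning the same data from
24 to 40 frames raises the nominal factor from 8 to 13 at no acquisition
cost.  Images are reconstructed per velocity segment by

    argmin_m ‖F_U S m − y‖² + λ‖T m‖₁,   λ = 0.001, 20 iterations,

with T a cyclic temporal total-variation operator (monotone FISTA, exact
per-voxel TV prox), and compared against a k-t PCA reconstruction (sheared
lattice R = 8, 11 training lines, regularization 0.2).  Downstream:
four-point velocity decoding (VENC = 150 cm/s), PC-MRA, threshold
segmentation, reslicing, ROI flow curves, peak flow, stroke volume,
PCHIP resampling to 40 frames, peak-systolic wall shear stress, and
Bland–Altman / Deming-regression / angular-difference statistics.

Who this is for: people developing or teaching dynamic-MRI sampling and
reconstruction who want a small, fully deterministic, analytically
verifiable stand-in for a scanner study.  See `docs/methods.md` for models,
conventions and limitations.

## Worked example

Simulate a continuous scan on the default phantom (64×64×16 voxels, tube
radius 12.5 mm, v_max = 120 cm/s under VENC 150), bin it at 24 frames,
reconstruct and quantify:

```python
from proudflow import pipeline, cs, phantom

cfg = pipeline.StudyConfig(seed=1)           # defaults: R≈8 at 24 frames
kt = pipeline.build_dataset(cfg)             # ~2600 acquired (ky,kz) groups
series = cs.pics_reconstruct(kt, config=cfg.cs_config, n_frames=24)
q = pipeline.quantify_series(series, cfg.phantom)
truth = phantom.GroundTruth(cfg.phantom)
print(f"peak flow {q['peak_flow']:.1f} ml/s (truth {truth.peak_flow:.1f}), "
      f"error {q['peak_flow_error_pct']:+.2f}%")
print(f"stroke volume {q['stroke_volume']:.1f} ml (truth {truth.stroke_volume:.1f}), "
      f"error {q['stroke_volume_error_pct']:+.2f}%")
```

prints

```
peak flow 292.1 ml/s (truth 294.5), error -0.82%
stroke volume 50.3 ml (truth 48.6), error +3.47%
```

i.e. the 24-frame CS reconstruction of a ~40 s simulated scan recovers the
phantom's analytic peak flow to under 1% and its stroke volume to a few
percent.  Rebinning the *same* dataset with `n_frames=40` gives the nominal
R = 13 reconstruction; the full sweep (12/24/27/35/40/60 frames plus the
k-t PCA comparator, with NRMSE and flow errors per row) is

```sh
proudflow study --out results/study      # writes study_report.csv + curves
```

The CLI also exposes the individual stages: `proudflow traj | phantom |
simulate | bin | recon-cs | recon-ktpca | quantify | wss | compare`.

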