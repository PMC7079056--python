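# Methods

`proudflow` implements, at desk scale, an accelerated 4D flow MRI
acquisition-and-reconstruction chain: pseudo-spiral golden-angle Cartesian
undersampling of the phase-encode plane, continuous un-triggered scanning
with retrospective cardiac binning at a flexible number of frames,
compressed-sensing reconstruction with a temporal total-variation penalty, a
k-t PCA comparator, and the downstream hemodynamic quantification (flow
curves, peak flow, stroke volume, wall shear stress) with
Bland–Altman/orthogonal-regression comparison statistics.  Everything runs
against a synthetic pulsatile tube-flow phantom whose hemodynamics are known
in closed form, so recovery can be judged against analytic truth rather than
a reference scan.

## Sampling model

Each spiral arm lives on the Cartesian phase-encode grid (ky, kz) and is
described in polar coordinates by

    r_n = phi_n^2,    phi_n = n · 2·pi·T / N + O,    n = 0 … N,

with N = 75 sampling locations per arm and T = 3 turns by default.  The
radius law uses the un-offset angle, so every arm shares one quadratic
density profile and the offset O only rotates it; consecutive arms advance O
by the golden angle 2·pi/φ² ≈ 2.39996 rad ≈ 137.51°.  The radius is
normalised to its value at n = N and scaled per axis to the grid half-sizes
(anisotropic "stretching" — necessary on non-square grids), then rounded to
integers.  Arms are generated centre-out by the formula and acquired
outer-in (a flag flips this).  The index range n ∈ [0, N] yields N + 1 raw
samples per arm; duplicates created by rounding stay in the trajectory file
and are resolved at scan time by the skip rule.

Acceleration is accounted two ways.  The nominal factor

    R = Nky · Nkz · Ncard · (pi/4) / N_acquired

compares against a fully sampled scan inside the elliptical shutter (the
pi/4 is the area ratio of the inscribed ellipse; the mask census converges
to it as the grid grows, checked at 512²).  The census factor R_true divides
the full Cartesian k-t grid by the acquired cell count and is reported, not
targeted: its value depends on the real-time skip mechanism and on binning
conventions that the accounting above does not fix.

## Acquisition simulation and binning

The scan runs continuously, not ECG-triggered.  RR intervals are i.i.d.
truncated normal (mean ± 3 SD, floored at 0.3 s); the default 1.0 ± 0.05 s
is a resting adult heart rate.  The four velocity segments of one (ky, kz)
are played back-to-back (TR = 3.9 ms each) and share one timestamp.
Retrospective binning maps a profile at time t to cardiac phase
p = (t − t_prev-R)/(t_next-R − t_prev-R) and frame ⌊p · n_frames⌋; profiles
before the first or after the last R-peak are dropped and counted.  Because
the true retrospective frame is unknown during the scan, the real-time
duplicate check uses a provisional bin: elapsed time since the last R-peak
over the running mean of the last 5 RR intervals, at the nominal 24-frame
resolution.  A coordinate whose (ky, kz, provisional bin) was already
acquired is skipped and costs no scan time.  Rebinning the same timeline at
a different frame count conserves the acquired profile count exactly (a
tested invariant), which is what makes the flexible temporal resolution
free at reconstruction time.

## Phantom

A straight tube (radius 12.5 mm) along z in a 64 × 64 × 16 volume at 2.5 mm
isotropic voxels carries parabolic flow v(r, t) = v_max · w(t) · (1 −
(r/R)²), v_max = 120 cm/s, with a raised-cosine systolic pulse w over the
first 33% of a 1.0 s cycle.  The analytic flow is Q(t) = (pi R²/2) · v_max ·
w(t) (peak ≈ 294.5 ml/s) and the stroke volume its cyclic integral
(≈ 48.6 ml) — aorta-like numbers.  Velocity maps to phase by referenced
four-point encoding (reference + one encode per axis, phase difference
pi·v/VENC, VENC = 150 cm/s, wrap-free since v_max < VENC).  Coil
sensitivities are smooth Gaussian lobes with low-order polynomial phase,
RSS-normalised to one (4 coils by default); noise is i.i.d. complex Gaussian
in k-space at 1% of the RMS acquired signal.  Magnitude is uniform in the
tube over a low background; no T1 dynamics, turbulence, wrapping or
background phase — the phantom tests the sampling/reconstruction chain, not
MR physics, so passing it says nothing about eddy currents, respiration or
segmentation ambiguity in vivo.

Per-profile k-space is synthesised from a 64-bin cardiac-phase library (the
phantom is periodic in phase), so one simulated scan can be rebinned at any
frame count from the same measured samples, exactly as on the scanner.  The
frame-synchronous path (`synthesize_kspace`) applies the forward model
y = M F S m directly and backs the machine-precision identity tests; the
forward/adjoint pair passes a dot-product test at 1e−10.

## CS reconstruction

Per velocity segment, minimise ½‖F_U S m − y‖² + λ‖T m‖₁ with T the cyclic
first difference over the cardiac dimension (the cycle wraps).  The printed
weight λ = 0.001 with 20 iterations is the default; it is interpreted
against unit-normalised data (y scaled so the zero-filled magnitude peaks at
one), with the data term written as a squared norm — the printed objective
is ambiguous between norm and squared norm, so the convention here is fixed
by the same L-curve-plus-flow-comparison procedure the operating point came
from (`lcurve_sweep`, λ ∈ [0.0001, 0.5], 20–50 iterations).

The solver is monotone FISTA: the accelerated proximal-gradient step is kept
only if it lowers the true objective, so the reported objective trace is
non-increasing by construction (a tested property).  The TV proximal map is
solved per voxel on the dual (projected gradient, step 1/4 = 1/‖DDᴴ‖, 20
inner iterations warm-started across outer iterations; a numba kernel).  The
step size comes from 10 power iterations on F_U S; the starting point is the
zero-filled adjoint.  Computation is single precision by default, as is
conventional for large MRI reconstructions; the exact-recovery tests run the
same code in double precision.  Empty frame masks (possible after severe
truncation) produce a warning and a regularization-dominated frame rather
than an error.

## k-t PCA comparator

The comparator arm undersamples on a sheared lattice — line ky sampled at
frame t iff (ky + t) mod R = 0, kz fully sampled, R = 8, frame count a
multiple of R — with 11 centre ky lines acquired at every frame as training
data, mirroring a prospectively gated acquisition (generated
frame-synchronous and noiseless).  Training images give a temporal PCA
basis (2 components by default: static + pulsatile; configurable).  The
aliased data are unfolded by least squares constrained to that subspace,
with Tikhonov regularization 0.2 · σ_n² / p_k on component k (p_k the
training signal power, σ_n² the measurement noise power), solved by
conjugate gradients.  Scaling the regularizer by the noise power gives the
classic signal-over-noise filter structure and makes the noiseless R = 1
case exactly consistent (the penalty vanishes, and with a complete basis
the reconstruction equals the direct inverse — a tested identity).  σ_n²
defaults to 0 because the comparator data are generated noiseless; callers
pass a measured value for noisy data.

## Quantification

Velocity decodes as v_d = angle(seg_d · conj(ref))/pi · VENC.  PC-MRA is
the frame-mean of magnitude × speed.  Segmentation thresholds the log
PC-MRA by Otsu (log, because the angiographic signal is parabolic-graded
inside the lumen and plain Otsu would bisect the vessel) and keeps the
largest connected component.  Reslicing interpolates linearly onto an
arbitrary plane; through-plane velocity is v · n̂.  ROI flow is
Σ v_through · pixel area (cm/s · cm² = ml/s); stroke volume is the cyclic
trapezoid of the flow curve (equal to mean × cycle on uniform frame
centres); curves at lower temporal resolution are resampled to 40 frames by
shape-preserving PCHIP on the periodically extended samples.

WSS: surface voxels of the mask (volume-edge faces excluded — a vessel
truncated by the FOV is open, not capped), inward normals from the gradient
of the Gaussian-smoothed mask (σ = 1 voxel), wall located at the 0.5 level
of that smoothed mask along the normal, tangential velocity sampled at 1 and
2 voxel-lengths inward, quadratic fit through (0, v₁, v₂) with v(0) = 0
enforced at the wall, WSS = μ · dv/ds at the wall with μ = 3.2 mPa·s.  On
the analytic Poiseuille tube this recovers μ·2·v_max/R to well within 10% at
2.5 mm resolution.  Degenerate normals are skipped and counted.

## Statistics

Bland–Altman reports mean difference ± SEM and limits of agreement as the
half width 1.96·SD (one number, matching how a single LoA column is usually
printed); relative measures are percentages of the grand mean of pair
averages.  Orthogonal regression is Deming with error-variance ratio 1
(total least squares) — symmetric under axis swap; Pearson r on the raw
pairs.  Angular agreement of 3-vectors uses arccos of the clamped cosine,
reported in degrees with the median; zero vectors are excluded and counted.
Paired t-tests are two-sided at 0.05; identical samples return (0, 1, not
significant) and a constant nonzero difference is an error.  Every statistic
is tested against an independent brute-force recomputation at 1e−10.

## Problem sizes and defaults

The study configuration simulates one continuous scan sized for nominal
R = 8 at 24 frames on the 64 × 64 × 16 phantom (≈ 2 500 acquired coordinate
groups, ≈ 40 s of scan time at TR 3.9 ms × 4 segments), reconstructs CS at
12/24/27/35/40/60 frames plus k-t PCA at 24, quantifies, and writes a CSV
report; reruns under the same seeds are byte-identical.  The test suite
exercises the same chain with 24/40-frame reconstructions (nominal R = 8
and 13) on the default phantom and smaller grids elsewhere; these sizes are
the package's chosen desk-scale operating point.  The incomplete-scan path
truncates the timeline to a leading fraction, which raises R by exactly the
inverse fraction and still reconstructs (empty frames permitted).

## Known limitations

Respiratory motion, eddy currents, phase wrapping, background-phase
correction, realistic vessel geometry and registration between scans are
all out of scope; the comparator implements plain k-t PCA (not k-t sPCA or
low-rank variants); the provisional-bin rule for the real-time skip is one
reading of a mechanism the acquisition only fixes operationally, so census
acceleration factors are reported rather than asserted against any
particular value.
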