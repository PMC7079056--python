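"""Synthetic pulsatile tube-flow phantom with analytic ground truth.

A straight tube of radius R along the z axis carries time-varying parabolic
(Poiseuille-like) flow: the axial velocity is

    v(r, t) = v_max * w(t) * (1 - (r/R)**2)      inside the tube, 0 outside,

with w a raised-cosine systolic pulse (w in [0, 1], peak 1).  The analytic
flow through any cross-section is Q(t) = (pi R^2 / 2) * v_max * w(t) and the
stroke volume its integral over one cycle — the ground truth against which
every reconstruction is judged.

Velocity is mapped to image phase by referenced four-point phase-contrast
encoding: a velocity-compensated reference plus one encode per axis, with a
phase difference of pi * v / VENC, so |v| = VENC gives a phase shift of pi.
Multi-coil k-space is synthesised through smooth complex sensitivities and a
unitary FFT, with optional i.i.d. complex Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as spfft

from .binning import AcquisitionTimeline, ECGRecord, cardiac_phase

__all__ = [
    "FlowPhantomConfig",
    "GroundTruth",
    "waveform",
    "velocity_field",
    "magnitude_volume",
    "tube_mask",
    "encode_pc",
    "coil_maps",
    "fft3",
    "ifft3",
    "SenseOperator",
    "synthesize_kspace",
    "acquire_profiles",
]


@dataclass(frozen=True)
class FlowPhantomConfig:
    """Geometry, dynamics and acquisition parameters of the flow phantom.

    Defaults: 64 x 64 x 16 voxels at 2.5 mm, tube radius 12.5 mm along z,
    v_max 120 cm/s under a VENC of 150 cm/s (wrap-free), 1.0 s cycle with a
    0.33 systolic fraction, 4 coils, 1% relative k-space noise.
    """

    shape: tuple[int, int, int] = (64, 64, 16)
    voxel_size_mm: float = 2.5
    tube_radius_mm: float = 12.5
    tube_axis: int = 2
    v_max: float = 120.0  # cm/s
    systole_fraction: float = 0.33
    cycle_s: float = 1.0
    venc: float = 150.0  # cm/s
    n_coils: int = 4
    noise_sd: float = 0.01  # relative to RMS k-space signal
    background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.venc):
            raise ValueError("VENC must be positive")
        if not (self.v_max < self.venc):
            raise ValueError("default fixture must be wrap-free: v_max < VENC")
        half_fov = min(self.shape[0], self.shape[1]) * self.voxel_size_mm / 2
        if self.tube_radius_mm >= half_fov:
            raise ValueError("tube does not fit in the grid")

    @property
    def pixel_area_cm2(self) -> float:
        return (self.voxel_size_mm / 10.0) ** 2

    def radial_grid_mm(self) -> np.ndarray:
        """Distance from the tube axis at each voxel centre (mm)."""
        nx, ny, nz = self.shape
        x = (np.arange(nx) - nx / 2 + 0.5) * self.voxel_size_mm
        y = (np.arange(ny) - ny / 2 + 0.5) * self.voxel_size_mm
        r2 = x[:, None] ** 2 + y[None, :] ** 2
        return np.sqrt(np.broadcast_to(r2[:, :, None], self.shape))


def waveform(phase: np.ndarray | float, systole_fraction: float = 0.33) -> np.ndarray:
    """Raised-cosine systolic pulse over cardiac phase in [0, 1).

    w(p) = 0.5 * (1 - cos(2 pi p / f_sys)) for p < f_sys, else 0; peaks at
    p = f_sys / 2 with value 1.
    """
    p = np.mod(np.asarray(phase, dtype=float), 1.0)
    w = np.where(p < systole_fraction,
                 0.5 * (1.0 - np.cos(2.0 * math.pi * p / systole_fraction)),
                 0.0)
    return w


def tube_mask(config: FlowPhantomConfig) -> np.ndarray:
    """Boolean mask of voxels whose centres lie inside the tube."""
    return config.radial_grid_mm() < config.tube_radius_mm


def velocity_field(config: FlowPhantomConfig, t: float) -> np.ndarray:
    """3-component velocity volume (cm/s), shape (3, nx, ny, nz), at time t (s)."""
    phase = (t % config.cycle_s) / config.cycle_s
    return velocity_field_at_phase(config, phase)


def velocity_field_at_phase(config: FlowPhantomConfig, phase: float) -> np.ndarray:
    r = config.radial_grid_mm()
    prof = np.clip(1.0 - (r / config.tube_radius_mm) ** 2, 0.0, None)
    w = float(waveform(phase, config.systole_fraction))
    v = np.zeros((3,) + config.shape)
    v[config.tube_axis] = config.v_max * w * prof
    return v


def magnitude_volume(config: FlowPhantomConfig) -> np.ndarray:
    """Uniform signal inside the tube over a low background."""
    m = np.full(config.shape, config.background)
    m[tube_mask(config)] = 1.0
    return m


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form hemodynamics of the phantom."""

    config: FlowPhantomConfig

    def flow(self, phase: np.ndarray | float) -> np.ndarray:
        """Analytic flow Q (ml/s) at cardiac phase(s) in [0, 1)."""
        c = self.config
        area_cm2 = math.pi * (c.tube_radius_mm / 10.0) ** 2
        return area_cm2 / 2.0 * c.v_max * waveform(phase, c.systole_fraction)

    @property
    def peak_flow(self) -> float:
        c = self.config
        return math.pi * (c.tube_radius_mm / 10.0) ** 2 / 2.0 * c.v_max

    @property
    def stroke_volume(self) -> float:
        # integral of the raised cosine over [0, f_sys] is f_sys/2
        c = self.config
        return self.peak_flow * c.cycle_s * c.systole_fraction / 2.0

    def frame_flow(self, n_frames: int) -> np.ndarray:
        """Analytic flow at the frame-centre phases."""
        phases = (np.arange(n_frames) + 0.5) / n_frames
        return self.flow(phases)


# ---------------------------------------------------------------------------
# phase-contrast encoding

def encode_pc(magnitude: np.ndarray, velocity: np.ndarray, venc: float) -> np.ndarray:
    """Referenced four-point encoding: reference + 3 one-sided encodes.

    Returns complex volumes of shape (4, *grid); the phase difference between
    encode d and the reference is pi * v_d / VENC, the magnitude is shared.
    """
    segs = np.empty((4,) + magnitude.shape, dtype=complex)
    segs[0] = magnitude.astype(complex)
    for d in range(3):
        segs[d + 1] = magnitude * np.exp(1j * math.pi * velocity[d] / venc)
    return segs


def segment_volumes_at_phase(config: FlowPhantomConfig, phase: float) -> np.ndarray:
    """The four encoded complex volumes of the phantom at a cardiac phase."""
    return encode_pc(magnitude_volume(config),
                     velocity_field_at_phase(config, phase), config.venc)


# ---------------------------------------------------------------------------
# coils and Fourier operators

def coil_maps(n_coils: int, shape: tuple[int, int, int], seed: int = 0) -> np.ndarray:
    """Smooth complex coil sensitivities, RSS-normalised to 1 everywhere.

    Coils are Gaussian lobes centred on the x-y perimeter with a low-order
    polynomial phase.  ``n_coils = 1`` returns a uniform map, so the SENSE
    operator degenerates to plain Fourier sampling.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if n_coils == 1:
        return np.ones((1,) + shape, dtype=complex)
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    x = np.linspace(-1, 1, nx)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    z = np.linspace(-1, 1, nz)[None, None, :]
    maps = np.empty((n_coils,) + shape, dtype=complex)
    for c in range(n_coils):
        th = 2 * math.pi * c / n_coils + rng.uniform(-0.2, 0.2)
        cx, cy = 1.3 * math.cos(th), 1.3 * math.sin(th)
        sigma = 1.1 + rng.uniform(-0.1, 0.1)
        amp = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2)))
        ph = (rng.uniform(-math.pi, math.pi)
              + rng.uniform(-1, 1) * x + rng.uniform(-1, 1) * y
              + rng.uniform(-0.5, 0.5) * z)
        maps[c] = (0.2 + amp) * np.exp(1j * ph)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return maps / rss


def fft3(img: np.ndarray) -> np.ndarray:
    """Unitary 3-D FFT over the last three axes, k-space DC centred.

    The image-domain origin convention is the array as-is (no pre-shift);
    ``ifft3`` is the exact unitary inverse, which is all the sampling,
    reconstruction and adjoint machinery relies on.
    """
    ax = (-3, -2, -1)
    return np.fft.fftshift(spfft.fftn(img, axes=ax, norm="ortho"), axes=ax)


def ifft3(ksp: np.ndarray) -> np.ndarray:
    ax = (-3, -2, -1)
    return spfft.ifftn(np.fft.ifftshift(ksp, axes=ax), axes=ax, norm="ortho")


class SenseOperator:
    """Undersampled multi-coil Fourier operator A = M F S for one segment.

    ``smaps``: (n_coils, nx, ny, nz); ``masks``: (n_frames, ny, nz) boolean
    phase-encode masks (kx fully sampled).  Forward maps an image series
    (n_frames, nx, ny, nz) to masked k-space (n_frames, n_coils, nx, ny, nz);
    ``adjoint`` is its exact conjugate transpose (unitary FFT), verified by
    the dot-product test.
    """

    def __init__(self, smaps: np.ndarray, masks: np.ndarray):
        self.smaps = smaps
        self.masks = masks.astype(bool)

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    def forward(self, m: np.ndarray) -> np.ndarray:
        coil_imgs = self.smaps[None, :, :, :, :] * m[:, None, :, :, :]
        y = fft3(coil_imgs)
        y *= self.masks[:, None, None, :, :]
        return y

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        y = y * self.masks[:, None, None, :, :]
        imgs = ifft3(y)
        return np.sum(np.conj(self.smaps)[None] * imgs, axis=1)


def synthesize_kspace(
    segment_series: np.ndarray,
    smaps: np.ndarray,
    masks: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Frame-synchronous forward model y = M F S m (+ noise).

    ``segment_series``: (n_frames, n_segments, nx, ny, nz) complex images;
    ``masks``: (ny, nz, n_frames, n_segments) boolean.  Returns k-space of
    shape (n_frames, n_segments, n_coils, nx, ny, nz).  Noise is i.i.d.
    complex Gaussian with sd ``noise_sd`` times the RMS of the noiseless
    acquired samples.
    """
    n_frames, n_seg = segment_series.shape[:2]
    if masks.shape[2] != n_frames or masks.shape[3] != n_seg:
        raise ValueError("mask dimensions do not match the image series")
    n_coils = smaps.shape[0]
    grid = segment_series.shape[2:]
    y = np.zeros((n_frames, n_seg, n_coils) + grid, dtype=complex)
    for d in range(n_seg):
        op = SenseOperator(smaps, np.moveaxis(masks[:, :, :, d], 2, 0))
        y[:, d] = op.forward(segment_series[:, d])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sampled = np.moveaxis(masks, (2, 3), (0, 1))[:, :, None, None, :, :]
        scale = np.sqrt(np.mean(np.abs(y[np.broadcast_to(sampled, y.shape)]) ** 2))
        noise = rng.normal(size=y.shape) + 1j * rng.normal(size=y.shape)
        y += noise_sd * scale / math.sqrt(2.0) * noise * sampled
    return y


# ---------------------------------------------------------------------------
# profile-level acquisition (continuous scan against the ECG)

def acquire_profiles(
    config: FlowPhantomConfig,
    timeline: AcquisitionTimeline,
    ecg: ECGRecord,
    smaps: np.ndarray,
    n_phase_bins: int = 64,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate the measured k-space columns of every acquired profile.

    Each accepted coordinate group reads a full kx column at its (ky, kz) for
    all four segments and coils, with the phantom evaluated at the profile's
    cardiac phase (quantised to ``n_phase_bins`` per cycle, so that rebinning
    at any frame count reuses the same measured samples).  Returns complex
    samples of shape (n_groups, n_segments, n_coils, nx).
    """
    if noise_sd is None:
        noise_sd = config.noise_sd
    if seed is None:
        seed = config.seed
    nx, ny, nz = config.shape
    acq = timeline.acquired
    grp = acq[acq["segment"] == 0]
    times = grp["time"].to_numpy()
    iy = grp["ky"].to_numpy() + ny // 2
    iz = grp["kz"].to_numpy() + nz // 2
    p, valid = cardiac_phase(times, ecg)
    if not np.all(valid):
        raise ValueError("acquired profile outside ECG coverage")
    pbin = np.minimum((p * n_phase_bins).astype(int), n_phase_bins - 1)
    n_groups = len(grp)
    n_coils = smaps.shape[0]
    y = np.zeros((n_groups, 4, n_coils, nx), dtype=np.complex64)
    for b in np.unique(pbin):
        sel = np.flatnonzero(pbin == b)
        segs = segment_volumes_at_phase(config, (b + 0.5) / n_phase_bins)
        ksp = fft3(segs[:, None] * smaps[None])  # (4, n_coils, nx, ny, nz)
        y[sel] = np.moveaxis(ksp[:, :, :, iy[sel], iz[sel]], 3, 0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        scale = np.sqrt(np.mean(np.abs(y) ** 2))
        noise = rng.normal(size=y.shape) + 1j * rng.normal(size=y.shape)
        y += noise_sd * scale / math.sqrt(2.0) * noise
    return y
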