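"""Continuous un-triggered acquisition, ECG timestamping and retrospective binning.

The pseudo-spiral scan runs continuously without ECG triggering; R-peak times
are recorded alongside each profile so that profiles can be sorted into an
arbitrary number of cardiac frames *after* the scan.  Physiological RR
variability is what randomises the k-t filling.  Oversampling of a k-t cell
is avoided in real time: a coordinate whose (ky, kz, provisional-bin) was
already scanned is skipped and the next trajectory coordinate is tried.

The provisional bin used by the real-time skip is computed from the running
ECG state (elapsed time since the last R-peak over the mean of the last few
RR intervals), since the true retrospective frame is unknown during the scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trajectory import Trajectory

__all__ = [
    "ECGRecord",
    "AcquisitionTimeline",
    "FrameAssignment",
    "simulate_rr_series",
    "simulate_acquisition",
    "assign_cardiac_frames",
    "realtime_skip",
    "build_kt_masks",
]

N_SEGMENTS = 4  # referenced four-point phase-contrast encoding
RR_FLOOR = 0.3  # s, physiological lower bound on an RR interval


@dataclass(frozen=True)
class ECGRecord:
    """Recorded R-peak times with the generating RR statistics."""

    r_peak_times: np.ndarray  # seconds, strictly increasing
    mean_rr: float
    sd_rr: float
    seed: int

    def __post_init__(self) -> None:
        t = np.asarray(self.r_peak_times, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("r_peak_times must be strictly increasing, >= 2 peaks")


def simulate_rr_series(
    mean_rr: float, sd_rr: float, n_beats: int, seed: int
) -> ECGRecord:
    """Draw ``n_beats`` RR intervals from a truncated normal distribution.

    Truncation at mean +/- 3 sd and at a 0.3 s physiological floor.  With
    ``sd_rr = 0`` the R-peaks are perfectly periodic.
    """
    if mean_rr <= 0:
        raise ValueError("mean_rr must be > 0")
    if sd_rr < 0:
        raise ValueError("sd_rr must be >= 0")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    rng = np.random.default_rng(seed)
    if sd_rr == 0:
        rr = np.full(n_beats, mean_rr)
    else:
        lo = max(mean_rr - 3 * sd_rr, RR_FLOOR)
        hi = mean_rr + 3 * sd_rr
        a, b = (lo - mean_rr) / sd_rr, (hi - mean_rr) / sd_rr
        rr = stats.truncnorm.rvs(a, b, loc=mean_rr, scale=sd_rr,
                                 size=n_beats, random_state=rng)
    peaks = np.concatenate([[0.0], np.cumsum(rr)])
    return ECGRecord(r_peak_times=peaks, mean_rr=mean_rr, sd_rr=sd_rr, seed=seed)


@dataclass
class AcquisitionTimeline:
    """Per-profile acquisition record.

    ``records`` has one row per profile with columns
    time (s), ky, kz, segment (0..3), status ('acquired' | 'skipped').
    The four velocity segments of one (ky, kz) are acquired back-to-back and
    share one timestamp for binning purposes.
    """

    records: pd.DataFrame
    tr: float
    n_segments: int = N_SEGMENTS

    @property
    def acquired(self) -> pd.DataFrame:
        return self.records[self.records["status"] == "acquired"]

    @property
    def n_acquired_groups(self) -> int:
        return len(self.acquired) // self.n_segments

    @property
    def n_skipped_groups(self) -> int:
        return (len(self.records) - len(self.acquired)) // self.n_segments


def realtime_skip(
    proposed: tuple[int, int], provisional_bin: int, acquired_set: set
) -> bool:
    """Real-time duplicate check: accept iff (ky, kz, bin) is unseen.

    Returns True for accept (and records the coordinate), False for skip.
    """
    key = (proposed[0], proposed[1], provisional_bin)
    if key in acquired_set:
        return False
    acquired_set.add(key)
    return True


def simulate_acquisition(
    trajectory: Trajectory,
    ecg: ECGRecord,
    tr: float = 3.9e-3,
    n_segments: int = N_SEGMENTS,
    nominal_frames: int = 24,
    rr_window: int = 5,
) -> AcquisitionTimeline:
    """Play the trajectory against the ECG with the real-time skip rule.

    Coordinates are visited arm by arm in acquisition order starting at the
    first R-peak; each accepted coordinate occupies ``n_segments`` TRs (one
    per velocity segment, sharing the group timestamp); a skipped coordinate
    consumes no scan time.  Acquisition stops at the last R-peak or when the
    trajectory is exhausted, whichever comes first.
    """
    peaks = ecg.r_peak_times
    rr = np.diff(peaks)
    t = float(peaks[0])
    t_end = float(peaks[-1])
    beat = 0  # index of the R-peak at or before t
    acquired_set: set = set()
    rows_t, rows_ky, rows_kz, rows_status = [], [], [], []
    group_tr = n_segments * tr
    done = False
    for arm in trajectory.arms:
        if done:
            break
        for ky, kz in arm:
            if t + group_tr > t_end:
                done = True
                break
            while beat + 1 < len(peaks) and peaks[beat + 1] <= t:
                beat += 1
            # running RR estimate from the last few completed intervals
            w0 = max(0, beat - rr_window)
            rr_running = float(np.mean(rr[w0:beat])) if beat > 0 else float(rr[0])
            prov = int(((t - peaks[beat]) / rr_running) * nominal_frames)
            prov = min(max(prov, 0), nominal_frames - 1)
            accept = realtime_skip((int(ky), int(kz)), prov, acquired_set)
            rows_t.append(t)
            rows_ky.append(int(ky))
            rows_kz.append(int(kz))
            rows_status.append("acquired" if accept else "skipped")
            if accept:
                t += group_tr
    n = len(rows_t)
    df = pd.DataFrame(
        {
            "time": np.repeat(rows_t, n_segments),
            "ky": np.repeat(rows_ky, n_segments),
            "kz": np.repeat(rows_kz, n_segments),
            "segment": np.tile(np.arange(n_segments), n),
            "status": np.repeat(rows_status, n_segments),
        }
    )
    return AcquisitionTimeline(records=df, tr=tr, n_segments=n_segments)


@dataclass
class FrameAssignment:
    """Retrospective frame index per acquired profile."""

    n_frames: int
    frames: np.ndarray  # frame index per acquired-profile row, -1 = excluded
    phase: np.ndarray  # cardiac phase in [0, 1) per acquired-profile row
    n_excluded: int


def cardiac_phase(times: np.ndarray, ecg: ECGRecord) -> tuple[np.ndarray, np.ndarray]:
    """Cardiac phase p = (t - t_prev)/(t_next - t_prev) in [0, 1).

    Returns (phase, valid) where valid marks times inside ECG coverage
    [first R-peak, last R-peak).
    """
    peaks = ecg.r_peak_times
    t = np.asarray(times, dtype=float)
    idx = np.searchsorted(peaks, t, side="right") - 1
    valid = (idx >= 0) & (idx < len(peaks) - 1)
    idx_c = np.clip(idx, 0, len(peaks) - 2)
    p = (t - peaks[idx_c]) / (peaks[idx_c + 1] - peaks[idx_c])
    p = np.clip(p, 0.0, np.nextafter(1.0, 0.0))
    return p, valid


def assign_cardiac_frames(
    timeline: AcquisitionTimeline, ecg: ECGRecord, n_frames: int
) -> FrameAssignment:
    """Bin acquired profiles into ``n_frames`` cardiac frames retrospectively."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    acq = timeline.acquired
    p, valid = cardiac_phase(acq["time"].to_numpy(), ecg)
    frames = np.floor(p * n_frames).astype(int)
    frames = np.minimum(frames, n_frames - 1)
    frames[~valid] = -1
    return FrameAssignment(
        n_frames=n_frames, frames=frames, phase=p, n_excluded=int((~valid).sum())
    )


def build_kt_masks(
    timeline: AcquisitionTimeline,
    assignment: FrameAssignment,
    grid: tuple[int, int],
    n_segments: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary sampling masks and per-cell profile counts.

    Returns ``(mask, counts)`` with shape (Nky, Nkz, n_frames, n_segments);
    ``mask`` is True where at least one acquired profile fell and ``counts``
    carries the multiplicity, so counts.sum() equals the accepted-profile
    count for every choice of n_frames (sample conservation).
    """
    nky, nkz = grid
    nseg = n_segments if n_segments is not None else timeline.n_segments
    acq = timeline.acquired
    frames = assignment.frames
    sel = frames >= 0
    iy = acq["ky"].to_numpy()[sel] + nky // 2
    iz = acq["kz"].to_numpy()[sel] + nkz // 2
    it = frames[sel]
    iseg = acq["segment"].to_numpy()[sel]
    if np.any((iy < 0) | (iy >= nky) | (iz < 0) | (iz >= nkz)):
        raise ValueError("trajectory coordinate outside the stated grid")
    counts = np.zeros((nky, nkz, assignment.n_frames, nseg), dtype=np.int32)
    np.add.at(counts, (iy, iz, it, iseg), 1)
    return counts > 0, counts
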