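"""File formats: KTDataset (HDF5), NIfTI volumes, CSV flow curves, JSON sidecars.

The KTDataset container holds everything a reconstruction needs: per-profile
multi-coil k-space samples with their acquisition timeline and ECG record,
coil sensitivity maps, grid geometry and the acquisition parameters (VENC,
TR, seed).  Retrospective binning happens at load/reconstruction time, so
one dataset can be re-binned into any number of cardiac frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .binning import (
    AcquisitionTimeline,
    ECGRecord,
    FrameAssignment,
    assign_cardiac_frames,
    build_kt_masks,
)

__all__ = ["KTDataset", "grid_kspace", "save_nifti", "load_nifti",
           "save_flow_curve_csv", "load_flow_curve_csv", "write_sidecar"]


@dataclass
class KTDataset:
    """Continuously acquired multi-coil, multi-segment k-space data.

    ``profiles``: complex samples (n_groups, n_segments, n_coils, nx) — one
    full kx column per accepted (ky, kz) coordinate group.
    """

    profiles: np.ndarray
    timeline: AcquisitionTimeline
    ecg: ECGRecord
    smaps: np.ndarray
    grid: tuple[int, int, int]  # (nx, ny, nz)
    venc: float
    voxel_size_mm: float
    cycle_s: float
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_segments(self) -> int:
        return self.profiles.shape[1]

    def assignment(self, n_frames: int) -> FrameAssignment:
        return assign_cardiac_frames(self.timeline, self.ecg, n_frames)

    def masks(self, n_frames: int) -> tuple[np.ndarray, np.ndarray]:
        """(mask, counts) on (ky, kz, frame, segment) for a frame count."""
        return build_kt_masks(
            self.timeline, self.assignment(n_frames), (self.grid[1], self.grid[2])
        )

    def truncated(self, fraction: float) -> "KTDataset":
        """Keep only the leading ``fraction`` of acquired coordinate groups.

        Emulates a scan stopped early; skipped records after the cut are
        dropped as well.
        """
        if not (0 < fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        n_keep = max(1, int(round(self.n_groups * fraction)))
        grp_times = self.timeline.acquired.loc[
            self.timeline.acquired["segment"] == 0, "time"
        ].to_numpy()
        t_cut = grp_times[n_keep - 1]
        rec = self.timeline.records
        tl = AcquisitionTimeline(
            records=rec[rec["time"] <= t_cut].reset_index(drop=True),
            tr=self.timeline.tr,
            n_segments=self.timeline.n_segments,
        )
        return KTDataset(
            profiles=self.profiles[:n_keep],
            timeline=tl,
            ecg=self.ecg,
            smaps=self.smaps,
            grid=self.grid,
            venc=self.venc,
            voxel_size_mm=self.voxel_size_mm,
            cycle_s=self.cycle_s,
            seed=self.seed,
            meta=dict(self.meta, truncated_fraction=fraction),
        )

    # -- HDF5 round trip ---------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("kspace", data=self.profiles.astype(np.complex64))
            f.create_dataset("smaps", data=self.smaps.astype(np.complex64))
            tl = self.timeline.records
            f.create_dataset("timeline/time", data=tl["time"].to_numpy())
            f.create_dataset("timeline/ky", data=tl["ky"].to_numpy())
            f.create_dataset("timeline/kz", data=tl["kz"].to_numpy())
            f.create_dataset("timeline/segment", data=tl["segment"].to_numpy())
            f.create_dataset(
                "timeline/acquired",
                data=(tl["status"] == "acquired").to_numpy(),
            )
            f.create_dataset("ecg/r_peak_times", data=self.ecg.r_peak_times)
            f.attrs.update(
                {
                    "grid": self.grid,
                    "venc": self.venc,
                    "voxel_size_mm": self.voxel_size_mm,
                    "cycle_s": self.cycle_s,
                    "tr": self.timeline.tr,
                    "n_segments": self.timeline.n_segments,
                    "seed": self.seed,
                    "ecg_mean_rr": self.ecg.mean_rr,
                    "ecg_sd_rr": self.ecg.sd_rr,
                    "ecg_seed": self.ecg.seed,
                    "meta_json": json.dumps(self.meta),
                }
            )

    @classmethod
    def from_hdf5(cls, path) -> "KTDataset":
        with h5py.File(path, "r") as f:
            profiles = f["kspace"][...].astype(complex)
            smaps = f["smaps"][...].astype(complex)
            status = np.where(f["timeline/acquired"][...], "acquired", "skipped")
            records = pd.DataFrame(
                {
                    "time": f["timeline/time"][...],
                    "ky": f["timeline/ky"][...],
                    "kz": f["timeline/kz"][...],
                    "segment": f["timeline/segment"][...],
                    "status": status,
                }
            )
            a = f.attrs
            tl = AcquisitionTimeline(
                records=records, tr=float(a["tr"]), n_segments=int(a["n_segments"])
            )
            ecg = ECGRecord(
                r_peak_times=f["ecg/r_peak_times"][...],
                mean_rr=float(a["ecg_mean_rr"]),
                sd_rr=float(a["ecg_sd_rr"]),
                seed=int(a["ecg_seed"]),
            )
            return cls(
                profiles=profiles,
                timeline=tl,
                ecg=ecg,
                smaps=smaps,
                grid=tuple(int(g) for g in a["grid"]),
                venc=float(a["venc"]),
                voxel_size_mm=float(a["voxel_size_mm"]),
                cycle_s=float(a["cycle_s"]),
                seed=int(a["seed"]),
                meta=json.loads(a["meta_json"]),
            )


def grid_kspace(
    ktdata: KTDataset, n_frames: int, segment: int
) -> tuple[np.ndarray, np.ndarray]:
    """Grid the profile data of one segment into cardiac frames.

    Returns ``(y, mask)`` with ``y`` of shape (n_frames, n_coils, nx, ny, nz)
    and ``mask`` (n_frames, ny, nz).  Profiles falling on the same
    (ky, kz, frame) cell are averaged.
    """
    nx, ny, nz = ktdata.grid
    asg = ktdata.assignment(n_frames)
    acq = ktdata.timeline.acquired
    grp_sel = (acq["segment"] == 0).to_numpy()
    frames = asg.frames[grp_sel]
    iy = acq["ky"].to_numpy()[grp_sel] + ny // 2
    iz = acq["kz"].to_numpy()[grp_sel] + nz // 2
    ok = frames >= 0
    n_coils = ktdata.profiles.shape[2]
    cnt = np.zeros((n_frames, ny, nz), dtype=np.int32)
    cols = ktdata.profiles[:, segment]  # (groups, n_coils, nx)
    np.add.at(cnt, (frames[ok], iy[ok], iz[ok]), 1)
    # accumulate coil columns
    acc = np.zeros((n_frames, ny, nz, n_coils, nx), dtype=cols.dtype)
    np.add.at(acc, (frames[ok], iy[ok], iz[ok]), cols[ok])
    nz_cells = cnt > 0
    acc[nz_cells] /= cnt[nz_cells][:, None, None]
    y = np.moveaxis(acc, (1, 2), (3, 4))  # (frames, n_coils, nx, ny, nz)
    return y, nz_cells


# ---------------------------------------------------------------------------
# NIfTI / CSV / JSON helpers

def save_nifti(volume: np.ndarray, voxel_size_mm: float, path) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_flow_curve_csv(times: np.ndarray, flow: np.ndarray, path) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(flow)), "time_s": times, "flow_ml_per_s": flow}
    ).to_csv(path, index=False)


def load_flow_curve_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sidecar(path, **fields) -> None:
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=str)
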