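"""Pseudo-spiral golden-angle Cartesian sampling trajectories.

Phase-encode points (ky, kz) are ordered along quadratic ("pseudo-spiral")
arms on the Cartesian grid.  Each arm follows the polar law

    r_n = phi_n**2,    phi_n = n * 2*pi*T / N + offset,    n = 0..N,

with the radius normalised so the last sample reaches the boundary of the
(elliptical) k-space extent, then stretched anisotropically to the grid and
rounded to integer coordinates.  Consecutive arms are rotated by the golden
angle (~137.51 degrees), which yields a non-repeating, near-uniform angular
coverage and a variable-density pattern: dense at the k-space centre, sparse
at the periphery.

Grid convention: ky in [-floor(Nky/2), ceil(Nky/2)-1] and likewise for kz;
DC is index 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GOLDEN_ANGLE",
    "SpiralArmSpec",
    "Trajectory",
    "AccelerationAccount",
    "generate_spiral_arm",
    "golden_angle_offsets",
    "acceleration_factor",
    "elliptical_shutter_mask",
    "radial_density_profile",
    "write_trajectory",
    "read_trajectory",
]

#: Golden angle in radians: 2*pi*(1 - 1/phi) = 2*pi/phi**2 ~ 2.39996 rad
#: ~ 137.51 degrees.
GOLDEN_ANGLE = 2.0 * math.pi * (1.0 - 2.0 / (1.0 + math.sqrt(5.0)))


class InvalidSpecError(ValueError):
    """Raised for invalid trajectory specifications."""


@dataclass(frozen=True)
class SpiralArmSpec:
    """Parameters of one pseudo-spiral arm.

    Parameters
    ----------
    num_samples : int
        N, number of sampling intervals along the arm; the arm carries
        N + 1 raw polar samples with index n = 0..N.
    turns : float
        T, number of spiral turns.
    offset_angle : float
        Azimuthal offset (radians); rotates the arm but does not enter
        the radius law, so all arms share one radius profile.
    ky_extent, kz_extent : int
        Half-sizes of the phase-encode grid; the last sample of an arm
        lands on the inscribed ellipse with these semi-axes.
    """

    num_samples: int = 75
    turns: float = 3.0
    offset_angle: float = 0.0
    ky_extent: int = 55
    kz_extent: int = 12

    def __post_init__(self) -> None:
        if self.num_samples < 1:
            raise InvalidSpecError("num_samples must be >= 1")
        if self.turns <= 0:
            raise InvalidSpecError("turns must be > 0")
        if self.ky_extent < 1 or self.kz_extent < 1:
            raise InvalidSpecError("grid extents must be >= 1")


def generate_spiral_arm(spec: SpiralArmSpec, *, outer_in: bool = True) -> np.ndarray:
    """Generate one gridded spiral arm.

    Returns an integer array of shape (N + 1, 2) holding (ky, kz) pairs.
    Samples are generated centre-out by the polar law and, with
    ``outer_in=True`` (default), reversed so the arm is *acquired* from the
    k-space periphery inward.
    """
    n = np.arange(spec.num_samples + 1, dtype=float)
    phi_unrot = n * 2.0 * math.pi * spec.turns / spec.num_samples
    phi = phi_unrot + spec.offset_angle
    # quadratic radius law, normalised so n = N sits on the boundary ellipse
    r = phi_unrot**2
    r /= r[-1]
    ky = np.rint(r * spec.ky_extent * np.cos(phi)).astype(int)
    kz = np.rint(r * spec.kz_extent * np.sin(phi)).astype(int)
    arm = np.stack([ky, kz], axis=1)
    if outer_in:
        arm = arm[::-1]
    return arm


def golden_angle_offsets(num_arms: int) -> np.ndarray:
    """Offset angles for ``num_arms`` consecutive arms.

    offsets[0] = 0 by convention; consecutive offsets differ by the golden
    angle exactly (not reduced mod 2*pi).
    """
    if num_arms < 0:
        raise InvalidSpecError("num_arms must be >= 0")
    return np.arange(num_arms, dtype=float) * GOLDEN_ANGLE


@dataclass
class Trajectory:
    """An ordered multi-arm pseudo-spiral trajectory on the phase-encode grid."""

    arms: list[np.ndarray]
    arm_offsets: np.ndarray
    spec: SpiralArmSpec

    @property
    def num_arms(self) -> int:
        return len(self.arms)

    def flattened(self) -> np.ndarray:
        """All (arm_index, sample_index, ky, kz) rows in acquisition order."""
        rows = []
        for a, arm in enumerate(self.arms):
            idx = np.arange(arm.shape[0])
            rows.append(
                np.column_stack([np.full_like(idx, a), idx, arm[:, 0], arm[:, 1]])
            )
        return np.concatenate(rows, axis=0)


def generate_trajectory(
    num_arms: int,
    num_samples: int = 75,
    turns: float = 3.0,
    ky_extent: int = 55,
    kz_extent: int = 12,
    *,
    outer_in: bool = True,
) -> Trajectory:
    """Generate ``num_arms`` golden-angle-rotated spiral arms."""
    offsets = golden_angle_offsets(num_arms)
    arms = []
    for off in offsets:
        spec = SpiralArmSpec(
            num_samples=num_samples,
            turns=turns,
            offset_angle=float(off),
            ky_extent=ky_extent,
            kz_extent=kz_extent,
        )
        arms.append(generate_spiral_arm(spec, outer_in=outer_in))
    base = SpiralArmSpec(
        num_samples=num_samples,
        turns=turns,
        offset_angle=0.0,
        ky_extent=ky_extent,
        kz_extent=kz_extent,
    )
    return Trajectory(arms=arms, arm_offsets=offsets, spec=base)


@dataclass(frozen=True)
class AccelerationAccount:
    """Nominal acceleration accounting for a pseudo-spiral acquisition.

    R_proud = Nky * Nkz * Ncard * (pi/4) / Nproud compares against a
    theoretical fully sampled scan inside the elliptical shutter; R_true
    (census accounting, no pi/4 factor) divides the full Cartesian k-t grid
    by the frame-wise acquired count and is reported, not targeted.
    """

    Nky: int
    Nkz: int
    Ncard: int
    Nproud: int
    R_proud: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "R_proud", acceleration_factor(self.Nky, self.Nkz, self.Ncard, self.Nproud)
        )

    @property
    def nominal(self) -> int:
        return int(round(self.R_proud))


def acceleration_factor(Nky: int, Nkz: int, Ncard: int, Nproud: int) -> float:
    """Nominal acceleration R_proud = Nky*Nkz*Ncard*(pi/4)/Nproud."""
    if min(Nky, Nkz, Ncard) <= 0:
        raise InvalidSpecError("counts must be positive")
    if Nproud <= 0:
        raise ZeroDivisionError("Nproud must be positive")
    return Nky * Nkz * Ncard * (math.pi / 4.0) / Nproud


def true_acceleration_factor(Nky: int, Nkz: int, Ncard: int, n_acquired_cells: int) -> float:
    """Census acceleration: full Cartesian k-t grid over acquired cells."""
    if n_acquired_cells <= 0:
        raise ZeroDivisionError("acquired cell count must be positive")
    return Nky * Nkz * Ncard / n_acquired_cells


def elliptical_shutter_mask(Nky: int, Nkz: int) -> np.ndarray:
    """Boolean (Nky, Nkz) mask, True inside the inscribed ellipse.

    The covered fraction tends to pi/4 as the grid grows; omitting the
    corners is the elliptical k-space shutter.
    """
    if Nky < 1 or Nkz < 1:
        raise InvalidSpecError("grid sizes must be >= 1")
    ky = grid_coords(Nky)
    kz = grid_coords(Nkz)
    a = max(Nky / 2.0, 0.5)
    b = max(Nkz / 2.0, 0.5)
    e = (ky[:, None] / a) ** 2 + (kz[None, :] / b) ** 2
    return e <= 1.0


def grid_coords(n: int) -> np.ndarray:
    """Signed grid coordinates [-floor(n/2), ceil(n/2)-1] with DC at 0."""
    return np.arange(n) - n // 2


def radial_density_profile(
    traj: Trajectory | np.ndarray, n_bins: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Sample density versus normalised k-space radius (diagnostic).

    Returns (bin_edges, density) where density = count / annulus area in
    normalised-radius units.  Radius is normalised per-axis by the grid
    extents so the boundary ellipse maps to radius 1.
    """
    if isinstance(traj, Trajectory):
        pts = np.concatenate(traj.arms, axis=0)
        ky_ext, kz_ext = traj.spec.ky_extent, traj.spec.kz_extent
    else:
        pts = np.asarray(traj)
        ky_ext = max(int(np.abs(pts[:, 0]).max()), 1)
        kz_ext = max(int(np.abs(pts[:, 1]).max()), 1)
    if pts.size == 0:
        raise InvalidSpecError("empty trajectory")
    r = np.hypot(pts[:, 0] / ky_ext, pts[:, 1] / kz_ext)
    edges = np.linspace(0.0, max(1.0, r.max()) + 1e-12, n_bins + 1)
    counts, _ = np.histogram(r, bins=edges)
    area = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    return edges, counts / area


# ---------------------------------------------------------------------------
# trajectory text file (the coordinate list handed to the scanner)

def write_trajectory(traj: Trajectory, path) -> None:
    """Write the trajectory as a plain-text coordinate list.

    Header lines are ``# key=value``; one tab-separated row per sample:
    arm_index, sample_index, ky, kz.  Round-trips bit-exactly.
    """
    rows = traj.flattened()
    with open(path, "w") as fh:
        fh.write(f"# N={traj.spec.num_samples}\n")
        fh.write(f"# T={traj.spec.turns!r}\n")
        fh.write(f"# ky_extent={traj.spec.ky_extent}\n")
        fh.write(f"# kz_extent={traj.spec.kz_extent}\n")
        fh.write(f"# num_arms={traj.num_arms}\n")
        fh.write(f"# golden_angle_rad={GOLDEN_ANGLE!r}\n")
        fh.write("# columns=arm_index\tsample_index\tky\tkz\n")
        for r in rows:
            fh.write(f"{r[0]}\t{r[1]}\t{r[2]}\t{r[3]}\n")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory text file written by :func:`write_trajectory`."""
    header: dict[str, str] = {}
    data = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    header[k.strip()] = v.strip()
                continue
            data.append([int(x) for x in line.split("\t")])
    arr = np.asarray(data, dtype=int)
    num_arms = int(header["num_arms"])
    spec = SpiralArmSpec(
        num_samples=int(header["N"]),
        turns=float(header["T"]),
        offset_angle=0.0,
        ky_extent=int(header["ky_extent"]),
        kz_extent=int(header["kz_extent"]),
    )
    arms = []
    for a in range(num_arms):
        sel = arr[arr[:, 0] == a]
        sel = sel[np.argsort(sel[:, 1])]
        arms.append(sel[:, 2:4].copy())
    return Trajectory(arms=arms, arm_offsets=golden_angle_offsets(num_arms), spec=spec)
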