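"""k-t PCA comparator: sheared-lattice undersampling with training lines.

The comparator arm undersamples k-t space on a regular sheared Cartesian
lattice (phase-encode line ky acquired at frame t iff (ky + t) mod R = 0),
while a block of centre ky lines — the training data — is acquired at every
frame.  Low-resolution training images provide a temporal principal-component
basis; the aliased lattice data are then unfolded by Tikhonov-regularized
least squares constrained to that subspace:

    m(x, t) = sum_k w_k(x) b_k(t),
    min_w ||A(sum_k w_k b_k) - y||^2 + reg * sigma_n^2 * sum_k ||w_k||^2 / p_k

with p_k the per-component signal-power prior from the training PCA and
sigma_n^2 the measurement noise power (0 for noiseless input, in which case
the regularizer vanishes and the fit is plain subspace least squares).  The
normal equations are solved by conjugate gradients; the whole procedure is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cs import ImageSeries
from .phantom import SenseOperator

__all__ = ["KtPcaConfig", "lattice_mask", "add_training_lines", "ktpca_reconstruct"]


@dataclass(frozen=True)
class KtPcaConfig:
    """k-t PCA parameters: lattice R, training lines, regularization factor."""

    R: int = 8
    n_training_lines: int = 11
    regularization: float = 0.2
    n_components: int = 2
    cg_iterations: int = 30
    noise_var: float = 0.0  # measured noise power of y; 0 for noiseless data

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.n_components < 1:
            raise ValueError("need at least one principal component")


def lattice_mask(grid: tuple[int, int], n_frames: int, R: int) -> np.ndarray:
    """Sheared k-t lattice mask of shape (nky, nkz, n_frames).

    Line ky (array index) is sampled at frame t iff (ky + t) mod R = 0; kz is
    fully sampled per acquired line.  Exactly ~1/R of the ky lines per frame;
    the union over any R consecutive frames covers all of ky.  The frame
    count must be a multiple of R so the lattice phases tile the cycle.
    """
    nky, nkz = grid
    if n_frames % R != 0:
        raise ValueError(
            "the number of cardiac frames must be a multiple of the "
            f"acceleration factor (got {n_frames} frames, R={R})"
        )
    ky = np.arange(nky)[:, None]
    t = np.arange(n_frames)[None, :]
    lines = (ky + t) % R == 0
    return np.broadcast_to(lines[:, None, :], (nky, nkz, n_frames)).copy()


def add_training_lines(mask: np.ndarray, n_training: int) -> np.ndarray:
    """Set the ``n_training`` centre ky lines true at every frame."""
    nky = mask.shape[0]
    if n_training > nky:
        raise ValueError("more training lines than ky lines")
    out = mask.copy()
    if n_training == 0:
        return out
    lo, hi = _training_range(nky, n_training)
    out[lo:hi] = True
    return out


def _training_range(nky: int, n_training: int) -> tuple[int, int]:
    # centre block around the DC index nky//2
    lo = nky // 2 - n_training // 2
    return lo, lo + n_training


def effective_acceleration(mask: np.ndarray) -> float:
    """Census R_true of a k-t mask: total cells / acquired cells."""
    return mask.size / int(mask.sum())


def _temporal_basis(
    train_imgs: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the training image series.

    ``train_imgs``: (n_frames, nx, ny, nz) complex.  Returns (basis B of
    shape (n_frames, K), per-component mean signal power p_k).  Components
    are right singular vectors of the voxel x time matrix; the temporal mean
    is kept (the dominant component carries the static anatomy).
    """
    nf = train_imgs.shape[0]
    X = train_imgs.reshape(nf, -1)  # time x voxel
    # SVD of the time-by-voxel matrix; temporal modes are left vectors
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(s))
    B = U[:, :k]
    power = (s[:k] ** 2) / X.shape[1]
    return B, power


def ktpca_reconstruct(
    y: np.ndarray,
    masks: np.ndarray,
    smaps: np.ndarray,
    config: KtPcaConfig | None = None,
    *,
    voxel_size_mm: float = 2.5,
    frame_duration_s: float | None = None,
) -> ImageSeries:
    """Reconstruct lattice + training k-t data in the PCA subspace.

    ``y``: (n_frames, n_segments, n_coils, nx, ny, nz) gridded k-space,
    sampled on ``masks`` (nky=ny, nkz=nz, n_frames) — the same mask applies
    to every segment (the lattice is segment-independent).  Training lines
    must be present in the mask at every frame.
    """
    config = config or KtPcaConfig()
    n_frames, n_seg = y.shape[:2]
    nky = masks.shape[0]
    if config.n_training_lines < config.n_components:
        raise ValueError("fewer training lines than requested components")
    lo, hi = _training_range(nky, config.n_training_lines)
    if not masks[lo:hi].all():
        raise ValueError("training lines missing from the sampling mask")
    frame_masks = np.moveaxis(masks, 2, 0)  # (n_frames, ny, nz)
    train_mask = np.zeros_like(frame_masks)
    train_mask[:, lo:hi, :] = True

    out = np.zeros((n_frames, n_seg) + y.shape[3:], dtype=complex)
    for d in range(n_seg):
        train_op = SenseOperator(smaps, train_mask)
        train_imgs = train_op.adjoint(y[:, d] * train_mask[:, None, None])
        B, power = _temporal_basis(train_imgs, config.n_components)
        out[:, d] = _unfold_segment(y[:, d], frame_masks, smaps, B, power, config)
    return ImageSeries(
        data=out,
        voxel_size_mm=voxel_size_mm,
        frame_duration_s=frame_duration_s or 1.0 / n_frames,
        meta={
            "method": "kt-pca",
            "R": config.R,
            "n_training_lines": config.n_training_lines,
            "regularization": config.regularization,
            "n_components": config.n_components,
        },
    )


def _unfold_segment(
    y: np.ndarray,
    frame_masks: np.ndarray,
    smaps: np.ndarray,
    B: np.ndarray,
    power: np.ndarray,
    config: KtPcaConfig,
) -> np.ndarray:
    """CG solve of the subspace normal equations for one segment."""
    op = SenseOperator(smaps, frame_masks)
    K = B.shape[1]
    grid = smaps.shape[1:]
    tik = config.regularization * config.noise_var / np.maximum(power, 1e-30)

    def expand(w):  # (K, *grid) -> (n_frames, *grid)
        return np.tensordot(B, w, axes=(1, 0))

    def contract(m):  # adjoint of expand
        return np.tensordot(np.conj(B).T, m, axes=(1, 0))

    def normal(w):
        return contract(op.adjoint(op.forward(expand(w)))) + tik[
            (slice(None),) + (None,) * len(grid)
        ] * w

    rhs = contract(op.adjoint(y))
    w = np.zeros((K,) + grid, dtype=complex)
    r = rhs - normal(w)
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    rhs_norm = float(np.vdot(rhs, rhs).real)
    for _ in range(config.cg_iterations):
        if rhs_norm == 0 or rs / rhs_norm < 1e-18:
            break
        Ap = normal(p)
        alpha = rs / float(np.vdot(p, Ap).real)
        w += alpha * p
        r -= alpha * Ap
        rs_new = float(np.vdot(r, r).real)
        p = r + (rs_new / rs) * p
        rs = rs_new
    return expand(w)
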