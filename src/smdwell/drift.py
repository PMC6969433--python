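"""Lateral stage-drift estimation and correction.

Drift is estimated from the localization table itself: frames are grouped
into temporal blocks, each block is rendered as a super-resolution 2D
histogram, and every block is registered to the first by sub-pixel phase
cross-correlation (redundant registration to block 0, not chained, so
errors do not accumulate).  Block shifts are interpolated linearly between
block centers to give a per-frame trajectory, extended linearly at the
ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = ["DriftTrajectory", "estimate_drift", "apply_drift"]


@dataclass
class DriftTrajectory:
    """Per-frame (dx, dy) displacement relative to frame 0, in pixels."""

    dx_px: np.ndarray
    dy_px: np.ndarray

    def __post_init__(self) -> None:
        self.dx_px = np.asarray(self.dx_px, dtype=float)
        self.dy_px = np.asarray(self.dy_px, dtype=float)
        if self.dx_px.shape != self.dy_px.shape or self.dx_px.ndim != 1:
            raise ValueError("dx_px and dy_px must be 1D arrays of equal length")
        if not (np.all(np.isfinite(self.dx_px)) and np.all(np.isfinite(self.dy_px))):
            raise ValueError("trajectory must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.dx_px)

    def __neg__(self) -> "DriftTrajectory":
        return DriftTrajectory(-self.dx_px, -self.dy_px)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(self.n_frames), "dx_px": self.dx_px, "dy_px": self.dy_px}
        )

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "DriftTrajectory":
        table = table.sort_values("frame")
        return cls(table["dx_px"].to_numpy(), table["dy_px"].to_numpy())


def _block_histogram(
    locs: pd.DataFrame, shape: tuple[int, int], zoom: int, blur_bins: float = 1.0
) -> np.ndarray:
    h, w = shape
    img, _, _ = np.histogram2d(
        locs["y_px"].to_numpy(),
        locs["x_px"].to_numpy(),
        bins=(h * zoom, w * zoom),
        range=((0, h), (0, w)),
    )
    # a little blur makes sparse point histograms overlap under small shifts
    return gaussian_filter(img, blur_bins)


def _masked_cc_shift(
    ref: np.ndarray,
    img: np.ndarray,
    center_bins: tuple[float, float],
    half_width_bins: int,
) -> tuple[float, float]:
    """Sub-bin (dy, dx) such that ``img ~ ref shifted by (dy, dx)``.

    Cross-correlation via FFT, with the admissible shift restricted to a
    window of ``+/- half_width_bins`` around ``center_bins`` — stage
    drift is continuous, so each block's shift lies near the previous
    block's, and sparse localization histograms of *different* molecule
    sets otherwise produce spurious distant correlation peaks.  The
    integer peak is refined per axis by parabolic interpolation.
    """
    H, W = ref.shape
    prod = np.fft.fft2(img) * np.conj(np.fft.fft2(ref))
    cc = np.fft.fftshift(np.fft.ifft2(prod).real)
    cy0, cx0 = H // 2, W // 2
    m = half_width_bins
    cy = cy0 + int(round(center_bins[0]))
    cx = cx0 + int(round(center_bins[1]))
    ylo, yhi = max(0, cy - m), min(cc.shape[0], cy + m + 1)
    xlo, xhi = max(0, cx - m), min(cc.shape[1], cx + m + 1)
    window = cc[ylo:yhi, xlo:xhi]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    dy0 = iy + ylo - cy0
    dx0 = ix + xlo - cx0

    # refine by evaluating the cross-correlation on a 0.05-bin grid around
    # the integer peak via matrix-multiply DFT (avoids the pixel-locking
    # bias of fitting a parabola to a peaked pedestal)
    fine = np.arange(-1.0, 1.0 + 1e-9, 0.05)
    ky = np.fft.fftfreq(H)[:, None]  # cycles per sample
    kx = np.fft.fftfreq(W)[:, None]
    ey = np.exp(2j * np.pi * ky * (dy0 + fine)[None, :])  # (H, n_fine)
    ex = np.exp(2j * np.pi * kx * (dx0 + fine)[None, :])  # (W, n_fine)
    cc_fine = np.real(ey.T @ prod @ ex)
    jy, jx = np.unravel_index(np.argmax(cc_fine), cc_fine.shape)
    return float(dy0 + fine[jy]), float(dx0 + fine[jx])


def estimate_drift(
    localizations: pd.DataFrame,
    n_frames: int,
    shape: tuple[int, int],
    block_frames: int = 250,
    zoom: int = 5,
    min_locs_per_block: int = 50,
    max_step_px: float = 3.0,
) -> DriftTrajectory:
    """Estimate a per-frame drift trajectory from localizations.

    Frames are grouped into ``n_frames // block_frames`` complete blocks
    (at least two required); each block's super-resolution histogram is
    registered to block 0 by windowed cross-correlation.  Because stage
    drift is continuous, the correlation peak for block ``b`` is searched
    within ``+/- max_step_px`` of block ``b-1``'s estimate; this rules out
    the spurious distant peaks that sparse histograms of different
    molecule sets produce, while still allowing arbitrarily large
    cumulative drift.  Raises if any block holds fewer than
    ``min_locs_per_block`` localizations, since the registration would be
    unreliable.
    """
    n_blocks = n_frames // block_frames
    if n_blocks < 2:
        raise ValueError(
            f"need >= 2 complete blocks of {block_frames} frames, have {n_blocks}"
        )
    frames = localizations["frame"].to_numpy()
    block_dx = np.zeros(n_blocks)
    block_dy = np.zeros(n_blocks)
    block_centers = block_frames * np.arange(n_blocks) + (block_frames - 1) / 2.0

    ref = None
    for b in range(n_blocks):
        sel = (frames >= b * block_frames) & (frames < (b + 1) * block_frames)
        block_locs = localizations[sel]
        if len(block_locs) < min_locs_per_block:
            raise ValueError(
                f"block {b} has only {len(block_locs)} localizations "
                f"(< {min_locs_per_block}); drift registration unreliable"
            )
        img = _block_histogram(block_locs, shape, zoom)
        if b == 0:
            ref = img
            continue
        dy, dx = _masked_cc_shift(
            ref,
            img,
            center_bins=(block_dy[b - 1] * zoom, block_dx[b - 1] * zoom),
            half_width_bins=max(1, int(round(max_step_px * zoom))),
        )
        block_dy[b] = dy / zoom
        block_dx[b] = dx / zoom

    all_frames = np.arange(n_frames, dtype=float)
    dx = _interp_extrapolate(all_frames, block_centers, block_dx)
    dy = _interp_extrapolate(all_frames, block_centers, block_dy)
    # trajectory is relative to frame 0 by construction of block 0; pin exactly
    dx -= dx[0]
    dy -= dy[0]
    return DriftTrajectory(dx, dy)


def _interp_extrapolate(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Linear interpolation with linear (first/last-segment slope) extension."""
    out = np.interp(x, xp, fp)
    if len(xp) >= 2:
        left = x < xp[0]
        right = x > xp[-1]
        slope_l = (fp[1] - fp[0]) / (xp[1] - xp[0])
        slope_r = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        out[left] = fp[0] + slope_l * (x[left] - xp[0])
        out[right] = fp[-1] + slope_r * (x[right] - xp[-1])
    return out


def apply_drift(localizations: pd.DataFrame, trajectory: DriftTrajectory) -> pd.DataFrame:
    """Subtract the drift trajectory from localization positions.

    Row order and count are preserved; raises if any frame index falls
    outside the trajectory.
    """
    frames = localizations["frame"].to_numpy().astype(int)
    if len(frames) and (frames.min() < 0 or frames.max() >= trajectory.n_frames):
        raise ValueError("localization frame index outside drift trajectory")
    out = localizations.copy()
    out["x_px"] = out["x_px"].to_numpy() - trajectory.dx_px[frames]
    out["y_px"] = out["y_px"].to_numpy() - trajectory.dy_px[frames]
    return out
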