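"""Sub-pixel spot detection and Gaussian localization.

A transparent detect / fit / subtract loop in the spirit of high-density
single-molecule localization algorithms: per frame, candidate peaks are
found on a background-subtracted, smoothed image; nearby candidates are
fit *jointly* as a cluster of pixel-integrated 2D Gaussians with a shared
local offset; fitted spots are subtracted, and detection is repeated to
recover emitters merged in the first pass.  The output is a localization
table (frame, sub-pixel x/y, photons, PSF width, local offset, residual).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, gaussian_filter
from scipy.optimize import least_squares
from scipy.special import erf
from skimage.feature import peak_local_max

from .frames import FrameStack

__all__ = [
    "Localization",
    "LocalizeParams",
    "estimate_background",
    "robust_noise_sd",
    "detect_candidates",
    "fit_spot",
    "localize_stack",
    "write_localizations",
    "read_localizations",
]

logger = logging.getLogger(__name__)

LOC_COLUMNS = ["frame", "x_px", "y_px", "photons", "sigma_px", "offset", "rss"]


@dataclass(frozen=True)
class Localization:
    """One sub-pixel spot detection in one frame."""

    frame: int
    x_px: float
    y_px: float
    photons: float
    sigma_px: float
    offset: float
    rss: float


@dataclass(frozen=True)
class LocalizeParams:
    """Detection/fitting parameters; defaults suit low-power EMCCD imaging."""

    k_sigma: float = 5.0  # detection threshold in robust noise SDs
    roi_px: int = 7  # fitting window (odd)
    psf_sigma_px: float = 1.3  # fixed PSF width
    fit_sigma: bool = False  # free the PSF width during fitting
    bg_window_px: int = 15  # median-filter window for background
    smooth_sigma_px: float = 1.0  # matched-ish filter before peak finding
    max_subtraction_rounds: int = 2
    min_separation_px: int = 2
    exclude_border_px: int = 2  # border spots cannot be fit reliably


def estimate_background(frame: np.ndarray, window_px: int = 15) -> np.ndarray:
    """Per-pixel median-filtered background (robust to sparse bright spots)."""
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    return median_filter(np.asarray(frame, dtype=float), size=window_px)


def robust_noise_sd(residual: np.ndarray) -> float:
    """Noise SD from the median absolute deviation (spot-contaminated safe)."""
    r = np.asarray(residual, dtype=float)
    return float(1.4826 * np.median(np.abs(r - np.median(r))))


def detect_candidates(
    frame: np.ndarray,
    background: np.ndarray,
    k_sigma: float = 5.0,
    smooth_sigma_px: float = 1.0,
    min_separation_px: int = 2,
    exclude_border_px: int = 2,
) -> np.ndarray:
    """Integer (row, col) candidate peaks above ``k_sigma`` x noise.

    The background-subtracted frame is Gaussian-smoothed; local maxima
    exceeding ``k_sigma`` times the robust noise SD of the smoothed
    residual are kept, with peaks closer than ``min_separation_px`` merged
    to the brighter one.  A ``exclude_border_px`` margin is skipped: the
    reflect-padded filters inflate the noise there and a spot that close
    to the edge cannot be fit reliably.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    residual = np.asarray(frame, dtype=float) - background
    smoothed = gaussian_filter(residual, smooth_sigma_px)
    sd = robust_noise_sd(smoothed)
    threshold = k_sigma * sd if sd > 0 else k_sigma * np.finfo(float).tiny
    peaks = peak_local_max(
        smoothed,
        min_distance=min_separation_px,
        threshold_abs=threshold,
        exclude_border=exclude_border_px if exclude_border_px > 0 else False,
    )
    return peaks  # (n, 2) array of (row, col)


def _integrated_gaussian_1d(coords: np.ndarray, center: float, sigma: float) -> np.ndarray:
    s = sigma * math.sqrt(2.0)
    return 0.5 * (erf((coords + 0.5 - center) / s) - erf((coords - 0.5 - center) / s))


def _spot_image(
    photons: float, x0: float, y0: float, sigma: float,
    xs: np.ndarray, ys: np.ndarray,
) -> np.ndarray:
    return photons * np.outer(
        _integrated_gaussian_1d(ys, y0, sigma), _integrated_gaussian_1d(xs, x0, sigma)
    )


def _fit_cluster(
    frame: np.ndarray,
    background: np.ndarray,
    peaks: np.ndarray,
    frame_index: int,
    roi_px: int,
    fixed_sigma: float | None,
) -> list[Localization | str]:
    """Jointly fit one or more nearby peaks with a shared local offset.

    Each spot contributes (photons, x, y) free parameters; the PSF width
    is shared (fixed or fitted).  Amplitudes are unconstrained during the
    fit so that non-spots resolve to non-positive photons and can be
    rejected.  Returns one entry per input peak: a :class:`Localization`
    or a rejection reason (``diverged`` | ``out-of-roi`` |
    ``negative-amplitude``).
    """
    h, w = frame.shape
    half = roi_px // 2
    ylo = max(0, int(peaks[:, 0].min()) - half)
    yhi = min(h, int(peaks[:, 0].max()) + half + 1)
    xlo = max(0, int(peaks[:, 1].min()) - half)
    xhi = min(w, int(peaks[:, 1].max()) + half + 1)
    if yhi - ylo < 3 or xhi - xlo < 3:
        return ["out-of-roi"] * len(peaks)
    data = np.asarray(frame, dtype=float)[ylo:yhi, xlo:xhi]
    bg = np.asarray(background, dtype=float)[ylo:yhi, xlo:xhi]
    xs = np.arange(xlo, xhi)
    ys = np.arange(ylo, yhi)
    n_spots = len(peaks)
    sigma0 = fixed_sigma if fixed_sigma is not None else 1.3
    free_sigma = fixed_sigma is None

    theta0, lower, upper = [], [], []
    amp0 = max(float((data - bg).sum()) / n_spots, 1.0)
    for row, col in peaks:
        theta0 += [amp0, float(col), float(row)]
        lower += [-np.inf, xlo - 0.5, ylo - 0.5]
        upper += [np.inf, xhi - 0.5, yhi - 0.5]
    if free_sigma:
        theta0.append(sigma0)
        lower.append(0.3)
        upper.append(10.0)
    theta0.append(float(np.median(bg)))  # offset
    lower.append(-np.inf)
    upper.append(np.inf)

    def residuals(theta):
        model = np.full_like(data, theta[-1])
        sigma = theta[3 * n_spots] if free_sigma else sigma0
        for j in range(n_spots):
            a, x0, y0 = theta[3 * j : 3 * j + 3]
            model = model + _spot_image(a, x0, y0, sigma, xs, ys)
        return (model - data).ravel()

    try:
        sol = least_squares(residuals, theta0, bounds=(lower, upper), method="trf")
    except Exception:
        return ["diverged"] * n_spots
    if not sol.success or not np.all(np.isfinite(sol.x)):
        return ["diverged"] * n_spots
    sigma = float(sol.x[3 * n_spots]) if free_sigma else sigma0
    offset = float(sol.x[-1])
    rss = float(np.sum(sol.fun**2))
    out: list[Localization | str] = []
    for j in range(n_spots):
        photons, x0, y0 = sol.x[3 * j : 3 * j + 3]
        if photons <= 0:
            out.append("negative-amplitude")
        elif not (xlo - 0.5 <= x0 <= xhi - 0.5 and ylo - 0.5 <= y0 <= yhi - 0.5):
            out.append("out-of-roi")
        else:
            out.append(
                Localization(
                    frame=frame_index,
                    x_px=float(np.clip(x0, 0.0, w - 1e-9)),
                    y_px=float(np.clip(y0, 0.0, h - 1e-9)),
                    photons=float(photons),
                    sigma_px=sigma,
                    offset=offset,
                    rss=rss,
                )
            )
    return out


def fit_spot(
    frame: np.ndarray,
    background: np.ndarray,
    peak: tuple[int, int],
    frame_index: int = 0,
    roi_px: int = 7,
    fixed_sigma: float | None = 1.3,
) -> Localization | str:
    """Least-squares pixel-integrated Gaussian fit around one peak.

    Returns a :class:`Localization`, or a rejection reason
    (``"diverged"`` | ``"out-of-roi"`` | ``"negative-amplitude"``).
    The ROI is shrunk at frame borders.
    """
    return _fit_cluster(
        frame,
        background,
        np.asarray([peak], dtype=int),
        frame_index,
        roi_px,
        fixed_sigma,
    )[0]


def _cluster_peaks(peaks: np.ndarray, link_dist: float) -> list[np.ndarray]:
    """Single-linkage clusters of peaks closer than ``link_dist``."""
    n = len(peaks)
    unvisited = set(range(n))
    clusters = []
    while unvisited:
        stack = [unvisited.pop()]
        members = [stack[0]]
        while stack:
            i = stack.pop()
            near = [
                j
                for j in list(unvisited)
                if np.hypot(*(peaks[i] - peaks[j])) <= link_dist
            ]
            for j in near:
                unvisited.remove(j)
                stack.append(j)
                members.append(j)
        clusters.append(peaks[sorted(members)])
    return clusters


def _subtract_spots(frame: np.ndarray, locs: list[Localization]) -> np.ndarray:
    """Original frame minus all fitted spot images (offsets excluded)."""
    working = frame.copy()
    h, w = frame.shape
    for loc in locs:
        pad = int(math.ceil(4 * loc.sigma_px)) + 1
        xlo, xhi = max(0, int(loc.x_px) - pad), min(w, int(loc.x_px) + pad + 1)
        ylo, yhi = max(0, int(loc.y_px) - pad), min(h, int(loc.y_px) + pad + 1)
        working[ylo:yhi, xlo:xhi] -= _spot_image(
            loc.photons, loc.x_px, loc.y_px, loc.sigma_px,
            np.arange(xlo, xhi), np.arange(ylo, yhi),
        )
    return working


def _localize_frame(
    frame: np.ndarray,
    background: np.ndarray,
    frame_index: int,
    params: LocalizeParams,
    fixed_sigma: float | None,
) -> list[Localization]:
    """Iterative detect / joint-fit / subtract loop for one frame.

    Each round detects peaks in the residual of the current model, adds
    them to the candidate set, and refits *all* candidates jointly against
    the original frame — so emitters merged into one fit in round one are
    teased apart once their residual shows up.
    """
    accepted: list[Localization] = []
    working = frame
    for _ in range(params.max_subtraction_rounds):
        peaks = detect_candidates(
            working,
            background,
            params.k_sigma,
            params.smooth_sigma_px,
            params.min_separation_px,
            params.exclude_border_px,
        )
        # keep only residual peaks not already explained by a fitted spot
        fresh = [
            p
            for p in peaks
            if all(
                np.hypot(p[1] - loc.x_px, p[0] - loc.y_px) >= params.min_separation_px
                for loc in accepted
            )
        ]
        if not fresh:
            break
        seeds = np.array(
            [[loc.y_px, loc.x_px] for loc in accepted] + [list(p) for p in fresh]
        )
        new_accepted: list[Localization] = []
        for cluster in _cluster_peaks(seeds, float(params.roi_px)):
            for loc in _fit_cluster(
                frame, background, cluster, frame_index, params.roi_px, fixed_sigma
            ):
                if isinstance(loc, Localization):
                    new_accepted.append(loc)
        # drop near-duplicates (degenerate splits), keeping the brighter
        new_accepted.sort(key=lambda l: -l.photons)
        deduped: list[Localization] = []
        for loc in new_accepted:
            if all(
                np.hypot(loc.x_px - k.x_px, loc.y_px - k.y_px) >= 1.0 for k in deduped
            ):
                deduped.append(loc)
        if not deduped:
            break
        accepted = deduped
        working = _subtract_spots(frame, accepted)
    return accepted


def localize_stack(stack: FrameStack, params: LocalizeParams | None = None) -> pd.DataFrame:
    """Localize every frame of a stack with iterative spot subtraction.

    Per frame: detect candidates, jointly fit clusters of nearby
    candidates, subtract the fitted Gaussians (without their offsets) from
    a working copy, and repeat up to ``max_subtraction_rounds`` to recover
    emitters merged in round one.  Frames where localization fails
    outright are logged and skipped, never silently dropped.

    Returns a DataFrame with columns
    ``frame, x_px, y_px, photons, sigma_px, offset, rss`` sorted by
    (frame, y_px, x_px).  Deterministic: no hidden randomness.
    """
    params = params or LocalizeParams()
    fixed_sigma = None if params.fit_sigma else params.psf_sigma_px
    rows: list[Localization] = []
    for f in range(stack.n_frames):
        frame = stack.data[f].astype(float)
        try:
            background = estimate_background(frame, params.bg_window_px)
            rows.extend(_localize_frame(frame, background, f, params, fixed_sigma))
        except Exception:
            logger.exception("frame %d failed to localize; skipped", f)
            continue
    table = pd.DataFrame([l.__dict__ for l in rows], columns=LOC_COLUMNS)
    return table.sort_values(["frame", "y_px", "x_px"], kind="mergesort").reset_index(
        drop=True
    )


def write_localizations(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_localizations(path) -> pd.DataFrame:
    return pd.read_csv(path)
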