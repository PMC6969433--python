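"""Synthetic single-molecule TIRFM data with known ground truth.

This module generates the data the analysis pipeline assumes: sparse
diffraction-limited spots appearing on linear fibril tracks and on the
background, with residence times drawn from a mixture of exponentials,
photobleaching acting as a competing exponential-mixture clock, optional
blinking, lateral stage drift, Poisson shot noise and Gaussian camera read
noise.  Every draw is reproducible from the seed carried by
:class:`SimulationTruth`.

The key photophysical assumption: a bound fluorophore disappears at the
*earlier* of unbinding and photobleaching, so the observed dwell is
``min(true_dwell, bleach_draw)``.  "Immobilized" populations have infinite
true dwell; their observed dwell is entirely set by the bleach model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import erf
from scipy.ndimage import binary_dilation
from skimage.draw import line as draw_line

from .frames import FrameStack, DEFAULT_PIXEL_NM, DEFAULT_FRAME_INTERVAL_S

__all__ = [
    "PopulationSpec",
    "BleachModel",
    "SimulationTruth",
    "TrueEvent",
    "simulate_event_list",
    "make_fibril_geometry",
    "render_movie",
    "events_to_table",
    "write_truth_table",
    "read_truth_table",
]

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class PopulationSpec:
    """One kinetic population of bound molecules.

    ``fraction`` is the share of binding events drawn from this population;
    ``tau_s`` its characteristic residence time (exponential mean).  An
    ``immobilized`` population never unbinds within any observation window:
    its true dwell is infinite and its observed dwell is set by
    photobleaching alone.
    """

    fraction: float
    tau_s: float | None = None
    immobilized: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.immobilized:
            if self.tau_s is not None:
                raise ValueError("immobilized populations take no tau_s")
        elif self.tau_s is None or self.tau_s <= 0:
            raise ValueError("tau_s must be > 0 for a non-immobilized population")


@dataclass(frozen=True)
class BleachModel:
    """Mixture-of-exponentials photobleach survival of the fluorophore label.

    Cy5 under the oxygen-scavenging buffer used for binding-time imaging
    decays with lifetimes 195 s and 1100 s; without scavenging, 5 s and
    20 s.  Mixture weights are not separately known and default to equal.
    """

    lifetimes_s: tuple[float, ...] = (195.0, 1100.0)
    weights: tuple[float, ...] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if len(self.lifetimes_s) != len(self.weights):
            raise ValueError("lifetimes_s and weights must have equal length")
        if any(t <= 0 for t in self.lifetimes_s):
            raise ValueError("bleach lifetimes must be positive")
        if any(w < 0 for w in self.weights):
            raise ValueError("bleach weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > _FRACTION_TOL:
            raise ValueError("bleach weights must sum to 1")

    @classmethod
    def oxygen_scavenged(cls) -> "BleachModel":
        """Cy5 under glucose-oxidase/catalase/Trolox imaging buffer."""
        return cls((195.0, 1100.0), (0.5, 0.5))

    @classmethod
    def unscavenged(cls) -> "BleachModel":
        """Cy5 in plain buffer (no oxygen scavenging)."""
        return cls((5.0, 20.0), (0.5, 0.5))

    @classmethod
    def disabled(cls) -> "BleachModel":
        """No photobleaching (infinite lifetime)."""
        return cls((math.inf,), (1.0,))

    @property
    def mean_s(self) -> float:
        return float(sum(w * t for w, t in zip(self.weights, self.lifetimes_s)))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` bleach times from the mixture."""
        comp = rng.choice(len(self.lifetimes_s), size=n, p=self.weights)
        out = np.empty(n)
        for j, tau in enumerate(self.lifetimes_s):
            sel = comp == j
            if math.isinf(tau):
                out[sel] = math.inf
            else:
                out[sel] = rng.exponential(tau, size=int(sel.sum()))
        return out

    def survival(self, t: np.ndarray) -> np.ndarray:
        """Mixture survival function S(t)."""
        t = np.asarray(t, dtype=float)
        s = np.zeros_like(t)
        for w, tau in zip(self.weights, self.lifetimes_s):
            s += w * (np.ones_like(t) if math.isinf(tau) else np.exp(-t / tau))
        return s


@dataclass
class SimulationTruth:
    """Generative parameters for one synthetic experiment.

    Defaults reflect the imaging conditions assumed throughout the package:
    1 s frames, 220 nm pixels, 2500-frame observation windows, sparse
    arrivals, and Cy5 photobleaching under oxygen scavenging.
    """

    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec(0.81, 15.0),
            PopulationSpec(0.19, immobilized=True),
        ]
    )
    populations_bg: list[PopulationSpec] | None = None
    arrival_rate_fibril: float = 0.5  # events per frame landing on fibril support
    arrival_rate_bg: float = 0.0  # events per frame landing on background
    n_frames: int = 2500
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    pixel_nm: float = DEFAULT_PIXEL_NM
    image_shape: tuple[int, int] = (256, 256)
    psf_sigma_px: float = 1.3
    photons_per_frame: float = 500.0
    bg_photons_px: float = 5.0
    read_noise: float = 1.0
    blink_off_prob: float = 0.0
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    bleach: BleachModel = field(default_factory=BleachModel.oxygen_scavenged)
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.arrival_rate_fibril < 0 or self.arrival_rate_bg < 0:
            raise ValueError("arrival rates must be non-negative")
        for pops in (self.populations, self.populations_bg):
            if pops is not None:
                total = sum(p.fraction for p in pops)
                if abs(total - 1.0) > _FRACTION_TOL:
                    raise ValueError(
                        f"population fractions must sum to 1, got {total!r}"
                    )

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass
class TrueEvent:
    """Ground truth for one binding event."""

    x_px: float
    y_px: float
    start_frame: int
    true_dwell_s: float
    observed_dwell_s: float
    n_frames_obs: int
    population_id: int
    region: str  # "fibril" | "background"


def _draw_dwells(
    rng: np.random.Generator,
    populations: list[PopulationSpec],
    bleach: BleachModel,
    n: int,
    frame_interval_s: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    fractions = np.array([p.fraction for p in populations])
    pop_id = rng.choice(len(populations), size=n, p=fractions / fractions.sum())
    true_dwell = np.empty(n)
    for j, pop in enumerate(populations):
        sel = pop_id == j
        k = int(sel.sum())
        if pop.immobilized:
            true_dwell[sel] = math.inf
        else:
            true_dwell[sel] = rng.exponential(pop.tau_s, size=k)
    bleach_time = bleach.sample(rng, n)
    observed = np.minimum(true_dwell, bleach_time)
    if np.any(~np.isfinite(observed)):
        # immobilized molecule with bleaching disabled: visible to end of time;
        # cap at an effectively infinite dwell so frame math stays integral
        observed = np.where(np.isfinite(observed), observed, 1e12)
    n_frames_obs = np.maximum(1, np.ceil(observed / frame_interval_s)).astype(np.int64)
    return pop_id, true_dwell, observed, n_frames_obs


def simulate_event_list(
    truth: SimulationTruth,
    fibril_mask: np.ndarray | None = None,
) -> list[TrueEvent]:
    """Draw a ground-truth binding-event list.

    Arrivals are Poisson over the observation window, uniform over frames
    and over the spatial support (the fibril mask for fibril events, its
    complement for background events; the whole field if no mask is given).
    Each event's true dwell is exponential with its population's time
    constant (infinite for immobilized populations), the observed dwell is
    the minimum of the true dwell and a photobleach draw, and the event is
    visible for ``ceil(observed / frame_interval)`` frames (minimum 1).
    """
    rng = np.random.default_rng(truth.seed)
    h, w = truth.image_shape
    if fibril_mask is not None:
        fibril_mask = np.asarray(fibril_mask, dtype=bool)
        if fibril_mask.shape != (h, w):
            raise ValueError("fibril_mask shape must match truth.image_shape")

    events: list[TrueEvent] = []
    for region, rate, pops in (
        ("fibril", truth.arrival_rate_fibril, truth.populations),
        ("background", truth.arrival_rate_bg, truth.populations_bg or truth.populations),
    ):
        n = int(rng.poisson(rate * truth.n_frames))
        if n == 0:
            continue
        start = rng.integers(0, truth.n_frames, size=n)
        if fibril_mask is None:
            x = rng.uniform(0, w, size=n)
            y = rng.uniform(0, h, size=n)
        else:
            support = fibril_mask if region == "fibril" else ~fibril_mask
            ys, xs = np.nonzero(support)
            if ys.size == 0:
                warnings.warn(f"no support pixels for region {region!r}; skipped")
                continue
            pick = rng.integers(0, ys.size, size=n)
            # jitter uniformly within the chosen pixel (centers at integers)
            x = xs[pick] + rng.uniform(-0.5, 0.5, size=n)
            y = ys[pick] + rng.uniform(-0.5, 0.5, size=n)
        pop_id, true_dwell, observed, n_frames_obs = _draw_dwells(
            rng, pops, truth.bleach, n, truth.frame_interval_s
        )
        for i in range(n):
            events.append(
                TrueEvent(
                    x_px=float(x[i]),
                    y_px=float(y[i]),
                    start_frame=int(start[i]),
                    true_dwell_s=float(true_dwell[i]),
                    observed_dwell_s=float(observed[i]),
                    n_frames_obs=int(n_frames_obs[i]),
                    population_id=int(pop_id[i]),
                    region=region,
                )
            )
    events.sort(key=lambda e: (e.start_frame, e.y_px, e.x_px))
    return events


def make_fibril_geometry(
    seed: int,
    n_fibrils: int,
    image_shape: tuple[int, int],
    width_px: tuple[int, int] = (1, 2),
    min_length_px: float = 30.0,
    max_tries: int = 200,
) -> tuple[np.ndarray, list[dict]]:
    """Lay random, non-touching line segments as a fibril support mask.

    Emulates isolated cellulose fibrils settled in random orientations:
    straight segments 1-2 px wide (fibrils are far thinner than a pixel;
    width here is the rasterized support, not a physical diameter).

    Returns the boolean mask and a segment list of dicts with keys
    ``x0, y0, x1, y1, width_px``.
    """
    h, w = image_shape
    if h <= 0 or w <= 0:
        raise ValueError("image_shape must be positive")
    rng = np.random.default_rng(seed)
    mask = np.zeros((h, w), dtype=bool)
    # forbid segments touching a 2 px halo of existing ones so components
    # stay separate and countable
    halo = np.zeros_like(mask)
    segments: list[dict] = []
    tries = 0
    while len(segments) < n_fibrils and tries < max_tries * max(1, n_fibrils):
        tries += 1
        y0, x0 = rng.integers(2, h - 2), rng.integers(2, w - 2)
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(min_length_px, max(min_length_px + 1, min(h, w) * 0.8))
        y1 = int(np.clip(round(y0 + length * np.sin(angle)), 2, h - 3))
        x1 = int(np.clip(round(x0 + length * np.cos(angle)), 2, w - 3))
        if np.hypot(y1 - y0, x1 - x0) < min_length_px / 2:
            continue
        width = int(rng.integers(width_px[0], width_px[1] + 1))
        seg = np.zeros_like(mask)
        rr, cc = draw_line(int(y0), int(x0), y1, x1)
        seg[rr, cc] = True
        for _ in range(width - 1):
            seg = binary_dilation(seg)
        if np.any(seg & halo):
            continue
        mask |= seg
        halo |= binary_dilation(binary_dilation(seg))
        segments.append(
            {"x0": int(x0), "y0": int(y0), "x1": x1, "y1": y1, "width_px": width}
        )
    if len(segments) < n_fibrils:
        warnings.warn(
            f"placed only {len(segments)}/{n_fibrils} fibrils without overlap"
        )
    return mask, segments


def _pixel_integrated_gaussian(
    x0: float, y0: float, sigma: float, photons: float, xlo: int, xhi: int, ylo: int, yhi: int
) -> np.ndarray:
    """Expected photons per pixel for an emitter at (x0, y0).

    Pixel i spans [i - 0.5, i + 0.5] (centers at integers); the PSF mass in
    a pixel is the product of error-function differences along each axis.
    """
    s = sigma * math.sqrt(2.0)
    xs = np.arange(xlo, xhi)
    ys = np.arange(ylo, yhi)
    fx = 0.5 * (erf((xs + 0.5 - x0) / s) - erf((xs - 0.5 - x0) / s))
    fy = 0.5 * (erf((ys + 0.5 - y0) / s) - erf((ys - 0.5 - y0) / s))
    return photons * np.outer(fy, fx)


def render_movie(events: list[TrueEvent], truth: SimulationTruth) -> FrameStack:
    """Render an event list into a noisy movie.

    Each active emitter contributes a pixel-integrated 2D Gaussian of width
    ``psf_sigma_px`` and expected brightness ``photons_per_frame``; global
    linear drift shifts all emitters; per-frame blinking turns an emitter
    off with probability ``blink_off_prob``.  Poisson shot noise is applied
    to signal plus uniform background (unless ``truth.shot_noise`` is
    False), then additive Gaussian read noise, clipped at zero.

    Emitters carried out of the field by drift are skipped for the affected
    frames; the count is recorded on ``FrameStack.n_clipped_emitters``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    h, w = truth.image_shape
    dx, dy = truth.drift_px_per_frame
    stack = np.zeros((truth.n_frames, h, w), dtype=np.float64)
    pad = int(math.ceil(4 * truth.psf_sigma_px)) + 1
    n_clipped = 0

    for ev in events:
        if not (0 <= ev.x_px < w and 0 <= ev.y_px < h):
            raise ValueError(f"event at ({ev.x_px}, {ev.y_px}) outside image bounds")
        f0 = ev.start_frame
        f1 = min(truth.n_frames, f0 + ev.n_frames_obs)
        n_active = f1 - f0
        if n_active <= 0:
            continue
        if truth.blink_off_prob > 0:
            on = rng.uniform(size=n_active) >= truth.blink_off_prob
        else:
            on = np.ones(n_active, dtype=bool)
        for k in range(n_active):
            if not on[k]:
                continue
            f = f0 + k
            x = ev.x_px + dx * f
            y = ev.y_px + dy * f
            if not (-pad < x < w + pad and -pad < y < h + pad):
                n_clipped += 1
                continue
            xlo, xhi = max(0, int(x) - pad), min(w, int(x) + pad + 1)
            ylo, yhi = max(0, int(y) - pad), min(h, int(y) + pad + 1)
            if xlo >= xhi or ylo >= yhi:
                n_clipped += 1
                continue
            stack[f, ylo:yhi, xlo:xhi] += _pixel_integrated_gaussian(
                x, y, truth.psf_sigma_px, truth.photons_per_frame, xlo, xhi, ylo, yhi
            )

    if n_clipped:
        warnings.warn(f"{n_clipped} emitter-frames drifted outside the field")
    expected = stack + truth.bg_photons_px
    if truth.shot_noise:
        out = rng.poisson(expected).astype(np.float64)
    else:
        out = expected
    if truth.read_noise > 0:
        out = out + rng.normal(0.0, truth.read_noise, size=out.shape)
    out = np.clip(out, 0.0, None)
    fs = FrameStack(out, pixel_nm=truth.pixel_nm, frame_interval_s=truth.frame_interval_s)
    fs.n_clipped_emitters = n_clipped
    return fs


_TRUTH_COLUMNS = [
    "x_px",
    "y_px",
    "start_frame",
    "true_dwell_s",
    "observed_dwell_s",
    "n_frames_obs",
    "population_id",
    "region",
]


def events_to_table(events: list[TrueEvent]) -> pd.DataFrame:
    """Ground-truth events as a DataFrame (one row per event)."""
    return pd.DataFrame([asdict(e) for e in events], columns=_TRUTH_COLUMNS)


def write_truth_table(path, events: list[TrueEvent]) -> None:
    events_to_table(events).to_csv(path, index=False)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
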