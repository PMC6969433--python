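"""End-to-end analysis pipeline and its configuration.

One call runs: localize -> drift-correct -> link -> censor -> mask ->
classify -> per-region dwell fits -> derived kinetics, writing every
intermediate table, a JSON report with per-stage counts, and the exact
configuration used, so a run is fully reproducible from its output
directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import drift as drift_mod
from . import dwell as dwell_mod
from . import kinetics as kinetics_mod
from . import linking, localize, masking
from .frames import read_stack
from .simulate import BleachModel

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage parameter of the analysis pipeline, serializable to YAML."""

    input_path: str = ""  # multi-frame TIFF, or localization CSV
    input_kind: str = "tiff"  # "tiff" | "localizations"
    out_dir: str = "smdwell_out"
    seed: int = 0
    pixel_nm: float = 220.0
    frame_interval_s: float = 1.0
    n_frames: int | None = None  # required when input is a localization CSV
    image_shape: tuple[int, int] | None = None  # idem

    # localization
    k_sigma: float = 5.0
    roi_px: int = 7
    psf_sigma_px: float = 1.3
    fit_sigma: bool = False
    bg_window_px: int = 15
    max_subtraction_rounds: int = 2

    # drift
    correct_drift: bool = True
    drift_block_frames: int = 250
    drift_zoom: int = 5

    # linking
    link_radius_px: float = 1.0
    max_gap_frames: int = 1

    # masking
    sr_zoom: int = 5
    mask_path: str | None = None  # user-supplied mask image (overrides auto)
    blur_sigma: float = 2.0
    threshold_method: str = "otsu"
    dilation_px: int = 2
    min_area_px: int = 20
    margin_px: int = 2

    # dwell fitting
    m_candidates: tuple[int, ...] = (1, 2, 3)
    bin_width_s: float | None = None  # default: frame interval
    bleach_lifetimes_s: tuple[float, ...] = (195.0, 1100.0)
    bleach_weights: tuple[float, ...] = (0.5, 0.5)
    bleach_rel_tol: float = 0.35
    min_events_per_region: int = 50

    # kinetics
    kcat_range_per_s: tuple[float, float] = (2.0, 11.0)
    step_nm: float = 1.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("image_shape", "m_candidates", "bleach_lifetimes_s",
                "bleach_weights", "kcat_range_per_s"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _fit_region(
    events_df: pd.DataFrame,
    region: str,
    config: PipelineConfig,
    bleach: BleachModel,
    window_s: float | None,
) -> dict | None:
    durations = events_df.loc[events_df["region"] == region, "duration_s"]
    if len(durations) < config.min_events_per_region:
        logger.info("region %s has %d events (< %d); skipped",
                    region, len(durations), config.min_events_per_region)
        return None
    model = dwell_mod.ExponentialMixtureModel(
        durations.to_numpy(),
        bin_width_s=config.bin_width_s or config.frame_interval_s,
        bleach=bleach,
        window_s=window_s,
    )
    result = model.fit_select(config.m_candidates, seed=config.seed)
    report = result.to_report()
    report["n_region_events"] = int(len(durations))
    # derived kinetics for the shortest-lived (dissociating) component
    not_bleach = (
        ~result.bleach_limited
        if result.bleach_limited is not None
        else np.ones(result.m, dtype=bool)
    )
    if not_bleach.any():
        tau_short = float(result.taus[not_bleach][0])
        report["kinetics"] = kinetics_mod.kinetics_report(
            tau_short, config.kcat_range_per_s, config.step_nm
        ).to_report()
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis described by ``config``; return the report dict.

    Writes to ``config.out_dir``: the config echo, localization /
    drift / event CSVs, the super-resolution image and fibril mask (TIFF),
    and ``report.json`` with per-stage counts and per-region fits.
    """
    in_path = Path(config.input_path)
    if not in_path.exists():
        raise FileNotFoundError(
            f"input {in_path} does not exist; set input_path to a multi-frame "
            "TIFF (input_kind: tiff) or a localization CSV (input_kind: localizations)"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    counts: dict[str, int] = {}

    # --- localize ---------------------------------------------------------
    if config.input_kind == "tiff":
        stack = read_stack(
            in_path, pixel_nm=config.pixel_nm, frame_interval_s=config.frame_interval_s
        )
        n_frames = stack.n_frames
        shape = stack.shape
        locs = localize.localize_stack(
            stack,
            localize.LocalizeParams(
                k_sigma=config.k_sigma,
                roi_px=config.roi_px,
                psf_sigma_px=config.psf_sigma_px,
                fit_sigma=config.fit_sigma,
                bg_window_px=config.bg_window_px,
                max_subtraction_rounds=config.max_subtraction_rounds,
            ),
        )
    elif config.input_kind == "localizations":
        if config.n_frames is None or config.image_shape is None:
            raise ValueError(
                "n_frames and image_shape are required for localization-CSV input"
            )
        locs = localize.read_localizations(in_path)
        n_frames = config.n_frames
        shape = tuple(config.image_shape)
    else:
        raise ValueError(f"unknown input_kind {config.input_kind!r}")
    counts["localizations"] = len(locs)
    localize.write_localizations(out / "localizations.csv", locs)
    logger.info("localized: %d spots in %d frames", len(locs), n_frames)

    # --- drift ------------------------------------------------------------
    if config.correct_drift:
        trajectory = drift_mod.estimate_drift(
            locs, n_frames, shape,
            block_frames=config.drift_block_frames, zoom=config.drift_zoom,
        )
        locs = drift_mod.apply_drift(locs, trajectory)
        trajectory.to_table().to_csv(out / "drift.csv", index=False)
        localize.write_localizations(out / "localizations_corrected.csv", locs)

    # --- link & censor ----------------------------------------------------
    events = linking.link_events(
        locs,
        radius_px=config.link_radius_px,
        max_gap_frames=config.max_gap_frames,
        frame_interval_s=config.frame_interval_s,
        n_frames_total=n_frames,
    )
    counts["events_linked"] = len(events)
    kept, n_censored = linking.censor_events(events, n_frames)
    counts["events_censored"] = n_censored
    counts["events_kept"] = len(kept)

    # --- mask & classify --------------------------------------------------
    sr = masking.build_sr_image(locs, config.sr_zoom, shape)
    tifffile.imwrite(out / "sr_image.tif",
                     np.clip(sr.counts, 0, 2**16 - 1).astype(np.uint16))
    if config.mask_path:
        mask_img = tifffile.imread(config.mask_path)
        mask = masking.FibrilMask(mask_img > 0, config.sr_zoom, "user")
    else:
        mask = masking.segment_fibrils(
            sr,
            masking.SegmentationParams(
                blur_sigma=config.blur_sigma,
                threshold_method=config.threshold_method,
                dilation_px=config.dilation_px,
                min_area_px=config.min_area_px,
            ),
        )
    tifffile.imwrite(out / "fibril_mask.tif", mask.mask.astype(np.uint8) * 255)
    kept = masking.classify_events(kept, mask, margin_px=config.margin_px)
    events_df = linking.event_table(kept)
    linking.write_events(out / "events.csv", events_df)
    for region in ("fibril", "background", "unassigned"):
        counts[f"events_{region}"] = int((events_df["region"] == region).sum())

    # --- dwell fits & kinetics --------------------------------------------
    bleach = BleachModel(config.bleach_lifetimes_s, config.bleach_weights)
    fits = {}
    for region in ("fibril", "background"):
        fit_report = _fit_region(
            events_df, region, config, bleach, n_frames * config.frame_interval_s
        )
        fits[region] = fit_report if fit_report is not None else "unavailable"

    report = {
        "config": config.to_dict(),
        "counts": counts,
        "fits": fits,
        "observation_window_min": kinetics_mod.observation_window_min(
            n_frames, config.frame_interval_s
        ),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("pipeline complete: %s", counts)
    return report
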