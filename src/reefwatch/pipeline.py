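"""End-to-end protocol: calibrate -> screen -> count -> rhythm analysis.

Runs the whole counting protocol over a directory of timestamped frames from
a single YAML config, writing per-stage CSV/JSON artifacts and a summary.
Frames discarded by quality screening enter the count series as MISSING
slots, never as zeros: a discarded frame says nothing about how many fish
were present.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .colorimetry import ChartReference
from .quality import build_feature_table, select_images
from .rhythms import (
    CountSeries,
    chi_square_periodogram,
    turbidity_diagnostic,
    waveform,
)
from .segmentation import ROIPolygon, SegmentationParams, segment_and_count
from .tps import apply_tps3d, extract_patch_means, fit_tps3d

logger = logging.getLogger("reefwatch")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "compare_series", "selection_percent"]

_TS_PATTERN = re.compile(r"(\d{8}T\d{6})")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for exit-code mapping."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    image_dir: Path
    chart: ChartReference
    center_region: tuple[int, int, int, int]
    roi: ROIPolygon
    training_ids: list[str]
    out_dir: Path
    screen_rule: str = "mahalanobis"
    screen_coverage: float = 0.99
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tps_lambda: float = 0.0
    interval_min: float = 30.0
    p_min: float = 660.0
    p_max: float = 1500.0
    alpha: float = 0.05
    night_window: tuple[time, time] = (time(20, 0), time(8, 0))
    green_patch_id: int = 5
    timestamp_pattern: str = r"(\d{8}T\d{6})"
    seed: int = 0
    save_calibrated: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        try:
            seg = cfg.get("segmentation", {})
            night = cfg.get("night_window", ["20:00", "08:00"])
            return cls(
                image_dir=Path(cfg["image_dir"]),
                chart=ChartReference.from_json(cfg["chart_reference"]),
                center_region=tuple(cfg["center_region"]),
                roi=ROIPolygon(np.array(cfg["roi_polygon"], dtype=float)),
                training_ids=_load_training(cfg["training_list"]),
                out_dir=Path(cfg["out_dir"]),
                screen_rule=cfg.get("screen_rule", "mahalanobis"),
                screen_coverage=float(cfg.get("screen_coverage", 0.99)),
                segmentation=SegmentationParams(
                    edge_threshold=seg.get("edge_threshold"),
                    closing_radius=int(seg.get("closing_radius", 2)),
                    min_area=int(seg.get("min_area", 30)),
                    distance_prethreshold=seg.get("distance_prethreshold"),
                ),
                tps_lambda=float(cfg.get("tps_lambda", 0.0)),
                interval_min=float(cfg.get("interval_min", 30.0)),
                p_min=float(cfg.get("p_min", 660.0)),
                p_max=float(cfg.get("p_max", 1500.0)),
                alpha=float(cfg.get("alpha", 0.05)),
                night_window=tuple(time.fromisoformat(t) for t in night),
                green_patch_id=int(cfg.get("green_patch_id", 5)),
                timestamp_pattern=cfg.get("timestamp_pattern", r"(\d{8}T\d{6})"),
                seed=int(cfg.get("seed", 0)),
                save_calibrated=bool(cfg.get("save_calibrated", False)),
            )
        except KeyError as exc:
            raise PipelineError("config", f"missing config key {exc}") from exc


def _load_training(spec) -> list[str]:
    if isinstance(spec, list):
        return [str(s) for s in spec]
    return [line.strip() for line in Path(spec).read_text().splitlines() if line.strip()]


def _parse_timestamp(name: str, pattern: str) -> datetime:
    match = re.search(pattern, name)
    if not match:
        raise PipelineError("ingest", f"no timestamp in filename {name!r}")
    return datetime.strptime(match.group(1), "%Y%m%dT%H%M%S")


def run_pipeline(config: RunConfig, stop_after: str | None = None) -> dict:
    """Execute every stage in order and return the summary dict.

    Stages: per-frame TPS calibration (each frame's own chart against the
    reference) -> panel-center feature table -> PCA screening -> segmentation
    of selected frames only -> count-series assembly (discarded slots
    MISSING) -> periodogram, waveform and green-channel turbidity diagnostic.
    Every stage writes its artifact under ``config.out_dir``; a stage failure
    aborts with a stage-tagged error, keeping partial outputs.
    """
    import imageio.v3 as iio

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = sorted(Path(config.image_dir).glob("*.png")) + sorted(
        Path(config.image_dir).glob("*.jpg")
    )
    if not files:
        raise PipelineError("ingest", f"no images found in {config.image_dir}")
    reference = config.chart.srgb_array

    # --- stage 1: per-image calibration --------------------------------
    calibrated: dict[str, np.ndarray] = {}
    timestamps: dict[str, datetime] = {}
    green_raw: dict[str, float] = {}
    green_patch = next(
        p for p in config.chart.patches if p.patch_id == config.green_patch_id
    )
    for path in files:
        name = path.name
        timestamps[name] = _parse_timestamp(name, config.timestamp_pattern)
        try:
            image = iio.imread(path)
        except Exception as exc:
            logger.warning("unreadable image %s: %s", name, exc)
            continue
        obs = extract_patch_means(image, config.chart)
        source = np.array([o.mean_rgb for o in obs])
        try:
            model = fit_tps3d(source, reference, lam=config.tps_lambda)
        except np.linalg.LinAlgError as exc:
            raise PipelineError("calibrate", f"{name}: {exc}") from exc
        calibrated[name] = apply_tps3d(model, image)
        gr0, gc0, gr1, gc1 = green_patch.central_window
        green_raw[name] = float(image[gr0:gr1, gc0:gc1, 1].mean())
        if config.save_calibrated:
            (out / "calibrated").mkdir(exist_ok=True)
            iio.imwrite(out / "calibrated" / name,
                        calibrated[name].astype(np.uint8))
    logger.info("calibrated %d/%d frames", len(calibrated), len(files))

    # --- stage 2: features + PCA screening ------------------------------
    feats = build_feature_table(
        [(n, timestamps[n], img) for n, img in calibrated.items()],
        config.center_region,
    )
    try:
        screen = select_images(feats, config.training_ids,
                               rule=config.screen_rule,
                               coverage=config.screen_coverage)
    except ValueError as exc:
        raise PipelineError("screen", str(exc)) from exc
    screen_df = screen.to_frame()
    screen_df.to_csv(out / "screening.csv", index=False)
    selected_names = set(screen_df.loc[screen_df.selected, "image_id"])
    logger.info("selected %d/%d frames", len(selected_names), len(feats))
    if stop_after == "screen":
        return {
            "n_acquired": len(files),
            "n_selected": int(len(selected_names)),
            "selection_percent": selection_percent(len(selected_names), len(files)),
        }

    # --- stage 3: segmentation on selected frames only ------------------
    rows = []
    for name in sorted(calibrated):
        if name not in selected_names:
            continue
        res = segment_and_count(calibrated[name], config.roi,
                                config.center_region, config.segmentation)
        rows.append({
            "image_id": name,
            "timestamp": timestamps[name].isoformat(),
            "count": res.count,
            "n_pixels_over_threshold": res.n_pixels_over_threshold,
            "background_r": res.background_rgb[0],
            "background_g": res.background_rgb[1],
            "background_b": res.background_rgb[2],
        })
    counts_df = pd.DataFrame(rows)
    counts_df.to_csv(out / "counts.csv", index=False)
    if stop_after == "count":
        return {
            "n_acquired": len(files),
            "n_selected": int(len(selected_names)),
            "selection_percent": selection_percent(len(selected_names), len(files)),
            "total_automated_count": float(counts_df["count"].sum()) if rows else 0.0,
        }

    # --- stage 4: count-series assembly ---------------------------------
    order = sorted(timestamps, key=lambda n: timestamps[n])
    start = timestamps[order[0]]
    step = timedelta(minutes=config.interval_min)
    n_slots = int(round((timestamps[order[-1]] - start) / step)) + 1
    values = np.full(n_slots, np.nan)
    selected_mask = np.zeros(n_slots, dtype=bool)
    green_values = np.full(n_slots, np.nan)
    count_by_name = {r["image_id"]: r["count"] for r in rows}
    for name in order:
        slot = int(round((timestamps[name] - start) / step))
        if name in green_raw:
            green_values[slot] = green_raw[name]
        if name in count_by_name:
            values[slot] = count_by_name[name]
            selected_mask[slot] = True
    series = CountSeries(start=start, interval_min=config.interval_min,
                         values=values, label="automated")
    series.to_csv(out / "count_series.csv")

    # --- stage 5: rhythm analysis ---------------------------------------
    try:
        pgram = chi_square_periodogram(series, config.p_min, config.p_max,
                                       config.alpha)
    except ValueError as exc:
        raise PipelineError("rhythms", str(exc)) from exc
    pgram.to_frame().to_csv(out / "periodogram.csv", index=False)
    wf = waveform(series, night_window=config.night_window)
    green_series = CountSeries(start=start, interval_min=config.interval_min,
                               values=green_values, label="green-channel")
    green_wf, discards = turbidity_diagnostic(green_series, selected_mask,
                                              config.night_window)
    with open(out / "waveform.json", "w") as fh:
        json.dump(wf.to_dict(), fh, indent=1)
    with open(out / "turbidity.json", "w") as fh:
        json.dump({"green_waveform": green_wf.to_dict(),
                   "discarded_per_bin": discards.tolist()}, fh, indent=1)

    summary = {
        "n_acquired": len(files),
        "n_selected": int(len(selected_names)),
        "selection_percent": selection_percent(len(selected_names), len(files)),
        "total_automated_count": float(np.nansum(values)),
        "peak_period_min": pgram.peak_period_min,
        "percent_variance": pgram.percent_variance,
        "mesor": wf.mesor,
        "onset": None if wf.onset is None else wf.onset.isoformat(),
        "offset": None if wf.offset is None else wf.offset.isoformat(),
        "daytime_activity_percent": wf.daytime_activity_percent,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def selection_percent(n_selected: int, n_acquired: int) -> float:
    """Share of acquired frames kept by screening, as a percentage (1 dp)."""
    if n_acquired <= 0:
        raise ValueError("no acquired images")
    return round(100.0 * n_selected / n_acquired, 1)


def compare_series(automated: CountSeries, manual: CountSeries,
                   p_min: float = 660.0, p_max: float = 1500.0,
                   alpha: float = 0.05,
                   night_window: tuple[time, time] = (time(20, 0), time(8, 0))) -> dict:
    """Side-by-side rhythm comparison of automated vs manual counts.

    Requires the two series to share the slot grid; reports paired
    periodograms and waveforms, totals, total ratio, onset/offset agreement
    in slots, and the daytime-percentage difference.
    """
    if (automated.start != manual.start
            or automated.interval_min != manual.interval_min
            or automated.n_slots != manual.n_slots):
        raise ValueError("series are not on the same slot grid")
    out = {}
    for key, s in (("automated", automated), ("manual", manual)):
        pg = chi_square_periodogram(s, p_min, p_max, alpha)
        wf = waveform(s, night_window=night_window)
        out[key] = {
            "total": float(np.nansum(s.values)),
            "peak_period_min": pg.peak_period_min,
            "percent_variance": pg.percent_variance,
            "mesor": wf.mesor,
            "onset": wf.onset,
            "offset": wf.offset,
            "daytime_activity_percent": wf.daytime_activity_percent,
        }
    slot = automated.interval_min
    a, m = out["automated"], out["manual"]
    out["comparison"] = {
        "total_ratio": (a["total"] / m["total"]) if m["total"] else None,
        "same_peak_period": a["peak_period_min"] == m["peak_period_min"],
        "onset_diff_slots": _clock_diff_slots(a["onset"], m["onset"], slot),
        "offset_diff_slots": _clock_diff_slots(a["offset"], m["offset"], slot),
        "daytime_percent_diff": (
            None if None in (a["daytime_activity_percent"], m["daytime_activity_percent"])
            else a["daytime_activity_percent"] - m["daytime_activity_percent"]
        ),
    }
    return out


def _clock_diff_slots(t1: time | None, t2: time | None, interval_min: float):
    if t1 is None or t2 is None:
        return None
    m1 = t1.hour * 60 + t1.minute
    m2 = t2.hour * 60 + t2.minute
    diff = abs(m1 - m2)
    diff = min(diff, 1440 - diff)
    return diff / interval_min
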