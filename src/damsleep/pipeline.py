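"""End-to-end orchestration: config validation, ingest/simulate -> QC ->
score -> analyses, with a machine-readable run manifest.

A run is described by one declarative YAML mapping (see :class:`RunConfig`).
Outputs — a per-fly, per-day metrics CSV, optional percent-change and
rebound tables, and ``manifest.json`` recording the config, package version
and seed — are reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import ChannelMap, read_single_beam, read_multibeam, write_canonical, read_canonical
from .series import MinuteSeries, LightSchedule, MINUTES_PER_DAY
from .sleep import (
    quiescence,
    detect_sleep_bouts,
    sleep_metrics,
    percent_change,
    flag_inviable,
    BaselineZeroError,
)
from .homeostasis import SDProtocol, rebound_from_series
from .synthetic import SimConfig, simulate_cohort, write_ground_truth

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "score_cohort"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and fly."""


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    output_dir: str
    mode: str = "single"  # single | multibeam
    # data source: either an input canonical file or a simulation block
    input_canonical: Optional[str] = None
    simulate: Optional[dict] = None
    lights_on_offset_min: int = 0
    baseline_day: Optional[int] = None
    activation_day: Optional[int] = None
    sd_window: Optional[Tuple[int, int]] = None
    checkpoints_h: Tuple[int, ...] = (4, 6, 12, 24, 48)
    qc_tail_hours: float = 6.0
    qc_min_counts: int = 1
    min_lost: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("single", "multibeam"):
            raise ValueError(f"mode must be single/multibeam, got {self.mode!r}")
        if (self.input_canonical is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of input_canonical / simulate must be given"
            )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "sd_window" in raw and raw["sd_window"] is not None:
            raw["sd_window"] = tuple(raw["sd_window"])
        if "checkpoints_h" in raw:
            raw["checkpoints_h"] = tuple(raw["checkpoints_h"])
        return cls(**raw)


def score_cohort(
    series_list: Sequence[MinuteSeries],
    mode: str,
    schedule: LightSchedule,
) -> pd.DataFrame:
    """Per-fly, per-day sleep metrics table."""
    rows = []
    for s in series_list:
        n_days = s.n // MINUTES_PER_DAY
        try:
            q = quiescence(s, mode)
            bouts = detect_sleep_bouts(q)
        except ValueError as exc:
            raise PipelineError(f"score: fly {s.fly_id}: {exc}") from exc
        for d in range(n_days):
            window = (d * MINUTES_PER_DAY, (d + 1) * MINUTES_PER_DAY)
            m = sleep_metrics(s, bouts, schedule, window)
            rows.append(
                {
                    "fly_id": s.fly_id,
                    "day": d,
                    "total_sleep_min": m.total_sleep_min,
                    "day_sleep_min": m.day_sleep_min,
                    "night_sleep_min": m.night_sleep_min,
                    "day_bout_count": m.day_bout_count,
                    "night_bout_count": m.night_bout_count,
                    "day_mean_bout_min": m.day_mean_bout_min,
                    "night_mean_bout_min": m.night_mean_bout_min,
                    "waking_activity": m.waking_activity,
                }
            )
    return pd.DataFrame(rows)


def _load_or_simulate(cfg: RunConfig, outdir: Path):
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        n_flies = int(sim.pop("n_flies", 8))
        n_days = int(sim.pop("n_days", 2))
        led_protocol = str(sim.pop("led_protocol", "off"))
        led_days = tuple(sim.pop("led_days", ()))
        sd_window = sim.pop("sd_window", None)
        if sd_window is not None:
            sd_window = tuple(sd_window)
        sc = SimConfig(seed=cfg.seed, **sim)
        series_list, truths = simulate_cohort(
            sc,
            n_flies,
            n_days,
            led_protocol=led_protocol,
            led_days=led_days,
            sd_window=sd_window,
        )
        write_canonical(series_list, outdir / "cohort.csv")
        write_ground_truth(truths, outdir / "truth.csv")
        return series_list
    series_list = read_canonical(cfg.input_canonical)
    if not series_list:
        raise PipelineError("ingest: input contains no flies")
    return series_list


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute ingest/simulate -> QC -> score -> requested analyses.

    Returns the manifest dict; all outputs land in ``cfg.output_dir``.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    series_list = _load_or_simulate(cfg, outdir)

    excluded = []
    kept = []
    for s in series_list:
        try:
            dead = flag_inviable(s, cfg.qc_tail_hours, cfg.qc_min_counts)
        except ValueError as exc:
            raise PipelineError(f"qc: fly {s.fly_id}: {exc}") from exc
        if dead:
            excluded.append({"fly_id": s.fly_id, "reason": "inviable (QC tail)"})
        else:
            kept.append(s)
    if not kept:
        raise PipelineError("qc: every fly excluded; nothing to score")

    schedule = LightSchedule(zt0_offset_min=cfg.lights_on_offset_min)
    metrics = score_cohort(kept, cfg.mode, schedule)
    metrics.to_csv(outdir / "metrics.csv", index=False)

    if cfg.baseline_day is not None and cfg.activation_day is not None:
        rows = []
        for fid, sub in metrics.groupby("fly_id", sort=False):
            by_day = sub.set_index("day")["total_sleep_min"]
            for d in (cfg.baseline_day, cfg.activation_day):
                if d not in by_day.index:
                    raise PipelineError(
                        f"percent-change: fly {fid}: day {d} not in data span"
                    )
            try:
                pc = percent_change(
                    by_day[cfg.baseline_day], by_day[cfg.activation_day]
                )
            except BaselineZeroError:
                excluded.append(
                    {"fly_id": fid, "reason": "zero baseline sleep"}
                )
                continue
            rows.append({"fly_id": fid, "pct_sleep_change": pc})
        pd.DataFrame(rows).to_csv(outdir / "percent_change.csv", index=False)

    if cfg.sd_window is not None:
        protocol = SDProtocol(
            sd_window=cfg.sd_window,
            checkpoints_h=cfg.checkpoints_h,
            min_lost=cfg.min_lost,
        )
        rows = []
        for s in kept:
            try:
                r = rebound_from_series(s, protocol, cfg.mode)
            except ValueError as exc:
                raise PipelineError(f"rebound: fly {s.fly_id}: {exc}") from exc
            row = {
                "fly_id": s.fly_id,
                "sleep_lost_min": r.sleep_lost_min,
                "valid": r.valid,
            }
            row.update(
                {f"pct_recovered_{h}h": v for h, v in r.pct_recovered.items()}
            )
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "rebound.csv", index=False)

    manifest = {
        "package": "damsleep",
        "version": __version__,
        "seed": cfg.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "n_flies_in": len(series_list),
        "n_flies_scored": len(kept),
        "excluded": excluded,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
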