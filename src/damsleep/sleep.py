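"""Sleep-bout detection and per-fly sleep metrics.

Sleep in beam-break data is defined behaviorally: any run of quiescent 1-min
bins lasting at least 5 minutes is a sleep bout.  A minute is quiescent when
it has zero counts (single-beam) or zero counts *and* zero cross-beam moves
(multibeam).  All downstream metrics — day/night totals, bout statistics,
waking activity, hourly profiles — derive from the bout list.

Coordinates are 0-based, half-open minute intervals throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .series import MinuteSeries, LightSchedule, MINUTES_PER_DAY

__all__ = [
    "SleepBout",
    "SleepMetrics",
    "BaselineZeroError",
    "MIN_BOUT_MIN",
    "quiescence",
    "detect_sleep_bouts",
    "bouts_to_minutes",
    "sleep_metrics",
    "percent_change",
    "flag_inviable",
]

log = logging.getLogger(__name__)

#: Minimum quiescence run length (minutes) that counts as sleep.
MIN_BOUT_MIN = 5


class BaselineZeroError(ValueError):
    """Percent change is undefined for a zero baseline; exclude the fly."""


@dataclass(frozen=True)
class SleepBout:
    """Half-open minute interval [start_min, end_min) of scored sleep."""

    start_min: int
    end_min: int

    def __post_init__(self) -> None:
        if self.duration_min < MIN_BOUT_MIN:
            raise ValueError(
                f"bout [{self.start_min}, {self.end_min}) shorter than "
                f"{MIN_BOUT_MIN} min"
            )

    @property
    def duration_min(self) -> int:
        return self.end_min - self.start_min


@dataclass
class SleepMetrics:
    """Per-fly sleep summary over one whole experimental day."""

    total_sleep_min: int
    day_sleep_min: int
    night_sleep_min: int
    day_bout_count: int
    night_bout_count: int
    day_mean_bout_min: Optional[float]
    night_mean_bout_min: Optional[float]
    waking_activity: Optional[float]  # counts per awake minute; None if never awake
    profile: np.ndarray  # 24 hourly sleep-minute values


def quiescence(series: MinuteSeries, mode: str = "single") -> np.ndarray:
    """Per-minute quiescence mask.

    ``single``: quiescent iff counts == 0.  ``multibeam``: quiescent iff
    counts == 0 and moves == 0 (in-place micromovements break quiescence).
    """
    if mode == "single":
        return series.counts == 0
    if mode == "multibeam":
        if series.moves is None:
            raise ValueError(
                f"{series.fly_id}: multibeam scoring requires a moves channel"
            )
        return (series.counts == 0) & (series.moves == 0)
    raise ValueError(f"mode must be 'single' or 'multibeam', got {mode!r}")


def detect_sleep_bouts(
    quiescent: Sequence[bool], min_duration: int = MIN_BOUT_MIN
) -> List[SleepBout]:
    """Maximal runs of quiescence lasting >= ``min_duration`` minutes.

    Runs touching the edges of the vector count if their observed length
    meets the threshold.
    """
    q = np.asarray(quiescent, dtype=bool)
    if q.size == 0:
        return []
    edges = np.diff(np.concatenate(([0], q.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [
        SleepBout(int(s), int(e))
        for s, e in zip(starts, ends)
        if e - s >= min_duration
    ]


def bouts_to_minutes(bouts: Sequence[SleepBout], n: int) -> np.ndarray:
    """Boolean asleep-per-minute vector implied by a bout list."""
    asleep = np.zeros(n, dtype=bool)
    for b in bouts:
        asleep[b.start_min : b.end_min] = True
    return asleep


def _fragment_stats(mask: np.ndarray) -> Tuple[int, Optional[float]]:
    """(#maximal runs, mean run length) of True runs in ``mask``."""
    edges = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    if starts.size == 0:
        return 0, None
    durs = ends - starts
    return int(starts.size), float(durs.mean())


def sleep_metrics(
    series: MinuteSeries,
    bouts: Sequence[SleepBout],
    schedule: LightSchedule,
    window: Tuple[int, int],
    split_boundary_bouts: bool = True,
) -> SleepMetrics:
    """Sleep summary for one whole day ``window = (start_min, end_min)``.

    Day totals cover ZT0-ZT12, night ZT12-ZT24.  Per-period bout statistics
    are computed on bout fragments truncated at ZT boundaries (default),
    which conserves sleep minutes across periods: each fragment counts
    toward its own period even when shorter than the 5-min threshold, since
    the bout as a whole met it.  With ``split_boundary_bouts=False`` a
    boundary-spanning bout is attributed wholly to the period containing its
    first minute.
    """
    start, end = window
    if end - start != MINUTES_PER_DAY:
        raise ValueError("window must span exactly one day (1440 min)")
    if start < 0 or end > series.n:
        raise ValueError(f"window {window} outside series of length {series.n}")

    asleep_full = bouts_to_minutes(bouts, series.n)
    asleep = asleep_full[start:end]
    zt = (np.arange(start, end) - schedule.zt0_offset_min) % MINUTES_PER_DAY
    is_day = zt < schedule.light_min

    total = int(asleep.sum())
    day_total = int((asleep & is_day).sum())
    night_total = total - day_total

    if split_boundary_bouts:
        day_count, day_mean = _fragment_stats(asleep & is_day)
        night_count, night_mean = _fragment_stats(asleep & ~is_day)
    else:
        day_durs, night_durs = [], []
        for b in bouts:
            s, e = max(b.start_min, start), min(b.end_min, end)
            if e <= s:
                continue
            (day_durs if is_day[s - start] else night_durs).append(e - s)
        day_count, night_count = len(day_durs), len(night_durs)
        day_mean = float(np.mean(day_durs)) if day_durs else None
        night_mean = float(np.mean(night_durs)) if night_durs else None

    awake = ~asleep
    n_awake = int(awake.sum())
    if n_awake == 0:
        log.warning("%s: no awake minutes in window; waking activity undefined",
                    series.fly_id)
        waking = None
    else:
        waking = float(series.counts[start:end][awake].sum() / n_awake)

    profile = np.bincount(zt[asleep] // 60, minlength=24)

    return SleepMetrics(
        total_sleep_min=total,
        day_sleep_min=day_total,
        night_sleep_min=night_total,
        day_bout_count=day_count,
        night_bout_count=night_count,
        day_mean_bout_min=day_mean,
        night_mean_bout_min=night_mean,
        waking_activity=waking,
        profile=profile,
    )


def percent_change(baseline_value: float, test_value: float) -> float:
    """100 x (test - baseline) / baseline; raises on a zero baseline."""
    if baseline_value <= 0:
        raise BaselineZeroError(
            f"baseline value {baseline_value} <= 0; percent change undefined"
        )
    return 100.0 * (test_value - baseline_value) / baseline_value


def flag_inviable(
    series: MinuteSeries, tail_hours: float = 6, min_counts: int = 1
) -> bool:
    """Dead-fly QC: True (exclude) iff total activity in the final
    ``tail_hours`` falls below ``min_counts``."""
    tail = int(round(tail_hours * 60))
    if series.n < tail:
        raise ValueError(
            f"{series.fly_id}: series ({series.n} min) shorter than QC tail "
            f"({tail} min)"
        )
    return int(series.counts[-tail:].sum()) < min_counts
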