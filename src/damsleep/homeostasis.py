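"""Sleep-deprivation bookkeeping: sleep lost, cumulative gain, and the
percent-of-lost-sleep-recovered statistic.

A fly is mechanically kept awake for 12 h (by default the dark phase of the
deprivation day).  Sleep lost is the baseline-day sleep in that window minus
the deprivation-day sleep in it.  During recovery, each minute's sleep is
compared with the *same clock minute of the baseline day*; the cumulative
sum of those differences is the gain curve, which may decrease when recovery
sleep dips below baseline.  Percent recovered at checkpoint h is
100 x gain(h) / lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .series import MinuteSeries, MINUTES_PER_DAY
from .sleep import quiescence, detect_sleep_bouts, bouts_to_minutes

__all__ = [
    "SDProtocol",
    "ReboundResult",
    "asleep_minutes",
    "sleep_lost",
    "cumulative_gain",
    "percent_recovered",
    "rebound_from_series",
]

log = logging.getLogger(__name__)

DEFAULT_CHECKPOINTS_H = (4, 6, 12, 24, 48)

#: Below this many minutes of lost sleep the recovery ratio is too noisy to
#: report; the fly is marked invalid instead.
DEFAULT_MIN_LOST = 60


@dataclass
class SDProtocol:
    """Deprivation window and recovery checkpoints.

    ``sd_window`` is a half-open minute interval into the scored series,
    conventionally the 12-h dark phase of the deprivation day.
    ``baseline_window`` defaults to the same clock window one day earlier.
    """

    sd_window: Tuple[int, int]
    checkpoints_h: Tuple[int, ...] = DEFAULT_CHECKPOINTS_H
    min_lost: int = DEFAULT_MIN_LOST
    baseline_window: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        s, e = self.sd_window
        if e <= s:
            raise ValueError(f"empty sd_window {self.sd_window}")
        if list(self.checkpoints_h) != sorted(self.checkpoints_h):
            raise ValueError("checkpoints must be sorted ascending")
        if self.baseline_window is None:
            self.baseline_window = (s - MINUTES_PER_DAY, e - MINUTES_PER_DAY)


@dataclass
class ReboundResult:
    """Per-fly rebound summary."""

    fly_id: str
    sleep_lost_min: float
    gain_curve: np.ndarray  # cumulative gain over the recovery window
    pct_recovered: Dict[int, Optional[float]]  # per checkpoint hour
    valid: bool


def asleep_minutes(series: MinuteSeries, mode: str = "single") -> np.ndarray:
    """Scored per-minute asleep vector (quiescence -> >=5-min bouts)."""
    q = quiescence(series, mode)
    return bouts_to_minutes(detect_sleep_bouts(q), series.n)


def sleep_lost(
    baseline_series: MinuteSeries,
    sd_series: MinuteSeries,
    protocol: SDProtocol,
    mode: str = "single",
) -> float:
    """Baseline-window sleep minus deprivation-window sleep, clamped at 0.

    ``baseline_series`` and ``sd_series`` may be the same multi-day series;
    the protocol's two windows select the matched 12-h spans.
    """
    bs, be = protocol.baseline_window
    ss, se = protocol.sd_window
    if be - bs != se - ss:
        raise ValueError("baseline and SD windows differ in length")
    base = asleep_minutes(baseline_series, mode)[bs:be].sum()
    dep = asleep_minutes(sd_series, mode)[ss:se].sum()
    lost = float(base - dep)
    if lost < 0:
        log.warning(
            "%s: slept %d min more during deprivation than baseline; "
            "sleep lost clamped to 0",
            sd_series.fly_id,
            int(-lost),
        )
        return 0.0
    return lost


def cumulative_gain(
    baseline_asleep: np.ndarray, recovery_asleep: np.ndarray
) -> np.ndarray:
    """Cumulative (recovery - baseline) sleep over matched windows.

    Inputs are per-minute asleep vectors over time-of-day-matched windows of
    equal length.  Negative excursions are retained: the curve tracks sleep
    lost then gained continuously.
    """
    baseline_asleep = np.asarray(baseline_asleep)
    recovery_asleep = np.asarray(recovery_asleep)
    if baseline_asleep.shape != recovery_asleep.shape:
        raise ValueError(
            f"window mismatch: baseline {baseline_asleep.shape} vs "
            f"recovery {recovery_asleep.shape}"
        )
    diff = recovery_asleep.astype(np.int64) - baseline_asleep.astype(np.int64)
    return np.cumsum(diff)


def percent_recovered(
    lost: float,
    gain_curve: np.ndarray,
    checkpoints_h: Sequence[int] = DEFAULT_CHECKPOINTS_H,
    min_lost: float = DEFAULT_MIN_LOST,
    fly_id: str = "",
) -> ReboundResult:
    """Percent of lost sleep recovered at each checkpoint.

    Gain is read at the last minute of hour h (0-based half-open bins).
    When ``lost < min_lost`` the fly is marked invalid and percentages are
    withheld (None).
    """
    if lost < 0:
        raise ValueError("lost must be >= 0")
    gain_curve = np.asarray(gain_curve)
    pct: Dict[int, Optional[float]] = {}
    valid = lost >= min_lost
    if not valid:
        log.info(
            "%s: only %.0f min of sleep lost (< %.0f); recovery ratio withheld",
            fly_id, lost, min_lost,
        )
    for h in checkpoints_h:
        idx = 60 * h - 1
        if idx >= len(gain_curve):
            raise ValueError(
                f"checkpoint {h} h beyond recovery curve "
                f"({len(gain_curve)} min)"
            )
        pct[h] = 100.0 * float(gain_curve[idx]) / lost if valid else None
    return ReboundResult(
        fly_id=fly_id,
        sleep_lost_min=lost,
        gain_curve=gain_curve,
        pct_recovered=pct,
        valid=valid,
    )


def rebound_from_series(
    series: MinuteSeries,
    protocol: SDProtocol,
    mode: str = "single",
    recovery_start: Optional[int] = None,
) -> ReboundResult:
    """Full rebound analysis on one multi-day series.

    Recovery starts at the end of the deprivation window (overridable) and
    runs to the last checkpoint.  Each recovery minute is matched to the
    same clock minute of the single baseline day, so recovery spans longer
    than a day reuse the baseline day cyclically.
    """
    asleep = asleep_minutes(series, mode)
    lost = sleep_lost(series, series, protocol, mode)
    start = protocol.sd_window[1] if recovery_start is None else recovery_start
    n_rec = 60 * max(protocol.checkpoints_h)
    if start + n_rec > series.n:
        raise ValueError(
            f"{series.fly_id}: recovery window [{start}, {start + n_rec}) "
            f"exceeds series length {series.n}"
        )
    # map each recovery minute onto the baseline day by time-of-day
    bs = protocol.baseline_window[0]
    # start of the baseline *day* containing the baseline window
    base_day0 = bs - (bs % MINUTES_PER_DAY)
    rec_idx = np.arange(start, start + n_rec)
    base_idx = base_day0 + (rec_idx % MINUTES_PER_DAY)
    if base_idx.min() < 0:
        raise ValueError("baseline day extends before the series start")
    curve = cumulative_gain(asleep[base_idx], asleep[rec_idx])
    return percent_recovered(
        lost,
        curve,
        protocol.checkpoints_h,
        protocol.min_lost,
        fly_id=series.fly_id,
    )
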