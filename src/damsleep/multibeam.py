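"""Minute-level behavior classification from multibeam channels, and its
validation against frame-labeled video.

A multibeam monitor reports, per 1-min bin, cross-beam ``moves``, within-beam
``counts``, and tube ``position``.  The classification hierarchy scores each
minute by the highest activity level it contains:

* any moves            -> **walking**
* counts but no moves  -> **micromovement** (feeding, grooming, ...)
* neither              -> **rest**

Video ground truth distinguishes seven behaviors (rest, walking, feeding,
grooming, posture change, proboscis extension, single leg movement); each
minute is labeled by the highest activity level seen in it, with ties among
micromovement behaviors broken by longest cumulative duration and then a
fixed precedence order.

Validation reports per-behavior sensitivity, per-class accuracy, the
combined walking/micromovement sensitivity (walking minutes scored as
micromovements still register as activity, not rest), the sleep-inclusive
rest accuracy (subtle immobile behaviors — posture change, proboscis
extension, single leg movement — are treated as part of sleep), and the
count of false sleep episodes (predicted-rest runs >= 5 min containing real
feeding or grooming).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .series import MinuteSeries

__all__ = [
    "PRED_CLASSES",
    "VIDEO_BEHAVIORS",
    "MICRO_BEHAVIORS",
    "SLEEP_PART_BEHAVIORS",
    "COARSE_OF",
    "ValidationReport",
    "classify_minutes",
    "video_minute_labels",
    "sensitivity",
    "accuracy",
    "combined_walk_micro_sensitivity",
    "sleep_inclusive_rest_accuracy",
    "count_false_sleep_episodes",
    "validate",
    "round_percent",
]

log = logging.getLogger(__name__)

PRED_CLASSES = ("walking", "micromovement", "rest")

#: Micromovement behaviors in video precedence order (tie-break order).
MICRO_BEHAVIORS = (
    "feeding",
    "grooming",
    "posture_change",
    "proboscis_extension",
    "single_leg_movement",
)

VIDEO_BEHAVIORS = ("rest", "walking") + MICRO_BEHAVIORS

#: Subtle immobile behaviors treated as part of sleep for the
#: sleep-inclusive rest accuracy.
SLEEP_PART_BEHAVIORS = (
    "posture_change",
    "proboscis_extension",
    "single_leg_movement",
)

#: Map from a video behavior to the monitor class that detects it.
COARSE_OF: Dict[str, str] = {
    "rest": "rest",
    "walking": "walking",
    **{b: "micromovement" for b in MICRO_BEHAVIORS},
    "micromovement": "micromovement",
}

#: False sleep = predicted rest while the fly was actually doing this.
FALSE_SLEEP_BEHAVIORS = ("feeding", "grooming")

MIN_SLEEP_RUN = 5


def round_percent(x: float) -> float:
    """Percentage rounded to 1 decimal place, half-up (88.85 -> 88.9)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def classify_minutes(series: MinuteSeries) -> np.ndarray:
    """Per-minute behavior class from multibeam channels.

    moves > 0 -> walking; else counts > 0 -> micromovement; else rest.
    """
    if series.moves is None:
        raise ValueError(
            f"{series.fly_id}: classification requires the moves channel"
        )
    out = np.full(series.n, "rest", dtype=object)
    out[series.counts > 0] = "micromovement"
    out[series.moves > 0] = "walking"
    return out


def video_minute_labels(
    interval_annotations: Sequence[Tuple[float, float, str]],
    n_minutes: int,
) -> np.ndarray:
    """Collapse labeled video intervals ``(start_s, end_s, behavior)`` to one
    label per minute by highest activity level.

    Any walking in a minute labels it walking; otherwise the micromovement
    behavior with the longest cumulative duration wins (ties broken by the
    fixed order feeding > grooming > posture_change > proboscis_extension >
    single_leg_movement); a minute with neither is rest.  Every minute must
    be covered by at least one annotation.
    """
    durations = np.zeros((n_minutes, len(VIDEO_BEHAVIORS)))
    b_index = {b: i for i, b in enumerate(VIDEO_BEHAVIORS)}
    for start_s, end_s, behavior in interval_annotations:
        if behavior not in b_index:
            raise ValueError(f"unknown behavior {behavior!r}")
        if end_s <= start_s:
            raise ValueError(f"empty interval ({start_s}, {end_s})")
        m0 = int(start_s // 60)
        m1 = int(np.ceil(end_s / 60))
        for m in range(max(m0, 0), min(m1, n_minutes)):
            lo, hi = max(start_s, m * 60), min(end_s, (m + 1) * 60)
            if hi > lo:
                durations[m, b_index[behavior]] += hi - lo
    covered = durations.sum(axis=1) > 0
    if not covered.all():
        raise ValueError(
            f"minute {int(np.flatnonzero(~covered)[0])} has no annotation"
        )
    labels = np.full(n_minutes, "rest", dtype=object)
    micro_cols = [b_index[b] for b in MICRO_BEHAVIORS]
    for m in range(n_minutes):
        if durations[m, b_index["walking"]] > 0:
            labels[m] = "walking"
            continue
        micro_d = durations[m, micro_cols]
        if micro_d.max() > 0:
            # argmax returns the first maximum -> fixed precedence tie-break
            labels[m] = MICRO_BEHAVIORS[int(np.argmax(micro_d))]
    return labels


def _as_arrays(pred: Sequence[str], truth: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.shape != truth.shape:
        raise ValueError(
            f"label vectors differ in length: {pred.shape} vs {truth.shape}"
        )
    return pred, truth


def _mapped(labels: np.ndarray, cmap: Optional[Dict[str, str]]) -> np.ndarray:
    if not cmap:
        return labels
    return np.asarray([cmap.get(x, x) for x in labels], dtype=object)


def sensitivity(
    pred: Sequence[str],
    truth: Sequence[str],
    behavior: str,
    collapse_map: Optional[Dict[str, str]] = None,
) -> Optional[float]:
    """Percent of truth-``behavior`` minutes the monitor identified.

    ``collapse_map`` (optional) maps labels — on both sides — into a common
    space first; ``behavior`` then names a collapsed class.  Without a map,
    the denominator is the raw truth behavior and agreement means the
    prediction equals that behavior's monitor class (grooming counts as
    identified when predicted micromovement).  Returns None (flagged) when
    the behavior never occurs in truth.
    """
    pred, truth = _as_arrays(pred, truth)
    t = _mapped(truth, collapse_map)
    p = _mapped(pred, collapse_map)
    target = (collapse_map or {}).get(behavior, COARSE_OF.get(behavior, behavior))
    denom = t == behavior
    n = int(denom.sum())
    if n == 0:
        log.warning("sensitivity(%s): no truth minutes; undefined", behavior)
        return None
    return 100.0 * int((denom & (p == target)).sum()) / n


def accuracy(
    pred: Sequence[str],
    truth: Sequence[str],
    cls: str,
    collapse_map: Optional[Dict[str, str]] = None,
) -> Optional[float]:
    """Percent of predicted-``cls`` minutes whose truth maps to ``cls``.

    Truth labels are mapped through ``collapse_map`` first (overriding the
    default behavior->class map).  Returns None (flagged) when the class is
    never predicted.
    """
    pred, truth = _as_arrays(pred, truth)
    cmap = dict(COARSE_OF)
    if collapse_map:
        cmap.update(collapse_map)
    t = _mapped(truth, cmap)
    denom = pred == cls
    n = int(denom.sum())
    if n == 0:
        log.warning("accuracy(%s): never predicted; undefined", cls)
        return None
    return 100.0 * int((denom & (t == cls)).sum()) / n


#: Collapse for the combined walking/micromovement sensitivity: every form
#: of movement, predicted or real, becomes one "activity" class.
_ACTIVITY_COLLAPSE = {
    "walking": "activity",
    "micromovement": "activity",
    **{b: "activity" for b in MICRO_BEHAVIORS},
}


def combined_walk_micro_sensitivity(
    pred: Sequence[str], truth: Sequence[str]
) -> Optional[float]:
    """Sensitivity for the collapsed walking+micromovement activity class.

    Walking minutes scored as micromovements still count as detected
    activity — the monitor did not falsely register them as rest.
    """
    return sensitivity(pred, truth, "activity", collapse_map=_ACTIVITY_COLLAPSE)


def sleep_inclusive_rest_accuracy(
    pred: Sequence[str], truth: Sequence[str]
) -> Optional[float]:
    """Rest accuracy after remapping posture change, proboscis extension and
    single leg movement — behaviors that occur within sleep — to rest."""
    remap = {b: "rest" for b in SLEEP_PART_BEHAVIORS}
    return accuracy(pred, truth, "rest", collapse_map=remap)


def count_false_sleep_episodes(
    pred: Sequence[str], truth: Sequence[str]
) -> int:
    """Number of predicted-rest runs >= 5 min containing >= 1 real feeding
    or grooming minute (micromovements the monitor missed for five straight
    minutes would be falsely scored as sleep)."""
    pred, truth = _as_arrays(pred, truth)
    rest = (pred == "rest").astype(np.int8)
    edges = np.diff(np.concatenate(([0], rest, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    is_fg = np.isin(truth, FALSE_SLEEP_BEHAVIORS)
    count = 0
    for s, e in zip(starts, ends):
        if e - s >= MIN_SLEEP_RUN and is_fg[s:e].any():
            count += 1
    return count


@dataclass
class ValidationReport:
    """Classifier-vs-video comparison summary.

    Percentages are reported to 1 decimal place (half-up).  Undefined
    entries (zero denominators) are None.
    """

    confusion: pd.DataFrame  # rows: predicted class, cols: truth behavior
    sensitivity_pct: Dict[str, Optional[float]]
    accuracy_pct: Dict[str, Optional[float]]
    overall_sensitivity_pct: Optional[float]
    combined_walk_micro_sensitivity_pct: Optional[float]
    sleep_inclusive_rest_accuracy_pct: Optional[float]
    false_sleep_episode_count: int
    n_minutes: int = field(default=0)

    def to_dict(self) -> dict:
        return {
            "n_minutes": self.n_minutes,
            "confusion": {
                p: {t: int(self.confusion.loc[p, t]) for t in self.confusion.columns}
                for p in self.confusion.index
            },
            "sensitivity_pct": self.sensitivity_pct,
            "accuracy_pct": self.accuracy_pct,
            "overall_sensitivity_pct": self.overall_sensitivity_pct,
            "combined_walk_micro_sensitivity_pct": (
                self.combined_walk_micro_sensitivity_pct
            ),
            "sleep_inclusive_rest_accuracy_pct": (
                self.sleep_inclusive_rest_accuracy_pct
            ),
            "false_sleep_episode_count": self.false_sleep_episode_count,
        }


def validate(pred: Sequence[str], truth: Sequence[str]) -> ValidationReport:
    """Full validation report for aligned predicted/truth label vectors."""
    pred, truth = _as_arrays(pred, truth)
    confusion = pd.DataFrame(
        0, index=list(PRED_CLASSES), columns=list(VIDEO_BEHAVIORS), dtype=int
    )
    for p, t in zip(pred, truth):
        confusion.loc[p, t] += 1
    assert int(confusion.to_numpy().sum()) == len(pred)

    def _r(v: Optional[float]) -> Optional[float]:
        return None if v is None else round_percent(v)

    sens = {b: _r(sensitivity(pred, truth, b)) for b in VIDEO_BEHAVIORS}
    acc = {c: _r(accuracy(pred, truth, c)) for c in PRED_CLASSES}
    coarse_truth = np.asarray([COARSE_OF[t] for t in truth], dtype=object)
    overall = 100.0 * float((pred == coarse_truth).sum()) / len(pred)
    return ValidationReport(
        confusion=confusion,
        sensitivity_pct=sens,
        accuracy_pct=acc,
        overall_sensitivity_pct=_r(overall),
        combined_walk_micro_sensitivity_pct=_r(
            combined_walk_micro_sensitivity(pred, truth)
        ),
        sleep_inclusive_rest_accuracy_pct=_r(
            sleep_inclusive_rest_accuracy(pred, truth)
        ),
        false_sleep_episode_count=count_false_sleep_episodes(pred, truth),
        n_minutes=len(pred),
    )
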