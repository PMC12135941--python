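"""Arousal-threshold quantification from escalating-intensity stimulus
trials.

Each trial presents a ladder of vibration intensities (20, 40, ..., 100% of
maximum).  One step is 4 pulses of (200 ms on + 800 ms off) followed by a
15-s break before the next, stronger step.  A fly counts as *sleeping* if it
was inactive for the full 5 minutes before the stimulus began; only sleeping
flies enter the curve.  The default (cumulative) curve reports, at each
intensity, the percent of sleeping flies whose first movement occurred at
that step or any weaker one — a monotone non-decreasing dose-response.  A
per-step hazard mode reports the fraction of still-asleep flies awakened at
each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "StimulusTrial",
    "ArousalCurve",
    "asleep_at_trial",
    "first_movement_step",
    "arousal_curve",
]

log = logging.getLogger(__name__)

DEFAULT_INTENSITIES = (20, 40, 60, 80, 100)
SLEEP_CRITERION_MIN = 5


@dataclass
class StimulusTrial:
    """One escalating-intensity trial.

    Step k (0-based) starts at ``k * (pulse block + break)`` seconds after
    stimulus onset; the pulse block is ``n_pulses x (on + off)``.
    """

    trial_onset_min: int
    intensities: Tuple[int, ...] = DEFAULT_INTENSITIES
    pulse_on_s: float = 0.2
    pulse_off_s: float = 0.8
    n_pulses: int = 4
    break_s: float = 15.0

    def __post_init__(self) -> None:
        if list(self.intensities) != sorted(self.intensities) or len(
            set(self.intensities)
        ) != len(self.intensities):
            raise ValueError("intensities must be strictly increasing")

    @property
    def step_duration_s(self) -> float:
        return self.n_pulses * (self.pulse_on_s + self.pulse_off_s) + self.break_s

    def step_windows(self, include_break: bool = True) -> List[Tuple[float, float]]:
        """Half-open (start_s, end_s) per step, relative to stimulus onset.

        With ``include_break`` (default) a movement during the trailing
        break still attributes to the step that preceded it — manual video
        scoring has no fixed response latency.
        """
        pulse_block = self.n_pulses * (self.pulse_on_s + self.pulse_off_s)
        out = []
        for k in range(len(self.intensities)):
            start = k * self.step_duration_s
            end = start + (self.step_duration_s if include_break else pulse_block)
            out.append((start, end))
        return out


@dataclass
class ArousalCurve:
    """Percent of sleeping flies awakened per intensity."""

    intensities: Tuple[int, ...]
    percent_awakened: np.ndarray
    n_sleeping: int
    mode: str = "cumulative"


def asleep_at_trial(
    activity_per_min: Sequence[float], trial_onset_min: int
) -> bool:
    """True iff the fly showed zero movement in the 5 min before onset."""
    if trial_onset_min < SLEEP_CRITERION_MIN:
        raise ValueError(
            f"trial onset {trial_onset_min} leaves no room for the "
            f"{SLEEP_CRITERION_MIN}-min sleep criterion"
        )
    a = np.asarray(activity_per_min)
    if len(a) < trial_onset_min:
        raise ValueError(
            f"record ({len(a)} min) does not cover trial onset "
            f"{trial_onset_min}"
        )
    window = a[trial_onset_min - SLEEP_CRITERION_MIN : trial_onset_min]
    return bool(window.sum() == 0)


def first_movement_step(
    movement_times_s: Sequence[float],
    trial: StimulusTrial,
    include_break: bool = True,
) -> Optional[int]:
    """Index of the first intensity step containing a movement, or None.

    Times are seconds since stimulus onset.
    """
    windows = trial.step_windows(include_break)
    times = np.sort(np.asarray(movement_times_s, dtype=float))
    for t in times:
        for k, (lo, hi) in enumerate(windows):
            if lo <= t < hi:
                return k
    return None


def arousal_curve(
    sleeping: Sequence[bool],
    first_steps: Sequence[Optional[int]],
    intensities: Tuple[int, ...] = DEFAULT_INTENSITIES,
    mode: str = "cumulative",
) -> ArousalCurve:
    """Arousal curve over a cohort of flies.

    ``sleeping[i]`` marks whether fly i met the 5-min pre-stimulus sleep
    criterion; ``first_steps[i]`` is the step index of its first movement
    (None if it never moved).  Awake-at-onset flies never enter numerator or
    denominator.  ``cumulative`` (default): percent whose first movement was
    at step <= k.  ``per_step``: hazard — percent of still-asleep flies
    awakened exactly at step k.
    """
    sleeping = np.asarray(sleeping, dtype=bool)
    steps = np.asarray(
        [-1 if s is None else int(s) for s in first_steps], dtype=int
    )
    if sleeping.shape != steps.shape:
        raise ValueError("sleeping and first_steps differ in length")
    steps = steps[sleeping]
    n = int(sleeping.sum())
    if n == 0:
        raise ValueError("no sleeping flies at trial onset; curve undefined")
    k_axis = np.arange(len(intensities))
    if mode == "cumulative":
        pct = np.array(
            [100.0 * ((steps >= 0) & (steps <= k)).sum() / n for k in k_axis]
        )
    elif mode == "per_step":
        pct = np.empty(len(k_axis))
        for k in k_axis:
            at_risk = ((steps < 0) | (steps >= k)).sum()
            woke = (steps == k).sum()
            pct[k] = 100.0 * woke / at_risk if at_risk else np.nan
    else:
        raise ValueError(f"mode must be 'cumulative' or 'per_step', got {mode!r}")
    return ArousalCurve(
        intensities=tuple(intensities),
        percent_awakened=pct,
        n_sleeping=n,
        mode=mode,
    )
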