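"""Courtship-memory statistics: courtship index (CI), the <10% exclusion
rule, and the suppression index (SI).

A male is paired with a tester female for a 10-min test and the time spent
on courtship behaviors is annotated as intervals.  CI is the percent of the
test spent courting (overlapping intervals are merged first).  Flies with
CI below 10% court too little to be informative and are excluded from both
groups.  Courtship memory is read out as

    SI = 100 x (1 - CI_trained / CI_untrained)

where trained and untrained flies are distinct individuals, so the group
mean of the untrained CIs serves as the denominator for both the group SI
and the per-fly SIs (used for testing SI = 0).  With a shared denominator,
mean(per-fly SI) equals the group SI exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CourtshipRecord",
    "GroupSI",
    "merge_intervals",
    "courtship_index",
    "apply_exclusion",
    "suppression_index",
    "CI_EXCLUSION_THRESHOLD",
]

log = logging.getLogger(__name__)

CI_EXCLUSION_THRESHOLD = 10.0
DEFAULT_TEST_DURATION_S = 600.0


@dataclass
class CourtshipRecord:
    """One male's annotated 10-min courtship test."""

    fly_id: str
    group: str  # "trained" or "untrained"
    courting_intervals: List[Tuple[float, float]]
    test_duration_s: float = DEFAULT_TEST_DURATION_S
    condition: str = ""

    def __post_init__(self) -> None:
        if self.group not in ("trained", "untrained"):
            raise ValueError(f"group must be trained/untrained, got {self.group!r}")
        for s, e in self.courting_intervals:
            if not (0 <= s < e <= self.test_duration_s):
                raise ValueError(
                    f"{self.fly_id}: interval ({s}, {e}) outside "
                    f"[0, {self.test_duration_s}]"
                )


@dataclass
class GroupSI:
    """Suppression-index summary for one condition."""

    ci_untrained: np.ndarray
    ci_trained: np.ndarray
    si_per_fly: np.ndarray
    si_group: float


def merge_intervals(
    intervals: Sequence[Tuple[float, float]],
) -> List[Tuple[float, float]]:
    """Union of possibly-overlapping intervals, sorted and disjoint."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def courtship_index(record: CourtshipRecord) -> float:
    """CI = 100 x merged courting time / test duration."""
    if record.test_duration_s <= 0:
        raise ValueError(f"{record.fly_id}: empty test")
    courting = sum(e - s for s, e in merge_intervals(record.courting_intervals))
    return 100.0 * courting / record.test_duration_s


def apply_exclusion(
    cis: Sequence[float], threshold: float = CI_EXCLUSION_THRESHOLD
) -> np.ndarray:
    """Drop CIs below ``threshold`` (applied to both groups alike).

    Order-independent and idempotent; removals are logged.
    """
    cis = np.asarray(cis, dtype=float)
    keep = cis >= threshold
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info(
            "excluded %d/%d flies with CI < %g%%", n_dropped, len(cis), threshold
        )
    return cis[keep]


def suppression_index(
    trained_cis: Sequence[float], untrained_cis: Sequence[float]
) -> GroupSI:
    """Group and per-fly SI with the untrained group mean as denominator."""
    trained = np.asarray(trained_cis, dtype=float)
    untrained = np.asarray(untrained_cis, dtype=float)
    if len(trained) == 0 or len(untrained) == 0:
        raise ValueError("both groups must be non-empty after exclusion")
    denom = untrained.mean()
    if denom == 0:
        raise ValueError("mean untrained CI is 0; SI undefined")
    si_per_fly = 100.0 * (1.0 - trained / denom)
    si_group = 100.0 * (1.0 - trained.mean() / denom)
    return GroupSI(
        ci_untrained=untrained,
        ci_trained=trained,
        si_per_fly=si_per_fly,
        si_group=float(si_group),
    )
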