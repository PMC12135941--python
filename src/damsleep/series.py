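"""Core per-fly containers.

A :class:`MinuteSeries` is one fly's contiguous record of 1-min binned
activity from a beam-break monitor.  Single-beam (DAM2-style) records carry
only ``counts``; multibeam (DAM5H-style) records additionally carry ``moves``
(cross-beam transitions) and ``position`` (beam index 1..15).  Every
per-minute vector has the same length and the bins are gapless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["MinuteSeries", "LightSchedule", "N_BEAMS"]

#: Number of independent infrared beams in a multibeam monitor tube.
N_BEAMS = 15

MINUTES_PER_DAY = 1440


@dataclass
class LightSchedule:
    """A 12:12 light:dark cycle anchored to the series clock.

    ``zt0_offset_min`` is the number of minutes from the start of the series
    to the first lights-on (ZT0).  It may be negative or exceed one day; only
    its value modulo 1440 matters.
    """

    zt0_offset_min: int = 0
    light_min: int = 720
    dark_min: int = 720

    def __post_init__(self) -> None:
        if self.light_min + self.dark_min != MINUTES_PER_DAY:
            raise ValueError(
                "photoperiod must sum to 1440 min, got "
                f"{self.light_min}+{self.dark_min}"
            )

    def zt_minutes(self, n: int) -> np.ndarray:
        """Zeitgeber time (minutes since lights-on, 0..1439) for bins 0..n-1."""
        return (np.arange(n) - self.zt0_offset_min) % MINUTES_PER_DAY

    def is_light(self, n: int) -> np.ndarray:
        """Boolean light-phase mask for bins 0..n-1."""
        return self.zt_minutes(n) < self.light_min


@dataclass
class MinuteSeries:
    """One fly's contiguous 1-min binned activity record.

    Parameters
    ----------
    fly_id:
        Identifier, unique within a cohort.
    t0:
        Timestamp of the first bin (bins are [t0 + i min, t0 + (i+1) min)).
    counts:
        Per-minute beam-break counts (single-beam activity, or within-beam
        activity for multibeam monitors).  Non-negative integers.
    light:
        Per-minute light state (True = lights on).
    led:
        Per-minute stimulation-LED duty fraction in [0, 1].
    moves:
        Optional per-minute cross-beam transition counts (multibeam only).
    position:
        Optional per-minute beam index in 1..15; present iff ``moves`` is.
    completeness:
        Optional per-bin fraction of expected raw readings actually present;
        bins below 0.5 are considered unreliable (see :attr:`flagged`).
    """

    fly_id: str
    t0: pd.Timestamp
    counts: np.ndarray
    light: np.ndarray
    led: np.ndarray
    moves: Optional[np.ndarray] = None
    position: Optional[np.ndarray] = None
    completeness: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t0 = pd.Timestamp(self.t0)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.light = np.asarray(self.light, dtype=bool)
        self.led = np.asarray(self.led, dtype=float)
        if self.moves is not None:
            self.moves = np.asarray(self.moves, dtype=np.int64)
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=np.int64)
        if self.completeness is not None:
            self.completeness = np.asarray(self.completeness, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n = len(self.counts)
        for name in ("light", "led", "moves", "position", "completeness"):
            vec = getattr(self, name)
            if vec is not None and len(vec) != n:
                raise ValueError(
                    f"{self.fly_id}: '{name}' has length {len(vec)}, "
                    f"expected {n}"
                )
        if np.any(self.counts < 0):
            raise ValueError(f"{self.fly_id}: negative counts")
        if (self.moves is None) != (self.position is None):
            raise ValueError(
                f"{self.fly_id}: moves and position must be present together"
            )
        if self.moves is not None:
            if np.any(self.moves < 0):
                raise ValueError(f"{self.fly_id}: negative moves")
            bad = (self.position < 1) | (self.position > N_BEAMS)
            if np.any(bad):
                raise ValueError(
                    f"{self.fly_id}: beam position outside 1..{N_BEAMS} "
                    f"at bin {int(np.flatnonzero(bad)[0])}"
                )
        if np.any((self.led < 0) | (self.led > 1)):
            raise ValueError(f"{self.fly_id}: led duty outside [0, 1]")

    @property
    def n(self) -> int:
        """Number of 1-min bins."""
        return len(self.counts)

    @property
    def is_multibeam(self) -> bool:
        return self.moves is not None

    @property
    def flagged(self) -> np.ndarray:
        """Boolean mask of bins with <50% of expected raw readings."""
        if self.completeness is None:
            return np.zeros(self.n, dtype=bool)
        return self.completeness < 0.5

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MinuteSeries):
            return NotImplemented

        def _opt_eq(a, b):
            if a is None or b is None:
                return a is None and b is None
            return np.array_equal(a, b)

        return (
            self.fly_id == other.fly_id
            and self.t0 == other.t0
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.light, other.light)
            and np.allclose(self.led, other.led)
            and _opt_eq(self.moves, other.moves)
            and _opt_eq(self.position, other.position)
            and _opt_eq(
                np.ones(self.n) if self.completeness is None else self.completeness,
                np.ones(other.n) if other.completeness is None else other.completeness,
            )
        )
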