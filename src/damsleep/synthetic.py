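"""Synthetic activity-monitor data with exported ground truth.

Every analysis in this package operates on 1-min binned beam-break records,
so the generator works at minute resolution: a two-state (wake/sleep)
Markov chain per fly, with the wake->sleep rate modulated multiplicatively
by circadian phase (flies fall asleep more readily in the dark), by
optogenetic stimulation while the LED duty fraction is positive, and by
accumulated sleep pressure after forced waking.  Sub-minute structure —
pulse trains, beam geometry — is represented only through per-minute duty
fractions and Poisson event rates.

Emissions follow the multibeam classifier's own vocabulary: awake minutes
draw cross-beam ``moves`` and within-beam ``counts`` from independent
Poissons and are labeled walking (moves > 0), a micromovement behavior
(counts > 0 only), or rest; sleeping minutes are silent except that with a
small probability a posture-change-like micromovement emits a single count.
Beam position performs a bounded random walk over beams 1..15 during wake.

Identical seed + config give bit-identical output; per-fly seeds derive
from a stable hash of (master seed, fly id), so cohorts reproduce under
insertion-order changes.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .series import MinuteSeries, MINUTES_PER_DAY, N_BEAMS

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PROTOCOL_DUTY",
    "led_schedule",
    "simulate_fly",
    "simulate_deprivation",
    "simulate_cohort",
    "write_ground_truth",
    "read_ground_truth",
    "fly_seed",
]

log = logging.getLogger(__name__)

#: Per-minute LED duty fraction for each stimulation protocol.
#: 1 Hz: 5 ms on / 995 ms off; regular: (5 on + 95 off) x 20 then a 4-s
#: delay; 10/20/50 Hz: 5 ms on with 95/45/15 ms off, flashing continuously.
PROTOCOL_DUTY: Dict[str, float] = {
    "off": 0.0,
    "1hz": 5.0 / 1000.0,
    "regular": (20 * 5.0) / (20 * 100.0 + 4000.0),
    "10hz": 5.0 / 100.0,
    "20hz": 5.0 / 50.0,
    "50hz": 5.0 / 20.0,
    "constant": 1.0,
}

#: Behavior emitted by awake minutes with counts but no moves, with the
#: relative frequencies the generator uses.
WAKE_MICRO_BEHAVIORS = (
    ("feeding", 0.35),
    ("grooming", 0.35),
    ("posture_change", 0.15),
    ("proboscis_extension", 0.10),
    ("single_leg_movement", 0.05),
)

#: Simulated recordings start at lights-on (ZT0).
SIM_T0 = pd.Timestamp("2024-01-01 08:00:00")


@dataclass
class SimConfig:
    """Generator parameters.

    p_ws, p_sw:
        Per-minute wake->sleep and sleep->wake base probabilities (p_ws
        applies during the light phase; see ``circadian_gain``).
    circadian_gain:
        Multiplier on p_ws during the dark phase (> 1: more night sleep).
    led_effect:
        Multiplier on p_ws while the LED duty fraction is positive
        (1.0 = stimulation has no effect).
    lambda_moves, lambda_counts:
        Mean cross-beam and within-beam events per awake minute.
    p_sleep_micro:
        Per-sleep-minute probability of a posture-change-like micromovement
        emitting one count.
    rebound_gain, rebound_decay:
        Sleep-pressure dynamics: pressure rises by ``rebound_gain`` per
        forced-wake minute and decays geometrically by ``rebound_decay``
        per minute; (1 + pressure) multiplies p_ws.
    """

    p_ws: float = 0.05
    p_sw: float = 0.05
    circadian_gain: float = 2.0
    led_effect: float = 1.0
    lambda_moves: float = 1.0
    lambda_counts: float = 2.0
    p_sleep_micro: float = 0.02
    rebound_gain: float = 0.003
    rebound_decay: float = 0.998
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_ws", "p_sw", "p_sleep_micro"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "circadian_gain",
            "led_effect",
            "lambda_moves",
            "lambda_counts",
            "rebound_gain",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.rebound_decay <= 1:
            raise ValueError("rebound_decay must be in [0, 1]")


@dataclass
class GroundTruth:
    """Simulator-exported per-minute latent state and behavior labels."""

    fly_id: str
    state: np.ndarray  # "wake" / "sleep"
    behavior: np.ndarray  # rest/walking/feeding/.../posture_change

    @property
    def n(self) -> int:
        return len(self.state)


def led_schedule(
    protocol_name: str, window: Union[int, Tuple[int, int]]
) -> np.ndarray:
    """Per-minute LED duty fraction for a named protocol.

    ``window`` is either a bin count (duty over [0, n)) or a half-open
    (start, end) minute interval — duty is the protocol value inside and the
    returned vector covers only the window.
    """
    key = protocol_name.lower()
    if key not in PROTOCOL_DUTY:
        raise ValueError(
            f"unknown protocol {protocol_name!r}; "
            f"choose from {sorted(PROTOCOL_DUTY)}"
        )
    n = window if isinstance(window, int) else window[1] - window[0]
    if n < 0:
        raise ValueError(f"empty window {window}")
    return np.full(n, PROTOCOL_DUTY[key])


def fly_seed(master_seed: int, fly_id: str) -> int:
    """Stable per-fly seed below 2**31 from (master seed, fly id)."""
    digest = hashlib.blake2s(
        f"{master_seed}:{fly_id}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _simulate_states(
    cfg: SimConfig,
    light: np.ndarray,
    duty: np.ndarray,
    forced_wake: np.ndarray,
    u: np.ndarray,
) -> np.ndarray:
    """Latent minute-by-minute chain; 0 = wake, 1 = sleep."""
    n = len(light)
    state = np.zeros(n, dtype=np.int8)
    s = 0  # recordings start at lights-on with the fly awake
    pressure = 0.0
    clipped = 0
    for t in range(n):
        if forced_wake[t]:
            s = 0
            pressure = pressure * cfg.rebound_decay + cfg.rebound_gain
            state[t] = s
            continue
        p = cfg.p_ws
        if not light[t]:
            p *= cfg.circadian_gain
        if duty[t] > 0:
            p *= cfg.led_effect
        p *= 1.0 + pressure
        if p > 1.0:
            p = 1.0
            clipped += 1
        if s == 0:
            if u[t] < p:
                s = 1
        else:
            if u[t] < cfg.p_sw:
                s = 0
        state[t] = s
        pressure *= cfg.rebound_decay
    if clipped:
        log.info("wake->sleep probability clipped to 1 on %d minutes", clipped)
    return state


def simulate_fly(
    config: SimConfig,
    n_days: int,
    led_protocol: str = "off",
    led_days: Sequence[int] = (),
    sd_window: Optional[Tuple[int, int]] = None,
    fly_id: str = "fly",
    rng: Optional[np.random.Generator] = None,
) -> Tuple[MinuteSeries, GroundTruth]:
    """Simulate one fly for ``n_days`` under a 12:12 light:dark cycle.

    ``led_days`` lists 0-based day indices on which the LED protocol runs
    (all day).  ``sd_window`` optionally forces wakefulness over a half-open
    minute interval (mechanical deprivation), engaging the sleep-pressure
    rebound dynamics.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = n_days * MINUTES_PER_DAY
    light = (np.arange(n) % MINUTES_PER_DAY) < 720
    duty = np.zeros(n)
    if led_protocol.lower() != "off":
        day_duty = led_schedule(led_protocol, MINUTES_PER_DAY)
        for d in led_days:
            if not 0 <= d < n_days:
                raise ValueError(f"led day {d} outside 0..{n_days - 1}")
            duty[d * MINUTES_PER_DAY : (d + 1) * MINUTES_PER_DAY] = day_duty
    forced = np.zeros(n, dtype=bool)
    if sd_window is not None:
        s, e = sd_window
        if not 0 <= s < e <= n:
            raise ValueError(f"sd_window {sd_window} outside simulated span")
        forced[s:e] = True

    u = rng.random(n)
    state = _simulate_states(config, light, duty, forced, u)
    wake = state == 0

    counts = np.zeros(n, dtype=np.int64)
    moves = np.zeros(n, dtype=np.int64)
    behavior = np.full(n, "rest", dtype=object)

    wake_idx = np.flatnonzero(wake)
    moves[wake_idx] = rng.poisson(config.lambda_moves, wake_idx.size)
    counts[wake_idx] = rng.poisson(config.lambda_counts, wake_idx.size)
    # forced-wake minutes always register activity (the device jolts the fly)
    counts[forced] += 1

    micro_draw = rng.random(wake_idx.size)
    micro_labels = [b for b, _ in WAKE_MICRO_BEHAVIORS]
    micro_cum = np.cumsum([p for _, p in WAKE_MICRO_BEHAVIORS])
    micro_cum /= micro_cum[-1]
    for j, t in enumerate(wake_idx):
        if moves[t] > 0:
            behavior[t] = "walking"
        elif counts[t] > 0:
            behavior[t] = micro_labels[int(np.searchsorted(micro_cum, micro_draw[j], side="right"))]

    sleep_idx = np.flatnonzero(~wake)
    if sleep_idx.size and config.p_sleep_micro > 0:
        hit = rng.random(sleep_idx.size) < config.p_sleep_micro
        counts[sleep_idx[hit]] = 1
        behavior[sleep_idx[hit]] = "posture_change"

    steps = rng.integers(-2, 3, n)
    position = np.empty(n, dtype=np.int64)
    pos = (N_BEAMS + 1) // 2
    for t in range(n):
        if wake[t]:
            pos = min(N_BEAMS, max(1, pos + int(steps[t])))
        position[t] = pos

    series = MinuteSeries(
        fly_id=fly_id,
        t0=SIM_T0,
        counts=counts,
        light=light,
        led=duty,
        moves=moves,
        position=position,
    )
    truth = GroundTruth(
        fly_id=fly_id,
        state=np.where(wake, "wake", "sleep").astype(object),
        behavior=behavior,
    )
    return series, truth


def simulate_deprivation(
    config: SimConfig,
    sd_window: Tuple[int, int],
    n_days: int = 4,
    fly_id: str = "fly",
    rng: Optional[np.random.Generator] = None,
) -> Tuple[MinuteSeries, GroundTruth]:
    """Simulate a deprivation experiment: forced wake over ``sd_window``
    with rebound dynamics afterwards (day 0 serves as baseline when the
    window sits in a later day)."""
    return simulate_fly(
        config, n_days, sd_window=sd_window, fly_id=fly_id, rng=rng
    )


def simulate_cohort(
    config: SimConfig,
    fly_ids: Union[int, Sequence[str]],
    n_days: int,
    led_protocol: str = "off",
    led_days: Sequence[int] = (),
    sd_window: Optional[Tuple[int, int]] = None,
    master_seed: Optional[int] = None,
) -> Tuple[List[MinuteSeries], List[GroundTruth]]:
    """Simulate many flies with per-fly seeds derived from a master seed.

    ``fly_ids`` is either a count (ids ``fly001``...) or explicit ids
    (duplicates rejected).  ``master_seed`` defaults to ``config.seed``.
    """
    if isinstance(fly_ids, int):
        fly_ids = [f"fly{i + 1:03d}" for i in range(fly_ids)]
    if len(set(fly_ids)) != len(fly_ids):
        raise ValueError("duplicate fly_ids in cohort")
    if master_seed is None:
        master_seed = config.seed
    series_list, truth_list = [], []
    for fid in fly_ids:
        rng = np.random.default_rng(fly_seed(master_seed, fid))
        s, t = simulate_fly(
            config,
            n_days,
            led_protocol=led_protocol,
            led_days=led_days,
            sd_window=sd_window,
            fly_id=fid,
            rng=rng,
        )
        series_list.append(s)
        truth_list.append(t)
    return series_list, truth_list


def write_ground_truth(
    truths: Sequence[GroundTruth], path: Union[str, Path]
) -> None:
    frames = [
        pd.DataFrame(
            {
                "fly_id": t.fly_id,
                "minute_index": np.arange(t.n),
                "state": t.state,
                "behavior": t.behavior,
            }
        )
        for t in truths
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_ground_truth(path: Union[str, Path]) -> List[GroundTruth]:
    df = pd.read_csv(path)
    out = []
    for fid, sub in df.groupby("fly_id", sort=False):
        sub = sub.sort_values("minute_index")
        out.append(
            GroundTruth(
                fly_id=str(fid),
                state=sub["state"].to_numpy(object),
                behavior=sub["behavior"].to_numpy(object),
            )
        )
    return out
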