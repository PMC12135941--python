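"""Monitor-file ingestion and the canonical interchange format.

Trikinetics-style monitor files are tab-separated with one row per reading:
a record index, date, time, a status code, a run of metadata columns, then
one value per channel.  Firmware variants shuffle the metadata columns, so
the layout is configured through a :class:`ChannelMap` rather than
hard-coded.

The canonical interchange format is a long-format CSV
(``fly_id, minute_index, iso_time, counts, moves, position, light, led,
completeness``) plus a JSON sidecar (``<path>.json``) holding the schema
version and per-fly metadata.  It round-trips losslessly and is byte-stable
under a fixed field ordering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .series import MinuteSeries, N_BEAMS

__all__ = [
    "ChannelMap",
    "ParseError",
    "SchemaError",
    "read_single_beam",
    "read_multibeam",
    "write_canonical",
    "read_canonical",
]

log = logging.getLogger(__name__)

CANONICAL_SCHEMA_VERSION = 1
CANONICAL_COLUMNS = [
    "fly_id",
    "minute_index",
    "iso_time",
    "counts",
    "moves",
    "position",
    "light",
    "led",
    "completeness",
]

#: Valid-data status code in Trikinetics monitor files.
STATUS_OK = 1


class ParseError(ValueError):
    """A monitor file violated its preconditions (row number in message)."""


class SchemaError(ValueError):
    """Canonical-file schema version mismatch."""


@dataclass
class ChannelMap:
    """Column layout and channel assignment for a raw monitor file.

    ``channels`` maps 1-based channel numbers to a fly id (single-beam) or to
    a ``(fly_id, quantity)`` pair with quantity in {"counts", "moves",
    "position"} (multibeam).  ``first_data_col`` is the 0-based index of
    channel 1's column; the conventional 42-column layout puts it at 10.
    """

    channels: Dict[int, Union[str, Tuple[str, str]]]
    first_data_col: int = 10
    date_col: int = 1
    time_col: int = 2
    status_col: int = 3

    QUANTITIES = ("counts", "moves", "position")

    def __post_init__(self) -> None:
        for ch, spec in self.channels.items():
            if not isinstance(ch, int) or ch < 1:
                raise ValueError(f"channel numbers are 1-based ints, got {ch!r}")
            if isinstance(spec, (tuple, list)):
                fly, qty = spec
                if qty not in self.QUANTITIES:
                    raise ValueError(
                        f"channel {ch}: quantity {qty!r} not in {self.QUANTITIES}"
                    )

    @property
    def is_multibeam(self) -> bool:
        return any(isinstance(v, (tuple, list)) for v in self.channels.values())

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ChannelMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        channels: Dict[int, Union[str, Tuple[str, str]]] = {}
        for ch, spec in raw["channels"].items():
            ch = int(ch)
            if isinstance(spec, dict):
                channels[ch] = (str(spec["fly"]), str(spec["quantity"]))
            else:
                channels[ch] = str(spec)
        kwargs = {
            k: int(raw[k])
            for k in ("first_data_col", "date_col", "time_col", "status_col")
            if k in raw
        }
        return cls(channels=channels, **kwargs)


def _parse_timestamps(date_s: pd.Series, time_s: pd.Series) -> pd.Series:
    joined = date_s.str.strip() + " " + time_s.str.strip()
    for fmt in ("%d %b %y %H:%M:%S", "%Y-%m-%d %H:%M:%S"):
        try:
            return pd.to_datetime(joined, format=fmt)
        except ValueError:
            continue
    raise ParseError(
        "unrecognised date/time format (expected '8 Jan 24 08:00:00' "
        "or ISO '2024-01-08 08:00:00')"
    )


def _load_raw(
    path: Union[str, Path], cmap: ChannelMap, reading_interval_s: int
) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Read a raw monitor TSV -> (frame, epoch minute of each row, ok mask)."""
    if 60 % reading_interval_s != 0:
        raise ValueError(
            f"reading_interval_s={reading_interval_s} must divide 60"
        )
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.empty:
        raise ParseError(f"{path}: empty monitor file")
    ts = _parse_timestamps(df.iloc[:, cmap.date_col], df.iloc[:, cmap.time_col])
    secs = ts.astype("int64") // 10**9
    diffs = np.diff(secs.to_numpy())
    bad = np.flatnonzero(diffs <= 0)
    if bad.size:
        row = int(bad[0]) + 1
        raise ParseError(
            f"{path}: non-monotone timestamp at row {row + 1} "
            f"({ts.iloc[row]!s} follows {ts.iloc[row - 1]!s})"
        )
    status = pd.to_numeric(df.iloc[:, cmap.status_col], errors="coerce")
    ok = (status == STATUS_OK).to_numpy()
    if not ok.all():
        log.warning(
            "%s: %d readings carry an error status; their bins are "
            "treated as incomplete, not zeroed",
            path,
            int((~ok).sum()),
        )
    minutes = (secs.to_numpy() // 60).astype(np.int64)
    return df, minutes, ok


def _channel_values(df: pd.DataFrame, cmap: ChannelMap, channel: int) -> np.ndarray:
    col = cmap.first_data_col + channel - 1
    if col >= df.shape[1]:
        raise ParseError(
            f"channel {channel} maps to column {col} but file has "
            f"{df.shape[1]} columns"
        )
    vals = pd.to_numeric(df.iloc[:, col], errors="raise").to_numpy()
    if np.any(vals < 0):
        raise ParseError(f"channel {channel}: negative reading")
    return vals.astype(np.int64)


def _bin_layout(
    minutes: np.ndarray, readings_per_bin: int
) -> Tuple[np.ndarray, int, int]:
    """Whole-minute bin span after dropping partial leading/trailing bins.

    Returns (per-row bin index relative to the first kept bin, first kept
    epoch minute, number of kept bins).  Rows outside the span get index -1.
    """
    uniq, counts_per_min = np.unique(minutes, return_counts=True)
    first, last = uniq[0], uniq[-1]
    if counts_per_min[0] < readings_per_bin:
        log.info("dropping partial leading minute %d", first)
        first += 1
    if counts_per_min[-1] < readings_per_bin and last >= first:
        log.info("dropping partial trailing minute %d", last)
        last -= 1
    n_bins = int(last - first + 1)
    if n_bins <= 0:
        raise ParseError("no whole-minute bins after trimming partial edges")
    rel = minutes - first
    rel[(rel < 0) | (rel >= n_bins)] = -1
    return rel, int(first), n_bins


def _light_vector(t0: pd.Timestamp, n: int, lights_on: str) -> np.ndarray:
    on_h, on_m = (int(x) for x in lights_on.split(":"))
    start = t0.hour * 60 + t0.minute
    zt = (np.arange(n) + start - (on_h * 60 + on_m)) % 1440
    return zt < 720


def _aggregate_sum(
    values: np.ndarray, rel: np.ndarray, ok: np.ndarray, n_bins: int
) -> np.ndarray:
    keep = (rel >= 0) & ok
    return np.bincount(rel[keep], weights=values[keep], minlength=n_bins).astype(
        np.int64
    )


def _completeness(
    rel: np.ndarray, ok: np.ndarray, n_bins: int, readings_per_bin: int
) -> np.ndarray:
    keep = (rel >= 0) & ok
    got = np.bincount(rel[keep], minlength=n_bins)
    frac = got / readings_per_bin
    n_flagged = int((frac < 0.5).sum())
    if n_flagged:
        log.warning("%d bins <50%% complete (flagged)", n_flagged)
    return frac


def read_single_beam(
    path: Union[str, Path],
    channel_map: ChannelMap,
    reading_interval_s: int = 60,
    lights_on: str = "08:00",
) -> List[MinuteSeries]:
    """Parse a single-beam (DAM2-style) monitor file into per-fly series.

    Counts are summed into whole 1-min bins of the monitor clock; partial
    leading/trailing minutes are dropped.  Missing or error-status readings
    inside a bin contribute zero activity but lower that bin's completeness
    fraction.  Light state follows a 12:12 cycle anchored at ``lights_on``.
    """
    cmap = channel_map
    if cmap.is_multibeam:
        raise ValueError("channel_map assigns quantities; use read_multibeam")
    df, minutes, ok = _load_raw(path, cmap, reading_interval_s)
    rpb = 60 // reading_interval_s
    rel, first_min, n_bins = _bin_layout(minutes, rpb)
    t0 = pd.Timestamp(first_min * 60, unit="s")
    light = _light_vector(t0, n_bins, lights_on)
    led = np.zeros(n_bins)
    comp = _completeness(rel, ok, n_bins, rpb)
    out = []
    for ch in sorted(cmap.channels):
        fly_id = cmap.channels[ch]
        counts = _aggregate_sum(_channel_values(df, cmap, ch), rel, ok, n_bins)
        out.append(
            MinuteSeries(
                fly_id=str(fly_id),
                t0=t0,
                counts=counts,
                light=light,
                led=led.copy(),
                completeness=comp.copy(),
            )
        )
    return out


def read_multibeam(
    path: Union[str, Path],
    channel_map: ChannelMap,
    reading_interval_s: int = 60,
    lights_on: str = "08:00",
) -> List[MinuteSeries]:
    """Parse a multibeam (DAM5H-style) monitor file into per-fly series.

    Per minute: ``moves`` and ``counts`` are summed; ``position`` is the last
    valid position reading in the bin (carried forward over empty bins).
    """
    cmap = channel_map
    if not cmap.is_multibeam:
        raise ValueError("channel_map has no quantities; use read_single_beam")
    df, minutes, ok = _load_raw(path, cmap, reading_interval_s)
    rpb = 60 // reading_interval_s
    rel, first_min, n_bins = _bin_layout(minutes, rpb)
    t0 = pd.Timestamp(first_min * 60, unit="s")
    light = _light_vector(t0, n_bins, lights_on)
    comp = _completeness(rel, ok, n_bins, rpb)

    per_fly: Dict[str, Dict[str, np.ndarray]] = {}
    for ch in sorted(cmap.channels):
        fly_id, qty = cmap.channels[ch]
        vals = _channel_values(df, cmap, ch)
        per_fly.setdefault(str(fly_id), {})[qty] = vals

    out = []
    for fly_id, chans in per_fly.items():
        missing = set(("counts", "moves", "position")) - set(chans)
        if missing:
            raise ParseError(f"{fly_id}: missing channels {sorted(missing)}")
        counts = _aggregate_sum(chans["counts"], rel, ok, n_bins)
        moves = _aggregate_sum(chans["moves"], rel, ok, n_bins)
        pos_raw = chans["position"]
        valid = (rel >= 0) & ok
        bad = valid & ((pos_raw < 1) | (pos_raw > N_BEAMS))
        if np.any(bad):
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{fly_id}: position {pos_raw[row]} outside 1..{N_BEAMS} "
                f"at row {row + 1}"
            )
        position = np.zeros(n_bins, dtype=np.int64)
        # last reading in each bin wins; empty bins carry the previous value
        for b, p in zip(rel[valid], pos_raw[valid]):
            position[b] = p
        last = 1
        for i in range(n_bins):
            if position[i] == 0:
                position[i] = last
            else:
                last = position[i]
        out.append(
            MinuteSeries(
                fly_id=fly_id,
                t0=t0,
                counts=counts,
                light=light,
                led=np.zeros(n_bins),
                moves=moves,
                position=position,
                completeness=comp.copy(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# canonical interchange format


def write_canonical(
    series_list: Sequence[MinuteSeries], path: Union[str, Path]
) -> None:
    """Write series to the canonical long CSV + JSON sidecar.

    Output is byte-stable: fixed column order, fixed float formatting, and
    fly blocks in input order.
    """
    path = Path(path)
    frames = []
    meta_flies = {}
    fly_order = []
    for s in series_list:
        if s.fly_id in meta_flies:
            raise ValueError(f"duplicate fly_id {s.fly_id!r}")
        fly_order.append(s.fly_id)
        meta_flies[s.fly_id] = {
            "t0": s.t0.isoformat(),
            "n": int(s.n),
            "multibeam": bool(s.is_multibeam),
        }
        idx = np.arange(s.n)
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": s.fly_id,
                    "minute_index": idx,
                    "iso_time": (
                        s.t0 + pd.to_timedelta(idx, unit="min")
                    ).strftime("%Y-%m-%dT%H:%M:%S"),
                    "counts": s.counts,
                    "moves": s.moves if s.moves is not None else "",
                    "position": s.position if s.position is not None else "",
                    "light": s.light.astype(int),
                    "led": s.led,
                    "completeness": (
                        s.completeness
                        if s.completeness is not None
                        else np.ones(s.n)
                    ),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=CANONICAL_COLUMNS
    )
    df.to_csv(path, index=False, columns=CANONICAL_COLUMNS, float_format="%.6g")
    sidecar = {
        "schema_version": CANONICAL_SCHEMA_VERSION,
        "fly_order": fly_order,
        "flies": meta_flies,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_canonical(path: Union[str, Path]) -> List[MinuteSeries]:
    """Read the canonical CSV + sidecar back into a list of series."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    version = sidecar.get("schema_version")
    if version != CANONICAL_SCHEMA_VERSION:
        raise SchemaError(
            f"canonical schema version {version!r}; this reader supports "
            f"{CANONICAL_SCHEMA_VERSION}"
        )
    df = pd.read_csv(path)
    out = []
    for fly_id in sidecar["fly_order"]:
        meta = sidecar["flies"][fly_id]
        sub = df[df["fly_id"] == fly_id].sort_values("minute_index")
        if len(sub) != meta["n"]:
            raise SchemaError(
                f"{fly_id}: sidecar says n={meta['n']} but CSV has {len(sub)}"
            )
        multibeam = meta["multibeam"]
        out.append(
            MinuteSeries(
                fly_id=fly_id,
                t0=pd.Timestamp(meta["t0"]),
                counts=sub["counts"].to_numpy(np.int64),
                light=sub["light"].to_numpy(bool),
                led=sub["led"].to_numpy(float),
                moves=sub["moves"].to_numpy(np.int64) if multibeam else None,
                position=(
                    sub["position"].to_numpy(np.int64) if multibeam else None
                ),
                completeness=sub["completeness"].to_numpy(float),
            )
        )
    return out
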