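"""Small arithmetic helpers for driver-line screen tallies.

An anatomical screen of Split-GAL4 driver lines yields per-line annotations
(does the line express in the dorsal fan-shaped body? in VNC sleep-promoting
cells?) and per-brain neuron-count ranges.  These helpers turn such tallies
into the fractions and coverage bounds used to summarise a screen.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Tuple

__all__ = ["fraction_pct", "coverage_bounds_pct"]


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fraction_pct(n_with_trait: int, n_total: int, ndigits: int = 0) -> float:
    """Percent of screened lines carrying a trait (half-up rounding)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_with_trait <= n_total:
        raise ValueError(f"{n_with_trait} not in 0..{n_total}")
    return _round_half_up(100.0 * n_with_trait / n_total, ndigits)


def coverage_bounds_pct(
    subset_range: Tuple[int, int],
    reference_range: Tuple[int, int],
    ndigits: int = 0,
) -> Tuple[float, float]:
    """Coverage bounds of a reference cell population by a subset driver.

    A driver labeling ``subset_range = (lo_s, hi_s)`` cells per brain covers
    between ``lo_s / lo_r`` and ``hi_s / hi_r`` of a reference driver
    labeling ``(lo_r, hi_r)`` cells, expressed as percentages (the low bound
    pairs the two range minima, the high bound the two maxima, matching how
    per-brain count ranges are reported).
    """
    lo_s, hi_s = subset_range
    lo_r, hi_r = reference_range
    if lo_s > hi_s or lo_r > hi_r:
        raise ValueError("ranges must be (min, max)")
    if lo_r <= 0 or hi_r <= 0:
        raise ValueError("reference counts must be positive")
    return (
        _round_half_up(100.0 * lo_s / lo_r, ndigits),
        _round_half_up(100.0 * hi_s / hi_r, ndigits),
    )
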