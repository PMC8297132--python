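"""Derived capacity metrics, contact histograms and correlation reports.

Rounding conventions are pinned per metric so recomputed values match the
published convention exactly: the social-distance circle area, area per
person, adjustment ratios and the coarse estimate truncate (floor), while
percentages and densities round half-up.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .engine import DayResult

SOCIAL_DISTANCE_RADIUS_M = 2.0

#: default contact-duration histogram bin upper edges, minutes
DEFAULT_CONTACT_BINS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 16, 32, 64)


def _trunc(x: float, decimals: int) -> float:
    q = 10 ** decimals
    return math.floor(x * q) / q


def _half_up(x: float, decimals: int) -> float:
    exp = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(exp, rounding=ROUND_HALF_UP))


def circle_area(radius: float = SOCIAL_DISTANCE_RADIUS_M) -> float:
    """Personal social-distancing circle area in m², truncated to 2 dp.

    With the 2 m radius this is the 12.56 m² each visitor needs to keep 2 m
    from everyone in all directions.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return _trunc(math.pi * radius * radius, 2)


def coarse_capacity(area_m2: float) -> int:
    """Naive capacity upper bound: accessible area / distancing circle."""
    if area_m2 < 0:
        raise ValueError("area must be non-negative")
    return int(area_m2 // circle_area())


def area_per_person(area_m2: float, capacity: int) -> int:
    """Accessible m² per visitor at the given capacity (floored)."""
    if capacity <= 0:
        raise ValueError("capacity must be positive")
    return int(area_m2 // capacity)


def density(capacity: int, area_m2: float) -> float:
    """Visitor density in persons/m², rounded to 4 dp."""
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    return _half_up(capacity / area_m2, 4)


def pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage 100·num/den, rounded half-up."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return _half_up(100.0 * numerator / denominator, decimals)


def adjustment_ratio(new_capacity: int, base_capacity: int) -> float:
    """Capacity ratio scenario/base, truncated to 2 dp."""
    if base_capacity <= 0:
        raise ValueError("base capacity must be positive")
    return _trunc(new_capacity / base_capacity, 2)


def contact_histogram_report(day: DayResult,
                             bins=DEFAULT_CONTACT_BINS) -> pd.DataFrame:
    """Histogram of pair-episode contact durations.

    Episodes (continuous sub-threshold contact between one pair) are binned
    by duration in minutes: (0,1], (1,2], ... then (10,16], (16,32], (32,64]
    and >64 by default. Bin totals sum to the number of episodes.
    """
    from .behavior import TICKS_PER_MINUTE

    durations = [t / TICKS_PER_MINUTE for t in day.contacts.durations_ticks()]
    edges = [0.0, *[float(b) for b in bins], math.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f">{lo:g}" if math.isinf(hi) else f"<={hi:g}")
    counts = np.zeros(len(labels), dtype=int)
    for d in durations:
        for i, hi in enumerate(edges[1:]):
            if d <= hi:
                counts[i] += 1
                break
    return pd.DataFrame({"duration_min": labels, "episodes": counts})


def correlation_report(rows: pd.DataFrame,
                       capacity_col: str = "capacity") -> pd.DataFrame:
    """Pearson correlation of capacity against every other numeric column.

    Returns one row per column with r and the two-sided p-value; constant
    columns are flagged undefined (NaN).
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 rows for a correlation report")
    y = rows[capacity_col].to_numpy(dtype=float)
    out = []
    for col in rows.columns:
        if col == capacity_col:
            continue
        x = rows[col].to_numpy(dtype=float)
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            out.append({"column": col, "r": math.nan, "p_value": math.nan,
                        "undefined": True})
            continue
        r, p = stats.pearsonr(y, x)
        out.append({"column": col, "r": float(r), "p_value": float(p),
                    "undefined": False})
    return pd.DataFrame(out)


def derived_report(area_m2: float, capacity: int, historical: int) -> dict:
    """The standard per-park derived quantities from (area, capacity,
    historical daily visitors)."""
    coarse = coarse_capacity(area_m2)
    return {
        "accessible_area_m2": area_m2,
        "capacity": capacity,
        "coarse_estimate": coarse,
        "area_per_person_m2": area_per_person(area_m2, capacity),
        "density_per_m2": density(capacity, area_m2),
        "pct_of_historical": pct(capacity, historical),
        "pct_of_coarse": pct(capacity, coarse),
    }
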