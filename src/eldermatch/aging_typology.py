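"""Aging-evolution typology and aging-vs-facility growth mismatch.

Each spatial unit is classified over a census period by crossing the aging
level at period end (PA, % of population aged 65+) with the annual growth
rate of the 65+ population (V_PA, %/yr), giving eight evolution types:

    PA band:  <=7   |  (7, 10]  |  (10, 14] |  > 14
    V_PA > 4: rapid non-aging / rapid shallow / rapid deep / rapid aging society
    V_PA <= 4: slow  non-aging / slow shallow  / slow deep  / slow aging society

The growth gap (V_PA minus the facility-count growth rate, in percentage
points) quantifies how far facility construction lags the aging process.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

PA_BANDS = ((7.0, "non-aging"), (10.0, "shallow aging"), (14.0, "deep aging"), (np.inf, "aging society"))
SPEED_THRESHOLD = 4.0  # V_PA above this is "rapid"

TYPE_LABELS = tuple(
    f"{speed} {band} type" for speed in ("Rapid", "Slow") for _, band in reversed(PA_BANDS)
)


@dataclass
class AgingType:
    label: str
    pa_band: str
    speed: str


@dataclass
class AgingIndicators:
    unit_id: str
    period: tuple[int, int]
    PA: float  # % population 65+ at period end
    V_PA: float  # annual growth rate of 65+ population, %/yr
    facility_growth: float  # annual growth rate of facility count, %/yr
    gap: float  # V_PA - facility_growth, percentage points


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1), matching reported-table convention."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def annual_growth_rate(
    start_value: float,
    end_value: float,
    n_years: int,
    method: str = "geometric",
) -> float:
    """Annualized growth rate in percent.

    geometric (CAGR): 100 * ((end/start)^(1/n) - 1)
    arithmetic:       100 * (end/start - 1) / n
    period_total:     100 * (end - start) / start  (total over the period,
                      not annualized; the convention behind headline
                      "grew X%" figures)
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if start_value <= 0:
        return float("nan")  # undefined: no base to grow from
    ratio = end_value / start_value
    if method == "geometric":
        return 100.0 * (ratio ** (1.0 / n_years) - 1.0)
    if method == "arithmetic":
        return 100.0 * (ratio - 1.0) / n_years
    if method == "period_total":
        return 100.0 * (ratio - 1.0)
    raise ValueError(f"unknown growth-rate method {method!r}")


def growth_gap(aging_rate: float, facility_rate: float, *, decimals: int = 1) -> float:
    """Aging minus facility growth rate, in percentage points (half-up rounded).

    Pass the unrounded rates to subtract before rounding; passing printed
    (already rounded) rates reproduces reported-table arithmetic exactly.
    """
    if not (np.isfinite(aging_rate) and np.isfinite(facility_rate)):
        raise ValueError("growth rates must be finite")
    return round_half_up(aging_rate - facility_rate, decimals)


def classify_aging_type(PA: float, V_PA: float) -> AgingType:
    """One of eight evolution types from (PA, V_PA).

    PA bands are left-open/right-closed; V_PA exactly 4 classifies as slow.
    """
    if not (np.isfinite(PA) and np.isfinite(V_PA)):
        raise ValueError("PA and V_PA must be finite")
    if not 0.0 <= PA <= 100.0:
        raise ValueError(f"PA must be a percentage in [0, 100], got {PA}")
    band = next(name for upper, name in PA_BANDS if PA <= upper)
    speed = "Rapid" if V_PA > SPEED_THRESHOLD else "Slow"
    return AgingType(label=f"{speed} {band} type", pa_band=band, speed=speed)


def typology_map(panel: pd.DataFrame, period: tuple[int, int]) -> pd.DataFrame:
    """Classify every unit over a census period.

    ``panel`` needs columns unit_id, year, pop_total, pop_65plus.  Returns one
    row per unit: unit_id, period_start, period_end, PA, V_PA, label (label is
    NaN for units missing either endpoint, reported rather than dropped).
    """
    start, end = period
    if end <= start:
        raise ValueError(f"period must be increasing, got {period}")
    rows = []
    for unit_id, grp in panel.groupby("unit_id", sort=True):
        by_year = grp.set_index("year")
        if start not in by_year.index or end not in by_year.index:
            rows.append((unit_id, start, end, np.nan, np.nan, np.nan))
            continue
        e0 = float(by_year.loc[start, "pop_65plus"])
        e1 = float(by_year.loc[end, "pop_65plus"])
        pa = 100.0 * e1 / float(by_year.loc[end, "pop_total"])
        v_pa = annual_growth_rate(e0, e1, end - start, "geometric")
        label = classify_aging_type(pa, v_pa).label if np.isfinite(v_pa) else np.nan
        rows.append((unit_id, start, end, pa, v_pa, label))
    return pd.DataFrame(
        rows, columns=["unit_id", "period_start", "period_end", "PA", "V_PA", "label"]
    )


def growth_gap_table(
    panel: pd.DataFrame,
    facility_counts: pd.DataFrame,
    period: tuple[int, int],
    method: str = "geometric",
) -> pd.DataFrame:
    """Per-unit aging vs facility growth rates and their gap over a period.

    ``facility_counts`` has columns unit_id, year, n_facilities (cumulative
    count of facilities established by that year).
    """
    start, end = period
    typ = typology_map(panel, period)
    fac = facility_counts.pivot(index="unit_id", columns="year", values="n_facilities")
    rows = []
    for _, r in typ.iterrows():
        uid = r["unit_id"]
        if uid in fac.index and start in fac.columns and end in fac.columns:
            f_rate = annual_growth_rate(
                float(fac.loc[uid, start]), float(fac.loc[uid, end]), end - start, method
            )
        else:
            f_rate = float("nan")
        gap = (
            growth_gap(r["V_PA"], f_rate)
            if np.isfinite(r["V_PA"]) and np.isfinite(f_rate)
            else float("nan")
        )
        rows.append((uid, start, end, r["PA"], r["V_PA"], f_rate, gap))
    return pd.DataFrame(
        rows,
        columns=["unit_id", "period_start", "period_end", "PA", "V_PA", "facility_growth", "gap"],
    )
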