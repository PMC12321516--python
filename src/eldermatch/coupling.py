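"""Coupling-coordination model between elderly population and facility access.

Two subsystem values per spatial unit — E (range-normalized elderly
population) and S (range-normalized facility accessibility) — combine into:

    coupling degree        C = 2*sqrt(E*S) / (E + S)      balance, 1 iff E = S
    comprehensive index    T = alpha*E + beta*S           overall level
    coordination degree    D = sqrt(C * T)                joint measure

D is banded into ten classes from extreme imbalance [0, 0.1) up to
high-quality coordination [0.9, 1.0].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from eldermatch.aging_typology import round_half_up

logger = logging.getLogger(__name__)

COORDINATION_LEVELS = (
    "extreme imbalance",          # [0.0, 0.1)
    "severe imbalance",           # [0.1, 0.2)
    "moderate imbalance",         # [0.2, 0.3)
    "mild imbalance",             # [0.3, 0.4)
    "approaching imbalance",      # [0.4, 0.5)
    "barely coordinated",         # [0.5, 0.6)
    "primary coordination",       # [0.6, 0.7)
    "intermediate coordination",  # [0.7, 0.8)
    "good coordination",          # [0.8, 0.9)
    "high-quality coordination",  # [0.9, 1.0]
)


@dataclass
class CouplingResult:
    unit_id: str
    year: int
    E: float
    S: float
    C: float
    T: float
    D: float
    level: str


def range_normalize(values, groups=None, *, mode: str = "per_group") -> np.ndarray:
    """Min-max normalization to [0, 1], by default within each group (year).

    mode="per_group" normalizes within each distinct group label (cross-
    sectional comparison within a census year); mode="pooled" uses the global
    min/max.  A constant group is mapped to 0.5 with a warning (no ordering
    information to preserve).
    """
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    if mode == "pooled" or groups is None:
        group_ids = np.zeros(len(values))
    elif mode == "per_group":
        group_ids = np.asarray(groups)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    for g in np.unique(group_ids):
        mask = group_ids == g
        lo, hi = values[mask].min(), values[mask].max()
        if hi - lo <= 0:
            logger.warning("constant normalization group %r mapped to 0.5", g)
            out[mask] = 0.5
        else:
            out[mask] = (values[mask] - lo) / (hi - lo)
    return out


def _check_unit(value: float, name: str) -> None:
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def coupling_degree(E: float, S: float) -> float:
    """C = 2*sqrt(E*S)/(E+S): 1 when the subsystems are equal, 0 when one is absent."""
    _check_unit(E, "E")
    _check_unit(S, "S")
    if E + S == 0:
        logger.warning("both subsystems zero; coupling degree defined as 0")
        return 0.0
    # sqrt(E)*sqrt(S) rather than sqrt(E*S): the product can underflow to 0
    # for subnormal inputs even when E = S; clamp 1+eps round-off
    return min(float(2.0 * np.sqrt(E) * np.sqrt(S) / (E + S)), 1.0)


def comprehensive_index(E: float, S: float, alpha: float = 0.5, beta: float = 0.5) -> float:
    """T = alpha*E + beta*S, the overall development level of the two subsystems."""
    _check_unit(E, "E")
    _check_unit(S, "S")
    if not np.isclose(alpha + beta, 1.0, atol=1e-9):
        raise ValueError("subsystem weights alpha + beta must sum to 1")
    return alpha * E + beta * S


def coordination_degree(C: float, T: float) -> float:
    """D = sqrt(C*T), monotone in each argument, in [0, 1]."""
    _check_unit(C, "C")
    _check_unit(T, "T")
    return float(np.sqrt(C * T))


def classify_coordination(D: float) -> str:
    """Ten-band coordination level; bands [a, a+0.1) with the last closed at 1."""
    if not np.isfinite(D) or not 0.0 <= D <= 1.0:
        raise ValueError(f"coordination degree must be in [0, 1], got {D}")
    idx = min(int(D * 10), 9)
    return COORDINATION_LEVELS[idx]


def coupling_table(
    panel: pd.DataFrame,
    access: pd.DataFrame,
    alpha: float = 0.5,
    beta: float = 0.5,
    *,
    normalization: str = "per_group",
    elderly_measure: str = "count",
) -> pd.DataFrame:
    """Per-unit-year E, S, C, T, D and level.

    ``panel`` needs unit_id, year, pop_65plus (and pop_total when
    ``elderly_measure="proportion"``); ``access`` needs unit_id, year, S_raw
    (the accessibility score).  Both subsystems are range-normalized, by
    default within each census year.  Units with missing accessibility are
    dropped with a warning.
    """
    df = panel.merge(access, on=["unit_id", "year"], how="left")
    missing = df["S_raw"].isna()
    if missing.any():
        logger.warning("dropping %d unit-years with missing accessibility", missing.sum())
        df = df[~missing].copy()
    if elderly_measure == "count":
        elderly = df["pop_65plus"].to_numpy(dtype=float)
    elif elderly_measure == "proportion":
        elderly = (df["pop_65plus"] / df["pop_total"]).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown elderly_measure {elderly_measure!r}")
    years = df["year"].to_numpy()
    df["E"] = range_normalize(elderly, years, mode=normalization)
    df["S"] = range_normalize(df["S_raw"].to_numpy(dtype=float), years, mode=normalization)
    df["C"] = [coupling_degree(e, s) for e, s in zip(df["E"], df["S"])]
    df["T"] = [comprehensive_index(e, s, alpha, beta) for e, s in zip(df["E"], df["S"])]
    df["D"] = [coordination_degree(c, t) for c, t in zip(df["C"], df["T"])]
    df["level"] = [classify_coordination(d) for d in df["D"]]
    return df[["unit_id", "year", "E", "S", "C", "T", "D", "level"]]


def level_distribution(results: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of units per coordination level per year.

    Percentages are 100*count/n_units, rounded half-up to one decimal.  All
    ten levels appear for every year, including empty ones.
    """
    rows = []
    for year, grp in results.groupby("year", sort=True):
        n = len(grp)
        counts = grp["level"].value_counts()
        for level in reversed(COORDINATION_LEVELS):
            c = int(counts.get(level, 0))
            rows.append((year, level, c, round_half_up(100.0 * c / n, 1)))
    return pd.DataFrame(rows, columns=["year", "level", "count", "percent"])
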