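"""Lorenz-curve / Gini matching equity between elderly population and access.

Units are sorted by accessibility per elderly resident; the Lorenz curve
plots the cumulative share of accessibility mass (S_i x elderly_i) against
the cumulative share of the elderly population.  The Gini coefficient is
one minus twice the area under the curve (trapezoid rule), and is banded
with the UNDP five-level classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

UNDP_CLASSES = (
    "high equality",          # G <= 0.2
    "moderate equality",      # 0.2 < G <= 0.3
    "relatively reasonable",  # 0.3 < G <= 0.4
    "significant disparity",  # 0.4 < G < 0.6
    "extreme inequality",     # G >= 0.6
)


@dataclass
class GiniResult:
    G: float
    method: str
    lorenz_points: np.ndarray  # (n+1, 2) cumulative (pop share, access share)
    undp_class: str


def _validate(weights: np.ndarray, values: np.ndarray) -> None:
    if len(weights) < 2:
        raise ValueError("need at least 2 units")
    if len(weights) != len(values):
        raise ValueError("weights and values must align")
    if np.any(weights < 0) or np.any(values < 0):
        raise ValueError("weights and accessibility values must be non-negative")
    if weights.sum() <= 0:
        raise ValueError("population weights must have positive sum")


def lorenz_curve(elderly: np.ndarray, access: np.ndarray) -> np.ndarray:
    """Cumulative (elderly share, accessibility-mass share) points.

    ``access`` is the per-1000-elderly accessibility score S_i; the mass
    attributed to a unit is S_i * elderly_i so that identical per-capita
    access for all units yields the diagonal.  Units are sorted ascending by
    S_i, which makes the curve convex.  Starts at (0,0), ends at (1,1).
    """
    elderly = np.asarray(elderly, dtype=float)
    access = np.asarray(access, dtype=float)
    _validate(elderly, access)
    mass = access * elderly
    order = np.argsort(access, kind="stable")
    x = np.concatenate([[0.0], np.cumsum(elderly[order])]) / elderly.sum()
    if mass.sum() <= 0:
        logger.warning("all accessibility mass is zero; Lorenz curve degenerate, G = 1")
        y = np.zeros_like(x)
        y[-1] = 1.0
    else:
        y = np.concatenate([[0.0], np.cumsum(mass[order])]) / mass.sum()
    return np.column_stack([x, y])


def gini(elderly: np.ndarray, access: np.ndarray, method: str = "lorenz_trapezoid") -> GiniResult:
    """Gini coefficient of accessibility relative to elderly-population shares.

    lorenz_trapezoid (default): G = 1 - sum (x_i - x_{i-1}) (y_i + y_{i-1})
    over the sorted Lorenz points; invariant to uniform rescaling of either
    margin and to unit ordering.

    covariance_form: a literal covariance-style reading
    G = 1 - sum (P_i - mean P)(S_i - mean S) over cumulative proportions,
    kept only for comparison; it is not guaranteed to lie in [0, 1].
    """
    pts = lorenz_curve(elderly, access)
    x, y = pts[:, 0], pts[:, 1]
    degenerate = float(np.sum(np.asarray(access) * np.asarray(elderly))) <= 0
    if method == "lorenz_trapezoid":
        if degenerate:
            g = 1.0  # curve lies on the x-axis: maximal inequality
        else:
            g = 1.0 - float(np.sum(np.diff(x) * (y[1:] + y[:-1])))
            g = min(max(g, 0.0), 1.0)  # clip trapezoid round-off at the boundaries
    elif method == "covariance_form":
        p, s = x[1:], y[1:]
        g = 1.0 - float(np.sum((p - p.mean()) * (s - s.mean())))
    else:
        raise ValueError(f"unknown Gini method {method!r}")
    cls = classify_gini(g) if 0.0 <= g <= 1.0 else "out of range"
    return GiniResult(G=g, method=method, lorenz_points=pts, undp_class=cls)


def classify_gini(G: float) -> str:
    """UNDP five-level equality band for a Gini coefficient.

    Boundaries: 0.2 and 0.3 and 0.4 close the lower band; 0.6 opens
    extreme inequality.
    """
    if not 0.0 <= G <= 1.0:
        raise ValueError(f"Gini coefficient must be in [0, 1], got {G}")
    if G <= 0.2:
        return UNDP_CLASSES[0]
    if G <= 0.3:
        return UNDP_CLASSES[1]
    if G <= 0.4:
        return UNDP_CLASSES[2]
    if G < 0.6:
        return UNDP_CLASSES[3]
    return UNDP_CLASSES[4]


def plot_lorenz(curves: dict[str, np.ndarray], path: str) -> None:
    """Write a Lorenz-curve figure (one line per labelled year) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="perfect equality")
    for label, pts in curves.items():
        ax.plot(pts[:, 0], pts[:, 1], marker="o", ms=3, label=str(label))
    ax.set_xlabel("cumulative share of population 65+")
    ax.set_ylabel("cumulative share of accessibility")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
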