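"""Geographical-detector attribution: factor q, interactions, VIF screening.

The q-statistic measures how much of the spatial variance of an outcome a
categorical stratification explains:

    q = 1 - (sum_h N_h * sigma_h^2) / (N * sigma^2)

with population (denominator-N) variances so the decomposition telescopes
exactly; q = 1 - SSW/SST.  Continuous factors are discretized with exact
Fisher-Jenks natural breaks (default 5 classes).  The interaction detector
computes q on the overlay of two stratifications and classifies the result
against the single-factor q values.  A VIF screen flags collinear factors
before detection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

INTERACTION_CLASSES = (
    "nonlinear weaken",                # q_ab < min(q_a, q_b)
    "single-factor nonlinear weaken",  # min <= q_ab < max
    "bivariate enhance",               # max < q_ab < q_a + q_b
    "independent",                     # q_ab == q_a + q_b
    "nonlinear enhance",               # q_ab > q_a + q_b
)


@dataclass
class StratifiedFactor:
    factor_id: str
    strata: np.ndarray  # one integer stratum label per unit
    n_strata: int
    breaks: np.ndarray | None = None  # jenks boundaries, when discretized here


@dataclass
class QResult:
    factor_id: str
    q: float
    p_value: float | None
    method: str | None
    N: int
    L: int
    stratum_sizes: np.ndarray = field(repr=False, default=None)
    stratum_variances: np.ndarray = field(repr=False, default=None)


@dataclass
class InteractionResult:
    factor_a: str
    factor_b: str
    q_a: float
    q_b: float
    q_ab: float
    interaction_class: str


@dataclass
class VifResult:
    factor_id: str
    r_squared: float
    vif: float
    flagged: bool  # VIF > 5


# ---------------------------------------------------------------------------
# Fisher-Jenks natural breaks (exact dynamic programming)
# ---------------------------------------------------------------------------

def _ssq_matrix(sorted_vals: np.ndarray):
    """Within-class sum of squared deviations for value range [i, j] in O(1)."""
    cs = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    cs2 = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])

    def ssq(i: int, j: int) -> float:  # inclusive indices
        n = j - i + 1
        s = cs[j + 1] - cs[i]
        return float(cs2[j + 1] - cs2[i] - s * s / n)

    return ssq


def jenks_breaks(values, k: int) -> np.ndarray:
    """Exact Fisher-Jenks class boundaries minimizing within-class SSD.

    Returns k+1 boundaries: the minimum, the k-1 internal break values (the
    largest member of each lower class, i.e. right-closed intervals), and the
    maximum.  Deterministic; requires at least k distinct values.
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if k < 2:
        raise ValueError("need at least 2 classes")
    if len(np.unique(values)) < k:
        raise ValueError(f"need at least {k} distinct values, got {len(np.unique(values))}")
    ssq = _ssq_matrix(values)
    # cost[m][j]: minimal SSD splitting values[0..j] into m+1 classes
    INF = np.inf
    cost = np.full((k, n), INF)
    split = np.zeros((k, n), dtype=int)  # first index of the last class
    for j in range(n):
        cost[0, j] = ssq(0, j)
    for m in range(1, k):
        for j in range(m, n):
            best, best_i = INF, m
            for i in range(m, j + 1):
                c = cost[m - 1, i - 1] + ssq(i, j)
                if c < best:
                    best, best_i = c, i
            cost[m, j] = best
            split[m, j] = best_i
    # backtrack class boundaries
    bounds = [values[-1]]
    j = n - 1
    for m in range(k - 1, 0, -1):
        i = split[m, j]
        bounds.append(values[i - 1])  # upper bound of the class below
        j = i - 1
    bounds.append(values[0])
    return np.array(bounds[::-1])


def jenks_labels(values, k: int) -> StratifiedFactor:
    """Assign 1..k natural-breaks class labels (boundary values go low)."""
    values = np.asarray(values, dtype=float)
    bounds = jenks_breaks(values, k)
    # interior bounds are right-closed: label = count of interior bounds < value
    labels = 1 + np.searchsorted(bounds[1:-1], values, side="left")
    return StratifiedFactor("", labels.astype(int), k, breaks=bounds)


# ---------------------------------------------------------------------------
# factor detector
# ---------------------------------------------------------------------------

def factor_q(strata, y, factor_id: str = "") -> QResult:
    """q-statistic of a stratification: explained share of outcome variance.

    Uses population variances (divide by N and N_h) so that
    q = 1 - SSW/SST exactly.  Requires >= 2 strata and positive total
    variance; a zero-variance outcome yields q = NaN.
    """
    if isinstance(strata, StratifiedFactor):
        factor_id = factor_id or strata.factor_id
        strata = strata.strata
    strata = np.asarray(strata)
    y = np.asarray(y, dtype=float)
    if len(strata) != len(y):
        raise ValueError("strata and outcome must align")
    labels, inverse = np.unique(strata, return_inverse=True)
    L = len(labels)
    if L < 2:
        raise ValueError("need at least 2 strata")
    N = len(y)
    total_var = float(np.var(y))
    sizes = np.bincount(inverse)
    variances = np.array([np.var(y[inverse == h]) for h in range(L)])
    if total_var <= 0:
        logger.warning("outcome has zero variance; q undefined")
        q = float("nan")
    else:
        q = 1.0 - float(np.sum(sizes * variances)) / (N * total_var)
    return QResult(factor_id, q, None, None, N, L, sizes, variances)


def q_significance(
    strata,
    y,
    method: str = "permutation",
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """p-value for the factor-detector q.

    permutation (default): relabel outcomes n_perm times with a seeded RNG;
    p = (1 + #{q_perm >= q_obs}) / (1 + n_perm).
    noncentral_F: the transformed-F test with
    F = (N-L)/(L-1) * q/(1-q) against a noncentral F(L-1, N-L; lambda)
    reference distribution.
    """
    if isinstance(strata, StratifiedFactor):
        strata = strata.strata
    strata = np.asarray(strata)
    y = np.asarray(y, dtype=float)
    obs = factor_q(strata, y)
    if not np.isfinite(obs.q):
        return float("nan")
    if method == "permutation":
        if n_perm < 99:
            warnings.warn("n_perm < 99 gives a coarse p-value grid", stacklevel=2)
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            q_perm = factor_q(rng.permutation(strata), y).q
            if q_perm >= obs.q - 1e-12:
                exceed += 1
        return (1 + exceed) / (1 + n_perm)
    if method == "noncentral_F":
        N, L, q = obs.N, obs.L, obs.q
        if q >= 1.0:
            return 0.0
        f_stat = (N - L) / (L - 1) * q / (1.0 - q)
        labels, inverse = np.unique(strata, return_inverse=True)
        means = np.array([y[inverse == h].mean() for h in range(L)])
        sizes = obs.stratum_sizes
        var = float(np.var(y))
        lam = (np.sum(sizes * means**2) - (np.sum(np.sqrt(sizes) * means)) ** 2 / N) / var
        return float(stats.ncf.sf(f_stat, L - 1, N - L, max(lam, 0.0)))
    raise ValueError(f"unknown significance method {method!r}")


# ---------------------------------------------------------------------------
# interaction detector
# ---------------------------------------------------------------------------

def overlay_strata(strata_a, strata_b) -> np.ndarray:
    """Cartesian overlay of two stratifications (only occupied cells)."""
    a = strata_a.strata if isinstance(strata_a, StratifiedFactor) else np.asarray(strata_a)
    b = strata_b.strata if isinstance(strata_b, StratifiedFactor) else np.asarray(strata_b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    _, labels = np.unique(ai * (bi.max() + 1) + bi, return_inverse=True)
    return labels


def classify_interaction(q_a: float, q_b: float, q_ab: float, atol: float = 1e-9) -> str:
    lo, hi = min(q_a, q_b), max(q_a, q_b)
    if abs(q_ab - (q_a + q_b)) <= atol:
        return "independent"
    if q_ab > q_a + q_b:
        return "nonlinear enhance"
    if q_ab > hi:
        return "bivariate enhance"
    if q_ab >= lo:
        return "single-factor nonlinear weaken"
    return "nonlinear weaken"


def interaction_q(strata_a, strata_b, y) -> InteractionResult:
    """q of the two-factor overlay, classified against the single-factor q's."""
    name_a = strata_a.factor_id if isinstance(strata_a, StratifiedFactor) else "a"
    name_b = strata_b.factor_id if isinstance(strata_b, StratifiedFactor) else "b"
    overlay = overlay_strata(strata_a, strata_b)
    if len(np.unique(overlay)) < 2:
        raise ValueError("overlay leaves fewer than 2 occupied cells")
    q_a = factor_q(strata_a, y).q
    q_b = factor_q(strata_b, y).q
    q_ab = factor_q(overlay, y).q
    return InteractionResult(name_a, name_b, q_a, q_b, q_ab, classify_interaction(q_a, q_b, q_ab))


# ---------------------------------------------------------------------------
# multicollinearity screen
# ---------------------------------------------------------------------------

def vif_screen(factors: pd.DataFrame, threshold: float = 5.0) -> tuple[list[VifResult], pd.DataFrame]:
    """Variance-inflation factors plus the Pearson correlation matrix.

    Each factor is regressed (OLS, intercept included) on all others;
    VIF = 1/(1-R^2).  Exact collinearity reports an infinite VIF.  When there
    are not more observations than factors the fit is rank-deficient; a
    warning is raised and pinv-based OLS used.
    """
    cols = list(factors.columns)
    X = factors.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        warnings.warn(
            f"only {n} observations for {p} factors; VIF estimates are unstable",
            stacklevel=2,
        )
    results = []
    for j, col in enumerate(cols):
        yj = X[:, j]
        others = sm.add_constant(np.delete(X, j, axis=1))
        fit = sm.OLS(yj, others).fit()
        r2 = min(float(fit.rsquared), 1.0)
        vif = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        results.append(VifResult(col, r2, vif, vif > threshold))
    return results, factors.corr(method="pearson")
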