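"""Seasonal and circadian rhythm statistics.

Seasonal differences between growth periods are tested with Tukey's HSD at
alpha = 0.05 and summarized by a compact letter display (groups sharing a
letter are not significantly different).  Circadian series are de-trended
by subtracting the average hourly seasonal growth rate, environmental
records are interpolated with a natural cubic spline to the observation
moments, and trait-environment relationships are quantified by the Pearson
correlation coefficient with two-sided p-values tiered at 0.05/0.01/0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

__all__ = [
    "SeasonalResult",
    "EnvCorrelation",
    "tukey_cld",
    "hourly_rate",
    "detrend_series",
    "retrend_series",
    "spline_interp",
    "pearson_env",
    "significance_tier",
    "circadian_pipeline",
]

TIER_THRESHOLDS = (0.05, 0.01, 0.001)


# --------------------------------------------------------------------------
# Tukey HSD + compact letter display
# --------------------------------------------------------------------------

@dataclass
class SeasonalResult:
    """Tukey multi-comparison outcome for one trait across periods."""

    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray
    p_matrix: np.ndarray  # pairwise Tukey p-values
    letters: List[str]  # compact letter display, 'a' = highest mean
    alpha: float

    def significant(self, i: int, j: int) -> bool:
        return bool(self.p_matrix[i, j] < self.alpha)


def _tukey_p_matrix(groups: Sequence[np.ndarray]) -> np.ndarray:
    """Pairwise studentized-range p-values from a one-way layout."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([np.mean(g) for g in groups])
    df = int(ns.sum() - k)
    sse = sum(float(np.sum((g - m) ** 2)) for g, m in zip(groups, means))
    mse = sse / df
    p = np.ones((k, k))
    if mse == 0:
        # degenerate zero-variance layout: distinct means are trivially
        # different, equal means trivially identical
        for i in range(k):
            for j in range(i + 1, k):
                p[i, j] = p[j, i] = 1.0 if means[i] == means[j] else 0.0
        return p
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            pij = float(stats.studentized_range.sf(q, k, df))
            p[i, j] = p[j, i] = min(max(pij, 0.0), 1.0)
    return p


def _insert_absorb_letters(p_matrix: np.ndarray, order: np.ndarray, alpha: float) -> List[str]:
    """Compact letter display by insert-and-absorb.

    Guarantees that two groups share a letter iff their pairwise p >= alpha.
    ``order`` lists group indices by descending mean so the first letter
    ('a') belongs to the highest-mean group.
    """
    k = len(order)
    columns: List[set] = [set(order)]
    for a in range(k):
        for b in range(a + 1, k):
            i, j = order[a], order[b]
            if p_matrix[i, j] >= alpha:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                columns.extend([col - {i}, col - {j}])
            # absorb: drop columns that are subsets of another
            columns = [
                c
                for ci, c in enumerate(columns)
                if not any(ci != cj and c <= other for cj, other in enumerate(columns))
            ]
    # connect every non-significant pair that ended up letterless together
    for a in range(k):
        for b in range(a + 1, k):
            i, j = order[a], order[b]
            if p_matrix[i, j] >= alpha and not any(i in c and j in c for c in columns):
                columns.append({i, j})  # pragma: no cover - absorb keeps pairs covered
    # order columns by the best (highest-mean) group they contain
    rank = {g: r for r, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    letters = ["" for _ in range(k)]
    for ci, col in enumerate(columns):
        ch = chr(ord("a") + ci)
        for g in col:
            letters[g] += ch
    return ["".join(sorted(s)) for s in letters]


def tukey_cld(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> SeasonalResult:
    """Tukey HSD over the groups plus a compact letter display.

    Letters encode pairwise non-significance exactly: two groups share a
    letter iff their Tukey p-value >= ``alpha``.  'a' is assigned to the
    highest-mean group.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs n >= 2")
    means = np.array([g.mean() for g in arrays])
    p = _tukey_p_matrix(arrays)
    order = np.argsort(-means, kind="stable")
    letters = _insert_absorb_letters(p, order, alpha)
    return SeasonalResult(
        means=means,
        sds=np.array([g.std(ddof=1) for g in arrays]),
        ns=np.array([len(g) for g in arrays]),
        p_matrix=p,
        letters=letters,
        alpha=alpha,
    )


# --------------------------------------------------------------------------
# growth-rate de-trending
# --------------------------------------------------------------------------

def hourly_rate(mean_a: float, day_a: float, mean_b: float, day_b: float) -> float:
    """Average growth rate per hour between two seasonal anchor days."""
    if day_b <= day_a:
        raise ValueError("day_b must exceed day_a")
    return (mean_b - mean_a) / ((day_b - day_a) * 24.0)


def detrend_series(
    values: np.ndarray, hours: np.ndarray, rate: float, t0: Optional[float] = None
) -> np.ndarray:
    """Subtract the linear seasonal growth: corrected = raw - rate * (t - t0).

    ``hours`` are observation times in hours; ``t0`` defaults to the first
    timestamp so the first corrected value equals the first raw value.
    """
    values = np.asarray(values, dtype=float)
    hours = np.asarray(hours, dtype=float)
    if t0 is None:
        t0 = float(hours[0]) if len(hours) else 0.0
    if len(hours) and t0 > hours[0]:
        raise ValueError("t0 must not exceed the first timestamp")
    return values - rate * (hours - t0)


def retrend_series(
    values: np.ndarray, hours: np.ndarray, rate: float, t0: Optional[float] = None
) -> np.ndarray:
    """Inverse of :func:`detrend_series` (adds the linear trend back)."""
    values = np.asarray(values, dtype=float)
    hours = np.asarray(hours, dtype=float)
    if t0 is None:
        t0 = float(hours[0]) if len(hours) else 0.0
    return values + rate * (hours - t0)


# --------------------------------------------------------------------------
# environment interpolation + correlation
# --------------------------------------------------------------------------

def spline_interp(
    knot_hours: np.ndarray, knot_values: np.ndarray, query_hours: np.ndarray
) -> np.ndarray:
    """Natural cubic spline through fixed-cadence records.

    Extrapolation is refused: all queries must lie within the knot range.
    """
    knot_hours = np.asarray(knot_hours, dtype=float)
    knot_values = np.asarray(knot_values, dtype=float)
    query_hours = np.asarray(query_hours, dtype=float)
    if np.any(query_hours < knot_hours[0]) or np.any(query_hours > knot_hours[-1]):
        raise ValueError("query times outside the recorded range (no extrapolation)")
    spline = CubicSpline(knot_hours, knot_values, bc_type="natural")
    return spline(query_hours)


def significance_tier(p: float) -> str:
    """Map a p-value onto the table tiers ns / p<0.05 / p<0.01 / p<0.001."""
    if p < 0.001:
        return "p<0.001"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


@dataclass
class EnvCorrelation:
    """Pearson correlation of one trait with one environmental factor."""

    trait: str
    factor: str
    r: float
    p: float
    tier: str
    n: int


def pearson_env(trait_values: Sequence[float], env_values: Sequence[float],
                trait: str = "", factor: str = "") -> EnvCorrelation:
    """Sample Pearson r with a two-sided t-test p-value (n - 2 df)."""
    x = np.asarray(trait_values, dtype=float)
    y = np.asarray(env_values, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return EnvCorrelation(
        trait=trait,
        factor=factor,
        r=float(res.statistic),
        p=float(res.pvalue),
        tier=significance_tier(float(res.pvalue)),
        n=len(x),
    )


# --------------------------------------------------------------------------
# full circadian pipeline
# --------------------------------------------------------------------------

def circadian_pipeline(
    trait_table: pd.DataFrame,
    env: pd.DataFrame,
    seasonal_anchors: Optional[Dict[str, Tuple[float, float, float, float]]] = None,
    factors: Sequence[str] = ("PAR", "RH", "T"),
    t0: Optional[float] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """De-trend per-moment trait means and correlate them with environment.

    Parameters
    ----------
    trait_table
        One row per (moment, sample) with a ``moment`` timestamp column and
        one column per trait; samples are averaged per moment first.
    env
        Environmental records with a ``time`` column at fixed cadence and
        one column per factor.
    seasonal_anchors
        Per trait ``(mean_a, day_a, mean_b, day_b)`` used to compute the
        hourly growth rate; traits without anchors get rate 0 (the
        cold-stress case, which has no seasonal series).
    t0
        De-trend anchor in hours; defaults to the first observation moment.

    Returns
    -------
    (series, corr)
        ``series``: per moment and trait, raw and corrected means.
        ``corr``: per (trait, factor), Pearson r, p and significance tier.
    """
    if "moment" not in trait_table.columns:
        raise ValueError("trait_table must have a 'moment' column")
    trait_cols = [c for c in trait_table.columns if c not in ("moment", "plant", "leaf")]
    agg = trait_table.groupby("moment", sort=True)[trait_cols].mean().reset_index()
    moments = pd.to_datetime(agg["moment"])
    epoch = pd.to_datetime(env["time"]).iloc[0]
    obs_hours = (moments - epoch).dt.total_seconds().to_numpy() / 3600.0
    env_hours = (pd.to_datetime(env["time"]) - epoch).dt.total_seconds().to_numpy() / 3600.0

    env_at_obs = {
        f: spline_interp(env_hours, env[f].to_numpy(), obs_hours) for f in factors
    }

    series_rows = []
    corr_rows = []
    for trait in trait_cols:
        raw = agg[trait].to_numpy(dtype=float)
        if seasonal_anchors and trait in seasonal_anchors:
            mean_a, day_a, mean_b, day_b = seasonal_anchors[trait]
            rate = hourly_rate(mean_a, day_a, mean_b, day_b)
        else:
            rate = 0.0
        corrected = detrend_series(raw, obs_hours, rate, t0=t0)
        for m, h, rv, cv in zip(agg["moment"], obs_hours, raw, corrected):
            series_rows.append(
                {"trait": trait, "moment": m, "hours": h, "raw": rv, "corrected": cv, "rate": rate}
            )
        for f in factors:
            ec = pearson_env(corrected, env_at_obs[f], trait=trait, factor=f)
            corr_rows.append(
                {"trait": trait, "factor": f, "r": ec.r, "p": ec.p, "tier": ec.tier, "n": ec.n}
            )
    return pd.DataFrame(series_rows), pd.DataFrame(corr_rows)
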