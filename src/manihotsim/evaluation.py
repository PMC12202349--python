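"""Goodness-of-fit statistics for simulated versus observed values.

Implements the four agreement measures standard in crop-model evaluation —
Pearson correlation r, root mean squared error (RMSE), RMSE normalised by the
observed mean (nRMSE, %), and Willmott's index of agreement d — together with
the conventional nRMSE quality classes (<10% excellent, 10-20% good, 20-30%
fair, >30% poor), per-group aggregation and a paired before/after comparison.

Statistics that are undefined for a vector pair (constant vectors, single
observations) are carried as NaN with an explicit flag, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FitStats",
    "pearson_r",
    "rmse",
    "nrmse",
    "d_index",
    "quality_class",
    "fit_stats",
    "evaluate_by_group",
    "paired_comparison",
]


def _pair(sim, obs) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(sim, dtype=float)
    o = np.asarray(obs, dtype=float)
    if s.shape != o.shape or s.ndim != 1:
        raise ValueError("sim and obs must be 1-D vectors of equal length")
    if s.size == 0:
        raise ValueError("empty vectors")
    return s, o


def pearson_r(sim, obs) -> float:
    """Product-moment correlation; NaN (undefined) if either vector is
    constant or fewer than two pairs are given."""
    s, o = _pair(sim, obs)
    if s.size < 2 or np.ptp(s) == 0 or np.ptp(o) == 0:
        return float("nan")
    return float(np.corrcoef(s, o)[0, 1])


def rmse(sim, obs) -> float:
    """Root mean squared deviation between simulated and observed values."""
    s, o = _pair(sim, obs)
    return float(np.sqrt(np.mean((s - o) ** 2)))


def nrmse(rmse_value: float, obs_mean: float) -> float:
    """RMSE as a percentage of the observed mean."""
    if obs_mean <= 0:
        raise ValueError("nRMSE requires a positive observed mean")
    return 100.0 * rmse_value / obs_mean


def d_index(sim, obs) -> float:
    """Willmott's index of agreement in [0, 1]; 1 iff the vectors match.

    d = 1 - sum((S-O)^2) / sum((|S - Obar| + |O - Obar|)^2) with Obar the
    observed mean.  NaN (undefined) when the denominator is zero, i.e. both
    vectors are constant at the observed mean.
    """
    s, o = _pair(sim, obs)
    obar = o.mean()
    denom = np.sum((np.abs(s - obar) + np.abs(o - obar)) ** 2)
    if denom == 0:
        return float("nan")
    return float(1.0 - np.sum((s - o) ** 2) / denom)


def quality_class(nrmse_pct: float) -> str:
    """nRMSE quality class on half-open bins: [0,10) excellent, [10,20) good,
    [20,30) fair, >=30 poor."""
    if nrmse_pct < 0:
        raise ValueError("nRMSE cannot be negative")
    if nrmse_pct < 10:
        return "excellent"
    if nrmse_pct < 20:
        return "good"
    if nrmse_pct < 30:
        return "fair"
    return "poor"


@dataclass
class FitStats:
    """Agreement statistics for one simulated/observed vector pair."""

    r: float
    rmse: float
    nrmse: float
    d: float
    n: int
    obs_mean: float
    sim_mean: float
    quality: str | None
    flags: list[str] = field(default_factory=list)


def fit_stats(sim, obs) -> FitStats:
    """All four agreement statistics, with undefined ones flagged."""
    s, o = _pair(sim, obs)
    flags: list[str] = []
    r = pearson_r(s, o)
    if np.isnan(r):
        flags.append("r_undefined")
    e = rmse(s, o)
    obar = float(o.mean())
    if obar > 0:
        nr = nrmse(e, obar)
        quality = quality_class(nr)
    else:
        nr = float("nan")
        quality = None
        flags.append("nrmse_undefined")
    d = d_index(s, o)
    if np.isnan(d):
        flags.append("d_undefined")
    return FitStats(r=r, rmse=e, nrmse=nr, d=d, n=int(s.size),
                    obs_mean=obar, sim_mean=float(s.mean()), quality=quality,
                    flags=flags)


def evaluate_by_group(paired: pd.DataFrame, group: str,
                      sim_col: str = "sim", obs_col: str = "obs") -> pd.DataFrame:
    """Agreement statistics per group (e.g. per cultivar or per environment).

    Expects a table with one row per simulated/observed pair and returns one
    row per group with columns group, obs, sim, r, rmse, nrmse, d, n, quality
    and flags.  Groups with a single pair keep their RMSE but have r and d
    flagged as undefined rather than being dropped.
    """
    rows = []
    for key, sub in paired.groupby(group):
        st = fit_stats(sub[sim_col].to_numpy(), sub[obs_col].to_numpy())
        rows.append(
            {
                group: key,
                "obs": st.obs_mean,
                "sim": st.sim_mean,
                "r": st.r,
                "rmse": st.rmse,
                "nrmse": st.nrmse,
                "d": st.d,
                "n": st.n,
                "quality": st.quality,
                "flags": ";".join(st.flags),
            }
        )
    return pd.DataFrame(rows)


def paired_comparison(stats_before: pd.DataFrame, stats_after: pd.DataFrame,
                      metric: str, key: str = "cultivar") -> dict[str, float]:
    """Paired t-test on a per-group metric before versus after calibration.

    Both tables must cover the same groups.  Returns the mean difference
    (after - before), the t statistic and two-sided p value; degenerate
    cases (zero variance of differences) are flagged with NaN t and p.
    """
    b = stats_before.set_index(key)[metric]
    a = stats_after.set_index(key)[metric]
    if set(b.index) != set(a.index):
        raise ValueError("before/after tables cover different groups")
    a = a.loc[b.index]
    mask = ~(b.isna() | a.isna())
    diff = (a[mask] - b[mask]).to_numpy(float)
    if diff.size < 3:
        raise ValueError("need at least three paired groups")
    mean_diff = float(diff.mean())
    if np.allclose(diff, diff[0]):
        if np.allclose(diff, 0.0):
            return {"mean_diff": mean_diff, "t": 0.0, "p": 1.0, "n": diff.size}
        return {"mean_diff": mean_diff, "t": float("nan"), "p": float("nan"), "n": diff.size}
    t, p = sps.ttest_rel(a[mask].to_numpy(float), b[mask].to_numpy(float))
    return {"mean_diff": mean_diff, "t": float(t), "p": float(p), "n": int(diff.size)}
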