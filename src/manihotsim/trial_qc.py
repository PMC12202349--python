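"""Per-trial quality control for multi-environment cassava trials.

Each trial (location-year) is screened for usable genetic signal before model
calibration.  The screening model is a mixed model for a plot-level trait

    y = mu + beta * H + R + G + e

with H the proportion of plants harvested per plot (fixed covariate), R the
replicate effect and G the cultivar effect (both random).  Broad-sense
heritability on an entry-mean basis and reliability are computed from the
variance components, and trials are retained when at least one yield trait
clears both thresholds (H2 > 0.25 and reliability > 0.40, strictly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrialStats",
    "fit_trial_model",
    "heritability",
    "reliability",
    "qc_report",
    "filter_trials",
    "H2_THRESHOLD",
    "RELIABILITY_THRESHOLD",
]

H2_THRESHOLD = 0.25
RELIABILITY_THRESHOLD = 0.40

#: traits whose signal can justify retaining a trial
FILTER_TRAITS = ("fresh_root", "fresh_aboveground")


@dataclass
class TrialStats:
    """Variance components and derived statistics for one trial x trait."""

    trial: str
    trait: str
    var_G: float
    var_R: float
    var_e: float
    beta_H: float
    n_rep: int
    n_gen: int
    H2: float
    reliability: float
    retained: bool | None = None

    def __post_init__(self) -> None:
        for name in ("var_G", "var_R", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def heritability(var_G: float, var_e: float, n_rep: int) -> float:
    """Broad-sense heritability on an entry-mean basis:
    ``var_G / (var_G + var_e / n_rep)``.  Returns NaN when both variances
    are zero (undefined)."""
    denom = var_G + var_e / n_rep
    if denom == 0:
        return float("nan")
    return var_G / denom


def reliability(var_G: float, var_e: float, n_rep: int, method: str = "shrinkage") -> float:
    """Reliability of cultivar effect predictions.

    ``"shrinkage"`` (default): 1 - PEV/var_G with the prediction error
    variance from the balanced-design shrinkage factor,
    PEV = var_G * var_e / (var_e + n_rep * var_G).  Under balance this
    coincides with the entry-mean heritability (``"entry_mean"``), which is
    kept as an explicit alternative.
    """
    if var_G == 0:
        return 0.0
    if method == "shrinkage":
        pev = var_G * var_e / (var_e + n_rep * var_G)
        return 1.0 - pev / var_G
    if method == "entry_mean":
        return heritability(var_G, var_e, n_rep)
    raise ValueError(f"unknown reliability method: {method!r}")


def _fit_moments(df: pd.DataFrame, trait: str) -> tuple[float, float, float, float]:
    """ANOVA method-of-moments on a (near-)balanced RCBD, after adjusting the
    trait for the harvested-proportion covariate by fixed-effects OLS.
    Negative variance estimates are truncated at zero."""
    import statsmodels.formula.api as smf

    work = df.rename(columns={trait: "_y"}).copy()
    if work["prop_harvested"].nunique() > 1:
        ols = smf.ols("_y ~ prop_harvested + C(replicate) + C(cultivar)", data=work).fit()
        beta = float(ols.params["prop_harvested"])
    else:
        beta = 0.0
    h_centered = work["prop_harvested"] - work["prop_harvested"].mean()
    work["_adj"] = work["_y"] - beta * h_centered

    cell = work.pivot_table(index="cultivar", columns="replicate", values="_adj", aggfunc="mean")
    cell = cell.dropna(axis=0, how="any")
    g, r = cell.shape
    if g < 2 or r < 2:
        raise ValueError("method of moments needs >=2 cultivars and >=2 replicates after balancing")
    y = cell.to_numpy(float)
    grand = y.mean()
    ms_g = r * np.sum((y.mean(axis=1) - grand) ** 2) / (g - 1)
    ms_r = g * np.sum((y.mean(axis=0) - grand) ** 2) / (r - 1)
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + grand
    ms_e = np.sum(resid**2) / ((g - 1) * (r - 1))
    var_e = ms_e
    var_g = max(0.0, (ms_g - ms_e) / r)
    var_r = max(0.0, (ms_r - ms_e) / g)
    return var_g, var_r, var_e, beta


def _fit_reml(df: pd.DataFrame, trait: str) -> tuple[float, float, float, float]:
    """Restricted maximum likelihood via a variance-components mixed model."""
    import statsmodels.formula.api as smf

    work = df.rename(columns={trait: "_y"}).copy()
    work["_one"] = 1
    fixed = "_y ~ prop_harvested" if work["prop_harvested"].nunique() > 1 else "_y ~ 1"
    model = smf.mixedlm(
        fixed,
        data=work,
        groups="_one",
        vc_formula={"gen": "0 + C(cultivar)", "rep": "0 + C(replicate)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            # tight tolerances: on balanced data REML must match the
            # closed-form ANOVA estimators to numerical precision
            fit = model.fit(reml=True, method=["lbfgs"], pgtol=1e-12,
                            factr=10.0, maxiter=20000)
        except Exception:
            fit = model.fit(reml=True, method=["powell"], maxiter=5000)
    names = model.exog_vc.names
    vcomp = dict(zip(names, fit.vcomp))
    beta = float(fit.fe_params.get("prop_harvested", 0.0))
    return (
        max(0.0, float(vcomp["gen"])),
        max(0.0, float(vcomp["rep"])),
        max(0.0, float(fit.scale)),
        beta,
    )


def fit_trial_model(
    plots: pd.DataFrame,
    trait: str,
    trial: str | None = None,
    method: str = "auto",
    reliability_method: str = "shrinkage",
) -> TrialStats:
    """Fit the QC mixed model for one trial and trait.

    Parameters
    ----------
    plots : DataFrame
        Plot observations of a single trial with columns ``replicate``,
        ``cultivar``, ``prop_harvested`` and the trait column.
    trait : str
        Trait column to analyse.
    method : {"auto", "reml", "moments"}
        ``"reml"`` maximises the restricted likelihood; ``"moments"`` uses
        the balanced-ANOVA expected mean squares; ``"auto"`` tries REML and
        falls back to the method of moments if it fails.
    """
    df = plots.dropna(subset=[trait]).copy()
    if trial is None:
        trial = str(df["trial"].iloc[0]) if "trial" in df.columns else "trial"
    if df["replicate"].nunique() < 2:
        raise ValueError(f"trial {trial!r} has fewer than two replicates")
    if df["cultivar"].nunique() < 2:
        raise ValueError(f"trial {trial!r} has fewer than two cultivars")

    if method == "moments":
        var_g, var_r, var_e, beta = _fit_moments(df, trait)
    elif method == "reml":
        var_g, var_r, var_e, beta = _fit_reml(df, trait)
    elif method == "auto":
        try:
            var_g, var_r, var_e, beta = _fit_reml(df, trait)
        except Exception:
            var_g, var_r, var_e, beta = _fit_moments(df, trait)
    else:
        raise ValueError(f"unknown method: {method!r}")

    n_rep = int(df["replicate"].nunique())
    h2 = heritability(var_g, var_e, n_rep)
    rel = reliability(var_g, var_e, n_rep, method=reliability_method)
    return TrialStats(
        trial=trial,
        trait=trait,
        var_G=var_g,
        var_R=var_r,
        var_e=var_e,
        beta_H=beta,
        n_rep=n_rep,
        n_gen=int(df["cultivar"].nunique()),
        H2=0.0 if np.isnan(h2) else h2,
        reliability=rel,
    )


def qc_report(
    plots: pd.DataFrame,
    traits: tuple[str, ...] = FILTER_TRAITS,
    method: str = "auto",
) -> pd.DataFrame:
    """Per-trial, per-trait variance components with the retention decision.

    Returns one row per trial x trait with the fitted components, H2,
    reliability, and a ``retained`` flag shared by all traits of a trial.
    """
    rows: list[TrialStats] = []
    for trial, group in plots.groupby("trial"):
        for trait in traits:
            rows.append(fit_trial_model(group, trait, trial=str(trial), method=method))
    retained = set(filter_trials(rows))
    table = pd.DataFrame(
        {
            "trial": [s.trial for s in rows],
            "trait": [s.trait for s in rows],
            "var_G": [s.var_G for s in rows],
            "var_R": [s.var_R for s in rows],
            "var_e": [s.var_e for s in rows],
            "beta_H": [s.beta_H for s in rows],
            "n_rep": [s.n_rep for s in rows],
            "n_gen": [s.n_gen for s in rows],
            "H2": [s.H2 for s in rows],
            "reliability": [s.reliability for s in rows],
        }
    )
    table["retained"] = table["trial"].isin(retained)
    return table


def filter_trials(all_stats: list[TrialStats]) -> list[str]:
    """Trials retained by the quality filter.

    A trial is kept iff, for at least one yield trait, H2 > 0.25 AND
    reliability > 0.40 — both strict inequalities, so boundary values drop.
    """
    by_trial: dict[str, bool] = {}
    for s in all_stats:
        ok = (s.H2 > H2_THRESHOLD) and (s.reliability > RELIABILITY_THRESHOLD)
        if s.trait in FILTER_TRAITS:
            by_trial[s.trial] = by_trial.get(s.trial, False) or ok
        else:
            by_trial.setdefault(s.trial, False)
    return [t for t, keep in by_trial.items() if keep]
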