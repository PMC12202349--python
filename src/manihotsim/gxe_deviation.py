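"""AMMI decomposition of model prediction error across environments.

The observed-minus-simulated storage-root dry-weight deviations form a
genotype x environment matrix that is decomposed with the additive main
effects and multiplicative interaction (AMMI) model:

    y_ij = mu + G_i + E_j + sum_m gamma_mi * delta_mj + eps_ij

Main effects come from the two-way ANOVA of cell means; the doubly-centred
interaction residual is decomposed by singular value decomposition.  Degrees
of freedom for the interaction principal components follow Gollob
(g + e - 1 - 2m for component m) and F tests are taken against the AMMI
residual mean square.  Environment main effects and PC loadings are then
correlated with weather and soil covariates to diagnose which environmental
drivers the growth model mishandles.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd
from scipy import stats as sps

from .growth_model import Environment

__all__ = [
    "DeviationMatrix",
    "AMMIResult",
    "build_deviation_matrix",
    "impute_additive",
    "fit_ammi",
    "ammi_anova_table",
    "build_env_covariates",
    "correlate_env_covariates",
    "MISSING_FRACTION_LIMIT",
]

MISSING_FRACTION_LIMIT = 0.10


@dataclass
class DeviationMatrix:
    """Genotype x environment matrix of observed - simulated deviations."""

    values: pd.DataFrame          # complete (post-imputation) matrix
    missing_mask: pd.DataFrame    # True where the original cell was missing
    excluded_genotypes: list[str]
    missing_fraction: pd.Series   # per retained genotype, before imputation

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def impute_additive(matrix: pd.DataFrame, tol: float = 1e-6, max_iter: int = 100) -> pd.DataFrame:
    """Fill missing cells with the converged additive fit mu + G_i + E_j.

    EM-style iteration: initialise missing cells at the grand mean, refit the
    additive model on the completed matrix, replace the missing cells with
    their additive predictions, and repeat until the largest change is below
    ``tol``.
    """
    y = matrix.to_numpy(float).copy()
    mask = np.isnan(y)
    if not mask.any():
        return matrix.copy()
    y[mask] = np.nanmean(matrix.to_numpy(float))
    for _ in range(max_iter):
        mu = y.mean()
        g = y.mean(axis=1, keepdims=True) - mu
        e = y.mean(axis=0, keepdims=True) - mu
        fitted = mu + g + e
        delta = np.max(np.abs(fitted[mask] - y[mask]))
        y[mask] = fitted[mask]
        if delta < tol:
            break
    return pd.DataFrame(y, index=matrix.index, columns=matrix.columns)


def build_deviation_matrix(
    obs: pd.DataFrame,
    sim: pd.DataFrame,
    value_obs: str = "storage_dry",
    value_sim: str = "storage",
    missing_limit: float = MISSING_FRACTION_LIMIT,
) -> DeviationMatrix:
    """Cell-wise observed - simulated matrix with exclusion and imputation.

    Both tables need ``cultivar`` and ``env`` key columns.  Genotypes missing
    in more than ``missing_limit`` of the environments are excluded before
    imputation; remaining missing cells are filled by the iterated additive
    fit.  An environment present in only one of the two tables is an error.
    """
    o = obs.pivot_table(index="cultivar", columns="env", values=value_obs, aggfunc="mean")
    s = sim.pivot_table(index="cultivar", columns="env", values=value_sim, aggfunc="mean")
    only_obs = set(o.columns) - set(s.columns)
    only_sim = set(s.columns) - set(o.columns)
    if only_obs or only_sim:
        raise ValueError(
            f"environments present in only one table: {sorted(only_obs | only_sim)}"
        )
    genotypes = o.index.intersection(s.index)
    dev = o.loc[genotypes] - s.loc[genotypes]

    frac_missing = dev.isna().mean(axis=1)
    excluded = sorted(frac_missing.index[frac_missing > missing_limit].tolist())
    dev = dev.drop(index=excluded)
    mask = dev.isna()
    filled = impute_additive(dev)
    return DeviationMatrix(
        values=filled,
        missing_mask=mask,
        excluded_genotypes=[str(x) for x in excluded],
        missing_fraction=frac_missing.drop(index=excluded),
    )


@dataclass
class AMMIResult:
    """Fitted AMMI decomposition of a complete deviation matrix."""

    grand_mean: float
    genotype_effects: pd.Series     # G_i, sum to zero
    environment_effects: pd.Series  # E_j, sum to zero
    genotype_scores: pd.DataFrame   # gamma, genotypes x components (unit norm)
    environment_loadings: pd.DataFrame  # delta, environments x components
    singular_values: np.ndarray     # all min(g-1, e-1) singular values
    n_components: int
    anova: pd.DataFrame

    @property
    def interaction_ss(self) -> float:
        return float(np.sum(self.singular_values**2))

    def env_mean_deviation(self) -> pd.Series:
        """Mean deviation per environment (mu + E_j): positive values mean
        the model under-predicts in that environment."""
        return self.grand_mean + self.environment_effects

    def reconstruct(self, n_components: int | None = None) -> pd.DataFrame:
        """mu + G + E plus the first ``n_components`` multiplicative terms
        (all retained components by default; with every singular value the
        reconstruction is exact)."""
        m = len(self.singular_values) if n_components is None else n_components
        g = self.genotype_effects.to_numpy()[:, None]
        e = self.environment_effects.to_numpy()[None, :]
        y = self.grand_mean + g + e
        gamma = self.genotype_scores.to_numpy()
        delta = self.environment_loadings.to_numpy()
        for k in range(min(m, gamma.shape[1])):
            y = y + self.singular_values[k] * np.outer(gamma[:, k], delta[:, k])
        return pd.DataFrame(y, index=self.genotype_effects.index,
                            columns=self.environment_effects.index)


def fit_ammi(matrix: DeviationMatrix | pd.DataFrame, n_components: int = 3) -> AMMIResult:
    """Fit the AMMI model to a complete genotype x environment matrix."""
    values = matrix.values if isinstance(matrix, DeviationMatrix) else matrix
    if values.isna().any().any():
        raise ValueError("AMMI requires a complete matrix; impute first")
    g, e = values.shape
    if g < 3 or e < 3:
        raise ValueError("AMMI needs at least 3 genotypes and 3 environments")
    max_m = min(g - 1, e - 1)
    if not 1 <= n_components <= max_m:
        raise ValueError(f"n_components must be in [1, {max_m}]")

    y = values.to_numpy(float)
    mu = y.mean()
    gi = y.mean(axis=1) - mu
    ej = y.mean(axis=0) - mu
    resid = y - mu - gi[:, None] - ej[None, :]

    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    s = s[:max_m]
    u = u[:, :max_m]
    vt = vt[:max_m]

    # fix a sign convention: largest-|loading| environment positive
    for k in range(max_m):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1

    comp_names = [f"PC{k + 1}" for k in range(max_m)]
    result = AMMIResult(
        grand_mean=float(mu),
        genotype_effects=pd.Series(gi, index=values.index, name="G"),
        environment_effects=pd.Series(ej, index=values.columns, name="E"),
        genotype_scores=pd.DataFrame(u, index=values.index, columns=comp_names),
        environment_loadings=pd.DataFrame(vt.T, index=values.columns, columns=comp_names),
        singular_values=s,
        n_components=n_components,
        anova=pd.DataFrame(),
    )
    result.anova = ammi_anova_table(result)
    return result


def ammi_anova_table(result: AMMIResult) -> pd.DataFrame:
    """ANOVA of the deviation matrix in the conventional AMMI layout.

    Rows: Environment, Genotype, Interactions, PC1..PCm, Residuals.  The PC
    rows use Gollob degrees of freedom (g + e - 1 - 2m) and are F-tested
    against the AMMI residual mean square; the main effects are tested
    against the full interaction mean square.  ``% Total SS`` is reported for
    the three top-level sources and the cumulative interaction proportion for
    the PCs.
    """
    g = len(result.genotype_effects)
    e = len(result.environment_effects)
    m = result.n_components
    s2 = result.singular_values**2

    ss_env = g * float(np.sum(result.environment_effects.to_numpy() ** 2))
    ss_gen = e * float(np.sum(result.genotype_effects.to_numpy() ** 2))
    ss_int = float(np.sum(s2))
    ss_total = ss_env + ss_gen + ss_int

    df_env = e - 1
    df_gen = g - 1
    df_int = (g - 1) * (e - 1)
    df_pcs = [g + e - 1 - 2 * k for k in range(1, m + 1)]
    df_resid = df_int - sum(df_pcs)
    ss_pcs = [float(s2[k]) for k in range(m)]
    ss_resid = ss_int - sum(ss_pcs)

    ms_int = ss_int / df_int
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    def row(source, df, ss, ms_denom, df_denom, pct_total, cum):
        ms = ss / df if df > 0 else np.nan
        if ms_denom and np.isfinite(ms_denom) and ms_denom > 0 and df_denom > 0:
            f = ms / ms_denom
            p = float(sps.f.sf(f, df, df_denom))
        else:
            f = np.nan
            p = np.nan
        return {"source": source, "df": df, "sum_sq": ss, "mean_sq": ms,
                "F": f, "p": p, "pct_total_ss": pct_total, "cum_interaction_pct": cum}

    rows = [
        row("Environment", df_env, ss_env, ms_int, df_int, 100 * ss_env / ss_total, np.nan),
        row("Genotype", df_gen, ss_gen, ms_int, df_int, 100 * ss_gen / ss_total, np.nan),
        row("Interactions", df_int, ss_int, ms_resid, df_resid, 100 * ss_int / ss_total, np.nan),
    ]
    cum = 0.0
    for k in range(m):
        cum += 100 * ss_pcs[k] / ss_int if ss_int > 0 else 0.0
        rows.append(row(f"PC{k + 1}", df_pcs[k], ss_pcs[k], ms_resid, df_resid, np.nan, cum))
    rows.append(row("Residuals", df_resid, ss_resid, None, 0, np.nan, np.nan))
    return pd.DataFrame(rows).set_index("source")


# ---------------------------------------------------------------------------
# Environment covariates
# ---------------------------------------------------------------------------

_MEAN_VARS = ("tmax", "tmin", "srad", "rh2m", "wind")


def build_env_covariates(
    envs: dict[str, Environment],
    months: tuple[int, ...] = (3, 6, 9, 12),
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Weather (and optional site/soil) aggregates per environment.

    For each window of ``k`` calendar months after planting (clipped at
    harvest): cumulative rainfall ``RAIN_k`` and means ``TMAX_k``, ``TMIN_k``,
    ``SRAD_k``, ``RH2M_k``, ``WIND_k``.  Topsoil descriptors from the first
    soil layer are appended, as are any columns of ``extra`` (indexed by
    environment, e.g. elevation or latitude).
    """
    rows = {}
    for name, env in envs.items():
        mgmt = env.management
        w = env.weather.slice(mgmt.planting_date, mgmt.harvest_date).data
        start = pd.Timestamp(mgmt.planting_date)
        cov: dict[str, float] = {}
        for k in months:
            cutoff = start + pd.DateOffset(months=k)
            win = w[w["date"] < cutoff]
            cov[f"RAIN_{k}"] = float(win["rain"].sum())
            for var in _MEAN_VARS:
                cov[f"{var.upper()}_{k}"] = float(win[var].mean())
        top = env.soil.topsoil()
        for col in ("slll", "sdul", "ssat", "ssks", "sbdm", "sloc", "slcl",
                    "slsi", "slhw", "scec"):
            cov[col.upper()] = float(top[col])
        rows[name] = cov
    table = pd.DataFrame(rows).T
    table.index.name = "env"
    if extra is not None:
        table = table.join(extra, how="left")
    return table


def correlate_env_covariates(
    result: AMMIResult,
    covariates: pd.DataFrame,
    n_pcs: int = 3,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each covariate with envMean and PC loadings.

    ``envMean`` is the mean observed-minus-simulated deviation per
    environment, so a positive correlation means the model under-estimates
    where the covariate is high.  Unadjusted p values are reported together
    with Benjamini-Hochberg significance flags at ``fdr_alpha``; constant
    covariates are flagged and given NaN correlations.
    """
    if len(result.environment_effects) < 4:
        raise ValueError("need at least four environments to correlate covariates")
    targets = {"envMean": result.env_mean_deviation()}
    for k in range(min(n_pcs, result.environment_loadings.shape[1])):
        name = f"PC{k + 1}"
        targets[name] = result.environment_loadings[name]

    rows = []
    for cov_name in covariates.columns:
        cov = covariates[cov_name]
        for tgt_name, tgt in targets.items():
            joined = pd.concat([cov, tgt], axis=1, join="inner").dropna()
            x = joined.iloc[:, 0].to_numpy(float)
            y = joined.iloc[:, 1].to_numpy(float)
            if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"covariate": cov_name, "target": tgt_name,
                             "r": np.nan, "p": np.nan, "n": len(x),
                             "flag": "constant_or_short"})
                continue
            r, p = sps.pearsonr(x, y)
            rows.append({"covariate": cov_name, "target": tgt_name,
                         "r": float(r), "p": float(p), "n": len(x), "flag": ""})
    table = pd.DataFrame(rows)

    # Benjamini-Hochberg over the valid tests
    valid = table["p"].notna()
    pvals = table.loc[valid, "p"].to_numpy()
    if len(pvals):
        order = np.argsort(pvals)
        ranked = np.empty_like(pvals)
        n = len(pvals)
        thresh = fdr_alpha * (np.arange(1, n + 1)) / n
        passed = pvals[order] <= thresh
        if passed.any():
            cut = pvals[order][np.max(np.nonzero(passed))]
        else:
            cut = -1.0
        ranked = pvals <= cut
        table.loc[valid, "bh_significant"] = ranked
    flags = table.get("bh_significant")
    if flags is None:
        table["bh_significant"] = False
    else:
        table["bh_significant"] = [bool(v) if pd.notna(v) else False for v in flags]
    return table
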