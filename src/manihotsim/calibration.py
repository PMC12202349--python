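"""Staged genotype-specific parameter calibration.

The protocol mirrors how cassava growth models are calibrated against
breeding-trial data, in four stages per cultivar:

1. *Stage A* — an automated grid search standing in for manual trial-and-error:
   phenology durations (B01ND..B34ND) are fitted sequentially, in the order
   the forking events occur, against observed fork dates; branch counts
   (BR1FX..BR4FX) come directly from field counts; leaf size and longevity
   (LAXS, LLIFA) are fitted against an observed LAI series.  Parameters with
   no observations keep their defaults.
2. *GLUE* — generalized likelihood uncertainty estimation: Monte-Carlo draws
   of {SLAS, LPEFR, LNSLP, NODWT, NODLT} from uniform priors are weighted by
   a Gaussian likelihood of the simulated aboveground dry biomass against
   observations across environments.
3. *Yield matching* — PARUE (and KCAN if PARUE saturates at its bounds) is
   adjusted by one-dimensional search to remove the mean storage-root yield
   bias of the cultivar across environments.
4. A second GLUE pass with the matched PARUE/KCAN.

Prior bounds are the published per-parameter calibration ranges for elite
West-African cassava germplasm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .evaluation import fit_stats, paired_comparison, rmse as _rmse
from .growth_model import (
    CultivarParams,
    Environment,
    PreparedEnvironment,
    SpeciesConfig,
    DEFAULT_SPECIES,
    prepare_environment,
    simulate,
    simulate_harvest,
)

__all__ = [
    "PRIOR_RANGES",
    "GLUE_PARAMS",
    "PriorSpec",
    "PosteriorEnsemble",
    "sample_priors",
    "glue_weight",
    "run_glue",
    "stage_a_calibrate",
    "yield_match",
    "full_protocol",
    "ProtocolResult",
    "simulate_targets",
]

#: Published calibration ranges (min, max) per genotype-specific parameter.
PRIOR_RANGES: dict[str, tuple[float, float]] = {
    "b01nd": (231, 1200),
    "b12nd": (80, 344),
    "b23nd": (101, 286),
    "b34nd": (100, 250),
    "br1fx": (2.0, 3.8),
    "br2fx": (2.0, 4.0),
    "br3fx": (1.0, 3.0),
    "br4fx": (1.4, 2.0),
    "laxs": (401, 920),
    "llifa": (600, 1800),
    "slas": (149, 280),
    "lpefr": (0.2, 0.3),
    "lnslp": (0.7, 1.7),
    "nodwt": (1.7, 6.0),
    "nodlt": (1.0, 4.0),
    "parue": (1.4, 2.6),
    "kcan": (0.5, 0.8),
}

#: The five growth parameters estimated by GLUE.
GLUE_PARAMS = ("slas", "lpefr", "lnslp", "nodwt", "nodlt")

# grid steps of the automated stage-A search
GRID_STEP_TT = 10.0     # degCd for B01ND..B34ND
GRID_STEP_LAXS = 20.0   # cm2
GRID_STEP_LLIFA = 50.0  # degCd


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior bounds per parameter."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PRIOR_RANGES)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo <= hi:
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    def subset(self, names) -> "PriorSpec":
        return PriorSpec({n: self.bounds[n] for n in names})

    def clip(self, name: str, value: float) -> float:
        lo, hi = self.bounds[name]
        return min(max(value, lo), hi)


@dataclass
class PosteriorEnsemble:
    """A weighted GLUE posterior sample."""

    draws: pd.DataFrame
    weights: np.ndarray
    point_estimate: dict[str, float]
    rmse_at_estimate: float

    def __post_init__(self) -> None:
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("weights must be non-negative and sum to one")


def sample_priors(spec: PriorSpec, n: int, seed) -> pd.DataFrame:
    """``n`` independent uniform draws within the prior bounds (seeded)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for name, (lo, hi) in spec.bounds.items():
        cols[name] = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)
    return pd.DataFrame(cols)


def glue_weight(sim, obs, sigma: float) -> float:
    """Unnormalised Gaussian likelihood exp(-SSE / (2 sigma^2))."""
    s = np.asarray(sim, float)
    o = np.asarray(obs, float)
    if s.shape != o.shape:
        raise ValueError("sim and obs must have equal length")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(np.exp(-np.sum((s - o) ** 2) / (2.0 * sigma**2)))


def _log_glue_weight(sim: np.ndarray, obs: np.ndarray, sigma: float) -> float:
    return -float(np.sum((sim - obs) ** 2)) / (2.0 * sigma**2)


def _prepare_envs(
    envs: dict[str, Environment | PreparedEnvironment],
    species: SpeciesConfig,
) -> dict[str, PreparedEnvironment]:
    return {
        name: env if isinstance(env, PreparedEnvironment) else prepare_environment(env, species)
        for name, env in envs.items()
    }


def simulate_targets(
    params: CultivarParams,
    envs: dict[str, Environment],
    species: SpeciesConfig = DEFAULT_SPECIES,
) -> pd.DataFrame:
    """Harvest outputs (t ha-1 dry) of one parameter set in every environment."""
    rows = []
    for name, prepared in _prepare_envs(envs, species).items():
        storage, aboveground = simulate_harvest(params, prepared, species)
        rows.append({"env": name, "storage": storage, "aboveground": aboveground})
    return pd.DataFrame(rows).set_index("env")


SIGMA_FLOOR = 0.5  # t ha-1


def _resolve_sigma(obs: np.ndarray, sigma) -> float:
    if sigma == "obs_sd":
        return max(SIGMA_FLOOR, float(np.std(obs, ddof=1)) if obs.size > 1 else 0.0)
    return float(sigma)


def run_glue(
    base_params: CultivarParams,
    envs: dict[str, Environment],
    obs: dict[str, float],
    target: str = "aboveground",
    priors: PriorSpec | None = None,
    n: int = 2000,
    seed=0,
    sigma: float | str = "obs_sd",
    point: str = "weighted_mean",
    species: SpeciesConfig = DEFAULT_SPECIES,
) -> PosteriorEnsemble:
    """GLUE estimation of the five growth parameters for one cultivar.

    Simulates every prior draw across all environments with observations of
    ``target`` ("aboveground" or "storage", t ha-1 dry), weights draws with a
    Gaussian likelihood (log-domain, so underflow cannot produce NaN), and
    returns the weight-normalised ensemble.  The point estimate is the
    likelihood-weighted posterior mean by default (``point="max_weight"``
    selects the single best draw instead).

    ``sigma`` is the likelihood scale in t ha-1.  The default ``"obs_sd"``
    uses the standard deviation of the observations across environments,
    floored at 0.5 t ha-1; a float fixes the scale explicitly (e.g. a known
    measurement-error magnitude).
    """
    if target not in ("aboveground", "storage"):
        raise ValueError("target must be 'aboveground' or 'storage'")
    env_names = [name for name in envs if name in obs and np.isfinite(obs[name])]
    if not env_names:
        raise ValueError("no environments with observations of the target")
    obs_vec = np.array([obs[name] for name in env_names], float)
    sig = _resolve_sigma(obs_vec, sigma)
    if sig <= 0:
        raise ValueError("likelihood sigma must be positive")

    spec = (priors or PriorSpec()).subset(GLUE_PARAMS)
    draws = sample_priors(spec, n, seed)
    prepared = _prepare_envs({k: envs[k] for k in env_names}, species)
    target_idx = 0 if target == "storage" else 1

    names = list(spec.bounds)
    draw_matrix = draws[names].to_numpy()
    log_w = np.empty(n)
    for i in range(n):
        cand = base_params.replace(**dict(zip(names, draw_matrix[i])))
        sims = np.array(
            [simulate_harvest(cand, prep, species)[target_idx] for prep in prepared.values()]
        )
        log_w[i] = _log_glue_weight(sims, obs_vec, sig)

    norm = logsumexp(log_w)
    weights = np.exp(log_w - norm)
    weights /= weights.sum()

    if point == "weighted_mean":
        estimate = {k: float(np.dot(weights, draws[k].to_numpy())) for k in spec.bounds}
    elif point == "max_weight":
        best = int(np.argmax(weights))
        estimate = {k: float(draws.iloc[best][k]) for k in spec.bounds}
    else:
        raise ValueError(f"unknown point estimator: {point!r}")
    for k, v in estimate.items():
        estimate[k] = spec.clip(k, v)

    fitted = base_params.replace(**estimate)
    sims = simulate_targets(fitted, {k: envs[k] for k in env_names}, species)
    rmse_at = _rmse(sims[target].to_numpy(), obs_vec)
    return PosteriorEnsemble(draws=draws, weights=weights,
                             point_estimate=estimate, rmse_at_estimate=rmse_at)


# ---------------------------------------------------------------------------
# Stage A: automated trial-and-error on phenology and LAI
# ---------------------------------------------------------------------------


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    values = np.arange(lo, hi + 0.5 * step, step)
    return np.clip(values, lo, hi)


def stage_a_calibrate(
    params: CultivarParams,
    env: Environment,
    fork_days: dict[int, float] | None = None,
    branch_counts: dict[int, float] | None = None,
    lai_obs: pd.DataFrame | None = None,
    priors: PriorSpec | None = None,
    species: SpeciesConfig = DEFAULT_SPECIES,
    max_rounds: int = 10,
    rel_tol: float = 0.01,
) -> CultivarParams:
    """Grid-search calibration of phenology and leaf parameters.

    ``fork_days`` maps fork number (1..4) to the observed day after planting;
    the thermal durations are fitted in fork order by a 10-degCd grid.
    ``branch_counts`` maps fork number to the measured branches per fork
    (clipped into the prior range).  ``lai_obs`` is a table with columns
    ``day`` (days after planting) and ``lai`` against which LAXS then LLIFA
    are grid-fitted, re-alternating until the RMSE improves by less than
    ``rel_tol`` (1%).  Missing observations leave the corresponding defaults
    untouched.
    """
    spec = priors or PriorSpec()
    mgmt = env.management
    cum = env.weather.slice(mgmt.planting_date, mgmt.harvest_date).cumulative_thermal_time(species)

    out = params

    if fork_days:
        b_names = ("b01nd", "b12nd", "b23nd", "b34nd")
        prev_sum = 0.0
        for k in range(1, 5):
            name = b_names[k - 1]
            if k in fork_days:
                lo, hi = spec.bounds[name]
                grid = _grid(lo, hi, GRID_STEP_TT)
                # predicted fork day = first day cumulative TT >= threshold
                pred_days = np.searchsorted(cum, prev_sum + grid)
                errors = (pred_days - float(fork_days[k])) ** 2
                out = out.replace(**{name: float(grid[int(np.argmin(errors))])})
            prev_sum += getattr(out, name)

    if branch_counts:
        for k, count in branch_counts.items():
            name = f"br{k}fx"
            out = out.replace(**{name: spec.clip(name, float(count))})

    if lai_obs is not None and len(lai_obs) > 0:
        days = lai_obs["day"].to_numpy(int)
        target = lai_obs["lai"].to_numpy(float)

        def lai_rmse(p: CultivarParams) -> float:
            res = simulate(p, env.weather, env.soil, mgmt, species)
            sim_lai = res.daily["lai"].to_numpy()[days]
            return _rmse(sim_lai, target)

        best = lai_rmse(out)
        for _ in range(max_rounds):
            previous = best
            for name, step in (("laxs", GRID_STEP_LAXS), ("llifa", GRID_STEP_LLIFA)):
                lo, hi = spec.bounds[name]
                grid = _grid(lo, hi, step)
                scores = [lai_rmse(out.replace(**{name: float(v)})) for v in grid]
                idx = int(np.argmin(scores))
                if scores[idx] < best:
                    best = scores[idx]
                    out = out.replace(**{name: float(grid[idx])})
            if previous <= 0 or (previous - best) / max(previous, 1e-12) < rel_tol:
                break

    return out


# ---------------------------------------------------------------------------
# Yield matching on PARUE / KCAN
# ---------------------------------------------------------------------------

BIAS_TOL = 0.1  # t ha-1


def _mean_bias(params: CultivarParams, envs, obs_vec, env_names, species) -> float:
    sims = simulate_targets(params, {k: envs[k] for k in env_names}, species)
    return float(np.mean(obs_vec - sims["storage"].to_numpy()))


def _bisect_param(params, name, lo, hi, envs, obs_vec, env_names, species,
                  iters: int = 40) -> CultivarParams:
    """Bisection on one parameter; storage yield increases with both PARUE
    and KCAN, so the mean bias (obs - sim) is decreasing in the parameter."""
    bias_lo = _mean_bias(params.replace(**{name: lo}), envs, obs_vec, env_names, species)
    bias_hi = _mean_bias(params.replace(**{name: hi}), envs, obs_vec, env_names, species)
    if bias_lo <= 0:  # even the lower bound over-predicts
        return params.replace(**{name: lo})
    if bias_hi >= 0:  # even the upper bound under-predicts
        return params.replace(**{name: hi})
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        bias = _mean_bias(params.replace(**{name: mid}), envs, obs_vec, env_names, species)
        if abs(bias) < BIAS_TOL:
            return params.replace(**{name: mid})
        if bias > 0:
            lo = mid
        else:
            hi = mid
    return params.replace(**{name: 0.5 * (lo + hi)})


def yield_match(
    params: CultivarParams,
    envs: dict[str, Environment],
    obs: dict[str, float],
    priors: PriorSpec | None = None,
    species: SpeciesConfig = DEFAULT_SPECIES,
) -> CultivarParams:
    """Remove the cultivar's mean storage-root yield bias via PARUE.

    One-dimensional search on PARUE within its prior bounds, minimising the
    absolute mean bias |mean(obs - sim)| across environments; if PARUE
    saturates at a bound and the bias still exceeds 0.1 t ha-1, KCAN is
    adjusted the same way.  Never increases the absolute mean bias.
    """
    spec = priors or PriorSpec()
    env_names = [name for name in envs if name in obs and np.isfinite(obs[name])]
    if not env_names:
        raise ValueError("no environments with storage-root observations")
    obs_vec = np.array([obs[name] for name in env_names], float)
    envs = _prepare_envs({k: envs[k] for k in env_names}, species)

    if abs(_mean_bias(params, envs, obs_vec, env_names, species)) < BIAS_TOL:
        return params

    lo, hi = spec.bounds["parue"]
    out = _bisect_param(params, "parue", lo, hi, envs, obs_vec, env_names, species)
    bias = _mean_bias(out, envs, obs_vec, env_names, species)
    if abs(bias) >= BIAS_TOL and out.parue in (lo, hi):
        klo, khi = spec.bounds["kcan"]
        out = _bisect_param(out, "kcan", klo, khi, envs, obs_vec, env_names, species)
    # keep the better of the original and matched parameter sets
    if abs(_mean_bias(out, envs, obs_vec, env_names, species)) <= abs(
        _mean_bias(params, envs, obs_vec, env_names, species)
    ):
        return out
    return params


# ---------------------------------------------------------------------------
# Full protocol
# ---------------------------------------------------------------------------


@dataclass
class ProtocolResult:
    """Output of the full calibration protocol."""

    params: pd.DataFrame            # cultivar x 17 calibrated parameters
    summary: pd.DataFrame           # min/max/mean/CV per parameter
    before: pd.DataFrame            # per-cultivar fit statistics, defaults
    after: pd.DataFrame             # per-cultivar fit statistics, calibrated
    paired_tests: dict[str, dict]   # paired t-tests per metric
    warnings: list[str]


def _eval_per_cultivar(param_map, envs, obs_table, species) -> pd.DataFrame:
    rows = []
    for cultivar, params in param_map.items():
        sub = obs_table[obs_table["cultivar"] == cultivar].dropna(subset=["storage_dry"])
        env_names = [e for e in sub["env"] if e in envs]
        if not env_names:
            continue
        sims = simulate_targets(params, {e: envs[e] for e in env_names}, species)
        sub = sub.set_index("env").loc[env_names]
        st = fit_stats(sims["storage"].to_numpy(), sub["storage_dry"].to_numpy())
        rows.append({"cultivar": cultivar, "r": st.r, "rmse": st.rmse,
                     "nrmse": st.nrmse, "d": st.d, "n": st.n})
    return pd.DataFrame(rows)


def parameter_summary(params_table: pd.DataFrame) -> pd.DataFrame:
    """Min/Max/Mean/CV(%) of each calibrated parameter across cultivars."""
    rows = []
    for name in params_table.columns:
        vals = params_table[name].to_numpy(float)
        mean = vals.mean()
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append({"parameter": name, "max": vals.max(), "min": vals.min(),
                     "mean": mean, "cv_pct": 100.0 * sd / mean if mean != 0 else np.nan})
    return pd.DataFrame(rows).set_index("parameter")


def full_protocol(
    obs_table: pd.DataFrame,
    envs: dict[str, Environment],
    stage_a_obs: dict[str, dict] | None = None,
    priors: PriorSpec | None = None,
    n_draws: int = 2000,
    seed=0,
    sigma: float | str = "obs_sd",
    species: SpeciesConfig = DEFAULT_SPECIES,
    defaults: CultivarParams | None = None,
) -> ProtocolResult:
    """Run the four calibration stages for every cultivar.

    Parameters
    ----------
    obs_table : DataFrame
        One row per cultivar x environment with columns ``cultivar``, ``env``,
        ``aboveground_dry`` and ``storage_dry`` (t ha-1, environment means of
        QC-retained trials).
    envs : dict
        Environment name -> :class:`Environment`.
    stage_a_obs : dict, optional
        Per cultivar: ``{"env": name, "fork_days": {...}, "branch_counts":
        {...}, "lai_obs": DataFrame}`` — cultivars without an entry keep the
        default phenology/leaf parameters, exactly as when no forks were
        observed in the field.
    """
    spec = priors or PriorSpec()
    base = defaults or CultivarParams.default()
    notes: list[str] = []
    if len(envs) < 2:
        notes.append("single environment: calibration is weakly informed")
        warnings.warn(notes[-1], stacklevel=2)

    cultivars = sorted(obs_table["cultivar"].unique())
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.spawn(len(cultivars))

    calibrated: dict[str, CultivarParams] = {}
    defaults_map: dict[str, CultivarParams] = {}
    for cultivar, child in zip(cultivars, child_seeds):
        sub = obs_table[obs_table["cultivar"] == cultivar]
        ag_obs = {r.env: r.aboveground_dry for r in sub.itertuples()
                  if r.env in envs and np.isfinite(r.aboveground_dry)}
        st_obs = {r.env: r.storage_dry for r in sub.itertuples()
                  if r.env in envs and np.isfinite(r.storage_dry)}
        if not ag_obs and not st_obs:
            notes.append(f"cultivar {cultivar!r} absent from all retained trials; skipped")
            warnings.warn(notes[-1], stacklevel=2)
            continue
        defaults_map[cultivar] = base

        params = base
        info = (stage_a_obs or {}).get(cultivar)
        if info is not None:
            params = stage_a_calibrate(
                params,
                envs[info["env"]],
                fork_days=info.get("fork_days"),
                branch_counts=info.get("branch_counts"),
                lai_obs=info.get("lai_obs"),
                priors=spec,
                species=species,
            )
        seeds = child.spawn(2)
        if ag_obs:
            post = run_glue(params, envs, ag_obs, target="aboveground", priors=spec,
                            n=n_draws, seed=seeds[0], sigma=sigma, species=species)
            params = params.replace(**post.point_estimate)
        if st_obs:
            params = yield_match(params, envs, st_obs, priors=spec, species=species)
        if ag_obs:
            post = run_glue(params, envs, ag_obs, target="aboveground", priors=spec,
                            n=n_draws, seed=seeds[1], sigma=sigma, species=species)
            params = params.replace(**post.point_estimate)
        calibrated[cultivar] = params

    params_table = pd.DataFrame({c: p.as_dict() for c, p in calibrated.items()}).T
    params_table.index.name = "cultivar"

    before = _eval_per_cultivar(defaults_map, envs, obs_table, species)
    after = _eval_per_cultivar(calibrated, envs, obs_table, species)

    tests = {}
    for metric in ("r", "rmse", "d"):
        try:
            tests[metric] = paired_comparison(before, after, metric)
        except ValueError as exc:
            notes.append(f"paired test on {metric} unavailable: {exc}")

    return ProtocolResult(
        params=params_table,
        summary=parameter_summary(params_table),
        before=before,
        after=after,
        paired_tests=tests,
        warnings=notes,
    )
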