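"""Seeded generators for synthetic multi-environment cassava trial studies.

No field data accompany this package, so every input of the pipeline can be
generated here with the statistical structure the analysis assumes: daily
weather from named Nigerian location archetypes (sinusoidal temperatures, a
first-order wet/dry rainfall occurrence chain with exponential amounts scaled
to the archetype's annual total), layered soil profiles by texture class,
"true" cultivar parameter sets drawn from the published calibration ranges,
plot-level trials built by running the growth simulator and adding replicate
effects, harvest-proportion effects and plot noise, leaf scans around the
leaf-area allometry, phenology observations, and deviation matrices with
prescribed variance shares.  Every generator is a pure function of its
arguments and seed, and emits the ground truth needed to score downstream
estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd

from .calibration import PriorSpec
from .growth_model import (
    CultivarParams,
    Environment,
    Management,
    SoilProfile,
    SpeciesConfig,
    DEFAULT_SPECIES,
    WeatherSeries,
    simulate,
)

__all__ = [
    "EnvironmentArchetype",
    "ARCHETYPES",
    "StudyDesign",
    "gen_weather",
    "gen_soil",
    "gen_environment",
    "make_study_environments",
    "gen_cultivars",
    "gen_trials",
    "gen_balanced_trial",
    "gen_leaf_scans",
    "gen_phenology_obs",
    "gen_deviation_fixture",
]


@dataclass(frozen=True)
class EnvironmentArchetype:
    """Climate and soil summary of one trial location.

    Monthly mean temperatures are taken constant with a small seasonal
    harmonic; ``annual_rain_mm`` is the growing-season rainfall target;
    ``wet_season`` gives the monthly rain-occurrence weights (Jan..Dec).
    """

    name: str
    tmin_mean: float
    tmax_mean: float
    annual_rain_mm: float
    rh2m: float
    srad: float
    wind: float
    soil_class: str   # SCL, SL or CL
    planting_month: int
    wet_season: tuple[float, ...] = (
        0.03, 0.05, 0.15, 0.40, 0.55, 0.65, 0.70, 0.65, 0.70, 0.50, 0.12, 0.04
    )

    def __post_init__(self) -> None:
        if not 1200 <= self.annual_rain_mm <= 3500:
            raise ValueError("annual rainfall target outside the plausible 1200-3500 mm span")
        if not 28 <= self.tmax_mean <= 34 or not 20 <= self.tmin_mean <= 24:
            raise ValueError("temperature means outside the plausible Nigerian range")
        if self.soil_class not in ("SCL", "SL", "CL"):
            raise ValueError("soil_class must be SCL, SL or CL")


#: One archetype per trial location retained in the source breeding network.
ARCHETYPES: dict[str, EnvironmentArchetype] = {
    a.name: a
    for a in (
        EnvironmentArchetype("Abuja", 20.8, 30.4, 2238, 73.2, 18.6, 1.6, "SCL", 6),
        EnvironmentArchetype("AgoOwu", 21.8, 29.1, 2491, 86.2, 16.7, 1.0, "SCL", 6),
        EnvironmentArchetype("Ibadan", 22.0, 29.3, 2297, 86.0, 16.7, 1.5, "SL", 7),
        EnvironmentArchetype("Ikenne", 22.9, 29.3, 2549, 88.2, 16.4, 1.1, "CL", 6),
        EnvironmentArchetype("Mokwa", 22.0, 32.5, 1443, 68.5, 18.6, 1.7, "SCL", 6),
        EnvironmentArchetype("Onne", 23.3, 29.6, 3319, 88.1, 14.9, 0.9, "SCL", 4),
        EnvironmentArchetype("Ubiaja", 22.1, 29.3, 2725, 84.1, 16.7, 1.6, "SCL", 6),
        EnvironmentArchetype("Umudike", 22.9, 29.4, 1966, 86.3, 16.2, 1.4, "SCL", 7),
    )
}


@dataclass
class StudyDesign:
    """Size and noise structure of a synthetic multi-environment study.

    Defaults reproduce the structure of the source breeding study: 67
    cultivars, 16 environments, a 3-replicate randomized complete block
    design.  ``plot_noise_sd`` is the residual plot error on the fresh-weight
    scale (t ha-1), ``rep_effect_sd`` the replicate (block) effect,
    ``beta_h`` the fixed effect of the proportion of plants harvested, and
    ``missing_rate`` the chance that a plot observation is lost.
    """

    n_cultivars: int = 67
    n_environments: int = 16
    n_replicates: int = 3
    plot_noise_sd: float = 4.0
    rep_effect_sd: float = 1.5
    beta_h: float = 8.0
    prop_harvested_range: tuple[float, float] = (0.7, 1.0)
    missing_rate: float = 0.02
    season_days: int = 300

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least two replicates")
        if self.plot_noise_sd < 0:
            raise ValueError("plot noise sd must be non-negative")


# ---------------------------------------------------------------------------
# Weather and soil
# ---------------------------------------------------------------------------


def gen_weather(
    archetype: EnvironmentArchetype,
    seed,
    start: _date = _date(2019, 1, 1),
    n_days: int = 730,
) -> WeatherSeries:
    """Synthetic daily weather for one location-year (seeded, deterministic).

    Temperatures follow a small annual harmonic (warm, dry early season)
    around the archetype means plus day-to-day noise.  Rainfall occurrence is
    a first-order wet/dry Markov chain whose marginal follows the archetype's
    monthly wet-season profile; wet-day amounts are exponential, and the
    whole series is rescaled so that the mean annual total matches a target
    drawn within a few percent of the archetype's annual rainfall (always
    within 15%).  Solar radiation and humidity co-vary with rain occurrence.
    """
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(float)
    month = dates.month.to_numpy() - 1

    harmonic = np.cos(2 * np.pi * (doy - 46) / 365.25)  # peaks mid-February
    tmax = archetype.tmax_mean + 1.5 * harmonic + rng.normal(0, 0.8, n_days)
    tmin = archetype.tmin_mean + 0.8 * harmonic + rng.normal(0, 0.6, n_days)
    tmin = np.minimum(tmin, tmax - 1.0)

    p_month = np.array(archetype.wet_season)[month]
    wet = np.zeros(n_days, dtype=bool)
    prev = False
    for t in range(n_days):
        p = p_month[t] + (0.2 if prev else -0.1)
        wet[t] = rng.random() < min(max(p, 0.01), 0.95)
        prev = wet[t]
    amounts = np.where(wet, rng.exponential(1.0, n_days), 0.0)

    # rescale so the first-year total hits a target near the archetype's
    target = archetype.annual_rain_mm * float(
        np.clip(rng.normal(1.0, 0.04), 0.9, 1.1)
    )
    year_sum = amounts[:365].sum()
    rain = amounts * (target / year_sum) if year_sum > 0 else amounts

    srad = (
        archetype.srad
        + 1.2 * harmonic
        - 2.0 * wet
        + rng.normal(0, 1.0, n_days)
    ).clip(4.0, 30.0)
    rh2m = (archetype.rh2m - 4.0 * harmonic + 4.0 * wet + rng.normal(0, 2.0, n_days)).clip(30, 100)
    wind = (archetype.wind + rng.normal(0, 0.3, n_days)).clip(0.1, None)

    return WeatherSeries(
        pd.DataFrame(
            {
                "date": dates,
                "tmin": np.round(tmin, 2),
                "tmax": np.round(tmax, 2),
                "srad": np.round(srad, 2),
                "rain": np.round(rain, 2),
                "rh2m": np.round(rh2m, 1),
                "wind": np.round(wind, 2),
            }
        )
    )


_SOIL_WATER = {
    # texture: (slll, sdul, ssat, ssks cm/h, sbdm, slcl, slsi)
    "SL": (0.08, 0.20, 0.41, 2.6, 1.45, 12.0, 25.0),
    "SCL": (0.15, 0.28, 0.43, 1.2, 1.40, 28.0, 20.0),
    "CL": (0.18, 0.32, 0.46, 0.6, 1.35, 34.0, 30.0),
}


def gen_soil(soil_class: str, seed=0) -> SoilProfile:
    """Four-layer profile (0-15-30-60-100 cm) typical of the texture class,
    with a small seeded jitter on the water limits."""
    if soil_class not in _SOIL_WATER:
        raise ValueError(f"unknown soil class {soil_class!r}")
    rng = np.random.default_rng(seed)
    slll, sdul, ssat, ssks, sbdm, slcl, slsi = _SOIL_WATER[soil_class]
    jitter = rng.normal(0, 0.005)
    bounds = [(0, 15), (15, 30), (30, 60), (60, 100)]
    srgf = [1.0, 0.8, 0.5, 0.25]
    sloc = [1.4, 0.9, 0.5, 0.3]
    rows = []
    for (top, bottom), rf, oc in zip(bounds, srgf, sloc):
        rows.append(
            {
                "depth_top": top,
                "depth_bottom": bottom,
                "slll": round(slll + jitter, 4),
                "sdul": round(sdul + jitter, 4),
                "ssat": round(ssat + jitter, 4),
                "srgf": rf,
                "ssks": ssks,
                "sbdm": sbdm,
                "sloc": oc,
                "slcl": slcl,
                "slsi": slsi,
                "slni": 0.08,
                "slhw": 5.8,
                "scec": 8.0,
            }
        )
    return SoilProfile(pd.DataFrame(rows))


def gen_environment(
    archetype: EnvironmentArchetype,
    seed,
    name: str | None = None,
    year: int = 2019,
    season_days: int = 300,
) -> Environment:
    """One location-year: weather, soil and management for the archetype."""
    weather = gen_weather(archetype, seed, start=_date(year, 1, 1), n_days=730)
    soil = gen_soil(archetype.soil_class, seed)
    planting = _date(year, archetype.planting_month, 15)
    mgmt = Management(planting_date=planting, duration_days=season_days)
    return Environment(
        name=name or f"{archetype.name}{year % 100:02d}",
        weather=weather,
        soil=soil,
        management=mgmt,
    )


def make_study_environments(
    n_environments: int = 16,
    seed=0,
    season_days: int = 300,
) -> dict[str, Environment]:
    """A set of location-year environments cycling over the archetypes."""
    seq = np.random.SeedSequence(seed).spawn(n_environments)
    names = list(ARCHETYPES)
    envs: dict[str, Environment] = {}
    for i, child in enumerate(seq):
        arch = ARCHETYPES[names[i % len(names)]]
        year = 2017 + (i // len(names))
        env = gen_environment(arch, child, year=year, season_days=season_days)
        envs[env.name] = env
    return envs


# ---------------------------------------------------------------------------
# Cultivars and trials
# ---------------------------------------------------------------------------


def gen_cultivars(n: int, seed, priors: PriorSpec | None = None) -> dict[str, CultivarParams]:
    """``n`` "true" cultivar parameter sets drawn uniformly within the prior
    ranges; these are the recovery ground truth for calibration tests."""
    if n < 1:
        raise ValueError("n must be at least 1")
    spec = priors or PriorSpec()
    rng = np.random.default_rng(seed)
    out: dict[str, CultivarParams] = {}
    for i in range(n):
        draws = {
            name: (rng.uniform(lo, hi) if hi > lo else lo)
            for name, (lo, hi) in spec.bounds.items()
        }
        out[f"CV{i + 1:03d}"] = CultivarParams(**draws)
    return out


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def gen_trials(
    cultivars: dict[str, CultivarParams],
    envs: dict[str, Environment],
    design: StudyDesign | None = None,
    seed=0,
    species: SpeciesConfig = DEFAULT_SPECIES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-level trial observations plus the per-cell simulator truth.

    Each cultivar x environment cell is simulated once (the truth); plot
    values add a replicate (block) effect, a harvested-proportion effect
    (``beta_h * (H - 1)``), plot noise and a per-plot dry-matter content
    drawn from a truncated Normal(0.35, 0.03) on (0.2, 0.5).  Missing plots
    are injected at the design's missing rate.  Returns ``(plots, truth)``.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    plot_rows = []
    truth_rows = []
    for env_name, env in envs.items():
        rep_effects = rng.normal(0, design.rep_effect_sd, design.n_replicates)
        for cult_name, params in cultivars.items():
            res = simulate(params, env.weather, env.soil, env.management, species)
            storage_dry = res.harvest_storage_t_ha
            above_dry = res.harvest_aboveground_t_ha
            truth_rows.append(
                {"cultivar": cult_name, "env": env_name,
                 "storage_dry": storage_dry, "aboveground_dry": above_dry}
            )
            for rep in range(design.n_replicates):
                h = rng.uniform(*design.prop_harvested_range)
                dmc = float(_truncated_normal(rng, 0.35, 0.03, 0.2, 0.5, 1)[0])
                fresh_root = (
                    storage_dry / dmc
                    + design.beta_h * (h - 1.0)
                    + rep_effects[rep]
                    + rng.normal(0, design.plot_noise_sd)
                )
                fresh_above = (
                    above_dry * 3.0
                    + design.beta_h * (h - 1.0)
                    + rep_effects[rep]
                    + rng.normal(0, design.plot_noise_sd)
                )
                missing = rng.random() < design.missing_rate
                plot_rows.append(
                    {
                        "environment": env_name,
                        "trial": env_name,
                        "replicate": rep + 1,
                        "cultivar": cult_name,
                        "fresh_root": np.nan if missing else max(0.0, fresh_root),
                        "fresh_aboveground": np.nan if missing else max(0.0, fresh_above),
                        "dmc": dmc,
                        "prop_harvested": h,
                    }
                )
    return pd.DataFrame(plot_rows), pd.DataFrame(truth_rows)


def gen_balanced_trial(
    var_g: float,
    var_r: float,
    var_e: float,
    beta_h: float = 0.0,
    n_rep: int = 3,
    n_gen: int = 60,
    mu: float = 20.0,
    seed=0,
    trial: str = "T1",
    trait: str = "fresh_root",
) -> pd.DataFrame:
    """A balanced single-trial table generated directly from the QC model
    ``y = mu + beta*H + R + G + e`` with known variance components."""
    rng = np.random.default_rng(seed)
    g_eff = rng.normal(0, np.sqrt(var_g), n_gen)
    r_eff = rng.normal(0, np.sqrt(var_r), n_rep)
    rows = []
    for i in range(n_gen):
        for j in range(n_rep):
            h = rng.uniform(0.6, 1.0)
            y = mu + beta_h * h + g_eff[i] + r_eff[j] + rng.normal(0, np.sqrt(var_e))
            rows.append(
                {
                    "environment": trial,
                    "trial": trial,
                    "replicate": j + 1,
                    "cultivar": f"CV{i + 1:03d}",
                    trait: y,
                    "prop_harvested": h,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Leaf scans and phenology
# ---------------------------------------------------------------------------


def gen_leaf_scans(
    cultivar_names,
    n_per: int = 30,
    noise_sd: float = 8.0,
    seed=0,
    intercept: float = 24.0,
    slope: float = 0.39,
) -> pd.DataFrame:
    """Leaf-scan table with areas generated from the allometric line
    ``area = intercept + slope * length * width * lobes`` plus Gaussian
    noise; thirty leaves per cultivar by default."""
    if n_per < 3:
        raise ValueError("need at least three scans per cultivar")
    rng = np.random.default_rng(seed)
    rows = []
    for cult in cultivar_names:
        for k in range(n_per):
            # round the recorded dimensions first so the stored area is an
            # exact function of the stored predictors when noise_sd == 0
            length = round(rng.uniform(10, 22), 2)
            width = round(rng.uniform(2.5, 5.5), 2)
            lobes = int(rng.choice([5, 7, 9]))
            x = length * width * lobes
            area = intercept + slope * x + rng.normal(0, noise_sd)
            rows.append(
                {
                    "cultivar": cult,
                    "plant": k // 3 + 1,
                    "position": ("top", "middle", "bottom")[k % 3],
                    "lobe_length": length,
                    "lobe_width": width,
                    "n_lobes": lobes,
                    "area_cm2": max(area, 1.0),
                }
            )
    return pd.DataFrame(rows)


def gen_phenology_obs(
    params: CultivarParams,
    env: Environment,
    seed=0,
    day_noise_sd: float = 1.0,
    lai_days: tuple[int, ...] = (60, 90, 120, 150, 180, 240),
    lai_noise_sd: float = 0.15,
    species: SpeciesConfig = DEFAULT_SPECIES,
) -> dict:
    """Fork dates, branch counts and an LAI series observed on one cultivar.

    Fork days come from inverting the cumulative thermal time at the true
    thermal-duration thresholds (only forks reached before harvest are
    observed); the LAI series samples the simulated trajectory at the given
    days after planting.  Gaussian observation noise is added to both.
    """
    rng = np.random.default_rng(seed)
    mgmt = env.management
    cum = env.weather.slice(mgmt.planting_date, mgmt.harvest_date).cumulative_thermal_time(species)
    fork_days: dict[int, float] = {}
    branch_counts: dict[int, float] = {}
    br = (params.br1fx, params.br2fx, params.br3fx, params.br4fx)
    for k, threshold in enumerate(params.fork_thresholds, start=1):
        idx = int(np.searchsorted(cum, threshold))
        if idx >= len(cum):
            break
        fork_days[k] = float(max(0, round(idx + rng.normal(0, day_noise_sd))))
        branch_counts[k] = br[k - 1]

    res = simulate(params, env.weather, env.soil, mgmt, species)
    lai = res.daily["lai"].to_numpy()
    days = [d for d in lai_days if d < len(lai)]
    lai_obs = pd.DataFrame(
        {
            "day": days,
            "lai": np.maximum(0.0, lai[days] + rng.normal(0, lai_noise_sd, len(days))),
        }
    )
    return {"env": env.name, "fork_days": fork_days,
            "branch_counts": branch_counts, "lai_obs": lai_obs}


# ---------------------------------------------------------------------------
# Deviation fixtures for AMMI recovery
# ---------------------------------------------------------------------------


def gen_deviation_fixture(
    g: int,
    e: int,
    ss_proportions: tuple[float, float, float] = (0.70, 0.02, 0.28),
    seed=0,
    total_ss: float | None = None,
    interaction_weights: tuple[float, ...] = (0.23, 0.16, 0.11),
    grand_mean: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Genotype x environment deviation matrix with prescribed SS shares.

    ``ss_proportions`` gives the (environment, genotype, interaction) shares
    of the total sum of squares about the grand mean; they must sum to 1.
    The environment and genotype effect vectors are drawn, centred and scaled
    to their exact SS targets; the interaction is a rank-3 structure (with
    within-interaction shares from ``interaction_weights``, remainder as
    unstructured noise), doubly centred and scaled, so the three components
    are mutually orthogonal and an AMMI fit recovers the shares.  Returns the
    matrix and a truth dictionary.
    """
    props = np.asarray(ss_proportions, float)
    if props.shape != (3,) or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("ss_proportions must be three non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    if total_ss is None:
        total_ss = 9.0 * g * e  # typical deviation scale of a few t/ha

    ss_env, ss_gen, ss_int = props * total_ss

    def scaled_centered(size, target_ss, mult):
        v = rng.normal(0, 1, size)
        v -= v.mean()
        norm = mult * np.sum(v**2)
        if target_ss == 0 or norm == 0:
            return np.zeros(size)
        return v * np.sqrt(target_ss / norm)

    env_eff = scaled_centered(e, ss_env, g)
    gen_eff = scaled_centered(g, ss_gen, e)

    # low-rank interaction plus unstructured noise, each piece scaled to its
    # within-interaction share, then doubly centred and scaled overall
    z = np.zeros((g, e))
    for w in interaction_weights:
        u = rng.normal(0, 1, g)
        v = rng.normal(0, 1, e)
        comp = np.outer(u - u.mean(), v - v.mean())
        css = np.sum(comp**2)
        if css > 0 and w > 0:
            z += comp * np.sqrt(w / css)
    noise_share = max(0.0, 1.0 - sum(interaction_weights))
    if noise_share > 0:
        noise = rng.normal(0, 1, (g, e))
        z += noise * np.sqrt(noise_share / np.sum(noise**2))
    z = z - z.mean(axis=0, keepdims=True) - z.mean(axis=1, keepdims=True) + z.mean()
    zss = np.sum(z**2)
    z = z * np.sqrt(ss_int / zss) if ss_int > 0 and zss > 0 else np.zeros((g, e))

    y = grand_mean + gen_eff[:, None] + env_eff[None, :] + z
    genotypes = [f"G{i + 1:03d}" for i in range(g)]
    environments = [f"E{j + 1:02d}" for j in range(e)]
    matrix = pd.DataFrame(y, index=genotypes, columns=environments)
    truth = {
        "ss_proportions": tuple(props),
        "total_ss": float(total_ss),
        "grand_mean": grand_mean,
        "env_effects": pd.Series(env_eff, index=environments),
        "gen_effects": pd.Series(gen_eff, index=genotypes),
        "interaction": pd.DataFrame(z, index=genotypes, columns=environments),
    }
    return matrix, truth
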