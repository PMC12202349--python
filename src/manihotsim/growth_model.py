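"""Simplified daily-time-step cassava growth simulator.

The model follows the architecture of radiation-use-efficiency crop models:
plant development is driven by accumulated thermal time with cardinal
temperatures, canopy light interception follows Beer's law, daily assimilate
is intercepted PAR times a conversion efficiency (PARUE), and biomass is
partitioned with a demand-first ("spill-over") strategy in which aboveground
organs and fibrous roots are satisfied first and the residual assimilate is
deposited in the storage roots.  A single-bucket soil water balance supplies
a stress factor that scales assimilation and leaf expansion.

The simulator is deliberately simplified: it is genotype-parameterised by the
fifteen cultivar and two ecotype coefficients used in cassava cropping-system
models (thermal durations between forkings, branches per fork, leaf size and
specific area, leaf longevity, petiole fraction, leaf-production slope, node
weight and length, PARUE and the canopy extinction coefficient KCAN), but it
does not attempt to reproduce any particular production model's internal
equations.  Nitrogen and phosphorus are assumed non-limiting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from datetime import date as _date
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesConfig",
    "CultivarParams",
    "WeatherSeries",
    "SoilProfile",
    "Management",
    "Environment",
    "WaterBucket",
    "SimResult",
    "thermal_time_increment",
    "phenology_stage",
    "shoot_count",
    "light_interception",
    "daily_assimilate",
    "aboveground_demand",
    "allocate_spillover",
    "water_stress_factor",
    "simulate",
    "PreparedEnvironment",
    "prepare_environment",
    "simulate_harvest",
]


# ---------------------------------------------------------------------------
# Species-level configuration
# ---------------------------------------------------------------------------


@dataclass
class SpeciesConfig:
    """Species-level constants shared by all cultivars.

    These play the role of species coefficients in cropping-system models:
    they are never touched by the cultivar calibration protocol.  Cardinal
    temperatures bound thermal-time accumulation; the remaining constants
    close the simplified demand, reserve and water-balance equations.

    Attributes
    ----------
    tbase, topt, tupper : float
        Cardinal temperatures (degC) for development: no development below
        ``tbase`` or above ``tupper``, maximal rate on the ``topt`` plateau.
    par_fraction : float
        Fraction of global solar radiation that is photosynthetically active.
    node_tt : float
        Thermal time (degCd) per node appearance per shoot at unit
        leaf-production slope.
    node_decay_tt : float
        E-folding thermal time (degCd) of the age decline in node appearance
        per shoot: the per-apex rate is multiplied by exp(-cum_tt/decay).
        Without this decline the multiplication of apices at successive
        forkings would make canopy demand grow without bound.
    branch_node_taper : float
        Multiplier on node weight per branch level: stems of higher-order
        branches are progressively thinner than the first stem (whose node
        weight is NODWT).
    branch_leaf_taper : float
        Multiplier on individual leaf area per branch level: leaves formed on
        higher-order branches are smaller than the LAXS maximum of the main
        stem.
    leaf_ramp_tt : float
        Thermal time (degCd) over which the area of newly formed leaves rises
        linearly from zero to the cultivar maximum LAXS.
    stem_maturity_tt : float
        Thermal time (degCd) at which node weight reaches the cultivar NODWT;
        before that the per-node stem demand scales linearly.
    fibrous_fraction : float
        Fibrous-root demand as a fraction of total aboveground demand.
    infiltration_cap_mm : float
        Maximum daily rainfall infiltration (mm); excess is lost to runoff.
    mm_per_mj_intercepted : float
        Potential crop water demand (mm) per MJ of intercepted solar
        radiation.
    cutting_reserve_g : float
        Carbohydrate reserve of the planted stem cutting (g dry matter per
        plant) available to satisfy early demand before the canopy closes.
    """

    tbase: float = 12.0
    topt: float = 30.0
    tupper: float = 42.0
    par_fraction: float = 0.5
    node_tt: float = 40.0
    node_decay_tt: float = 3000.0
    branch_node_taper: float = 0.8
    branch_leaf_taper: float = 0.7
    leaf_ramp_tt: float = 450.0
    stem_maturity_tt: float = 3400.0
    fibrous_fraction: float = 0.15
    infiltration_cap_mm: float = 50.0
    mm_per_mj_intercepted: float = 0.3
    cutting_reserve_g: float = 15.0

    def to_file(self, path: str | Path) -> None:
        """Write the configuration as a plain ``key = value`` text file."""
        lines = [f"{f.name} = {getattr(self, f.name)!r}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesConfig":
        kwargs = {}
        valid = {f.name for f in fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in valid:
                raise ValueError(f"unknown species config key: {key!r}")
            kwargs[key] = float(value.strip())
        return cls(**kwargs)


DEFAULT_SPECIES = SpeciesConfig()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_PARAM_NAMES = (
    "b01nd", "b12nd", "b23nd", "b34nd",
    "br1fx", "br2fx", "br3fx", "br4fx",
    "laxs", "slas", "llifa", "lpefr", "lnslp", "nodwt", "nodlt",
    "parue", "kcan",
)


@dataclass(frozen=True)
class CultivarParams:
    """Genotype-specific parameters of the growth model.

    Fifteen cultivar-level coefficients plus the two ecotype-level radiation
    coefficients (PARUE, KCAN) that the calibration protocol adjusts per
    cultivar.  Thermal durations are in degree-days (degCd), LAXS in cm2 per
    leaf, SLAS in cm2 g-1, NODWT in g, NODLT in cm, PARUE in g dry matter per
    MJ of PAR.
    """

    b01nd: float  # planting -> first forking (degCd)
    b12nd: float  # first -> second forking (degCd)
    b23nd: float  # second -> third forking (degCd)
    b34nd: float  # third -> fourth forking (degCd)
    br1fx: float  # branches per fork at fork 1..4 (population means,
    br2fx: float  # may be fractional)
    br3fx: float
    br4fx: float
    laxs: float   # maximum single-leaf area without stress (cm2)
    slas: float   # specific leaf lamina area (cm2 g-1)
    llifa: float  # leaf life from full expansion to senescence (degCd)
    lpefr: float  # petiole fraction of leaf (petiole mass / lamina mass ratio base)
    lnslp: float  # slope for leaf (node) production
    nodwt: float  # node weight of the first stem before branching (g)
    nodlt: float  # mean internode length when lignified (cm)
    parue: float  # PAR use efficiency (g DM MJ-1)
    kcan: float   # canopy PAR extinction coefficient

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and positive, got {value}")
        if not 0 < self.lpefr < 1:
            raise ValueError(f"lpefr must be in (0, 1), got {self.lpefr}")

    @classmethod
    def default(cls) -> "CultivarParams":
        """Default (uncalibrated) parameter set: the centre of the published
        per-parameter calibration ranges for elite West-African germplasm."""
        return cls(
            b01nd=487, b12nd=247, b23nd=235, b34nd=243,
            br1fx=2.5, br2fx=2.7, br3fx=2.1, br4fx=1.5,
            laxs=754, slas=252, llifa=1282, lpefr=0.3, lnslp=0.8,
            nodwt=3.3, nodlt=2.9, parue=1.8, kcan=0.6,
        )

    def replace(self, **changes: float) -> "CultivarParams":
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _PARAM_NAMES}

    @property
    def fork_thresholds(self) -> tuple[float, float, float, float]:
        """Cumulative thermal-time thresholds of forks 1..4 (degCd)."""
        t1 = self.b01nd
        t2 = t1 + self.b12nd
        t3 = t2 + self.b23nd
        t4 = t3 + self.b34nd
        return (t1, t2, t3, t4)


_WEATHER_COLUMNS = ["date", "tmin", "tmax", "srad", "rain", "rh2m", "wind"]


@dataclass
class WeatherSeries:
    """Daily weather for one environment.

    Wraps a DataFrame with columns ``date, tmin, tmax, srad, rain, rh2m,
    wind`` (degC, MJ m-2 d-1, mm, %, m s-1) covering a contiguous date range.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _WEATHER_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"weather table missing columns: {missing}")
        df = df.loc[:, _WEATHER_COLUMNS].copy()
        df["date"] = pd.to_datetime(df["date"]).dt.normalize()
        df = df.sort_values("date").reset_index(drop=True)
        if len(df) == 0:
            raise ValueError("weather table is empty")
        deltas = df["date"].diff().dropna()
        if len(deltas) and not (deltas == pd.Timedelta(days=1)).all():
            raise ValueError("weather dates must be contiguous daily values")
        if (df["tmin"] > df["tmax"]).any():
            raise ValueError("tmin exceeds tmax on some days")
        if (df["srad"] < 0).any() or (df["rain"] < 0).any():
            raise ValueError("srad and rain must be non-negative")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def start(self) -> _date:
        return self.data["date"].iloc[0].date()

    @property
    def end(self) -> _date:
        return self.data["date"].iloc[-1].date()

    def slice(self, start: _date, end: _date) -> "WeatherSeries":
        """Inclusive date-range subset; raises if not fully covered."""
        if start < self.start or end > self.end:
            raise ValueError(
                f"weather covers {self.start}..{self.end}, requested {start}..{end}"
            )
        mask = (self.data["date"] >= pd.Timestamp(start)) & (
            self.data["date"] <= pd.Timestamp(end)
        )
        return WeatherSeries(self.data.loc[mask].reset_index(drop=True))

    def cumulative_thermal_time(self, species: SpeciesConfig = DEFAULT_SPECIES) -> np.ndarray:
        """Cumulative thermal time (degCd) at the end of each day."""
        tmin = self.data["tmin"].to_numpy(float)
        tmax = self.data["tmax"].to_numpy(float)
        inc = np.array(
            [
                thermal_time_increment(lo, hi, species.tbase, species.topt, species.tupper)
                for lo, hi in zip(tmin, tmax)
            ]
        )
        return np.cumsum(inc)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "WeatherSeries":
        return cls(pd.read_csv(path))


_SOIL_COLUMNS = [
    "depth_top", "depth_bottom", "slll", "sdul", "ssat", "srgf",
    "ssks", "sbdm", "sloc", "slcl", "slsi", "slni", "slhw", "scec",
]


@dataclass
class SoilProfile:
    """Layered soil profile.

    One row per layer with depth bounds in cm and the standard profile
    descriptors: lower limit / drained upper limit / saturation of plant
    extractable water (cm3 cm-3), root growth factor, saturated conductivity,
    bulk density, organic carbon, clay, silt, total nitrogen, pH, CEC.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _SOIL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"soil table missing columns: {missing}")
        df = df.loc[:, _SOIL_COLUMNS].reset_index(drop=True)
        if len(df) == 0:
            raise ValueError("soil profile has no layers")
        if not (df["depth_top"].to_numpy() < df["depth_bottom"].to_numpy()).all():
            raise ValueError("each layer needs depth_top < depth_bottom")
        tops = df["depth_top"].to_numpy()
        if not (np.diff(tops) > 0).all():
            raise ValueError("layer depths must be strictly increasing")
        bad = ~(
            (0 < df["slll"]) & (df["slll"] < df["sdul"]) & (df["sdul"] < df["ssat"]) & (df["ssat"] < 1)
        )
        if bad.any():
            raise ValueError("require 0 < slll < sdul < ssat < 1 in every layer")
        if ((df["srgf"] < 0) | (df["srgf"] > 1)).any():
            raise ValueError("srgf must be in [0, 1]")
        self.data = df

    @property
    def plant_available_capacity_mm(self) -> float:
        """Root-weighted plant-available water capacity of the profile (mm).

        Sum over layers of (SDUL - SLLL) x thickness x SRGF, converted from
        cm of water to mm.
        """
        df = self.data
        thickness_cm = (df["depth_bottom"] - df["depth_top"]).to_numpy(float)
        frac = (df["sdul"] - df["slll"]).to_numpy(float)
        return float(np.sum(frac * thickness_cm * df["srgf"].to_numpy(float)) * 10.0)

    def topsoil(self) -> pd.Series:
        """The shallowest layer's descriptors (used as environment covariates)."""
        return self.data.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SoilProfile":
        return cls(pd.read_csv(path))


@dataclass
class Management:
    """Planting and harvest management for one trial.

    ``occupied_area`` is the ground area per plant (default 0.8 m2 from
    1 m x 0.8 m spacing); ``initial_water_fraction`` initialises the soil
    water bucket as a fraction of plant-available capacity.
    """

    planting_date: _date
    harvest_date: _date | None = None
    duration_days: int | None = None
    occupied_area: float = 0.8
    initial_water_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.occupied_area <= 0:
            raise ValueError("occupied_area must be positive")
        if self.harvest_date is None:
            if self.duration_days is None:
                raise ValueError("provide harvest_date or duration_days")
            self.harvest_date = self.planting_date + timedelta(days=int(self.duration_days))
        if self.harvest_date <= self.planting_date:
            raise ValueError("harvest must come after planting")
        self.duration_days = (self.harvest_date - self.planting_date).days


# ---------------------------------------------------------------------------
# Elementary process functions
# ---------------------------------------------------------------------------


def thermal_time_increment(
    tmin: float,
    tmax: float,
    tbase: float = DEFAULT_SPECIES.tbase,
    topt: float = DEFAULT_SPECIES.topt,
    tupper: float = DEFAULT_SPECIES.tupper,
) -> float:
    """Daily thermal-time increment (degCd) from a trapezoidal response.

    The daily mean temperature ``(tmin + tmax)/2`` accumulates linearly above
    ``tbase``, plateaus at ``topt`` (rate ``topt - tbase``) and declines
    linearly to zero at ``tupper``.
    """
    for v in (tmin, tmax, tbase, topt, tupper):
        if not math.isfinite(v):
            raise ValueError("thermal_time_increment requires finite inputs")
    if tmin > tmax:
        raise ValueError("tmin must not exceed tmax")
    tmean = 0.5 * (tmin + tmax)
    if tmean <= tbase or tmean >= tupper:
        return 0.0
    if tmean <= topt:
        return tmean - tbase
    return (topt - tbase) * (tupper - tmean) / (tupper - topt)


def phenology_stage(cum_tt: float, params: CultivarParams) -> int:
    """Branch (forking) level reached at cumulative thermal time ``cum_tt``.

    Level k is reached when ``cum_tt`` meets the k-th partial sum of the
    thermal durations B01ND..B34ND (boundary inclusive); capped at 4.
    """
    if cum_tt < 0:
        raise ValueError("cum_tt must be non-negative")
    level = 0
    for threshold in params.fork_thresholds:
        if cum_tt >= threshold:
            level += 1
        else:
            break
    return level


def shoot_count(level: int, params: CultivarParams) -> float:
    """Active apices per plant at branch level ``level``.

    The product of branches-per-fork over the forks already reached; kept
    fractional because the branch counts are population means.
    """
    factors = (params.br1fx, params.br2fx, params.br3fx, params.br4fx)
    count = 1.0
    for k in range(min(level, 4)):
        count *= factors[k]
    return count


def light_interception(lai: float, kcan: float) -> float:
    """Beer's-law fraction of radiation intercepted: ``1 - exp(-kcan*lai)``."""
    if lai < 0:
        raise ValueError("lai must be non-negative")
    if kcan <= 0:
        raise ValueError("kcan must be positive")
    return 1.0 - math.exp(-kcan * lai)


def daily_assimilate(srad: float, f_int: float, parue: float, stress: float,
                     par_fraction: float = DEFAULT_SPECIES.par_fraction) -> float:
    """Daily assimilate (g DM m-2): PARUE x PAR x interception x stress."""
    return parue * (par_fraction * srad) * f_int * stress


def aboveground_demand(
    new_nodes: float,
    params: CultivarParams,
    cum_tt: float,
    stress: float = 1.0,
    branch_level: int = 0,
    species: SpeciesConfig = DEFAULT_SPECIES,
) -> dict[str, float]:
    """Daily organ growth demands (g DM m-2) for ``new_nodes`` new nodes.

    Stem demand is node count times NODWT scaled linearly up to maturity at
    ``species.stem_maturity_tt`` and tapered per branch level (branch stems
    are thinner than the first stem); each new node carries one leaf whose
    area ramps linearly to LAXS over ``species.leaf_ramp_tt`` (reduced by
    water stress and by the per-level leaf taper), converted to mass through
    SLAS; petiole demand is ``LPEFR/(1-LPEFR)`` of leaf demand; fibrous-root
    demand is a fixed fraction of the total aboveground demand.
    """
    if new_nodes < 0:
        raise ValueError("new_nodes must be non-negative")
    maturity = min(1.0, cum_tt / species.stem_maturity_tt)
    stem = new_nodes * params.nodwt * maturity * species.branch_node_taper**branch_level
    per_leaf_area = (
        params.laxs
        * min(1.0, cum_tt / species.leaf_ramp_tt)
        * species.branch_leaf_taper**branch_level
        * stress
    )
    leaf = new_nodes * per_leaf_area / params.slas
    petiole = params.lpefr / (1.0 - params.lpefr) * leaf
    fibrous = species.fibrous_fraction * (leaf + petiole + stem)
    return {"leaf": leaf, "petiole": petiole, "stem": stem, "fibrous": fibrous}


def allocate_spillover(assimilate: float, demands: dict[str, float]) -> dict[str, float]:
    """Demand-first allocation with storage roots as the residual sink.

    If assimilate covers the summed demands every organ receives its demand
    and the surplus spills over to storage; otherwise demands are rationed
    proportionally and storage receives nothing.  The allocation sums exactly
    to the assimilate.
    """
    if assimilate < 0:
        raise ValueError("assimilate must be non-negative")
    total = sum(demands.values())
    if total <= assimilate:
        out = dict(demands)
        out["storage"] = assimilate - total
    else:
        scale = assimilate / total if total > 0 else 0.0
        out = {organ: d * scale for organ, d in demands.items()}
        out["storage"] = 0.0
    return out


@dataclass
class Environment:
    """A named (weather, soil, management) bundle: one location-year."""

    name: str
    weather: WeatherSeries
    soil: SoilProfile
    management: Management


@dataclass
class WaterBucket:
    """Single-bucket soil water balance over the rooted profile."""

    capacity_mm: float
    content_mm: float

    @classmethod
    def from_profile(cls, soil: SoilProfile, initial_fraction: float = 1.0) -> "WaterBucket":
        cap = soil.plant_available_capacity_mm
        return cls(capacity_mm=cap, content_mm=cap * initial_fraction)

    def add_rain(self, rain_mm: float, infiltration_cap_mm: float = DEFAULT_SPECIES.infiltration_cap_mm) -> None:
        self.content_mm = min(self.capacity_mm, self.content_mm + min(rain_mm, infiltration_cap_mm))

    def extract(self, demand_mm: float) -> float:
        """Remove up to ``demand_mm`` of water; returns the stress factor."""
        stress = water_stress_factor(self, demand_mm)
        self.content_mm -= min(demand_mm, self.content_mm)
        return stress


def water_stress_factor(bucket: WaterBucket, demand_mm: float) -> float:
    """Supply/demand ratio capped at 1; 1 when there is no demand."""
    if demand_mm <= 0:
        return 1.0
    supply = max(0.0, bucket.content_mm)
    return 1.0 if supply >= demand_mm else supply / demand_mm


# ---------------------------------------------------------------------------
# The daily season loop
# ---------------------------------------------------------------------------


def _run_season(
    tmin, tmax, srad, rain,
    b01, b12, b23, b34, br1, br2, br3, br4,
    laxs, slas, llifa, lpefr, lnslp, nodwt, nodlt, parue, kcan,
    tbase, topt, tupper, par_fraction, node_tt, node_decay_tt,
    node_taper, leaf_taper, leaf_ramp_tt,
    stem_maturity_tt, fibrous_frac, infil_cap, mm_per_mj,
    capacity, init_water, occupied_area, reserve0,
):  # pragma: no cover - exercised through simulate()
    n = tmin.shape[0]
    cum_tt_a = np.zeros(n)
    level_a = np.zeros(n)
    nodes_a = np.zeros(n)
    lai_a = np.zeros(n)
    fint_a = np.zeros(n)
    stress_a = np.zeros(n)
    assim_a = np.zeros(n)
    supply_a = np.zeros(n)
    leaf_a = np.zeros(n)
    pet_a = np.zeros(n)
    stem_a = np.zeros(n)
    fib_a = np.zeros(n)
    stor_a = np.zeros(n)
    sen_a = np.zeros(n)

    cohort_tt = np.zeros(n)
    cohort_area = np.zeros(n)
    cohort_leaf = np.zeros(n)
    cohort_pet = np.zeros(n)

    th1 = b01
    th2 = th1 + b12
    th3 = th2 + b23
    th4 = th3 + b34
    pet_ratio = lpefr / (1.0 - lpefr)

    cum_tt = 0.0
    lai = 0.0
    leaf = 0.0
    pet = 0.0
    stem = 0.0
    fib = 0.0
    stor = 0.0
    sen = 0.0
    nodes = 0.0
    reserve = reserve0
    water = capacity * init_water
    j = 0

    for t in range(n):
        tmean = 0.5 * (tmin[t] + tmax[t])
        if tmean <= tbase or tmean >= tupper:
            dtt = 0.0
        elif tmean <= topt:
            dtt = tmean - tbase
        else:
            dtt = (topt - tbase) * (tupper - tmean) / (tupper - topt)
        cum_tt += dtt

        if cum_tt >= th4:
            level = 4.0
            shoots = br1 * br2 * br3 * br4
            t_node = node_taper * node_taper * node_taper * node_taper
            t_leaf = leaf_taper * leaf_taper * leaf_taper * leaf_taper
        elif cum_tt >= th3:
            level = 3.0
            shoots = br1 * br2 * br3
            t_node = node_taper * node_taper * node_taper
            t_leaf = leaf_taper * leaf_taper * leaf_taper
        elif cum_tt >= th2:
            level = 2.0
            shoots = br1 * br2
            t_node = node_taper * node_taper
            t_leaf = leaf_taper * leaf_taper
        elif cum_tt >= th1:
            level = 1.0
            shoots = br1
            t_node = node_taper
            t_leaf = leaf_taper
        else:
            level = 0.0
            shoots = 1.0
            t_node = 1.0
            t_leaf = 1.0

        fint = 1.0 - math.exp(-kcan * lai)

        water = water + rain[t] if rain[t] < infil_cap else water + infil_cap
        if water > capacity:
            water = capacity
        demand_mm = mm_per_mj * fint * srad[t]
        if demand_mm <= 0.0:
            stress = 1.0
        elif water >= demand_mm:
            stress = 1.0
            water -= demand_mm
        else:
            stress = water / demand_mm
            water = 0.0

        assim = parue * par_fraction * srad[t] * fint * stress

        age_factor = math.exp(-cum_tt / node_decay_tt)
        new_nodes = shoots * (dtt / node_tt) * lnslp * age_factor / occupied_area
        ramp = cum_tt / leaf_ramp_tt
        if ramp > 1.0:
            ramp = 1.0
        per_leaf_area = laxs * ramp * t_leaf * stress
        leaf_d = new_nodes * per_leaf_area / slas
        pet_d = pet_ratio * leaf_d
        maturity = cum_tt / stem_maturity_tt
        if maturity > 1.0:
            maturity = 1.0
        stem_d = new_nodes * nodwt * maturity * t_node
        ag = leaf_d + pet_d + stem_d
        fib_d = fibrous_frac * ag
        total_d = ag + fib_d

        shortfall = total_d - assim
        if shortfall > 0.0:
            res_used = reserve if reserve < shortfall else shortfall
        else:
            res_used = 0.0
        reserve -= res_used
        supply = assim + res_used

        if total_d <= 0.0:
            la = 0.0
            lp = 0.0
            ls = 0.0
            lf = 0.0
            storage_inc = supply
        elif supply >= total_d:
            la = leaf_d
            lp = pet_d
            ls = stem_d
            lf = fib_d
            storage_inc = supply - total_d
        else:
            scale = supply / total_d
            la = leaf_d * scale
            lp = pet_d * scale
            ls = stem_d * scale
            lf = fib_d * scale
            storage_inc = 0.0

        leaf += la
        pet += lp
        stem += ls
        fib += lf
        stor += storage_inc
        nodes += new_nodes

        area_real = la * slas  # realised lamina area, cm2 m-2
        cohort_tt[t] = cum_tt
        cohort_area[t] = area_real
        cohort_leaf[t] = la
        cohort_pet[t] = lp
        lai += area_real * 1e-4

        while j <= t and cum_tt - cohort_tt[j] >= llifa:
            lai -= cohort_area[j] * 1e-4
            leaf -= cohort_leaf[j]
            pet -= cohort_pet[j]
            sen += cohort_leaf[j] + cohort_pet[j]
            j += 1
        if lai < 0.0:
            lai = 0.0

        cum_tt_a[t] = cum_tt
        level_a[t] = level
        nodes_a[t] = nodes
        lai_a[t] = lai
        fint_a[t] = fint
        stress_a[t] = stress
        assim_a[t] = assim
        supply_a[t] = supply
        leaf_a[t] = leaf
        pet_a[t] = pet
        stem_a[t] = stem
        fib_a[t] = fib
        stor_a[t] = stor
        sen_a[t] = sen

    return (
        cum_tt_a, level_a, nodes_a, lai_a, fint_a, stress_a, assim_a,
        supply_a, leaf_a, pet_a, stem_a, fib_a, stor_a, sen_a,
    )


try:  # JIT-compile the season loop when numba is available
    from numba import njit as _njit

    _run_season_jit = _njit(cache=False)(_run_season)
except Exception:  # pragma: no cover
    _run_season_jit = _run_season


@dataclass(frozen=True)
class PreparedEnvironment:
    """Weather arrays and scalars of one environment, ready for the season
    loop — avoids re-slicing and re-validating inside Monte-Carlo loops."""

    weather_arrays: tuple  # (tmin, tmax, srad, rain) as float64 arrays
    capacity_mm: float
    initial_water_fraction: float
    occupied_area: float


def prepare_environment(
    env: Environment, species: SpeciesConfig = DEFAULT_SPECIES
) -> PreparedEnvironment:
    """Extract the season's weather arrays and soil/management scalars."""
    mgmt = env.management
    d = env.weather.slice(mgmt.planting_date, mgmt.harvest_date).data
    arrays = (
        np.ascontiguousarray(d["tmin"].to_numpy(float)),
        np.ascontiguousarray(d["tmax"].to_numpy(float)),
        np.ascontiguousarray(d["srad"].to_numpy(float)),
        np.ascontiguousarray(d["rain"].to_numpy(float)),
    )
    return PreparedEnvironment(
        weather_arrays=arrays,
        capacity_mm=env.soil.plant_available_capacity_mm,
        initial_water_fraction=mgmt.initial_water_fraction,
        occupied_area=mgmt.occupied_area,
    )


def _param_args(params: CultivarParams, species: SpeciesConfig,
                prepared: PreparedEnvironment) -> tuple:
    return (
        params.b01nd, params.b12nd, params.b23nd, params.b34nd,
        params.br1fx, params.br2fx, params.br3fx, params.br4fx,
        params.laxs, params.slas, params.llifa, params.lpefr,
        params.lnslp, params.nodwt, params.nodlt, params.parue, params.kcan,
        species.tbase, species.topt, species.tupper, species.par_fraction,
        species.node_tt, species.node_decay_tt, species.branch_node_taper,
        species.branch_leaf_taper, species.leaf_ramp_tt,
        species.stem_maturity_tt, species.fibrous_fraction,
        species.infiltration_cap_mm, species.mm_per_mj_intercepted,
        prepared.capacity_mm, prepared.initial_water_fraction,
        prepared.occupied_area,
        species.cutting_reserve_g / prepared.occupied_area,
    )


def simulate_harvest(
    params: CultivarParams,
    prepared: PreparedEnvironment,
    species: SpeciesConfig = DEFAULT_SPECIES,
) -> tuple[float, float]:
    """Harvest outputs only — (storage, aboveground) dry weight in t ha-1.

    The fast path for calibration loops: skips the daily DataFrame.
    """
    out = _run_season_jit(*prepared.weather_arrays, *_param_args(params, species, prepared))
    leaf, pet, stem = out[8], out[9], out[10]
    stor = out[12]
    return float(stor[-1] * 0.01), float((leaf[-1] + pet[-1] + stem[-1]) * 0.01)


@dataclass
class SimResult:
    """Daily trajectory and harvest outputs of one simulation."""

    daily: pd.DataFrame
    harvest_storage_t_ha: float
    harvest_aboveground_t_ha: float
    params: CultivarParams
    management: Management

    def mass_balance_error(self) -> float:
        """Largest daily relative discrepancy between cumulative carbon
        supply (assimilate plus cutting reserve drawn) and the sum of live
        pools and senesced mass."""
        d = self.daily
        pools = d[["leaf", "petiole", "stem", "fibrous", "storage"]].sum(axis=1)
        supplied = d["supply"].cumsum()
        denom = np.maximum(supplied.to_numpy(), 1.0)
        return float(np.max(np.abs(supplied - pools - d["senesced"]) / denom))


def simulate(
    params: CultivarParams,
    weather: WeatherSeries,
    soil: SoilProfile,
    mgmt: Management,
    species: SpeciesConfig = DEFAULT_SPECIES,
) -> SimResult:
    """Run the daily growth loop from planting to harvest.

    Deterministic for fixed inputs.  Each day: thermal time accumulates and
    sets the branch level and shoot count; the canopy intercepts light from
    the previous day's LAI; the water bucket supplies a stress factor;
    intercepted PAR is converted to assimilate; new nodes generate organ
    demands which are satisfied demand-first with the surplus spilling to
    storage roots; leaf cohorts senesce LLIFA degCd after expansion.

    Raises
    ------
    ValueError
        If the weather series does not cover planting to harvest.
    """
    prepared = prepare_environment(
        Environment("", weather, soil, mgmt), species
    )
    (cum_tt, level, nodes, lai, fint, stress, assim, supply,
     leaf, pet, stem, fib, stor, sen) = _run_season_jit(
        *prepared.weather_arrays, *_param_args(params, species, prepared)
    )
    d = weather.slice(mgmt.planting_date, mgmt.harvest_date).data

    daily = pd.DataFrame(
        {
            "date": d["date"].to_numpy(),
            "cum_tt": cum_tt,
            "branch_level": level.astype(int),
            "nodes": nodes,
            "lai": lai,
            "fint": fint,
            "stress": stress,
            "assimilate": assim,
            "supply": supply,
            "leaf": leaf,
            "petiole": pet,
            "stem": stem,
            "fibrous": fib,
            "storage": stor,
            "senesced": sen,
        }
    )
    # g m-2 -> t ha-1 is a factor 0.01
    storage_t_ha = float(stor[-1] * 0.01)
    above_t_ha = float((leaf[-1] + pet[-1] + stem[-1]) * 0.01)
    return SimResult(
        daily=daily,
        harvest_storage_t_ha=storage_t_ha,
        harvest_aboveground_t_ha=above_t_ha,
        params=params,
        management=mgmt,
    )
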