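"""Growth-model unit tests: elementary process functions, domain-type
validation, and whole-season invariants with independent replay oracles."""

from __future__ import annotations

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest

from manihotsim import (
    CultivarParams,
    Management,
    SoilProfile,
    SpeciesConfig,
    WaterBucket,
    WeatherSeries,
    aboveground_demand,
    allocate_spillover,
    daily_assimilate,
    light_interception,
    phenology_stage,
    shoot_count,
    simulate,
    thermal_time_increment,
    water_stress_factor,
)
from manihotsim.growth_model import DEFAULT_SPECIES

from .conftest import make_flat_weather


# ---------------------------------------------------------------------------
# thermal time
# ---------------------------------------------------------------------------


class TestThermalTime:
    def test_linear_phase(self):
        assert thermal_time_increment(20, 30, tbase=12, topt=30) == pytest.approx(13.0)

    def test_below_base(self):
        assert thermal_time_increment(5, 11, tbase=12) == 0.0

    def test_plateau_boundary(self):
        # tmean == topt gives the maximum rate topt - tbase
        assert thermal_time_increment(28, 32, tbase=12, topt=30) == pytest.approx(18.0)

    def test_declining_phase(self):
        # tmean 32 between topt 30 and tupper 42: 18 * 10/12
        assert thermal_time_increment(30, 34, 12, 30, 42) == pytest.approx(15.0)

    def test_above_upper(self):
        assert thermal_time_increment(42, 46, 12, 30, 42) == 0.0

    def test_tmin_above_tmax_rejected(self):
        with pytest.raises(ValueError):
            thermal_time_increment(25, 20)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            thermal_time_increment(float("nan"), 30)


# ---------------------------------------------------------------------------
# phenology and shoots
# ---------------------------------------------------------------------------


class TestPhenology:
    def test_zero(self):
        assert phenology_stage(0.0, CultivarParams.default()) == 0

    def test_first_fork_at_default_duration(self):
        params = CultivarParams.default()  # b01nd = 487
        assert phenology_stage(500.0, params) == 1
        assert phenology_stage(486.9, params) == 0

    def test_boundary_inclusive_second_fork(self):
        params = CultivarParams.default().replace(b01nd=231, b12nd=247)
        assert phenology_stage(478.0, params) == 2
        assert phenology_stage(477.9, params) == 1

    def test_capped_at_four(self):
        assert phenology_stage(1e9, CultivarParams.default()) == 4

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            phenology_stage(-1.0, CultivarParams.default())

    def test_fork_thresholds_are_partial_sums(self):
        p = CultivarParams.default()
        t1, t2, t3, t4 = p.fork_thresholds
        assert t1 == p.b01nd
        assert t2 == pytest.approx(p.b01nd + p.b12nd)
        assert t4 == pytest.approx(p.b01nd + p.b12nd + p.b23nd + p.b34nd)

    def test_shoot_count_products(self):
        p = CultivarParams.default().replace(br1fx=2.5, br2fx=3.0)
        assert shoot_count(0, p) == 1.0
        assert shoot_count(1, p) == pytest.approx(2.5)
        assert shoot_count(2, p) == pytest.approx(7.5)


# ---------------------------------------------------------------------------
# interception, assimilation, demand, allocation
# ---------------------------------------------------------------------------


class TestInterception:
    def test_bare_ground(self):
        assert light_interception(0.0, 0.6) == 0.0

    def test_hand_value(self):
        assert light_interception(3.0, 0.6) == pytest.approx(0.83470, abs=5e-6)

    def test_asymptote(self):
        assert light_interception(200.0, 0.6) == pytest.approx(1.0)

    def test_strictly_increasing(self):
        lo = light_interception(1.0, 0.6)
        assert light_interception(2.0, 0.6) > lo
        assert light_interception(1.0, 0.7) > lo

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            light_interception(-0.1, 0.6)
        with pytest.raises(ValueError):
            light_interception(1.0, 0.0)


class TestAssimilate:
    def test_hand_value(self):
        assert daily_assimilate(16, 0.8, 1.8, 1.0) == pytest.approx(11.52)

    def test_zero_stress(self):
        assert daily_assimilate(16, 0.8, 1.8, 0.0) == 0.0

    def test_max_parue(self):
        assert daily_assimilate(16, 1.0, 2.6, 1.0) == pytest.approx(20.8)

    def test_linear_in_radiation(self):
        assert daily_assimilate(32, 0.8, 1.8, 1.0) == pytest.approx(
            2 * daily_assimilate(16, 0.8, 1.8, 1.0)
        )


class TestDemand:
    def test_zero_nodes(self):
        out = aboveground_demand(0.0, CultivarParams.default(), cum_tt=1000)
        assert all(v == 0.0 for v in out.values())

    def test_stem_demand_at_maturity(self):
        p = CultivarParams.default().replace(nodwt=3.3)
        out = aboveground_demand(2.0, p, cum_tt=DEFAULT_SPECIES.stem_maturity_tt)
        assert out["stem"] == pytest.approx(6.6)

    def test_petiole_ratio(self):
        p = CultivarParams.default().replace(lpefr=0.3)
        out = aboveground_demand(3.0, p, cum_tt=2000)
        assert out["petiole"] == pytest.approx(0.3 / 0.7 * out["leaf"])
        # 10 g of leaf demand implies 4.286 g of petiole demand
        assert 0.3 / 0.7 * 10.0 == pytest.approx(4.286, abs=5e-4)

    def test_fibrous_fraction(self):
        out = aboveground_demand(2.0, CultivarParams.default(), cum_tt=2000)
        ag = out["leaf"] + out["petiole"] + out["stem"]
        assert out["fibrous"] == pytest.approx(DEFAULT_SPECIES.fibrous_fraction * ag)

    def test_all_non_negative_and_negative_nodes_rejected(self):
        out = aboveground_demand(1.5, CultivarParams.default(), cum_tt=300, stress=0.4)
        assert all(v >= 0 for v in out.values())
        with pytest.raises(ValueError):
            aboveground_demand(-1.0, CultivarParams.default(), cum_tt=300)


class TestAllocation:
    DEMANDS = {"leaf": 3.0, "petiole": 1.0, "stem": 2.0, "fibrous": 1.0}

    def test_surplus_to_storage(self):
        out = allocate_spillover(10.0, self.DEMANDS)
        assert out["storage"] == pytest.approx(3.0)
        for organ, d in self.DEMANDS.items():
            assert out[organ] == pytest.approx(d)

    def test_proportional_rationing(self):
        out = allocate_spillover(5.0, self.DEMANDS)
        assert out["storage"] == 0.0
        for organ, d in self.DEMANDS.items():
            assert out[organ] == pytest.approx(d * 5.0 / 7.0)

    def test_zero_assimilate(self):
        out = allocate_spillover(0.0, self.DEMANDS)
        assert all(v == 0.0 for v in out.values())

    def test_allocation_sums_to_assimilate(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            demands = {k: float(v) for k, v in zip("abcd", rng.uniform(0, 5, 4))}
            assim = float(rng.uniform(0, 20))
            out = allocate_spillover(assim, demands)
            assert sum(out.values()) == pytest.approx(assim, abs=1e-12)

    def test_negative_assimilate_rejected(self):
        with pytest.raises(ValueError):
            allocate_spillover(-1.0, self.DEMANDS)


class TestWaterBucket:
    def test_no_stress_when_supplied(self, simple_soil):
        bucket = WaterBucket.from_profile(simple_soil)
        assert water_stress_factor(bucket, bucket.content_mm / 2) == 1.0

    def test_empty_bucket(self, simple_soil):
        bucket = WaterBucket(capacity_mm=50, content_mm=0.0)
        assert water_stress_factor(bucket, 3.0) == 0.0

    def test_ratio_rule(self):
        bucket = WaterBucket(capacity_mm=50, content_mm=2.0)
        assert water_stress_factor(bucket, 4.0) == pytest.approx(0.5)

    def test_capacity_formula(self, simple_soil):
        df = simple_soil.data
        expected = float(
            np.sum(
                (df["sdul"] - df["slll"])
                * (df["depth_bottom"] - df["depth_top"])
                * df["srgf"]
            )
            * 10.0
        )
        assert simple_soil.plant_available_capacity_mm == pytest.approx(expected)

    def test_rain_capped_by_infiltration_and_capacity(self):
        bucket = WaterBucket(capacity_mm=100, content_mm=10.0)
        bucket.add_rain(500.0, infiltration_cap_mm=50.0)
        assert bucket.content_mm == pytest.approx(60.0)
        bucket.add_rain(50.0, infiltration_cap_mm=50.0)
        assert bucket.content_mm == pytest.approx(100.0)

    def test_extract_depletes(self):
        bucket = WaterBucket(capacity_mm=100, content_mm=5.0)
        stress = bucket.extract(10.0)
        assert stress == pytest.approx(0.5)
        assert bucket.content_mm == 0.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class TestDomainTypes:
    def test_params_validation(self):
        with pytest.raises(ValueError):
            CultivarParams.default().replace(nodwt=-1.0)
        with pytest.raises(ValueError):
            CultivarParams.default().replace(lpefr=1.2)

    def test_weather_validation(self):
        df = make_flat_weather(10).data.copy()
        df.loc[3, "tmin"] = 40.0
        with pytest.raises(ValueError):
            WeatherSeries(df)
        gap = make_flat_weather(10).data.drop(index=4)
        with pytest.raises(ValueError):
            WeatherSeries(gap)

    def test_weather_csv_round_trip(self, tmp_path, flat_weather):
        path = tmp_path / "w.csv"
        flat_weather.to_csv(path)
        again = WeatherSeries.from_csv(path)
        pd.testing.assert_frame_equal(flat_weather.data, again.data)

    def test_soil_validation(self, simple_soil):
        bad = simple_soil.data.copy()
        bad.loc[0, "slll"] = 0.5  # above sdul
        with pytest.raises(ValueError):
            SoilProfile(bad)

    def test_soil_csv_round_trip(self, tmp_path, simple_soil):
        path = tmp_path / "s.csv"
        simple_soil.to_csv(path)
        pd.testing.assert_frame_equal(simple_soil.data, SoilProfile.from_csv(path).data)

    def test_management_validation(self):
        with pytest.raises(ValueError):
            Management(planting_date=date(2019, 1, 1), harvest_date=date(2018, 12, 1))
        with pytest.raises(ValueError):
            Management(planting_date=date(2019, 1, 1))
        mgmt = Management(planting_date=date(2019, 1, 1), duration_days=300)
        assert mgmt.harvest_date == date(2019, 10, 28)

    def test_species_config_file_round_trip(self, tmp_path):
        species = SpeciesConfig(tbase=13.0, fibrous_fraction=0.2)
        path = tmp_path / "species.cfg"
        species.to_file(path)
        assert SpeciesConfig.from_file(path) == species
        path.write_text("bogus_key = 1\n")
        with pytest.raises(ValueError):
            SpeciesConfig.from_file(path)


# ---------------------------------------------------------------------------
# whole-season behavior
# ---------------------------------------------------------------------------


def run_flat(params=None, srad=16.0, rain=6.0, duration=300, soil=None):
    weather = make_flat_weather(srad=srad, rain=rain)
    from manihotsim import synthetic_data as syn

    soil = soil or syn.gen_soil("SCL", seed=0)
    mgmt = Management(planting_date=date(2019, 1, 15), duration_days=duration)
    return simulate(params or CultivarParams.default(), weather, soil, mgmt)


class TestSimulate:
    def test_zero_radiation_no_yield(self):
        res = run_flat(srad=0.0)
        # only the cutting reserve can be spent; nothing reaches storage
        assert res.harvest_storage_t_ha == 0.0

    def test_mass_balance_flat(self):
        assert run_flat().mass_balance_error() < 1e-6

    def test_mass_balance_realistic(self, study_envs):
        params = CultivarParams.default()
        for env in study_envs.values():
            res = simulate(params, env.weather, env.soil, env.management)
            assert res.mass_balance_error() < 1e-6

    def test_parue_monotonicity_without_water_stress(self):
        yields = [
            run_flat(CultivarParams.default().replace(parue=v), rain=30.0).harvest_storage_t_ha
            for v in (1.4, 1.8, 2.2, 2.6)
        ]
        assert all(b > a for a, b in zip(yields, yields[1:]))

    def test_season_length_monotonicity_without_water_stress(self):
        short = run_flat(rain=30.0, duration=240).harvest_storage_t_ha
        long = run_flat(rain=30.0, duration=330).harvest_storage_t_ha
        assert long >= short

    def test_bit_identical_reruns(self, study_envs):
        env = next(iter(study_envs.values()))
        a = simulate(CultivarParams.default(), env.weather, env.soil, env.management)
        b = simulate(CultivarParams.default(), env.weather, env.soil, env.management)
        pd.testing.assert_frame_equal(a.daily, b.daily)
        assert a.harvest_storage_t_ha == b.harvest_storage_t_ha
        assert a.harvest_aboveground_t_ha == b.harvest_aboveground_t_ha

    def test_branch_level_non_decreasing_and_matches_stage(self):
        res = run_flat()
        levels = res.daily["branch_level"].to_numpy()
        assert (np.diff(levels) >= 0).all()
        recomputed = [
            phenology_stage(t, res.params) for t in res.daily["cum_tt"]
        ]
        assert (levels == np.array(recomputed)).all()

    def test_interception_equivalence(self):
        res = run_flat()
        lai_prev = np.concatenate([[0.0], res.daily["lai"].to_numpy()[:-1]])
        expected = 1.0 - np.exp(-res.params.kcan * lai_prev)
        np.testing.assert_allclose(res.daily["fint"].to_numpy(), expected, rtol=1e-12)

    def test_pools_non_negative(self, study_envs):
        env = next(iter(study_envs.values()))
        res = simulate(CultivarParams.default(), env.weather, env.soil, env.management)
        for col in ("leaf", "petiole", "stem", "fibrous", "storage", "lai", "senesced"):
            assert (res.daily[col].to_numpy() >= -1e-12).all(), col

    def test_weather_gap_rejected(self, simple_soil):
        weather = make_flat_weather(100)
        mgmt = Management(planting_date=date(2019, 1, 15), duration_days=300)
        with pytest.raises(ValueError):
            simulate(CultivarParams.default(), weather, simple_soil, mgmt)


class TestReplayOracle:
    """Replay the daily recurrence with the public process functions and
    compare against the season kernel, day by day, for the first 10 days."""

    def test_ten_day_replay(self, simple_soil):
        params = CultivarParams.default()
        species = DEFAULT_SPECIES
        weather = make_flat_weather()
        mgmt = Management(planting_date=date(2019, 1, 15), duration_days=300)
        res = simulate(params, weather, simple_soil, mgmt)
        w = weather.slice(mgmt.planting_date, mgmt.harvest_date).data

        bucket = WaterBucket.from_profile(simple_soil, mgmt.initial_water_fraction)
        cum_tt = 0.0
        lai = 0.0
        pools = {"leaf": 0.0, "petiole": 0.0, "stem": 0.0, "fibrous": 0.0, "storage": 0.0}
        reserve = species.cutting_reserve_g / mgmt.occupied_area

        for t in range(10):
            day = w.iloc[t]
            cum_tt += thermal_time_increment(
                day["tmin"], day["tmax"], species.tbase, species.topt, species.tupper
            )
            level = phenology_stage(cum_tt, params)
            shoots = shoot_count(level, params)
            fint = light_interception(lai, params.kcan)
            bucket.add_rain(day["rain"], species.infiltration_cap_mm)
            stress = bucket.extract(species.mm_per_mj_intercepted * fint * day["srad"])
            assim = daily_assimilate(day["srad"], fint, params.parue, stress,
                                     species.par_fraction)
            new_nodes = (
                shoots
                * (thermal_time_increment(day["tmin"], day["tmax"], species.tbase,
                                          species.topt, species.tupper) / species.node_tt)
                * params.lnslp
                * math.exp(-cum_tt / species.node_decay_tt)
                / mgmt.occupied_area
            )
            demands = aboveground_demand(new_nodes, params, cum_tt, stress, level, species)
            total = sum(demands.values())
            used = min(reserve, max(0.0, total - assim))
            reserve -= used
            alloc = allocate_spillover(assim + used, demands)
            for organ in pools:
                pools[organ] += alloc[organ]
            lai += alloc["leaf"] * params.slas * 1e-4  # no senescence in 10 days

            row = res.daily.iloc[t]
            assert row["cum_tt"] == pytest.approx(cum_tt, rel=1e-12)
            assert row["branch_level"] == level
            assert row["fint"] == pytest.approx(fint, rel=1e-12)
            assert row["stress"] == pytest.approx(stress, rel=1e-12)
            assert row["assimilate"] == pytest.approx(assim, rel=1e-12)
            for organ in pools:
                assert row[organ] == pytest.approx(pools[organ], rel=1e-10, abs=1e-12), organ
            assert row["lai"] == pytest.approx(lai, rel=1e-10, abs=1e-14)
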