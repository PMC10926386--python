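"""Population initialization, development, mating, oviposition, and
whole-season behavior."""

import numpy as np
import pandas as pd
import pytest

from egisim.genetics import GeneticsConfig, GenotypeClass, parse_genotype
from egisim.interventions import ReleaseStrategy, build_schedule
from egisim.lifecycle import (ADULT, EGG, Agent, LifecycleParams,
                              TemperatureSeries, develop,
                              initialize_population, mate, oviposit,
                              run_season, step)
from egisim.synthetic import (TemperatureModelParams,
                              generate_temperature_series,
                              make_fixture_population)


def constant_temps(t=25.0, days=245):
    from egisim.lifecycle import SEASON_START
    return TemperatureSeries(SEASON_START, np.full(days, float(t)))


class TestInitialize:
    def test_pure_wildtype(self, rng):
        params = LifecycleParams(initial_adults=500)
        state = initialize_population(params, {"wildtype": 1.0}, rng)
        assert state.n == 500
        assert (state.stage == ADULT).all()
        n_female = int((~state.is_male()).sum())
        assert 200 < n_female < 300  # binomial around 250

    def test_overwinter_composition(self, rng):
        params = LifecycleParams(initial_adults=1000)
        state = initialize_population(
            params, {"dualEGI": 0.95, "wildtype": 0.05}, rng)
        reg = state.registry
        dual = sum(reg.genotypes[g].display[:12] == "BBDDPPTTllWW"
                   for g in state.gid)
        assert dual == 950

    def test_bad_fractions_rejected(self, rng):
        with pytest.raises(ValueError):
            initialize_population(LifecycleParams(), {"wildtype": 0.7}, rng)


class TestDevelop:
    def test_no_degree_days_at_base_temperature(self, rng):
        params = LifecycleParams()
        agent = Agent(0, parse_genotype("bbddppttllWWXX"), "female",
                      stage=EGG)
        out = None
        while out is None:
            out = develop(agent, params.base_temp, params, rng)
        assert out.stage == EGG and out.degree_days_accrued == 0.0

    def test_median_development_time_near_thermal_expectation(self, rng):
        """At constant 25 C the median egg-to-adult time is close to
        (total degree-days)/(25 - T0) days."""
        params = LifecycleParams()
        expected = sum(params.dd_requirements) / (25.0 - params.base_temp)
        times = []
        for _ in range(300):
            agent = Agent(0, parse_genotype("bbddppttllWWXX"), "female",
                          stage=EGG)
            days = 0
            while agent is not None and agent.stage < ADULT:
                agent = develop(agent, 25.0, params, rng)
                days += 1
            if agent is not None:
                times.append(days)
        assert abs(np.median(times) - expected) <= 2.0

    def test_adult_max_age_enforced(self, rng):
        params = LifecycleParams(adult_max_age=5, adult_survival=1.0,
                                 heat_floor=1.0)
        agent = Agent(0, parse_genotype("bbddppttllWWXX"), "female",
                      stage=ADULT)
        days = 0
        while agent is not None:
            agent = develop(agent, 15.0, params, rng)
            days += 1
        assert days == 6  # dies when age exceeds the cap

    def test_heat_lowers_adult_survival(self):
        params = LifecycleParams()
        assert params.adult_daily_survival(33.0) < \
            params.adult_daily_survival(20.0)
        assert params.adult_daily_survival(33.0) >= params.heat_floor - 1e-9


class TestMateAndOviposit:
    def test_sire_choice_uniform_over_males(self):
        state = make_fixture_population(
            {"bbddppttllWWXX": 200, "BBDDppttllWWXY": 9, "bbddppttllWWXY": 1})
        wild_m = state.registry.id_for_code("bbddppttllWWXY")
        rng = np.random.default_rng(5)
        draws = []
        for _ in range(50):
            state.mate_gid[:] = -1
            mate(state, rng)
            female = ~state.is_male()
            draws.append((state.mate_gid[female] == wild_m).mean())
        assert np.mean(draws) == pytest.approx(0.1, abs=0.02)

    def test_no_males_no_matings(self):
        state = make_fixture_population({"bbddppttllWWXX": 10})
        mate(state)
        assert (state.mate_gid == -1).all()
        laid, inviable = oviposit(state, LifecycleParams(), 25.0)
        assert laid == 0 and inviable == 0

    def test_wild_pair_poisson_mean(self):
        params = LifecycleParams()
        state = make_fixture_population({"wildtype": 400})
        mate(state)
        n_f = int((~state.is_male()).sum())
        expected = n_f * params.fecundity(21.0, state.timestep)
        laid, inviable = oviposit(state, params, 21.0)
        assert inviable == 0
        assert laid == pytest.approx(expected, rel=0.15)

    def test_wild_female_by_egi_sire_all_eggs_inviable(self):
        state = make_fixture_population(
            {"bbddppttllWWXX": 100, "BBDDppttllWWXY": 100})
        mate(state)
        laid, inviable = oviposit(state, LifecycleParams(), 21.0)
        assert laid == 0 and inviable > 0


class TestSeason:
    def test_empty_population_stays_empty(self):
        params = LifecycleParams(initial_adults=0)
        res = run_season(params, constant_temps(20.0, 30), seed=1)
        assert res.census.filter(regex="_(female|male)_").to_numpy().sum() == 0

    def test_determinism(self, fast_params):
        temps = generate_temperature_series(TemperatureModelParams(seed=9))
        a = run_season(fast_params, temps, seed=42)
        b = run_season(fast_params, temps, seed=42)
        pd.testing.assert_frame_equal(a.census, b.census)

    def test_missing_temperature_errors(self, fast_params):
        with pytest.raises(ValueError):
            run_season(fast_params, constant_temps(20.0, 10), n_steps=20)

    def test_release_event_adds_exact_males(self, fast_params):
        strategy = ReleaseStrategy(id="i", males_per_release=800,
                                   first_release_timestep=5,
                                   last_release_timestep=5)
        temps = constant_temps(15.0, 8)
        res = run_season(fast_params, temps,
                         schedule=build_schedule(strategy), seed=0)
        released = res.census["released_this_step"]
        assert released[5] == 800 and released.sum() == 800

    def test_no_inviable_genotype_in_census(self, fast_params):
        """Inviable eggs are tallied but never instantiated as agents."""
        strategy = ReleaseStrategy(id="i")
        temps = generate_temperature_series(TemperatureModelParams(seed=2))
        res = run_season(fast_params, temps,
                         schedule=build_schedule(strategy), seed=2)
        state = res.state
        assert all(state.registry.cls[g] >= 0 for g in state.gid)
        assert res.census["inviable_eggs"].sum() > 0

    def test_counters_monotone(self, fast_params):
        temps = generate_temperature_series(TemperatureModelParams(seed=3))
        res = run_season(fast_params, temps, seed=3, n_steps=150)
        cum = res.census["cumulative_adult_females"].to_numpy()
        assert (np.diff(cum) >= 0).all()

    def test_peak_scales_with_initial_adults(self):
        """Without density dependence the untreated peak is roughly linear
        in the founding population."""
        peaks = {}
        for n0 in (4000, 8000):
            vals = []
            for seed in (1, 2, 3):
                temps = generate_temperature_series(
                    TemperatureModelParams(seed=seed))
                res = run_season(LifecycleParams(initial_adults=n0), temps,
                                 seed=seed)
                vals.append(res.peak_adults)
            peaks[n0] = np.mean(vals)
        ratio = peaks[8000] / peaks[4000]
        assert 1.4 < ratio < 2.8

    def test_control_replicates_reproducible_dynamics(self):
        """Untreated replicate peaks vary within a modest band (the paper's
        'highly reproducible seasonal dynamics')."""
        peaks = []
        for seed in range(1, 7):
            temps = generate_temperature_series(
                TemperatureModelParams(seed=seed))
            res = run_season(LifecycleParams(), temps, seed=seed)
            peaks.append(res.peak_adults)
        logs = np.log10(peaks)
        assert logs.std() < 0.45
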