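"""Monte Carlo engine: null processes, determinism, oracle checks, two-pass loop."""
import copy

import numpy as np
import pytest
from helpers import AGES, empirical_occupancy, panel_from_cohort, toy_setup

import demproj as dp
from demproj.engine import NEVER


def _sim(tset, exposure, n, seed, scenario=None, effect_free=False):
    scenario = scenario or dp.ScenarioSpec.from_id(0)
    rng = np.random.default_rng(seed)
    return dp.simulate_cohort(1975, n, tset, exposure, scenario, rng, effect_free)


class TestSimulateCohort:
    def test_null_process(self):
        tset, exposure = toy_setup()
        out = _sim(tset, exposure, 200, seed=0)
        assert np.all(out["age_at_death"] == NEVER)
        assert np.all(out["age_at_dementia"] == NEVER)
        assert np.all(out["age_at_exposure"] == NEVER)

    def test_geometric_survival(self):
        q = 0.1
        rate = -np.log(1 - q)
        tset, exposure = toy_setup(a02=rate, a12=rate)
        n = 100_000
        out = _sim(tset, exposure, n, seed=1)
        panel = panel_from_cohort(out)
        for k in (1, 5, 20, 40):
            expected = (1 - q) ** k
            se = np.sqrt(expected * (1 - expected) / n)
            observed = panel.alive_at(65 + k).mean()
            assert abs(observed - expected) < 4 * se

    def test_determinism_under_seed(self, bundle):
        scen = dp.ScenarioSpec.from_id(1)
        p1 = dp.simulate_population(
            bundle, scen, 200, np.random.default_rng(42), np.arange(1960, 1963)
        )
        p2 = dp.simulate_population(
            bundle, scen, 200, np.random.default_rng(42), np.arange(1960, 1963)
        )
        for sex in ("female", "male"):
            assert p1[sex] == p2[sex]

    def test_dementia_strictly_before_death(self, small_panels):
        for panel in small_panels.panels.values():
            both = (panel.age_at_dementia != NEVER) & (panel.age_at_death != NEVER)
            assert np.all(panel.age_at_dementia[both] < panel.age_at_death[both])

    def test_state_conservation(self, small_panels):
        panel = small_panels.panels["female"]
        for b in (1935, 1955, 1975):
            m = panel.cohort_mask(b)
            n = m.sum()
            for age in (65, 80, 105):
                alive = panel.alive_at(age)[m]
                dem = panel.demented_at(age)[m]
                assert (alive & ~dem).sum() + (alive & dem).sum() + (~alive).sum() == n


class TestSimulatePopulation:
    def test_bookkeeping(self, bundle):
        years = np.arange(1950, 1953)
        panels = dp.simulate_population(
            bundle, dp.ScenarioSpec.from_id(0), 10, np.random.default_rng(0), years
        )
        for sex in ("female", "male"):
            assert panels[sex].n == 30
            assert sorted(np.unique(panels[sex].birth_year)) == [1950, 1951, 1952]

    def test_weights_from_population_size(self, bundle):
        panels = dp.simulate_population(
            bundle, dp.ScenarioSpec.from_id(0), 50, np.random.default_rng(0),
            np.arange(1970, 1972),
        )
        for sex in ("female", "male"):
            panel = panels[sex]
            for b in (1970, 1971):
                w = panel.weight[panel.cohort_mask(b)]
                expected = bundle.pop65.size_at(sex, b + 65) / 50
                assert np.allclose(w, expected)

    def test_missing_pop65_coverage_raises(self, bundle):
        with pytest.raises(KeyError, match="pop65"):
            dp.simulate_population(
                bundle, dp.ScenarioSpec.from_id(0), 10, np.random.default_rng(0),
                np.arange(1990, 1992),  # would need pop65 beyond 2040
            )


class TestExposurePrevalence:
    def test_no_exposure(self):
        tset, exposure = toy_setup(a01=0.02, a02=0.02, a12=0.05)
        panel = panel_from_cohort(_sim(tset, exposure, 2000, seed=2))
        surf = dp.estimate_exposure_prevalence(panel)
        assert np.all(surf.p_nd == 0.0) and np.all(surf.p_d == 0.0)

    def test_full_exposure(self):
        tset, exposure = toy_setup(a01=0.02, a02=0.02, a12=0.05, prev65=1.0)
        panel = panel_from_cohort(_sim(tset, exposure, 2000, seed=3))
        surf = dp.estimate_exposure_prevalence(panel)
        assert np.all(surf.p_nd[surf.defined_nd] == 1.0)
        assert np.all(surf.p_d[surf.defined_d] == 1.0)

    def test_against_oracle_occupancy(self):
        tset, exposure = toy_setup(
            a01=0.02, a02=0.03, a12=0.08, theta01=1.6, theta_mort=1.3,
            prev65=0.2, bzd_inc=0.03,
        )
        scen = dp.ScenarioSpec.from_id(0)
        n = 20_000
        panel = panel_from_cohort(_sim(tset, exposure, n, seed=4, scenario=scen))
        surf = dp.estimate_exposure_prevalence(panel)
        oracle = dp.dp_oracle(tset, exposure, scen, 1975)
        expected = oracle.exposure_prevalence_nondem()
        for j in (0, 5, 15, 25):
            p = expected[j]
            n_nd = oracle.alive_nondem[j] * n
            se = np.sqrt(p * (1 - p) / n_nd)
            assert abs(surf.p_nd[0, j] - p) < 4 * se + 1e-9


class TestTwoPass:
    def test_no_exposure_makes_passes_identical(self, bundle):
        b = copy.deepcopy(bundle)
        for sex in ("female", "male"):
            b.exposure.prev65[sex] = dp.Prev65(0.0, 0.0, 0.0)
            b.exposure.incidence[sex].values[:] = 0.0
        scen = dp.ScenarioSpec.from_id(0)
        years = np.arange(1970, 1976)
        # with nobody exposed, effect-free and effectful runs under a common
        # seed produce bit-identical histories
        tsets = {
            sex: dp.build_transition_set(b, sex, years) for sex in ("female", "male")
        }
        p_free = dp.simulate_population(
            b, scen, 300, np.random.default_rng(9), years, tsets=tsets, effect_free=True
        )
        p_eff = dp.simulate_population(
            b, scen, 300, np.random.default_rng(9), years, tsets=tsets
        )
        for sex in ("female", "male"):
            assert p_free[sex] == p_eff[sex]

    def test_null_effect_calibration_is_noop(self, bundle):
        b = copy.deepcopy(bundle)
        b.effects = dp.ExposureEffect(
            theta01=1.0, theta_mort_bands=((65.0, float("inf"), 1.0),)
        )
        res = dp.run_two_pass(b, dp.ScenarioSpec.from_id(0), 300, seed=5,
                              birth_years=np.arange(1970, 1976))
        for sex in ("female", "male"):
            tset = res.tsets[sex]
            assert np.allclose(tset.a01_0, tset.a01, rtol=1e-14)
            assert np.allclose(tset.a02_0, tset.a02, rtol=1e-14)
            assert np.allclose(tset.a12_0, tset.a12, rtol=1e-14)

    def test_population_average_incidence_recovered(self, bundle):
        """Eq-4-style self-consistency: after calibration, the simulated
        population-average dementia hazard matches the input incidence."""
        res = dp.run_two_pass(bundle, dp.ScenarioSpec.from_id(0), 60_000, seed=6,
                              birth_years=np.array([1975]), sexes=("female",))
        panel = res.panels["female"]
        tset = res.tsets["female"]
        for age in (70, 75, 80):
            at_risk = panel.alive_at(age) & ~panel.demented_at(age)
            onset = panel.age_at_dementia == age + 1
            p_obs = onset[at_risk].mean()
            p_exp = -np.expm1(-tset.a01[0, age - 65])
            se = np.sqrt(p_exp * (1 - p_exp) / at_risk.sum())
            assert abs(p_obs - p_exp) < 4 * se
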