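"""Calibration: generational trend, mortality split, exposure-mixture inversion."""
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import demproj as dp
from demproj.calibration import annual_prob


class TestIncidenceTrend:
    base = np.array([0.01, 0.02, 0.05])

    def test_reference_generation_unchanged(self):
        out = dp.apply_incidence_trend(self.base, 1915, 0.01)
        assert np.array_equal(out, self.base)

    def test_zero_trend_unchanged(self):
        # constant-incidence sensitivity analysis
        out = dp.apply_incidence_trend(self.base, 1960, 0.0)
        assert np.array_equal(out, self.base)

    def test_1975_cohort_factor(self):
        out = dp.apply_incidence_trend(self.base, 1975, 0.01)
        factor = out[0] / self.base[0]
        assert factor == 0.99**60
        assert round(factor, 5) == 0.54716

    def test_pre_reference_cohort_factor_above_one(self):
        out = dp.apply_incidence_trend(self.base, 1900, 0.01)
        assert np.all(out > self.base)

    @given(
        b1=st.integers(1915, 1974),
        delta=st.integers(1, 60),
        trend=st.floats(0.001, 0.05),
    )
    def test_monotone_in_birth_year(self, b1, delta, trend):
        lo = dp.apply_incidence_trend(self.base, b1 + delta, trend)
        hi = dp.apply_incidence_trend(self.base, b1, trend)
        assert np.all(lo < hi)


class TestUnexposedRate:
    def test_no_exposed_subjects(self):
        assert dp.solve_unexposed_rate(0.05, 0.0, 1.6) == 0.05

    def test_null_effect(self):
        assert dp.solve_unexposed_rate(0.05, 0.4, 1.0) == 0.05

    def test_worked_value(self):
        assert dp.solve_unexposed_rate(0.013, 0.25, 1.6) == pytest.approx(
            0.013 / 1.15, rel=1e-12
        )

    @given(
        rate=st.floats(1e-6, 1.0),
        prev=st.floats(0.0, 1.0),
        theta=st.floats(0.1, 5.0),
    )
    def test_mixture_inversion_identity(self, rate, prev, theta):
        r0 = dp.solve_unexposed_rate(rate, prev, theta)
        assert prev * r0 * theta + (1 - prev) * r0 == pytest.approx(rate, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dp.solve_unexposed_rate(0.05, 1.5, 1.6)
        with pytest.raises(ValueError):
            dp.solve_unexposed_rate(0.05, 0.5, 0.0)


class TestMortalitySplit:
    def test_first_age_no_demented(self):
        mu = np.full(5, 0.04)
        a02, a12 = dp.split_overall_mortality(mu, np.full(5, 0.02), np.full(5, 3.0))
        assert a02[0] == mu[0]
        assert a12[0] == 3.0 * mu[0]

    def test_rr_one_no_differential_mortality(self):
        mu = np.linspace(0.01, 0.3, 41)
        a01 = np.linspace(0.002, 0.1, 41)
        a02, a12 = dp.split_overall_mortality(mu, a01, np.ones(41))
        assert np.allclose(a02, mu, rtol=1e-14)
        assert np.allclose(a12, mu, rtol=1e-14)

    def test_hand_enumerated_second_age(self):
        # constant mu=0.05, a01=0.02, RR=3: after one year the dementia
        # prevalence among the alive is pi = 1 - exp(-0.02) (death strikes
        # non-demented and future-demented alike in year one), so
        # a02(66) = mu / (1 + 2*pi).
        mu = np.full(3, 0.05)
        a02, _ = dp.split_overall_mortality(mu, np.full(3, 0.02), np.full(3, 3.0))
        pi = -np.expm1(-0.02)
        assert a02[1] == pytest.approx(0.05 / (1.0 + 2.0 * pi), rel=1e-12)

    def test_closure_on_full_bundle(self, bundle):
        # independently re-run the one-year prevalence recursion and check the
        # strata recombine to the input overall mortality
        for sex in ("female", "male"):
            tset = dp.build_transition_set(bundle, sex, np.arange(1935, 1976))
            for i, b in enumerate(tset.birth_years[::7]):
                idx = tset.index_of(b)
                mu_in = bundle.overall_mortality[sex].cohort_rates(int(b))
                a01, a02, a12 = tset.a01[idx], tset.a02[idx], tset.a12[idx]
                pi = 0.0
                for j in range(tset.ages.size):
                    recombined = (1 - pi) * a02[j] + pi * a12[j]
                    assert recombined == pytest.approx(mu_in[j], abs=1e-10)
                    q01, q02, q12 = annual_prob([a01[j], a02[j], a12[j]])
                    nd = (1 - pi) * (1 - q02) * (1 - q01)
                    d = pi * (1 - q12) + (1 - pi) * (1 - q02) * q01
                    pi = d / (nd + d)

    def test_invalid_rr(self):
        with pytest.raises(ValueError):
            dp.split_overall_mortality(np.full(3, 0.1), np.zeros(3), np.zeros(3))


class TestBuildTransitionSet:
    birth_years = np.arange(1935, 1976)

    def test_zero_prevalence_means_no_adjustment(self, bundle):
        tset = dp.build_transition_set(bundle, "female", self.birth_years)
        assert np.array_equal(tset.a01_0, tset.a01)
        assert np.array_equal(tset.a02_0, tset.a02)
        assert np.array_equal(tset.a12_0, tset.a12)

    def test_no_mortality_effect_switch(self, bundle):
        rng = np.random.default_rng(5)
        prev = SimpleNamespace(
            p_nd=rng.random((41, 41)) * 0.5, p_d=rng.random((41, 41)) * 0.5
        )
        scen = dp.ScenarioSpec.from_id(0, no_mortality_effect=True)
        tset = dp.build_transition_set(bundle, "male", self.birth_years, prev, scen)
        assert np.all(tset.theta_mort == 1.0)
        assert np.array_equal(tset.a02_0, tset.a02)
        assert np.array_equal(tset.a12_0, tset.a12)
        assert not np.array_equal(tset.a01_0, tset.a01)  # dementia effect stays

    def test_reconstruction_identity_random_cells(self, bundle):
        rng = np.random.default_rng(7)
        prev = SimpleNamespace(p_nd=rng.random((41, 41)), p_d=rng.random((41, 41)))
        tset = dp.build_transition_set(bundle, "female", self.birth_years, prev)
        r01, r02, r12 = tset.reconstruct_population_average(prev.p_nd, prev.p_d)
        for _ in range(20):
            i, j = rng.integers(0, 41, 2)
            assert r01[i, j] == pytest.approx(tset.a01[i, j], rel=1e-12)
            assert r02[i, j] == pytest.approx(tset.a02[i, j], rel=1e-12)
            assert r12[i, j] == pytest.approx(tset.a12[i, j], rel=1e-12)

    def test_no_trend_switch_flattens_cohort_incidence(self, bundle):
        scen = dp.ScenarioSpec.from_id(0, no_trend=True)
        tset = dp.build_transition_set(bundle, "female", self.birth_years, None, scen)
        assert np.array_equal(tset.a01[0], tset.a01[-1])
        tset_trend = dp.build_transition_set(bundle, "female", self.birth_years)
        assert np.all(tset_trend.a01[-1] < tset_trend.a01[0])
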