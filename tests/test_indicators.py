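"""Burden indicators: degenerate cases, closed forms, oracle expectations."""
import numpy as np
import pytest
from helpers import AGES, panel_from_cohort, toy_setup

import demproj as dp
from demproj.engine import NEVER, TrajectoryPanel
from demproj.indicators import (
    exposure_prevalence_by_age,
    life_expectancy_without_dementia,
    lifelong_probability,
    mean_age_at_dementia,
    mean_years_with_dementia,
    panel_indicators,
    prevalence,
)


def _blank_panel(n_per_cohort=10):
    """Event-free panel covering cohorts 1935-1975, unit weights."""
    births = np.repeat(np.arange(1935, 1976), n_per_cohort)
    n = births.size
    return TrajectoryPanel(
        sex="female",
        birth_year=births.astype(np.int32),
        age_at_exposure=np.full(n, NEVER, np.int16),
        age_at_dementia=np.full(n, NEVER, np.int16),
        age_at_death=np.full(n, NEVER, np.int16),
        weight=np.ones(n),
    )


class TestDegenerateCases:
    def test_no_dementia_anywhere(self):
        panel = _blank_panel()
        prev = prevalence(panel, 2040)
        assert prev.total_count == 0.0 and prev.rate_pct == 0.0
        assert lifelong_probability(panel, 2040) == 0.0
        assert mean_years_with_dementia(panel, 2040) == 0.0
        assert np.isnan(mean_age_at_dementia(panel, 2040))

    def test_zero_hazards_life_expectancy_is_horizon(self):
        panel = _blank_panel()
        assert life_expectancy_without_dementia(panel, 65, 2040) == 40.0
        assert life_expectancy_without_dementia(panel, 80, 2040) == 25.0
        assert life_expectancy_without_dementia(panel, 100, 2040) == 5.0

    def test_forced_onset_age(self):
        panel = _blank_panel()
        cohort = panel.cohort_mask(1975)
        panel.age_at_dementia[cohort] = 80
        assert mean_age_at_dementia(panel, 2040) == 80.0
        # alive to the cap: years with dementia truncated at 99
        assert mean_years_with_dementia(panel, 2040) == 100.0 - 80.0

    def test_missing_cohort_raises(self):
        panel = _blank_panel()
        with pytest.raises(ValueError, match="cohort"):
            lifelong_probability(panel, 2100)


class TestPrevalence:
    def test_linearity_in_weights(self, small_panels):
        panel = small_panels.panels["female"]
        prev1 = prevalence(panel, 2040)
        doubled = TrajectoryPanel(
            sex=panel.sex,
            birth_year=panel.birth_year,
            age_at_exposure=panel.age_at_exposure,
            age_at_dementia=panel.age_at_dementia,
            age_at_death=panel.age_at_death,
            weight=panel.weight * 2,
        )
        prev2 = prevalence(doubled, 2040)
        assert np.allclose(prev2.counts, 2 * prev1.counts)
        assert prev2.rate_pct == pytest.approx(prev1.rate_pct, rel=1e-12)

    def test_rate_consistent_with_raw_panel(self, small_panels):
        panel = small_panels.panels["male"]
        prev = prevalence(panel, 2040)
        num = den = 0.0
        for age in range(65, 100):
            m = panel.cohort_mask(2040 - age)
            w = panel.weight[m]
            alive = panel.alive_at(age)[m]
            dem = panel.demented_at(age)[m]
            num += w[alive & dem].sum()
            den += w[alive].sum()
        assert prev.rate_pct == pytest.approx(100 * num / den, rel=1e-12)

    def test_subject_order_invariance(self, small_panels):
        panel = small_panels.panels["female"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.n)
        shuffled = TrajectoryPanel(
            sex=panel.sex,
            birth_year=panel.birth_year[perm],
            age_at_exposure=panel.age_at_exposure[perm],
            age_at_dementia=panel.age_at_dementia[perm],
            age_at_death=panel.age_at_death[perm],
            weight=panel.weight[perm],
        )
        a = panel_indicators(panel, 2040)
        b = panel_indicators(shuffled, 2040)
        assert np.allclose(a["value"].to_numpy(), b["value"].to_numpy(), equal_nan=True)


class TestAgainstOracle:
    """Empirical indicators converge to the exact DP expectations."""

    def setup_method(self):
        self.tset, self.exposure = toy_setup(
            a01=0.025, a02=0.035, a12=0.10, theta01=1.6,
            theta_mort=1.4, prev65=0.18, bzd_inc=0.02,
        )
        self.scen = dp.ScenarioSpec.from_id(0)
        self.n = 40_000
        rng = np.random.default_rng(17)
        self.panel = panel_from_cohort(
            dp.simulate_cohort(1975, self.n, self.tset, self.exposure, self.scen, rng)
        )
        self.oracle = dp.dp_oracle(self.tset, self.exposure, self.scen, 1975)

    def test_lifelong_probability(self):
        got = lifelong_probability(self.panel, 2040)
        exp = self.oracle.lifelong_probability()
        se = 100 * np.sqrt(exp / 100 * (1 - exp / 100) / self.n)
        assert abs(got - exp) < 4 * se

    def test_life_expectancy(self):
        got = life_expectancy_without_dementia(self.panel, 65, 2040)
        exp = self.oracle.le_without_dementia()
        # empirical SE of the per-subject years-without-dementia count
        dem = self.panel.age_at_dementia
        death = self.panel.age_at_death
        last = np.minimum(
            np.where(dem == NEVER, 105, dem - 1),
            np.where(death == NEVER, 105, death - 1),
        )
        se = np.std(last - 65) / np.sqrt(self.n)
        assert abs(got - exp) < 4 * se

    def test_mean_age_and_years_with_dementia(self):
        got_age = mean_age_at_dementia(self.panel, 2040)
        exp_age = self.oracle.mean_age_at_dementia()
        onsets = self.panel.age_at_dementia
        onsets = onsets[onsets != NEVER]
        assert abs(got_age - exp_age) < 4 * onsets.std() / np.sqrt(onsets.size)

        got_years = mean_years_with_dementia(self.panel, 2040)
        exp_years = self.oracle.mean_years_with_dementia()
        dem = self.panel.age_at_dementia.astype(float)
        death = self.panel.age_at_death.astype(float)
        end = np.minimum(np.where(death == NEVER, 105, death), 100.0)
        years = np.where(dem == NEVER, 0.0, np.maximum(0.0, end - dem))
        assert abs(got_years - exp_years) < 4 * years.std() / np.sqrt(self.n)

    def test_geometric_life_expectancy_closed_form(self):
        # death-only exit at constant annual probability 0.28: the horizon cap
        # at 105 is negligible and LE ~ s/(1-s) for s = 0.72
        s = 0.72
        tset, exposure = toy_setup(a02=-np.log(s), a12=-np.log(s))
        oracle = dp.dp_oracle(tset, exposure, self.scen, 1975)
        capped = s * (1 - s**40) / (1 - s)
        assert oracle.le_without_dementia() == pytest.approx(capped, abs=1e-10)
        assert oracle.le_without_dementia() == pytest.approx(s / (1 - s), abs=5e-4)


def test_le_monotone_in_age(small_panels):
    panel = small_panels.panels["female"]
    le65 = life_expectancy_without_dementia(panel, 65, 2040)
    le80 = life_expectancy_without_dementia(panel, 80, 2040)
    assert le80 < le65


def test_exposure_prevalence_by_age_bounds(small_panels):
    expo = exposure_prevalence_by_age(small_panels.panels["female"], 2040)
    vals = expo.dropna().to_numpy()
    assert np.all((vals >= 0) & (vals <= 100))


def test_panel_indicators_shape(small_panels):
    df = panel_indicators(small_panels.panels["male"], 2040)
    assert set(df["indicator"]) == {
        "prevalence_count",
        "exposure_prevalence",
        "le_without_dementia",
        "prevalence_count_total",
        "prevalence_rate",
        "lifelong_probability",
        "le_without_dementia_at_65",
        "mean_age_at_dementia",
        "mean_years_with_dementia",
    }
    assert (df[df.indicator == "prevalence_count"]["age"].to_numpy()
            == np.arange(65, 100)).all()
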