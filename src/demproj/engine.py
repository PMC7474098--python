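"""Discrete-time Monte Carlo cohort simulator and two-pass calibration loop.

Each birth cohort ``b`` (default 1935-1975) contributes ``n_per_cohort``
subjects who enter alive and non-demented at age 65 in calendar year
``b + 65``.  For every subsequent year until age 105 or death, three events
are drawn sequentially from their annual incidences:

1. an unexposed subject becomes (irreversibly) exposed;
2. the subject dies, with the mortality of their current stratum
   (non-demented/demented, unexposed/exposed) — dementia acquired later in
   the same year does not affect this draw;
3. an alive non-demented subject develops dementia.

Intensities are converted to annual probabilities by ``1 - exp(-rate)``;
rates for the year starting at age ``a`` are read at ``(a, b + a)`` and a
newly exposed subject uses exposed rates for that same year's death and
dementia draws.  Event ages are recorded as the age attained that year.

The two-pass loop mirrors the calibration procedure: a first, effect-free run
under the status-quo exposure process estimates the prevalence of (past or
current) exposure among alive non-demented and demented subjects; those
surfaces feed the mixture inversion that yields the unexposed baseline
intensities used by the second, definitive run.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import TransitionIntensitySet, annual_prob, build_transition_set
from .rates_io import SEXES, InputBundle, _dataclass_eq
from .scenarios import ScenarioSpec, draw_initial_exposure, scenario_incidence

__all__ = [
    "TrajectoryPanel",
    "ExposurePrevalenceSurfaces",
    "simulate_cohort",
    "simulate_population",
    "estimate_exposure_prevalence",
    "run_two_pass",
    "TwoPassResult",
    "default_birth_years",
]

NEVER = -1  # sentinel for events that did not occur by the end of follow-up


def default_birth_years(target_year: int = 2040) -> np.ndarray:
    """Cohorts contributing to the target year: ages 65-105 in that year."""
    return np.arange(target_year - 105, target_year - 65 + 1)


@dataclass(eq=False)
class TrajectoryPanel:
    """Simulated life histories for one sex, all cohorts stacked.

    Event ages use ``-1`` for "never" (``age_at_death == -1`` means alive at
    the age cap).  ``weight`` is the number of real subjects each simulated
    subject stands for: ``pop65(b + 65) / n_per_cohort``.
    """

    sex: str
    birth_year: np.ndarray
    age_at_exposure: np.ndarray
    age_at_dementia: np.ndarray
    age_at_death: np.ndarray
    weight: np.ndarray
    start_age: int = 65
    end_age: int = 105

    __eq__ = _dataclass_eq

    @property
    def n(self) -> int:
        return self.birth_year.size

    # -- status at an attained age -------------------------------------------

    def alive_at(self, age: int) -> np.ndarray:
        return (self.age_at_death == NEVER) | (self.age_at_death > age)

    def demented_at(self, age: int) -> np.ndarray:
        return (self.age_at_dementia != NEVER) & (self.age_at_dementia <= age)

    def exposed_at(self, age: int) -> np.ndarray:
        return (self.age_at_exposure != NEVER) & (self.age_at_exposure <= age)

    def cohort_mask(self, birth_year: int) -> np.ndarray:
        return self.birth_year == birth_year

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sex": self.sex,
                "birth_year": self.birth_year,
                "age_at_exposure": self.age_at_exposure,
                "age_at_dementia": self.age_at_dementia,
                "age_at_death": self.age_at_death,
                "weight": self.weight,
            }
        )


@dataclass(eq=False)
class ExposurePrevalenceSurfaces:
    """Fraction ever exposed among alive non-demented / demented subjects.

    Arrays are shaped ``(n_cohorts, n_ages)`` along cohort diagonals
    ``(a, b + a)``.  ``defined_*`` flags cells whose alive count was positive;
    undefined cells are filled by carrying the nearest defined age of the same
    cohort (demented cells with no demented subject at all fall back to the
    non-demented surface).
    """

    sex: str
    birth_years: np.ndarray
    ages: np.ndarray
    p_nd: np.ndarray
    p_d: np.ndarray
    defined_nd: np.ndarray
    defined_d: np.ndarray

    __eq__ = _dataclass_eq

    @classmethod
    def zeros(cls, sex, birth_years, ages) -> "ExposurePrevalenceSurfaces":
        nb, na = len(birth_years), len(ages)
        return cls(
            sex=sex,
            birth_years=np.asarray(birth_years, dtype=int),
            ages=np.asarray(ages, dtype=int),
            p_nd=np.zeros((nb, na)),
            p_d=np.zeros((nb, na)),
            defined_nd=np.ones((nb, na), dtype=bool),
            defined_d=np.ones((nb, na), dtype=bool),
        )


def _annual_probabilities(
    tset: TransitionIntensitySet,
    cohort_idx: int,
    effect_free: bool,
):
    """Per-age annual probabilities for each (dementia, exposure) stratum."""
    i = cohort_idx
    if effect_free:
        a01_u = a01_e = tset.a01[i]
        a02_u = a02_e = tset.a02[i]
        a12_u = a12_e = tset.a12[i]
    else:
        a01_u = tset.a01_0[i]
        a01_e = tset.a01_0[i] * tset.theta01
        a02_u = tset.a02_0[i]
        a02_e = tset.a02_0[i] * tset.theta_mort
        a12_u = tset.a12_0[i]
        a12_e = tset.a12_0[i] * tset.theta_mort
    return (
        annual_prob(a01_u),
        annual_prob(a01_e),
        annual_prob(a02_u),
        annual_prob(a02_e),
        annual_prob(a12_u),
        annual_prob(a12_e),
    )


def exposure_probabilities(
    exposure_incidence: np.ndarray,
    ages: np.ndarray,
    birth_year: int,
    scenario: ScenarioSpec,
) -> np.ndarray:
    """Annual probability of becoming exposed, per start age, scenario applied."""
    years = birth_year + np.asarray(ages)
    return annual_prob(scenario_incidence(exposure_incidence, years, scenario))


def simulate_cohort(
    birth_year: int,
    n: int,
    intensities: TransitionIntensitySet,
    exposure,
    scenario: ScenarioSpec,
    rng: np.random.Generator,
    effect_free: bool = False,
) -> dict:
    """Simulate one cohort; returns event-age arrays (see TrajectoryPanel).

    ``exposure`` is an :class:`~demproj.rates_io.ExposureInputs`.  The number
    of random draws per subject-year is fixed (three uniforms) regardless of
    state, so runs with a common seed are coupled draw-for-draw across
    scenarios.
    """
    i = intensities.index_of(birth_year)
    ages = intensities.ages
    na = ages.size
    sex = intensities.sex

    p01_u, p01_e, p02_u, p02_e, p12_u, p12_e = _annual_probabilities(
        intensities, i, effect_free
    )
    pe = exposure_probabilities(
        exposure.incidence[sex].values, ages, birth_year, scenario
    )

    exposed = draw_initial_exposure(exposure.prev65[sex].prev, n, rng)
    alive = np.ones(n, dtype=bool)
    dem = np.zeros(n, dtype=bool)
    age_exp = np.where(exposed, ages[0], NEVER).astype(np.int16)
    age_dem = np.full(n, NEVER, dtype=np.int16)
    age_death = np.full(n, NEVER, dtype=np.int16)

    for k in range(na - 1):
        attained = ages[k + 1]
        u_exp = rng.random(n)
        u_die = rng.random(n)
        u_dem = rng.random(n)

        newly = alive & ~exposed & (u_exp < pe[k])
        exposed |= newly
        age_exp[newly] = attained

        p_die = np.where(
            dem,
            np.where(exposed, p12_e[k], p12_u[k]),
            np.where(exposed, p02_e[k], p02_u[k]),
        )
        dies = alive & (u_die < p_die)
        age_death[dies] = attained
        alive &= ~dies

        p_dem = np.where(exposed, p01_e[k], p01_u[k])
        new_dem = alive & ~dem & (u_dem < p_dem)
        dem |= new_dem
        age_dem[new_dem] = attained

    return {
        "age_at_exposure": age_exp,
        "age_at_dementia": age_dem,
        "age_at_death": age_death,
    }


def simulate_population(
    bundle: InputBundle,
    scenario: ScenarioSpec,
    n_per_cohort: int,
    rng: np.random.Generator,
    birth_years: np.ndarray | None = None,
    tsets: dict | None = None,
    prevalence: dict | None = None,
    effect_free: bool = False,
    sexes=SEXES,
) -> dict:
    """Simulate all cohorts for the requested sexes.

    Returns ``{sex: TrajectoryPanel}``.  Transition sets are built from the
    bundle (with ``prevalence`` surfaces, or all-zero) unless passed in
    ``tsets``; cohort weights come from the population size at 65.
    """
    if birth_years is None:
        birth_years = default_birth_years()
    birth_years = np.asarray(birth_years, dtype=int)
    for sex in sexes:
        for b in birth_years:
            bundle.pop65.size_at(sex, int(b) + bundle.grid.start_age)  # coverage check

    panels = {}
    for sex in sexes:
        if tsets is not None:
            tset = tsets[sex]
        else:
            prev = prevalence[sex] if prevalence is not None else None
            tset = build_transition_set(bundle, sex, birth_years, prev, scenario)

        chunks = {k: [] for k in ("age_at_exposure", "age_at_dementia", "age_at_death")}
        b_col, w_col = [], []
        for b in birth_years:
            out = simulate_cohort(
                int(b), n_per_cohort, tset, bundle.exposure, scenario, rng, effect_free
            )
            for k in chunks:
                chunks[k].append(out[k])
            b_col.append(np.full(n_per_cohort, b, dtype=np.int32))
            w = bundle.pop65.size_at(sex, int(b) + bundle.grid.start_age) / n_per_cohort
            w_col.append(np.full(n_per_cohort, w))

        panels[sex] = TrajectoryPanel(
            sex=sex,
            birth_year=np.concatenate(b_col),
            age_at_exposure=np.concatenate(chunks["age_at_exposure"]),
            age_at_dementia=np.concatenate(chunks["age_at_dementia"]),
            age_at_death=np.concatenate(chunks["age_at_death"]),
            weight=np.concatenate(w_col),
            start_age=int(bundle.grid.start_age),
            end_age=int(bundle.grid.end_age),
        )
    return panels


def _fill_undefined(values: np.ndarray, defined: np.ndarray, fallback: np.ndarray):
    """Carry nearest defined cell along age; fall back row-wise if none defined."""
    out = values.copy()
    for i in range(out.shape[0]):
        d = defined[i]
        if not d.any():
            out[i] = fallback[i]
            continue
        idx = np.where(d, np.arange(d.size), -1)
        np.maximum.accumulate(idx, out=idx)  # forward fill
        first = np.argmax(d)
        idx[idx < 0] = first  # leading gap: take first defined age
        out[i] = out[i, idx]
    return out


def estimate_exposure_prevalence(panel: TrajectoryPanel) -> ExposurePrevalenceSurfaces:
    """Empirical exposure prevalence among alive non-demented / demented.

    For each cohort and attained age, the fraction of alive subjects in the
    stratum whose exposure started at or before that age.
    """
    birth_years = np.unique(panel.birth_year)
    ages = np.arange(panel.start_age, panel.end_age + 1)
    nb, na = birth_years.size, ages.size
    p_nd = np.zeros((nb, na))
    p_d = np.zeros((nb, na))
    defined_nd = np.zeros((nb, na), dtype=bool)
    defined_d = np.zeros((nb, na), dtype=bool)

    for i, b in enumerate(birth_years):
        m = panel.cohort_mask(int(b))
        exp_age = panel.age_at_exposure[m]
        dem_age = panel.age_at_dementia[m]
        death_age = panel.age_at_death[m]
        for j, a in enumerate(ages):
            alive = (death_age == NEVER) | (death_age > a)
            dem = (dem_age != NEVER) & (dem_age <= a)
            exposed = (exp_age != NEVER) & (exp_age <= a)
            nd = alive & ~dem
            d = alive & dem
            n_nd = int(nd.sum())
            n_d = int(d.sum())
            if n_nd:
                p_nd[i, j] = exposed[nd].sum() / n_nd
                defined_nd[i, j] = True
            if n_d:
                p_d[i, j] = exposed[d].sum() / n_d
                defined_d[i, j] = True

    p_nd = _fill_undefined(p_nd, defined_nd, np.zeros((nb, na)))
    p_d = _fill_undefined(p_d, defined_d, p_nd)
    return ExposurePrevalenceSurfaces(
        sex=panel.sex,
        birth_years=birth_years,
        ages=ages,
        p_nd=p_nd,
        p_d=p_d,
        defined_nd=defined_nd,
        defined_d=defined_d,
    )


@dataclass(eq=False)
class TwoPassResult:
    """Output of the two-pass algorithm for one scenario."""

    scenario: ScenarioSpec
    panels: dict
    panels_pass1: dict
    prevalence: dict
    tsets: dict

    __eq__ = _dataclass_eq


def run_two_pass(
    bundle: InputBundle,
    scenario: ScenarioSpec,
    n_per_cohort: int,
    seed,
    birth_years: np.ndarray | None = None,
    calibration_scenario: ScenarioSpec | None = None,
    sexes=SEXES,
) -> TwoPassResult:
    """Central two-pass projection for one scenario.

    Pass 1 simulates the population with population-average intensities and
    the exposure process switched on but effect-free, solely to estimate the
    exposure-prevalence surfaces.  Those surfaces calibrate the unexposed
    baseline intensities used by pass 2, which produces the returned panels.

    Calibration always reflects the population the input rates were estimated
    in, so pass 1 runs under the status-quo exposure process (the scenario
    with its intervention removed) unless ``calibration_scenario`` overrides
    it; the unexposed baselines are therefore shared across scenarios.
    """
    if birth_years is None:
        birth_years = default_birth_years()
    if calibration_scenario is None:
        calibration_scenario = scenario.status_quo()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_pass1, seed_pass2 = ss.spawn(2)

    panels1 = simulate_population(
        bundle,
        calibration_scenario,
        n_per_cohort,
        np.random.default_rng(seed_pass1),
        birth_years,
        effect_free=True,
        sexes=sexes,
    )
    prevalence = {sex: estimate_exposure_prevalence(panels1[sex]) for sex in sexes}
    tsets = {
        sex: build_transition_set(
            bundle, sex, birth_years, prevalence[sex], calibration_scenario
        )
        for sex in sexes
    }
    panels2 = simulate_population(
        bundle,
        scenario,
        n_per_cohort,
        np.random.default_rng(seed_pass2),
        birth_years,
        tsets=tsets,
        sexes=sexes,
    )
    return TwoPassResult(
        scenario=scenario,
        panels=panels2,
        panels_pass1=panels1,
        prevalence=prevalence,
        tsets=tsets,
    )
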