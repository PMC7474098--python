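"""Synthetic input bundles and the exact dynamic-programming oracle.

The generator produces complete, validated input bundles with the shapes a
French-style application would exhibit: Gompertz dementia incidence and
overall mortality (mortality improving by a constant annual factor),
a declining-with-age incidence of chronic benzodiazepine use, age-65
prevalence of chronic use near 18.3% for women and 11.2% for men, a
decreasing age-specific relative risk of death for demented subjects, and a
1%-per-generation decline of dementia incidence anchored on the generation
aged 75 in 1990.  Default magnitudes are chosen so the projected 2040 burden
is of realistic order (prevalence rate roughly 8-13% over ages 65-99, life
expectancy without dementia at 65 roughly 22-26 years); they emulate the
shape of real calibration inputs, not any particular estimate.

``dp_oracle`` propagates the exact joint state distribution of one cohort —
(non-demented/demented) x (unexposed/exposed) plus death — with the same
within-year event order and probability conversions as the simulation
engine, and returns exact expectations for every burden indicator.  It is
the ground truth the stochastic engine is tested against.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .calibration import TransitionIntensitySet
from .engine import _annual_probabilities, exposure_probabilities
from .rates_io import (
    SEXES,
    AgeGrid,
    ExposureEffect,
    ExposureInputs,
    HazardSurface,
    InputBundle,
    PopulationAt65,
    Prev65,
    RelativeRiskCurve,
    _dataclass_eq,
)
from .scenarios import ScenarioSpec

__all__ = ["SyntheticSpec", "make_synthetic_bundle", "dp_oracle", "OccupancyTable"]


def _d(**kw):
    return field(default_factory=lambda: dict(kw))


@dataclass(eq=False)
class SyntheticSpec:
    """Parameters of the synthetic bundle generator.

    Hazards are Gompertz in age: ``rate(a) = rate65 * exp(slope * (a - 65))``;
    chronic-use incidence declines with age at rate ``bzd_decay``; the
    mortality surface scales by ``mortality_improvement_factor`` per calendar
    year around ``mortality_ref_year`` (a factor of 1 gives a surface constant
    in time).  ``noise_sd`` > 0 adds a smooth log-normal tilt per curve so
    that different seeds yield distinct but equally plausible bundles.
    """

    dementia_rate65: dict = _d(female=0.0040, male=0.0036)
    dementia_slope: dict = _d(female=0.125, male=0.115)
    dementia_se_log: float = 0.05
    rr_amplitude: dict = _d(female=6.5, male=5.5)
    rr_decay: float = 0.07
    rr_se_log: float = 0.10
    mortality_rate65: dict = _d(female=0.0062, male=0.0095)
    mortality_slope: dict = _d(female=0.102, male=0.098)
    mortality_improvement_factor: float = 0.988
    mortality_ref_year: int = 2015
    bzd_rate65: dict = _d(female=0.022, male=0.012)
    bzd_decay: float = 0.03
    bzd_se_log: float = 0.08
    prev65: dict = _d(female=(0.183, 0.167, 0.199), male=(0.112, 0.099, 0.126))
    pop65_base: dict = _d(female=400_000.0, male=360_000.0)
    pop65_growth: float = 0.002
    mortality_years: tuple = (1950, 2070)
    pop_years: tuple = (2000, 2040)
    trend_rate: float = 0.01
    reference_age: int = 75
    reference_year: int = 1990
    noise_sd: float = 0.0
    grid: AgeGrid = AgeGrid()

    __eq__ = _dataclass_eq

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        spec = cls()
        for key, val in raw.items():
            if not hasattr(spec, key):
                raise ValueError(f"unknown synthetic spec key: {key}")
            current = getattr(spec, key)
            if isinstance(current, dict) and isinstance(val, dict):
                merged = dict(current)
                merged.update(
                    {s: tuple(v) if isinstance(v, list) else v for s, v in val.items()}
                )
                setattr(spec, key, merged)
            elif key == "grid":
                setattr(spec, key, AgeGrid(**val))
            elif isinstance(current, tuple):
                setattr(spec, key, tuple(val))
            else:
                setattr(spec, key, val)
        return spec


def _tilt(rng: np.random.Generator, ages: np.ndarray, sd: float) -> np.ndarray:
    """Smooth multiplicative perturbation: log-linear tilt with random level/slope."""
    if sd == 0.0:
        return np.ones(ages.size)
    level = rng.normal(0.0, sd)
    slope = rng.normal(0.0, sd / 20.0)
    return np.exp(level + slope * (ages - ages[0]))


def make_synthetic_bundle(spec: SyntheticSpec | None = None, seed: int = 0) -> InputBundle:
    """Deterministic synthetic bundle on the full age grid and year range.

    The seed matters only when ``spec.noise_sd`` > 0; otherwise the bundle is
    an exact function of the spec.
    """
    if spec is None:
        spec = SyntheticSpec()
    rng = np.random.default_rng(seed)
    ages = spec.grid.ages
    rel_age = ages - ages[0]
    y0, y1 = spec.mortality_years
    years = np.arange(y0, y1 + 1)

    dementia, rr, mortality, bzd_inc, prev65 = {}, {}, {}, {}, {}
    for sex in SEXES:
        inc = spec.dementia_rate65[sex] * np.exp(spec.dementia_slope[sex] * rel_age)
        inc = inc * _tilt(rng, ages, spec.noise_sd)
        dementia[sex] = HazardSurface(
            sex,
            "dementia_incidence",
            ages,
            inc,
            se_log=np.full(ages.size, spec.dementia_se_log),
        )

        rr_vals = 1.0 + spec.rr_amplitude[sex] * np.exp(-spec.rr_decay * rel_age)
        rr_vals = rr_vals * _tilt(rng, ages, spec.noise_sd)
        rr[sex] = RelativeRiskCurve(
            sex, ages, rr_vals, se_log=np.full(ages.size, spec.rr_se_log)
        )

        base_mu = spec.mortality_rate65[sex] * np.exp(spec.mortality_slope[sex] * rel_age)
        base_mu = base_mu * _tilt(rng, ages, spec.noise_sd)
        factors = spec.mortality_improvement_factor ** (years - spec.mortality_ref_year)
        surface = base_mu[:, None] * factors[None, :]
        if np.any(surface >= -np.log(1e-3)):  # annual death probability > 0.999
            raise ValueError(
                "synthetic mortality implies an annual death probability above 0.999"
            )
        mortality[sex] = HazardSurface(
            sex, "overall_mortality", ages, surface, years=years
        )

        bzd = spec.bzd_rate65[sex] * np.exp(-spec.bzd_decay * rel_age)
        bzd = bzd * _tilt(rng, ages, spec.noise_sd)
        bzd_inc[sex] = HazardSurface(
            sex, "bzd_incidence", ages, bzd, se_log=np.full(ages.size, spec.bzd_se_log)
        )

        p, lo, hi = spec.prev65[sex]
        prev65[sex] = Prev65(p, lo, hi)

    pop_years = np.arange(spec.pop_years[0], spec.pop_years[1] + 1)
    pop65 = PopulationAt65(
        pop_years,
        {
            sex: spec.pop65_base[sex]
            * (1.0 + spec.pop65_growth) ** (pop_years - pop_years[0])
            for sex in SEXES
        },
    )

    bundle = InputBundle(
        dementia_incidence=dementia,
        rr_death=rr,
        overall_mortality=mortality,
        pop65=pop65,
        exposure=ExposureInputs(prev65=prev65, incidence=bzd_inc),
        effects=ExposureEffect(),
        trend_rate=spec.trend_rate,
        reference_age=spec.reference_age,
        reference_year=spec.reference_year,
        grid=spec.grid,
    )
    return bundle.validate()


# -- exact dynamic-programming oracle -----------------------------------------

STATES = ("nd_unexposed", "nd_exposed", "dem_unexposed", "dem_exposed", "dead")


@dataclass(eq=False)
class OccupancyTable:
    """Exact joint state distribution of one cohort, by attained age.

    ``occ[j]`` is the probability vector over ``STATES`` at age ``ages[j]``;
    ``onset[j]`` is the probability of dementia onset recorded at that age.
    Indicator expectations mirror the empirical definitions of the
    :mod:`~demproj.indicators` module exactly.
    """

    birth_year: int
    ages: np.ndarray
    occ: np.ndarray
    onset: np.ndarray

    __eq__ = _dataclass_eq

    @property
    def alive_nondem(self) -> np.ndarray:
        return self.occ[:, 0] + self.occ[:, 1]

    @property
    def alive_dem(self) -> np.ndarray:
        return self.occ[:, 2] + self.occ[:, 3]

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occ[:, 4]

    def check_mass(self, tol: float = 1e-12) -> None:
        err = np.abs(self.occ.sum(axis=1) - 1.0).max()
        if err > tol:
            raise AssertionError(f"occupancy mass error {err} exceeds {tol}")
        if np.any(np.diff(self.occ[:, 4]) < -tol):
            raise AssertionError("death mass must be non-decreasing")

    def prevalence_at(self, age: int) -> float:
        j = int(np.searchsorted(self.ages, age))
        return float(self.alive_dem[j])

    def lifelong_probability(self) -> float:
        return float(100.0 * self.onset.sum())

    def le_without_dementia(self) -> float:
        """Expected years alive and non-demented after the start age."""
        return float(self.alive_nondem[1:].sum())

    def mean_age_at_dementia(self) -> float:
        total = self.onset.sum()
        if total == 0:
            return float("nan")
        return float((self.ages * self.onset).sum() / total)

    def mean_years_with_dementia(self, cap: int = 99) -> float:
        mask = (self.ages > self.ages[0]) & (self.ages <= cap)
        return float(self.alive_dem[mask].sum())

    def exposure_prevalence_nondem(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.occ[:, 1] / self.alive_nondem

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occ, columns=list(STATES))
        df.insert(0, "age", self.ages)
        df["onset"] = self.onset
        return df


def dp_oracle(
    intensities: TransitionIntensitySet,
    exposure: ExposureInputs,
    scenario: ScenarioSpec,
    birth_year: int,
    effect_free: bool = False,
    start_age: int | None = None,
    start_exposure_split: tuple | None = None,
) -> OccupancyTable:
    """Exact forward propagation of one cohort's joint state distribution.

    Uses the same within-year event order (exposure, then death, then
    dementia; a newly exposed subject uses exposed rates that same year;
    death uses the dementia status from the previous year's end) and the same
    intensity-to-probability conversion as the Monte Carlo engine.

    ``start_age``/``start_exposure_split`` restart the recursion from a later
    age with a given (non-demented unexposed, non-demented exposed) split —
    used for conditional quantities such as life expectancy at ages above 65.
    """
    i = intensities.index_of(birth_year)
    ages = intensities.ages
    sex = intensities.sex
    p01_u, p01_e, p02_u, p02_e, p12_u, p12_e = _annual_probabilities(
        intensities, i, effect_free
    )
    pe = exposure_probabilities(
        exposure.incidence[sex].values, ages, birth_year, scenario
    )

    if start_age is None:
        j0 = 0
        prev = exposure.prev65[sex].prev
        init = np.array([1.0 - prev, prev, 0.0, 0.0, 0.0])
    else:
        j0 = int(np.searchsorted(ages, start_age))
        if j0 >= ages.size or ages[j0] != start_age:
            raise KeyError(f"start age {start_age} not on the grid")
        if start_exposure_split is None:
            raise ValueError("start_exposure_split required with start_age")
        ndu, nde = start_exposure_split
        init = np.array([ndu, nde, 0.0, 0.0, 0.0], dtype=float)
        init /= init.sum()

    sub_ages = ages[j0:]
    occ = np.zeros((sub_ages.size, 5))
    onset = np.zeros(sub_ages.size)
    occ[0] = init

    for j in range(sub_ages.size - 1):
        k = j0 + j  # index of the start age of this year
        ndu, nde, du, de, dead = occ[j]
        nxt = np.zeros(5)

        # non-demented unexposed: may become exposed first
        for mass, exposed_now in ((ndu * pe[k], True), (ndu * (1.0 - pe[k]), False)):
            q_die = p02_e[k] if exposed_now else p02_u[k]
            q_dem = p01_e[k] if exposed_now else p01_u[k]
            nxt[4] += mass * q_die
            survived = mass * (1.0 - q_die)
            dem_mass = survived * q_dem
            onset[j + 1] += dem_mass
            nxt[3 if exposed_now else 2] += dem_mass
            nxt[1 if exposed_now else 0] += survived * (1.0 - q_dem)

        # non-demented exposed
        nxt[4] += nde * p02_e[k]
        survived = nde * (1.0 - p02_e[k])
        onset[j + 1] += survived * p01_e[k]
        nxt[3] += survived * p01_e[k]
        nxt[1] += survived * (1.0 - p01_e[k])

        # demented unexposed: may still become exposed
        for mass, exposed_now in ((du * pe[k], True), (du * (1.0 - pe[k]), False)):
            q_die = p12_e[k] if exposed_now else p12_u[k]
            nxt[4] += mass * q_die
            nxt[3 if exposed_now else 2] += mass * (1.0 - q_die)

        # demented exposed
        nxt[4] += de * p12_e[k]
        nxt[3] += de * (1.0 - p12_e[k])

        nxt[4] += dead
        occ[j + 1] = nxt

    return OccupancyTable(
        birth_year=int(birth_year), ages=sub_ages, occ=occ, onset=onset
    )
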