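"""Calibration of stratum-specific transition intensities.

The inputs are population-average rates: dementia incidence for a reference
generation, overall mortality, and the relative risk of death for demented
subjects.  The simulation needs the intensities of the illness-death model
split two ways: by dementia status (mortality of non-demented ``a02`` vs
demented ``a12``) and by exposure status (unexposed baseline intensities
``a01_0``, ``a02_0``, ``a12_0`` with multiplicative relative risks
``theta01`` and ``theta_mort(a)`` for exposed subjects).

Three transformations live here:

1. the generational incidence trend, a multiplicative ``(1 - r)^(b - b_ref)``
   decline of dementia incidence by birth cohort (reference: the generation
   aged 75 in 1990, i.e. born 1915);
2. the split of overall mortality into non-demented and demented strata,
   done cohort by cohort with an exact discrete-time recursion for the
   prevalence of dementia among the alive (the discrete analogue of the
   continuous-time differential-equation approach);
3. the mixture inversion that recovers unexposed intensities from
   population-average ones given the prevalence of exposure:
   ``rate = P * rate0 * theta + (1 - P) * rate0``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rates_io import InputBundle, _dataclass_eq
from .scenarios import ScenarioSpec

__all__ = [
    "TransitionIntensitySet",
    "annual_prob",
    "apply_incidence_trend",
    "split_overall_mortality",
    "solve_unexposed_rate",
    "build_transition_set",
]


def annual_prob(rate):
    """Annual event probability implied by a constant within-year intensity."""
    return -np.expm1(-np.asarray(rate, dtype=float))


@dataclass(eq=False)
class TransitionIntensitySet:
    """All transition intensities for one sex, per birth cohort and age.

    Arrays are shaped ``(n_cohorts, n_ages)``; ``a01``/``a02``/``a12`` are the
    population-average intensities (trend and mortality split applied) and the
    ``*_0`` arrays are the corresponding unexposed baselines.  ``theta_mort``
    is the per-age mortality relative risk of exposure (already forced to 1
    under the no-mortality-effect sensitivity switch).
    """

    sex: str
    birth_years: np.ndarray
    ages: np.ndarray
    a01: np.ndarray
    a02: np.ndarray
    a12: np.ndarray
    a01_0: np.ndarray
    a02_0: np.ndarray
    a12_0: np.ndarray
    theta01: float
    theta_mort: np.ndarray

    __eq__ = _dataclass_eq

    def index_of(self, birth_year: int) -> int:
        idx = int(np.searchsorted(self.birth_years, birth_year))
        if idx >= self.birth_years.size or self.birth_years[idx] != birth_year:
            raise KeyError(f"cohort {birth_year} not in transition set")
        return idx

    def reconstruct_population_average(self, p_nd: np.ndarray, p_d: np.ndarray):
        """Population-average rates implied by the unexposed baselines.

        Returns the mixture ``P * rate0 * theta + (1 - P) * rate0`` for the
        three transitions; used by tests to assert the calibration identity.
        """
        r01 = self.a01_0 * (1.0 + p_nd * (self.theta01 - 1.0))
        r02 = self.a02_0 * (1.0 + p_nd * (self.theta_mort - 1.0))
        r12 = self.a12_0 * (1.0 + p_d * (self.theta_mort - 1.0))
        return r01, r02, r12


def apply_incidence_trend(
    base_incidence: np.ndarray,
    birth_year: int,
    trend_rate: float,
    reference_birth_year: int = 1915,
) -> np.ndarray:
    """Dementia incidence for one birth cohort under the generational trend.

    The reference-generation curve is multiplied by
    ``(1 - trend_rate) ** (birth_year - reference_birth_year)``; cohorts born
    before the reference generation get a factor above one.
    """
    if not 0.0 <= trend_rate < 1.0:
        raise ValueError("trend_rate must be in [0, 1)")
    factor = (1.0 - trend_rate) ** (birth_year - reference_birth_year)
    return np.asarray(base_incidence, dtype=float) * factor


def solve_unexposed_rate(pop_average_rate, exposure_prev, theta):
    """Invert the exposure mixture: unexposed rate given the population average.

    Solves ``rate = P * rate0 * theta + (1 - P) * rate0`` for ``rate0``; the
    exposed rate is ``rate0 * theta``.
    """
    prev = np.asarray(exposure_prev, dtype=float)
    if np.any(prev < 0) or np.any(prev > 1):
        raise ValueError("exposure prevalence must be in [0, 1]")
    if np.any(np.asarray(theta) <= 0):
        raise ValueError("theta must be > 0")
    out = np.asarray(pop_average_rate, dtype=float) / (1.0 + prev * (np.asarray(theta) - 1.0))
    return float(out) if out.ndim == 0 else out


def split_overall_mortality(
    overall_mortality: np.ndarray,
    dementia_incidence: np.ndarray,
    rr: np.ndarray,
) -> tuple:
    """Split one cohort's overall mortality into non-demented/demented strata.

    ``overall_mortality``, ``dementia_incidence`` and ``rr`` are aligned
    per-age arrays along the cohort diagonal.  Starting from zero dementia
    prevalence at the first age (cohorts enter non-demented), each age solves
    ``mu = (1 - pi) * a02 + pi * RR * a02`` for ``a02``, sets
    ``a12 = RR * a02``, then advances the prevalence of dementia among the
    alive by one year using the same one-year transition probabilities the
    simulation engine uses (death decided before dementia onset within the
    year).  By construction ``(1 - pi) * a02 + pi * a12`` reproduces the input
    overall mortality at every age.
    """
    mu = np.asarray(overall_mortality, dtype=float)
    a01 = np.asarray(dementia_incidence, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("RR(a) must be > 0")
    if np.any(mu < 0) or np.any(~np.isfinite(mu)):
        raise ValueError("overall mortality must be finite and nonnegative")

    n = mu.size
    a02 = np.empty(n)
    a12 = np.empty(n)
    pi = 0.0
    for i in range(n):
        a02[i] = mu[i] / (1.0 - pi + pi * rr[i])
        a12[i] = rr[i] * a02[i]
        q02 = -np.expm1(-a02[i])
        q12 = -np.expm1(-a12[i])
        q01 = -np.expm1(-a01[i])
        alive_nd = (1.0 - pi) * (1.0 - q02) * (1.0 - q01)
        alive_d = pi * (1.0 - q12) + (1.0 - pi) * (1.0 - q02) * q01
        total = alive_nd + alive_d
        pi = alive_d / total if total > 0 else 1.0
    return a02, a12


def build_transition_set(
    bundle: InputBundle,
    sex: str,
    birth_years: np.ndarray,
    prevalence=None,
    scenario: ScenarioSpec | None = None,
) -> TransitionIntensitySet:
    """Assemble the full per-cohort transition intensity set for one sex.

    ``prevalence`` is an object exposing ``p_nd`` and ``p_d`` arrays of shape
    ``(n_cohorts, n_ages)`` (the exposure prevalence among alive non-demented
    and demented subjects, typically estimated from a first simulation pass);
    ``None`` means all-zero prevalence, under which the unexposed baselines
    equal the population-average intensities.
    """
    birth_years = np.asarray(birth_years, dtype=int)
    ages = bundle.grid.ages
    nb, na = birth_years.size, ages.size

    trend = bundle.trend_rate
    no_mort_effect = False
    if scenario is not None:
        if scenario.no_trend:
            trend = 0.0
        no_mort_effect = scenario.no_mortality_effect

    theta01 = float(bundle.effects.theta01)
    theta_mort = (
        np.ones(na) if no_mort_effect else bundle.effects.theta_mort_at(ages)
    )

    if prevalence is None:
        p_nd = np.zeros((nb, na))
        p_d = np.zeros((nb, na))
    else:
        p_nd = np.asarray(prevalence.p_nd, dtype=float)
        p_d = np.asarray(prevalence.p_d, dtype=float)
        if p_nd.shape != (nb, na) or p_d.shape != (nb, na):
            raise ValueError("prevalence surfaces do not match (cohorts, ages) shape")

    base_inc = bundle.dementia_incidence[sex].values
    rr = bundle.rr_death[sex].values
    mort = bundle.overall_mortality[sex]

    a01 = np.empty((nb, na))
    a02 = np.empty((nb, na))
    a12 = np.empty((nb, na))
    for i, b in enumerate(birth_years):
        a01[i] = apply_incidence_trend(base_inc, int(b), trend, bundle.reference_birth_year)
        mu = mort.cohort_rates(int(b))
        a02[i], a12[i] = split_overall_mortality(mu, a01[i], rr)

    a01_0 = solve_unexposed_rate(a01, p_nd, theta01)
    a02_0 = solve_unexposed_rate(a02, p_nd, theta_mort)
    a12_0 = solve_unexposed_rate(a12, p_d, theta_mort)

    return TransitionIntensitySet(
        sex=sex,
        birth_years=birth_years,
        ages=ages,
        a01=a01,
        a02=a02,
        a12=a12,
        a01_0=a01_0,
        a02_0=a02_0,
        a12_0=a12_0,
        theta01=theta01,
        theta_mort=theta_mort,
    )
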