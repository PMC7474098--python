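"""Empirical burden indicators computed from simulated life histories.

All indicators refer to a target calendar year (default 2040).  Prevalence is
cross-sectional: at each age ``a`` it pools the cohort born in
``target_year - a``, weighting simulated subjects up to population size.
The cohort-style indicators (lifelong probability of dementia, life
expectancy without dementia, mean age at onset, mean years lived with
dementia) follow the single cohort reaching 65 in the target year through the
rest of its life, under that cohort's own projected future rates — they are
cohort quantities, not period (Sullivan-type) ones.

Discrete-time conventions: a subject's status at an (attained) age reflects
all events recorded at or before that age; life expectancy counts whole
person-years with no half-year continuity correction; years with dementia are
truncated at age 99.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import NEVER, TrajectoryPanel

__all__ = [
    "PrevalenceResult",
    "prevalence",
    "lifelong_probability",
    "life_expectancy_without_dementia",
    "mean_age_at_dementia",
    "mean_years_with_dementia",
    "exposure_prevalence_by_age",
    "panel_indicators",
    "SCALAR_AGE",
]

#: sentinel used in tidy indicator frames for age-independent indicators
SCALAR_AGE = -1


def _cohort(panel: TrajectoryPanel, birth_year: int) -> np.ndarray:
    m = panel.cohort_mask(birth_year)
    if not m.any():
        raise ValueError(f"cohort born {birth_year} absent from panel ({panel.sex})")
    return m


@dataclass
class PrevalenceResult:
    """Weighted cross-sectional dementia prevalence in the target year."""

    ages: np.ndarray
    counts: np.ndarray  # weighted demented count per age
    alive: np.ndarray  # weighted alive count per age
    total_count: float
    rate_pct: float


def prevalence(
    panel: TrajectoryPanel, target_year: int, age_range=(65, 99)
) -> PrevalenceResult:
    """Weighted count of alive demented subjects by age, plus the total rate.

    At age ``a`` the contributing cohort is the one born ``target_year - a``;
    the rate is weighted demented over weighted alive across the age range,
    in percent.
    """
    ages = np.arange(age_range[0], age_range[1] + 1)
    counts = np.empty(ages.size)
    alive_w = np.empty(ages.size)
    for j, a in enumerate(ages):
        m = _cohort(panel, target_year - int(a))
        w = panel.weight[m]
        alive = panel.alive_at(int(a))[m]
        dem = panel.demented_at(int(a))[m]
        counts[j] = w[alive & dem].sum()
        alive_w[j] = w[alive].sum()
    total = counts.sum()
    return PrevalenceResult(
        ages=ages,
        counts=counts,
        alive=alive_w,
        total_count=float(total),
        rate_pct=float(100.0 * total / alive_w.sum()),
    )


def lifelong_probability(panel: TrajectoryPanel, target_year: int) -> float:
    """% of the cohort aged 65 in the target year developing dementia before death."""
    m = _cohort(panel, target_year - panel.start_age)
    return float(100.0 * np.mean(panel.age_at_dementia[m] != NEVER))


def life_expectancy_without_dementia(
    panel: TrajectoryPanel, age: int, target_year: int
) -> float:
    """Expected years lived free of dementia after ``age`` in the target year.

    Conditions on being alive and non-demented at ``age`` in the cohort aged
    ``age`` in the target year, and counts the later annual steps at which the
    subject is still alive and non-demented (whole years, capped at 105).
    """
    m = _cohort(panel, target_year - int(age))
    alive = panel.alive_at(int(age))[m]
    nondem = ~panel.demented_at(int(age))[m]
    qual = alive & nondem
    if not qual.any():
        raise ValueError(
            f"no subjects alive and non-demented at age {age} ({panel.sex})"
        )
    dem = panel.age_at_dementia[m][qual]
    death = panel.age_at_death[m][qual]
    last_nd = np.minimum(
        np.where(dem == NEVER, panel.end_age, dem - 1),
        np.where(death == NEVER, panel.end_age, death - 1),
    )
    return float(np.mean(last_nd - int(age)))


def mean_age_at_dementia(panel: TrajectoryPanel, target_year: int) -> float:
    """Mean onset age among demented subjects of the cohort aged 65 in the target year.

    ``nan`` when the cohort has no dementia case.
    """
    m = _cohort(panel, target_year - panel.start_age)
    onsets = panel.age_at_dementia[m]
    onsets = onsets[onsets != NEVER]
    if onsets.size == 0:
        return float("nan")
    return float(onsets.mean())


def mean_years_with_dementia(
    panel: TrajectoryPanel, target_year: int, cap: int = 99
) -> float:
    """Mean years lived with dementia up to age ``cap``, per subject healthy at 65.

    Averages over the whole cohort aged 65 in the target year, never-demented
    subjects contributing zero.
    """
    m = _cohort(panel, target_year - panel.start_age)
    dem = panel.age_at_dementia[m].astype(float)
    death = panel.age_at_death[m].astype(float)
    end = np.minimum(np.where(death == NEVER, panel.end_age, death), cap + 1)
    years = np.where(dem == NEVER, 0.0, np.maximum(0.0, end - dem))
    return float(years.mean())


def mean_years_with_dementia_conditional(
    panel: TrajectoryPanel, target_year: int, cap: int = 99
) -> float:
    """Variant conditional on developing dementia (not the headline indicator)."""
    m = _cohort(panel, target_year - panel.start_age)
    dem = panel.age_at_dementia[m].astype(float)
    death = panel.age_at_death[m].astype(float)
    has = dem != NEVER
    if not has.any():
        return float("nan")
    end = np.minimum(np.where(death == NEVER, panel.end_age, death), cap + 1)
    years = np.maximum(0.0, end - dem)[has]
    return float(years.mean())


def exposure_prevalence_by_age(
    panel: TrajectoryPanel, target_year: int, age_range=(65, 99)
) -> pd.Series:
    """% ever chronically exposed among alive subjects, by age in the target year."""
    ages = np.arange(age_range[0], age_range[1] + 1)
    out = np.empty(ages.size)
    for j, a in enumerate(ages):
        m = _cohort(panel, target_year - int(a))
        alive = panel.alive_at(int(a))[m]
        exposed = panel.exposed_at(int(a))[m]
        out[j] = 100.0 * exposed[alive].sum() / alive.sum() if alive.any() else np.nan
    return pd.Series(out, index=ages, name="exposure_prevalence")


def panel_indicators(
    panel: TrajectoryPanel,
    target_year: int,
    age_range=(65, 99),
    le_ages=None,
) -> pd.DataFrame:
    """Tidy frame of every indicator for one sex/scenario panel.

    Columns: ``indicator``, ``age`` (``SCALAR_AGE`` for age-independent
    indicators) and ``value``.  Ages at which an indicator is undefined (e.g.
    no alive non-demented subject left) yield ``nan``.
    """
    if le_ages is None:
        le_ages = np.arange(65, 101)
    prev = prevalence(panel, target_year, age_range)
    rows = [
        pd.DataFrame(
            {"indicator": "prevalence_count", "age": prev.ages, "value": prev.counts}
        ),
    ]
    expo = exposure_prevalence_by_age(panel, target_year, age_range)
    rows.append(
        pd.DataFrame(
            {
                "indicator": "exposure_prevalence",
                "age": expo.index.to_numpy(),
                "value": expo.to_numpy(),
            }
        )
    )
    le_vals = []
    for a in le_ages:
        try:
            le_vals.append(life_expectancy_without_dementia(panel, int(a), target_year))
        except ValueError:
            le_vals.append(np.nan)
    rows.append(
        pd.DataFrame(
            {
                "indicator": "le_without_dementia",
                "age": np.asarray(le_ages, dtype=int),
                "value": le_vals,
            }
        )
    )
    scalars = {
        "prevalence_count_total": prev.total_count / 1e3,  # thousands
        "prevalence_rate": prev.rate_pct,
        "lifelong_probability": lifelong_probability(panel, target_year),
        "le_without_dementia_at_65": life_expectancy_without_dementia(
            panel, panel.start_age, target_year
        ),
        "mean_age_at_dementia": mean_age_at_dementia(panel, target_year),
        "mean_years_with_dementia": mean_years_with_dementia(panel, target_year),
    }
    rows.append(
        pd.DataFrame(
            {
                "indicator": list(scalars),
                "age": SCALAR_AGE,
                "value": list(scalars.values()),
            }
        )
    )
    return pd.concat(rows, ignore_index=True)
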