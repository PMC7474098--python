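"""Shared test utilities: toy transition sets and empirical occupancy tables."""
import numpy as np

from demproj import (
    ExposureInputs,
    HazardSurface,
    Prev65,
    TrajectoryPanel,
    TransitionIntensitySet,
)

AGES = np.arange(65, 106)


def toy_setup(
    a01=0.0,
    a02=0.0,
    a12=0.0,
    theta01=1.0,
    theta_mort=1.0,
    prev65=0.0,
    bzd_inc=0.0,
    birth_year=1975,
    sex="female",
    ages=AGES,
):
    """A single-cohort transition set + exposure inputs with given intensities.

    Scalar arguments are broadcast over ages; array arguments must have one
    value per age.  The population-average and unexposed intensities are set
    equal (the engine only reads the unexposed ones outside effect-free mode).
    """
    ages = np.asarray(ages)
    na = ages.size

    def row(x):
        x = np.asarray(x, dtype=float)
        return np.full((1, na), float(x)) if x.ndim == 0 else x.reshape(1, na)

    tset = TransitionIntensitySet(
        sex=sex,
        birth_years=np.array([birth_year]),
        ages=ages,
        a01=row(a01),
        a02=row(a02),
        a12=row(a12),
        a01_0=row(a01),
        a02_0=row(a02),
        a12_0=row(a12),
        theta01=float(theta01),
        theta_mort=(
            np.full(na, float(theta_mort))
            if np.isscalar(theta_mort)
            else np.asarray(theta_mort, dtype=float)
        ),
    )
    inc = np.asarray(bzd_inc, dtype=float)
    inc = np.full(na, float(inc)) if inc.ndim == 0 else inc
    exposure = ExposureInputs(
        prev65={sex: Prev65(prev65, prev65, prev65)},
        incidence={sex: HazardSurface(sex, "bzd_incidence", ages, inc)},
    )
    return tset, exposure


def panel_from_cohort(sim: dict, birth_year=1975, sex="female", ages=AGES):
    """Wrap simulate_cohort output arrays into a unit-weight TrajectoryPanel."""
    n = sim["age_at_dementia"].size
    return TrajectoryPanel(
        sex=sex,
        birth_year=np.full(n, birth_year, dtype=np.int32),
        age_at_exposure=sim["age_at_exposure"],
        age_at_dementia=sim["age_at_dementia"],
        age_at_death=sim["age_at_death"],
        weight=np.ones(n),
        start_age=int(ages[0]),
        end_age=int(ages[-1]),
    )


def empirical_occupancy(panel: TrajectoryPanel, ages=AGES):
    """Fractions of subjects per joint state and age, matching OccupancyTable."""
    n = panel.n
    occ = np.zeros((len(ages), 5))
    for j, a in enumerate(ages):
        alive = panel.alive_at(int(a))
        dem = panel.demented_at(int(a))
        exp = panel.exposed_at(int(a))
        occ[j, 0] = np.sum(alive & ~dem & ~exp) / n
        occ[j, 1] = np.sum(alive & ~dem & exp) / n
        occ[j, 2] = np.sum(alive & dem & ~exp) / n
        occ[j, 3] = np.sum(alive & dem & exp) / n
        occ[j, 4] = np.sum(~alive) / n
    return occ
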