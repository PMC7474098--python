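"""Input rate tables for the dementia projection model.

The projection is driven entirely by population-average rate tables: dementia
incidence by age (for a reference generation), the age-specific relative risk
of death for demented versus non-demented subjects, overall mortality by age
and calendar year, the size of the population reaching age 65 each year, and
the incidence and age-65 prevalence of the chronic exposure (benzodiazepine
use for six consecutive months or more).  This module defines the in-memory
containers for those tables, CSV/YAML readers and writers, and the validation
that guarantees a bundle can be projected without any runtime lookup failure.

Conventions
-----------
* All hazards are continuous-time intensities in units of events per
  person-year; conversion to annual probabilities (``1 - exp(-rate)``) happens
  only inside the simulation engine.
* Grids are annual and exact-match: no interpolation is ever performed.
* Standard errors are stored on the log-rate scale for hazards and implied on
  the logit scale (via the confidence interval) for the age-65 exposure
  prevalence, so that resampled parameter draws stay positive / within [0, 1].
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SEXES = ("female", "male")

__all__ = [
    "SEXES",
    "AgeGrid",
    "BundleValidationError",
    "HazardSurface",
    "RelativeRiskCurve",
    "ExposureEffect",
    "Prev65",
    "ExposureInputs",
    "PopulationAt65",
    "InputBundle",
    "load_input_bundle",
    "save_input_bundle",
]


class BundleValidationError(ValueError):
    """An input table failed validation.

    The message names the offending table and cell(s); ``missing_ages`` holds
    the sorted list of absent ages when the failure is an age-coverage gap.
    """

    def __init__(self, message: str, missing_ages: list[int] | None = None):
        super().__init__(message)
        self.missing_ages = missing_ages


def _eq(a, b) -> bool:
    """Field-wise equality that understands numpy arrays and nested containers."""
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        return (
            isinstance(a, np.ndarray)
            and isinstance(b, np.ndarray)
            and a.shape == b.shape
            and np.array_equal(a, b)
        )
    if isinstance(a, dict) and isinstance(b, dict):
        return a.keys() == b.keys() and all(_eq(a[k], b[k]) for k in a)
    if isinstance(a, (list, tuple)) and isinstance(b, (list, tuple)):
        return len(a) == len(b) and all(_eq(x, y) for x, y in zip(a, b))
    return a == b


def _dataclass_eq(self, other) -> bool:
    if other.__class__ is not self.__class__:
        return NotImplemented
    return all(
        _eq(getattr(self, f.name), getattr(other, f.name))
        for f in dataclasses.fields(self)
    )


@dataclass(frozen=True)
class AgeGrid:
    """Annual integer age grid spanned by the simulation (default 65-105)."""

    start_age: int = 65
    end_age: int = 105

    def __post_init__(self):
        if not (
            isinstance(self.start_age, (int, np.integer))
            and isinstance(self.end_age, (int, np.integer))
        ):
            raise TypeError("AgeGrid bounds must be integers")
        if self.start_age >= self.end_age:
            raise ValueError("start_age must be < end_age")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.start_age, self.end_age + 1)

    @property
    def n_ages(self) -> int:
        return self.end_age - self.start_age + 1

    def index(self, age: int) -> int:
        if not self.start_age <= age <= self.end_age:
            raise KeyError(f"age {age} outside grid [{self.start_age}, {self.end_age}]")
        return int(age) - self.start_age


@dataclass(eq=False)
class HazardSurface:
    """A nonnegative rate per person-year indexed by age (and optionally year).

    ``values`` has shape ``(n_ages,)`` for age-only surfaces and
    ``(n_ages, n_years)`` for age-by-calendar-year surfaces.  ``se_log`` is an
    optional per-age standard error on the log-rate scale.
    """

    sex: str
    quantity: str
    ages: np.ndarray
    values: np.ndarray
    years: np.ndarray | None = None
    se_log: np.ndarray | None = None

    __eq__ = _dataclass_eq

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years is not None:
            self.years = np.asarray(self.years, dtype=int)
            if self.values.shape != (self.ages.size, self.years.size):
                raise BundleValidationError(
                    f"{self.quantity}[{self.sex}]: values shape {self.values.shape} "
                    f"does not match (n_ages={self.ages.size}, n_years={self.years.size})"
                )
        elif self.values.shape != (self.ages.size,):
            raise BundleValidationError(
                f"{self.quantity}[{self.sex}]: values shape {self.values.shape} "
                f"does not match n_ages={self.ages.size}"
            )
        if self.se_log is not None:
            self.se_log = np.asarray(self.se_log, dtype=float)

    # -- lookup ---------------------------------------------------------------

    def rate_at(self, age: int, year: int | None = None) -> float:
        """Exact cell lookup (no interpolation); raises on out-of-grid access."""
        idx = np.searchsorted(self.ages, age)
        if idx >= self.ages.size or self.ages[idx] != age:
            raise KeyError(
                f"{self.quantity}[{self.sex}]: age {age} outside grid "
                f"[{self.ages[0]}, {self.ages[-1]}]"
            )
        if self.years is None:
            return float(self.values[idx])
        if year is None:
            raise KeyError(f"{self.quantity}[{self.sex}] is year-dependent: year required")
        jdx = np.searchsorted(self.years, year)
        if jdx >= self.years.size or self.years[jdx] != year:
            raise KeyError(
                f"{self.quantity}[{self.sex}]: year {year} outside grid "
                f"[{self.years[0]}, {self.years[-1]}]"
            )
        return float(self.values[idx, jdx])

    def cohort_rates(self, birth_year: int) -> np.ndarray:
        """Rates along a cohort diagonal ``(a, birth_year + a)`` for all grid ages.

        Calendar years outside the stored range are clamped to the nearest
        available year (the last projection year is carried forward), so a
        cohort can be followed past the end of the mortality projection.
        """
        if self.years is None:
            return self.values.copy()
        t = np.clip(birth_year + self.ages, self.years[0], self.years[-1])
        return self.values[np.arange(self.ages.size), t - self.years[0]]

    # -- validation -----------------------------------------------------------

    def validate(self, grid: AgeGrid) -> None:
        name = f"{self.quantity}[{self.sex}]"
        missing = sorted(set(grid.ages.tolist()) - set(self.ages.tolist()))
        if missing:
            raise BundleValidationError(
                f"{name}: missing ages {missing[0]}-{missing[-1]} "
                f"(absent cells: {missing})",
                missing_ages=missing,
            )
        bad = np.argwhere(np.isnan(self.values))
        if bad.size:
            raise BundleValidationError(f"{name}: NaN rate at {self._cell(bad[0])}")
        bad = np.argwhere(self.values < 0)
        if bad.size:
            raise BundleValidationError(f"{name}: negative rate at {self._cell(bad[0])}")
        if self.se_log is not None and (
            np.any(np.isnan(self.se_log)) or np.any(self.se_log < 0)
        ):
            raise BundleValidationError(f"{name}: se_log must be nonnegative and finite")
        if self.years is not None and np.any(np.diff(self.years) != 1):
            raise BundleValidationError(f"{name}: calendar years must be contiguous")
        if np.any(np.diff(self.ages) != 1):
            raise BundleValidationError(f"{name}: ages must be contiguous")

    def _cell(self, idx) -> str:
        if self.years is None:
            return f"sex={self.sex}, age={self.ages[idx[0]]}"
        return f"sex={self.sex}, age={self.ages[idx[0]]}, year={self.years[idx[1]]}"


@dataclass(eq=False)
class RelativeRiskCurve:
    """Age-specific relative risk of death for demented vs non-demented, RR(a)."""

    sex: str
    ages: np.ndarray
    values: np.ndarray
    se_log: np.ndarray | None = None

    __eq__ = _dataclass_eq

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.se_log is not None:
            self.se_log = np.asarray(self.se_log, dtype=float)

    def validate(self, grid: AgeGrid) -> None:
        missing = sorted(set(grid.ages.tolist()) - set(self.ages.tolist()))
        if missing:
            raise BundleValidationError(
                f"rr_death[{self.sex}]: missing ages {missing[0]}-{missing[-1]}",
                missing_ages=missing,
            )
        if np.any(np.isnan(self.values)) or np.any(self.values < 0):
            raise BundleValidationError(
                f"rr_death[{self.sex}]: RR(a) must be nonnegative and finite"
            )


#: Default mortality relative risks for exposed subjects, piecewise-constant by
#: five-year age band and identical for demented and non-demented subjects.
DEFAULT_THETA_MORT_BANDS = (
    (65.0, 70.0, 2.45),
    (70.0, 75.0, 1.69),
    (75.0, 80.0, 1.30),
    (80.0, 85.0, 1.10),
    (85.0, math.inf, 1.00),
)


@dataclass(eq=False)
class ExposureEffect:
    """Relative risks attached to the irreversible chronic-use exposure.

    ``theta01`` multiplies dementia incidence for ever-exposed subjects;
    ``theta_mort_bands`` gives the mortality relative risk (same for demented
    and non-demented strata) as ``(age_from, age_to, value)`` bands that
    partition [65, inf).
    """

    theta01: float = 1.6
    theta_mort_bands: tuple = DEFAULT_THETA_MORT_BANDS

    __eq__ = _dataclass_eq

    def theta_mort_at(self, ages) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        out = np.full(ages.shape, np.nan)
        for lo, hi, val in self.theta_mort_bands:
            out[(ages >= lo) & (ages < hi)] = val
        if np.any(np.isnan(out)):
            raise BundleValidationError(
                "effects: theta_mort bands do not cover all requested ages"
            )
        return out

    def validate(self) -> None:
        if self.theta01 <= 0:
            raise BundleValidationError("effects: theta01 must be > 0")
        bands = sorted(self.theta_mort_bands)
        if not bands or bands[0][0] > 65 or not math.isinf(bands[-1][1]):
            raise BundleValidationError("effects: theta_mort bands must cover [65, inf)")
        for (lo1, hi1, v1), (lo2, _hi2, _v2) in zip(bands, bands[1:]):
            if hi1 != lo2:
                raise BundleValidationError(
                    f"effects: theta_mort bands must be contiguous (gap at {hi1})"
                )
        if any(v <= 0 for _, _, v in bands):
            raise BundleValidationError("effects: theta_mort values must be > 0")


@dataclass(eq=False)
class Prev65:
    """Prevalence of chronic use at age 65 with its 95% confidence interval."""

    prev: float
    ci_low: float
    ci_high: float

    __eq__ = _dataclass_eq

    def validate(self, sex: str) -> None:
        if not 0.0 <= self.prev <= 1.0:
            raise BundleValidationError(f"bzd_prev65[{sex}]: prev must be in [0, 1]")
        if not (0.0 <= self.ci_low <= self.prev <= self.ci_high <= 1.0):
            raise BundleValidationError(
                f"bzd_prev65[{sex}]: CI must satisfy 0 <= low <= prev <= high <= 1"
            )


@dataclass(eq=False)
class ExposureInputs:
    """Exposure process inputs: prevalence at 65 and incidence of chronic use."""

    prev65: dict
    incidence: dict

    __eq__ = _dataclass_eq

    def validate(self, grid: AgeGrid) -> None:
        for sex in SEXES:
            if sex not in self.prev65 or sex not in self.incidence:
                raise BundleValidationError(f"exposure inputs missing sex '{sex}'")
            self.prev65[sex].validate(sex)
            self.incidence[sex].validate(grid)


@dataclass(eq=False)
class PopulationAt65:
    """Population size at age 65 by sex and calendar year of the 65th birthday."""

    years: np.ndarray
    size: dict

    __eq__ = _dataclass_eq

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.size = {s: np.asarray(v, dtype=float) for s, v in self.size.items()}

    def size_at(self, sex: str, year: int) -> float:
        idx = np.searchsorted(self.years, year)
        if idx >= self.years.size or self.years[idx] != year:
            raise KeyError(
                f"pop65[{sex}]: year {year} outside coverage "
                f"[{self.years[0]}, {self.years[-1]}]"
            )
        return float(self.size[sex][idx])

    def validate(self) -> None:
        if np.any(np.diff(self.years) != 1):
            raise BundleValidationError("pop65: years must be contiguous")
        for sex in SEXES:
            if sex not in self.size:
                raise BundleValidationError(f"pop65 missing sex '{sex}'")
            v = self.size[sex]
            if v.shape != self.years.shape:
                raise BundleValidationError(f"pop65[{sex}]: size/year length mismatch")
            if np.any(np.isnan(v)) or np.any(v <= 0):
                bad = int(np.argwhere(~(v > 0))[0][0])
                raise BundleValidationError(
                    f"pop65[{sex}]: nonpositive size at year={self.years[bad]}"
                )


@dataclass(eq=False)
class InputBundle:
    """All calibrated inputs required for one projection (both sexes).

    The dementia incidence curves are on the reference-generation scale (the
    generation aged ``reference_age`` in ``reference_year``); the generational
    trend ``trend_rate`` rescales them per birth cohort.
    """

    dementia_incidence: dict
    rr_death: dict
    overall_mortality: dict
    pop65: PopulationAt65
    exposure: ExposureInputs
    effects: ExposureEffect
    trend_rate: float = 0.01
    reference_age: int = 75
    reference_year: int = 1990
    grid: AgeGrid = AgeGrid()

    __eq__ = _dataclass_eq

    @property
    def reference_birth_year(self) -> int:
        return self.reference_year - self.reference_age

    def validate(self) -> "InputBundle":
        if not 0.0 <= self.trend_rate < 1.0:
            raise BundleValidationError("trend_rate must be in [0, 1)")
        for sex in SEXES:
            for table, name in (
                (self.dementia_incidence, "dementia_incidence"),
                (self.rr_death, "rr_death"),
                (self.overall_mortality, "overall_mortality"),
            ):
                if sex not in table:
                    raise BundleValidationError(f"{name} missing sex '{sex}'")
            self.dementia_incidence[sex].validate(self.grid)
            self.rr_death[sex].validate(self.grid)
            surf = self.overall_mortality[sex]
            if surf.years is None:
                raise BundleValidationError(
                    f"overall_mortality[{sex}] must be indexed by calendar year"
                )
            surf.validate(self.grid)
        self.pop65.validate()
        self.exposure.validate(self.grid)
        self.effects.validate()
        return self


# -- CSV / YAML round trip ----------------------------------------------------

_FILES = {
    "dementia_incidence": "dementia_incidence.csv",
    "rr_death": "rr_death.csv",
    "overall_mortality": "overall_mortality.csv",
    "pop65": "pop65.csv",
    "bzd_incidence": "bzd_incidence.csv",
    "bzd_prev65": "bzd_prev65.csv",
    "effects": "effects.yaml",
}
_FLOAT_FMT = "%.17g"  # exact float64 round trip


def _read_csv(directory: Path, key: str) -> pd.DataFrame:
    path = directory / _FILES[key]
    if not path.exists():
        raise BundleValidationError(f"missing input file: {path}")
    return pd.read_csv(path, float_precision="round_trip")


def _age_surface(df: pd.DataFrame, sex: str, quantity: str, value_col: str) -> tuple:
    sub = df[df["sex"] == sex].sort_values("age")
    if sub.empty:
        raise BundleValidationError(f"{quantity}: no rows for sex '{sex}'")
    se = sub["se_log"].to_numpy() if "se_log" in sub.columns else None
    return sub["age"].to_numpy(int), sub[value_col].to_numpy(float), se


def load_input_bundle(path, config=None) -> InputBundle:
    """Load and validate a full input bundle from a directory of CSV tables.

    ``config`` optionally overrides ``effects.yaml`` with an already-parsed
    mapping (same keys).  Every surface must be complete on its grid; units
    are rates per person-year.
    """
    directory = Path(path)
    inc_df = _read_csv(directory, "dementia_incidence")
    rr_df = _read_csv(directory, "rr_death")
    mort_df = _read_csv(directory, "overall_mortality")
    pop_df = _read_csv(directory, "pop65")
    bzd_df = _read_csv(directory, "bzd_incidence")
    prev_df = _read_csv(directory, "bzd_prev65")
    if config is None:
        eff_path = directory / _FILES["effects"]
        if not eff_path.exists():
            raise BundleValidationError(f"missing input file: {eff_path}")
        with open(eff_path) as fh:
            config = yaml.safe_load(fh)

    dementia, rr, mortality, bzd_inc, prev65 = {}, {}, {}, {}, {}
    for sex in SEXES:
        ages, vals, se = _age_surface(inc_df, sex, "dementia_incidence", "rate")
        dementia[sex] = HazardSurface(sex, "dementia_incidence", ages, vals, se_log=se)
        ages, vals, se = _age_surface(rr_df, sex, "rr_death", "rr")
        rr[sex] = RelativeRiskCurve(sex, ages, vals, se_log=se)
        ages, vals, se = _age_surface(bzd_df, sex, "bzd_incidence", "rate")
        bzd_inc[sex] = HazardSurface(sex, "bzd_incidence", ages, vals, se_log=se)

        sub = mort_df[mort_df["sex"] == sex]
        if sub.empty:
            raise BundleValidationError(f"overall_mortality: no rows for sex '{sex}'")
        pivot = sub.pivot(index="age", columns="year", values="rate").sort_index()
        if pivot.isna().any().any():
            a = pivot.index[pivot.isna().any(axis=1)][0]
            y = pivot.columns[pivot.isna().any(axis=0)][0]
            raise BundleValidationError(
                f"overall_mortality[{sex}]: missing cell at sex={sex}, age={a}, year={y}"
            )
        mortality[sex] = HazardSurface(
            sex,
            "overall_mortality",
            pivot.index.to_numpy(int),
            pivot.to_numpy(float),
            years=pivot.columns.to_numpy(int),
        )

        row = prev_df[prev_df["sex"] == sex]
        if row.empty:
            raise BundleValidationError(f"bzd_prev65: no row for sex '{sex}'")
        prev65[sex] = Prev65(
            float(row["prev"].iloc[0]),
            float(row["ci_low"].iloc[0]),
            float(row["ci_high"].iloc[0]),
        )

    pop_pivot = pop_df.pivot(index="year", columns="sex", values="size").sort_index()
    pop65 = PopulationAt65(
        pop_pivot.index.to_numpy(int),
        {sex: pop_pivot[sex].to_numpy(float) for sex in SEXES},
    )

    effects = ExposureEffect(
        theta01=float(config["theta01"]),
        theta_mort_bands=tuple(
            (float(b["from"]), float(b["to"]), float(b["value"]))
            for b in config["theta_mort"]
        ),
    )
    reference = config.get("reference", {})
    bundle = InputBundle(
        dementia_incidence=dementia,
        rr_death=rr,
        overall_mortality=mortality,
        pop65=pop65,
        exposure=ExposureInputs(prev65=prev65, incidence=bzd_inc),
        effects=effects,
        trend_rate=float(config.get("trend_rate", 0.01)),
        reference_age=int(reference.get("age", 75)),
        reference_year=int(reference.get("year", 1990)),
    )
    return bundle.validate()


def save_input_bundle(bundle: InputBundle, path) -> Path:
    """Write a bundle to a directory of CSV tables plus ``effects.yaml``."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)

    def _age_frame(surfaces, value_col):
        rows = []
        for sex in SEXES:
            s = surfaces[sex]
            se = s.se_log if s.se_log is not None else np.zeros(s.ages.size)
            rows.append(
                pd.DataFrame(
                    {"sex": sex, "age": s.ages, value_col: s.values, "se_log": se}
                )
            )
        return pd.concat(rows, ignore_index=True)

    _age_frame(bundle.dementia_incidence, "rate").to_csv(
        directory / _FILES["dementia_incidence"], index=False, float_format=_FLOAT_FMT
    )
    _age_frame(bundle.rr_death, "rr").to_csv(
        directory / _FILES["rr_death"], index=False, float_format=_FLOAT_FMT
    )
    _age_frame(bundle.exposure.incidence, "rate").to_csv(
        directory / _FILES["bzd_incidence"], index=False, float_format=_FLOAT_FMT
    )

    rows = []
    for sex in SEXES:
        s = bundle.overall_mortality[sex]
        aa, yy = np.meshgrid(s.ages, s.years, indexing="ij")
        rows.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "age": aa.ravel(),
                    "year": yy.ravel(),
                    "rate": s.values.ravel(),
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(
        directory / _FILES["overall_mortality"], index=False, float_format=_FLOAT_FMT
    )

    pd.concat(
        [
            pd.DataFrame(
                {"sex": sex, "year": bundle.pop65.years, "size": bundle.pop65.size[sex]}
            )
            for sex in SEXES
        ],
        ignore_index=True,
    ).to_csv(directory / _FILES["pop65"], index=False, float_format=_FLOAT_FMT)

    pd.DataFrame(
        [
            {
                "sex": sex,
                "prev": bundle.exposure.prev65[sex].prev,
                "ci_low": bundle.exposure.prev65[sex].ci_low,
                "ci_high": bundle.exposure.prev65[sex].ci_high,
            }
            for sex in SEXES
        ]
    ).to_csv(directory / _FILES["bzd_prev65"], index=False, float_format=_FLOAT_FMT)

    effects = {
        "theta01": float(bundle.effects.theta01),
        "theta_mort": [
            {"from": lo, "to": ("inf" if math.isinf(hi) else hi), "value": v}
            for lo, hi, v in bundle.effects.theta_mort_bands
        ],
        "trend_rate": float(bundle.trend_rate),
        "reference": {"age": bundle.reference_age, "year": bundle.reference_year},
    }
    with open(directory / _FILES["effects"], "w") as fh:
        yaml.safe_dump(effects, fh, sort_keys=False)
    return directory
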