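"""Model / results facade for the dementia burden projection.

``DementiaProjectionModel`` wraps a validated :class:`~demproj.rates_io.InputBundle`
(the calibrated population-average rate tables); ``fit`` runs the full
two-pass Monte Carlo projection — central run plus resampled runs for
confidence intervals — and returns a :class:`ProjectionResults` carrying the
tidy indicator tables, scenario differences, a ``summary()`` table and simple
diagnostic plots.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .indicators import SCALAR_AGE
from .rates_io import InputBundle, load_input_bundle
from .uncertainty import ProjectionTables, RunConfig, run_projection

__all__ = ["DementiaProjectionModel", "ProjectionResults"]

_SUMMARY_ROWS = [
    ("prevalence_count_total", "Prevalence ages 65-99 (thousands)", 0),
    ("prevalence_rate", "Prevalence rate ages 65-99 (%)", 1),
    ("lifelong_probability", "Lifelong probability of dementia at 65 (%)", 1),
    ("le_without_dementia_at_65", "Life expectancy w/o dementia at 65 (years)", 1),
    ("mean_age_at_dementia", "Mean age at dementia (years)", 1),
    ("mean_years_with_dementia", "Mean years with dementia, ages 65-99 (years)", 2),
]


class DementiaProjectionModel:
    """Illness-death Monte Carlo projection of dementia burden.

    The model couples a three-state illness-death process (non-demented,
    demented, dead) with an irreversible binary exposure (chronic
    benzodiazepine use) that multiplies dementia incidence by ``theta01`` and
    mortality by age-banded relative risks.  Cohorts born 1935-1975 are
    simulated year by year from age 65 to 105 and summarised into burden
    indicators for a target year under intervention scenarios on the
    incidence of chronic use.
    """

    def __init__(self, bundle: InputBundle):
        self.bundle = bundle.validate()

    @classmethod
    def from_directory(cls, path) -> "DementiaProjectionModel":
        """Build the model from a directory of CSV rate tables + effects.yaml."""
        return cls(load_input_bundle(path))

    @classmethod
    def from_synthetic(cls, spec=None, seed: int = 0) -> "DementiaProjectionModel":
        """Build the model from a synthetic (generated) input bundle."""
        from .synthetic import make_synthetic_bundle

        return cls(make_synthetic_bundle(spec, seed))

    def fit(
        self,
        scenarios=(0, 1, 2),
        target_year: int = 2040,
        n_per_cohort: int = 10_000,
        n_ci_runs: int = 100,
        seed: int = 0,
        level: float = 0.95,
        intervention_year: int = 2020,
        no_mortality_effect: bool = False,
        no_trend: bool = False,
        sexes=("female", "male"),
    ) -> "ProjectionResults":
        """Run the projection and return results with percentile CIs.

        ``n_ci_runs`` resampled projections feed the confidence intervals
        (set it below 2 for a central run only); scenario differences are
        paired within runs through shared parameter draws and common random
        numbers.
        """
        config = RunConfig(
            scenarios=tuple(scenarios),
            target_year=target_year,
            n_per_cohort=n_per_cohort,
            n_ci_runs=n_ci_runs,
            seed=seed,
            level=level,
            intervention_year=intervention_year,
            no_mortality_effect=no_mortality_effect,
            no_trend=no_trend,
            sexes=tuple(sexes),
        )
        tables = run_projection(self.bundle, config)
        return ProjectionResults(tables)


class ProjectionResults:
    """Fitted projection: indicator estimates, CIs, differences, summary."""

    def __init__(self, tables: ProjectionTables):
        self.indicators: pd.DataFrame = tables.indicators
        self.differences: pd.DataFrame = tables.differences
        self.config: RunConfig = tables.config
        self.n_runs: int = tables.n_runs

    # -- access ---------------------------------------------------------------

    def scalar(self, sex: str, scenario, indicator: str, column: str = "estimate"):
        """One age-independent indicator value (or CI bound) as a float."""
        table = self.differences if isinstance(scenario, str) else self.indicators
        row = table[
            (table["sex"] == sex)
            & (table["scenario"] == scenario)
            & (table["indicator"] == indicator)
            & (table["age"] == SCALAR_AGE)
        ]
        if row.empty:
            raise KeyError((sex, scenario, indicator))
        return float(row[column].iloc[0])

    def by_age(self, sex: str, scenario, indicator: str) -> pd.DataFrame:
        table = self.differences if isinstance(scenario, str) else self.indicators
        rows = table[
            (table["sex"] == sex)
            & (table["scenario"] == scenario)
            & (table["indicator"] == indicator)
            & (table["age"] != SCALAR_AGE)
        ]
        return rows.sort_values("age").reset_index(drop=True)

    # -- presentation ---------------------------------------------------------

    def _fmt(self, sex, scenario, indicator, digits) -> str:
        est = self.scalar(sex, scenario, indicator)
        out = f"{est:.{digits}f}"
        if self.n_runs >= 2:
            lo = self.scalar(sex, scenario, indicator, "ci_low")
            hi = self.scalar(sex, scenario, indicator, "ci_high")
            out += f" ({lo:.{digits}f}; {hi:.{digits}f})"
        return out

    def summary(self) -> str:
        """Table-style text summary per sex: one column per scenario + differences."""
        lines = [
            f"Dementia burden projections for {self.config.target_year} "
            f"(n_per_cohort={self.config.n_per_cohort}, "
            f"{self.n_runs} resampled runs, seed={self.config.seed})",
        ]
        scen_cols = list(self.config.scenarios)
        diff_cols = [f"{s}-0" for s in scen_cols if s != 0]
        for sex in self.config.sexes:
            lines.append("")
            lines.append(sex.capitalize())
            header = ["indicator"] + [f"scenario {s}" for s in scen_cols] + [
                f"diff {d}" for d in diff_cols
            ]
            rows = []
            for key, label, digits in _SUMMARY_ROWS:
                row = [label]
                for s in scen_cols:
                    row.append(self._fmt(sex, s, key, digits))
                for d in diff_cols:
                    row.append(self._fmt(sex, d, key, max(digits, 2)))
                rows.append(row)
            widths = [
                max(len(str(r[i])) for r in [header] + rows) for i in range(len(header))
            ]
            for r in [header] + rows:
                lines.append("  ".join(str(c).ljust(w) for c, w in zip(r, widths)))
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<ProjectionResults target_year={self.config.target_year} "
            f"scenarios={self.config.scenarios} n_runs={self.n_runs}>"
        )

    # -- plotting -------------------------------------------------------------

    def plot_prevalence(self, sex: str, ax=None):
        """Dementia prevalence counts by age, one line per scenario."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for s in self.config.scenarios:
            sub = self.by_age(sex, s, "prevalence_count")
            ax.plot(sub["age"], sub["estimate"] / 1e3, label=f"scenario {s}")
            if self.n_runs >= 2:
                ax.fill_between(
                    sub["age"], sub["ci_low"] / 1e3, sub["ci_high"] / 1e3, alpha=0.2
                )
        ax.set_xlabel("age")
        ax.set_ylabel("demented subjects (thousands)")
        ax.set_title(f"Dementia prevalence by age, {self.config.target_year} ({sex})")
        ax.legend()
        return ax

    def plot_life_expectancy(self, sex: str, ax=None):
        """Life expectancy without dementia by age, one line per scenario."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for s in self.config.scenarios:
            sub = self.by_age(sex, s, "le_without_dementia")
            ax.plot(sub["age"], sub["estimate"], label=f"scenario {s}")
        ax.set_xlabel("age")
        ax.set_ylabel("years without dementia")
        ax.set_title(
            f"Life expectancy without dementia, {self.config.target_year} ({sex})"
        )
        ax.legend()
        return ax

    # -- persistence ----------------------------------------------------------

    def manifest(self) -> dict:
        cfg = asdict(self.config)
        cfg["scenarios"] = list(self.config.scenarios)
        cfg["sexes"] = list(self.config.sexes)
        return {
            "package": "demproj",
            "version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "config": cfg,
        }

    def save(self, outdir) -> Path:
        """Write indicators.csv, differences.csv, summary.txt and manifest.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.indicators.to_csv(outdir / "indicators.csv", index=False)
        self.differences.to_csv(outdir / "differences.csv", index=False)
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
        return outdir
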