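"""Propagation of input-estimate uncertainty into indicator confidence intervals.

The four estimated inputs — the dementia incidence curve, the RR(a) curve of
death for demented subjects, the chronic-use incidence curve and the age-65
prevalence of chronic use — are resampled around their central estimates:
log-normally for the curves (one shared standard-normal deviate per curve,
scaled by the per-age standard error of the log-rate, which preserves each
curve's smoothness) and logit-normally for the prevalence (standard error
derived from its confidence interval).  The exposure relative risks and the
overall mortality/population projections are treated as fixed.

Each of ``n_ci_runs`` resampled bundles is pushed through the full two-pass
projection; confidence intervals are empirical percentiles across runs, with
point estimates taken from the central (unperturbed) run.  Within a run the
parameter draw and the simulation random numbers are shared across scenarios,
so scenario differences are computed within-run before taking percentiles —
the pairing makes difference intervals much tighter than the marginal ones.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .calibration import build_transition_set
from .engine import (
    default_birth_years,
    estimate_exposure_prevalence,
    simulate_population,
)
from .indicators import SCALAR_AGE, panel_indicators
from .rates_io import SEXES, InputBundle, Prev65
from .scenarios import ScenarioSpec

__all__ = [
    "RunConfig",
    "draw_parameter_set",
    "confidence_intervals",
    "run_projection",
    "ProjectionTables",
]

_KEY = ["sex", "scenario", "indicator", "age"]


@dataclass
class RunConfig:
    """Configuration of one full projection run."""

    scenarios: tuple = (0, 1, 2)
    target_year: int = 2040
    n_per_cohort: int = 10_000
    n_ci_runs: int = 100
    seed: int = 0
    level: float = 0.95
    intervention_year: int = 2020
    no_mortality_effect: bool = False
    no_trend: bool = False
    sexes: tuple = SEXES

    def __post_init__(self):
        self.scenarios = tuple(self.scenarios)
        if 0 not in self.scenarios and len(self.scenarios) > 1:
            raise ValueError("difference indicators need scenario 0 in the list")

    @property
    def birth_years(self) -> np.ndarray:
        return default_birth_years(self.target_year)

    def scenario_specs(self) -> list:
        return [
            ScenarioSpec.from_id(
                s,
                intervention_year=self.intervention_year,
                no_mortality_effect=self.no_mortality_effect,
                no_trend=self.no_trend,
            )
            for s in self.scenarios
        ]


def _curve_se(curve, name: str):
    if curve.se_log is None:
        raise ValueError(
            f"{name}: no standard errors stored; supply se_log columns "
            "(or set them to zero) to enable parameter resampling"
        )
    return curve.se_log


def draw_parameter_set(bundle: InputBundle, rng: np.random.Generator) -> InputBundle:
    """One joint resample of the estimated inputs (a perturbed bundle).

    One standard-normal deviate is drawn per (sex, curve) and applied on the
    log scale across all ages, so perturbed curves keep their shape; the
    age-65 prevalence moves on the logit scale.  All perturbed rates stay
    positive and prevalences stay in [0, 1] by construction.
    """
    draw = copy.deepcopy(bundle)
    z = norm.ppf(0.975)
    for sex in SEXES:
        inc = draw.dementia_incidence[sex]
        inc.values = inc.values * np.exp(
            rng.standard_normal() * _curve_se(inc, f"dementia_incidence[{sex}]")
        )
        rr = draw.rr_death[sex]
        rr.values = rr.values * np.exp(
            rng.standard_normal() * _curve_se(rr, f"rr_death[{sex}]")
        )
        bzd = draw.exposure.incidence[sex]
        bzd.values = bzd.values * np.exp(
            rng.standard_normal() * _curve_se(bzd, f"bzd_incidence[{sex}]")
        )
        p = draw.exposure.prev65[sex]
        if p.ci_high > p.ci_low:
            se_logit = (logit(p.ci_high) - logit(p.ci_low)) / (2.0 * z)
            new_p = float(expit(logit(p.prev) + rng.standard_normal() * se_logit))
        else:
            rng.standard_normal()  # keep the stream aligned with the se>0 path
            new_p = p.prev
        draw.exposure.prev65[sex] = Prev65(
            new_p, min(p.ci_low, new_p), max(p.ci_high, new_p)
        )
    return draw


def _percentiles(values: np.ndarray, level: float) -> tuple:
    alpha = (100.0 - 100.0 * level) / 2.0
    lo, hi = np.percentile(values, [alpha, 100.0 - alpha], method="linear")
    return float(lo), float(hi)


def confidence_intervals(
    central: pd.DataFrame, indicator_runs: list, level: float = 0.95
) -> pd.DataFrame:
    """Percentile confidence intervals across resampled runs.

    ``central`` and each element of ``indicator_runs`` are tidy frames with
    columns ``sex, scenario, indicator, age, value``; the point estimate comes
    from the central run, the CI bounds are the empirical ``alpha/2`` and
    ``1 - alpha/2`` percentiles (linear interpolation between order
    statistics) across runs.
    """
    if len(indicator_runs) < 2:
        raise ValueError("confidence intervals need at least 2 resampled runs")
    stacked = pd.concat(
        [df.assign(run=i) for i, df in enumerate(indicator_runs)], ignore_index=True
    )
    grouped = stacked.groupby(_KEY, dropna=False)["value"]
    lo = grouped.apply(lambda v: _percentiles(v.to_numpy(), level)[0])
    hi = grouped.apply(lambda v: _percentiles(v.to_numpy(), level)[1])
    out = central.rename(columns={"value": "estimate"}).set_index(_KEY)
    out["ci_low"] = lo
    out["ci_high"] = hi
    return out.reset_index()


def _project_run(
    bundle: InputBundle, config: RunConfig, sim_seed: np.random.SeedSequence
) -> pd.DataFrame:
    """One full projection (all sexes and scenarios) under one parameter set.

    Pass 1 (status-quo, effect-free) is run once and its calibration shared;
    pass 2 re-seeds the same stream for every scenario so that trajectories
    are coupled through common random numbers.
    """
    specs = config.scenario_specs()
    status_quo = specs[0].status_quo()
    seed_pass1, seed_pass2 = sim_seed.spawn(2)
    birth_years = config.birth_years

    panels1 = simulate_population(
        bundle,
        status_quo,
        config.n_per_cohort,
        np.random.default_rng(seed_pass1),
        birth_years,
        effect_free=True,
        sexes=config.sexes,
    )
    tsets = {
        sex: build_transition_set(
            bundle,
            sex,
            birth_years,
            estimate_exposure_prevalence(panels1[sex]),
            status_quo,
        )
        for sex in config.sexes
    }

    frames = []
    for spec in specs:
        panels = simulate_population(
            bundle,
            spec,
            config.n_per_cohort,
            np.random.default_rng(seed_pass2),
            birth_years,
            tsets=tsets,
            sexes=config.sexes,
        )
        for sex in config.sexes:
            df = panel_indicators(panels[sex], config.target_year)
            df.insert(0, "scenario", spec.id)
            df.insert(0, "sex", sex)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _differences(table: pd.DataFrame, scenarios) -> pd.DataFrame:
    """Within-run scenario differences (scenario s minus scenario 0)."""
    base = table[table["scenario"] == 0].set_index(["sex", "indicator", "age"])["value"]
    frames = []
    for s in scenarios:
        if s == 0:
            continue
        other = table[table["scenario"] == s].set_index(["sex", "indicator", "age"])[
            "value"
        ]
        diff = (other - base).reset_index()
        diff["scenario"] = f"{s}-0"
        frames.append(diff)
    if not frames:
        return pd.DataFrame(columns=["sex", "scenario", "indicator", "age", "value"])
    return pd.concat(frames, ignore_index=True)[
        ["sex", "scenario", "indicator", "age", "value"]
    ]


@dataclass
class ProjectionTables:
    """Raw output of :func:`run_projection` before the results facade."""

    indicators: pd.DataFrame
    differences: pd.DataFrame
    config: RunConfig
    n_runs: int


def run_projection(bundle: InputBundle, config: RunConfig) -> ProjectionTables:
    """Central two-pass run plus resampled runs, with percentile CIs.

    The master seed deterministically spawns one simulation stream per run
    and one parameter stream per resample; scenario pairing (common random
    numbers and common parameter draws across scenarios within a run) is
    guaranteed by construction.
    """
    bundle.validate()
    root = np.random.SeedSequence(config.seed)
    sim_root, param_root = root.spawn(2)
    sim_seeds = sim_root.spawn(config.n_ci_runs + 1)
    param_seeds = param_root.spawn(config.n_ci_runs)

    central = _project_run(bundle, config, sim_seeds[0])
    central_diff = _differences(central, config.scenarios)

    run_tables, run_diffs = [], []
    for k in range(config.n_ci_runs):
        perturbed = draw_parameter_set(bundle, np.random.default_rng(param_seeds[k]))
        table = _project_run(perturbed, config, sim_seeds[k + 1])
        run_tables.append(table)
        run_diffs.append(_differences(table, config.scenarios))

    if config.n_ci_runs >= 2:
        indicators = confidence_intervals(central, run_tables, config.level)
        differences = (
            confidence_intervals(central_diff, run_diffs, config.level)
            if not central_diff.empty
            else central_diff.rename(columns={"value": "estimate"})
        )
    else:
        indicators = central.rename(columns={"value": "estimate"})
        indicators["ci_low"] = np.nan
        indicators["ci_high"] = np.nan
        differences = central_diff.rename(columns={"value": "estimate"})
        if not differences.empty:
            differences["ci_low"] = np.nan
            differences["ci_high"] = np.nan

    return ProjectionTables(
        indicators=indicators,
        differences=differences,
        config=config,
        n_runs=config.n_ci_runs,
    )
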