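"""Chronic-exposure process and intervention scenarios.

Chronic benzodiazepine use is modelled as an irreversible binary exposure:
a subject either starts follow-up exposed (Bernoulli draw against the age-65
prevalence) or becomes exposed later according to the age-specific incidence
of chronic use.  Once exposed, a subject stays exposed for life.

Three named scenarios act on the post-65 incidence of chronic use from the
intervention year onward (default 2020): scenario 0 leaves it unchanged,
scenario 1 halves it, scenario 2 sets it to zero.  Prevalence at age 65 is
left unchanged in every scenario; only incidence after 65 is intervened on.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ScenarioSpec", "scenario_incidence", "draw_initial_exposure"]

_NAMED_MULTIPLIERS = {0: 1.0, 1: 0.5, 2: 0.0}


@dataclass(frozen=True)
class ScenarioSpec:
    """An intervention on the incidence of chronic exposure.

    ``incidence_multiplier`` applies to annual risk intervals starting in or
    after ``intervention_year``.  The two sensitivity switches select the
    paper-style sensitivity analyses: no exposure effect on mortality, and no
    generational decline of dementia incidence.
    """

    id: int
    intervention_year: int = 2020
    incidence_multiplier: float = 1.0
    no_mortality_effect: bool = False
    no_trend: bool = False

    @classmethod
    def from_id(cls, scenario_id: int, **kwargs) -> "ScenarioSpec":
        if scenario_id not in _NAMED_MULTIPLIERS:
            raise ValueError(f"unknown scenario id {scenario_id}; expected 0, 1 or 2")
        return cls(
            id=scenario_id,
            incidence_multiplier=_NAMED_MULTIPLIERS[scenario_id],
            **kwargs,
        )

    def status_quo(self) -> "ScenarioSpec":
        """The same run configuration with the exposure intervention removed."""
        return replace(self, id=0, incidence_multiplier=1.0)


def scenario_incidence(base_incidence, year, scenario: ScenarioSpec):
    """Exposure incidence after applying the scenario's intervention.

    Rates for years before ``scenario.intervention_year`` are untouched; later
    years are multiplied by the scenario's incidence multiplier.  Broadcasts
    over array-valued rates and years.
    """
    base = np.asarray(base_incidence, dtype=float)
    year = np.asarray(year)
    factor = np.where(year < scenario.intervention_year, 1.0, scenario.incidence_multiplier)
    out = base * factor
    if out.ndim == 0:
        return float(out)
    return out


def draw_initial_exposure(prev65: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(prev65) exposure flags at age 65."""
    if not 0.0 <= prev65 <= 1.0:
        raise ValueError("prev65 must be in [0, 1]")
    return rng.random(n) < prev65
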