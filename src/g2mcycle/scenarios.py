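"""Canonical study conditions: p53 status crossed with Plk1 depletion.

A scenario bundles the parameter edits and initial-condition overrides
that define one simulated cell population: wild-type p53 versus p53-null
(p53 synthesis zeroed and p53(0) = 0), under normal Plk1 or a given
fractional depletion of the Plk1 synthesis rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

from .parameters import ParameterSet

__all__ = ["Scenario", "make_scenario", "SENSITIVITY_SCENARIOS"]


@dataclass(frozen=True)
class Scenario:
    label: str
    p53_null: bool = False
    plk1_depletion: float = 0.0  # fraction of k_s12 removed, in [0, 1]

    def apply(self, params: ParameterSet) -> ParameterSet:
        edits: Dict[str, float] = {}
        if self.p53_null:
            edits["k_s28"] = 0.0
        if self.plk1_depletion:
            edits["k_s12"] = params["k_s12"] * (1.0 - self.plk1_depletion)
        return params.with_edits(edits) if edits else params

    @property
    def init_overrides(self) -> Optional[Dict[str, float]]:
        return {"p53": 0.0} if self.p53_null else None


def make_scenario(p53_null: bool = False, plk1_depletion: float = 0.0) -> Scenario:
    if not 0.0 <= plk1_depletion <= 1.0:
        raise ValueError("plk1_depletion must be a fraction in [0, 1]")
    label = ("p53-null" if p53_null else "p53-wt")
    if plk1_depletion:
        label += f"+plk1-depleted-{int(round(100 * plk1_depletion))}%"
    return Scenario(label, p53_null, plk1_depletion)


#: the four cases the sensitivity analyses are run for; the depleted
#: conditions use a 45% reduction of the Plk1 synthesis rate
SENSITIVITY_SCENARIOS = (
    make_scenario(False, 0.0),
    make_scenario(False, 0.45),
    make_scenario(True, 0.0),
    make_scenario(True, 0.45),
)
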