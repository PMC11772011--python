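"""Incremental cost-effectiveness arithmetic: ICER, dominance, net benefit.

Conventions: increments are intervention minus control.  An intervention is
*dominant* when it is both cheaper and more effective (the ICER is not
reported), *dominated* in the mirror case, and otherwise the ICER is the
cost increment per unit of effectiveness gained.  The net monetary benefit
at willingness-to-pay ``w`` is ``w * dE - dC``; for positive increments it
crosses zero exactly at ``w = ICER``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path


class Verdict(str, Enum):
    ICER = "icer"
    DOMINANT = "dominant"
    DOMINATED = "dominated"
    EQUIVALENT = "equivalent"
    NO_EFFECT_DIFFERENCE = "no effectiveness difference"


@dataclass(frozen=True)
class CEAResult:
    """Arm-level costs and effectiveness with their increments and verdict."""

    cost_intervention: float
    cost_control: float
    eff_intervention: float
    eff_control: float
    effect_unit: str = "effect"
    horizon_years: int | None = None
    discount_rate_costs: float | None = None
    discount_rate_effects: float | None = None

    @property
    def delta_cost(self) -> float:
        return self.cost_intervention - self.cost_control

    @property
    def delta_effect(self) -> float:
        return self.eff_intervention - self.eff_control

    @property
    def verdict(self) -> Verdict:
        dc, de = self.delta_cost, self.delta_effect
        if de == 0:
            return Verdict.EQUIVALENT if dc == 0 else Verdict.NO_EFFECT_DIFFERENCE
        if dc < 0 and de > 0:
            return Verdict.DOMINANT
        if dc > 0 and de < 0:
            return Verdict.DOMINATED
        return Verdict.ICER

    @property
    def icer(self) -> float | None:
        """Cost per effectiveness unit; None when not a meaningful ratio."""
        if self.verdict is not Verdict.ICER:
            return None
        return self.delta_cost / self.delta_effect

    @property
    def icer_reported(self) -> float | str:
        """ICER rounded to 2 decimals, or the verdict label."""
        value = self.icer
        return round(value, 2) if value is not None else self.verdict.value

    def to_dict(self) -> dict:
        return {
            "cost_intervention_usd": self.cost_intervention,
            "cost_control_usd": self.cost_control,
            "effectiveness_intervention": self.eff_intervention,
            "effectiveness_control": self.eff_control,
            "effect_unit": self.effect_unit,
            "delta_cost_usd": self.delta_cost,
            "delta_effect": self.delta_effect,
            "verdict": self.verdict.value,
            "icer": self.icer_reported if self.icer is not None else None,
            "horizon_years": self.horizon_years,
            "discount_rate_costs": self.discount_rate_costs,
            "discount_rate_effects": self.discount_rate_effects,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def compute_icer(
    cost_intervention: float,
    cost_control: float,
    eff_intervention: float,
    eff_control: float,
    effect_unit: str = "effect",
    **metadata,
) -> CEAResult:
    """Increments, dominance verdict and ICER for intervention vs control."""
    for value in (cost_intervention, cost_control, eff_intervention, eff_control):
        if not math.isfinite(value):
            raise ValueError("costs and effectiveness must be finite")
    return CEAResult(
        cost_intervention=cost_intervention,
        cost_control=cost_control,
        eff_intervention=eff_intervention,
        eff_control=eff_control,
        effect_unit=effect_unit,
        **metadata,
    )


def avoided_episodes(events_control: int, events_intervention: int) -> int:
    """Episodes avoided by the intervention (sign-preserving)."""
    if events_control < 0 or events_intervention < 0:
        raise ValueError("episode counts must be >= 0")
    return events_control - events_intervention


def net_monetary_benefit(delta_c: float, delta_e: float, wtp: float) -> float:
    """``wtp * delta_e - delta_c`` in US$."""
    if wtp < 0:
        raise ValueError("willingness to pay must be >= 0")
    return wtp * delta_e - delta_c
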