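"""Model/Results facade tying the pipeline together.

:class:`InductionCEA` is built from the three input tables (event counts,
unit costs, configuration); :meth:`InductionCEA.fit` evaluates the decision
model at a horizon and outcome and returns an
:class:`InductionCEAResults` carrying arm-level costs, effectiveness, the
incremental comparison and a printable summary.  Sensitivity analyses hang
off the model (:meth:`InductionCEA.psa`, :meth:`InductionCEA.tornado`) and
off the PSA results (:meth:`PSAResults.ceac`).

>>> model = InductionCEA.from_packaged_data()
>>> res = model.fit(horizon=1, outcome="ar_episodes")
>>> round(res.cea.icer, 2)
399.96
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import sensitivity as sens
from .cea import CEAResult, avoided_episodes, compute_icer
from .costing import AnnualCostProfile, ArmCostBreakdown, attach_costs, first_year_costs
from .inputs import (
    ArmYearEvents,
    ModelConfig,
    UnitCostTable,
    ValidationError,
    default_config,
    events_for,
    load_config,
    load_cost_table,
    load_event_table,
    packaged_cost_table,
    packaged_event_table,
)
from .markov import CohortTrace, build_schedule, graft_survival_years, run_cohort

ARMS = ("no_induction", "r_atg")
OUTCOME_UNITS = {
    "ar_episodes": "avoided AR episode",
    "graft_years": "graft-survival year",
}


class InductionCEA:
    """Cost-effectiveness model of r-ATG induction versus no induction."""

    def __init__(
        self,
        events: list[ArmYearEvents],
        costs: UnitCostTable,
        config: ModelConfig | None = None,
    ):
        self.events = events
        self.costs = costs
        self.config = config or default_config()
        arms = {r.arm for r in events}
        missing = set(ARMS) - arms
        if missing:
            raise ValidationError(f"event table missing arms: {sorted(missing)}")

    @classmethod
    def from_files(
        cls,
        events_csv: str | Path,
        costs_csv: str | Path,
        config_path: str | Path | None = None,
    ) -> "InductionCEA":
        config = load_config(config_path) if config_path else default_config()
        return cls(
            events=load_event_table(events_csv),
            costs=load_cost_table(costs_csv, config=config),
            config=config,
        )

    @classmethod
    def from_packaged_data(
        cls, config: ModelConfig | None = None
    ) -> "InductionCEA":
        config = config or default_config()
        return cls(
            events=packaged_event_table(),
            costs=packaged_cost_table(config),
            config=config,
        )

    # -- base case ---------------------------------------------------------

    def fit(
        self,
        horizon: int = 1,
        outcome: str = "ar_episodes",
        discount_rate: float | None = None,
    ) -> "InductionCEAResults":
        """Evaluate both arms and return the incremental comparison.

        The one-year analysis is undiscounted; longer horizons default to
        the configured annual rates (5%).
        """
        if outcome not in OUTCOME_UNITS:
            raise ValidationError(
                f"unknown outcome {outcome!r}; valid: {tuple(OUTCOME_UNITS)}"
            )
        if outcome == "ar_episodes" and horizon != 1:
            raise ValidationError(
                "the avoided-AR-episode outcome is a first-year analysis"
            )
        if discount_rate is not None:
            rate_c = rate_e = discount_rate
        elif horizon == 1:
            rate_c = rate_e = 0.0
        else:
            rate_c = self.config.discount_rate_costs
            rate_e = self.config.discount_rate_effects

        traces: dict[str, CohortTrace] = {}
        profiles: dict[str, AnnualCostProfile] = {}
        breakdowns: dict[str, ArmCostBreakdown] = {}
        cost: dict[str, float] = {}
        eff: dict[str, float] = {}
        for arm in ARMS:
            year1 = events_for(self.events, arm, 1)
            breakdowns[arm] = first_year_costs(year1, self.costs, arm)
            schedule = build_schedule(self.events, arm, self.config, horizon)
            trace = run_cohort(schedule, horizon=horizon, start_size=year1.n_at_risk)
            traces[arm] = trace
            profiles[arm] = attach_costs(
                trace,
                self.costs,
                rate_c,
                maintenance_timing=self.config.maintenance_timing,
            )
            if outcome == "ar_episodes":
                cost[arm] = breakdowns[arm].grand_total
                # effectiveness framed as episodes avoided relative to the
                # control arm: control 0, intervention control - intervention
                eff[arm] = year1.acute_rejection
            else:
                cost[arm] = profiles[arm].total_per_patient()
                eff[arm] = graft_survival_years(trace, rate_e)

        if outcome == "ar_episodes":
            eff = {
                "no_induction": 0.0,
                "r_atg": float(
                    avoided_episodes(
                        int(eff["no_induction"]), int(eff["r_atg"])
                    )
                ),
            }
        cea = compute_icer(
            cost["r_atg"],
            cost["no_induction"],
            eff["r_atg"],
            eff["no_induction"],
            effect_unit=OUTCOME_UNITS[outcome],
            horizon_years=horizon,
            discount_rate_costs=rate_c,
            discount_rate_effects=rate_e,
        )
        return InductionCEAResults(
            model=self,
            outcome=outcome,
            horizon=horizon,
            cea=cea,
            traces=traces,
            cost_profiles=profiles,
            first_year=breakdowns,
        )

    # -- sensitivity -------------------------------------------------------

    def psa(
        self,
        outcome: str = "ar_episodes",
        horizon: int = 1,
        iterations: int | None = None,
        seed: int | None = None,
    ) -> "PSAResults":
        draws = sens.run_psa(
            self.events,
            self.costs,
            self.config,
            outcome=outcome,
            horizon=horizon,
            iterations=iterations,
            seed=seed,
        )
        grid = self.config.wtp_grid(outcome)
        return PSAResults(draws=draws, curve=sens.ceac(draws, grid))

    def tornado(
        self,
        outcome: str = "ar_episodes",
        horizon: int = 1,
        parameters: list[str] | None = None,
        **kwargs,
    ) -> list[sens.TornadoEntry]:
        return sens.tornado(
            self.events,
            self.costs,
            self.config,
            outcome=outcome,
            horizon=horizon,
            parameters=parameters,
            **kwargs,
        )


@dataclass
class InductionCEAResults:
    """Fitted base-case results: traces, cost profiles and the ICER verdict."""

    model: InductionCEA
    outcome: str
    horizon: int
    cea: CEAResult
    traces: dict[str, CohortTrace]
    cost_profiles: dict[str, AnnualCostProfile]
    first_year: dict[str, ArmCostBreakdown]

    def summary(self) -> str:
        c = self.cea
        unit = c.effect_unit
        lines = [
            "Cost-effectiveness: r-ATG 3 mg/kg induction vs no induction",
            "=" * 62,
            f"Horizon: {self.horizon} year(s)   Outcome: {self.outcome}",
            f"Discount rates (costs/effects): "
            f"{c.discount_rate_costs:.0%} / {c.discount_rate_effects:.0%}",
            "-" * 62,
            f"{'':24s}{'no induction':>16s}{'r-ATG':>16s}",
            f"{'Cost (US$)':24s}{c.cost_control:>16,.2f}{c.cost_intervention:>16,.2f}",
            f"{'Effectiveness':24s}{c.eff_control:>16,.4f}{c.eff_intervention:>16,.4f}",
            "-" * 62,
            f"Incremental cost (US$):   {c.delta_cost:,.2f}",
            f"Incremental effect:       {c.delta_effect:,.4f} {unit}(s)",
        ]
        if c.icer is not None:
            lines.append(f"ICER:                     {c.icer:,.2f} US$ per {unit}")
        else:
            lines.append(f"Verdict:                  {c.verdict.value}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return self.cea.to_dict() | {"outcome": self.outcome}


@dataclass
class PSAResults:
    """Probabilistic sensitivity draws with their acceptability curve."""

    draws: sens.PSADraws
    curve: sens.CEACurve

    def probability_cost_effective(self, wtp: float) -> float:
        """Fraction of draws with non-negative net benefit at ``wtp``."""
        nmb = wtp * self.draws.delta_e - self.draws.delta_c
        return float((nmb >= 0).mean())

    def summary(self) -> str:
        dc, de = self.draws.delta_c, self.draws.delta_e
        lines = [
            f"Probabilistic sensitivity analysis "
            f"({self.draws.iterations} iterations, seed {self.draws.seed})",
            f"Outcome: {self.draws.outcome}   Horizon: {self.draws.horizon} year(s)",
            f"Mean incremental cost (US$): {dc.mean():,.2f} "
            f"(2.5-97.5%: {np.percentile(dc, 2.5):,.2f} to {np.percentile(dc, 97.5):,.2f})",
            f"Mean incremental effect:     {de.mean():,.4f} "
            f"(2.5-97.5%: {np.percentile(de, 2.5):,.4f} to {np.percentile(de, 97.5):,.4f})",
        ]
        return "\n".join(lines)
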