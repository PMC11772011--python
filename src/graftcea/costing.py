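"""Cost accrual: first-year arm accounting and per-cycle trace costing.

Two accounting views are provided.  :func:`first_year_costs` reproduces the
published first-year ledger: every entering patient is billed a full year
of immunosuppression and follow-up, each clinical episode is billed once,
and the r-ATG arm is billed one induction dose per patient.
:func:`attach_costs` generalises this to any horizon by attaching state
and event costs to a cohort trace: maintenance costs (immunosuppression +
follow-up for functioning states, dialysis for the graft-loss state) accrue
on the occupancy at the start of each cycle — decedents consumed resources
before death, and the death state itself is cost-free — while one-off event
costs are booked in the cycle the transition occurs.  Costs in cycle ``c``
are discounted by ``(1+r)^(c-1)``, so a one-year analysis is undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .inputs import ArmYearEvents, UnitCostTable, ValidationError
from .markov import FUNCTIONING_STATES, CohortTrace, HealthState

#: Component order in annual cost profiles.
PROFILE_COMPONENTS = (
    "r_atg_induction",
    "immunosuppression",
    "follow_up",
    "cmv",
    "acute_rejection",
    "graft_loss_event",
    "dialysis",
    "retransplant",
)


def _cents(value: Decimal) -> Decimal:
    return value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class ArmCostBreakdown:
    """First-year cohort cost ledger for one arm: units x unit cost, to the cent."""

    arm: str
    components: dict[str, tuple[int, float]]  # name -> (units, total US$)
    grand_total: float
    n_patients: int

    @property
    def per_patient(self) -> float:
        return self.grand_total / self.n_patients

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": name, "units": units, "total_usd": total}
            for name, (units, total) in self.components.items()
        ]
        return pd.DataFrame(rows)


def first_year_costs(
    events: ArmYearEvents, costs: UnitCostTable, arm: str | None = None
) -> ArmCostBreakdown:
    """First-year cohort costs from year-1 event counts and unit costs.

    Exact decimal arithmetic: each component total is units x unit cost
    rounded to the cent, and the grand total is their sum.
    """
    arm = arm if arm is not None else events.arm
    if events.year != 1:
        raise ValidationError("first_year_costs requires the year-1 record")
    n = events.n_at_risk
    units = {
        "r_atg_induction": n if arm == "r_atg" else 0,
        "immunosuppression_year": n,
        "follow_up_year": n,
        "cmv_episode": events.cmv,
        "ar_episode": events.acute_rejection,
        "graft_loss_event": events.graft_losses,
    }
    components: dict[str, tuple[int, float]] = {}
    grand = Decimal("0")
    for name, count in units.items():
        total = _cents(Decimal(str(costs[name])) * count)
        components[name] = (count, float(total))
        grand += total
    return ArmCostBreakdown(
        arm=arm,
        components=components,
        grand_total=float(_cents(grand)),
        n_patients=n,
    )


@dataclass
class AnnualCostProfile:
    """Per-cycle, per-component costs for one arm, per patient and per cohort.

    ``undiscounted`` has shape (horizon, n_components) in US$ per entering
    patient; discounting divides cycle ``c`` by ``(1+rate)^(c-1)``.
    """

    arm: str
    undiscounted: np.ndarray
    discount_rate: float
    start_size: float

    @property
    def horizon(self) -> int:
        return self.undiscounted.shape[0]

    @property
    def discount_factors(self) -> np.ndarray:
        cycles = np.arange(1, self.horizon + 1)
        return (1.0 + self.discount_rate) ** -(cycles - 1.0)

    @property
    def discounted(self) -> np.ndarray:
        return self.undiscounted * self.discount_factors[:, None]

    def cycle_totals(self, discounted: bool = True) -> np.ndarray:
        matrix = self.discounted if discounted else self.undiscounted
        return matrix.sum(axis=1)

    def total_per_patient(self, discounted: bool = True) -> float:
        return float(self.cycle_totals(discounted).sum())

    def total_cohort(self, discounted: bool = True) -> float:
        return self.total_per_patient(discounted) * self.start_size

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cohort table: (arm, cycle, component, undiscounted, discounted)."""
        disc = self.discounted
        rows = []
        for c in range(self.horizon):
            for j, comp in enumerate(PROFILE_COMPONENTS):
                rows.append(
                    {
                        "arm": self.arm,
                        "cycle": c + 1,
                        "component": comp,
                        "undiscounted_usd": self.undiscounted[c, j]
                        * self.start_size,
                        "discounted_usd": disc[c, j] * self.start_size,
                    }
                )
        return pd.DataFrame(rows)


def attach_costs(
    trace: CohortTrace,
    costs: UnitCostTable,
    discount_rate: float = 0.0,
    maintenance_timing: str = "start",
) -> AnnualCostProfile:
    """Attach state and event costs to a cohort trace.

    Maintenance (immunosuppression + follow-up on functioning states,
    dialysis on the graft-loss state) accrues on start-of-cycle occupancy by
    default (``maintenance_timing="end"`` switches to end-of-cycle).  Graft
    loss and retransplantation are one-off event costs on the transition
    flows; retransplanted patients also receive induction.  First-cycle
    transient CMV/AR episodes and (for the r-ATG arm) one induction dose per
    entering patient are booked in cycle 1.  DEAD accrues nothing.
    """
    if discount_rate < 0:
        raise ValidationError("discount rate must be >= 0")
    if maintenance_timing not in ("start", "end"):
        raise ValidationError("maintenance_timing must be 'start' or 'end'")
    trace.validate()

    horizon = trace.horizon
    profile = np.zeros((horizon, len(PROFILE_COMPONENTS)))
    col = {name: j for j, name in enumerate(PROFILE_COMPONENTS)}
    functioning_idx = [int(s) for s in FUNCTIONING_STATES]
    gl_idx = int(HealthState.GRAFT_LOSS_DIALYSIS)

    for c in range(1, horizon + 1):
        occ = trace.occupancy[c - 1 if maintenance_timing == "start" else c]
        functioning = occ[functioning_idx].sum()
        row = profile[c - 1]
        row[col["immunosuppression"]] = (
            functioning * costs["immunosuppression_year"]
        )
        row[col["follow_up"]] = functioning * costs["follow_up_year"]
        row[col["dialysis"]] = occ[gl_idx] * costs["dialysis_year"]
        row[col["graft_loss_event"]] = (
            trace.new_graft_loss[c - 1] * costs["graft_loss_event"]
        )
        row[col["retransplant"]] = (
            trace.new_retransplant[c - 1] * costs["retransplant_event"]
        )
        # retransplanted patients are induced with r-ATG
        row[col["r_atg_induction"]] = (
            trace.new_retransplant[c - 1] * costs["r_atg_induction"]
        )
        row[col["cmv"]] = trace.cmv_intensity[c - 1] * costs["cmv_episode"]
        row[col["acute_rejection"]] = (
            trace.ar_intensity[c - 1] * costs["ar_episode"]
        )
    if trace.arm == "r_atg":
        profile[0, col["r_atg_induction"]] += costs["r_atg_induction"]

    return AnnualCostProfile(
        arm=trace.arm,
        undiscounted=profile,
        discount_rate=discount_rate,
        start_size=trace.start_size,
    )
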