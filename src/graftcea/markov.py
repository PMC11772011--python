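"""Annual-cycle Markov cohort engine for post-transplant health states.

The cohort starts with a functioning graft and no rejection history and
moves each year among five states::

    FUNCTIONING_NO_AR_HISTORY --AR (year 1)--> FUNCTIONING_AR_HISTORY
    functioning states --graft loss--> GRAFT_LOSS_DIALYSIS
    GRAFT_LOSS_DIALYSIS --retransplant--> RETRANSPLANT_FUNCTIONING
    every state --death--> DEAD (absorbing)

CMV infection and acute rejection are transient first-year events: they
carry one-off costs, and acute rejection additionally routes survivors into
the AR-history state, which faces a higher subsequent graft-loss hazard.
Within a cycle events resolve in a fixed priority order — death, graft
loss, retransplantation, then transient events among survivors — so each
state's outgoing probability mass always sums to one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from .inputs import (
    ArmYearEvents,
    ModelConfig,
    ValidationError,
    events_for,
    year1_graft_losses,
)


class HealthState(IntEnum):
    FUNCTIONING_NO_AR_HISTORY = 0
    FUNCTIONING_AR_HISTORY = 1
    GRAFT_LOSS_DIALYSIS = 2
    RETRANSPLANT_FUNCTIONING = 3
    DEAD = 4


N_STATES = len(HealthState)

FUNCTIONING_STATES = (
    HealthState.FUNCTIONING_NO_AR_HISTORY,
    HealthState.FUNCTIONING_AR_HISTORY,
    HealthState.RETRANSPLANT_FUNCTIONING,
)

#: Event keys accepted in config ``post_year4_probabilities``.
POST_YEAR4_EVENTS = (
    "death_functioning",
    "graft_loss_prior_ar",
    "graft_loss_no_prior_ar",
    "death_after_graft_loss",
    "retransplant",
)


@dataclass(frozen=True)
class CycleProbabilities:
    """Conditional per-cycle event probabilities for one arm and cycle.

    All values are probabilities conditional on occupying the relevant
    source state at the start of the cycle, after higher-priority events
    have not occurred.
    """

    death_functioning: float
    graft_loss_no_ar: float
    graft_loss_ar: float
    death_after_graft_loss: float
    retransplant: float
    cmv: float = 0.0
    acute_rejection: float = 0.0

    def validate(self, label: str = "") -> None:
        for name in (
            "death_functioning",
            "graft_loss_no_ar",
            "graft_loss_ar",
            "death_after_graft_loss",
            "retransplant",
            "cmv",
            "acute_rejection",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(
                    f"probability {name}={value} outside [0, 1]"
                    + (f" ({label})" if label else "")
                )

    def transition_matrix(self) -> np.ndarray:
        """5x5 row-stochastic matrix composing the within-cycle event sequence."""
        d = self.death_functioning
        g0 = self.graft_loss_no_ar
        g1 = self.graft_loss_ar
        dg = self.death_after_graft_loss
        r = self.retransplant
        ar = self.acute_rejection

        T = np.zeros((N_STATES, N_STATES))
        F0, F1, GL, RT, DE = (
            HealthState.FUNCTIONING_NO_AR_HISTORY,
            HealthState.FUNCTIONING_AR_HISTORY,
            HealthState.GRAFT_LOSS_DIALYSIS,
            HealthState.RETRANSPLANT_FUNCTIONING,
            HealthState.DEAD,
        )
        # no AR history: death, then graft loss, then (year 1) AR among survivors
        T[F0, DE] = d
        T[F0, GL] = (1 - d) * g0
        T[F0, F1] = (1 - d) * (1 - g0) * ar
        T[F0, F0] = (1 - d) * (1 - g0) * (1 - ar)
        # AR history: higher graft-loss hazard stream
        T[F1, DE] = d
        T[F1, GL] = (1 - d) * g1
        T[F1, F1] = (1 - d) * (1 - g1)
        # dialysis after graft loss: death, then retransplantation
        T[GL, DE] = dg
        T[GL, RT] = (1 - dg) * r
        T[GL, GL] = (1 - dg) * (1 - r)
        # post-retransplant behaves like functioning without AR history
        T[RT, DE] = d
        T[RT, GL] = (1 - d) * g0
        T[RT, RT] = (1 - d) * (1 - g0)
        # death absorbs
        T[DE, DE] = 1.0
        return T


@dataclass
class TransitionSchedule:
    """Per-cycle transition probabilities for one arm over the model horizon."""

    arm: str
    cycles: list[CycleProbabilities]

    @property
    def horizon(self) -> int:
        return len(self.cycles)

    def validate(self) -> None:
        if not self.cycles:
            raise ValidationError("schedule has no cycles")
        for i, cp in enumerate(self.cycles, start=1):
            cp.validate(label=f"arm={self.arm}, cycle {i}")
            rows = cp.transition_matrix().sum(axis=1)
            if not np.allclose(rows, 1.0, atol=1e-12):
                raise ValidationError(
                    f"outgoing probabilities do not sum to 1 in cycle {i}"
                )

    def matrix(self, cycle: int) -> np.ndarray:
        """Transition matrix for 1-based ``cycle``."""
        return self.cycles[cycle - 1].transition_matrix()


def _derived(count: int, denom: int, cell: str) -> float:
    if denom == 0:
        if count == 0:
            return 0.0
        raise ValidationError(
            f"cannot derive probability for {cell}: zero denominator"
        )
    p = count / denom
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"derived probability for {cell} outside [0,1]")
    return p


def pooled_post_year4(events: list[ArmYearEvents]) -> dict[str, float]:
    """Late-period probabilities pooled across arms from the recurring rows.

    Both arms share the same late-period incidences; absent external
    estimates, the recurring ("year 4+") observed rows are pooled: counts
    summed over arms, denominators summed likewise (cohort size for
    functioning-state events, cumulative first-year graft losses for
    post-graft-loss events).
    """
    rows = [r for r in events if r.recurring]
    if not rows:
        raise ValidationError("no recurring (year 4+) rows to pool")
    n_total = sum(r.n_at_risk for r in rows)
    gl_total = sum(year1_graft_losses(events, r.arm) for r in rows)
    return {
        "death_functioning": _derived(
            sum(r.death_functioning for r in rows), n_total, "pooled death"
        ),
        "graft_loss_prior_ar": _derived(
            sum(r.graft_loss_prior_ar for r in rows),
            n_total,
            "pooled graft loss (prior AR)",
        ),
        "graft_loss_no_prior_ar": _derived(
            sum(r.graft_loss_no_prior_ar for r in rows),
            n_total,
            "pooled graft loss (no prior AR)",
        ),
        "death_after_graft_loss": _derived(
            sum(r.death_after_graft_loss for r in rows),
            gl_total,
            "pooled death after graft loss",
        ),
        "retransplant": _derived(
            sum(r.retransplant for r in rows), gl_total, "pooled retransplant"
        ),
    }


def _cycle_from_events(
    rec: ArmYearEvents, gl_denominator: int, first_cycle: bool
) -> CycleProbabilities:
    n = rec.n_at_risk
    label = f"{rec.arm} year {rec.year_label}"
    if first_cycle:
        # everyone starts without AR history; year-1 graft loss applies as
        # the combined incidence, and AR assigns the history split
        gl = _derived(rec.graft_losses, n, f"{label} graft loss")
        g0, g1 = gl, gl
    else:
        g0 = _derived(
            rec.graft_loss_no_prior_ar, n, f"{label} graft loss (no prior AR)"
        )
        g1 = _derived(
            rec.graft_loss_prior_ar, n, f"{label} graft loss (prior AR)"
        )
    return CycleProbabilities(
        death_functioning=_derived(rec.death_functioning, n, f"{label} death"),
        graft_loss_no_ar=g0,
        graft_loss_ar=g1,
        death_after_graft_loss=_derived(
            rec.death_after_graft_loss,
            gl_denominator,
            f"{label} death after graft loss",
        ),
        retransplant=_derived(
            rec.retransplant, gl_denominator, f"{label} retransplant"
        ),
        cmv=_derived(rec.cmv, n, f"{label} CMV") if first_cycle else 0.0,
        acute_rejection=(
            _derived(rec.acute_rejection, n, f"{label} acute rejection")
            if first_cycle
            else 0.0
        ),
    )


def build_schedule(
    events: list[ArmYearEvents],
    arm: str,
    config: ModelConfig,
    horizon: int | None = None,
) -> TransitionSchedule:
    """Derive the per-cycle transition schedule for one arm.

    Cycles with observed data (years 1 through the recurring "4+" row) use
    the arm's own counts; probabilities are count/denominator with the
    cohort size as denominator for functioning-state events and the arm's
    cumulative first-year graft losses for post-graft-loss events.  Cycles
    beyond the observed window use ``config.post_year4_probabilities``
    (identical for both arms), defaulting to the pooled recurring row.
    """
    horizon = horizon if horizon is not None else config.horizon_years
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    gl_denom = year1_graft_losses(events, arm)
    last_observed = max(r.year for r in events if r.arm == arm)

    late: CycleProbabilities | None = None
    if horizon > last_observed:
        if config.post_year4_probabilities is not None:
            raw = config.post_year4_probabilities
            unknown = set(raw) - set(POST_YEAR4_EVENTS)
            if unknown:
                raise ValidationError(
                    f"unknown post-year-4 events: {sorted(unknown)}"
                )
            pooled = {k: float(raw.get(k, 0.0)) for k in POST_YEAR4_EVENTS}
        else:
            pooled = pooled_post_year4(events)
        late = CycleProbabilities(
            death_functioning=pooled["death_functioning"],
            graft_loss_no_ar=pooled["graft_loss_no_prior_ar"],
            graft_loss_ar=pooled["graft_loss_prior_ar"],
            death_after_graft_loss=pooled["death_after_graft_loss"],
            retransplant=pooled["retransplant"],
        )

    cycles: list[CycleProbabilities] = []
    for c in range(1, horizon + 1):
        if c <= last_observed:
            rec = events_for(events, arm, c)
            cycles.append(_cycle_from_events(rec, gl_denom, first_cycle=c == 1))
        else:
            assert late is not None
            cycles.append(late)
    schedule = TransitionSchedule(arm=arm, cycles=cycles)
    schedule.validate()
    return schedule


@dataclass
class CohortTrace:
    """State occupancy per cycle plus within-cycle event flows for one arm.

    ``occupancy`` has shape (horizon+1, 5); row 0 is the entry distribution
    (all mass in FUNCTIONING_NO_AR_HISTORY).  ``new_graft_loss`` /
    ``new_retransplant`` record the mass making that transition during each
    cycle (index 0 = cycle 1); ``cmv_intensity`` / ``ar_intensity`` are
    transient first-year episodes per entering patient.
    """

    arm: str
    occupancy: np.ndarray
    new_graft_loss: np.ndarray
    new_retransplant: np.ndarray
    cmv_intensity: np.ndarray
    ar_intensity: np.ndarray
    start_size: float = 1.0

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def validate(self) -> None:
        rows = self.occupancy.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValidationError("cohort mass not conserved in trace")
        if np.any(self.occupancy < -1e-12):
            raise ValidationError("negative occupancy in trace")
        dead = self.occupancy[:, HealthState.DEAD]
        if np.any(np.diff(dead) < -1e-12):
            raise ValidationError("DEAD occupancy must be non-decreasing")

    def functioning(self) -> np.ndarray:
        """Mass with a functioning graft at each cycle boundary."""
        return self.occupancy[:, list(FUNCTIONING_STATES)].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "cycle": c,
                "state": HealthState(s).name,
                "occupancy": self.occupancy[c, s],
            }
            for c in range(self.occupancy.shape[0])
            for s in range(N_STATES)
        ]
        return pd.DataFrame(records)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "arm": self.arm,
            "start_size": self.start_size,
            "states": [s.name for s in HealthState],
            "occupancy": self.occupancy.tolist(),
            "new_graft_loss": self.new_graft_loss.tolist(),
            "new_retransplant": self.new_retransplant.tolist(),
            "cmv_intensity": self.cmv_intensity.tolist(),
            "ar_intensity": self.ar_intensity.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def run_cohort(
    schedule: TransitionSchedule,
    horizon: int | None = None,
    start_size: float = 1.0,
    validate: bool = True,
) -> CohortTrace:
    """Propagate the cohort distribution through the schedule.

    Occupancy is tracked as fractions of the entering cohort;
    ``start_size`` scales cohort-level cost accounting downstream.
    ``validate=False`` skips schedule/trace revalidation on hot paths where
    the schedule is known valid (e.g. inside the probabilistic sensitivity
    loop).
    """
    if validate:
        schedule.validate()
    horizon = horizon if horizon is not None else schedule.horizon
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    if horizon > schedule.horizon:
        raise ValidationError(
            f"schedule covers {schedule.horizon} cycles, horizon {horizon} requested"
        )

    occupancy = np.zeros((horizon + 1, N_STATES))
    occupancy[0, HealthState.FUNCTIONING_NO_AR_HISTORY] = 1.0
    new_gl = np.zeros(horizon)
    new_rt = np.zeros(horizon)
    cmv = np.zeros(horizon)
    ar = np.zeros(horizon)

    GL, RT = HealthState.GRAFT_LOSS_DIALYSIS, HealthState.RETRANSPLANT_FUNCTIONING
    for c in range(1, horizon + 1):
        cp = schedule.cycles[c - 1]
        T = cp.transition_matrix()
        prev = occupancy[c - 1]
        occupancy[c] = prev @ T
        # inbound flows into dialysis / retransplant states during the cycle
        new_gl[c - 1] = sum(
            prev[s] * T[s, GL] for s in range(N_STATES) if s != GL
        )
        new_rt[c - 1] = prev[GL] * T[GL, RT]
        # transient episodes per entering patient (cost accounting keeps the
        # published convention of episodes over the full entering cohort)
        cmv[c - 1] = cp.cmv
        ar[c - 1] = cp.acute_rejection

    trace = CohortTrace(
        arm=schedule.arm,
        occupancy=occupancy,
        new_graft_loss=new_gl,
        new_retransplant=new_rt,
        cmv_intensity=cmv,
        ar_intensity=ar,
        start_size=start_size,
    )
    if validate:
        trace.validate()
    return trace


def graft_survival_years(trace: CohortTrace, discount_rate: float = 0.0) -> float:
    """Discounted expected years with a functioning graft per patient.

    End-of-cycle state membership with annual cycles: each cycle ``c``
    contributes the functioning occupancy at its end, discounted by
    ``(1+r)^(c-1)`` so the first year is undiscounted.
    """
    if discount_rate < 0:
        raise ValidationError("discount rate must be >= 0")
    functioning = trace.functioning()[1:]
    cycles = np.arange(1, trace.horizon + 1)
    return float(np.sum(functioning / (1.0 + discount_rate) ** (cycles - 1)))
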