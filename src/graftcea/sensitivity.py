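"""One-way (tornado) and probabilistic sensitivity analysis.

Every transition probability in the model traces back to a binomial count,
so parameter uncertainty is expressed naturally: one-way analysis sweeps
each probability across its Wilson 95% interval (and each unit cost across
+/-10%) holding everything else at base case; the probabilistic analysis
(second-order Monte Carlo) draws probabilities from
``Beta(alpha=events, beta=n-events)`` — with a Jeffreys floor of 0.5 on
zero counts — and unit costs from Gamma distributions with the base value
as mean and a configurable coefficient of variation (default 0.10, i.e. the
"+/-10%" convention).  Each draw rebuilds the schedule and cost table,
reruns both arms, and records the incremental cost/effect pair; the
cost-effectiveness acceptability curve is the fraction of draws with
non-negative net monetary benefit across a willingness-to-pay grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import net_monetary_benefit
from .costing import attach_costs, first_year_costs
from .inputs import (
    ArmYearEvents,
    COST_COMPONENTS,
    ModelConfig,
    UnitCostTable,
    ValidationError,
    events_for,
    year1_graft_losses,
)
from .markov import (
    CycleProbabilities,
    TransitionSchedule,
    build_schedule,
    graft_survival_years,
    pooled_post_year4,
    run_cohort,
)
from .probability import estimate_probability

logger = logging.getLogger(__name__)

OUTCOMES = ("ar_episodes", "graft_years")

_ROW_EVENTS = (
    "cmv",
    "acute_rejection",
    "graft_loss_prior_ar",
    "graft_loss_no_prior_ar",
    "death_functioning",
)
_POST_GL_EVENTS = ("death_after_graft_loss", "retransplant")


@dataclass(frozen=True)
class ProbabilityParameter:
    """A model probability with its underlying binomial count."""

    name: str  # "p:<arm>:<year>:<event>"
    events: int
    n: int

    @property
    def point(self) -> float:
        return self.events / self.n if self.n else 0.0


def probability_parameters(
    events: list[ArmYearEvents], config: ModelConfig, horizon: int
) -> list[ProbabilityParameter]:
    """Enumerate every count-backed probability the model uses up to ``horizon``."""
    params: list[ProbabilityParameter] = []
    arms = sorted({r.arm for r in events})
    for arm in arms:
        gl_denom = year1_graft_losses(events, arm)
        for rec in sorted(
            (r for r in events if r.arm == arm), key=lambda r: r.year
        ):
            if rec.year > horizon and not rec.recurring:
                continue
            row_events = _ROW_EVENTS if rec.year == 1 else _ROW_EVENTS[2:]
            for ev in row_events:
                params.append(
                    ProbabilityParameter(
                        f"p:{arm}:{rec.year_label}:{ev}",
                        getattr(rec, ev),
                        rec.n_at_risk,
                    )
                )
            for ev in _POST_GL_EVENTS:
                params.append(
                    ProbabilityParameter(
                        f"p:{arm}:{rec.year_label}:{ev}",
                        getattr(rec, ev),
                        gl_denom,
                    )
                )
    # pooled late-period cells (only exercised beyond the observed window)
    last = max(r.year for r in events)
    if horizon > last and config.post_year4_probabilities is None:
        recurring = [r for r in events if r.recurring]
        n_total = sum(r.n_at_risk for r in recurring)
        gl_total = sum(year1_graft_losses(events, r.arm) for r in recurring)
        label = f"{last}+"
        for ev in _ROW_EVENTS[2:]:
            params.append(
                ProbabilityParameter(
                    f"p:pooled:{label}:{ev}",
                    sum(getattr(r, ev) for r in recurring),
                    n_total,
                )
            )
        for ev in _POST_GL_EVENTS:
            params.append(
                ProbabilityParameter(
                    f"p:pooled:{label}:{ev}",
                    sum(getattr(r, ev) for r in recurring),
                    gl_total,
                )
            )
    return params


def _clip_unit(value: float, counter: list[int]) -> float:
    if value > 1.0:
        counter[0] += 1
        return 1.0
    return max(value, 0.0)


def schedule_from_values(
    arm: str,
    events: list[ArmYearEvents],
    config: ModelConfig,
    horizon: int,
    values: dict[str, float],
    renorm_counter: list[int] | None = None,
) -> TransitionSchedule:
    """Build an arm's schedule from a parameter-name -> probability mapping.

    Mirrors :func:`graftcea.markov.build_schedule`: observed years use their
    own cells, the first cycle combines the two graft-loss cells, and cycles
    past the observed window use the pooled (or config-supplied) late-period
    probabilities.  A combined probability exceeding 1 is renormalized
    (clipped) and counted.
    """
    counter = renorm_counter if renorm_counter is not None else [0]
    last_observed = max(r.year for r in events if r.arm == arm)

    def val(prefix: str, event: str) -> float:
        return values[f"{prefix}:{event}"]

    cycles: list[CycleProbabilities] = []
    for c in range(1, horizon + 1):
        if c <= last_observed:
            rec = events_for(events, arm, c)
            prefix = f"p:{arm}:{rec.year_label}"
            if c == 1:
                gl = _clip_unit(
                    val(prefix, "graft_loss_prior_ar")
                    + val(prefix, "graft_loss_no_prior_ar"),
                    counter,
                )
                g0, g1 = gl, gl
                cmv = val(prefix, "cmv")
                ar = val(prefix, "acute_rejection")
            else:
                g0 = val(prefix, "graft_loss_no_prior_ar")
                g1 = val(prefix, "graft_loss_prior_ar")
                cmv = ar = 0.0
            cycles.append(
                CycleProbabilities(
                    death_functioning=val(prefix, "death_functioning"),
                    graft_loss_no_ar=g0,
                    graft_loss_ar=g1,
                    death_after_graft_loss=val(
                        prefix, "death_after_graft_loss"
                    ),
                    retransplant=val(prefix, "retransplant"),
                    cmv=cmv,
                    acute_rejection=ar,
                )
            )
        else:
            if config.post_year4_probabilities is not None:
                raw = config.post_year4_probabilities
                late = {k: float(raw.get(k, 0.0)) for k in raw}
                get = lambda ev: late.get(ev, 0.0)  # noqa: E731
            else:
                prefix = f"p:pooled:{last_observed}+"
                get = lambda ev: val(prefix, ev)  # noqa: E731
            cycles.append(
                CycleProbabilities(
                    death_functioning=get("death_functioning"),
                    graft_loss_no_ar=get("graft_loss_no_prior_ar"),
                    graft_loss_ar=get("graft_loss_prior_ar"),
                    death_after_graft_loss=get("death_after_graft_loss"),
                    retransplant=get("retransplant"),
                )
            )
    return TransitionSchedule(arm=arm, cycles=cycles)


def _base_values(params: list[ProbabilityParameter]) -> dict[str, float]:
    return {p.name: p.point for p in params}


def evaluate_increments(
    events: list[ArmYearEvents],
    costs: UnitCostTable,
    config: ModelConfig,
    outcome: str,
    horizon: int,
    prob_values: dict[str, float] | None = None,
    validate: bool = True,
) -> tuple[float, float]:
    """(delta cost, delta effect) of r-ATG vs no induction at given parameter values.

    For the avoided-AR-episode outcome both quantities are cohort level
    (US$ and episodes over 466 patients); for graft-survival years both are
    per patient.  The one-year analysis is undiscounted; longer horizons
    use the configured rates.
    """
    if outcome not in OUTCOMES:
        raise ValidationError(f"unknown outcome {outcome!r}; valid: {OUTCOMES}")
    rate_c = 0.0 if horizon == 1 else config.discount_rate_costs
    rate_e = 0.0 if horizon == 1 else config.discount_rate_effects

    if outcome == "ar_episodes":
        if horizon != 1:
            raise ValidationError(
                "the avoided-AR-episode outcome is a first-year analysis"
            )
        totals, ar_counts = {}, {}
        for arm in ("no_induction", "r_atg"):
            rec = events_for(events, arm, 1)
            n = rec.n_at_risk
            if prob_values is None:
                breakdown = first_year_costs(rec, costs, arm)
                totals[arm] = breakdown.grand_total
                ar_counts[arm] = rec.acute_rejection
            else:
                prefix = f"p:{arm}:1"
                p_cmv = prob_values[f"{prefix}:cmv"]
                p_ar = prob_values[f"{prefix}:acute_rejection"]
                p_gl = (
                    prob_values[f"{prefix}:graft_loss_prior_ar"]
                    + prob_values[f"{prefix}:graft_loss_no_prior_ar"]
                )
                total = n * (
                    costs["immunosuppression_year"]
                    + costs["follow_up_year"]
                    + p_cmv * costs["cmv_episode"]
                    + p_ar * costs["ar_episode"]
                    + p_gl * costs["graft_loss_event"]
                )
                if arm == "r_atg":
                    total += n * costs["r_atg_induction"]
                totals[arm] = total
                ar_counts[arm] = n * p_ar
        return (
            totals["r_atg"] - totals["no_induction"],
            ar_counts["no_induction"] - ar_counts["r_atg"],
        )

    values = prob_values
    if values is None:
        values = _base_values(probability_parameters(events, config, horizon))
    results = {}
    for arm in ("no_induction", "r_atg"):
        schedule = schedule_from_values(arm, events, config, horizon, values)
        trace = run_cohort(schedule, horizon=horizon, validate=validate)
        profile = attach_costs(
            trace, costs, rate_c, maintenance_timing=config.maintenance_timing
        )
        results[arm] = (
            profile.total_per_patient(),
            graft_survival_years(trace, rate_e),
        )
    return (
        results["r_atg"][0] - results["no_induction"][0],
        results["r_atg"][1] - results["no_induction"][1],
    )


# ---------------------------------------------------------------------------
# one-way (tornado)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    outcome_low: float
    outcome_high: float
    metric: str = "icer"

    @property
    def width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _cost_parameter_names() -> list[str]:
    return [f"c:{name}" for name in COST_COMPONENTS]


def one_way(
    events: list[ArmYearEvents],
    costs: UnitCostTable,
    config: ModelConfig,
    parameter: str,
    outcome: str = "ar_episodes",
    horizon: int = 1,
    metric: str = "icer",
    wtp_ref: float = 1000.0,
    cost_variation: float = 0.10,
) -> TornadoEntry:
    """Re-run the model at a parameter's lower and upper plausible bound.

    Probabilities sweep their Wilson 95% interval; unit costs sweep
    +/- ``cost_variation``.  ``metric`` is the raw incremental ratio
    ("icer") or the net monetary benefit at ``wtp_ref`` ("nmb"), the
    latter being well-defined even when an increment changes sign.
    """
    params = probability_parameters(events, config, horizon)
    by_name = {p.name: p for p in params}
    cost_names = _cost_parameter_names()

    if parameter in by_name:
        p = by_name[parameter]
        ci = estimate_probability(p.events, p.n)
        low_in, high_in = ci.lower, ci.upper
        base = _base_values(params)

        def run(bound: float) -> tuple[float, float]:
            values = dict(base)
            values[parameter] = bound
            return evaluate_increments(
                events, costs, config, outcome, horizon, prob_values=values
            )

        dc_lo, de_lo = run(low_in)
        dc_hi, de_hi = run(high_in)
    elif parameter in cost_names:
        component = parameter.split(":", 1)[1]
        base_cost = costs[component]
        low_in = base_cost * (1 - cost_variation)
        high_in = base_cost * (1 + cost_variation)

        def run_cost(bound: float) -> tuple[float, float]:
            perturbed = costs.replace(**{component: bound})
            return evaluate_increments(
                events, perturbed, config, outcome, horizon
            )

        dc_lo, de_lo = run_cost(low_in)
        dc_hi, de_hi = run_cost(high_in)
    else:
        valid = sorted(by_name) + cost_names
        raise ValidationError(
            f"unknown parameter {parameter!r}; valid names: {valid}"
        )

    if metric == "icer":
        out_lo = dc_lo / de_lo if de_lo != 0 else float("nan")
        out_hi = dc_hi / de_hi if de_hi != 0 else float("nan")
    elif metric == "nmb":
        out_lo = net_monetary_benefit(dc_lo, de_lo, wtp_ref)
        out_hi = net_monetary_benefit(dc_hi, de_hi, wtp_ref)
    else:
        raise ValidationError("metric must be 'icer' or 'nmb'")
    return TornadoEntry(
        parameter=parameter,
        low_input=low_in,
        high_input=high_in,
        outcome_low=out_lo,
        outcome_high=out_hi,
        metric=metric,
    )


def tornado(
    events: list[ArmYearEvents],
    costs: UnitCostTable,
    config: ModelConfig,
    outcome: str = "ar_episodes",
    horizon: int = 1,
    parameters: list[str] | None = None,
    **kwargs,
) -> list[TornadoEntry]:
    """One-way entries for every (or the named) parameters, widest first."""
    if parameters is None:
        parameters = [
            p.name for p in probability_parameters(events, config, horizon)
        ] + _cost_parameter_names()
    entries = [
        one_way(
            events, costs, config, name, outcome=outcome, horizon=horizon,
            **kwargs,
        )
        for name in parameters
    ]
    return sorted(entries, key=lambda e: e.width, reverse=True)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_input": e.low_input,
                "high_input": e.high_input,
                "outcome_low": e.outcome_low,
                "outcome_high": e.outcome_high,
                "width": e.width,
                "metric": e.metric,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSADraws:
    """Paired incremental draws from the second-order Monte Carlo run."""

    outcome: str
    horizon: int
    seed: int
    delta_c: np.ndarray
    delta_e: np.ndarray
    prob_draws: dict[str, np.ndarray] = field(default_factory=dict)
    cost_draws: dict[str, np.ndarray] = field(default_factory=dict)
    n_renormalized: int = 0

    @property
    def iterations(self) -> int:
        return self.delta_c.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Scatter-plane table of (delta effect, delta cost) pairs."""
        return pd.DataFrame(
            {
                "iteration": np.arange(self.iterations),
                "delta_effect": self.delta_e,
                "delta_cost_usd": self.delta_c,
            }
        )


def draw_parameters(
    params: list[ProbabilityParameter],
    costs: UnitCostTable,
    rng: np.random.Generator,
    cost_cv: float = 0.10,
    size: int = 1,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Beta draws for each count-backed probability, gamma draws for costs.

    Beta uses ``alpha=events, beta=n-events`` with a Jeffreys floor of 0.5
    on either parameter when a count is zero.  Gamma uses shape
    ``1/cv**2`` and scale ``mean*cv**2`` (mean = base cost, coefficient of
    variation = ``cost_cv``); ``cost_cv=0`` degenerates to the base cost.
    Draw order is fixed (parameters then components, declaration order) so
    the output is a pure function of the generator state.
    """
    prob_draws: dict[str, np.ndarray] = {}
    for p in params:
        alpha = p.events if p.events > 0 else 0.5
        beta = (p.n - p.events) if p.n - p.events > 0 else 0.5
        prob_draws[p.name] = rng.beta(alpha, beta, size=size)
    cost_draws: dict[str, np.ndarray] = {}
    for name in COST_COMPONENTS:
        mean = costs[name]
        if cost_cv == 0 or mean == 0:
            cost_draws[name] = np.full(size, mean)
        else:
            shape = 1.0 / cost_cv**2
            cost_draws[name] = rng.gamma(shape, mean / shape, size=size)
    return prob_draws, cost_draws


def run_psa(
    events: list[ArmYearEvents],
    costs: UnitCostTable,
    config: ModelConfig,
    outcome: str = "ar_episodes",
    horizon: int = 1,
    iterations: int | None = None,
    seed: int | None = None,
) -> PSADraws:
    """Second-order Monte Carlo: redraw parameters, rerun the model, record increments."""
    if outcome not in OUTCOMES:
        raise ValidationError(f"unknown outcome {outcome!r}; valid: {OUTCOMES}")
    iterations = (
        iterations if iterations is not None else config.psa_iterations
    )
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    seed = seed if seed is not None else config.rng_seed
    rng = np.random.default_rng(seed)

    params = probability_parameters(events, config, horizon)
    prob_draws, cost_draws = draw_parameters(
        params, costs, rng, cost_cv=config.psa_cost_cv, size=iterations
    )

    renorm = [0]
    if outcome == "ar_episodes":
        # fully vectorised first-year cohort accounting
        totals = {}
        n_by_arm, p_ar_by_arm = {}, {}
        for arm in ("no_induction", "r_atg"):
            rec = events_for(events, arm, 1)
            n = rec.n_at_risk
            prefix = f"p:{arm}:1"
            p_gl = (
                prob_draws[f"{prefix}:graft_loss_prior_ar"]
                + prob_draws[f"{prefix}:graft_loss_no_prior_ar"]
            )
            renorm[0] += int(np.sum(p_gl > 1.0))
            p_gl = np.minimum(p_gl, 1.0)
            total = n * (
                cost_draws["immunosuppression_year"]
                + cost_draws["follow_up_year"]
                + prob_draws[f"{prefix}:cmv"] * cost_draws["cmv_episode"]
                + prob_draws[f"{prefix}:acute_rejection"]
                * cost_draws["ar_episode"]
                + p_gl * cost_draws["graft_loss_event"]
            )
            if arm == "r_atg":
                total = total + n * cost_draws["r_atg_induction"]
            totals[arm] = total
            n_by_arm[arm] = n
            p_ar_by_arm[arm] = prob_draws[f"{prefix}:acute_rejection"]
        delta_c = totals["r_atg"] - totals["no_induction"]
        delta_e = (
            n_by_arm["no_induction"] * p_ar_by_arm["no_induction"]
            - n_by_arm["r_atg"] * p_ar_by_arm["r_atg"]
        )
    else:
        delta_c = np.empty(iterations)
        delta_e = np.empty(iterations)
        for i in range(iterations):
            values = {name: arr[i] for name, arr in prob_draws.items()}
            drawn_costs = UnitCostTable(
                **{name: arr[i] for name, arr in cost_draws.items()}
            )
            rate_c = config.discount_rate_costs if horizon > 1 else 0.0
            rate_e = config.discount_rate_effects if horizon > 1 else 0.0
            per_arm = {}
            for arm in ("no_induction", "r_atg"):
                schedule = schedule_from_values(
                    arm, events, config, horizon, values, renorm_counter=renorm
                )
                trace = run_cohort(schedule, horizon=horizon, validate=False)
                profile = attach_costs(
                    trace,
                    drawn_costs,
                    rate_c,
                    maintenance_timing=config.maintenance_timing,
                )
                per_arm[arm] = (
                    profile.total_per_patient(),
                    graft_survival_years(trace, rate_e),
                )
            delta_c[i] = per_arm["r_atg"][0] - per_arm["no_induction"][0]
            delta_e[i] = per_arm["r_atg"][1] - per_arm["no_induction"][1]

    if renorm[0]:
        logger.warning(
            "renormalized %d drawn probability sets with outgoing mass > 1",
            renorm[0],
        )
    return PSADraws(
        outcome=outcome,
        horizon=horizon,
        seed=seed,
        delta_c=np.asarray(delta_c, dtype=float),
        delta_e=np.asarray(delta_e, dtype=float),
        prob_draws=prob_draws,
        cost_draws=cost_draws,
        n_renormalized=renorm[0],
    )


@dataclass
class CEACurve:
    """Probability the intervention is cost-effective across a WTP grid."""

    wtp: np.ndarray
    probability: np.ndarray

    def at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp)))
        if not np.isclose(self.wtp[idx], wtp):
            raise ValidationError(f"WTP {wtp} not on the curve's grid")
        return float(self.probability[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp_usd": self.wtp, "probability_cost_effective": self.probability}
        )


def ceac(draws: PSADraws, wtp_grid) -> CEACurve:
    """Fraction of draws with ``wtp * dE - dC >= 0`` at each grid point."""
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise ValidationError("willingness-to-pay grid is empty")
    if draws.iterations == 0:
        raise ValidationError("no PSA draws")
    nmb = wtp[:, None] * draws.delta_e[None, :] - draws.delta_c[None, :]
    return CEACurve(wtp=wtp, probability=(nmb >= 0).mean(axis=1))
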