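# Methods

## Model structure

A Markov cohort state-transition model with annual cycles and five health
states:

1. `FUNCTIONING_NO_AR_HISTORY` — functioning graft, no acute rejection (AR)
   to date (initial state for the whole cohort);
2. `FUNCTIONING_AR_HISTORY` — functioning graft after at least one AR
   episode;
3. `GRAFT_LOSS_DIALYSIS` — graft lost, on dialysis;
4. `RETRANSPLANT_FUNCTIONING` — functioning graft after retransplantation;
5. `DEAD` — absorbing.

Within a cycle, competing events are resolved sequentially on the
conditional scale: death first, then graft loss among survivors, then (from
dialysis) retransplantation among survivors, then the first-year transient
events (CMV infection and AR). AR among patients who keep a functioning
graft routes them to the AR-history state. This sequential composition
guarantees each transition-matrix row sums to exactly 1 for any probability
inputs in [0, 1], so the probabilistic sensitivity analysis never needs row
renormalization (a renormalization counter exists for contract completeness
and always reads 0).

Transition probabilities are event counts divided by their denominators:
466 patients at risk per arm for events from a functioning graft, and the
arm's cumulative year-1 graft losses for death-after-graft-loss and
retransplantation. Observed data cover years 1–4 per arm ("4+" rows apply
to cycle 4). Cycles 5 and beyond use the "4+" rows **pooled across arms**
(denominators 932 functioning / 34 post-graft-loss), reflecting the
assumption that the treatment effect is exhausted after the observed
window; a config override (`post_year4_probabilities`) accepts alternative
late-period probabilities.

## Effectiveness outcomes

- `ar_episodes` (1-year horizon only): avoided AR episodes, framed so the
  comparator contributes 0 and the intervention contributes the difference
  in observed episode counts (236 − 64 = 172 per 466 patients).
- `graft_years`: expected years with a functioning graft (states 1, 2 and
  4), measured by end-of-cycle occupancy. Year-1 analyses are undiscounted;
  multi-year analyses discount both costs and effects at 5%/year
  (configurable), with cycle *c* weighted by (1+r)^−(c−1).

No half-cycle correction is applied; occupancy is taken at cycle
boundaries, matching the annual-accounting convention of the source data.

## Costs

Unit costs (US$, converted from BRL at 5.12): r-ATG induction 255.85/dose,
annual maintenance immunosuppression 2,627.71, CMV episode 412.70, AR
episode 364.46, graft-loss event 510.60, annual outpatient follow-up 15.77.
Two components are not part of the published unit-cost set and are supplied
as configuration defaults chosen once on realism grounds (approximate
public-payer reimbursement levels), before results were inspected:

- `dialysis_year_usd` = 7,800 (≈ R$ 40,000/year of hemodialysis);
- `retransplant_event_usd` = 5,300 (≈ R$ 27,000 transplant package; a
  retransplant also incurs a new induction dose).

Maintenance-type costs (immunosuppression, follow-up, dialysis) accrue on
**start-of-cycle** occupancy — patients who die or lose the graft during a
year are assumed to have already incurred that year's maintenance. This is
the `maintenance_timing: start` default; `end` is available. One-off event
costs (CMV, AR, graft loss, retransplant, induction) accrue on within-cycle
transition flows. The dead state accrues nothing. First-year arm totals are
also computed exactly in decimal arithmetic (`first_year_costs`) as an
auditable ledger.

## Decision metrics

ICER = ΔC/ΔE (intervention minus comparator), with dominance verdicts
(dominant, dominated, equivalent, no-effect-difference) where a ratio is
not meaningful. Net monetary benefit NMB(w) = w·ΔE − ΔC. The
cost-effectiveness acceptability curve (CEAC) is the fraction of PSA draws
with NMB ≥ 0 across a willingness-to-pay grid.

## Sensitivity analysis

- **One-way (tornado):** each transition probability is swept across its
  Wilson 95% confidence interval; each unit cost across ±10%. Bars are
  sorted by the width of the resulting ICER (or NMB) range.
- **Probabilistic:** probabilities drawn from Beta(events, n − events) with
  a Jeffreys floor of 0.5 on zero cells (so structural zeros still carry
  uncertainty); costs from Gamma distributions with the unit cost as mean
  and a coefficient of variation of 0.10 (shape = 1/cv², scale = mean·cv²).
  Draws use `numpy.random.default_rng(seed)`; identical seeds give
  bit-identical results. Default 10,000 iterations.

## Patient-level microsimulation

`graftcea.microsim` replays any transition schedule patient-by-patient with
vectorized Bernoulli draws in the same fixed order as the cohort engine
(death, graft loss, death-after-loss, retransplant, AR, CMV). Because the
cohort trace is the exact expectation of the microsimulation, the two are
cross-validated in the test suite: state occupancy must agree within 3
standard errors at 100,000 patients on the study schedules (and within
4.5 SE on randomized-schedule sweeps, a family-wise allowance across
hundreds of jointly tested cells). `aggregate()` converts simulated
histories back into the arm-by-year count-table schema, with `n_at_risk`
decremented as patients leave the functioning states.

## Numerical conventions

- Incidence percentages use decimal round-half-up to one decimal place.
- The first-year cost ledger uses exact `Decimal` arithmetic; engine
  accounting uses float64.
- Multi-year annualization of cumulative incidences uses
  p = 1 − (1 − λ)^(1/t); instantaneous rates convert via 1 − exp(−rate).
- All random seeds are explicit; derived seeds stay below 2³¹.

## Limitations

- Late-period (post-year-4) transition probabilities are an assumption, not
  data. Under the default pooled late-period rows the 10-year incremental
  cost remains negative (induction stays cost-saving) but the 10-year
  incremental graft-survival effect is slightly **negative** (≈ −0.04
  discounted years): the intervention arm shows more deaths with a
  functioning graft in the observed years, and identical late-period
  probabilities in both arms cannot recover that deficit. A 10-year
  effectiveness advantage for induction therefore requires arm-specific
  late-period inputs (supply them via `post_year4_probabilities`). The
  4-year dominance verdict is robust to plausible dialysis-cost choices
  (tested at 5,000 / 7,800 / 12,000 US$/year).
- Dialysis and retransplant costs are configuration defaults, not observed
  unit costs; conclusions that hinge on them should be swept.
- Costs and probabilities are drawn independently in the PSA; no
  correlation structure between parameters is modeled.
- The model has no age structure, no background-mortality table, and no
  utility weights (no QALYs): effectiveness is clinical (AR episodes,
  graft-survival years).
- The microsimulation generates synthetic event tables for testing and
  exploration; it is calibrated to the packaged schedules, not to external
  registries.
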