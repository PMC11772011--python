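# Default model configuration for the r-ATG induction cost-effectiveness model.
# Monetary values in US$ (SUS reimbursement perspective, R$ converted at 5.12).

horizon_years: 10
cycle_length_years: 1

# Annual discount rates. The 1-year analysis applies no discounting; the
# multi-year analyses use 5%/year for both costs and effects.
discount_rate_costs: 0.05
discount_rate_effects: 0.05

exchange_rate_brl_per_usd: 5.12

# State costs not itemised in the first-year cost table.
# dialysis_year: annual SUS reimbursement for maintenance haemodialysis
# (~R$ 40,000/yr -> US$ 7,800). retransplant_event: SUS kidney-transplant
# procedure package (~R$ 27,000 -> US$ 5,300).
dialysis_year_usd: 7800.0
retransplant_event_usd: 5300.0

# Maintenance (immunosuppression + follow-up, dialysis) accrues on the state
# occupied at the START of each cycle; "end" switches to end-of-cycle.
maintenance_timing: start

# Annual event probabilities applied from cycle 5 onward, identical for both
# arms. null -> pooled "Year 4+" observed row across arms.
post_year4_probabilities: null

# Willingness-to-pay grids (US$).
wtp_grid_ar_episodes: {start: 0, stop: 2000, step: 25}
wtp_grid_graft_years: {start: 0, stop: 20000, step: 250}

# Probabilistic sensitivity analysis.
psa_iterations: 10000
psa_cost_cv: 0.10
rng_seed: 20140617
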