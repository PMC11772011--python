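component,unit_cost_usd
r_atg_induction,255.85
immunosuppression_year,2627.71
follow_up_year,510.60
cmv_episode,412.70
ar_episode,364.46
graft_loss_event,15.77
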