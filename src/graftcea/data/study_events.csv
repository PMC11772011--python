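arm,year,n_at_risk,cmv,acute_rejection,graft_loss_prior_ar,graft_loss_no_prior_ar,death_functioning,death_after_graft_loss,retransplant
no_induction,1,466,127,236,15,6,7,4,0
no_induction,2,466,0,0,4,1,4,1,1
no_induction,3,466,0,0,4,5,2,1,0
no_induction,4+,466,0,0,3,2,4,3,2
r_atg,1,466,157,64,6,7,13,0,0
r_atg,2,466,0,0,1,2,2,1,0
r_atg,3,466,0,0,2,6,5,1,0
r_atg,4+,466,0,0,3,6,3,2,0
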