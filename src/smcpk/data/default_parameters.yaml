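# Final population pharmacokinetic parameter estimates for amodiaquine (AQ)
# and desethylamodiaquine (DEAQ) in children aged 3-59 months receiving
# seasonal malaria chemoprevention.  Values refer to a typical 10-kg child
# with full enzyme maturation; clearances/volumes are apparent (/F).
# Units: clearances L/h, volumes L, ka 1/h, ages months, LLOQ nmol/L.
f_aq: 1.0
ka: 2.85
cl_aq: 101.0
vc_aq: 314.0
q_aq: 119.0
vp_aq: 1820.0
cl_deaq: 2.33
vc_deaq: 49.1
q1_deaq: 2.31
vp1_deaq: 363.0
q2_deaq: 4.34
vp2_deaq: 98.1
age50_aq: 4.66
age50_deaq: 2.42
ref_weight: 10.0
allo_exp_cl: 0.75
allo_exp_v: 1.0
# Inter-individual variability, log-scale SDs (from printed CV%:
# 37.5, 173, 22.2, 80.4, 15.2, 68.3 respectively)
omega_f_aq: 0.36273455554815737
omega_ka: 1.1766553377862123
omega_cl_aq: 0.21933542077085294
omega_vc_aq: 0.7061167072258031
omega_cl_deaq: 0.15113286731006628
omega_vp1_deaq: 0.618765794590221
# Additive residual error on the log-concentration scale
sigma_aq: 0.829
sigma_deaq: 0.204
# Lower limits of quantification (nmol/L); configurable, set so that DEAQ
# censoring is negligible within 30 days of dosing
lloq_aq: 1.0
lloq_deaq: 1.0
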