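cause,pathway,beta,sbp_slope,beta_sbp,se,reference_exposure,age_low,age_high,sex
cerebrovascular_disease,sbp_mediated,,1.0,0.040,0.010,7.4,,,
ischaemic_heart_disease,sbp_mediated,,1.0,0.028,0.007,7.4,,,
heart_failure,sbp_mediated,,1.0,0.035,0.009,7.4,,,
aortic_aneurysm,sbp_mediated,,1.0,0.025,0.008,7.4,,,
pulmonary_embolism,sbp_mediated,,1.0,0.010,0.004,7.4,,,
rheumatic_heart_disease,sbp_mediated,,1.0,0.010,0.004,7.4,,,
hypertensive_disease,sbp_mediated,,1.0,0.050,0.013,7.4,,,
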