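# Operational cutoffs for the 13 dichotomous CSSI risk factors.
# Boundary operators are literal: "ge" fires at the threshold, "gt"/"lt"
# are strict. Editing this file changes the coding rules without a release.
obesity:
  bmi_ge: 25.0            # kg/m^2
  waist_ge_male: 90.0     # cm
  waist_ge_female: 85.0   # cm
hypertension:
  sbp_ge: 140.0           # mmHg
  dbp_ge: 90.0            # mmHg  (medication counts regardless of values)
diabetes:
  glucose_ge: 126.0       # mg/dL fasting
  hba1c_ge: 6.5           # %
dyslipidemia:
  ldl_ge: 160.0           # mg/dL
  hdl_lt: 40.0            # mg/dL
  total_chol_ge: 240.0    # mg/dL
elevated_liver_enzymes:
  ast_gt: 40.0            # IU/L
  alt_gt: 40.0            # IU/L
  ggtp_gt: 50.0           # IU/L
abnormal_resting_hr:
  hr_lt: 50.0             # beats/min (bradycardia)
  hr_gt: 100.0            # beats/min (tachycardia)
anemia:
  hb_lt_male: 13.0        # g/dL
  hb_lt_female: 12.0      # g/dL
hearing_loss:
  pta_gt: 25.0            # dB, pure-tone average 0.5-4 kHz
abnormal_pulmonary:
  fev1_fvc_lt: 70.0       # percent scale
  fev1_pred_lt: 80.0      # % of predicted
significant_smoking:
  pack_years_ge: 20.0
habitual_alcohol:
  times_per_week_ge: 2.0
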