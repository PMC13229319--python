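# Age- and sex-specific lower bounds of the "normal" VO2max category
# (mL/kg/min). A worker is coded as having low cardiorespiratory fitness
# when measured VO2max falls STRICTLY BELOW the band's lower bound.
#
# PLACEHOLDER DEFAULTS: occupational-guideline reference tables (e.g.
# KOSHA H-43-2021, Canadian Public Health Association norms) are licensed
# documents whose band boundaries are not reproduced here. The values below
# are plausible 5-year-band placeholders in the usual range for healthy
# adults; replace this file with the guideline table you intend to apply.
# Bands are [age_min, age_max) and must tile the adult range with no gaps.
male:
  - {age_min: 18, age_max: 30, lower_bound: 36.0}
  - {age_min: 30, age_max: 35, lower_bound: 34.0}
  - {age_min: 35, age_max: 40, lower_bound: 33.0}
  - {age_min: 40, age_max: 45, lower_bound: 32.0}
  - {age_min: 45, age_max: 50, lower_bound: 31.0}
  - {age_min: 50, age_max: 55, lower_bound: 29.0}
  - {age_min: 55, age_max: 60, lower_bound: 28.0}
  - {age_min: 60, age_max: 65, lower_bound: 26.0}
  - {age_min: 65, age_max: 120, lower_bound: 24.0}
female:
  - {age_min: 18, age_max: 30, lower_bound: 28.0}
  - {age_min: 30, age_max: 35, lower_bound: 26.0}
  - {age_min: 35, age_max: 40, lower_bound: 25.0}
  - {age_min: 40, age_max: 45, lower_bound: 24.0}
  - {age_min: 45, age_max: 50, lower_bound: 23.0}
  - {age_min: 50, age_max: 55, lower_bound: 21.0}
  - {age_min: 55, age_max: 60, lower_bound: 20.0}
  - {age_min: 60, age_max: 65, lower_bound: 19.0}
  - {age_min: 65, age_max: 120, lower_bound: 17.0}
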