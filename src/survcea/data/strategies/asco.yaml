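# ASCO (2013) surveillance programme, transcribed for a 60-month horizon.
# Provenance: schedule figure in the source analysis is graphical; intervals
# here are resolved toward the guideline text — history/physical and CEA
# every 3-6 months for 5 years (3-monthly in years 1-3, 6-monthly in years
# 4-5 here), abdominal/chest CT annually for 3 years, colonoscopy at 1 and
# 3 years. Month-0 (surgery-time) examinations are excluded.
name: asco
duration_months: 60
visits:
  3:  [clinical_evaluation, laboratory]
  6:  [clinical_evaluation, laboratory]
  9:  [clinical_evaluation, laboratory]
  12: [clinical_evaluation, laboratory, cect, colonoscopy]
  15: [clinical_evaluation, laboratory]
  18: [clinical_evaluation, laboratory]
  21: [clinical_evaluation, laboratory]
  24: [clinical_evaluation, laboratory, cect]
  27: [clinical_evaluation, laboratory]
  30: [clinical_evaluation, laboratory]
  33: [clinical_evaluation, laboratory]
  36: [clinical_evaluation, laboratory, cect, colonoscopy]
  42: [clinical_evaluation, laboratory]
  48: [clinical_evaluation, laboratory]
  54: [clinical_evaluation, laboratory]
  60: [clinical_evaluation, laboratory]
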