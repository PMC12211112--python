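# ESMO (2014) surveillance programme, transcribed for a 60-month horizon.
# Provenance: resolved toward the guideline text — visit and CEA every
# 3-6 months for 3 years (3-monthly here) then 6-monthly in years 4-5;
# CT every 6-12 months for the first 3 years (6-monthly here) then annually;
# colonoscopy at 1 and 3 years. Month-0 examinations are excluded.
name: esmo
duration_months: 60
visits:
  3:  [clinical_evaluation, laboratory]
  6:  [clinical_evaluation, laboratory, cect]
  9:  [clinical_evaluation, laboratory]
  12: [clinical_evaluation, laboratory, cect, colonoscopy]
  15: [clinical_evaluation, laboratory]
  18: [clinical_evaluation, laboratory, cect]
  21: [clinical_evaluation, laboratory]
  24: [clinical_evaluation, laboratory, cect]
  27: [clinical_evaluation, laboratory]
  30: [clinical_evaluation, laboratory, cect]
  33: [clinical_evaluation, laboratory]
  36: [clinical_evaluation, laboratory, cect, colonoscopy]
  42: [clinical_evaluation, laboratory]
  48: [clinical_evaluation, laboratory, cect]
  54: [clinical_evaluation, laboratory]
  60: [clinical_evaluation, laboratory, cect]
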