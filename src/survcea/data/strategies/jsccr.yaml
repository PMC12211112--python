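# JSCCR (2019) surveillance programme after curative resection of
# metastatic disease, transcribed for a 60-month horizon. Provenance:
# resolved toward the guideline text — visit and tumour markers every 3
# months for 5 years; chest/abdomen CT every 4 months in years 1-3 and
# every 6 months in years 4-5; colonoscopy at 1 and 3 years. Month-0
# examinations are excluded.
name: jsccr
duration_months: 60
visits:
  3:  [clinical_evaluation, laboratory]
  4:  [cect]
  6:  [clinical_evaluation, laboratory]
  8:  [cect]
  9:  [clinical_evaluation, laboratory]
  12: [clinical_evaluation, laboratory, cect, colonoscopy]
  15: [clinical_evaluation, laboratory]
  16: [cect]
  18: [clinical_evaluation, laboratory]
  20: [cect]
  21: [clinical_evaluation, laboratory]
  24: [clinical_evaluation, laboratory, cect]
  27: [clinical_evaluation, laboratory]
  28: [cect]
  30: [clinical_evaluation, laboratory]
  32: [cect]
  33: [clinical_evaluation, laboratory]
  36: [clinical_evaluation, laboratory, cect, colonoscopy]
  39: [clinical_evaluation, laboratory]
  42: [clinical_evaluation, laboratory, cect]
  45: [clinical_evaluation, laboratory]
  48: [clinical_evaluation, laboratory, cect]
  51: [clinical_evaluation, laboratory]
  54: [clinical_evaluation, laboratory, cect]
  57: [clinical_evaluation, laboratory]
  60: [clinical_evaluation, laboratory, cect]
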