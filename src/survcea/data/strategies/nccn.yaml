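# NCCN (2021) surveillance programme for resected metastatic disease,
# transcribed for a 60-month horizon. Provenance: resolved toward the
# guideline text — history/physical and CEA every 3 months for 2 years then
# every 6 months through year 5; chest/abdomen/pelvis CT every 6 months for
# 2 years then annually through year 5; colonoscopy at 1 and 3 years.
# Month-0 examinations are excluded.
name: nccn
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
  30: [clinical_evaluation, laboratory]
  36: [clinical_evaluation, laboratory, cect, colonoscopy]
  42: [clinical_evaluation, laboratory]
  48: [clinical_evaluation, laboratory, cect]
  54: [clinical_evaluation, laboratory]
  60: [clinical_evaluation, laboratory, cect]
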