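# Strategy 6: a deliberately more intensive programme than any guideline
# schedule, used to probe whether surveillance benefit plateaus. Visit,
# laboratory work-up and CT every 3 months for the full 5 years;
# colonoscopy at 1 and 3 years. Month-0 examinations are excluded.
name: strategy6
duration_months: 60
visits:
  3:  [clinical_evaluation, laboratory, cect]
  6:  [clinical_evaluation, laboratory, cect]
  9:  [clinical_evaluation, laboratory, cect]
  12: [clinical_evaluation, laboratory, cect, colonoscopy]
  15: [clinical_evaluation, laboratory, cect]
  18: [clinical_evaluation, laboratory, cect]
  21: [clinical_evaluation, laboratory, cect]
  24: [clinical_evaluation, laboratory, cect]
  27: [clinical_evaluation, laboratory, cect]
  30: [clinical_evaluation, laboratory, cect]
  33: [clinical_evaluation, laboratory, cect]
  36: [clinical_evaluation, laboratory, cect, colonoscopy]
  39: [clinical_evaluation, laboratory, cect]
  42: [clinical_evaluation, laboratory, cect]
  45: [clinical_evaluation, laboratory, cect]
  48: [clinical_evaluation, laboratory, cect]
  51: [clinical_evaluation, laboratory, cect]
  54: [clinical_evaluation, laboratory, cect]
  57: [clinical_evaluation, laboratory, cect]
  60: [clinical_evaluation, laboratory, cect]
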