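# survcea

Cost-effectiveness microsimulation of postoperative surveillance strategies
after curative resection of stage IV colorectal cancer with liver and/or
lung metastases.

## The problem

After curative (R0) resection of metastatic colorectal cancer, roughly
three quarters of patients recur, and whether a recurrence can itself be
resected — rather than managed with palliative chemotherapy — drives both
survival and cost. Professional societies (ASCO, ASCRS, NCCN, ESMO, JSCCR)
recommend surveillance schedules of very different intensity: office
visits with tumour markers, contrast-enhanced CT, and colonoscopy at
different frequencies over five years. `survcea` is for health-economics
and clinical-epidemiology researchers who want to compare such schedules
on cost per quality-adjusted life year from a payer's perspective.

## The model

A semi-Markov patient-level simulation over six health states — no
recurrence, undetected recurrence, resectable recurrence (a one-cycle
surgery tunnel), unresectable recurrence (chemotherapy), after resection
of recurrence, and death — in 180 monthly cycles (15 years):

- **Hazards** come from Kaplan–Meier anchor summaries S(12), S(36), S(60)
  via piecewise-exponential fits, λ_k = −ln(S_k/S_{k−1})/(t_k−t_{k−1}),
  which reproduce every anchor exactly. Recurrence risk is clocked from
  the latest curative resection; disease mortality from recurrence onset
  (it carries through detection into chemotherapy, so early detection
  helps only via the resection pathway — no lead-time artefact).
- **Detection**: a visit detects a latent recurrence with probability
  1 − Π(1 − sens_i) over the examinations performed (clinical evaluation
  0.23, laboratory 0.58, CECT 0.92; colonoscopy contributes cost only).
- **Treatment**: a detected, still-operable recurrence is resected with
  fixed probability 0.38 (hepatectomy 70% / pneumonectomy 30%), after
  which surveillance restarts from the beginning of the schedule;
  otherwise monthly chemotherapy, from which conversion surgery occurs at
  the per-cycle rate matching a 19.2% five-year cumulative probability.
  While undetected, an operable lesion becomes chemotherapy-only with
  per-month probability θ (calibrated; see `calibrate_theta`).
- **Accrual**: utilities 0.74 (disease-free / post-resection) and 0.25
  (chemotherapy); costs in JPY (reported in USD at 150 JPY/USD); costs,
  QALYs and life-years discounted at 2% per year.

The decision layer computes simple-dominance frontiers, incremental
cost-effectiveness ratios (ICER = ΔC/ΔE), net monetary benefit
(NMB = λ·QALYs − cost) and, via probabilistic sensitivity analysis with
beta/gamma parameter distributions and common random numbers,
cost-effectiveness acceptability curves.

## Worked example

```bash
python examples/base_case.py
```

prints (50 000 simulated patients per schedule, seed 7):

```
strategy     cost (JPY)     LYs   QALYs  resect.
asco         12,769,212   8.061   4.983    0.451
ascrs        12,774,674   8.064   4.986    0.451
esmo         13,142,023   8.083   4.979    0.456
jsccr        13,499,488   8.098   4.972    0.460
nccn         12,984,492   8.078   4.986    0.455
strategy6    13,659,847   8.086   4.963    0.457

dominated by simple dominance: ['esmo', 'jsccr', 'strategy6']
  frontier: asco       ICER vs previous = - JPY/QALY
  frontier: ascrs      ICER vs previous = 1,538,963 JPY/QALY
  frontier: nccn       ICER vs previous = 973,486,346 JPY/QALY
optimal at WTP 5,000,000 JPY/QALY: ascrs
```

Each row is one surveillance schedule: expected discounted cost per
patient, life-years, QALYs, and the share of first recurrences ever
treated surgically (upfront resection or conversion). Intensive schedules
detect recurrences a few weeks earlier, which raises resectability and
life-years slightly but also moves unresectable patients onto
chemotherapy (utility 0.25) sooner, so under this transition structure
the cheaper schedules carry the net monetary benefit at a willingness to
pay of 5 million JPY/QALY. `docs/methods.md` discusses this behaviour and
how it relates to the reconstruction choices in detail.

Other entry points: `examples/survival_from_anchors.py` (hazard fitting),
`examples/psa_ceac.py` (acceptability curves),
`examples/synthetic_cohort_roundtrip.py` (cohort generation and parameter
re-derivation), `examples/calibrate_progression.py` (θ calibration), and
the `survcea` CLI (`run-base-case`, `analyze`, `run-psa`,
`make-synthetic`, `calibrate-theta`, `run-pipeline`).

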