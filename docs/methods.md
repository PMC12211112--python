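# Methods

## Model structure

`survcea` implements a patient-level (microsimulation) state-transition
model of the clinical course after curative resection of stage IV
colorectal cancer with liver/lung metastases. Six states: *no
recurrence*, *undetected recurrence*, *resectable recurrence*,
*unresectable recurrence* (on chemotherapy), *after resection of
recurrence*, *death*. Cycles are one month; the horizon is 180 cycles
(15 years); scheduled surveillance stops after 60 recurrence-free cycles
on the current surveillance clock and restarts from the beginning of the
schedule after re-resection of a recurrence.

Within a cycle events are resolved in a fixed order: (0) the one-cycle
surgery tunnel resolves into *after resection*; (1) disease transition by
the time-in-state hazard (recurrence, or death); (2) latent progression
of an undetected operable lesion at rate θ; (3) the scheduled visit —
cost first, then detection; (4) treatment assignment on detection
(resection with fixed probability 0.38, else chemotherapy); (5) accrual
of cost, QALYs and life-years at the cycle's discount factor. Death
accrues nothing in the cycle it occurs; no half-cycle correction is
applied (with monthly cycles and event-per-cycle simulation the
correction is far below Monte-Carlo error).

The model is semi-Markov through three clocks:

- recurrence risk after the primary resection uses months since surgery;
- recurrence risk after re-resection uses months since that resection;
- disease mortality uses months since **recurrence onset**.

The last choice deserves emphasis. The overall-survival input is
measured from the diagnosis of the recurrence, and a model that starts
the death clock only at detection makes an undetected recurrence
immortal: detection would then *start* the hazard, surveillance would be
strictly harmful, and the qualitative finding that intensity buys
life-years would invert. Clocking mortality from onset — carried through
detection into chemotherapy, cleared only by resection — removes both
that artefact and classic lead-time bias: earlier detection improves
survival exactly insofar as it enables surgery. In the cohort the input
curve derives from, detection followed onset closely (quarterly
surveillance), so using the diagnosis-anchored curve from onset is a
close approximation.

## Survival inputs

All time-to-event inputs are Kaplan–Meier summaries at 12/36/60 months
(recurrence-free survival after primary resection: 47.9/28.5/26.7%;
after re-resection: 66.7/30.3/23.9%; overall survival from chemotherapy
induction: 85.5/52.9/26.7%). A piecewise-exponential hazard — constant
within (0,12], (12,36], (36,60] — is the minimal model that reproduces
every anchor exactly and gives per-cycle probabilities in closed form.
Beyond 60 months the recurrence hazards use a `zero` tail (no recurrence
after five recurrence-free years, matching the near-flat 3→5-year
anchors and the surveillance stopping rule) and the chemotherapy OS
hazard uses `continue_last` (patients keep dying beyond five years);
both are configurable per endpoint in the parameter file. The conversion
pathway inverts the 19.2% five-year cumulative rate to a per-cycle
probability of 0.003547 ignoring competing death, the only
reconstruction the single printed number supports.

## Detection

Examinations at a visit detect a latent distant recurrence independently
(sensitivities: clinical evaluation 0.23, laboratory 0.58, CECT 0.92),
combined as 1 − Π(1 − sens). Colonoscopy carries cost but no
distant-recurrence sensitivity. Specificity is treated as 1 — no
false-positive work-ups. Sensitivities are per-visit and constant over
lesion age.

## The resectability mechanism and θ

The data behind the model fix the resection probability at detection
(0.38) but report strategy-dependent resectability outcomes, so some
mechanism must link detection delay to operability. We model it as a
latent per-month probability θ that an undetected, still-operable lesion
becomes chemotherapy-only. θ is not identifiable from the inputs and is
calibrated by bisection so that a reference schedule (JSCCR) reproduces
a target resectability of the initial recurrence (46.1%), with common
random numbers making the objective deterministic and monotone.
Calibration at 200 000 trials pins θ to 0: the fixed 38% resection rate
plus the conversion pathway already reproduce the target under that
schedule (achieved 45.9% ± 0.13%, within Monte-Carlo noise). The
calibration log ships in `data/params.yaml`; targets within 3 Monte-Carlo
SEs of an endpoint of the achievable range are pinned to that endpoint
rather than rejected, since a hard error there would be
noise-triggered. Resectability is counted as the share of patients with
a first recurrence whose first recurrence was ever treated surgically —
upfront resection or later conversion — which is what lets outcomes
exceed the 38% input.

## Costs, utilities, discounting

Costs are JPY per the Japanese fee schedule: laboratory 11 750, CECT
38 190, colonoscopy 15 500 per examination; hepatectomy 1 950 000 and
pneumonectomy 1 477 000 charged in the surgery tunnel cycle (70/30
split); chemotherapy 485 000 per cycle in the unresectable state until
death or conversion. Utilities: 0.74 disease-free and post-resection
(also applied to the undetected state — the patient is asymptomatic and
unaware — and the tunnel cycle), 0.25 under chemotherapy, 0 dead. Costs,
QALYs and life-years are discounted at 2%/year as (1.02)^(−t/12); a
`discount_lys` flag exposes undiscounted life-years. USD figures are
reporting-only at a fixed 150 JPY/USD.

## Surveillance schedules

Schedules are pure data (`data/strategies/*.yaml`): month-since-clock-
reset → set of examinations, 60-month duration, colonoscopy at months 12
and 36 in every programme. The guideline figures the six programmes come
from are graphical, so the shipped files are transcriptions resolved
toward each issuing guideline's text, with provenance comments in each
file; engine correctness is tested against small documented stand-in
schedules so nothing depends on the transcription. Month-0
(surgery-time) examinations are excluded.

## Simulation engine and randomness

The engine consumes a pre-generated uniform array indexed by (patient,
cycle, purpose) — seven purposes per cycle in fixed order — produced by
one seeded PCG64 stream and evaluated by a numba kernel; a line-by-line
pure-Python stepper serves as the reference implementation and the test
suite checks the two draw-for-draw. Because draws are positional, runs
are bit-reproducible given the seed, simulations at different θ or
different schedules share the same underlying disease process (common
random numbers), and the PSA shares one inner draw array across all
strategies and all outer draws — so collapsing every distribution to a
point mass reproduces the base-case decision exactly, and strategy
contrasts are free of between-run Monte-Carlo noise.

## Decision analysis

Strategies more costly and less effective than another are removed by
simple dominance; extended dominance is deliberately not applied, so the
willingness-to-pay decision maximises net monetary benefit over all
strategies (ties break to lower cost, then name). ICERs are reported
along the cost-ordered frontier. The PSA samples betas for probabilities
(from raw counts — 33 resectable of 88 recurrences — where available,
otherwise moment-matched with the printed low/high read as a central 95%
interval; a `range_is_95ci` switch exposes the alternative
read-as-±2 SD convention) and gammas for costs (mean at base, ±25%
bounds as a 95% interval). Survival anchors are resampled jointly with
monotonicity enforced by rejection (≤1000 tries); the
hepatectomy/pneumonectomy split always sums to one; θ, being a
calibrated structural constant, is not resampled.

## Synthetic cohorts

`generate_cohort` emulates the 119-patient study structure: recurrence
times from the fitted recurrence hazard, Bernoulli(0.38) resectability,
chemotherapy survival from the OS hazard, exponential conversion times
matching 19.2%/60 months, and administrative censoring from uniform
accrual over 120 months (median follow-up ≈ 58 months, near the study's
58.4). Demographics (age, sex, tumour site at the study's frequencies —
including 38.7% rectal) are inert labels. What the generator does not
emulate: covariate-dependent hazards, non-adherence, inter-visit
symptomatic presentation, site-specific recurrence biology. Passing
round-trip tests therefore show the estimation and simulation machinery
is self-consistent, not that the model captures every feature of real
surveillance data.

## Problem sizes and numerical choices

Test and script scales were chosen to keep full runs in minutes on one
CPU: base-case checks use 100 000 trials (Monte-Carlo SE ≈ 0.005 QALYs,
0.2 points of resectability), parameter-recovery checks use 10 000
patient cohorts over 100 replicates, and the PSA uses 500 outer × 10 000
inner draws. Anchor round-trips are exact to 1e−12; monthly compounding
is checked to 1e−9; bisection tolerance for θ is 5e−4 with at most 40
iterations. Degenerate inputs fail loudly: zero-survival anchors,
non-monotone anchors, cumulative probabilities of 1, unknown
examinations, and unreachable calibration targets all raise validation
or calibration errors.

## Known limitations and observed behaviour

- With mortality clocked at onset and θ calibrated to 0, detection
  timing affects survival only through rescue-before-death and earlier
  conversion, so the simulated spread in resectability across the six
  schedules is about one percentage point, and detection of an
  unresectable recurrence moves utility from 0.74 to 0.25 without
  changing its survival. Net effect: denser schedules buy slightly more
  life-years at slightly fewer QALYs and higher cost, and the cheapest
  schedules carry the net monetary benefit. The QALY component of
  schedule-intensity monotonicity is therefore guaranteed only when the
  latent-progression mechanism is active (θ meaningfully > 0); the
  property tests exercise it at θ = 0.05, where denser schedules gain
  both resectability and QALYs.
- A fixed share (26.7%) of patients never recur under the zero-tail
  recurrence hazard and accrue the full discounted 15-year annuity;
  together with post-resection survivors this puts mean discounted
  life-years near 8. Evaluations whose published totals are
  substantially lower imply additional death pathways (e.g. background
  or perioperative mortality) that the six-state structure modeled here
  does not contain.
- No background (other-cause) or perioperative mortality; no
  radiofrequency ablation or stereotactic radiotherapy; no adherence
  modelling; no false-positive costs; resection and conversion rates are
  time-fixed by design.
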