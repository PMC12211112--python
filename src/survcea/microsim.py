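"""Semi-Markov patient-level simulation of surveillance after curative resection.

Patients move monthly between six states — no recurrence, undetected
recurrence, resectable recurrence (a one-cycle surgery tunnel), unresectable
recurrence (on chemotherapy), after resection of recurrence, and death —
over a 15-year horizon (180 one-month cycles).  Hazards are semi-Markov:
recurrence risk is clocked from the most recent curative resection, and
disease mortality from the onset of the recurrence — the clock runs
whether or not the lesion has been detected and carries over into
chemotherapy, so earlier detection improves survival only through the
resection pathway (no lead-time artefact).  Scheduled visits (per the
surveillance strategy and the patient's surveillance clock, which resets
after re-resection) accrue cost and may detect a latent recurrence; detected
lesions that are still operable are resected with a fixed probability,
others go to chemotherapy, from which conversion surgery remains possible.
Costs, QALYs and (by default) life-years are discounted at 2% per year.

The resectability mechanism the data cannot identify directly is
reconstructed as a latent progression rate ``theta``: while a recurrence
remains undetected, it shifts from operable to chemotherapy-only with
per-month probability ``theta``.  ``theta`` is calibrated so a reference
strategy reproduces its observed resectability of the initial recurrence
(see :func:`calibrate_theta`).

Two implementations share one contract: a readable pure-Python stepper
(:func:`step`, the reference) and a numba kernel (production); the test
suite checks them draw-for-draw against each other.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import _engine
from ._engine import (
    AFTER_RES,
    CHEMO,
    DEATH,
    FR_NONE,
    FR_NOT_RESECTED,
    FR_PENDING,
    FR_RESECTED,
    N_PURPOSES,
    N_STATES,
    NO_REC,
    TUNNEL,
    UNDET,
    D_CONV,
    D_DEATH,
    D_DET,
    D_ORGAN,
    D_PROG,
    D_REC,
    D_RESECT,
)
from .detection import visit_detection_prob
from .errors import CalibrationError, ValidationError
from .params import ParamSet
from .strategies import SurveillanceStrategy, tests_due
from .survival import cumulative_to_per_cycle, fit_piecewise_exponential, per_cycle_probs

STATE_NAMES = (
    "no_recurrence",
    "undetected_recurrence",
    "resectable_recurrence",
    "unresectable_recurrence",
    "after_resection_of_recurrence",
    "death",
)
_FR_LABELS = {FR_NONE: None, FR_PENDING: "pending", FR_RESECTED: "yes", FR_NOT_RESECTED: "no"}


@dataclass(frozen=True)
class SimSettings:
    """Simulation settings (defaults are the base-case analysis settings)."""

    n_trials: int = 500_000
    horizon_cycles: int = 180
    cycle_months: int = 1
    surveillance_stop: int = 60
    discount_rate_annual: float = 0.02
    discount_lys: bool = True
    seed: int = 0
    initial_state: str = "no_recurrence"
    chunk_size: int = 25_000

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if self.discount_rate_annual < 0:
            raise ValidationError("discount rate must be >= 0")
        if self.initial_state not in STATE_NAMES:
            raise ValidationError(f"unknown initial state {self.initial_state!r}")


@dataclass(frozen=True)
class SimulationResult:
    """Cohort means with Monte-Carlo standard errors for one strategy."""

    strategy: str
    n_trials: int
    seed: int
    theta: float
    mean_cost: float
    se_cost: float
    mean_lys: float
    se_lys: float
    mean_qalys: float
    se_qalys: float
    resectability: float
    se_resectability: float
    n_first_recurrence: int


class EngineInputs(NamedTuple):
    p_rec1: np.ndarray
    p_rec2: np.ndarray
    p_death: np.ndarray
    theta: float
    p_resect: float
    p_conv: float
    prop_hep: float
    has_visit: np.ndarray
    visit_cost: np.ndarray
    det_prob: np.ndarray
    util: np.ndarray
    chemo_cost: float
    hep_cost: float
    pneu_cost: float
    disc: np.ndarray
    disc_ly: np.ndarray
    horizon: int
    surv_stop: int
    init_state: int


def discount_factor(cycle_index: int, annual_rate: float) -> float:
    """Discount factor ``(1 + r)^(-cycle/12)`` for a monthly cycle index."""
    if cycle_index < 0:
        raise ValidationError("cycle_index must be >= 0")
    return (1.0 + annual_rate) ** (-cycle_index / 12.0)


def build_engine_inputs(
    params: ParamSet, strategy: SurveillanceStrategy, settings: SimSettings
) -> EngineInputs:
    """Precompute every per-cycle array the engine consumes."""
    horizon = settings.horizon_cycles
    pw1 = fit_piecewise_exponential(
        params.rfs_primary, params.tail_policies.get("rfs_primary", "zero")
    )
    pw2 = fit_piecewise_exponential(
        params.rfs_post_resection, params.tail_policies.get("rfs_post_resection", "zero")
    )
    pwd = fit_piecewise_exponential(
        params.os_chemo, params.tail_policies.get("os_chemo", "continue_last")
    )
    stop = settings.surveillance_stop
    has_visit = np.zeros(stop + 1, dtype=np.int8)
    vcost = np.zeros(stop + 1)
    dprob = np.zeros(stop + 1)
    for month in range(1, stop + 1):
        exams = tests_due(strategy, month)
        if exams:
            has_visit[month] = 1
            vcost[month] = sum(params.costs.exam_cost(e) for e in exams)
            dprob[month] = visit_detection_prob(exams, params.sensitivities)
    u = params.utilities
    util = np.array(
        [
            u.no_evidence_of_disease,  # no recurrence
            u.no_evidence_of_disease,  # undetected: asymptomatic and unaware
            u.after_resection,         # surgery tunnel cycle
            u.under_chemotherapy,
            u.after_resection,
            u.death,
        ]
    )
    cycles = np.arange(horizon + 1, dtype=float)
    disc = (1.0 + settings.discount_rate_annual) ** (-cycles / 12.0)
    disc_ly = disc if settings.discount_lys else np.ones_like(disc)
    return EngineInputs(
        p_rec1=per_cycle_probs(pw1, horizon),
        p_rec2=per_cycle_probs(pw2, horizon),
        p_death=per_cycle_probs(pwd, horizon),
        theta=params.theta,
        p_resect=params.rates.resection_rate_at_first_recurrence,
        p_conv=cumulative_to_per_cycle(
            params.rates.conversion_cum_5yr, params.conversion_window_months
        ),
        prop_hep=params.rates.prop_hepatectomy,
        has_visit=has_visit,
        visit_cost=vcost,
        det_prob=dprob,
        util=util,
        chemo_cost=params.costs.chemotherapy_per_month,
        hep_cost=params.costs.hepatectomy,
        pneu_cost=params.costs.pneumonectomy,
        disc=disc,
        disc_ly=disc_ly,
        horizon=horizon,
        surv_stop=stop,
        init_state=STATE_NAMES.index(settings.initial_state),
    )


# ---------------------------------------------------------------------------
# Pure-Python reference implementation
# ---------------------------------------------------------------------------

@dataclass
class PatientRecord:
    """Trajectory bookkeeping for a single simulated patient."""

    current_state: int = NO_REC
    months_in_state: int = 0
    surveillance_clock: int = 0
    latent_surgery_eligible: bool = False
    first_recurrence: int = FR_NONE
    alive_months: int = 0
    discounted_cost: float = 0.0
    discounted_qalys: float = 0.0
    discounted_lys: float = 0.0

    @property
    def state_name(self) -> str:
        return STATE_NAMES[self.current_state]

    @property
    def first_recurrence_resected(self) -> str | None:
        """Tri-state: 'pending' / 'yes' / 'no', or None if never recurred."""
        return _FR_LABELS[self.first_recurrence]


def step(
    patient: PatientRecord,
    cycle_index: int,
    inputs: EngineInputs,
    draws_row: np.ndarray,
) -> PatientRecord:
    """Advance one patient by exactly one cycle (reference implementation).

    ``draws_row`` holds this cycle's uniforms in purpose order.  Mutates and
    returns ``patient``.  The numba kernel follows this function line by
    line; the test suite asserts draw-for-draw agreement.
    """
    if patient.current_state == DEATH:
        raise ValidationError("cannot step a dead patient")
    t = cycle_index
    df = inputs.disc[t]
    entered_tunnel = False
    # (0) tunnel resolution
    if patient.current_state == TUNNEL:
        patient.current_state = AFTER_RES
        patient.months_in_state = 0
        patient.surveillance_clock = 0
    # (1) disease transition
    s = patient.current_state
    if s == NO_REC:
        if draws_row[D_REC] < inputs.p_rec1[t]:
            patient.current_state = UNDET
            patient.latent_surgery_eligible = True
            patient.months_in_state = 0  # recurrence-onset clock starts
            if patient.first_recurrence == FR_NONE:
                patient.first_recurrence = FR_PENDING
    elif s == AFTER_RES:
        patient.months_in_state += 1
        if draws_row[D_REC] < inputs.p_rec2[patient.months_in_state]:
            patient.current_state = UNDET
            patient.latent_surgery_eligible = True
            patient.months_in_state = 0
    elif s == UNDET:
        # disease mortality is clocked from recurrence onset, detected or
        # not; resection is what clears the clock (no lead-time bias)
        patient.months_in_state += 1
        if draws_row[D_DEATH] < inputs.p_death[patient.months_in_state]:
            patient.current_state = DEATH
            if patient.first_recurrence == FR_PENDING:
                patient.first_recurrence = FR_NOT_RESECTED
            return patient
    elif s == CHEMO:
        patient.months_in_state += 1
        if draws_row[D_DEATH] < inputs.p_death[patient.months_in_state]:
            patient.current_state = DEATH
            if patient.first_recurrence == FR_PENDING:
                patient.first_recurrence = FR_NOT_RESECTED
            return patient  # accruals frozen at death
        if draws_row[D_CONV] < inputs.p_conv:
            if patient.first_recurrence == FR_PENDING:
                patient.first_recurrence = FR_RESECTED
            patient.current_state = TUNNEL
            entered_tunnel = True
    # (2) latent progression
    if (
        patient.current_state == UNDET
        and patient.latent_surgery_eligible
        and draws_row[D_PROG] < inputs.theta
    ):
        patient.latent_surgery_eligible = False
    # (3)+(4) scheduled visit
    if patient.current_state in (NO_REC, UNDET, AFTER_RES):
        patient.surveillance_clock += 1
        sc = patient.surveillance_clock
        if sc <= inputs.surv_stop and inputs.has_visit[sc]:
            patient.discounted_cost += inputs.visit_cost[sc] * df
            if patient.current_state == UNDET and draws_row[D_DET] < inputs.det_prob[sc]:
                if patient.latent_surgery_eligible and draws_row[D_RESECT] < inputs.p_resect:
                    if patient.first_recurrence == FR_PENDING:
                        patient.first_recurrence = FR_RESECTED
                    patient.current_state = TUNNEL
                    entered_tunnel = True
                else:
                    patient.current_state = CHEMO  # onset clock carries over
    # (5) accrual
    if entered_tunnel:
        surgery = inputs.hep_cost if draws_row[D_ORGAN] < inputs.prop_hep else inputs.pneu_cost
        patient.discounted_cost += surgery * df
    if patient.current_state == CHEMO:
        patient.discounted_cost += inputs.chemo_cost * df
    patient.discounted_qalys += inputs.util[patient.current_state] / 12.0 * df
    patient.discounted_lys += inputs.disc_ly[t] / 12.0
    patient.alive_months += 1
    return patient


def simulate_patient_reference(inputs: EngineInputs, draws: np.ndarray) -> PatientRecord:
    """Run one patient to death or horizon with the pure-Python stepper."""
    patient = PatientRecord(current_state=inputs.init_state)
    if inputs.init_state == UNDET:
        patient.latent_surgery_eligible = True
    if inputs.init_state in (UNDET, CHEMO):
        patient.first_recurrence = FR_PENDING
    for t in range(1, inputs.horizon + 1):
        step(patient, t, inputs, draws[t - 1])
        if patient.current_state == DEATH:
            break
    if patient.first_recurrence == FR_PENDING:
        patient.first_recurrence = FR_NOT_RESECTED
    return patient


# ---------------------------------------------------------------------------
# Production path
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientArrays:
    """Per-patient terminal accruals for a whole simulated cohort."""

    cost: np.ndarray
    qalys: np.ndarray
    lys: np.ndarray
    alive_months: np.ndarray
    first_recurrence: np.ndarray  # FR_* codes


def simulate_patients(
    params: ParamSet, strategy: SurveillanceStrategy, settings: SimSettings
) -> PatientArrays:
    """Simulate ``settings.n_trials`` independent patients (chunked)."""
    inputs = build_engine_inputs(params, strategy, settings)
    rng = np.random.default_rng(settings.seed)
    parts: list[tuple] = []
    remaining = settings.n_trials
    while remaining > 0:
        m = min(settings.chunk_size, remaining)
        draws = rng.random((m, settings.horizon_cycles, N_PURPOSES))
        parts.append(_engine.run_engine(inputs, draws)[:5])
        remaining -= m
    cost, qaly, ly, alive, fr = (np.concatenate(cols) for cols in zip(*parts))
    return PatientArrays(cost, qaly, ly, alive, fr)


def summarize(
    arrays: PatientArrays, strategy_name: str, settings: SimSettings, theta: float
) -> SimulationResult:
    n = arrays.cost.size

    def mean_se(x):
        return float(np.mean(x)), float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else 0.0

    mc, sc = mean_se(arrays.cost)
    ml, sl = mean_se(arrays.lys)
    mq, sq = mean_se(arrays.qalys)
    recurred = arrays.first_recurrence != FR_NONE
    n_rec = int(np.count_nonzero(recurred))
    if n_rec:
        p = float(np.count_nonzero(arrays.first_recurrence == FR_RESECTED) / n_rec)
        se_p = math.sqrt(p * (1.0 - p) / n_rec)
    else:
        p, se_p = float("nan"), float("nan")
    return SimulationResult(
        strategy=strategy_name,
        n_trials=n,
        seed=settings.seed,
        theta=theta,
        mean_cost=mc,
        se_cost=sc,
        mean_lys=ml,
        se_lys=sl,
        mean_qalys=mq,
        se_qalys=sq,
        resectability=p,
        se_resectability=se_p,
        n_first_recurrence=n_rec,
    )


def simulate_cohort(
    params: ParamSet, strategy: SurveillanceStrategy, settings: SimSettings
) -> SimulationResult:
    """Cohort means and Monte-Carlo SEs; bit-reproducible given the seed."""
    arrays = simulate_patients(params, strategy, settings)
    return summarize(arrays, strategy.name, settings, params.theta)


def simulate_patient(
    params: ParamSet, strategy: SurveillanceStrategy, seed: int,
    settings: SimSettings | None = None,
) -> PatientRecord:
    """Simulate a single patient trajectory (reference stepper)."""
    settings = dataclasses.replace(settings or SimSettings(n_trials=1), n_trials=1, seed=seed)
    inputs = build_engine_inputs(params, strategy, settings)
    draws = np.random.default_rng(seed).random((settings.horizon_cycles, N_PURPOSES))
    return simulate_patient_reference(inputs, draws)


def occupancy_trace(
    params: ParamSet, strategy: SurveillanceStrategy, settings: SimSettings
) -> np.ndarray:
    """State-occupancy counts, shape ``(horizon+1, 6)``; rows sum to n_trials."""
    inputs = build_engine_inputs(params, strategy, settings)
    rng = np.random.default_rng(settings.seed)
    occ_total = np.zeros((settings.horizon_cycles + 1, N_STATES), dtype=np.int64)
    remaining = settings.n_trials
    while remaining > 0:
        m = min(settings.chunk_size, remaining)
        draws = rng.random((m, settings.horizon_cycles, N_PURPOSES))
        occ_total += _engine.run_engine(inputs, draws, trace=True)[5]
        remaining -= m
    return occ_total


# ---------------------------------------------------------------------------
# Calibration of the latent progression rate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    theta: float
    achieved: float
    target: float
    n_trials: int
    seed: int
    iterations: int
    achievable_range: tuple[float, float]


def _resectability_at(params, strategy, settings, theta) -> tuple[float, float]:
    res = simulate_cohort(params.replace(theta=theta), strategy, settings)
    return res.resectability, res.se_resectability


def calibrate_theta(
    params: ParamSet,
    reference_strategy: SurveillanceStrategy,
    target_resectability: float,
    settings: SimSettings,
    tol: float = 5e-4,
    max_iter: int = 40,
) -> CalibrationResult:
    """Bisection on ``theta`` so the reference strategy hits its
    resectability-of-initial-recurrence target.

    Resectability is monotone non-increasing in ``theta``; evaluations share
    one seed (common random numbers), so the objective is deterministic and
    bisection converges.  Raises :class:`CalibrationError` with the
    achievable range if the target lies outside ``theta`` in [0, 1]; a
    target within Monte-Carlo noise (3 SEs) of an endpoint is treated as
    reachable and pinned to that endpoint.
    """
    if not (0.0 <= target_resectability <= 1.0):
        raise ValidationError("target resectability must be in [0, 1]")
    lo, hi = 0.0, 1.0
    r_lo, se_lo = _resectability_at(params, reference_strategy, settings, lo)  # max
    r_hi, se_hi = _resectability_at(params, reference_strategy, settings, hi)  # min
    slack_lo = max(tol, 3.0 * se_lo)
    slack_hi = max(tol, 3.0 * se_hi)
    if not (r_hi - slack_hi <= target_resectability <= r_lo + slack_lo):
        raise CalibrationError(
            f"target {target_resectability:.3f} outside achievable resectability "
            f"range [{r_hi:.3f}, {r_lo:.3f}] for strategy {reference_strategy.name!r}"
        )
    if target_resectability >= r_lo:  # pinned at the no-progression endpoint
        return CalibrationResult(
            theta=lo, achieved=r_lo, target=target_resectability,
            n_trials=settings.n_trials, seed=settings.seed, iterations=0,
            achievable_range=(r_hi, r_lo),
        )
    if target_resectability <= r_hi:
        return CalibrationResult(
            theta=hi, achieved=r_hi, target=target_resectability,
            n_trials=settings.n_trials, seed=settings.seed, iterations=0,
            achievable_range=(r_hi, r_lo),
        )
    best_theta, best_r = (lo, r_lo) if abs(r_lo - target_resectability) < abs(
        r_hi - target_resectability
    ) else (hi, r_hi)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        r_mid, _ = _resectability_at(params, reference_strategy, settings, mid)
        if abs(r_mid - target_resectability) < abs(best_r - target_resectability):
            best_theta, best_r = mid, r_mid
        if abs(r_mid - target_resectability) <= tol:
            break
        if r_mid > target_resectability:
            lo = mid  # need more progression
        else:
            hi = mid
    return CalibrationResult(
        theta=best_theta,
        achieved=best_r,
        target=target_resectability,
        n_trials=settings.n_trials,
        seed=settings.seed,
        iterations=iterations,
        achievable_range=(r_hi, r_lo),
    )
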