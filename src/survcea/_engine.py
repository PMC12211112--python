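"""Numba kernel for the patient-level simulation.

The kernel consumes a pre-generated uniform draw array of shape
``(n_patients, horizon, N_PURPOSES)``: draws are indexed positionally by
(patient, cycle, purpose), so results are bit-reproducible given the seed
and the same underlying disease-process draws are shared when two
strategies (or two theta values) are simulated from the same array —
common random numbers by construction.

Event order within a cycle is fixed: (0) resolve the one-cycle surgery
tunnel, (1) disease transition by time-in-state hazard, (2) latent
progression of an undetected operable lesion, (3) scheduled visit — cost
then detection, (4) treatment assignment on detection, (5) accrual at this
cycle's discount factor.  Death accrues nothing in the cycle it occurs
(no half-cycle correction).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Health states.
NO_REC, UNDET, TUNNEL, CHEMO, AFTER_RES, DEATH = 0, 1, 2, 3, 4, 5
N_STATES = 6

# Draw purposes per (patient, cycle).
D_REC, D_PROG, D_DET, D_RESECT, D_CONV, D_DEATH, D_ORGAN = range(7)
N_PURPOSES = 7

# First-recurrence bookkeeping codes.
FR_NONE, FR_PENDING, FR_RESECTED, FR_NOT_RESECTED = 0, 1, 2, 3


@njit(cache=False)
def simulate_kernel(
    draws,          # (n, horizon, N_PURPOSES) uniforms in [0, 1)
    p_rec1,         # (horizon+1,) recurrence prob by month since curative surgery
    p_rec2,         # (horizon+1,) recurrence prob by month since re-resection
    p_death,        # (horizon+1,) death prob by month since chemotherapy start
    theta,          # per-month latent progression prob (operable -> chemo-only)
    p_resect,       # resection probability at detection while operable
    p_conv,         # per-cycle conversion-surgery probability under chemo
    prop_hep,       # share of recurrence surgeries that are hepatectomies
    has_visit,      # (surv_stop+1,) int8, visit scheduled at this clock month
    visit_cost,     # (surv_stop+1,) JPY per visit
    det_prob,       # (surv_stop+1,) detection probability per visit
    util,           # (N_STATES,) utility per state
    chemo_cost, hep_cost, pneu_cost,
    disc,           # (horizon+1,) discount factor per cycle
    disc_ly,        # (horizon+1,) discount factor applied to life-years
    horizon, surv_stop, init_state,
    trace,          # record per-cycle state occupancy
    out_cost, out_qaly, out_ly, out_alive, out_firstrec,
    occ,            # (horizon+1, N_STATES) int64 occupancy tallies
):
    n = draws.shape[0]
    for i in range(n):
        state = init_state
        m = 0
        sclock = 0
        elig = init_state == UNDET
        fr = FR_PENDING if (init_state == UNDET or init_state == CHEMO) else FR_NONE
        c = 0.0
        q = 0.0
        ly = 0.0
        alive = 0
        if trace:
            occ[0, state] += 1
        for t in range(1, horizon + 1):
            df = disc[t]
            entered_tunnel = False
            # (0) tunnel resolution: surgery happened last cycle
            if state == TUNNEL:
                state = AFTER_RES
                m = 0
                sclock = 0
            # (1) disease transition by time-in-state hazard
            if state == NO_REC:
                if draws[i, t - 1, D_REC] < p_rec1[t]:
                    state = UNDET
                    elig = True
                    m = 0  # recurrence-onset clock starts
                    if fr == FR_NONE:
                        fr = FR_PENDING
            elif state == AFTER_RES:
                m += 1
                if draws[i, t - 1, D_REC] < p_rec2[m]:
                    state = UNDET
                    elig = True
                    m = 0
            elif state == UNDET:
                # disease mortality is clocked from recurrence onset,
                # detected or not; resection is what clears the clock
                m += 1
                if draws[i, t - 1, D_DEATH] < p_death[m]:
                    state = DEATH
                    if fr == FR_PENDING:
                        fr = FR_NOT_RESECTED
                    if trace:
                        for s in range(t, horizon + 1):
                            occ[s, DEATH] += 1
                    break
            elif state == CHEMO:
                m += 1
                if draws[i, t - 1, D_DEATH] < p_death[m]:
                    state = DEATH
                    if fr == FR_PENDING:
                        fr = FR_NOT_RESECTED
                    if trace:
                        for s in range(t, horizon + 1):
                            occ[s, DEATH] += 1
                    break
                elif draws[i, t - 1, D_CONV] < p_conv:
                    if fr == FR_PENDING:
                        fr = FR_RESECTED
                    state = TUNNEL
                    entered_tunnel = True
            # (2) latent progression while undetected
            if state == UNDET and elig and draws[i, t - 1, D_PROG] < theta:
                elig = False
            # (3)+(4) scheduled visit: cost, then detection, then treatment
            if state == NO_REC or state == UNDET or state == AFTER_RES:
                sclock += 1
                if sclock <= surv_stop and has_visit[sclock]:
                    c += visit_cost[sclock] * df
                    if state == UNDET and draws[i, t - 1, D_DET] < det_prob[sclock]:
                        if elig and draws[i, t - 1, D_RESECT] < p_resect:
                            if fr == FR_PENDING:
                                fr = FR_RESECTED
                            state = TUNNEL
                            entered_tunnel = True
                        else:
                            state = CHEMO  # onset clock carries over
            # (5) accrual
            if entered_tunnel:
                if draws[i, t - 1, D_ORGAN] < prop_hep:
                    c += hep_cost * df
                else:
                    c += pneu_cost * df
            if state == CHEMO:
                c += chemo_cost * df
            q += util[state] / 12.0 * df
            ly += disc_ly[t] / 12.0
            alive += 1
            if trace:
                occ[t, state] += 1
        if fr == FR_PENDING:
            fr = FR_NOT_RESECTED
        out_cost[i] = c
        out_qaly[i] = q
        out_ly[i] = ly
        out_alive[i] = alive
        out_firstrec[i] = fr


def run_engine(inputs, draws: np.ndarray, trace: bool = False):
    """Run the kernel over one draw array; returns per-patient arrays.

    ``inputs`` is an :class:`~survcea.microsim.EngineInputs` tuple.
    """
    n = draws.shape[0]
    out_cost = np.empty(n)
    out_qaly = np.empty(n)
    out_ly = np.empty(n)
    out_alive = np.empty(n, dtype=np.int64)
    out_firstrec = np.empty(n, dtype=np.int8)
    occ = np.zeros((inputs.horizon + 1, N_STATES), dtype=np.int64)
    simulate_kernel(
        draws,
        inputs.p_rec1, inputs.p_rec2, inputs.p_death,
        inputs.theta, inputs.p_resect, inputs.p_conv, inputs.prop_hep,
        inputs.has_visit, inputs.visit_cost, inputs.det_prob,
        inputs.util, inputs.chemo_cost, inputs.hep_cost, inputs.pneu_cost,
        inputs.disc, inputs.disc_ly,
        inputs.horizon, inputs.surv_stop, inputs.init_state,
        trace,
        out_cost, out_qaly, out_ly, out_alive, out_firstrec,
        occ,
    )
    return out_cost, out_qaly, out_ly, out_alive, out_firstrec, occ
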