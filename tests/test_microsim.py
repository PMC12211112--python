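import dataclasses
import math

import numpy as np
import pytest

import survcea as sc
from survcea import _engine
from survcea.microsim import (
    N_PURPOSES,
    SimSettings,
    build_engine_inputs,
    simulate_patient_reference,
    simulate_patients,
)

from conftest import monthly_annuity


class TestDiscounting:
    def test_discount_factor_values(self):
        assert sc.discount_factor(0, 0.02) == 1.0
        assert sc.discount_factor(12, 0.02) == pytest.approx(1 / 1.02, rel=1e-12)
        assert sc.discount_factor(180, 0.02) == pytest.approx(1.02**-15, rel=1e-12)
        assert sc.discount_factor(180, 0.02) == pytest.approx(0.74301, abs=1e-5)

    def test_negative_cycle_rejected(self):
        with pytest.raises(sc.ValidationError):
            sc.discount_factor(-1, 0.02)


class TestReferenceKernelAgreement:
    def test_kernel_matches_python_stepper_draw_for_draw(self, params, jsccr):
        inputs = build_engine_inputs(
            params.replace(theta=0.05), jsccr, SimSettings(n_trials=1)
        )
        draws = np.random.default_rng(123).random((250, 180, N_PURPOSES))
        cost, qaly, ly, alive, fr, _ = _engine.run_engine(inputs, draws)
        code = {None: 0, "pending": 1, "yes": 2, "no": 3}
        for i in range(draws.shape[0]):
            p = simulate_patient_reference(inputs, draws[i])
            assert p.discounted_cost == pytest.approx(cost[i], abs=1e-9)
            assert p.discounted_qalys == pytest.approx(qaly[i], abs=1e-12)
            assert p.discounted_lys == pytest.approx(ly[i], abs=1e-12)
            assert p.alive_months == alive[i]
            assert code[p.first_recurrence_resected] == fr[i]


class TestDegenerateTrajectories:
    def test_zero_hazards_give_full_survival_annuity(
        self, zero_hazard_params, no_visit_strategy
    ):
        p = sc.simulate_patient(zero_hazard_params, no_visit_strategy, seed=5)
        assert p.alive_months == 180
        assert p.discounted_cost == 0.0
        annuity = monthly_annuity(180, 0.02)
        assert p.discounted_lys == pytest.approx(annuity, rel=1e-12)
        assert p.discounted_qalys == pytest.approx(0.74 * annuity, rel=1e-12)
        assert p.discounted_qalys == pytest.approx(9.595, abs=2e-3)

    def test_unit_utilities_no_discount_make_qalys_equal_lys(
        self, params, jsccr
    ):
        p = params.replace(
            utilities=sc.UtilitySet(1.0, 1.0, 1.0, 0.0)
        )
        settings = SimSettings(n_trials=3000, seed=8, discount_rate_annual=0.0)
        arrays = simulate_patients(p, jsccr, settings)
        assert np.allclose(arrays.qalys, arrays.lys)

    def test_chemo_only_patient_matches_geometric_lifetime_oracle(self, params):
        # two-state configuration: start on chemotherapy with a constant
        # monthly hazard, no conversion, no visits
        exp_anchor = sc.SurvivalAnchors(((12.0, 0.7),), "exp")
        p = params.replace(
            os_chemo=exp_anchor,
            tail_policies={**params.tail_policies, "os_chemo": "continue_last"},
            rates=dataclasses.replace(params.rates, conversion_cum_5yr=0.0),
        )
        no_visits = sc.load_strategy("name: none\nvisits: {}\n")
        settings = SimSettings(
            n_trials=30_000, seed=13, initial_state="unresectable_recurrence"
        )
        r = sc.simulate_cohort(p, no_visits, settings)
        monthly_p = 1 - 0.7 ** (1 / 12)
        v = 1.02 ** (-1 / 12)
        t = np.arange(1, 181)
        expected_ly = float(np.sum((v * (1 - monthly_p)) ** t) / 12)
        assert abs(r.mean_lys - expected_ly) < 3 * r.se_lys
        # whole lifetime is spent on chemotherapy at utility 0.25
        assert r.mean_qalys == pytest.approx(0.25 * r.mean_lys, rel=1e-9)

    def test_immediate_chemo_cost_equals_price_times_lifetime(self, params):
        p = params.replace(
            rates=dataclasses.replace(params.rates, conversion_cum_5yr=0.0)
        )
        no_visits = sc.load_strategy("name: none\nvisits: {}\n")
        settings = SimSettings(
            n_trials=20_000, seed=21, discount_rate_annual=0.0,
            initial_state="unresectable_recurrence",
        )
        arrays = simulate_patients(p, no_visits, settings)
        assert np.allclose(arrays.cost, 485_000 * arrays.alive_months)


class TestEngineInvariants:
    def test_same_seed_runs_are_bit_identical(self, params, jsccr):
        settings = SimSettings(n_trials=20_000, seed=99)
        r1 = sc.simulate_cohort(params, jsccr, settings)
        r2 = sc.simulate_cohort(params, jsccr, settings)
        assert r1 == r2

    def test_occupancy_conserved_and_death_absorbing(self, params, jsccr):
        settings = SimSettings(n_trials=20_000, seed=31)
        occ = sc.occupancy_trace(params.replace(theta=0.05), jsccr, settings)
        assert (occ.sum(axis=1) == settings.n_trials).all()
        assert (np.diff(occ[:, 5]) >= 0).all()  # deaths never leave

    def test_discounting_reduces_accruals(self, params, jsccr):
        disc = sc.simulate_cohort(params, jsccr, SimSettings(n_trials=20_000, seed=44))
        undisc = sc.simulate_cohort(
            params, jsccr,
            SimSettings(n_trials=20_000, seed=44, discount_rate_annual=0.0),
        )
        assert disc.mean_cost < undisc.mean_cost
        assert disc.mean_qalys < undisc.mean_qalys
        assert disc.mean_lys < undisc.mean_lys

    def test_qaly_ceiling_patientwise(self, params, jsccr):
        arrays = simulate_patients(
            params.replace(theta=0.03), jsccr, SimSettings(n_trials=20_000, seed=55)
        )
        assert (arrays.qalys <= 0.74 * arrays.lys + 1e-9).all()
        assert np.isfinite(arrays.cost).all()

    def test_accruals_match_alive_months_bounds(self, params, jsccr):
        arrays = simulate_patients(params, jsccr, SimSettings(n_trials=5000, seed=7))
        # life-years are discounted, so they never exceed alive months / 12
        assert (arrays.lys <= arrays.alive_months / 12 + 1e-12).all()
        assert (arrays.alive_months <= 180).all()


class TestIntensityMonotonicity:
    @pytest.mark.parametrize("theta", [0.0, 0.05])
    def test_denser_schedule_non_lower_resectability_and_lys(
        self, params, sparse_dense, theta
    ):
        sparse, dense = sparse_dense
        p = params.replace(theta=theta)
        rs = sc.simulate_cohort(p, sparse, SimSettings(n_trials=60_000, seed=5))
        rd = sc.simulate_cohort(p, dense, SimSettings(n_trials=60_000, seed=5))
        tol_res = 3 * math.hypot(rs.se_resectability, rd.se_resectability)
        tol_ly = 3 * math.hypot(rs.se_lys, rd.se_lys)
        assert rd.resectability >= rs.resectability - tol_res
        assert rd.mean_lys >= rs.mean_lys - tol_ly

    def test_denser_schedule_non_lower_qalys_with_active_progression(
        self, params, sparse_dense
    ):
        # the latent-progression mechanism is what makes early detection
        # valuable; with it active, denser schedules buy QALYs
        sparse, dense = sparse_dense
        p = params.replace(theta=0.05)
        rs = sc.simulate_cohort(p, sparse, SimSettings(n_trials=60_000, seed=5))
        rd = sc.simulate_cohort(p, dense, SimSettings(n_trials=60_000, seed=5))
        tol = 3 * math.hypot(rs.se_qalys, rd.se_qalys)
        assert rd.mean_qalys >= rs.mean_qalys - tol


class TestCalibration:
    def test_unreachable_target_raises_with_range(self, params, jsccr):
        with pytest.raises(sc.CalibrationError, match="achievable"):
            sc.calibrate_theta(
                params, jsccr, 0.9, SimSettings(n_trials=5000, seed=3)
            )

    def test_boundary_target_pins_to_no_progression(self, params, jsccr):
        result = sc.calibrate_theta(
            params, jsccr, 0.461, SimSettings(n_trials=30_000, seed=17)
        )
        assert result.theta == 0.0
        assert result.iterations == 0
        assert abs(result.achieved - 0.461) < 0.01

    def test_interior_target_recovered_by_bisection(self, params, jsccr):
        settings = SimSettings(n_trials=30_000, seed=23)
        result = sc.calibrate_theta(params, jsccr, 0.40, settings, tol=2e-3)
        assert 0.0 < result.theta < 1.0
        assert abs(result.achieved - 0.40) <= 2e-3
        # re-simulation at theta* with a fresh seed reproduces the target
        fresh = sc.simulate_cohort(
            params.replace(theta=result.theta), jsccr,
            SimSettings(n_trials=30_000, seed=77),
        )
        assert abs(fresh.resectability - 0.40) < 4 * fresh.se_resectability
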