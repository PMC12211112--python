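import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import survcea as sc
from survcea.survival import greenwood_se, km_survival, per_cycle_probs

RFS_ANCHORS = sc.SurvivalAnchors(((12, 0.479), (36, 0.285), (60, 0.267)), "rfs")
OS_ANCHORS = sc.SurvivalAnchors(((12, 0.855), (36, 0.529), (60, 0.267)), "os")


class TestFit:
    def test_segment_rates_match_closed_form(self):
        pw = sc.fit_piecewise_exponential(RFS_ANCHORS)
        expected = [
            -math.log(0.479) / 12,
            -math.log(0.285 / 0.479) / 24,
            -math.log(0.267 / 0.285) / 24,
        ]
        assert np.allclose(pw.rates, expected, rtol=1e-12)
        assert np.allclose(pw.rates, (0.06134, 0.02163, 0.00272), atol=2e-5)

    def test_no_events_gives_zero_rate(self):
        pw = sc.fit_piecewise_exponential(sc.SurvivalAnchors(((12, 1.0),)))
        assert pw.rates == (0.0,)
        assert sc.survival_at(pw, 12) == 1.0

    @pytest.mark.parametrize("anchors", [RFS_ANCHORS, OS_ANCHORS])
    def test_round_trip_reproduces_anchors_exactly(self, anchors):
        pw = sc.fit_piecewise_exponential(anchors)
        for t, s in anchors.points:
            assert sc.survival_at(pw, t) == pytest.approx(s, abs=1e-12)

    def test_zero_survival_anchor_rejected(self):
        anchors = sc.SurvivalAnchors(((12, 0.0),))
        with pytest.raises(sc.ValidationError):
            sc.fit_piecewise_exponential(anchors)

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(sc.ValidationError):
            sc.SurvivalAnchors(((12, 0.4), (36, 0.6)))
        with pytest.raises(sc.ValidationError):
            sc.SurvivalAnchors(((36, 0.5), (12, 0.6)))


class TestEvaluation:
    def test_survival_values(self):
        pw = sc.fit_piecewise_exponential(RFS_ANCHORS)
        assert sc.survival_at(pw, 0) == 1.0
        assert sc.survival_at(pw, 24) == pytest.approx(
            0.479 * math.exp(-pw.rates[1] * 12), rel=1e-12
        )
        assert sc.survival_at(pw, 24) == pytest.approx(0.3695, abs=5e-4)
        assert sc.survival_at(pw, 36) == pytest.approx(0.285, abs=1e-12)
        with pytest.raises(sc.ValidationError):
            sc.survival_at(pw, -1)

    def test_tail_policies(self):
        zero = sc.fit_piecewise_exponential(RFS_ANCHORS, "zero")
        cont = sc.fit_piecewise_exponential(RFS_ANCHORS, "continue_last")
        assert sc.survival_at(zero, 120) == pytest.approx(0.267, abs=1e-12)
        assert sc.survival_at(cont, 120) < 0.267

    def test_per_cycle_prob(self):
        pw = sc.fit_piecewise_exponential(RFS_ANCHORS)
        assert sc.per_cycle_prob(pw, 1) == pytest.approx(0.0595, abs=1e-4)
        # brute force: 12 months of the first-segment probability compound to S(12)
        p1 = sc.per_cycle_prob(pw, 1)
        assert (1 - p1) ** 12 == pytest.approx(0.479, rel=1e-9)
        assert sc.per_cycle_prob(pw, 40) == pytest.approx(0.00271, abs=2e-5)
        flat = sc.fit_piecewise_exponential(sc.SurvivalAnchors(((12, 1.0),)))
        assert sc.per_cycle_prob(flat, 5) == 0.0

    def test_monthly_compounding_matches_survival(self):
        pw = sc.fit_piecewise_exponential(RFS_ANCHORS)
        probs = per_cycle_probs(pw, 60)
        assert np.prod(1 - probs[1:]) == pytest.approx(sc.survival_at(pw, 60), abs=1e-9)
        assert ((probs >= 0) & (probs < 1)).all()


class TestCumulativeInversion:
    def test_round_trip(self):
        p = sc.cumulative_to_per_cycle(0.192, 60)
        assert p == pytest.approx(0.003547, abs=1e-6)
        assert 1 - (1 - p) ** 60 == pytest.approx(0.192, abs=1e-12)

    def test_edge_cases(self):
        assert sc.cumulative_to_per_cycle(0.0, 60) == 0.0
        assert sc.cumulative_to_per_cycle(0.5, 1) == 0.5
        with pytest.raises(sc.ValidationError):
            sc.cumulative_to_per_cycle(1.0, 60)


class TestKaplanMeier:
    def test_hand_example(self):
        # events at months 1 and 2 in four subjects, two censored at 10:
        # S(2) = (3/4) * (2/3) = 1/2 by the product limit
        anchors = sc.km_estimate([1, 2, 10, 10], [True, True, False, False], [2])
        assert anchors.points[0][1] == pytest.approx(0.5)

    def test_all_censored(self):
        vals = km_survival([5, 8, 10], [False] * 3, [0, 6, 12])
        assert np.allclose(vals, 1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(sc.ValidationError):
            sc.km_estimate([], [], [12])

    def test_parameter_recovery_on_synthetic_times(self):
        pw = sc.fit_piecewise_exponential(RFS_ANCHORS)
        rng = np.random.default_rng(42)
        t = sc.sample_event_times(pw, 10_000, rng)
        observed = np.isfinite(t)
        durations = np.where(observed, t, 180.0)
        est = km_survival(durations, observed, [60.0])[0]
        se = greenwood_se(durations, observed, [60.0])[0]
        assert abs(est - 0.267) < 3 * se

    def test_never_event_fraction_matches_tail(self):
        pw = sc.fit_piecewise_exponential(RFS_ANCHORS, "zero")
        rng = np.random.default_rng(7)
        t = sc.sample_event_times(pw, 20_000, rng)
        frac_never = np.mean(~np.isfinite(t))
        assert frac_never == pytest.approx(0.267, abs=3 * math.sqrt(0.267 * 0.733 / 20_000))


@st.composite
def anchor_sets(draw):
    n = draw(st.integers(1, 4))
    times = sorted(draw(st.lists(st.floats(1, 120), min_size=n, max_size=n, unique=True)))
    surv = sorted(
        draw(st.lists(st.floats(0.01, 1.0), min_size=n, max_size=n)), reverse=True
    )
    return sc.SurvivalAnchors(tuple(zip(times, surv)))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(anchor_sets())
def test_fit_round_trip_and_monotonicity_property(anchors):
    pw = sc.fit_piecewise_exponential(anchors)
    for t, s in anchors.points:
        assert sc.survival_at(pw, t) == pytest.approx(s, abs=1e-9)
    grid = np.linspace(0, anchors.times[-1] + 24, 50)
    vals = sc.survival_at(pw, grid)
    assert (np.diff(vals) <= 1e-12).all()
    assert vals[0] == pytest.approx(1.0)
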