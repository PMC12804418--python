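"""Closed-form values, invariants and oracles for the choice models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teaminterrupt import decision_models as dm

# bounded so the linear predictor stays below float64 logistic saturation (~36.7)
finite = st.floats(-15, 15, allow_nan=False)
tp_vals = st.floats(0.0, 5.0, allow_nan=False)


class TestTimePressure:
    @pytest.mark.parametrize(
        "tasks,tpt,ta,expected",
        [
            (106, 11.0, 1320.0, 1166.0 / 1320.0),  # full workload, medium deadline
            (0, 7.0, 500.0, 0.0),
            (50, 1.0, 50.0, 1.0),                  # time required equals available
        ],
    )
    def test_ratio(self, tasks, tpt, ta, expected):
        ctx = dm.TimePressureContext(tasks, ta, tpt)
        assert dm.compute_time_pressure(ctx) == pytest.approx(expected, abs=1e-12)

    def test_undefined_past_deadline(self):
        with pytest.raises(dm.UndefinedTimePressureError):
            dm.compute_time_pressure(dm.TimePressureContext(5, 0.0))
        with pytest.raises(dm.UndefinedTimePressureError):
            dm.compute_time_pressure(dm.TimePressureContext(5, -10.0))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dm.TimePressureContext(-1, 100.0)
        with pytest.raises(ValueError):
            dm.TimePressureContext(1, 100.0, time_per_task=0.0)


class TestChoiceProbabilities:
    @pytest.mark.parametrize(
        "bias,sens,b,c,expected",
        [
            (0.0, 1.0, 0.7, 0.7, 0.5),
            (math.log(3), 0.0, 2.0, 0.1, 0.75),
            (0.0, 2.0, 1.5, 0.5, 1 / (1 + math.exp(-2))),
        ],
    )
    def test_monotonic_closed_form(self, bias, sens, b, c, expected):
        p = dm.p_choice_monotonic(bias, sens, dm.BenefitCost(b, c))
        assert p == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "bias,b,c,expected",
        [
            (0.0, 0.3, 0.3, 0.5),
            (2.0, 1.0, 1.0, 1 / (1 + math.exp(-2))),
        ],
    )
    def test_nonmonotonic_closed_form(self, bias, b, c, expected):
        p = dm.p_choice_nonmonotonic(bias, dm.BenefitCost(b, c))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            dm.p_choice_monotonic(float("nan"), 1.0, dm.BenefitCost(0.0, 0.0))
        with pytest.raises(ValueError):
            dm.BenefitCost(float("inf"), 0.0)

    @given(bias=finite, x=finite)
    @settings(max_examples=100, deadline=None)
    def test_bias_symmetry_and_open_interval(self, bias, x):
        """With zero bias, p(+x) + p(-x) = 1; probabilities never hit 0 or 1."""
        p_pos = dm.p_choice_monotonic(0.0, 1.0, dm.BenefitCost(x, 0.0))
        p_neg = dm.p_choice_monotonic(0.0, 1.0, dm.BenefitCost(-x, 0.0))
        assert p_pos + p_neg == pytest.approx(1.0, abs=1e-12)
        q = dm.p_choice_monotonic(bias, 1.0, dm.BenefitCost(x, 0.0))
        assert 0.0 < q < 1.0
        qn = dm.p_choice_nonmonotonic(bias, dm.BenefitCost(x, 0.0))
        assert 0.0 < qn < 1.0

    @given(sens=st.floats(0.0, 10.0), bias=finite,
           d1=st.floats(-5, 5), d2=st.floats(-5, 5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_benefit_cost_difference(self, sens, bias, d1, d2):
        lo, hi = sorted((d1, d2))
        p_lo = dm.p_choice_monotonic(bias, sens, dm.BenefitCost(lo, 0.0))
        p_hi = dm.p_choice_monotonic(bias, sens, dm.BenefitCost(hi, 0.0))
        assert p_hi >= p_lo - 1e-15
        if sens > 1e-6 and hi - lo > 1e-6:
            assert p_hi > p_lo


class TestBenefitCost:
    @pytest.mark.parametrize(
        "tau,omega,tp_p,tp_c,b,c",
        [
            (1.0, -1.0, 0.5, 0.5, 0.25, 0.25),
            (0.7, 0.0, 1.1, 0.4, 0.7 * 1.1, 0.7 * 0.4),
            (0.0, 0.0, 1.3, 0.2, 0.0, 0.0),
        ],
    )
    def test_interrupt_quadratic(self, tau, omega, tp_p, tp_c, b, c):
        bc = dm.benefit_cost_nonmono_interrupt(tau, omega, tp_p, tp_c)
        assert bc.b == pytest.approx(b, abs=1e-12)
        assert bc.c == pytest.approx(c, abs=1e-12)

    @pytest.mark.parametrize(
        "kappa,lam,tp_c,tp_p,b,c",
        [
            (1.0, 0.0, 1.2, 0.8, 1.2, 0.8),
            (2.0, -1.0, 1.0, 0.3, 1.0, 2 * 0.3 - 0.09),
        ],
    )
    def test_respond_quadratic(self, kappa, lam, tp_c, tp_p, b, c):
        bc = dm.benefit_cost_nonmono_respond(kappa, lam, tp_c, tp_p)
        assert bc.b == pytest.approx(b, abs=1e-12)
        assert bc.c == pytest.approx(c, abs=1e-12)

    @given(kappa=finite, lam=finite, tp=tp_vals)
    @settings(max_examples=50, deadline=None)
    def test_equal_pressures_give_equal_benefit_cost(self, kappa, lam, tp):
        bc = dm.benefit_cost_nonmono_respond(kappa, lam, tp, tp)
        assert bc.b == pytest.approx(bc.c, abs=1e-9)


class TestFamilyRelations:
    def test_reduction_to_monotonic_on_grid(self):
        """With zero quadratic terms the families coincide to 1e-12."""
        grid = np.linspace(0.0, 2.5, 10)
        for bias in (-1.0, 0.0, 0.8):
            for lin in (-0.5, 1.0, 2.0):
                for tp_p in grid:
                    for tp_c in grid:
                        bc = dm.benefit_cost_nonmono_interrupt(lin, 0.0, tp_p, tp_c)
                        p_non = dm.p_choice_nonmonotonic(bias, bc)
                        p_mono = dm.p_choice_monotonic(
                            bias, lin, dm.BenefitCost(tp_p, tp_c))
                        assert p_non == pytest.approx(p_mono, abs=1e-12)

    def test_nonmono_equals_monotonic_with_unit_sensitivity(self):
        bc = dm.BenefitCost(1.7, 0.4)
        assert dm.p_choice_nonmonotonic(0.3, bc) == pytest.approx(
            dm.p_choice_monotonic(0.3, 1.0, bc), abs=1e-15)

    def test_inverted_u_peak_location(self):
        """For omega < 0 the interrupt probability peaks at tp = -tau/(2*omega)."""
        tau, omega, tp_c = 2.0, -1.5, 0.9
        grid = np.linspace(0.0, 2.0, 2001)
        probs = [
            dm.p_choice_nonmonotonic(
                0.0, dm.benefit_cost_nonmono_interrupt(tau, omega, tp, tp_c))
            for tp in grid
        ]
        peak = grid[int(np.argmax(probs))]
        assert peak == pytest.approx(-tau / (2 * omega), abs=2e-3)

    def test_translation_invariance_discriminates_families(self):
        """A common shift of both tps moves only the non-monotonic probability."""
        tp_p, tp_c, shift = 1.2, 0.5, 0.4
        p0 = dm.p_choice_monotonic(0.1, 1.3, dm.BenefitCost(tp_p, tp_c))
        p1 = dm.p_choice_monotonic(0.1, 1.3, dm.BenefitCost(tp_p + shift, tp_c + shift))
        assert p0 == pytest.approx(p1, abs=1e-12)
        q0 = dm.p_choice_nonmonotonic(
            0.1, dm.benefit_cost_nonmono_interrupt(1.3, -0.8, tp_p, tp_c))
        q1 = dm.p_choice_nonmonotonic(
            0.1, dm.benefit_cost_nonmono_interrupt(1.3, -0.8, tp_p + shift, tp_c + shift))
        assert abs(q0 - q1) > 1e-6


class TestEventProbability:
    def test_respond_symmetric(self, event_factory):
        ev = event_factory(decision_type="respond", tp_er=0.9, tp_ee=0.9)
        p = dm.event_probability(ev, dm.MonotonicParams(gamma=0.0, delta=1.0),
                                 "monotonic")
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_interrupt_nonmono_gap(self, event_factory):
        ev = event_factory(decision_type="interrupt", tp_er=1.5, tp_ee=0.5)
        p = dm.event_probability(
            ev, dm.NonMonotonicParams(alpha=0.0, tau=1.0, omega=0.0),
            "nonmonotonic")
        assert p == pytest.approx(1 / (1 + math.exp(-1.0)), abs=1e-12)

    def test_kind_mismatch(self, event_factory):
        with pytest.raises(TypeError):
            dm.event_probability(event_factory(), dm.MonotonicParams(),
                                 "nonmonotonic")


class TestPointwiseLoglik:
    def test_single_event_half(self, event_factory):
        ev = event_factory(decision_type="respond", tp_er=1.0, tp_ee=1.0)
        ll = dm.pointwise_loglik([ev], {"S0": dm.MonotonicParams(0, 1, 0, 1)},
                                 "monotonic")
        assert ll[0] == pytest.approx(math.log(0.5), abs=1e-12)

    def test_matches_bruteforce_oracle(self, random_events):
        """Vectorized log-likelihoods agree with a naive per-event recomputation."""
        events = random_events(n=10)
        params = {f"S{i}": dm.MonotonicParams(0.2 * i, 1.0 - 0.1 * i,
                                              -0.3 + 0.2 * i, 0.5)
                  for i in range(3)}
        ll = dm.pointwise_loglik(events, params, "monotonic")
        for n, ev in enumerate(events):
            p = dm.event_probability(ev, params[ev.subject_id], "monotonic")
            expected = math.log(p if ev.outcome == 1 else 1.0 - p)
            assert ll[n] == pytest.approx(expected, abs=1e-10)

    def test_order_preserved_under_concatenation(self, random_events):
        a, b = random_events(4), random_events(5)
        params = {f"S{i}": dm.MonotonicParams(0.1, 1.0, 0.1, 1.0) for i in range(3)}
        lla = dm.pointwise_loglik(a, params, "monotonic")
        llb = dm.pointwise_loglik(b, params, "monotonic")
        llab = dm.pointwise_loglik(a + b, params, "monotonic")
        np.testing.assert_allclose(llab, np.concatenate([lla, llb]), atol=1e-15)

    def test_missing_subject_raises(self, event_factory):
        with pytest.raises(KeyError):
            dm.pointwise_loglik([event_factory(subject="GHOST")], {}, "monotonic")
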