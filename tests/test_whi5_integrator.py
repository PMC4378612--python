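"""Whi5 phosphorylation integrator, integral law, and network model."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from startint import (
    IntegralLaw,
    IntegratorParams,
    NetworkParams,
    TriggerSpec,
    constant_trace,
    first_passage_integration,
    law_from_params,
    memory_window,
    network_effective_law,
    predict_tg1,
    simulate_network,
    simulate_whi5p,
    ssa_simulate,
    tg1_from_integrator,
)
from startint.cln3_stochastic import ConcentrationTrace


class TestKinetics:
    def test_balance_point_saturated(self, integrator):
        c = integrator.k2 / integrator.k1  # phosphorylation = dephosphorylation
        _, whi5p, _ = simulate_whi5p(constant_trace(c, 60.0), integrator)
        assert np.allclose(whi5p, 0.0, atol=1e-12)

    def test_linear_mode_closed_form(self):
        p = IntegratorParams(k1=0.05, k2=0.1, mode="linear", t0=0.0)
        c = 50.0
        t, whi5p, _ = simulate_whi5p(constant_trace(c, 40.0), p)
        exact = (p.k1 * c / p.k2) * (1.0 - np.exp(-p.k2 * t))
        assert np.max(np.abs(whi5p - exact)) < 1e-9

    def test_mass_conservation(self, integrator):
        _, whi5p, nuc = simulate_whi5p(constant_trace(120.0, 80.0), integrator)
        assert np.max(np.abs(whi5p + nuc - integrator.whi5_tot)) < 1e-6

    def test_clamped_nonnegative_below_critical_signal(self, integrator):
        # Cln3 below k2/k1 forever: Whi5P pinned at 0, never fires
        res = tg1_from_integrator(constant_trace(5.0, 200.0), integrator)
        assert res.censored
        _, whi5p, _ = simulate_whi5p(constant_trace(5.0, 200.0), integrator)
        assert np.all(whi5p >= 0.0)


class TestIntegralLaw:
    def test_constant_cln3_closed_form_grid(self):
        """First-passage time equals the inverse law on a parameter grid."""
        for k1 in (0.02, 0.05, 0.1):
            for k2 in (0.3, 0.75, 1.5):
                for wt, wc in ((100.0, 40.0), (130.0, 40.0), (80.0, 10.0)):
                    p = IntegratorParams(k1=k1, k2=k2, whi5_tot=wt, whi5_c=wc)
                    cc = k2 / k1
                    c = 2.5 * cc + 20.0
                    expected = p.t0 + (wt - wc) / (k1 * (c - cc))
                    res = tg1_from_integrator(constant_trace(c, expected * 3), p)
                    assert not res.censored
                    assert res.tg1 == pytest.approx(expected, abs=0.1)

    def test_law_from_params_arithmetic(self):
        p = IntegratorParams(k1=0.01, k2=1.0, whi5_tot=100.0, whi5_c=40.0)
        law = law_from_params(p)
        assert law.integral_a == pytest.approx(6000.0)
        assert law.cln3_c == pytest.approx(100.0)

    def test_degenerate_zero_reserve(self):
        p = IntegratorParams(whi5_c=0.0, whi5_tot=1e-9)
        assert law_from_params(p).integral_a == pytest.approx(0.0, abs=1e-6)

    def test_doubling_whi5tot_increases_a(self, integrator):
        a1 = law_from_params(integrator).integral_a
        a2 = law_from_params(replace(integrator, whi5_tot=2 * integrator.whi5_tot)).integral_a
        assert a2 > a1

    def test_predict_tg1_example(self):
        law = IntegralLaw(integral_a=6000.0, cln3_c=100.0, t0=5.0)
        assert predict_tg1(law, 400.0) == pytest.approx(25.0)

    def test_predict_tg1_asymptote_and_error(self):
        law = IntegralLaw(integral_a=6000.0, cln3_c=100.0, t0=5.0)
        assert predict_tg1(law, 1e9) == pytest.approx(5.0, abs=1e-4)
        with pytest.raises(ValueError, match="never passes"):
            predict_tg1(law, 50.0)

    def test_loglog_slope_is_exactly_minus_one(self):
        law = IntegralLaw(integral_a=6000.0, cln3_c=100.0, t0=5.0)
        c = np.array([150.0, 300.0, 600.0, 1200.0])
        tg1 = np.array([predict_tg1(law, x) for x in c])
        slope = np.polyfit(np.log(c - law.cln3_c), np.log(tg1 - law.t0), 1)[0]
        assert slope == pytest.approx(-1.0, abs=1e-12)

    def test_equivalent_to_signed_integral_first_passage(self, params, integrator):
        """Start via the integrator == first passage of ∫(Cln3 - Cln3c) at A."""
        trace = ssa_simulate(params, 120.0, seed=13)
        law = law_from_params(integrator)
        # keep the signal above Cln3c so clamping never engages
        shifted = ConcentrationTrace(
            times=trace.event_times,
            values=trace.protein_counts + 2.0 * law.cln3_c,
        )
        a = tg1_from_integrator(shifted, integrator)
        spec = TriggerSpec(
            model="integration", threshold=law.integral_a, baseline=law.cln3_c
        )
        # the trigger rule integrates from time zero: re-anchor the trace at
        # t0, keeping the value of the segment that straddles it
        idx = np.searchsorted(shifted.times, integrator.t0, side="right") - 1
        tail = ConcentrationTrace(
            times=np.concatenate([[0.0], shifted.times[idx + 1 :] - integrator.t0]),
            values=shifted.values[idx:],
        )
        b = first_passage_integration(tail, spec)
        assert a.tg1 - integrator.t0 == pytest.approx(b.tg1, abs=1e-9)

    @given(scale=st.floats(min_value=0.2, max_value=5.0))
    @settings(max_examples=30, deadline=None)
    def test_catalytic_efficiency_rescales_a_and_cln3c_together(self, scale):
        """Changing k1 by c scales A and Cln3c by 1/c: TG1 is unchanged when
        the Cln3 signal is rescaled accordingly (the Cln3* hypomorph)."""
        base = IntegratorParams(k1=0.05, k2=0.75)
        scaled = IntegratorParams(k1=0.05 * scale, k2=0.75)
        law_b, law_s = law_from_params(base), law_from_params(scaled)
        assert law_s.integral_a * scale == pytest.approx(law_b.integral_a)
        assert law_s.cln3_c * scale == pytest.approx(law_b.cln3_c)
        t_base = tg1_from_integrator(constant_trace(120.0, 400.0), base).tg1
        t_scaled = tg1_from_integrator(
            constant_trace(120.0 / scale, 400.0), scaled
        ).tg1
        assert t_scaled == pytest.approx(t_base, rel=1e-9)

    def test_monotonicity_in_signal_and_dosage(self, integrator):
        tg = [
            tg1_from_integrator(constant_trace(c, 300.0), integrator).tg1
            for c in (80.0, 120.0, 200.0, 400.0)
        ]
        assert np.all(np.diff(tg) < 0)
        tg_dose = [
            tg1_from_integrator(
                constant_trace(120.0, 300.0), replace(integrator, whi5_tot=wt)
            ).tg1
            for wt in (80.0, 100.0, 140.0)
        ]
        assert np.all(np.diff(tg_dose) > 0)


class TestMemory:
    def test_memory_window_value(self):
        p = IntegratorParams(k2=0.1, mode="linear")
        assert memory_window(p) == pytest.approx(10.0)

    def test_saturated_memory_is_infinite(self, integrator):
        with pytest.raises(ValueError, match="infinite"):
            memory_window(integrator)

    def test_linear_mode_forgets_transient_pulse(self):
        """A pulse far in the past leaves no trace beyond the memory window."""
        p = IntegratorParams(k1=0.05, k2=0.2, mode="linear", t0=0.0)
        t = np.arange(0.0, 101.0, 1.0)
        base = np.full_like(t, 30.0)
        pulsed = base.copy()
        pulsed[5:10] += 200.0
        _, w_base, _ = simulate_whi5p(ConcentrationTrace(times=t, values=base), p)
        _, w_pulse, _ = simulate_whi5p(ConcentrationTrace(times=t, values=pulsed), p)
        # at t = 100 ≫ 1/k2 = 5 the pulse has been erased
        assert abs(w_pulse[-1] - w_base[-1]) < 1e-4 * p.whi5_tot

    def test_linear_limit_converges_to_saturated(self):
        sat = IntegratorParams(k1=0.05, k2=1e-9, mode="saturated")
        lin = IntegratorParams(k1=0.05, k2=1e-9, mode="linear")
        a = tg1_from_integrator(constant_trace(100.0, 60.0), sat).tg1
        b = tg1_from_integrator(constant_trace(100.0, 60.0), lin).tg1
        assert a == pytest.approx(b, rel=1e-4)


class TestNetwork:
    def test_mass_conserved_across_states(self):
        p = NetworkParams()
        out = simulate_network(p, 150.0)
        totals = out["whi5_states"].sum(axis=0)
        assert np.max(np.abs(totals - p.whi5_tot)) < 1e-6

    def test_start_fires_and_cln12_surges(self):
        out = simulate_network(NetworkParams(), 150.0)
        assert not out["g1"].censored
        assert out["cln12"][-1] > out["cln12"][0]

    def test_perturbation_directions(self):
        """The three network-level predictions of the integrator model."""
        base = network_effective_law(NetworkParams())
        hi_dose = network_effective_law(replace(NetworkParams(), whi5_tot=200.0))
        hi_phos = network_effective_law(replace(NetworkParams(), k2_site=1.0))
        weak_fb = network_effective_law(replace(NetworkParams(), feedback_strength=0.8))
        assert hi_dose.integral_a > base.integral_a
        assert hi_phos.cln3_c > base.cln3_c
        assert weak_fb.integral_a > base.integral_a
        assert weak_fb.cln3_c > base.cln3_c

    def test_subcritical_input_censored(self):
        out = simulate_network(NetworkParams(), 1.0, t_max=60.0)
        assert out["g1"].censored
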