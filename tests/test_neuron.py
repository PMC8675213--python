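import numpy as np
import pytest

import navkit as nk
from navkit.neuron import (IntegrationError, NeuronParams, StimulusProgram,
                           build_stimulus, resting_potential, steady_gates,
                           stimulus_preset, _m_inf_np, _rates_m)


def test_variant_validation():
    with pytest.raises(ValueError):
        nk.VariantSpec(inact_rate_multiplier=-1.0)
    with pytest.raises(ValueError):
        nk.VariantSpec(persistent_fraction=1.2)
    with pytest.raises(ValueError):
        NeuronParams(g_na=float("nan"))
    with pytest.raises(ValueError):
        NeuronParams(e_leak=-95.0)  # below E_K


def test_variant_conductance_wiring(wt_neuron, lq_neuron):
    assert wt_neuron.g_nap == pytest.approx(0.10 * wt_neuron.g_na * 0.018)
    assert lq_neuron.g_nap == pytest.approx(0.10 * lq_neuron.g_na * 0.046)
    assert wt_neuron.h_rate_scale == 1.0
    assert lq_neuron.h_rate_scale == pytest.approx(1.485)


def test_separate_effect_variants(wt_neuron, lq_neuron):
    po = nk.build_neuron(nk.persistent_only_variant())
    io = nk.build_neuron(nk.inactivation_only_variant())
    assert po.h_rate_scale == 1.0 and po.g_nap == lq_neuron.g_nap
    assert io.h_rate_scale == pytest.approx(1.485)
    assert io.g_nap == wt_neuron.g_nap


def test_both_effects_off_is_exactly_wildtype(wt_neuron):
    """Identity contract for the separate-effects decomposition."""
    off = nk.VariantSpec(1.485, 0.046, apply_inactivation_effect=False,
                         apply_persistent_effect=False, label="WT")
    assert nk.build_neuron(off) == wt_neuron


def test_wildtype_rest_is_stable(wt_neuron):
    rest = resting_potential(wt_neuron)
    trace = nk.integrate(wt_neuron,
                         StimulusProgram(kind="step", amplitude=0.0,
                                         duration=1000.0), 1000.0)
    assert trace.spike_times.size == 0
    assert abs(trace.v_m[-1] - rest) < 1.0
    assert np.all(np.abs(trace.v_m - rest) < 1.0)


def test_equal_reversals_pin_membrane():
    p = NeuronParams(e_na=-65.0, e_k=-65.0, e_leak=-65.0)
    trace = nk.integrate(p, StimulusProgram(kind="step", amplitude=0.0,
                                            duration=50.0), 50.0)
    assert np.allclose(trace.v_m, -65.0, atol=1e-9)


def test_integration_is_deterministic(lq_neuron):
    prog = StimulusProgram(kind="step", amplitude=5.0, duration=300.0)
    a = nk.integrate(lq_neuron, prog, 300.0)
    b = nk.integrate(lq_neuron, prog, 300.0)
    assert np.array_equal(a.v_m, b.v_m)
    assert np.array_equal(a.spike_times, b.spike_times)


def test_dt_convergence(wt_neuron):
    """Halving dt preserves the spike count, and early spike times move
    by less than 0.1 ms (the integrator is first order, so phase drift
    accumulates linearly along the train)."""
    prog = StimulusProgram(kind="step", amplitude=10.0, duration=400.0)
    a = nk.integrate(wt_neuron, prog, 400.0, dt=0.005)
    b = nk.integrate(wt_neuron, prog, 400.0, dt=0.0025)
    assert a.spike_times.size == b.spike_times.size > 5
    assert np.max(np.abs(a.spike_times[:5] - b.spike_times[:5])) < 0.1


def test_gating_variables_bounded(lq_neuron):
    prog = StimulusProgram(kind="step", amplitude=20.0, duration=500.0)
    trace = nk.integrate(lq_neuron, prog, 500.0)
    assert 0.0 <= trace.gate_min and trace.gate_max <= 1.0


def test_spike_times_strictly_increasing(lq_neuron):
    prog = StimulusProgram(kind="step", amplitude=10.0, duration=500.0)
    trace = nk.integrate(lq_neuron, prog, 500.0)
    assert trace.spike_times.size > 5
    assert np.all(np.diff(trace.spike_times) >= 1.0)  # refractory


def test_numerical_blowup_reported_with_time(wt_neuron):
    prog = StimulusProgram(kind="step", amplitude=1e9, duration=10.0)
    with pytest.raises(IntegrationError, match="t = "):
        nk.integrate(wt_neuron, prog, 10.0)


class TestTestPulse:
    def test_identical_variants_identical_peaks(self, wt_neuron):
        off = nk.VariantSpec(1.485, 0.046, False, False)
        assert nk.test_pulse_peak_current(nk.build_neuron(off)) == \
            nk.test_pulse_peak_current(wt_neuron)

    def test_peak_is_inward(self, wt_neuron):
        assert nk.test_pulse_peak_current(wt_neuron) < 0

    def test_fast_inactivation_limit_kills_peak(self, wt_neuron):
        fast = wt_neuron.replace(h_rate_scale=500.0)
        assert abs(nk.test_pulse_peak_current(fast, transient_only=True)) < \
            0.01 * abs(nk.test_pulse_peak_current(wt_neuron,
                                                  transient_only=True))


def test_nap_current_does_not_decay(lq_neuron):
    """Under a sustained commanded depolarization the NaP component has
    no inactivation gate: its conductance tracks m_inf and stays put."""
    v = 0.0
    am, bm = _rates_m(v, lq_neuron.v_t)
    m_inf = float(am / (am + bm))
    t = np.array([1.0, 10.0, 100.0, 500.0])
    tau_mp = 1.0 / (float(am + bm) * lq_neuron.nap_rate_scale)
    mp0 = steady_gates(-120.0, lq_neuron)[4]
    mp = m_inf + (mp0 - m_inf) * np.exp(-t / tau_mp)
    i_nap = lq_neuron.g_nap * mp ** lq_neuron.nap_gate_exponent * (v - lq_neuron.e_na)
    assert np.allclose(i_nap, i_nap[0], rtol=1e-12)
    assert i_nap[0] < 0


class TestExcitabilityMetrics:
    def test_zero_amplitude_zero_rate(self, wt_neuron):
        rates = nk.firing_rate_curve(wt_neuron, [0.0])
        assert rates[0.0] == 0.0

    def test_rate_nondecreasing_below_block(self, wt_neuron):
        rates = nk.firing_rate_curve(wt_neuron, [2.0, 5.0, 10.0, 20.0])
        vals = [rates[a] for a in sorted(rates)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 0

    def test_rheobase_validation_and_leak_scaling(self, wt_neuron):
        with pytest.raises(ValueError):
            nk.rheobase(wt_neuron, resolution=0.0)
        rb = nk.rheobase(wt_neuron, resolution=0.25, duration=500.0)
        stiff = wt_neuron.replace(g_leak=2.0 * wt_neuron.g_leak)
        rb2 = nk.rheobase(stiff, resolution=0.25, duration=500.0)
        assert rb2 > rb

    def test_sodium_free_neuron_never_fires(self, wt_neuron):
        passive = wt_neuron.replace(g_na=0.0, g_nap=0.0)
        assert nk.rheobase(passive, resolution=1.0, duration=200.0) is None
        assert nk.ramp_block_test(
            passive, stimulus_preset("ramp_rest", duration=2000.0)) is None


class TestStimulus:
    def test_program_validation(self):
        with pytest.raises(ValueError):
            StimulusProgram(kind="ramp", start=5.0, stop=1.0)
        with pytest.raises(ValueError):
            StimulusProgram(kind="ramp", start=0.0, stop=10.0)  # exp ramp
        with pytest.raises(ValueError):
            StimulusProgram(kind="wiggle")

    def test_exponential_ramp_endpoints(self):
        prog = stimulus_preset("ramp_rest")
        stim = build_stimulus(prog, prog.duration, dt=0.01)
        assert stim[0] == pytest.approx(0.002, rel=0.01)
        assert stim[-1] == pytest.approx(400.0, rel=0.01)
        assert np.all(np.diff(stim) >= 0)

    def test_pre_stimulus_segment(self):
        prog = stimulus_preset("ramp_prestim")
        stim = build_stimulus(prog, prog.pre_stimulus[1] + prog.duration,
                              dt=0.01)
        assert np.allclose(stim[:999], 10.0)
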