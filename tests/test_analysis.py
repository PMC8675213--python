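import numpy as np
import pytest

import navkit as nk
from navkit.analysis import (ProtocolMismatchError, estimate_v_rev,
                             conductance_curve, recovery_fractions,
                             ssfi_availability)
from navkit.fits import FitError
from navkit.protocols import protocol_preset
from navkit.synth import TraceSet, boltzmann_asc

CONDITIONS = [("WT", 22), ("L1624Q", 22), ("WT", 37), ("L1624Q", 37)]


def _flat_traceset(value, capacitance=20.0, duration=10.0):
    proto = protocol_preset("activation", step_voltages=(0.0,),
                            step_duration=duration)
    n = round((proto.baseline_ms + duration) / proto.sample_interval) + 1
    time = np.arange(n) * proto.sample_interval
    cur = np.full((1, n), 0.0)
    cur[0, time >= proto.baseline_ms] = value
    return TraceSet(time=time, sweep_keys=[0.0], currents=cur,
                    capacitance=capacitance, protocol=proto)


class TestPeaksAndDensity:
    def test_peak_magnitude_from_constructed_density(self, protocols):
        """Density 72.82 pA/pF at 20 pF gives a 1456.4 pA peak at 0 mV."""
        phen = nk.default_phenotype("WT", 37)
        ts = nk.simulate_protocol(phen, protocols["activation"], 20.0)
        peaks = nk.measure_peaks(ts)
        assert abs(peaks[0.0]) == pytest.approx(1456.4, rel=1e-6)
        assert peaks[0.0] < 0  # inward

    def test_all_zero_sweep_peak_is_zero(self):
        ts = _flat_traceset(0.0)
        assert nk.measure_peaks(ts)[0.0] == 0.0

    def test_density_from_peak_and_capacitance(self, protocols):
        phen = nk.default_phenotype("WT", 37)
        ts = nk.simulate_protocol(phen, protocols["activation"], 20.0)
        assert nk.current_density(ts) == pytest.approx(72.82, rel=1e-6)

    def test_density_halves_when_capacitance_doubles(self):
        a = _flat_traceset(-1000.0, capacitance=10.0)
        b = _flat_traceset(-1000.0, capacitance=20.0)
        assert nk.current_density(a) == pytest.approx(
            2 * nk.current_density(b))

    def test_density_requires_zero_mv_sweep(self, protocols):
        phen = nk.default_phenotype("WT", 37)
        proto = protocol_preset("activation",
                                step_voltages=(-40.0, -20.0, 20.0, 40.0))
        ts = nk.simulate_protocol(phen, proto, 20.0)
        with pytest.raises(ProtocolMismatchError):
            nk.current_density(ts)


class TestConductance:
    def test_estimated_reversal_matches_generator(self, clean_suites):
        peaks = nk.measure_peaks(clean_suites[("WT", 37)]["activation"])
        assert estimate_v_rev(peaks) == pytest.approx(65.0, abs=1e-3)

    def test_gv_curve_inverts_activation_boltzmann(self, clean_suites):
        """Normalized G-V from noise-free sweeps equals the generator's
        activation Boltzmann within 1e-3."""
        phen = nk.default_phenotype("WT", 37)
        peaks = nk.measure_peaks(clean_suites[("WT", 37)]["activation"])
        g = conductance_curve(peaks)
        for v, val in g.items():
            expected = float(boltzmann_asc(v, phen.v_half_act, phen.k_act))
            assert val == pytest.approx(expected, abs=1e-3)

    def test_gv_fit_recovers_phenotype(self, clean_suites):
        phen = nk.default_phenotype("WT", 37)
        fit = nk.fit_gv_boltzmann(clean_suites[("WT", 37)]["activation"])
        assert fit.v_half == pytest.approx(phen.v_half_act, rel=1e-3)
        assert fit.k == pytest.approx(phen.k_act, rel=1e-3)

    def test_ohmic_peaks_give_flat_conductance(self):
        v = np.arange(-100.0, 40.0, 10.0)
        peaks = {float(vv): 3.0 * (vv - 65.0) for vv in v}
        g = conductance_curve(peaks, v_rev=65.0)
        assert all(val == pytest.approx(1.0, abs=1e-12) for val in g.values())

    def test_all_zero_peaks_rejected(self):
        peaks = {float(v): 0.0 for v in np.arange(-100.0, 40.0, 10.0)}
        with pytest.raises(FitError):
            conductance_curve(peaks)


class TestOnsetTau:
    def test_tau_recovered_exactly(self, clean_suites):
        phen = nk.default_phenotype("WT", 37)
        taus = nk.fit_onset_tau(clean_suites[("WT", 37)]["activation"])
        for v, fit in taus.items():
            assert fit.tau == pytest.approx(phen.tau_onset(v), rel=1e-6)

    def test_lq_wt_tau_ratio_at_37(self, clean_suites):
        """The fitted onset tau ratio reproduces the 1.485-fold rate
        acceleration at every voltage on the reporting grid."""
        wt = nk.fit_onset_tau(clean_suites[("WT", 37)]["activation"])
        lq = nk.fit_onset_tau(clean_suites[("L1624Q", 37)]["activation"])
        for v in wt:
            assert lq[v].tau / wt[v].tau == pytest.approx(1 / 1.485, rel=1e-6)

    def test_constant_trace_fails(self):
        ts = _flat_traceset(-500.0)
        with pytest.raises(FitError):
            nk.fit_onset_tau(ts, voltages=[0.0])


class TestSsfi:
    def test_full_availability_at_hyperpolarized_prepulse(self, clean_suites):
        avail = ssfi_availability(clean_suites[("WT", 22)]["ssfi"])
        assert avail[-130.0] == pytest.approx(1.0, abs=1e-6)

    def test_fit_recovers_inactivation_boltzmann(self, clean_suites):
        for gen, temp in CONDITIONS:
            phen = nk.default_phenotype(gen, temp)
            fit = nk.ssfi_curve(clean_suites[(gen, temp)]["ssfi"])
            assert fit.v_half == pytest.approx(phen.v_half_inact, rel=1e-3)
            assert fit.k == pytest.approx(phen.k_inact, rel=1e-3)

    def test_midpoint_right_shift_with_temperature(self, clean_suites):
        f22 = nk.ssfi_curve(clean_suites[("WT", 22)]["ssfi"])
        f37 = nk.ssfi_curve(clean_suites[("WT", 37)]["ssfi"])
        assert f37.v_half > f22.v_half


class TestRecovery:
    def test_zero_time_point_gives_zero_fraction(self):
        phen = nk.default_phenotype("WT", 22)
        proto = protocol_preset(
            "recovery", recovery_times=(0.0, 1.0, 2.0, 5.0, 10.0, 20.0,
                                        50.0, 100.0, 200.0))
        ts = nk.simulate_protocol(phen, proto, 15.0)
        frac = recovery_fractions(ts)
        assert frac[0.0] == pytest.approx(0.0, abs=1e-9)

    def test_double_exp_constants_recovered(self, clean_suites):
        phen = nk.default_phenotype("WT", 22)
        fit = nk.recovery_curve(clean_suites[("WT", 22)]["recovery"])
        assert fit.tau_fast == pytest.approx(phen.rec_tau_fast, rel=1e-3)
        assert fit.tau_slow == pytest.approx(phen.rec_tau_slow, rel=1e-3)
        assert fit.frac_fast == pytest.approx(phen.rec_frac_fast, rel=1e-3)


class TestPersistent:
    @pytest.mark.parametrize("gen,temp,expected", [
        ("WT", 22, 0.95), ("L1624Q", 22, 3.20),
        ("WT", 37, 2.27), ("L1624Q", 37, 4.58),
    ])
    def test_measured_fractions(self, clean_suites, gen, temp, expected):
        pct_end, pct_mid = nk.persistent_fraction(
            clean_suites[(gen, temp)]["persistent"])
        assert pct_end == pytest.approx(expected, rel=1e-6)
        assert pct_mid == pytest.approx(expected, rel=1e-4)

    def test_square_pulse_is_100_percent(self):
        ts = _flat_traceset(-800.0, duration=50.0)
        proto = protocol_preset("persistent")
        ts.protocol = proto
        pct_end, _ = nk.persistent_fraction(ts)
        assert pct_end == pytest.approx(100.0)

    def test_fully_decaying_trace_is_zero_percent(self, protocols):
        phen = nk.default_phenotype("WT", 22).with_(f_persistent=0.0)
        ts = nk.simulate_protocol(phen, protocols["persistent"], 15.0)
        pct_end, _ = nk.persistent_fraction(ts)
        assert pct_end == pytest.approx(0.0, abs=1e-9)

    def test_unstabilized_persistent_current_warns(self, protocols):
        """A slow decay (tau comparable to the pulse) leaves the end and
        25-30 ms windows inconsistent and triggers the stability check."""
        phen = nk.default_phenotype("WT", 22).with_(
            tau_onset_table={0: 15.0}, f_persistent=0.01)
        ts = nk.simulate_protocol(phen, protocols["persistent"], 15.0)
        with pytest.warns(UserWarning, match="not stabilized"):
            nk.persistent_fraction(ts)


class TestFullPipelineRoundTrip:
    @pytest.mark.parametrize("gen,temp", CONDITIONS)
    def test_cell_metrics_match_ground_truth(self, clean_suites, gen, temp):
        """Every measured CellMetrics field reproduces its generative
        parameter within 1e-3 relative error on noise-free data."""
        phen = nk.default_phenotype(gen, temp)
        m = nk.analyze_cell(clean_suites[(gen, temp)])
        assert m.current_density_0mV == pytest.approx(
            phen.density_at_0mV, rel=1e-3)
        assert m.gv_fit.v_half == pytest.approx(phen.v_half_act, rel=1e-3)
        assert m.ssfi_fit.v_half == pytest.approx(phen.v_half_inact, rel=1e-3)
        assert m.persistent_pct_end == pytest.approx(
            100 * phen.f_persistent, rel=1e-3)
        assert m.recovery_fit.tau_fast == pytest.approx(
            phen.rec_tau_fast, rel=1e-3)
        assert m.recovery_fit.tau_slow == pytest.approx(
            phen.rec_tau_slow, rel=1e-3)
        for v, tau in m.tau_onset_by_v.items():
            assert tau == pytest.approx(phen.tau_onset(v), rel=1e-3)

    def test_noisy_cohort_mean_persistent_within_tolerance(self,
                                                           coarse_protocols):
        """With 2%-of-peak noise and 20 cells, the cohort-mean measured
        persistent fraction stays within 0.3 percentage points of truth."""
        phen = nk.default_phenotype("L1624Q", 37)
        peak = phen.density_at_0mV * 15.0
        cells = nk.generate_cohort(
            phen, coarse_protocols["persistent"], n_cells=20,
            cell_variability=0.0, noise_sd=0.02 * peak, seed=99)
        vals = [nk.persistent_fraction(ts)[0] for ts in cells]
        assert np.mean(vals) == pytest.approx(100 * phen.f_persistent,
                                              abs=0.3)

    def test_analysis_is_deterministic(self, clean_suites):
        a = nk.analyze_cell(clean_suites[("WT", 37)])
        b = nk.analyze_cell(clean_suites[("WT", 37)])
        assert a.gv_fit == b.gv_fit
        assert a.tau_onset_by_v == b.tau_onset_by_v
        assert a.recovery_fit == b.recovery_fit
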