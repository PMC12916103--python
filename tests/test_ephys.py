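"""Current-clamp analysis: spike detection, AP features, passive properties."""

import numpy as np
import pytest

from epiphys import ephys, synth
from epiphys.io import StepProtocol


RATE = 100_000.0
DT_MS = 1000.0 / RATE


class TestDvdt:
    def test_linear_ramp_has_constant_slope(self):
        t_ms = np.arange(0, 10, DT_MS)
        v = -70.0 + 1.0 * t_ms  # 1 mV per ms
        dvdt = ephys.compute_dvdt(v, RATE)
        np.testing.assert_allclose(dvdt, 1.0, rtol=1e-9)

    def test_sine_peak_slope_matches_closed_form(self):
        f, a = 100.0, 20.0  # Hz, mV
        t = np.arange(0, 0.05, 1 / RATE)
        v = a * np.sin(2 * np.pi * f * t)
        dvdt = ephys.compute_dvdt(v, RATE)
        expected = 2 * np.pi * f * a / 1000.0  # mV/ms
        assert dvdt.max() == pytest.approx(expected, rel=5e-3)

    def test_constant_trace_is_flat(self):
        dvdt = ephys.compute_dvdt(np.full(100, -65.0), RATE)
        np.testing.assert_array_equal(dvdt, 0.0)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            ephys.compute_dvdt(np.array([1.0, 2.0]), RATE)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        assert ephys.detect_spikes(np.full(10000, -70.0), RATE).size == 0

    def test_counts_inserted_template_spikes(self):
        ramp, _, truth = synth.gen_current_clamp(seed=0)
        peaks = ephys.detect_spikes(ramp.sweeps[0], ramp.sampling_rate)
        assert peaks.size == truth["ramp_spike_times_s"].size
        np.testing.assert_allclose(peaks / ramp.sampling_rate,
                                   truth["ramp_spike_times_s"],
                                   atol=2 / ramp.sampling_rate)

    def test_peak_below_floor_not_counted(self):
        # spike-like deflection peaking at -15 mV: below the -10 mV floor
        v = np.full(5000, -70.0)
        v[2000:2050] = np.linspace(-70, -15, 50)
        v[2050:2100] = np.linspace(-15, -70, 50)
        assert ephys.detect_spikes(v, RATE).size == 0

    def test_dc_offset_invariance(self):
        ramp, _, _ = synth.gen_current_clamp(seed=1)
        v = ramp.sweeps[0]
        base = ephys.detect_spikes(v, RATE)
        shifted = ephys.detect_spikes(v + 5.0, RATE)
        np.testing.assert_array_equal(base, shifted)

    def test_slow_artifact_rejected_by_upstroke_gate(self):
        # slow hump reaching 0 mV but rising at only ~2 mV/ms
        t_ms = np.arange(0, 100, DT_MS)
        v = -70.0 + 70.0 * np.exp(-((t_ms - 50) / 15.0) ** 2)
        assert ephys.detect_spikes(v, RATE).size == 0


class TestApThreshold:
    def test_hand_evaluated_rule(self):
        # first sample with dvdt > 5% of upstroke (400 -> 20) is Vm = -40
        dvdt = np.array([0.0, 1.0, 2.0, 6.0, 100.0, 400.0])
        vm = np.array([-70.0, -69.0, -67.0, -55.0, -40.0, -10.0])
        thr, idx = ephys.ap_threshold(vm, dvdt, peak_index=5)
        assert thr == -40.0 and idx == 4

    def test_threshold_not_above_vm_at_max_dvdt(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = 50
            dvdt = np.abs(rng.normal(0, 1, n))
            peak = n - 1
            dvdt[peak - 5] = 300.0  # max dvdt before peak
            vm = np.sort(rng.normal(-40, 15, n))
            thr, idx = ephys.ap_threshold(vm, dvdt, peak_index=peak)
            assert thr <= vm[peak - 5]

    def test_no_positive_upstroke_errors(self):
        with pytest.raises(ValueError, match="no threshold"):
            ephys.ap_threshold(np.array([-70.0, -70.0]),
                               np.array([-1.0, -2.0]), peak_index=1)


class TestApFeatures:
    def _triangle(self, thr=-40.0, peak=10.0, up=100.0, down=-100.0):
        """Baseline, linear rise thr->peak at `up`, fall to AHP at `down`."""
        n_pre = 500
        rise = np.arange(thr, peak, up * DT_MS)
        fall = np.arange(peak, -60.0, down * DT_MS)
        tail = np.full(1500, -60.0)
        v = np.concatenate([np.full(n_pre, thr - 0.001), rise, fall, tail])
        return v

    def test_triangle_amplitude_and_half_level(self):
        v = self._triangle()
        f = ephys.ap_features(v, RATE)
        assert f.amplitude_mV == pytest.approx(50.0, abs=0.1)
        assert f.threshold_mV == pytest.approx(-40.0, abs=0.1)
        assert f.peak_mV == pytest.approx(10.0, abs=0.05)

    def test_symmetric_triangle_apd50_geometry(self):
        # rise 100 mV/ms, fall -100 mV/ms, amplitude 50 -> APD50 = 0.5 ms
        v = self._triangle()
        f = ephys.ap_features(v, RATE)
        assert f.apd50_ms == pytest.approx(0.5, abs=2 * DT_MS)
        # oracle: dense piecewise-linear resampling and crossing count
        half = f.threshold_mV + f.amplitude_mV / 2
        t = np.arange(v.size) * DT_MS
        t_dense = np.arange(0, t[-1], DT_MS / 100)
        v_dense = np.interp(t_dense, t, v)
        oracle = np.count_nonzero(v_dense > half) * DT_MS / 100
        assert f.apd50_ms == pytest.approx(oracle, abs=2 * DT_MS)

    def test_template_apd50_recovered_within_one_sample(self):
        ramp, _, truth = synth.gen_current_clamp(seed=3)
        f = ephys.extract_first_ap_features(ramp.sweeps[0], RATE)
        assert f.apd50_ms == pytest.approx(truth["apd50_ms"], abs=DT_MS)

    def test_threshold_leq_peak_invariant(self):
        for seed in range(5):
            ramp, _, _ = synth.gen_current_clamp(seed=seed, jitter=True)
            f = ephys.extract_first_ap_features(ramp.sweeps[0], RATE)
            assert f.threshold_mV <= f.peak_mV
            assert f.apd50_ms < 15.0  # window length bound


class TestTemplateRecovery:
    """Parameter-recovery on generator templates (the ground-truth suite)."""

    @pytest.mark.parametrize("seed", range(10))
    def test_features_match_analytic_truth(self, seed):
        ramp, _, truth = synth.gen_current_clamp(seed=seed, jitter=True)
        f = ephys.extract_first_ap_features(ramp.sweeps[0], RATE)
        assert f.threshold_mV == pytest.approx(truth["threshold_mV"], abs=1.0)
        assert f.apd50_ms == pytest.approx(truth["apd50_ms"], abs=DT_MS)
        assert f.upstroke_mV_per_ms == pytest.approx(
            truth["upstroke_mV_per_ms"], rel=0.02)
        assert f.downstroke_mV_per_ms == pytest.approx(
            truth["downstroke_mV_per_ms"], rel=0.02)
        assert f.ahp_mV == pytest.approx(truth["ahp_mV"], abs=0.5)


class TestPassive:
    def test_resting_vm_constant(self):
        assert ephys.resting_vm(np.full(1000, -72.0)) == -72.0

    def test_resting_vm_robust_to_spikes(self):
        v = np.full(10_000, -70.0)
        v[:: 100] = 0.0  # 1% of samples at 0 mV
        assert ephys.resting_vm(v) == -70.0

    def test_resting_vm_gaussian_sampling(self):
        rng = np.random.default_rng(4)
        v = rng.normal(-65.0, 2.0, 1_000_000)
        assert ephys.resting_vm(v) == pytest.approx(-65.0, abs=0.01)

    @pytest.mark.parametrize("dv,expected", [(-2.0, 100.0), (-4.0, 200.0)])
    def test_input_resistance_ohms_law(self, dv, expected):
        rate = 10_000.0
        protocol = StepProtocol(amplitudes=[-20.0], onset_s=0.1,
                                duration_s=1.0)
        v = np.full(13_000, -70.0)
        i0, i1 = protocol.window(rate)
        v[i0:i1] = -70.0 + dv
        assert ephys.input_resistance(v, rate, protocol) == pytest.approx(expected)

    def test_input_resistance_rc_model(self):
        # R = 150 MOhm, tau = 15 ms, 1 s step: settles within 0.1%
        rate, r, tau = 10_000.0, 150.0, 0.015
        protocol = StepProtocol(amplitudes=[-20.0], onset_s=0.1, duration_s=1.0)
        t = np.arange(13_000) / rate
        v = np.full(13_000, -70.0)
        step = (t >= 0.1) & (t < 1.1)
        v[step] = -70.0 + (-20.0 * r / 1000.0) * (1 - np.exp(-(t[step] - 0.1) / tau))
        v[t >= 1.1] = -70.0
        assert ephys.input_resistance(v, rate, protocol) == pytest.approx(150.0, abs=1.0)


class TestRheobase:
    def test_largest_silent_step(self):
        fi = ephys.FICurve([0, 50, 100, 150, 200], [0, 0, 0, 2, 5])
        rheo, info = ephys.rheobase(fi)
        assert rheo == 100.0
        assert info["first_spiking_step_pA"] == 150.0
        assert not info["non_monotonic"]

    def test_non_monotonic_counts_use_literal_rule(self):
        fi = ephys.FICurve([0, 50, 100, 150], [0, 1, 0, 3])
        with pytest.warns(UserWarning, match="non-monotonic"):
            rheo, info = ephys.rheobase(fi)
        assert rheo == 100.0
        assert info["non_monotonic"]

    def test_all_spiking_and_all_silent_flagged_distinctly(self):
        with pytest.raises(ValueError, match="all steps spiking"):
            ephys.rheobase(ephys.FICurve([50, 100], [1, 2]))
        with pytest.raises(ValueError, match="all steps silent"):
            ephys.rheobase(ephys.FICurve([50, 100], [0, 0]))

    def test_monotonic_rheobase_below_first_spiking(self):
        fi = ephys.FICurve([0, 50, 100, 150], [0, 0, 1, 4])
        rheo, info = ephys.rheobase(fi)
        assert rheo < info["first_spiking_step_pA"]


class TestFICurve:
    def test_silent_sweeps_all_zero(self):
        rate = 10_000.0
        protocol = StepProtocol(amplitudes=[-100.0, 0.0, 100.0],
                                onset_s=0.1, duration_s=1.0)
        from epiphys.io import SweepSet
        ss = SweepSet(sampling_rate=rate, sweeps=np.full((3, 13_000), -70.0),
                      unit="mV", protocol=protocol)
        fi = ephys.fi_curve(ss)
        np.testing.assert_array_equal(fi.spike_counts, 0)

    def test_lif_counts_match_analytic_isi(self):
        # counts from the generator's closed-form inter-spike interval
        _, steps, truth = synth.gen_current_clamp(seed=5, rate_hz=50_000.0)
        fi = ephys.fi_curve(steps)
        np.testing.assert_array_equal(fi.spike_counts,
                                      truth["step_spike_counts"])
        for amp, count, isi in zip(truth["step_amplitudes_pA"],
                                   truth["step_spike_counts"],
                                   truth["step_isi_ms"]):
            if np.isfinite(isi):
                # first spike latency differs; expect 1 + floor over remainder
                assert abs(count - 1000.0 / isi) <= max(2, 0.1 * count)

    def test_spikes_outside_step_window_not_counted(self):
        rate = 10_000.0
        protocol = StepProtocol(amplitudes=[100.0], onset_s=0.5,
                                duration_s=0.5)
        v = np.full(12_000, -70.0)
        # sharp spike at t = 0.2 s, before the step
        v[2000:2003] = [0.0, 30.0, 0.0]
        from epiphys.io import SweepSet
        ss = SweepSet(sampling_rate=rate, sweeps=v[None, :], unit="mV",
                      protocol=protocol)
        assert ephys.fi_curve(ss).spike_counts[0] == 0


class TestQc:
    def test_depolarized_cell_fails(self):
        res = ephys.qc_cell(-49.0, [10.0, 10.0])
        assert not res.passed and "depolarized" in res.reasons[0]

    def test_access_drift_fails(self):
        res = ephys.qc_cell(-65.0, [10.0, 12.1])
        assert not res.passed and "drift" in res.reasons[0]

    def test_healthy_cell_passes(self):
        assert ephys.qc_cell(-65.0, [10.0, 11.0]).passed
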