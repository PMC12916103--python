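"""Seed-controlled ground-truth generators for every analysis modality.

Each generator returns ``(data, truth)`` where ``truth`` is a plain dict
sufficient to score the paired detector (event times, amplitudes, labels,
analytic parameter values) without re-deriving anything.  Identical
parameters and seed give bit-identical output.

Default parameters emulate the study conditions the analyses assume:

* Current clamp: fast-spiking leaky-integrate-and-fire cells (R = 150 MOhm,
  tau_m = 15 ms, threshold -40 mV) with piecewise-linear spike templates
  whose threshold, slopes, APD50 and AHP are analytically known; ramp
  (100 pA/s) and 1 s step (-100..500 pA) protocols.
* Voltage clamp: 100 ms steps from -80 to +40 mV in 5 mV increments,
  Boltzmann activation times an exponential approach with voltage-dependent
  tau and no inactivation.
* Paired recordings: trains of 10 presynaptic APs at 5-120 Hz, stochastic
  release with Bernoulli failures, geometric per-pulse depression, Gaussian
  latency jitter, difference-of-exponentials PSC kernels.
* Calcium: Poisson transients (1.2 per minute at rest) convolved with an
  exponential-decay kernel (tau 0.7 s) on a positive baseline with slow
  drift and white noise; optional global hypersynchronous discharges.
* EEG: 1/f colored background noise with inserted biphasic spike templates,
  spike trains, myoclonic singles, and a fatal-seizure scenario with
  post-ictal amplitude collapse; a matching behavior-annotation track.
"""

from __future__ import annotations

import numpy as np

from .io import (EEGRecord, RampProtocol, RoiFluorescence, StepProtocol,
                 SweepSet, TrainProtocol)
from .pairs import PairedSweep
from .vclamp import VoltageStepFamily

# ---------------------------------------------------------------------------
# Current clamp
# ---------------------------------------------------------------------------


def _snap_spike_template(rate_hz: float, v_thresh: float, amplitude_mV: float,
                         upstroke_mV_per_ms: float, ahp_mV: float,
                         downstroke_mV_per_ms: float):
    """Piecewise-linear spike template with corners snapped to the sample grid.

    Returns ``(samples, truth)`` where truth holds the exact (post-snap)
    threshold, peak, slopes, APD50 and AHP realized by the template.
    """
    dt_ms = 1000.0 / rate_hz
    if downstroke_mV_per_ms >= 0:
        raise ValueError("inconsistent template: fall slope must be negative")
    peak = v_thresh + amplitude_mV
    n_rise = max(2, int(round(amplitude_mV / upstroke_mV_per_ms / dt_ms)))
    n_fall = max(2, int(round((ahp_mV - peak) / downstroke_mV_per_ms / dt_ms)))
    up = amplitude_mV / (n_rise * dt_ms)
    down = (ahp_mV - peak) / (n_fall * dt_ms)
    rise = v_thresh + up * dt_ms * np.arange(n_rise + 1)
    fall = peak + down * dt_ms * np.arange(1, n_fall + 1)
    samples = np.concatenate([rise, fall])  # starts at threshold, ends at AHP
    half = v_thresh + amplitude_mV / 2.0
    apd50 = (amplitude_mV / 2.0) / up + (peak - half) / abs(down)
    truth = {
        "threshold_mV": v_thresh, "peak_mV": peak,
        "amplitude_mV": amplitude_mV,
        "upstroke_mV_per_ms": up, "downstroke_mV_per_ms": down,
        "apd50_ms": apd50, "ahp_mV": ahp_mV,
        "n_samples": samples.size,
    }
    return samples, truth


def _ramp_voltage(t_ms, t0_ms, v0, v_rest, r_MOhm, tau_ms, slope_pA_per_ms):
    """Leaky-integrator response to a current ramp, from (t0, v0)."""
    rc = r_MOhm * slope_pA_per_ms / 1000.0  # mV per ms of ramp growth
    part = v_rest + rc * (t_ms - tau_ms)
    part0 = v_rest + rc * (t0_ms - tau_ms)
    return part + (v0 - part0) * np.exp(-(t_ms - t0_ms) / tau_ms)


def gen_current_clamp(seed: int = 0, *,
                      rate_hz: float = 100_000.0,
                      r_MOhm: float = 150.0,
                      tau_ms: float = 15.0,
                      v_rest_mV: float = -70.0,
                      v_thresh_mV: float = -40.0,
                      spike_amplitude_mV: float = 60.0,
                      upstroke_mV_per_ms: float = 400.0,
                      downstroke_mV_per_ms: float = -200.0,
                      ahp_mV: float = -58.0,
                      ramp_slope_pA_per_s: float = 100.0,
                      ramp_duration_s: float = 3.0,
                      step_amplitudes_pA: np.ndarray | None = None,
                      step_duration_s: float = 1.0,
                      noise_sd_mV: float = 0.0,
                      jitter: bool = False,
                      make_steps: bool = True,
                      rng: np.random.Generator | None = None):
    """Current-clamp ramp and step sweeps from an analytic LIF cell.

    Subthreshold trajectories are exact exponential solutions of the leaky
    integrator; when the trajectory crosses threshold a grid-snapped spike
    template is pasted in and integration resumes from its AHP.  With
    ``jitter`` the per-cell parameters are perturbed (for population suites).

    Returns ``(ramp_sweepset, step_sweepset, truth)``; truth carries the
    template feature values, per-sweep spike times, the analytic rheobase
    (V_thresh - V_rest)/R, and the analytic inter-spike interval per step.
    """
    rng = rng or np.random.default_rng(seed)
    if jitter:
        v_thresh_mV += rng.uniform(-3, 3)
        spike_amplitude_mV += rng.uniform(-10, 10)
        upstroke_mV_per_ms *= rng.uniform(0.8, 1.3)
        downstroke_mV_per_ms *= rng.uniform(0.8, 1.3)
        ahp_mV += rng.uniform(-3, 3)
        r_MOhm *= rng.uniform(0.85, 1.15)
    template, feat = _snap_spike_template(
        rate_hz, v_thresh_mV, spike_amplitude_mV, upstroke_mV_per_ms,
        ahp_mV, downstroke_mV_per_ms)
    dt_ms = 1000.0 / rate_hz

    # --- ramp sweep -------------------------------------------------------
    n_ramp = int(round(ramp_duration_s * rate_hz))
    slope_ms = ramp_slope_pA_per_s / 1000.0  # pA per ms
    t_ms = np.arange(n_ramp) * dt_ms
    v = np.empty(n_ramp)
    spike_times_s = []
    i = 0
    t0, v0 = 0.0, v_rest_mV
    while i < n_ramp:
        seg_t = t_ms[i:]
        seg_v = _ramp_voltage(seg_t, t0, v0, v_rest_mV, r_MOhm, tau_ms, slope_ms)
        above = np.nonzero(seg_v >= v_thresh_mV)[0]
        if above.size == 0:
            v[i:] = seg_v
            break
        j = i + int(above[0])  # first suprathreshold sample: spike onset
        v[i:j] = seg_v[:above[0]]
        stop = min(j + template.size, n_ramp)
        v[j:stop] = template[:stop - j]
        spike_times_s.append((j + feat["n_samples"] - template.size +
                              np.argmax(template)) / rate_hz)
        i = stop
        t0, v0 = t_ms[min(stop, n_ramp - 1)], ahp_mV
    if noise_sd_mV > 0:
        v = v + rng.normal(0.0, noise_sd_mV, n_ramp)
    ramp = SweepSet(sampling_rate=rate_hz, sweeps=v[None, :], unit="mV",
                    protocol=RampProtocol(slope_pA_per_s=ramp_slope_pA_per_s,
                                          onset_s=0.0,
                                          duration_s=ramp_duration_s),
                    metadata={"kind": "synthetic_ramp"})

    # --- step sweeps ------------------------------------------------------
    if not make_steps:
        truth = dict(feat)
        truth.update({
            "v_rest_mV": v_rest_mV, "r_MOhm": r_MOhm, "tau_ms": tau_ms,
            "ramp_spike_times_s": np.asarray(spike_times_s),
            "rheobase_pA": (v_thresh_mV - v_rest_mV) / r_MOhm * 1000.0,
        })
        return ramp, None, truth
    if step_amplitudes_pA is None:
        step_amplitudes_pA = np.arange(-100.0, 501.0, 50.0)
    step_amplitudes_pA = np.asarray(step_amplitudes_pA, dtype=float)
    onset_s, tail_s = 0.1, 0.15
    n_step = int(round((onset_s + step_duration_s + tail_s) * rate_hz))
    i_on = int(round(onset_s * rate_hz))
    i_off = int(round((onset_s + step_duration_s) * rate_hz))
    sweeps = np.empty((step_amplitudes_pA.size, n_step))
    counts = []
    isis_analytic = []
    for s, amp in enumerate(step_amplitudes_pA):
        v_inf = v_rest_mV + r_MOhm * amp / 1000.0
        sweep = np.full(n_step, v_rest_mV)
        count = 0
        if v_inf > v_thresh_mV:
            # closed-form crossing times, template pasted at each
            i = i_on
            v0 = v_rest_mV
            while i < i_off:
                # time (ms) to threshold from current state
                dtc = tau_ms * np.log((v_inf - v0) / (v_inf - v_thresh_mV))
                j = i + int(np.ceil(dtc / dt_ms))
                if j >= i_off:
                    tt = (np.arange(i, i_off) - i) * dt_ms
                    sweep[i:i_off] = v_inf + (v0 - v_inf) * np.exp(-tt / tau_ms)
                    break
                tt = (np.arange(i, j) - i) * dt_ms
                sweep[i:j] = v_inf + (v0 - v_inf) * np.exp(-tt / tau_ms)
                stop = min(j + template.size, i_off)
                sweep[j:stop] = template[:stop - j]
                if stop - j > np.argmax(template):
                    count += 1
                i = stop
                v0 = ahp_mV
            # tail decays back to rest
            tt = (np.arange(i_off, n_step) - i_off) * dt_ms
            v_last = sweep[i_off - 1] if i_off > 0 else v_rest_mV
            sweep[i_off:] = v_rest_mV + (v_last - v_rest_mV) * np.exp(-tt / tau_ms)
            isi = (tau_ms * np.log((v_inf - ahp_mV) / (v_inf - v_thresh_mV))
                   + template.size * dt_ms)
        else:
            tt = (np.arange(i_on, i_off) - i_on) * dt_ms
            sweep[i_on:i_off] = v_inf + (v_rest_mV - v_inf) * np.exp(-tt / tau_ms)
            tt = (np.arange(i_off, n_step) - i_off) * dt_ms
            sweep[i_off:] = v_rest_mV + (sweep[i_off - 1] - v_rest_mV) * np.exp(-tt / tau_ms)
            isi = np.inf
        if noise_sd_mV > 0:
            sweep = sweep + rng.normal(0.0, noise_sd_mV, n_step)
        sweeps[s] = sweep
        counts.append(count)
        isis_analytic.append(isi)
    steps = SweepSet(sampling_rate=rate_hz, sweeps=sweeps, unit="mV",
                     protocol=StepProtocol(amplitudes=step_amplitudes_pA,
                                           onset_s=onset_s,
                                           duration_s=step_duration_s,
                                           holding=0.0),
                     metadata={"kind": "synthetic_steps"})

    truth = dict(feat)
    truth.update({
        "v_rest_mV": v_rest_mV,
        "r_MOhm": r_MOhm, "tau_ms": tau_ms,
        "ramp_spike_times_s": np.asarray(spike_times_s),
        "step_amplitudes_pA": step_amplitudes_pA,
        "step_spike_counts": np.asarray(counts, dtype=int),
        "step_isi_ms": np.asarray(isis_analytic),
        "rheobase_pA": (v_thresh_mV - v_rest_mV) / r_MOhm * 1000.0,
    })
    return ramp, steps, truth


# ---------------------------------------------------------------------------
# Voltage clamp
# ---------------------------------------------------------------------------

def default_tau_of_voltage(v_mV: np.ndarray) -> np.ndarray:
    """Activation tau (ms) decreasing with depolarization (fast Kv3-like)."""
    return 1.0 + 9.0 * np.exp(-(np.asarray(v_mV, float) + 80.0) / 40.0)


def gen_vclamp_family(seed: int = 0, *,
                      gmax_nS: float = 20.0,
                      vhalf_mV: float = -5.0,
                      k_mV: float = 8.0,
                      e_rev_mV: float = -97.0,
                      holding_mV: float = -80.0,
                      step_mV: np.ndarray | None = None,
                      duration_ms: float = 100.0,
                      onset_ms: float = 10.0,
                      rate_hz: float = 20_000.0,
                      tau_fn=default_tau_of_voltage,
                      trace_noise_sd_pA: float = 2.0,
                      g_noise_sd_nS: float = 0.0,
                      capacitance_pF: float = 8.0,
                      rng: np.random.Generator | None = None):
    """Voltage-step K+ current family with Boltzmann activation.

    I(V, t) = G(V) (V - E_rev) (1 - exp(-t/tau(V))) during the step, with
    G(V) = Gmax / (1 + exp(-(V - Vhalf)/k)).  ``g_noise_sd_nS`` adds one
    Gaussian conductance perturbation per step (measurement-level scatter of
    the G-V curve); ``trace_noise_sd_pA`` adds white current noise.

    Returns ``(family, truth)``.
    """
    if k_mV <= 0:
        raise ValueError("k must be > 0")
    rng = rng or np.random.default_rng(seed)
    if step_mV is None:
        step_mV = np.arange(-80.0, 40.1, 5.0)
    step_mV = np.asarray(step_mV, dtype=float)
    n = int(round((onset_ms + duration_ms + 10.0) * rate_hz / 1000.0))
    i_on = int(round(onset_ms * rate_hz / 1000.0))
    i_off = int(round((onset_ms + duration_ms) * rate_hz / 1000.0))
    t_ms = (np.arange(n) - i_on) / rate_hz * 1000.0
    g_true = gmax_nS / (1.0 + np.exp(-(step_mV - vhalf_mV) / k_mV))
    g_jitter = rng.normal(0.0, g_noise_sd_nS, step_mV.size) if g_noise_sd_nS > 0 else 0.0
    g_eff = np.clip(g_true + g_jitter, 0.0, None)
    taus = tau_fn(step_mV)
    traces = np.zeros((step_mV.size, n))
    for i, (v, g, tau) in enumerate(zip(step_mV, g_eff, taus)):
        act = np.where((t_ms >= 0) & (t_ms < duration_ms),
                       1.0 - np.exp(-np.clip(t_ms, 0, None) / tau), 0.0)
        traces[i] = g * (v - e_rev_mV) * act  # nS * mV = pA
    if trace_noise_sd_pA > 0:
        traces = traces + rng.normal(0.0, trace_noise_sd_pA, traces.shape)
    family = VoltageStepFamily(holding_mV=holding_mV, step_mV=step_mV,
                               traces=traces, sampling_rate=rate_hz,
                               onset_s=onset_ms / 1000.0,
                               duration_s=duration_ms / 1000.0,
                               capacitance_pF=capacitance_pF)
    truth = {"gmax_nS": gmax_nS, "vhalf_mV": vhalf_mV, "k_mV": k_mV,
             "e_rev_mV": e_rev_mV, "tau_ms": taus,
             "g_true_nS": g_true, "g_effective_nS": g_eff}
    return family, truth


# ---------------------------------------------------------------------------
# Paired recordings
# ---------------------------------------------------------------------------

def _psc_kernel(rate_hz: float, rise_ms: float = 0.5, decay_ms: float = 8.0,
                length_ms: float = 60.0) -> np.ndarray:
    """Difference-of-exponentials PSC kernel, normalized to unit peak."""
    t = np.arange(int(length_ms * rate_hz / 1000.0)) / rate_hz * 1000.0
    k = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    return k / k.max()


def gen_paired_recording(seed: int = 0, *,
                         frequency_hz: float = 20.0,
                         n_pulses: int = 10,
                         n_sweeps: int = 1,
                         rate_hz: float = 20_000.0,
                         a1_pA: float = 50.0,
                         depression_ratio: float = 0.7,
                         failure_prob: float = 0.3,
                         latency_mean_ms: float = 1.2,
                         latency_sd_ms: float = 0.1,
                         psc_rise_ms: float = 0.5,
                         psc_decay_ms: float = 8.0,
                         noise_sd_pA: float = 2.0,
                         polarity: str = "inward",
                         rng: np.random.Generator | None = None):
    """Paired presynaptic-AP / postsynaptic-current sweeps with known release.

    Pulse i (1-based) releases with probability 1 - failure_prob and
    amplitude a1 * depression_ratio**(i-1); the PSC kernel is placed at the
    AP peak plus a Gaussian latency.  Returns ``(sweeps, truth)`` with truth
    recording every intended amplitude, success flag and latency.
    """
    if depression_ratio <= 0:
        raise ValueError("depression ratio must be > 0")
    rng = rng or np.random.default_rng(seed)
    onset_s = 0.05
    duration_s = onset_s + (n_pulses - 1) / frequency_hz + 0.1
    n = int(round(duration_s * rate_hz))
    sign = -1.0 if polarity == "inward" else 1.0
    kernel = _psc_kernel(rate_hz, psc_rise_ms, psc_decay_ms)

    # presynaptic AP template (same for every sweep)
    ap_rise = int(round(0.3e-3 * rate_hz))
    ap_fall = int(round(0.6e-3 * rate_hz))
    ap = np.concatenate([
        -70.0 + 100.0 * np.arange(ap_rise + 1) / ap_rise,
        30.0 - 100.0 * np.arange(1, ap_fall + 1) / ap_fall,
    ])
    pulse_idx = (onset_s + np.arange(n_pulses) / frequency_hz)
    pulse_idx = np.round(pulse_idx * rate_hz).astype(int)

    sweeps, truth_rows = [], []
    for s in range(n_sweeps):
        pre = np.full(n, -70.0)
        post = np.zeros(n)
        for i, p in enumerate(pulse_idx):
            stop = min(p + ap.size, n)
            pre[p:stop] = np.maximum(pre[p:stop], ap[:stop - p])
            ap_peak = p + ap_rise
            success = rng.random() >= failure_prob
            amp = a1_pA * depression_ratio ** i
            latency = rng.normal(latency_mean_ms, latency_sd_ms)
            if success:
                k0 = ap_peak + int(round(latency * rate_hz / 1000.0))
                kstop = min(k0 + kernel.size, n)
                post[k0:kstop] += sign * amp * kernel[:kstop - k0]
            truth_rows.append({"sweep": s, "pulse": i + 1,
                               "ap_peak_time_s": ap_peak / rate_hz,
                               "success": bool(success),
                               "amplitude_pA": amp if success else 0.0,
                               "latency_ms": latency if success else np.nan})
        post = post + rng.normal(0.0, noise_sd_pA, n)
        sweeps.append(PairedSweep(pre_voltage_mV=pre, post_current_pA=post,
                                  rate_hz=rate_hz,
                                  train_frequency_hz=frequency_hz,
                                  n_pulses=n_pulses, polarity=polarity,
                                  metadata={"sweep": str(s)}))
    truth = {"a1_pA": a1_pA, "depression_ratio": depression_ratio,
             "failure_prob": failure_prob,
             "latency_mean_ms": latency_mean_ms, "events": truth_rows}
    return sweeps, truth


# ---------------------------------------------------------------------------
# Calcium imaging
# ---------------------------------------------------------------------------

def gen_calcium(seed: int = 0, *,
                n_cells: int = 100,
                duration_s: float = 600.0,
                frame_rate: float = 30.0,
                baseline_F: float = 100.0,
                transient_amp_F: float = 46.0,
                peak_snr: float = 35.0,
                decay_s: float = 0.7,
                rate_rest_per_min: float = 1.2,
                rate_loco_per_min: float = 3.0,
                drift_amp_F: float = 3.0,
                drift_period_s: float = 300.0,
                discharge_times_s: np.ndarray | None = None,
                discharge_amp_dff: float = 1.0,
                discharge_decay_s: float = 0.3,
                locomotion_schedule: list[tuple[float, float]] | None = None,
                min_event_separation_s: float = 0.25,
                rng: np.random.Generator | None = None):
    """ROI fluorescence with Poisson transients, drift, noise, discharges.

    Transients are exponential-decay kernels (instantaneous rise) of
    amplitude ``transient_amp_F`` on a baseline of ``baseline_F``; white
    per-frame noise has SD ``transient_amp_F / peak_snr``.  Event rates
    switch between the rest and locomotion values per the schedule (default:
    all rest).  Discharges are global additive deflections of
    ``discharge_amp_dff`` (in dF/F0 units, scaled by the baseline).

    Returns ``(roi, speed_trace, truth)``; truth lists per-cell event frames
    and the discharge frames.
    """
    if rate_rest_per_min < 0 or rate_loco_per_min < 0:
        raise ValueError("event rates must be >= 0")
    rng = rng or np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate))
    noise_sd = transient_amp_F / peak_snr

    # locomotion speed trace and per-frame rate
    speed = np.zeros(n_frames)
    rate_per_frame = np.full(n_frames, rate_rest_per_min / 60.0 / frame_rate)
    if locomotion_schedule:
        for a, b in locomotion_schedule:
            ia, ib = int(a * frame_rate), int(b * frame_rate)
            speed[ia:ib] = 5.0
            rate_per_frame[ia:ib] = rate_loco_per_min / 60.0 / frame_rate

    kernel = transient_amp_F * np.exp(
        -np.arange(int(6 * decay_s * frame_rate)) / (decay_s * frame_rate))
    min_sep = max(1, int(round(min_event_separation_s * frame_rate)))

    F = np.empty((n_cells, n_frames))
    event_frames: list[np.ndarray] = []
    for c in range(n_cells):
        fires = np.where(rng.random(n_frames) < rate_per_frame)[0]
        # enforce a minimum separation (two somatic events this close merge)
        keep = []
        last = -min_sep - 1
        for f in fires:
            if f - last >= min_sep:
                keep.append(f)
                last = f
        events = np.asarray(keep, dtype=int)
        trace = np.full(n_frames, baseline_F)
        for e in events:
            stop = min(e + kernel.size, n_frames)
            trace[e:stop] += kernel[:stop - e]
        event_frames.append(events)
        phase = rng.uniform(0, 2 * np.pi)
        drift = drift_amp_F * np.sin(
            2 * np.pi * np.arange(n_frames) / (drift_period_s * frame_rate) + phase)
        F[c] = trace + drift + rng.normal(0.0, noise_sd, n_frames)

    discharge_frames = np.array([], dtype=int)
    if discharge_times_s is not None and len(discharge_times_s):
        discharge_frames = np.round(np.asarray(discharge_times_s) * frame_rate
                                    ).astype(int)
        dk = discharge_amp_dff * baseline_F * np.exp(
            -np.arange(int(6 * discharge_decay_s * frame_rate))
            / (discharge_decay_s * frame_rate))
        for d in discharge_frames:
            stop = min(d + dk.size, n_frames)
            F[:, d:stop] += dk[:stop - d]

    roi = RoiFluorescence(F=F, frame_rate=frame_rate)
    truth = {"event_frames": event_frames,
             "discharge_frames": discharge_frames,
             "noise_sd_F": noise_sd, "transient_amp_F": transient_amp_F,
             "rate_rest_per_min": rate_rest_per_min}
    return roi, speed, truth


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _colored_noise(n: int, alpha: float, sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha Gaussian noise of length n, scaled to the given SD."""
    white = rng.normal(0.0, 1.0, n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-alpha / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x / x.std() * sd


def _eeg_spike_template(rate_hz: float, amplitude_uV: float,
                        width_ms: float) -> np.ndarray:
    """Biphasic (one-cycle sine) epileptiform spike template."""
    n = max(4, int(round(width_ms * rate_hz / 1000.0)))
    t = np.arange(n) / n
    return amplitude_uV * np.sin(2 * np.pi * t)


def gen_eeg(seed: int = 0, *,
            duration_s: float = 3600.0,
            rate_hz: float = 500.0,
            background_sd_uV: float = 30.0,
            one_over_f_alpha: float = 1.0,
            spike_amplitude_uV: float = 400.0,
            spike_width_ms: float = 80.0,
            train_schedule: list[dict] | None = None,
            myoclonic_times_s: list[float] | None = None,
            myoclonic_amplitude_uV: float = 500.0,
            fatal_scenario: bool = False,
            fatal_train_start_s: float | None = None,
            suppression_factor: float = 0.05,
            suppression_duration_s: float = 60.0,
            rng: np.random.Generator | None = None):
    """Colored-noise EEG with inserted spikes, trains and behavior annotations.

    ``train_schedule`` is a list of dicts with keys ``start_s``, ``n_spikes``
    (default 10), ``isi_s`` (default 0.4) and ``behavior`` (None for an
    interictal run of spikes, or ``"convulsive"`` / ``"loss_of_balance"``
    for a seizure).  ``myoclonic_times_s`` insert single large spikes with
    matching ``spasm`` annotations.  With ``fatal_scenario`` a convulsive
    train with hindlimb extension is inserted at ``fatal_train_start_s`` and
    the background collapses by ``suppression_factor`` afterwards.

    Returns ``(record, truth)``; the annotation track is attached to the
    record and truth lists every inserted event with its intended label.
    """
    if spike_amplitude_uV <= 0:
        raise ValueError("spike amplitude must be > 0")
    rng = rng or np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    signal = _colored_noise(n, one_over_f_alpha, background_sd_uV, rng)
    template = _eeg_spike_template(rate_hz, spike_amplitude_uV, spike_width_ms)
    annotations: list[tuple[float, float, str]] = []
    truth_events: list[dict] = []

    def insert_spike(t_s: float, amp_scale: float = 1.0) -> None:
        i = int(round(t_s * rate_hz))
        stop = min(i + template.size, n)
        signal[i:stop] += amp_scale * template[:stop - i]

    train_schedule = list(train_schedule or [])
    if fatal_scenario:
        start = fatal_train_start_s
        if start is None:
            start = duration_s * 0.5
        train_schedule.append({"start_s": start, "n_spikes": 12, "isi_s": 0.35,
                               "behavior": "convulsive", "fatal": True})

    for sched in train_schedule:
        start = float(sched["start_s"])
        n_spikes = int(sched.get("n_spikes", 10))
        isi = float(sched.get("isi_s", 0.4))
        behavior = sched.get("behavior")
        times = start + np.arange(n_spikes) * isi
        for t in times:
            insert_spike(t)
        span = (float(times[0]), float(times[-1]) + spike_width_ms / 1000.0)
        label = "run_of_spikes"
        if behavior:
            annotations.append((span[0] - 0.5, span[1] + 0.5, behavior))
            label = "seizure"
        if sched.get("fatal"):
            annotations.append((span[1] - 1.0, span[1] + 2.0,
                                "hindlimb_extension"))
            lo = int(round((span[1] + 0.5) * rate_hz))
            hi = min(n, int(round((span[1] + 0.5 + suppression_duration_s)
                                  * rate_hz)))
            signal[lo:hi] *= suppression_factor
            label = "fatal_seizure"
        truth_events.append({"label": label, "onset_s": span[0],
                             "offset_s": span[1],
                             "spike_times_s": times.tolist()})

    for t in (myoclonic_times_s or []):
        insert_spike(t, amp_scale=myoclonic_amplitude_uV / spike_amplitude_uV)
        annotations.append((t - 0.2, t + 0.5, "spasm"))
        truth_events.append({"label": "myoclonic", "onset_s": t,
                             "offset_s": t + spike_width_ms / 1000.0,
                             "spike_times_s": [t]})

    record = EEGRecord(signal=signal, sampling_rate=rate_hz,
                       behavior_annotations=sorted(annotations),
                       metadata={"kind": "synthetic_eeg"})
    truth = {"events": truth_events,
             "background_sd_uV": background_sd_uV,
             "spike_amplitude_uV": spike_amplitude_uV,
             "spike_width_ms": spike_width_ms}
    return record, truth
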