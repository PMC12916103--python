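"""Current-clamp analysis: spike detection, AP waveform features, passive
properties, F-I curves, and cell-level quality control.

The feature definitions follow standard fast-spiking interneuron practice:

* A spike is a local maximum reaching at least -10 mV that is preceded
  (within 2 ms) by a dV/dt upstroke exceeding 20 mV/ms; peaks closer than a
  1 ms refractory period are merged.  The -10 mV peak floor is the counting
  rule; the upstroke gate rejects stimulus artifacts and is configurable.
* Threshold is the membrane potential at which dV/dt first exceeds 5% of the
  maximal upstroke velocity of that spike, scanning forward toward the peak.
* Amplitude is peak minus threshold; APD50 is the time spent above the
  half-amplitude level (threshold + amplitude/2) with linearly interpolated
  crossings; AHP is the absolute post-spike minimum within a 10 ms window.
* Rheobase is reported as the largest current step that evoked no spikes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .io import StepProtocol, SweepSet


@dataclass
class APFeatureSet:
    """Waveform features of a single action potential."""

    threshold_mV: float
    peak_mV: float
    amplitude_mV: float
    upstroke_mV_per_ms: float
    downstroke_mV_per_ms: float
    apd50_ms: float
    ahp_mV: float
    spike_time_s: float

    def __post_init__(self) -> None:
        if self.amplitude_mV < 0:
            raise ValueError("amplitude must be >= 0")
        if not (self.upstroke_mV_per_ms > 0 >= self.downstroke_mV_per_ms):
            raise ValueError("upstroke must be > 0 and downstroke <= 0")
        if self.apd50_ms <= 0:
            raise ValueError("APD50 must be > 0")


@dataclass
class FICurve:
    """Spike counts per current step (1 s injections by default)."""

    current_steps_pA: np.ndarray
    spike_counts: np.ndarray
    step_duration_s: float = 1.0

    def __post_init__(self) -> None:
        self.current_steps_pA = np.asarray(self.current_steps_pA, dtype=float)
        self.spike_counts = np.asarray(self.spike_counts, dtype=int)
        if np.any(np.diff(self.current_steps_pA) <= 0):
            raise ValueError("current steps must be strictly increasing")
        if np.any(self.spike_counts < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def frequency_Hz(self) -> np.ndarray:
        return self.spike_counts / self.step_duration_s


@dataclass
class PassiveProps:
    resting_vm_mV: float
    input_resistance_MOhm: float
    rheobase_pA: float


@dataclass
class QCResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)


def compute_dvdt(voltage_mV: np.ndarray, rate_hz: float) -> np.ndarray:
    """First derivative of the voltage trace in mV/ms.

    Central differences on the raw trace (one-sided at the ends), no
    pre-smoothing; returns an array of the same length.
    """
    v = np.asarray(voltage_mV, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 samples for a derivative")
    dt_ms = 1000.0 / rate_hz
    return np.gradient(v, dt_ms)


def detect_spikes(voltage_mV: np.ndarray, rate_hz: float, *,
                  peak_floor_mV: float = -10.0,
                  min_upstroke_mV_per_ms: float = 20.0,
                  upstroke_window_ms: float = 2.0,
                  refractory_ms: float = 1.0) -> np.ndarray:
    """Indices of action-potential peaks in a voltage trace.

    A peak counts as a spike when it reaches ``peak_floor_mV`` (APs are
    counted only if the peak is at least -10 mV) and the preceding
    ``upstroke_window_ms`` contains a dV/dt exceeding
    ``min_upstroke_mV_per_ms``.  Peaks within ``refractory_ms`` of a kept
    spike are merged (the larger peak wins).  Returns sorted indices; an
    empty result is valid.
    """
    v = np.asarray(voltage_mV, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage trace contains non-finite values")
    if rate_hz <= 0:
        raise ValueError("rate must be > 0")
    if v.size < 3:
        return np.array([], dtype=int)
    refractory = max(1, int(round(refractory_ms * rate_hz / 1000.0)))
    peaks, _ = find_peaks(v, height=peak_floor_mV, distance=refractory)
    if peaks.size == 0:
        return peaks
    if min_upstroke_mV_per_ms > 0:
        dvdt = compute_dvdt(v, rate_hz)
        win = max(1, int(round(upstroke_window_ms * rate_hz / 1000.0)))
        keep = [p for p in peaks
                if np.max(dvdt[max(0, p - win):p + 1]) > min_upstroke_mV_per_ms]
        peaks = np.asarray(keep, dtype=int)
    return peaks


def ap_threshold(voltage_window_mV: np.ndarray, dvdt_window: np.ndarray,
                 peak_index: int | None = None,
                 fraction_of_upstroke: float = 0.05) -> tuple[float, int]:
    """Threshold potential of one spike: Vm where dV/dt first exceeds 5% of
    the upstroke velocity.

    Scans forward from the window start toward the peak; returns
    ``(threshold_mV, index)``.  The upstroke velocity is the max dV/dt up to
    and including the peak.
    """
    v = np.asarray(voltage_window_mV, dtype=float)
    dvdt = np.asarray(dvdt_window, dtype=float)
    if peak_index is None:
        peak_index = int(np.argmax(v))
    upstroke = float(np.max(dvdt[:peak_index + 1]))
    if upstroke <= 0:
        raise ValueError("no threshold: window has no positive upstroke")
    crossing = np.nonzero(dvdt[:peak_index + 1] > fraction_of_upstroke * upstroke)[0]
    if crossing.size == 0:
        raise ValueError("no threshold: criterion never met")
    idx = int(crossing[0])
    return float(v[idx]), idx


def _interp_crossing_time(t0: float, t1: float, v0: float, v1: float,
                          level: float) -> float:
    """Linear-interpolation crossing time of `level` between two samples."""
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_features(voltage_window_mV: np.ndarray, rate_hz: float, *,
                peak_index: int | None = None,
                window_start_time_s: float = 0.0,
                ahp_window_ms: float = 10.0) -> APFeatureSet:
    """Full waveform feature set for the spike in ``voltage_window_mV``.

    The window must bracket exactly one spike peak with at least ~5 ms after
    it.  APD50 is the time above the half-amplitude level (threshold +
    amplitude/2), with the two crossings linearly interpolated; upstroke and
    downstroke are the extrema of dV/dt over the window; AHP is the absolute
    minimum of Vm within ``ahp_window_ms`` after the peak.
    """
    v = np.asarray(voltage_window_mV, dtype=float)
    dvdt = compute_dvdt(v, rate_hz)
    if peak_index is None:
        peak_index = int(np.argmax(v))
    dt_ms = 1000.0 / rate_hz
    threshold, thr_idx = ap_threshold(v, dvdt, peak_index)
    peak = float(v[peak_index])
    amplitude = peak - threshold
    half_level = threshold + amplitude / 2.0

    # rising crossing of the half level: last sub-level sample before peak
    t = np.arange(v.size) * dt_ms
    below_rise = np.nonzero(v[:peak_index] < half_level)[0]
    if below_rise.size == 0:
        raise ValueError("cannot locate rising half-amplitude crossing")
    i = int(below_rise[-1])
    t_rise = _interp_crossing_time(t[i], t[i + 1], v[i], v[i + 1], half_level)
    # falling crossing: first sub-level sample after peak
    below_fall = np.nonzero(v[peak_index:] < half_level)[0]
    if below_fall.size == 0:
        raise ValueError("spike never repolarizes below half amplitude in window")
    j = peak_index + int(below_fall[0])
    t_fall = _interp_crossing_time(t[j - 1], t[j], v[j - 1], v[j], half_level)
    apd50 = t_fall - t_rise

    ahp_stop = min(v.size, peak_index + 1 + int(round(ahp_window_ms / dt_ms)))
    ahp = float(np.min(v[peak_index:ahp_stop]))

    # downstroke restricted to the repolarization (peak -> AHP minimum)
    downstroke = float(np.min(dvdt[peak_index:ahp_stop]))
    upstroke = float(np.max(dvdt[:peak_index + 1]))

    return APFeatureSet(
        threshold_mV=threshold,
        peak_mV=peak,
        amplitude_mV=amplitude,
        upstroke_mV_per_ms=upstroke,
        downstroke_mV_per_ms=downstroke,
        apd50_ms=float(apd50),
        ahp_mV=ahp,
        spike_time_s=window_start_time_s + peak_index / rate_hz,
    )


def extract_first_ap_features(sweep_mV: np.ndarray, rate_hz: float, *,
                              pre_ms: float = 5.0,
                              post_ms: float = 10.0) -> APFeatureSet:
    """Features of the first AP in a sweep (ramp-evoked by convention)."""
    peaks = detect_spikes(sweep_mV, rate_hz)
    if peaks.size == 0:
        raise ValueError("no spikes in sweep")
    p = int(peaks[0])
    pre = int(round(pre_ms * rate_hz / 1000.0))
    post = int(round(post_ms * rate_hz / 1000.0))
    start = max(0, p - pre)
    window = np.asarray(sweep_mV[start:p + post + 1], dtype=float)
    return ap_features(window, rate_hz, peak_index=p - start,
                       window_start_time_s=start / rate_hz)


def resting_vm(gap_free_trace_mV: np.ndarray) -> float:
    """Resting membrane potential: the median of a gap-free recording.

    The median is robust to the small fraction of samples occupied by spikes.
    """
    v = np.asarray(gap_free_trace_mV, dtype=float)
    if v.size == 0:
        raise ValueError("empty trace")
    return float(np.median(v))


def input_resistance(sweep_mV: np.ndarray, rate_hz: float,
                     protocol: StepProtocol, *,
                     step_pA: float = -20.0,
                     steady_fraction: float = 0.2) -> float:
    """Input resistance (MOhm) from the voltage response to a -20 pA step.

    R = dV_ss / I with dV_ss = mean Vm over the last ``steady_fraction`` of
    the step minus the mean over the pre-step baseline.  mV / pA = GOhm, so
    the result is scaled to MOhm.  Positive for a hyperpolarizing response to
    a negative step.
    """
    amps = np.asarray(protocol.amplitudes, dtype=float)
    matches = np.nonzero(np.isclose(amps, step_pA))[0]
    if matches.size == 0:
        raise ValueError(f"protocol has no {step_pA} pA step")
    i0, i1 = protocol.window(rate_hz)
    v = np.asarray(sweep_mV, dtype=float)
    baseline = float(np.mean(v[:i0])) if i0 > 0 else float(v[0])
    ss_start = i1 - max(1, int(round(steady_fraction * (i1 - i0))))
    delta_v = float(np.mean(v[ss_start:i1])) - baseline
    return delta_v / step_pA * 1000.0  # mV/pA = GOhm -> MOhm


def rheobase(fi: FICurve) -> tuple[float, dict]:
    """Rheobase approximated as the largest current step that evoked no APs.

    Returns ``(rheobase_pA, info)`` where info carries the first spiking step
    and a ``non_monotonic`` flag (the literal rule is applied even when a
    silent step sits above a spiking one, with a warning).  Raises on
    all-spiking or all-silent curves, which are flagged distinctly.
    """
    counts = fi.spike_counts
    steps = fi.current_steps_pA
    silent = np.nonzero(counts == 0)[0]
    spiking = np.nonzero(counts > 0)[0]
    if silent.size == 0:
        raise ValueError("all steps spiking: rheobase below tested range")
    if spiking.size == 0:
        raise ValueError("all steps silent: rheobase above tested range")
    rheo = float(steps[silent[-1]])
    first_spiking = float(steps[spiking[0]])
    non_monotonic = bool(silent[-1] > spiking[0])
    if non_monotonic:
        warnings.warn("non-monotonic F-I counts: literal rheobase rule applied",
                      stacklevel=2)
    return rheo, {"first_spiking_step_pA": first_spiking,
                  "non_monotonic": non_monotonic}


def fi_curve(sweepset: SweepSet) -> FICurve:
    """Spike counts per current step, restricted to the step interval."""
    if sweepset.unit != "mV":
        raise ValueError("F-I analysis needs membrane potential sweeps (mV)")
    protocol = sweepset.protocol
    if not isinstance(protocol, StepProtocol):
        raise ValueError("F-I analysis needs a step protocol")
    i0, i1 = protocol.window(sweepset.sampling_rate)
    order = np.argsort(protocol.amplitudes)
    counts = []
    for k in order:
        peaks = detect_spikes(sweepset.sweeps[k], sweepset.sampling_rate)
        counts.append(int(np.sum((peaks >= i0) & (peaks < i1))))
    return FICurve(current_steps_pA=protocol.amplitudes[order],
                   spike_counts=np.asarray(counts),
                   step_duration_s=protocol.duration_s)


def qc_cell(resting_vm_mV: float, access_resistance_MOhm: np.ndarray, *,
            vm_ceiling_mV: float = -50.0,
            max_access_change: float = 0.20) -> QCResult:
    """Cell-level QC: fail on depolarized Vm (> -50 mV) or >20% access drift.

    ``access_resistance_MOhm`` needs at least a start and an end value; drift
    is measured as max |Ra(t) - Ra(0)| / Ra(0) over the series.
    """
    ra = np.asarray(access_resistance_MOhm, dtype=float)
    if ra.size < 2:
        raise ValueError("need at least start and end access resistance")
    reasons = []
    if resting_vm_mV > vm_ceiling_mV:
        reasons.append(f"depolarized: Vm {resting_vm_mV:.1f} mV > {vm_ceiling_mV:.0f} mV")
    drift = float(np.max(np.abs(ra - ra[0])) / ra[0])
    if drift > max_access_change:
        reasons.append(f"access drift {drift:.0%} > {max_access_change:.0%}")
    return QCResult(passed=not reasons, reasons=reasons)
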