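"""Paired-recording synaptic analysis.

Given simultaneous presynaptic voltage and postsynaptic current sweeps, this
module measures unitary postsynaptic currents (uPSCs) evoked by each
presynaptic action potential: amplitude, failure labeling, onset and peak
latency, frequency-resolved failure rates and amplitude profiles,
paired-pulse ratios, and connection-probability statistics.

Conventions
-----------
* A uPSC counts as detected only when its amplitude exceeds 10 pA; otherwise
  the pulse is a failure and contributes 0 pA to amplitude averages (the
  efficacy convention; a switch excludes failures instead).
* The search window for each AP runs from its peak to the next AP or 50 ms,
  whichever comes first; amplitude is measured against a local pre-pulse
  baseline.
* Onset is the first excursion beyond 2x the pre-pulse baseline SD in the
  declared polarity direction sustained for 0.5 ms.
* With a depolarized chloride reversal (~-17 mV) and a -70 mV holding
  potential, IPSCs are inward; polarity is declared per sweep, never guessed.
* Paired-pulse ratios are ratios of mean amplitudes (mean_i / mean_1), which
  stay defined when some first pulses fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.stats import fisher_exact

from . import ephys


@dataclass
class PairedSweep:
    """One presynaptic-voltage / postsynaptic-current sweep of a pulse train."""

    pre_voltage_mV: np.ndarray
    post_current_pA: np.ndarray
    rate_hz: float
    train_frequency_hz: float
    n_pulses: int = 10
    polarity: str = "inward"  # direction of the PSC on the current trace
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pre_voltage_mV = np.asarray(self.pre_voltage_mV, dtype=float)
        self.post_current_pA = np.asarray(self.post_current_pA, dtype=float)
        if self.pre_voltage_mV.shape != self.post_current_pA.shape:
            raise ValueError("pre and post traces must share length")
        if self.polarity not in {"inward", "outward"}:
            raise ValueError("polarity must be 'inward' or 'outward'")


def measure_upsc(sweep: PairedSweep, *,
                 detection_floor_pA: float = 10.0,
                 max_window_ms: float = 50.0,
                 baseline_ms: float = 2.0,
                 onset_sd_mult: float = 2.0,
                 onset_sustain_ms: float = 0.5,
                 peak_average_ms: float = 0.75) -> pd.DataFrame:
    """Per-AP unitary PSC measurements for one sweep.

    Returns a DataFrame with one row per presynaptic AP: ``pulse``,
    ``ap_peak_time_s``, ``amplitude_pA`` (0 for failures), ``raw_amplitude_pA``,
    ``onset_latency_ms``, ``peak_latency_ms``, ``is_failure``.  Events whose
    amplitude does not exceed ``detection_floor_pA`` are failures (an exactly
    10.0 pA excursion is a failure under the strict "exceeded" rule).

    Amplitude is the maximum of the deflection after a ``peak_average_ms``
    boxcar average: a raw single-sample extremum over a long window carries
    an upward max-statistic noise bias that the short average suppresses.
    """
    ap_peaks = ephys.detect_spikes(sweep.pre_voltage_mV, sweep.rate_hz)
    if ap_peaks.size == 0:
        raise ValueError("no presynaptic APs detected")
    rate = sweep.rate_hz
    sign = -1.0 if sweep.polarity == "inward" else 1.0
    post = sweep.post_current_pA
    max_win = int(round(max_window_ms * rate / 1000.0))
    n_base = max(1, int(round(baseline_ms * rate / 1000.0)))
    sustain = max(1, int(round(onset_sustain_ms * rate / 1000.0)))

    rows = []
    for i, p in enumerate(ap_peaks):
        stop = ap_peaks[i + 1] if i + 1 < ap_peaks.size else post.size
        stop = min(stop, p + max_win, post.size)
        seg = post[p:stop]
        if seg.size < 2:
            continue
        base_seg = post[max(0, p - n_base):p]
        baseline = float(np.mean(base_seg)) if base_seg.size else 0.0
        base_sd = float(np.std(base_seg)) if base_seg.size > 1 else 0.0
        # signed deflection in the declared polarity direction
        deflection = sign * (seg - baseline)
        n_avg = max(1, int(round(peak_average_ms * rate / 1000.0)))
        smoothed = uniform_filter1d(deflection, n_avg, mode="nearest")
        peak_idx = int(np.argmax(smoothed))
        amplitude = float(smoothed[peak_idx])
        is_failure = not (amplitude > detection_floor_pA)

        onset_ms = np.nan
        peak_ms = peak_idx / rate * 1000.0
        if not is_failure and base_sd > 0:
            above = deflection > onset_sd_mult * base_sd
            # first crossing sustained for `sustain` samples
            onset_idx = None
            run = 0
            for j, a in enumerate(above[:peak_idx + 1]):
                run = run + 1 if a else 0
                if run >= sustain:
                    onset_idx = j - sustain + 1
                    break
            if onset_idx is not None:
                onset_ms = onset_idx / rate * 1000.0
        rows.append({
            "pulse": i + 1,
            "ap_peak_time_s": p / rate,
            "amplitude_pA": 0.0 if is_failure else amplitude,
            "raw_amplitude_pA": amplitude,
            "onset_latency_ms": onset_ms,
            "peak_latency_ms": peak_ms,
            "is_failure": is_failure,
            "frequency_hz": sweep.train_frequency_hz,
        })
    return pd.DataFrame(rows)


def _pool(tables: list[pd.DataFrame]) -> pd.DataFrame:
    if not tables:
        raise ValueError("no event tables provided")
    return pd.concat(tables, ignore_index=True)


def failure_rate_by_frequency(tables: list[pd.DataFrame],
                              first_n: int = 5) -> pd.Series:
    """Fraction of failures among pulses 1..first_n, pooled per frequency."""
    df = _pool(tables)
    df = df[df["pulse"] <= first_n]
    return df.groupby("frequency_hz")["is_failure"].mean()


def amplitude_profile(tables: list[pd.DataFrame], first_n: int = 5, *,
                      include_failures_as_zero: bool = True) -> pd.DataFrame:
    """Mean uPSC amplitude per pulse index (1..first_n) per frequency.

    Failures contribute 0 pA by default; set
    ``include_failures_as_zero=False`` to average successes only (potency).
    """
    df = _pool(tables)
    df = df[df["pulse"] <= first_n].copy()
    if not include_failures_as_zero:
        df = df[~df["is_failure"]]
    return (df.groupby(["frequency_hz", "pulse"])["amplitude_pA"].mean()
            .unstack("pulse"))


def paired_pulse_ratios(tables: list[pd.DataFrame], *,
                        include_failures_as_zero: bool = True) -> pd.DataFrame:
    """PPR_2/1 and PPR_last/1 per frequency, as ratios of mean amplitudes."""
    df = _pool(tables)
    if not include_failures_as_zero:
        df = df[~df["is_failure"]]
    out = {}
    for freq, grp in df.groupby("frequency_hz"):
        means = grp.groupby("pulse")["amplitude_pA"].mean()
        if means.get(1, 0.0) <= 0:
            raise ZeroDivisionError(
                f"mean first-pulse amplitude is zero at {freq} Hz")
        last = means.index.max()
        out[freq] = {"ppr_2_1": means.get(2, np.nan) / means[1],
                     "ppr_last_1": means[last] / means[1]}
    return pd.DataFrame(out).T.rename_axis("frequency_hz")


def synaptic_latency(tables: list[pd.DataFrame],
                     which: str = "onset") -> float:
    """Mean latency (ms) from presynaptic AP peak over non-failure events.

    ``which`` selects the endpoint: ``"onset"`` (AP peak to uPSC onset, the
    headline definition) or ``"peak"`` (AP peak to uPSC peak).  Events with
    acausal (negative) latencies are excluded with a warning.
    """
    col = {"onset": "onset_latency_ms", "peak": "peak_latency_ms"}[which]
    df = _pool(tables)
    lat = df.loc[~df["is_failure"], col].dropna()
    if lat.empty:
        raise ValueError("all events are failures: latency undefined")
    acausal = lat <= 0
    if acausal.any():
        import warnings
        warnings.warn(f"excluding {int(acausal.sum())} acausal event(s)",
                      stacklevel=2)
        lat = lat[~acausal]
    return float(lat.mean())


@dataclass
class ConnectionSummary:
    """Connection probability of one group and an exact-test comparison."""

    n_connected: int
    n_tested: int
    n_connected_other: int | None = None
    n_tested_other: int | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_connected <= self.n_tested:
            raise ValueError("need 0 <= n_connected <= n_tested")

    @property
    def probability(self) -> float:
        return self.n_connected / self.n_tested

    @property
    def percent(self) -> float:
        return 100.0 * self.probability


def connection_stats(n_connected_a: int, n_a: int,
                     n_connected_b: int | None = None,
                     n_b: int | None = None) -> ConnectionSummary:
    """Connection probability, optionally with a two-sided Fisher exact test.

    The test compares connected/unconnected counts between two groups of
    tested pairs via the hypergeometric distribution (Fisher's exact test,
    two-sided).
    """
    summary = ConnectionSummary(n_connected=n_connected_a, n_tested=n_a)
    if n_connected_b is not None and n_b is not None:
        if not 0 <= n_connected_b <= n_b:
            raise ValueError("need 0 <= n_connected_b <= n_b")
        table = [[n_connected_a, n_a - n_connected_a],
                 [n_connected_b, n_b - n_connected_b]]
        _, p = fisher_exact(table, alternative="two-sided")
        summary.n_connected_other = n_connected_b
        summary.n_tested_other = n_b
        summary.p_value = float(p)
    return summary
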