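"""EEG preprocessing, epileptiform spike and spike-train detection, and
rule-based event classification for chronic rodent video-EEG.

Pipeline
--------
1. Preprocess: zero-phase 60 Hz notch (powerline, Q = 30) then zero-phase
   1 Hz high-pass (2nd-order Butterworth).
2. Spike detection: a sample qualifies when its absolute deviation from the
   filtered zero line exceeds BOTH the 200 uV floor and the root-mean-square
   of the preceding minute (expanding window during the first minute, where
   detections are flagged); peaks closer than 50 ms are merged into one
   spike complex, and width is measured at half amplitude.
3. Train detection: greedy left-to-right chaining of consecutive spikes with
   inter-spike intervals in [0.05, 0.6] s; a chain qualifies as a spike
   train when it has at least 5 spikes and spans at least 3 s.
4. Classification against a behavior-annotation track (video review):
   train + convulsive/loss-of-balance overlap -> seizure; train without
   behavioral correlate -> run_of_spikes; isolated spike narrower than
   200 ms + spasm annotation -> myoclonic; seizure + hindlimb extension +
   post-event EEG suppression (RMS < 25% of pre-event for >= 30 s) ->
   fatal_seizure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks, iirnotch, sosfiltfilt

from .io import EEGRecord

BEHAVIOR_LABELS = {"convulsive", "loss_of_balance", "spasm", "hindlimb_extension"}
SEIZURE_BEHAVIORS = {"convulsive", "loss_of_balance"}


@dataclass
class SpikeEvent:
    """One epileptiform spike on the filtered trace."""

    time_s: float
    amplitude_uV: float
    width_ms: float
    in_rms_warmup: bool = False

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width must be > 0")


@dataclass
class SpikeTrain:
    """A qualifying run of chained epileptiform spikes."""

    spike_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.n_spikes < 5:
            raise ValueError("a spike train needs at least 5 spikes")
        if self.duration_s < 3.0:
            raise ValueError("a spike train must span at least 3 s")

    @property
    def n_spikes(self) -> int:
        return self.spike_times_s.size

    @property
    def onset_s(self) -> float:
        return float(self.spike_times_s[0])

    @property
    def duration_s(self) -> float:
        return float(self.spike_times_s[-1] - self.spike_times_s[0])

    @property
    def mean_isi_s(self) -> float:
        return float(np.mean(np.diff(self.spike_times_s)))


@dataclass
class ClassifiedEvent:
    """A detected event with its rule-based label and evidence trail."""

    onset_s: float
    duration_s: float
    label: str  # run_of_spikes | seizure | myoclonic | fatal_seizure
    evidence: dict = field(default_factory=dict)


def preprocess(record: EEGRecord, *, notch_hz: float = 60.0,
               notch_q: float = 30.0, highpass_hz: float = 1.0) -> np.ndarray:
    """Zero-phase 60 Hz notch then zero-phase 1 Hz high-pass."""
    fs = record.sampling_rate
    if fs < 2 * notch_hz:
        raise ValueError(f"sampling rate {fs} Hz below Nyquist for "
                         f"{notch_hz} Hz notch")
    b, a = iirnotch(notch_hz, notch_q, fs=fs)
    x = filtfilt(b, a, record.signal)
    sos = butter(2, highpass_hz, btype="highpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def rolling_rms(trace: np.ndarray, sampling_rate: float,
                window_s: float = 60.0) -> np.ndarray:
    """Causal RMS over the preceding ``window_s`` seconds, same length.

    Uses an expanding window before t = window_s (the preceding-minute RMS is
    undefined until a minute has elapsed).
    """
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    w = max(1, int(round(window_s * sampling_rate)))
    csum = np.concatenate([[0.0], np.cumsum(x * x)])
    idx = np.arange(1, x.size + 1)
    start = np.maximum(0, idx - w)
    counts = idx - start
    return np.sqrt((csum[idx] - csum[start]) / counts)


def detect_spikes_eeg(filtered: np.ndarray, rms: np.ndarray,
                      sampling_rate: float, *,
                      amplitude_floor_uV: float = 200.0,
                      refractory_ms: float = 50.0,
                      rms_window_s: float = 60.0) -> list[SpikeEvent]:
    """Epileptiform spikes: |signal| above both the 200 uV floor and the
    causal RMS of the preceding minute.

    Candidate peaks of |signal| are merged within a 50 ms refractory window
    (the largest wins) and the width is measured at half the peak amplitude.
    Events inside the RMS warm-up (first ``rms_window_s``) carry
    ``in_rms_warmup=True``.
    """
    x = np.asarray(filtered, dtype=float)
    absx = np.abs(x)
    distance = max(1, int(round(refractory_ms * sampling_rate / 1000.0)))
    peaks, _ = find_peaks(absx, height=amplitude_floor_uV, distance=distance)
    peaks = peaks[absx[peaks] > rms[peaks]]
    events = []
    warmup = rms_window_s
    for p in peaks:
        amp = float(absx[p])
        half = amp / 2.0
        # width at half amplitude: nearest crossings around the peak
        left = p
        while left > 0 and absx[left - 1] >= half:
            left -= 1
        right = p
        while right < absx.size - 1 and absx[right + 1] >= half:
            right += 1
        width_ms = max(right - left, 1) / sampling_rate * 1000.0
        t = p / sampling_rate
        events.append(SpikeEvent(time_s=t, amplitude_uV=amp, width_ms=width_ms,
                                 in_rms_warmup=t < warmup))
    return events


def detect_trains(spikes: list[SpikeEvent] | np.ndarray, *,
                  isi_band_s: tuple[float, float] = (0.05, 0.6),
                  min_spikes: int = 5,
                  min_duration_s: float = 3.0) -> list[SpikeTrain]:
    """Greedy left-to-right grouping of spikes into trains.

    Consecutive spikes are chained while the ISI lies in ``isi_band_s``; an
    ISI above the band breaks the chain.  Spikes closer than the lower band
    edge to their predecessor are part of the same spike complex (the
    refractory merge in spike detection normally removes them) and are
    absorbed rather than breaking the chain.  A chain qualifies when it has
    at least ``min_spikes`` spikes and its first-to-last span is at least
    ``min_duration_s``.
    """
    if len(spikes) == 0:
        return []
    if isinstance(spikes[0], SpikeEvent):
        times = np.array([s.time_s for s in spikes], dtype=float)
    else:
        times = np.asarray(spikes, dtype=float)
    times = np.sort(times)
    lo, hi = isi_band_s
    # absorb same-complex spikes (greedy left-to-right)
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= lo:
            kept.append(t)
    trains: list[SpikeTrain] = []
    chain = [kept[0]]
    for t in kept[1:]:
        if t - chain[-1] <= hi:
            chain.append(t)
        else:
            if len(chain) >= min_spikes and chain[-1] - chain[0] >= min_duration_s:
                trains.append(SpikeTrain(np.array(chain)))
            chain = [t]
    if len(chain) >= min_spikes and chain[-1] - chain[0] >= min_duration_s:
        trains.append(SpikeTrain(np.array(chain)))
    return trains


def _overlapping_labels(annotations, onset: float, offset: float) -> set[str]:
    return {label for a, b, label in annotations if a < offset and b > onset}


def classify_events(trains: list[SpikeTrain], spikes: list[SpikeEvent],
                    annotations: list[tuple[float, float, str]],
                    filtered: np.ndarray | None = None,
                    sampling_rate: float | None = None, *,
                    myoclonic_max_width_ms: float = 200.0,
                    suppression_ratio: float = 0.25,
                    suppression_duration_s: float = 30.0) -> list[ClassifiedEvent]:
    """Classify detected activity into the four event categories.

    * Spike train overlapping a convulsive / loss-of-balance annotation ->
      ``seizure``; without behavioral correlate -> ``run_of_spikes``.
    * Isolated spike (not inside any train) narrower than 200 ms overlapping
      a ``spasm`` annotation -> ``myoclonic``.
    * A seizure whose span overlaps a ``hindlimb_extension`` annotation and is
      followed by EEG suppression (post-event RMS below ``suppression_ratio``
      of the pre-event RMS for at least ``suppression_duration_s``) ->
      ``fatal_seizure``.  Checking suppression requires the filtered trace.

    Every event receives exactly one label; contradictory annotation overlap
    (e.g. spasm and convulsive on the same train) is recorded in the evidence
    trail rather than silently resolved.
    """
    events: list[ClassifiedEvent] = []
    train_spans = [(tr.onset_s, tr.onset_s + tr.duration_s) for tr in trains]

    for tr, (a, b) in zip(trains, train_spans):
        labels = _overlapping_labels(annotations, a, b)
        evidence = {"n_spikes": tr.n_spikes, "behavior": sorted(labels)}
        if labels & SEIZURE_BEHAVIORS:
            label = "seizure"
            if "hindlimb_extension" in labels:
                suppressed = False
                if filtered is not None and sampling_rate is not None:
                    suppressed = _post_event_suppressed(
                        filtered, sampling_rate, a, b,
                        suppression_ratio, suppression_duration_s)
                evidence["post_event_suppression"] = suppressed
                if suppressed:
                    label = "fatal_seizure"
            if "spasm" in labels:
                evidence["contradictory_annotations"] = True
        else:
            label = "run_of_spikes"
        events.append(ClassifiedEvent(onset_s=a, duration_s=b - a,
                                      label=label, evidence=evidence))

    # isolated spikes: not inside any detected train span
    for s in spikes:
        if any(a - 1e-9 <= s.time_s <= b + 1e-9 for a, b in train_spans):
            continue
        if s.width_ms < myoclonic_max_width_ms:
            labels = _overlapping_labels(annotations, s.time_s - 0.5,
                                         s.time_s + 0.5)
            if "spasm" in labels:
                events.append(ClassifiedEvent(
                    onset_s=s.time_s, duration_s=s.width_ms / 1000.0,
                    label="myoclonic",
                    evidence={"amplitude_uV": s.amplitude_uV,
                              "width_ms": s.width_ms,
                              "behavior": sorted(labels)}))
    events.sort(key=lambda e: e.onset_s)
    return events


def _post_event_suppressed(filtered: np.ndarray, fs: float,
                           onset_s: float, offset_s: float,
                           ratio: float, duration_s: float,
                           guard_s: float = 1.0) -> bool:
    """Post-ictal suppression: post-event RMS < ratio * pre-event RMS.

    A ``guard_s`` gap after the event end keeps residual ictal energy at the
    event boundary out of the post-event window.
    """
    pre_lo = max(0, int((onset_s - guard_s - duration_s) * fs))
    pre = filtered[pre_lo:int((onset_s - guard_s) * fs)]
    post_lo = int((offset_s + guard_s) * fs)
    post = filtered[post_lo:post_lo + int(duration_s * fs)]
    if pre.size == 0 or post.size < int(duration_s * fs):
        return False
    pre_rms = np.sqrt(np.mean(pre ** 2))
    post_rms = np.sqrt(np.mean(post ** 2))
    return bool(pre_rms > 0 and post_rms < ratio * pre_rms)


def export_raster(events: list[ClassifiedEvent] | dict[str, list[ClassifiedEvent]]
                  ) -> pd.DataFrame:
    """Raster table for plotting: one row per event, grouped by animal.

    Accepts a flat event list (single animal) or a mapping
    ``animal_id -> events``.  Columns: animal_id, label, onset_s, duration_s.
    """
    if isinstance(events, dict):
        groups = events
    else:
        groups = {"animal_0": events}
    rows = [{"animal_id": animal, "label": e.label,
             "onset_s": e.onset_s, "duration_s": e.duration_s}
            for animal in sorted(groups) for e in groups[animal]]
    return pd.DataFrame(rows, columns=["animal_id", "label", "onset_s",
                                       "duration_s"])
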