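"""Two-photon ROI fluorescence analysis.

dF/F0 with a block-percentile baseline, field-of-view hypersynchronous
discharge detection, per-cell calcium transient detection, locomotion-state
epoching, and per-cell activity metrics with threshold-robustness sweeps.

Baseline definition: F0 for each cell is the 10th percentile of the trace
computed per 1000-frame block, linearly interpolated between block centers
(constant extrapolation outside the first/last center; a shorter tail block
gets its own percentile), and dF/F0 = (F - F0) / F0.

Detection rules:

* Hypersynchronous discharges in the FOV-mean dF/F0: zero-phase 1 Hz
  high-pass (2nd-order Butterworth), z-score the filtered trace, keep peaks
  with z > 5 separated by at least 1 s.
* Per-cell transients: moving-mean smoothing, z-score, peak finding with
  minimum z-score 1, minimum inter-peak distance 200 ms, and minimum
  prominence 0.5 z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt


@dataclass
class DffMatrix:
    """dF/F0 (cells x frames) with the baseline that produced it."""

    dff: np.ndarray
    F0: np.ndarray
    frame_rate: float

    @property
    def fov_mean(self) -> np.ndarray:
        return self.dff.mean(axis=0)


@dataclass
class EpochSet:
    """Disjoint labeled intervals (seconds): quiet rest vs locomotion."""

    rest: list[tuple[float, float]]
    locomotion: list[tuple[float, float]]
    total_duration_s: float

    @property
    def rest_minutes(self) -> float:
        return sum(b - a for a, b in self.rest) / 60.0

    def in_rest(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.rest)


def compute_dff(F: np.ndarray, frame_rate: float, *,
                block_frames: int = 1000,
                percentile: float = 10.0) -> DffMatrix:
    """Block-percentile-baseline dF/F0 for a cells x frames matrix.

    For each cell the 10th percentile is taken per 1000-frame block; the
    baseline trace F0(t) linearly interpolates those per-block values between
    block centers and holds constant beyond the outer centers.  Raises when
    any F0 value is non-positive (add a positive offset to the raw
    fluorescence before calling if the acquisition produced negative values).
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if not np.all(np.isfinite(F)):
        raise ValueError("F contains non-finite values")
    n_cells, n_frames = F.shape
    if n_frames < 1:
        raise ValueError("empty fluorescence matrix")
    edges = list(range(0, n_frames, block_frames)) + [n_frames]
    centers = np.array([(a + b - 1) / 2.0 for a, b in zip(edges[:-1], edges[1:])])
    frames = np.arange(n_frames, dtype=float)
    F0 = np.empty_like(F)
    for c in range(n_cells):
        block_vals = np.array([np.percentile(F[c, a:b], percentile)
                               for a, b in zip(edges[:-1], edges[1:])])
        F0[c] = np.interp(frames, centers, block_vals)
    if np.any(F0 <= 0):
        raise ValueError("baseline F0 <= 0: offset the raw fluorescence to be "
                         "positive before computing dF/F0")
    return DffMatrix(dff=(F - F0) / F0, F0=F0, frame_rate=frame_rate)


def detect_discharges(fov_mean_dff: np.ndarray, frame_rate: float, *,
                      z_threshold: float = 5.0,
                      highpass_hz: float = 1.0,
                      min_separation_s: float = 1.0,
                      edge_guard_s: float = 2.0) -> pd.DataFrame:
    """Hypersynchronous discharges in the FOV-mean dF/F0 trace.

    Returns a DataFrame with ``time_s``, ``z_score`` and ``frame`` per event.
    A constant trace has zero variance and yields no events.  Peaks within
    ``edge_guard_s`` of either end are discarded (zero-phase filter warm-up).
    """
    x = np.asarray(fov_mean_dff, dtype=float)
    sos = butter(2, highpass_hz, btype="highpass", fs=frame_rate, output="sos")
    filtered = sosfiltfilt(sos, x)
    sd = filtered.std()
    if sd == 0:
        return pd.DataFrame(columns=["time_s", "z_score", "frame"])
    z = (filtered - filtered.mean()) / sd
    distance = max(1, int(round(min_separation_s * frame_rate)))
    peaks, props = find_peaks(z, height=z_threshold, distance=distance)
    guard = int(round(edge_guard_s * frame_rate))
    keep = (peaks >= guard) & (peaks < x.size - guard)
    peaks = peaks[keep]
    props = {"peak_heights": props["peak_heights"][keep]}
    return pd.DataFrame({"time_s": peaks / frame_rate,
                         "z_score": props["peak_heights"],
                         "frame": peaks})


def detect_transients(dff_trace: np.ndarray, frame_rate: float, *,
                      min_z: float = 1.0,
                      min_distance_ms: float = 200.0,
                      min_prominence_z: float = 0.5,
                      smooth_window_frames: int = 5,
                      robust_z: bool = False) -> pd.DataFrame:
    """Calcium transients in a single-cell dF/F0 trace.

    The trace is smoothed with a moving mean (default 5 frames, ~167 ms at
    30 Hz), z-scored (mean/SD of the full trace, or median/1.4826*MAD when
    ``robust_z``), and peaks are kept when z >= ``min_z``, inter-peak distance
    >= ``min_distance_ms``, and prominence >= ``min_prominence_z``.  Peak
    times are reported at the unsmoothed local maximum.  Returns columns
    ``peak_time_s``, ``peak_z``, ``peak_dff``, ``prominence_z``, ``frame``.
    """
    x = np.asarray(dff_trace, dtype=float)
    cols = ["peak_time_s", "peak_z", "peak_dff", "prominence_z", "frame"]
    if x.size < 2 * frame_rate:
        raise ValueError("trace shorter than 2 s")
    smoothed = uniform_filter1d(x, size=max(1, smooth_window_frames),
                                mode="nearest")
    if robust_z:
        center = np.median(smoothed)
        scale = 1.4826 * np.median(np.abs(smoothed - center))
    else:
        center, scale = smoothed.mean(), smoothed.std()
    if scale == 0:
        return pd.DataFrame(columns=cols)
    z = (smoothed - center) / scale
    distance = max(1, int(round(min_distance_ms * frame_rate / 1000.0)))
    peaks, props = find_peaks(z, height=min_z, distance=distance,
                              prominence=min_prominence_z)
    half = max(1, smooth_window_frames // 2 + 1)
    raw_peaks = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        raw_peaks.append(lo + int(np.argmax(x[lo:hi])))
    raw_peaks = np.asarray(raw_peaks, dtype=int)
    return pd.DataFrame({
        "peak_time_s": raw_peaks / frame_rate,
        "peak_z": props["peak_heights"],
        "peak_dff": x[raw_peaks] if raw_peaks.size else np.array([]),
        "prominence_z": props["prominences"],
        "frame": raw_peaks,
    })


def detect_transients_matrix(dff: DffMatrix, **kwargs) -> pd.DataFrame:
    """Transients for every cell of a DffMatrix, with a ``cell`` column."""
    tables = []
    for c in range(dff.dff.shape[0]):
        t = detect_transients(dff.dff[c], dff.frame_rate, **kwargs)
        t.insert(0, "cell", c)
        tables.append(t)
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()


def segment_epochs(speed: np.ndarray, frame_rate: float, *,
                   rest_speed_threshold: float = 0.5,
                   min_rest_duration_s: float = 1.0,
                   merge_gap_s: float = 0.2) -> EpochSet:
    """Quiet-rest vs locomotion epochs from a treadmill speed trace (cm/s).

    Rest = |speed| below ``rest_speed_threshold`` sustained at least
    ``min_rest_duration_s``; sub-threshold gaps in locomotion shorter than
    ``merge_gap_s`` are merged into the surrounding locomotion.  Locomotion
    is the complement.
    """
    v = np.abs(np.asarray(speed, dtype=float))
    n = v.size
    total = n / frame_rate
    is_rest = v < rest_speed_threshold

    # contiguous runs of rest
    def runs(mask: np.ndarray) -> list[tuple[int, int]]:
        out = []
        start = None
        for i, m in enumerate(mask):
            if m and start is None:
                start = i
            elif not m and start is not None:
                out.append((start, i))
                start = None
        if start is not None:
            out.append((start, n))
        return out

    min_rest = int(round(min_rest_duration_s * frame_rate))
    max_gap = int(round(merge_gap_s * frame_rate))
    rest_runs = [(a, b) for a, b in runs(is_rest)
                 if (b - a) >= min_rest or (b - a) == n]
    # short sub-threshold blips (< merge_gap) inside locomotion are dropped
    rest_runs = [(a, b) for a, b in rest_runs if (b - a) > max_gap]
    rest = [(a / frame_rate, b / frame_rate) for a, b in rest_runs]
    # locomotion = complement of rest
    loco = []
    prev = 0.0
    for a, b in rest:
        if a > prev:
            loco.append((prev, a))
        prev = b
    if prev < total:
        loco.append((prev, total))
    return EpochSet(rest=rest, locomotion=loco, total_duration_s=total)


def per_cell_metrics(transients: pd.DataFrame, epochs: EpochSet,
                     n_cells: int,
                     cell_labels=None) -> pd.DataFrame:
    """Per-cell activity metrics.

    ``transients_per_min_rest`` = transients whose peak lies within a rest
    epoch divided by total rest minutes (NaN with a ``rate_undefined`` flag
    when there is no rest time); ``mean_peak_z`` / ``mean_peak_dff`` are the
    mean transient peak heights in both unit systems; ``active`` marks cells
    with at least one transient anywhere.
    """
    rest_min = epochs.rest_minutes
    rows = []
    for c in range(n_cells):
        sub = transients[transients["cell"] == c] if "cell" in transients else transients
        n_total = len(sub)
        if rest_min > 0:
            n_rest = int(sum(epochs.in_rest(t) for t in sub["peak_time_s"])) if n_total else 0
            rate = n_rest / rest_min
            undefined = False
        else:
            rate, undefined = np.nan, True
        rows.append({
            "cell": c,
            "label": cell_labels[c] if cell_labels is not None else "unknown",
            "transients_per_min_rest": rate,
            "rate_undefined": undefined,
            "mean_peak_z": float(sub["peak_z"].mean()) if n_total else np.nan,
            "mean_peak_dff": float(sub["peak_dff"].mean()) if n_total else np.nan,
            "n_transients": n_total,
            "active": n_total > 0,
        })
    return pd.DataFrame(rows)


def threshold_robustness_sweep(dff_trace: np.ndarray, frame_rate: float,
                               min_z_grid=(0.5, 1.0, 1.5, 2.0, 3.0),
                               min_prominence_grid=(0.25, 0.5, 1.0),
                               **kwargs) -> pd.DataFrame:
    """Transient counts across a grid of detection thresholds.

    Re-runs :func:`detect_transients` at each (min_z, min_prominence_z)
    setting; counts are monotone non-increasing in each threshold, providing
    a robustness check on the default parameters.
    """
    rows = []
    for mz in min_z_grid:
        for mp in min_prominence_grid:
            n = len(detect_transients(dff_trace, frame_rate, min_z=mz,
                                      min_prominence_z=mp, **kwargs))
            rows.append({"min_z": mz, "min_prominence_z": mp, "n_transients": n})
    return pd.DataFrame(rows)
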