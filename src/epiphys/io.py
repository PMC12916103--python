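"""Readers and writers for sweep sets, ROI fluorescence, EEG records, and event tables.

This module is pure plumbing: it never resamples, rescales, or converts units
implicitly.  Time is represented as (sampling rate, 0-based sample index)
internally; everything written to disk reports seconds from record start.

Internal exchange formats
-------------------------
* Sweep sets: HDF5 (one dataset per sweep, protocol stored as attributes) or
  CSV (one column per sweep) with a YAML sidecar carrying rate/units/protocol.
* Event and feature tables: plain CSV, header row, UTF-8.
* ROI fluorescence: NPY or CSV matrix plus YAML metadata declaring orientation.

ABF (Axon binary) and EDF support are optional: ABF requires ``pyabf`` and EDF
requires ``mne``; both are imported lazily so the CSV/HDF5/NPY path has no
optional dependencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

VALID_UNITS = {"mV", "pA"}

EVENT_COLUMNS = ["onset_s", "duration_s", "amplitude", "label"]


# ---------------------------------------------------------------------------
# Stimulus protocols
# ---------------------------------------------------------------------------

@dataclass
class StepProtocol:
    """Square step per sweep: ``amplitudes[i]`` applied from onset for duration.

    Amplitudes are pA in current clamp and mV in voltage clamp; ``holding`` is
    the pre/post-step level in the same unit.
    """

    amplitudes: np.ndarray
    onset_s: float
    duration_s: float
    holding: float = 0.0
    unit: str = "pA"

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.onset_s < 0:
            raise ValueError("step onset must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("step duration must be > 0")

    def window(self, rate: float) -> tuple[int, int]:
        """(start, stop) sample indices of the step at sampling rate `rate`."""
        i0 = int(round(self.onset_s * rate))
        i1 = int(round((self.onset_s + self.duration_s) * rate))
        return i0, i1


@dataclass
class RampProtocol:
    """Linear current ramp: I(t) = holding + slope * (t - onset) during the ramp."""

    slope_pA_per_s: float
    onset_s: float
    duration_s: float
    holding: float = 0.0
    unit: str = "pA"


@dataclass
class TrainProtocol:
    """Train of brief square pulses driving presynaptic APs."""

    frequency_hz: float
    n_pulses: int
    pulse_width_s: float
    amplitude: float
    onset_s: float
    unit: str = "pA"

    def pulse_times(self) -> np.ndarray:
        return self.onset_s + np.arange(self.n_pulses) / self.frequency_hz


Protocol = StepProtocol | RampProtocol | TrainProtocol


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SweepSet:
    """Ordered set of equal-length sweeps sharing one sampling rate.

    Parameters
    ----------
    sampling_rate : float
        Samples per second; must be positive.
    sweeps : ndarray, shape (n_sweeps, n_samples)
        Membrane potential (mV) or current (pA) depending on ``unit``.
    unit : str
        ``"mV"`` or ``"pA"``; unknown units are rejected.
    protocol : StepProtocol | RampProtocol | TrainProtocol | None
        Stimulus descriptor shared by the sweeps.
    metadata : dict
        Free-form string map (cell id, genotype label, age group, ...).
    """

    sampling_rate: float
    sweeps: np.ndarray
    unit: str
    protocol: Protocol | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown units {self.unit!r}; expected one of {sorted(VALID_UNITS)}")
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def time(self) -> np.ndarray:
        """Seconds from sweep start, one entry per sample."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class RoiFluorescence:
    """Suite2p-style ROI fluorescence: cells x frames, arbitrary units."""

    F: np.ndarray
    frame_rate: float
    cell_labels: Sequence[str] | None = None
    neuropil_or_fov_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        bad = np.where(~np.isfinite(self.F).all(axis=1))[0]
        if bad.size:
            raise ValueError(f"non-finite fluorescence values in ROIs {bad.tolist()}")

    @property
    def n_cells(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class EEGRecord:
    """Single-channel EEG trace in microvolts with optional behavior annotations.

    ``behavior_annotations`` is a list of ``(onset_s, offset_s, label)`` tuples
    produced by video review (labels such as ``convulsive``, ``loss_of_balance``,
    ``spasm``, ``hindlimb_extension``).
    """

    signal: np.ndarray
    sampling_rate: float
    behavior_annotations: list[tuple[float, float, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        self.signal = np.asarray(self.signal, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.sampling_rate


# ---------------------------------------------------------------------------
# Sweep set I/O
# ---------------------------------------------------------------------------

_PROTOCOL_CLASSES = {
    "step": StepProtocol,
    "ramp": RampProtocol,
    "train": TrainProtocol,
}


def _protocol_to_dict(protocol: Protocol | None) -> dict | None:
    if protocol is None:
        return None
    for kind, cls in _PROTOCOL_CLASSES.items():
        if isinstance(protocol, cls):
            d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in vars(protocol).items()}
            d["kind"] = kind
            return d
    raise TypeError(f"unknown protocol type {type(protocol)}")


def _protocol_from_dict(d: dict | None) -> Protocol | None:
    if d is None:
        return None
    d = dict(d)
    cls = _PROTOCOL_CLASSES[d.pop("kind")]
    return cls(**d)


def write_sweepset(sweepset: SweepSet, path: str | Path) -> None:
    """Write a SweepSet to HDF5 (``.h5``/``.hdf5``) or CSV+YAML sidecar."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.attrs["sampling_rate"] = sweepset.sampling_rate
            f.attrs["unit"] = sweepset.unit
            f.attrs["metadata"] = json.dumps(sweepset.metadata)
            proto = _protocol_to_dict(sweepset.protocol)
            f.attrs["protocol"] = json.dumps(proto)
            for i, sweep in enumerate(sweepset.sweeps):
                f.create_dataset(f"sweep_{i:04d}", data=sweep)
    elif path.suffix == ".csv":
        cols = {f"sweep_{i}": sweepset.sweeps[i] for i in range(sweepset.n_sweeps)}
        pd.DataFrame(cols).to_csv(path, index=False)
        sidecar = {
            "sampling_rate": float(sweepset.sampling_rate),
            "unit": sweepset.unit,
            "metadata": sweepset.metadata,
            "protocol": _protocol_to_dict(sweepset.protocol),
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))
    else:
        raise ValueError(f"unsupported sweepset format {path.suffix!r}")


def read_sweepset(path: str | Path, format: str | None = None) -> SweepSet:
    """Read a SweepSet from HDF5, CSV+YAML sidecar, or ABF (requires pyabf).

    The format is inferred from the suffix unless given explicitly as one of
    ``{"hdf5", "csv", "abf"}``.
    """
    path = Path(path)
    fmt = format or {".h5": "hdf5", ".hdf5": "hdf5", ".csv": "csv", ".abf": "abf"}.get(path.suffix)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "sampling_rate" not in f.attrs:
                raise ValueError(f"{path}: missing sampling rate")
            if "unit" not in f.attrs:
                raise ValueError(f"{path}: unknown units (no unit attribute)")
            keys = sorted(k for k in f.keys() if k.startswith("sweep_"))
            sweeps = [f[k][()] for k in keys]
            lengths = {len(s) for s in sweeps}
            if len(lengths) > 1:
                raise ValueError(f"{path}: ragged sweep lengths {sorted(lengths)}")
            return SweepSet(
                sampling_rate=float(f.attrs["sampling_rate"]),
                sweeps=np.asarray(sweeps),
                unit=str(f.attrs["unit"]),
                protocol=_protocol_from_dict(json.loads(f.attrs["protocol"])),
                metadata=json.loads(f.attrs["metadata"]),
            )
    elif fmt == "csv":
        sidecar_path = path.with_suffix(".yaml")
        if not sidecar_path.exists():
            raise ValueError(f"{path}: missing sampling rate (no YAML sidecar)")
        sidecar = yaml.safe_load(sidecar_path.read_text())
        if "sampling_rate" not in sidecar:
            raise ValueError(f"{path}: missing sampling rate in sidecar")
        if "unit" not in sidecar:
            raise ValueError(f"{path}: unknown units (no unit key in sidecar)")
        df = pd.read_csv(path)
        return SweepSet(
            sampling_rate=float(sidecar["sampling_rate"]),
            sweeps=df.to_numpy(dtype=float).T,
            unit=sidecar["unit"],
            protocol=_protocol_from_dict(sidecar.get("protocol")),
            metadata=sidecar.get("metadata", {}),
        )
    elif fmt == "abf":
        try:
            import pyabf  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("ABF support requires the optional 'pyabf' package; "
                              "convert to CSV/HDF5 instead") from exc
        abf = pyabf.ABF(str(path))  # pragma: no cover
        sweeps = []  # pragma: no cover
        for i in abf.sweepList:  # pragma: no cover
            abf.setSweep(i)
            sweeps.append(np.asarray(abf.sweepY, dtype=float))
        unit = "mV" if "mV" in abf.sweepUnitsY else "pA"  # pragma: no cover
        return SweepSet(sampling_rate=float(abf.dataRate), sweeps=np.asarray(sweeps),
                        unit=unit, metadata={"source": str(path)})  # pragma: no cover
    raise ValueError(f"unsupported sweepset format {format or path.suffix!r}")


# ---------------------------------------------------------------------------
# ROI fluorescence I/O
# ---------------------------------------------------------------------------

def write_roi_fluorescence(roi: RoiFluorescence, path: str | Path) -> None:
    """Write F to NPY (rows = cells) plus a YAML metadata file."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), roi.F)
    meta = {
        "frame_rate": float(roi.frame_rate),
        "orientation": "cells_x_frames",
        "cell_labels": list(roi.cell_labels) if roi.cell_labels is not None else None,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))
    if roi.neuropil_or_fov_mean is not None:
        np.save(path.with_name(path.stem + "_fov.npy"), roi.neuropil_or_fov_mean)


def read_roi_fluorescence(path: str | Path) -> RoiFluorescence:
    """Read an F matrix (NPY or CSV) with its YAML metadata.

    Orientation is taken from the metadata's ``orientation`` key
    (``cells_x_frames`` or ``frames_x_cells``), never guessed from shape.
    """
    path = Path(path)
    meta_path = path.with_suffix(".yaml")
    if not meta_path.exists():
        raise ValueError(f"{path}: missing YAML metadata (frame_rate/orientation)")
    meta = yaml.safe_load(meta_path.read_text())
    if "frame_rate" not in meta or "orientation" not in meta:
        raise ValueError(f"{meta_path}: metadata must declare frame_rate and orientation")
    if path.with_suffix(".npy").exists():
        F = np.load(path.with_suffix(".npy"))
    elif path.with_suffix(".csv").exists():
        F = pd.read_csv(path.with_suffix(".csv"), header=None).to_numpy(dtype=float)
    else:
        raise FileNotFoundError(f"no NPY or CSV matrix at {path}")
    if meta["orientation"] == "frames_x_cells":
        F = F.T
    elif meta["orientation"] != "cells_x_frames":
        raise ValueError(f"unknown orientation {meta['orientation']!r}")
    fov_path = path.with_name(path.stem + "_fov.npy")
    fov = np.load(fov_path) if fov_path.exists() else None
    return RoiFluorescence(F=F, frame_rate=float(meta["frame_rate"]),
                           cell_labels=meta.get("cell_labels"),
                           neuropil_or_fov_mean=fov)


# ---------------------------------------------------------------------------
# EEG I/O
# ---------------------------------------------------------------------------

def read_eeg(path: str | Path, format: str | None = None,
             channel: str | None = None) -> EEGRecord:
    """Read an EEG record from EDF (via mne, lazily imported) or CSV+YAML.

    For EDF, ``channel`` selects the channel by name; an absent name is an
    error.  Acquisition-time anti-alias filter settings are passed through as
    metadata only — no attempt is made to recover or undo them.
    """
    path = Path(path)
    fmt = format or {".edf": "edf", ".csv": "csv"}.get(path.suffix)
    if fmt == "edf":
        try:
            import mne  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("EDF support requires the optional 'mne' package") from exc
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        names = raw.ch_names
        if channel is None:
            channel = names[0]
        if channel not in names:
            raise ValueError(f"channel {channel!r} not in EDF (has {names})")
        data = raw.get_data(picks=[channel])[0] * 1e6  # volts -> microvolts
        return EEGRecord(signal=data, sampling_rate=float(raw.info["sfreq"]),
                         metadata={"channel": channel, "source": str(path)})
    elif fmt == "csv":
        sidecar_path = path.with_suffix(".yaml")
        if not sidecar_path.exists():
            raise ValueError(f"{path}: missing sampling rate (no YAML sidecar)")
        meta = yaml.safe_load(sidecar_path.read_text())
        if "sampling_rate" not in meta:
            raise ValueError(f"{path}: missing sampling rate in sidecar")
        df = pd.read_csv(path)
        col = channel or df.columns[0]
        if col not in df.columns:
            raise ValueError(f"channel {col!r} not in CSV (has {list(df.columns)})")
        return EEGRecord(signal=df[col].to_numpy(dtype=float),
                         sampling_rate=float(meta["sampling_rate"]),
                         metadata={k: str(v) for k, v in meta.items()
                                   if k != "sampling_rate"})
    raise ValueError(f"unsupported EEG format {format or path.suffix!r}")


def write_eeg_csv(record: EEGRecord, path: str | Path, channel: str = "eeg") -> None:
    path = Path(path)
    pd.DataFrame({channel: record.signal}).to_csv(path, index=False)
    path.with_suffix(".yaml").write_text(
        yaml.safe_dump({"sampling_rate": float(record.sampling_rate)}))


def read_annotations(path: str | Path) -> list[tuple[float, float, str]]:
    """Read a behavior annotation CSV with columns onset_s, offset_s, label."""
    df = pd.read_csv(path)
    return [(float(r.onset_s), float(r.offset_s), str(r.label))
            for r in df.itertuples()]


def write_annotations(annotations: Sequence[tuple[float, float, str]],
                      path: str | Path) -> None:
    pd.DataFrame(annotations, columns=["onset_s", "offset_s", "label"]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# Event tables and summaries
# ---------------------------------------------------------------------------

def write_event_table(events: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write an event table CSV with the fixed schema columns first.

    An empty event list still produces a header-only CSV with the schema
    columns (onset_s, duration_s, amplitude, label).
    """
    df = pd.DataFrame(events)
    if df.empty:
        df = pd.DataFrame(columns=EVENT_COLUMNS)
    ordered = [c for c in EVENT_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    df[ordered].to_csv(path, index=False)


def read_event_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_summary(summary: dict, path: str | Path) -> None:
    """Write a JSON summary; numpy scalars are converted to plain Python."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(summary, indent=2, default=_default))


def read_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
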