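"""Auxiliary quantifications outside the main time-series chains.

Immunofluorescence membrane/cytosol intensity ratio, interneuron-labeling
validation rates, cell density, Y-maze spontaneous alternation, and the
Barnes-maze latency ingest rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt


@dataclass
class CellMasks:
    """Manually traced soma and nucleus masks with the intensity image.

    The soma mask comes from the cytoplasmic marker channel (e.g.
    parvalbumin), the nucleus mask from DAPI; the nucleus must lie inside
    the soma.  ``pixel_size_um`` converts pixel distances to micrometers.
    """

    soma_mask: np.ndarray
    nucleus_mask: np.ndarray
    intensity: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.soma_mask = np.asarray(self.soma_mask, dtype=bool)
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if np.any(self.nucleus_mask & ~self.soma_mask):
            raise ValueError("nucleus mask must lie inside the soma mask")


def membrane_cytosol_ratio(masks: CellMasks,
                           membrane_width_um: float = 1.0) -> float:
    """Mean membrane intensity over mean cytosol intensity for one cell.

    The membrane compartment is the outermost ``membrane_width_um`` of the
    soma, carved out by thresholding the Euclidean distance transform of the
    soma mask (sub-pixel-faithful, anisotropy-robust); the cytosol is the
    eroded interior minus the nucleus.  Raises when either compartment is
    empty (soma too thin, or nucleus filling the interior).
    """
    dist_um = distance_transform_edt(masks.soma_mask) * masks.pixel_size_um
    interior = dist_um > membrane_width_um
    membrane = masks.soma_mask & ~interior
    cytosol = interior & ~masks.nucleus_mask
    if not membrane.any():
        raise ValueError("empty membrane compartment")
    if not cytosol.any():
        raise ValueError("empty cytosol compartment (erosion leaves nothing "
                         "outside the nucleus)")
    return float(masks.intensity[membrane].mean() /
                 masks.intensity[cytosol].mean())


def pv_density(count: int, area_mm2: float) -> float:
    """Labeled-cell density in cells per mm^2."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if area_mm2 <= 0:
        raise ValueError("area must be > 0")
    return count / area_mm2


def labeling_validation(true_positive: int, false_positive: int,
                        total_reference: int) -> dict[str, float]:
    """Sensitivity and false-positive rate of a genetic labeling strategy.

    ``true_positive``: labeled cells confirmed by the reference stain;
    ``false_positive``: labeled cells not in the reference population;
    ``total_reference``: reference-positive cells available to label.
    Sensitivity = TP / total_reference; false-positive rate =
    FP / (TP + FP).
    """
    if min(true_positive, false_positive, total_reference) < 0:
        raise ValueError("counts must be >= 0")
    if total_reference == 0:
        raise ValueError("reference population is empty")
    labeled = true_positive + false_positive
    if labeled == 0:
        raise ValueError("no labeled cells")
    return {"sensitivity": true_positive / total_reference,
            "false_positive_rate": false_positive / labeled}


def spontaneous_alternation(entries: Sequence[str]) -> float:
    """Y-maze spontaneous alternation percentage.

    An alternation is a window of three consecutive arm entries into three
    different arms; the score is alternations / (total entries - 2) * 100,
    using overlapping (sliding) windows.  Immediate self-repeats must have
    been collapsed upstream; fewer than 3 entries is an error.
    """
    seq = list(entries)
    if len(seq) < 3:
        raise ValueError("need at least 3 arm entries")
    for a, b in zip(seq, seq[1:]):
        if a == b:
            raise ValueError("immediate re-entries must be collapsed upstream")
    n = len(seq)
    alternations = sum(len({seq[i], seq[i + 1], seq[i + 2]}) == 3
                       for i in range(n - 2))
    return 100.0 * alternations / (n - 2)


def read_barnes_latencies(path: str | Path,
                          cap_s: float = 150.0) -> pd.DataFrame:
    """Barnes-maze trial latency table with the no-entry cap applied.

    Trials where the mouse never entered the escape compartment (missing
    latency) are assigned the trial-duration cap (150 s).  Expects columns
    ``mouse``, ``day``, ``trial``, ``latency_s``.
    """
    df = pd.read_csv(path)
    required = {"mouse", "day", "trial", "latency_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"latency table needs columns {sorted(required)}")
    df = df.copy()
    df["latency_s"] = df["latency_s"].fillna(cap_s).clip(upper=cap_s)
    return df
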