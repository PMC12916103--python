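"""Voltage-clamp analysis of voltage-gated K+ current families.

Covers nucleated-macropatch and heterologous-cell step families: baseline
subtraction, peak and steady-state current, current density (pA/pF),
conductance-voltage curves with Boltzmann fits, single-exponential activation
kinetics, and Nernst reversal potentials assembled from solution recipes.

The activation curve model is the two-state Boltzmann

    G(V) / Gmax = 1 / (1 + exp(-(V - Vhalf) / k))

with Vhalf the half-activation voltage and k > 0 the slope factor in mV.
Kv3-family currents show little/no inactivation over 100 ms steps, so peak
and steady-state current are nearly interchangeable for the G-V curve; peak
is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

# Gas constant (J/mol/K) and Faraday constant (C/mol)
R_GAS = 8.31446
FARADAY = 96485.332

# Stoichiometric dissociation of common recording-solution salts:
# salt -> {ion: count}.  Weak/chelated species (HEPES, EGTA, gluconate,
# phosphocreatine) are treated as contributing their counter-ions only where
# those are free monatomic ions.
SALT_IONS: dict[str, dict[str, int]] = {
    "NaCl": {"Na": 1, "Cl": 1},
    "KCl": {"K": 1, "Cl": 1},
    "CaCl2": {"Ca": 1, "Cl": 2},
    "MgCl2": {"Mg": 1, "Cl": 2},
    "KOH": {"K": 1, "OH": 1},
    "K-gluconate": {"K": 1, "gluconate": 1},
    "NaH2PO4": {"Na": 1, "H2PO4": 1},
    "NaHCO3": {"Na": 1, "HCO3": 1},
    "Na2ATP": {"Na": 2, "ATP": 1},
    "Na-pyruvate": {"Na": 1, "pyruvate": 1},
}


@dataclass
class SolutionComposition:
    """Free-ion concentrations (mM) of a recording solution at a temperature.

    Build directly from an ion map, or from salt concentrations with
    :meth:`from_salts`, which applies full stoichiometric dissociation
    (e.g. 2 mM MgCl2 contributes 4 mM Cl-).
    """

    ions_mM: dict[str, float]
    temperature_C: float = 22.0

    def __post_init__(self) -> None:
        for ion, conc in self.ions_mM.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {ion}")

    @classmethod
    def from_salts(cls, salts_mM: dict[str, float],
                   temperature_C: float = 22.0) -> "SolutionComposition":
        ions: dict[str, float] = {}
        for salt, conc in salts_mM.items():
            if salt not in SALT_IONS:
                raise KeyError(f"unknown salt {salt!r}; add it to SALT_IONS")
            for ion, count in SALT_IONS[salt].items():
                ions[ion] = ions.get(ion, 0.0) + count * conc
        return cls(ions_mM=ions, temperature_C=temperature_C)


@dataclass
class BoltzmannParams:
    """Fitted activation parameters: Gmax (normalization), Vhalf, slope k."""

    Gmax: float
    Vhalf_mV: float
    k_mV: float
    residual_rms: float
    quality_ok: bool = True

    def __post_init__(self) -> None:
        if self.k_mV <= 0:
            raise ValueError("slope factor k must be > 0")
        if self.Gmax <= 0:
            raise ValueError("Gmax must be > 0")

    def __call__(self, v_mV: np.ndarray) -> np.ndarray:
        return self.Gmax / (1.0 + np.exp(-(np.asarray(v_mV, float) - self.Vhalf_mV) / self.k_mV))


@dataclass
class VoltageStepFamily:
    """Family of current traces (pA), one per command step, aligned to onset.

    ``traces[i]`` is the response to ``step_mV[i]``; ``onset_s`` and
    ``duration_s`` locate the step within each trace.
    """

    holding_mV: float
    step_mV: np.ndarray
    traces: np.ndarray
    sampling_rate: float
    onset_s: float
    duration_s: float = 0.1
    capacitance_pF: float | None = None

    def __post_init__(self) -> None:
        self.step_mV = np.asarray(self.step_mV, dtype=float)
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if np.any(np.diff(self.step_mV) <= 0):
            raise ValueError("steps must be strictly increasing")
        if self.traces.shape[0] != self.step_mV.size:
            raise ValueError("one trace per step required")

    def step_window(self) -> tuple[int, int]:
        i0 = int(round(self.onset_s * self.sampling_rate))
        i1 = int(round((self.onset_s + self.duration_s) * self.sampling_rate))
        if i1 > self.traces.shape[1]:
            raise ValueError("step interval outside trace")
        return i0, i1


def baseline_subtract(family: VoltageStepFamily,
                      baseline_ms: float = 5.0) -> VoltageStepFamily:
    """Subtract the mean of the `baseline_ms` pre-step from each trace."""
    i0, _ = family.step_window()
    n = max(1, min(i0, int(round(baseline_ms * family.sampling_rate / 1000.0))))
    baselines = family.traces[:, i0 - n:i0].mean(axis=1, keepdims=True)
    return VoltageStepFamily(
        holding_mV=family.holding_mV, step_mV=family.step_mV,
        traces=family.traces - baselines, sampling_rate=family.sampling_rate,
        onset_s=family.onset_s, duration_s=family.duration_s,
        capacitance_pF=family.capacitance_pF)


def peak_current(family: VoltageStepFamily) -> np.ndarray:
    """Signed extremum of each (baseline-subtracted) trace over the step."""
    i0, i1 = family.step_window()
    seg = family.traces[:, i0:i1]
    idx = np.argmax(np.abs(seg), axis=1)
    return seg[np.arange(seg.shape[0]), idx]


def steady_state_current(family: VoltageStepFamily,
                         tail_fraction: float = 0.1) -> np.ndarray:
    """Mean current over the last ``tail_fraction`` of the step."""
    i0, i1 = family.step_window()
    n = max(1, int(round(tail_fraction * (i1 - i0))))
    return family.traces[:, i1 - n:i1].mean(axis=1)


def current_density(peaks_pA: np.ndarray, capacitance_pF: float | None) -> np.ndarray:
    """Current density in pA/pF (peak current / membrane capacitance)."""
    if capacitance_pF is None:
        raise ValueError("capacitance missing: report raw currents (pA) instead, "
                         "or supply capacitance_pF")
    if capacitance_pF <= 0:
        raise ValueError("capacitance must be > 0")
    return np.asarray(peaks_pA, dtype=float) / capacitance_pF


def conductance_curve(peaks_pA: np.ndarray, steps_mV: np.ndarray,
                      e_rev_mV: float, *,
                      drop_within_mV: float = 1.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized chord conductance G(V)/Gmax from peak currents.

    G = I / (V - E_rev); steps within ``drop_within_mV`` of E_rev are dropped
    (division blow-up) with a warning; negative leak-noise conductances are
    clamped to 0 before normalizing by the maximum.

    Returns ``(voltages, g_normalized)``.
    """
    peaks = np.asarray(peaks_pA, dtype=float)
    v = np.asarray(steps_mV, dtype=float)
    keep = np.abs(v - e_rev_mV) > drop_within_mV
    if not np.any(keep):
        raise ValueError("all steps at the reversal potential")
    if not np.all(keep):
        warnings.warn(f"dropping {np.sum(~keep)} step(s) within "
                      f"{drop_within_mV} mV of E_rev", stacklevel=2)
    g = peaks[keep] / (v[keep] - e_rev_mV)
    g = np.clip(g, 0.0, None)
    gmax = g.max()
    if gmax <= 0:
        raise ValueError("no positive conductance in family")
    return v[keep], g / gmax


def _boltzmann(v, gmax, vhalf, k):
    return gmax / (1.0 + np.exp(-(v - vhalf) / k))


def fit_boltzmann(g_norm: np.ndarray, steps_mV: np.ndarray, *,
                  residual_flag: float = 0.05,
                  k_bounds: tuple[float, float] = (0.5, 50.0)) -> BoltzmannParams:
    """Least-squares Boltzmann fit of a normalized conductance curve.

    Initializer: Vhalf from linear interpolation of the half-max crossing,
    k = 8 mV; bounded optimization keeps k in ``k_bounds``.  The fit is
    order-invariant in the voltage points and tolerant of an unnormalized
    curve (Gmax is free).  ``quality_ok`` is False when residual RMS exceeds
    ``residual_flag``.
    """
    g = np.asarray(g_norm, dtype=float)
    v = np.asarray(steps_mV, dtype=float)
    if g.size < 5:
        raise ValueError("need at least 5 points spanning the rise")
    order = np.argsort(v)
    v, g = v[order], g[order]
    gmax0 = float(g.max())
    half = gmax0 / 2.0
    above = np.nonzero(g >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        vhalf0 = float(np.interp(half, [g[i - 1], g[i]], [v[i - 1], v[i]]))
    else:
        vhalf0 = float(v[g.size // 2])
    try:
        popt, _ = curve_fit(
            _boltzmann, v, g, p0=[gmax0, vhalf0, 8.0],
            bounds=([1e-9, v.min() - 100.0, k_bounds[0]],
                    [10.0 * max(gmax0, 1e-9), v.max() + 100.0, k_bounds[1]]),
            maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Boltzmann fit failed (initializer Gmax={gmax0:.3g}, "
            f"Vhalf={vhalf0:.3g}, k=8.0): {exc}") from exc
    resid = g - _boltzmann(v, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return BoltzmannParams(Gmax=float(popt[0]), Vhalf_mV=float(popt[1]),
                           k_mV=float(popt[2]), residual_rms=rms,
                           quality_ok=rms <= residual_flag)


@dataclass
class ActivationTauCurve:
    """Single-exponential activation time constant per step voltage."""

    step_mV: np.ndarray
    tau_ms: np.ndarray

    def __post_init__(self) -> None:
        self.step_mV = np.asarray(self.step_mV, dtype=float)
        self.tau_ms = np.asarray(self.tau_ms, dtype=float)
        if np.any(self.tau_ms <= 0):
            raise ValueError("tau must be > 0")


def fit_activation_tau(trace_pA: np.ndarray, sampling_rate: float,
                       step_onset_s: float, *,
                       skip_ms: float = 0.5,
                       step_end_s: float | None = None) -> float:
    """Activation time constant (ms) from a mono-exponential rise fit.

    Fits I(t) = A (1 - exp(-t/tau)) from ``skip_ms`` after step onset (to
    skip the clamp artifact) to the time of the absolute peak.  The trace
    must be activating: the current magnitude at the peak must exceed that
    at the fit start.
    """
    trace = np.asarray(trace_pA, dtype=float)
    i0 = int(round(step_onset_s * sampling_rate))
    i_start = i0 + max(1, int(round(skip_ms * sampling_rate / 1000.0)))
    i_end = trace.size if step_end_s is None else int(round(step_end_s * sampling_rate))
    seg = trace[i_start:i_end]
    if seg.size < 5:
        raise ValueError("too few samples in fit window")
    sign = np.sign(seg[np.argmax(np.abs(seg))]) or 1.0
    seg = sign * seg
    i_peak = int(np.argmax(seg))
    if i_peak < 3 or seg[i_peak] <= seg[0]:
        raise ValueError("non-activating trace: no growing current after onset")
    tseg = (np.arange(i_start, i_start + i_peak + 1) - i0) / sampling_rate * 1000.0
    yseg = seg[:i_peak + 1]
    amp0 = float(seg[i_peak])
    tau0 = max(tseg[-1] / 3.0, 0.1)
    popt, _ = curve_fit(lambda t, a, tau: a * (1.0 - np.exp(-t / tau)),
                        tseg, yseg, p0=[amp0, tau0],
                        bounds=([0.0, 1e-3], [np.inf, 1e4]), maxfev=10000)
    return float(popt[1])


def activation_tau_curve(family: VoltageStepFamily, *,
                         min_step_mV: float = -20.0) -> ActivationTauCurve:
    """Fit activation tau for every step at or above ``min_step_mV``."""
    i0, i1 = family.step_window()
    voltages, taus = [], []
    for v, trace in zip(family.step_mV, family.traces):
        if v < min_step_mV:
            continue
        try:
            tau = fit_activation_tau(trace, family.sampling_rate,
                                     family.onset_s,
                                     step_end_s=family.onset_s + family.duration_s)
        except (ValueError, RuntimeError):
            continue
        voltages.append(v)
        taus.append(tau)
    if not voltages:
        raise ValueError("no step produced an activation fit")
    return ActivationTauCurve(step_mV=np.asarray(voltages), tau_ms=np.asarray(taus))


def nernst_potential(internal: SolutionComposition, external: SolutionComposition,
                     ion: str, valence: int) -> float:
    """Nernst equilibrium potential in mV: E = (RT/zF) ln([out]/[in]).

    Temperatures of the two compositions must agree (the external bath
    temperature is the recording temperature).  For chloride use
    ``valence=-1``; e.g. the whole-cell internal with 65 mM KCl + 2 mM MgCl2
    (69 mM Cl-) against ACSF (133.5 mM Cl-) at 32 C gives about -17 mV.
    """
    if valence == 0:
        raise ValueError("valence must be nonzero")
    c_in = internal.ions_mM.get(ion, 0.0)
    c_out = external.ions_mM.get(ion, 0.0)
    if c_in <= 0 or c_out <= 0:
        raise ValueError(f"{ion} must be present with positive concentration "
                         "on both sides")
    t_kelvin = external.temperature_C + 273.15
    return (R_GAS * t_kelvin / (valence * FARADAY)) * np.log(c_out / c_in) * 1000.0
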