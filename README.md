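# epiphys

Analysis toolkit for the quantitative procedures used in studying epileptic
encephalopathy in mouse models with impaired fast-spiking interneurons:
patch-clamp electrophysiology, paired-recording synaptic physiology,
two-photon calcium imaging, and chronic video-EEG seizure monitoring — plus
seed-controlled synthetic-data generators so every analysis stage can be
validated against known ground truth without raw recordings.

## Who it is for

Cellular neurophysiology labs analyzing:

- **Current clamp** — action-potential waveform features (threshold by the
  dV/dt criterion, amplitude, APD50, up/downstroke velocity, AHP), passive
  properties (median resting Vm, input resistance from a −20 pA step,
  rheobase as the largest silent step), F–I curves, and cell QC
  (Vm ≤ −50 mV, access-resistance drift ≤ 20%).
- **Voltage clamp** — K⁺ current families from 100 ms steps (−80…+40 mV in
  5 mV increments): current density (pA/pF), normalized conductance–voltage
  curves fit with the Boltzmann function
  `G/Gmax = 1 / (1 + exp(−(V − V½)/k))`, single-exponential activation
  kinetics τ(V), and Nernst reversal potentials assembled from solution
  recipes with full salt stoichiometry.
- **Paired recordings** — unitary PSCs per presynaptic AP (detected when
  amplitude exceeds 10 pA, otherwise a failure), failure rates and amplitude
  profiles for the first five pulses by train frequency (5–120 Hz),
  paired-pulse ratios uPSC₂/uPSC₁ and uPSC_last/uPSC₁, synaptic latency
  (AP peak → PSC onset), and connection probabilities with Fisher's exact
  test.
- **Calcium imaging** — dF/F₀ with a per-1000-frame 10th-percentile
  interpolated baseline, hypersynchronous-discharge detection (1 Hz
  high-pass, z > 5), per-cell transient detection (moving-mean smoothing,
  z ≥ 1, ≥ 200 ms separation, prominence ≥ 0.5 z), locomotion-state
  epoching, and per-cell activity metrics with threshold-robustness sweeps.
- **EEG** — 60 Hz notch + 1 Hz high-pass preprocessing, spike detection
  (> 200 µV and above the preceding-minute RMS), spike-train grouping
  (≥ 5 spikes, ISI 0.05–0.6 s, span ≥ 3 s), and rule-based classification
  into runs of spikes, seizures, myoclonic seizures, and fatal seizures with
  post-ictal suppression, with raster export.

Auxiliary metrics (membrane/cytosol immunofluorescence ratio via a 1 µm
distance-transform erosion, labeling validation rates, Y-maze spontaneous
alternation, Barnes-maze latency ingest) and a thin `compare` wrapper that
delegates inferential statistics to scipy/statsmodels round out the package.

## Worked example

```python
import numpy as np
from epiphys import synth, ephys, vclamp

# a synthetic fast-spiking cell with analytically known spike shape
ramp, steps, truth = synth.gen_current_clamp(seed=1)
feats = ephys.extract_first_ap_features(ramp.sweeps[0], ramp.sampling_rate)
print(feats.threshold_mV, feats.apd50_ms, feats.upstroke_mV_per_ms)
# -40.0 0.22500000000000053 400.0   (generator truth: -40, 0.225, 400)

fi = ephys.fi_curve(steps)
print(ephys.rheobase(fi)[0], truth["rheobase_pA"])
# 200.0 200.0   (largest silent step; analytic (V_thr - V_rest)/R)

# chloride reversal potential from the recording solutions, at 32 C
internal = vclamp.SolutionComposition.from_salts(
    {"KCl": 65.0, "MgCl2": 2.0, "K-gluconate": 65.0}, temperature_C=32.0)
external = vclamp.SolutionComposition.from_salts(
    {"NaCl": 125.0, "KCl": 2.5, "CaCl2": 2.0, "MgCl2": 1.0}, temperature_C=32.0)
print(vclamp.nernst_potential(internal, external, "Cl", valence=-1))
# -17.355085391280472   (69 mM Cl- inside vs 133.5 mM outside -> ~-17 mV)
```

The first block builds a leaky-integrate-and-fire cell whose spike template
has exactly known threshold, half-width and slopes, then shows that the
feature extractor recovers them; the rheobase printed is both the pipeline
estimate (largest current step with zero spikes) and the closed-form value.
The Nernst example sums chloride per salt stoichiometry (2 mM MgCl₂
contributes 4 mM Cl⁻) and evaluates `E = (RT/zF)·ln([Cl]out/[Cl]in)`.

A command-line interface mirrors the library:

```bash
epiphys simulate --modality calcium --seed 7 --out sim/
epiphys calcium --fluorescence sim/F --speed sim/speed.csv --out results/
```

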