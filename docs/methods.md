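# Methods

This note documents the models, detection rules, numerical choices and known
limitations of the package, in the order of the analysis chains.

## Current-clamp analysis

**Spike detection.** A spike is a local maximum of the membrane potential
reaching at least −10 mV (the counting rule; configurable
`peak_floor_mV`) that is preceded within 2 ms by a dV/dt excursion above
20 mV/ms. The upstroke gate is our addition to reject slow stimulus
artifacts that can cross the peak floor; it is configurable and can be
disabled (`min_upstroke_mV_per_ms=0`). Peaks within a 1 ms refractory
window merge (the larger wins).

**Derivative.** Central differences on the raw trace, one-sided at the
ends, in mV/ms. No pre-smoothing by default: at the 100 kHz sampling used
for waveform analysis, raw differences are stable; a boxcar width is
exposed for noisier data.

**Threshold.** The membrane potential at the first sample, scanning forward
toward the peak, where dV/dt exceeds 5% of that spike's maximal upstroke
velocity. **Amplitude** is peak minus threshold. **APD50** is the time
spent above threshold + amplitude/2, with both crossings linearly
interpolated between samples (sub-sample accuracy on noiseless input).
The alternative peak-referenced half-height was rejected because amplitude
is defined threshold-to-peak. **AHP** is the absolute minimum of Vm within
a 10 ms post-peak window; the window length is not standardized and is
configurable. **Downstroke** is restricted to the repolarization between
peak and the AHP minimum so a subsequent spike's upstroke cannot leak in.

**Passive properties.** Resting Vm is the median of a gap-free recording
(robust to the small sample fraction occupied by spikes). Input resistance
is ΔV_ss/I for the −20 pA step, with ΔV_ss the mean over the last 20% of
the step minus the pre-step baseline mean; an RC cell with τ = 15 ms
settles to within 0.1% over a 1 s step, so no exponential extrapolation is
attempted. Rheobase is reported as the largest current step that evoked no
spikes — the convention of reporting the sub-threshold step — and the first
supra-threshold step is exposed alongside it. With non-monotonic F–I counts
the rule is applied literally and the result flagged; all-silent and
all-spiking inputs are distinct errors rather than extrapolations.

## Voltage-clamp analysis

Current families come from 100 ms steps in 5 mV increments. Traces are
baseline-subtracted (mean of the 5 ms pre-step). Peak current is the
signed extremum over the step; steady-state is the mean of the last 10%.
Kv3-family currents show essentially no inactivation on this timescale, so
the two agree within ~1% for activation τ ≤ 10 ms, and peak feeds the G–V
curve by default (configurable).

Chord conductance G = I/(V − E_rev) uses a reversal potential computed by
the Nernst equation from the stated internal/external compositions rather
than an assumed constant, with an override. Steps within 1 mV of E_rev are
dropped (division blow-up); small negative conductances from leak noise are
clamped to zero before normalizing by the maximum. No P/n leak subtraction
is modeled; an optional linear-leak fit over hyperpolarized steps is the
escape hatch.

The Boltzmann fit is bounded least squares (`k ∈ [0.5, 50]` mV) with the
half-max crossing (linear interpolation) as the V½ initializer and
k ← 8 mV. The fit is invariant to point order and to uniform scaling of the
unnormalized conductance (Gmax is free). A residual RMS above 0.05 sets a
quality flag. Activation kinetics are fit as a single exponential
`A(1 − e^(−t/τ))` from 0.5 ms after step onset (skipping the clamp
artifact) to the time of peak; a sigmoidal delay (power model) was not
adopted because the data this emulates are adequately described by one
exponential, and the window and model order are configurable.

Nernst potentials use full stoichiometric dissociation of the recipe salts
(e.g. MgCl₂ contributes 2 Cl⁻); temperature enters in kelvin from the bath
composition. The canonical check: 69 mM internal vs 133.5 mM external
chloride at 32 °C gives −17.4 mV.

## Paired-recording analysis

Presynaptic APs are detected with the current-clamp detector. Each AP
opens a search window to the next AP or 50 ms, whichever is sooner (at
120 Hz the 8.3 ms inter-pulse interval governs). The deflection is
measured against a local 2 ms pre-AP baseline in the declared polarity
direction — with a depolarized chloride reversal (≈ −17 mV) and −70 mV
holding, IPSCs are inward, so polarity is declared per sweep, never
inferred. Amplitude is the maximum of the deflection after a 0.75 ms
boxcar average: a raw single-sample extremum over a ~50 ms window carries
an upward max-statistic noise bias of several pA that the short average
suppresses, while flattening an 8 ms-decay PSC peak by well under 2%.

Events are detected when amplitude exceeds 10 pA, otherwise the pulse is a
failure; failures enter amplitude means as 0 pA (efficacy convention; a
switch excludes them for potency). Paired-pulse ratios are ratios of mean
amplitudes, not means of per-sweep ratios, so pulse-1 failures cannot
produce divisions by zero. Onset latency is the first excursion beyond 2×
the baseline SD sustained for 0.5 ms; both onset-referenced (headline) and
peak-referenced latencies are available. Acausal events are excluded with
a warning. Connection probabilities use Fisher's exact test (scipy); the
test suite verifies it against a brute-force hypergeometric enumeration on
every table with group sizes up to 30.

## Calcium imaging

dF/F₀ uses F₀ = per-cell 10th percentile per 1000-frame block, linearly
interpolated between block centers with constant extrapolation beyond the
outer centers; a tail block shorter than 1000 frames receives its own
percentile. The alternative reading (block mean of a rolling percentile)
gives a nearly identical baseline on drifting data and was not adopted as
default. F₀ ≤ 0 is an error with offset guidance, since dF/F₀ is undefined.

Discharges in the FOV-mean trace: zero-phase 2nd-order Butterworth 1 Hz
high-pass, z-score, peaks with z > 5 separated by ≥ 1 s (the separation
prevents double-counting multi-peaked events). Peaks within 2 s of either
end are discarded — zero-phase filtering produces edge transients there.

Transients: 5-frame (~167 ms at 30 Hz) moving mean, z-score against the
full smoothed trace (mean/SD; a robust median/MAD variant is available),
then peak finding with z ≥ 1, ≥ 200 ms separation, prominence ≥ 0.5 z.
Times are reported at the unsmoothed local maximum. **These thresholds
presuppose a signal-dominated trace.** Because the z denominator is the
trace's own SD, the z = 1 cut sits at ~1.3 smoothed-noise SDs when the
trace is noise-dominated, and precision collapses; with transient peak
SNR ≳ 30 (typical for modern somatic indicators at 30 Hz) the same
thresholds give precision and recall above 0.95. The synthetic generator's
default peak SNR is 35 for this reason, and the threshold-robustness sweep
exposes the sensitivity of event counts to the cut.

Rest epochs: |speed| < 0.5 cm/s sustained ≥ 1 s, sub-0.2 s gaps absorbed;
all numerical criteria are configurable and recorded in output metadata.
Transient rates are counted over rest epochs per minute of rest; mean peak
height is reported in both z and dF/F₀ units since either convention is
found in practice.

## EEG

Preprocessing is a zero-phase 60 Hz notch (Q = 30) followed by a zero-phase
1 Hz high-pass (2nd-order Butterworth). Spikes are samples whose absolute
filtered amplitude exceeds both the 200 µV floor and the causal RMS of the
preceding minute (conjunctive reading); the RMS uses an expanding window
during the first minute and events there are flagged. Amplitude is the
absolute deviation from the filtered zero line, not peak-to-peak
(configurable). Candidate peaks merge within 50 ms; width is measured at
half amplitude.

Trains are greedy left-to-right chains: spikes closer than 0.05 s to their
predecessor belong to the same spike complex and are absorbed; an ISI above
0.6 s breaks the chain; a chain qualifies with ≥ 5 spikes spanning ≥ 3 s.
This grouping provably equals a brute-force maximal-segment search, which
the tests verify on random spike sets.

Classification consumes a behavior-annotation track (video review or the
generator) — behavior is never inferred from the EEG. A train overlapping
convulsive/loss-of-balance annotations is a seizure; without behavioral
correlate, a run of spikes; an isolated spike narrower than 200 ms with a
spasm annotation is myoclonic. A seizure with a hindlimb-extension
annotation is fatal when followed by post-ictal suppression, operationalized
as post-event RMS below 25% of the pre-event RMS for ≥ 30 s, with a 1 s
guard after the event end to keep residual ictal energy out of the window;
the 25%/30 s criterion is this package's concrete rendering of "suppressed
EEG". Contradictory annotation overlap is recorded in the evidence trail,
not silently resolved.

## Synthetic generators

Every generator returns data plus a truth record sufficient to score its
paired detector; identical seeds give bit-identical output.

- **Current clamp**: leaky integrate-and-fire with R = 150 MΩ, τ = 15 ms,
  rest −70 mV, threshold −40 mV. Subthreshold trajectories are exact
  closed-form exponential/ramp solutions (no Euler stepping), so spike
  times, rheobase (V_thr − V_rest)/R = 200 pA and per-step ISIs are
  analytic. Spike templates are piecewise linear with corners snapped to
  the sample grid, making threshold, slopes, APD50 and AHP exactly known.
  Default noise is zero (waveform-recovery conditions); Gaussian noise is
  available.
- **Voltage clamp**: I(V,t) = G(V)(V − E_rev)(1 − e^(−t/τ(V))) with
  Boltzmann G(V) (defaults Gmax 20 nS, V½ −5 mV, k 8 mV, E_rev −97 mV) and
  τ falling from ~10 to ~1.5 ms with depolarization. Noise enters as white
  trace noise (pA) and/or one conductance perturbation per step
  (G–V-curve scatter).
- **Paired recordings**: 10 presynaptic APs at 5–120 Hz; pulse i releases
  with probability 1 − p_f (default p_f = 0.3) and amplitude
  A₁·r^(i−1) (defaults A₁ = 50 pA, r = 0.7); latency is Gaussian
  (1.2 ± 0.1 ms); the PSC kernel is a difference of exponentials (rise
  0.5 ms, decay 8 ms); white noise 2 pA. Deep geometric depression pushes
  late-pulse amplitudes below the 10 pA floor — real behavior of the
  detection rule, visible as rising late-pulse failure rates.
- **Calcium**: per-cell Poisson transients (1.2/min at rest, 3/min during
  locomotion) with instantaneous rise and 0.7 s exponential decay
  (typical somatic indicator kinetics), amplitude 0.46 dF/F₀ on a baseline
  of 100, slow sinusoidal drift, white noise at peak SNR 35 (see above),
  and optional global discharges (1.0 dF/F₀, 0.3 s decay). Events within
  250 ms are merged at generation (two somatic events this close are
  inseparable at 30 Hz).
- **EEG**: 1/f colored Gaussian background (σ = 30 µV) — a standard
  stand-in for cortical background since no background model is prescribed
  — with one-cycle-sine biphasic spike templates (400 µV, 80 ms),
  scheduled trains (default 10 spikes at 0.4 s ISI, span 3.6 s), myoclonic
  singles (500 µV), and a fatal scenario that collapses the background to
  5% for 60 s after the train, with matching annotations.

What the generators do **not** emulate: bursting and adaptation in spike
trains, series-resistance and space-clamp errors, PSC kinetic variability
and tonic currents, neuropil contamination and motion artifacts in imaging,
and state-dependent EEG background (sleep spindles, movement artifact).
Passing recovery suites therefore demonstrates correctness of the
implementations under the stated statistical models, not robustness to
every pathology of real recordings.

## Problem sizes in the verification suite

The test suite validates at desk scale: Boltzmann recovery across 100
seeded families (26 voltages each, cross-checked against a 0.25 mV/0.25 mV
grid-search oracle), AP features across 50 jittered cells at 100 kHz,
train detection on 1,000 random spike sets plus 20 one-hour synthetic EEG
records, calcium detection on 100 cells × 10 min plus 20 discharge seeds,
synaptic recovery at 200 sweeps, and the Fisher comparison exhaustively
over all 2×2 tables with group sizes ≤ 30.

## Known limitations

- ABF reading requires `pyabf` and EDF requires `mne` at runtime; the
  CSV/HDF5/NPY paths are fully self-sufficient.
- The uPSC local-baseline convention biases amplitudes of strongly
  summating trains (slow decays at 80–120 Hz); the paired-pulse and
  failure statistics at the default kinetics are unaffected.
- Acquisition-time filter settings on EEG records are metadata passthrough
  only; no attempt is made to invert them.
- The transient detector's published thresholds are not reliable on
  noise-dominated traces (see Calcium imaging above); inspect the
  robustness sweep before trusting counts on low-SNR data.
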