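# Methods

## Analysis procedure

The pipeline classifies single 20 s system-vigilant segments into mental
arithmetic (MA), mental singing (MS) or no-control (NC):

1. **Per-trial normalization.** Each of the 18 channels is standardized by
   its own whole-trial mean and standard deviation (statistics include the
   12 s separation intervals). This absorbs inter-trial optode-coupling
   differences; consequently only signal *shape*, not absolute intensity,
   carries information downstream.
2. **Linear detrending** of each whole-trial channel (instrument drift).
3. **Segment extraction.** The three 20 s vigilant periods (625 samples at
   31.25 Hz) are cut out with their class labels.
4. **Low-pass filtering** of each segment: 3rd-order Chebyshev type II,
   cut-off 0.1 Hz, stop edge 0.5 Hz, ≥ 50 dB stopband attenuation,
   ≤ 6 dB passband loss, suppressing respiration (0.2–0.3 Hz), cardiac
   pulsation (0.8–1.2 Hz) and most of the Mayer wave (~0.1 Hz).
5. **Features.** OLS regression slopes (units/second) of every channel
   over the ten windows with starts {0,5,10,15} s and ends {5,10,15,20} s,
   end > start: 18 × 10 = 180 candidates per segment.
6. **Selection + classification.** Inside each training fold of a
   stratified 6-fold CV, five GA runs each select a subset of prescribed
   size (8–12; 10 by default); the subset with the lowest training mean
   probability of error trains a pooled-covariance LDA; adjusted accuracy
   is measured on the held-out fold. Five CV repetitions give 30 per-fold
   values. Held-out folds never participate in selection or fitting.
7. **Controls.** The identical procedure on uniformly permuted labels must
   score at the three-class chance level (~33%); observed accuracies are
   compared against the chance upper confidence limit (40.8% for n = 288,
   α = 0.01 by the adjusted-Wald construction).

Classification is always within-participant; study-level numbers are
arithmetic means of per-participant adjusted accuracies.

## Synthetic signal model

Raw intensity on channel i of one trial (96 s: three [12 s rest, 20 s
task] blocks):

    x_i(t) = B + d·t + o + g · [ Σ_c a_c sin(2π f_c t + φ_c) + ε_i(t) + τ_i(t) ]

- `B = 100` raw units (arbitrary; normalization removes scale).
- `d` instrument drift, 0.02 units/s.
- `o, g` per-trial coupling offset (sd 2.0) and gain (1 + sd 0.05),
  emulating headband re-seating between trials.
- Oscillatory noise: Mayer wave a = 1.0 at 0.1 Hz; respiration a = 0.6 at
  a per-participant frequency drawn from [0.2, 0.3] Hz; cardiac a = 0.4
  from [0.8, 1.2] Hz. Phases are redrawn per trial per component and
  shared across channels (these sources are systemic). Amplitude ratios
  follow the usual ordering of low-frequency dominance in optical
  recordings.
- `ε_i` white sensor noise, sd 0.3.
- `τ_i` task component: during a vigilant interval labelled c, a linear
  ramp of slope `effect_slope[c, i]` starting 2 s after interval onset
  (haemodynamic lag), then exponential relaxation toward baseline with a
  6 s time constant. NC plants no component — the no-control state is
  modelled as the *absence* of a consistent evoked response. Spontaneous
  NC activations are not injected (configurable choice left off by
  default, since nothing constrains their statistics).

The two wavelengths of one location are independent channels with
independently drawn effect slopes whose signs may differ, mimicking the
opposite absorption trends of oxy-/deoxy-haemoglobin; no Beer–Lambert
conversion is performed — the classifier operates on normalized raw
intensity throughout.

**Effect calibration.** A default participant plants effects on 6
randomly chosen channels per IC class with magnitude
`effect_snr × (noise slope sd) × (raw trial sd)`, where the noise slope sd
is measured on the profile's own task-free signal after full
preprocessing. `effect_snr = 2.5` keeps the realized post-normalization
contrast comfortably above 1.5× the noise slope sd even though the task
ramps themselves inflate the per-trial normalization variance. The default
cohort is 7 profiles, 4 MS-responders and 3 non-responders (zero MS
effect), so a non-responder's MS segments are statistically identical to
NC. With these defaults the planted effects are strong enough that the
nested CV saturates near 100% adjusted accuracy: the generator reproduces
the *statistical structure* the analysis assumes (slope-coded class
information in band-limited noise), not the empirical difficulty of real
recordings — real fNIRS effects are weaker, non-stationary, and
contaminated by motion and systemic confounds the model omits. Passing
tests therefore validate the machinery (balance, leakage-freedom,
calibration of chance), not field performance.

## Protocol balance

Each session holds `trials/8` complete sets of the eight
answer-combination patterns over the three highlighted choices. Within a
set, four trials are assigned MA and four MS such that MA covers exactly
6 of the 12 IC intervals; which task receives the all-NC pattern
alternates between sets so trials *showing* each task also balance. At
the defaults this yields exactly 72 MA, 72 MS and 144 NC periods, and in
general #MA = #MS and #NC = #MA + #MS.

## Numerical choices

- **Zero-phase filtering** (forward–backward `sosfiltfilt`, cascaded
  second-order sections): a causal 0.1 Hz 3rd-order filter has a group
  delay of several seconds, which would corrupt window slopes on a 20 s
  segment. Edge padding is odd-reflection of one full segment length — the
  filter settles over tens of seconds, so short default padding leaks
  transients across the entire window. Note that on a finite 20 s segment
  a truncated stop-band sinusoid still leaks low-frequency energy *into*
  the passband; segment-level attenuation is therefore bounded by leakage
  (~20–25 dB for a 1 Hz tone), while the filter itself meets its ≥ 50 dB
  steady-state specification.
- **Filter design** places exactly 50 dB at the 0.5 Hz stop edge, then
  verifies the 6 dB passband constraint on a dense grid and rejects the
  spec as unachievable otherwise (measured passband loss ≈ 1.5 dB).
- **Windows** are half-open in seconds, `floor(start·fs) ≤ i < floor(end·fs)`,
  so adjacent windows share no samples and (0, 20) covers all 625 samples;
  regression is against time in seconds, making slopes sample-rate
  invariant. No feature scaling is applied before LDA (per-feature affine
  maps do not change LDA decisions).
- **LDA**: pooled covariance normalized by (n − k); default ridge
  1e-6·trace(Σ)/p guarantees invertibility at subset dimension ≤ 12 with
  ~240 training samples; equal priors (adjusted accuracy weights classes
  equally; empirical priors would bias toward NC). Prediction uses the
  Mahalanobis form of the discriminant, which preserves exact ties so the
  deterministic class-order tie-break is honoured; the GA fitness path
  uses the algebraically equivalent linear form for speed. The fitness is
  the resubstitution mean probability of error on the GA's training data
  (no inner CV) — "estimated by the training set" read literally; the
  external CV alone provides unbiased accuracy estimates.
- **GA encoding**: scattered crossover is defined on fixed-length strings,
  so chromosomes are 180-bit masks constrained to exactly `subset_dim`
  ones; crossover mixes parent bits through a random binary template and a
  repair step randomly deletes surplus / adds missing ones. Uniform
  mutation swaps each selected index with probability 0.2 for a uniformly
  random unselected one. Roulette-wheel weights are max(1 − error, 1e-6).
  70% of non-elite offspring come from crossover, the rest are cloned from
  wheel-selected parents; all offspring are then mutated; the single elite
  passes unchanged. Stopping is by generation count only. Fitness values
  are cached per subset, so converged populations are cheap.
- **Folds** are stratified (each fold keeps the 2:1:1 imbalance: 24 NC,
  12 MA, 12 MS at defaults); unstratified small folds could miss a class
  entirely. Per-class percent-correct is pooled over all test folds of all
  repetitions rather than averaged per fold.
- **Chance bound**: the adjusted-Wald (Agresti–Coull) upper limit at
  two-sided α around chance proportion 1/k; it reproduces the standard
  published values for (k=3, n=288) and (k=2, n=144) within ±0.5
  percentage points; an exact binomial-quantile bound is available via
  `method="exact"`.
- **Determinism**: every stochastic step (protocol shuffling, signal
  noise, fold shuffling, permutations, GA) derives from explicit seeds;
  one master seed fully determines a simulate-or-analyze run.

## Problem sizes used in the shipped checks

The reduced evaluation schedule used by the packaged benchmarks — 1 CV
repetition, 2 GA runs per fold, subset dimensionality 10, one synthetic
participant (288 segments) — was chosen as the smallest configuration
that still exercises every stage at study scale. Under label permutation
its mean adjusted accuracy is distributed around 33.3% with a standard
deviation of ≈ 3 percentage points across seeds (6 per-fold values only);
individual runs typically land within ±5 points of chance.

## Limitations

- The generator omits motion artefacts, slow scalp-haemodynamic
  confounds, non-sinusoidal physiological noise, and session-level
  non-stationarity; its accuracy levels are not predictive of real data.
- The task response is a ramp-and-recover shape chosen because the
  downstream features are window slopes; other plausible response shapes
  (plateau, biphasic) are expressible only by reconfiguring the generator.
- Only intensity is modelled — no frequency-domain phase/modulation
  quantities, no conversion to haemoglobin concentrations, no SNIRF I/O.
- Online/real-time classification is out of scope; the pipeline is
  offline and per-participant.
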