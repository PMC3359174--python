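# nirsbci

Three-class mental-state discrimination for a system-paced fNIRS
brain-computer interface, with a synthetic-recording generator so the
entire analysis is runnable without participant data.

## The problem

A system-paced near-infrared spectroscopy (NIRS) BCI presents the user
with choices that are highlighted in sequence for 20 s "system-vigilant"
periods. To select a choice the user enters an intentional-control (IC)
mental state — **mental arithmetic (MA)** (serial subtraction) or
**mental singing (MS)** (emotionally engaged song rehearsal) — during the
corresponding period; otherwise they remain in the **no-control (NC)**
state, thinking freely. The analysis question: can MA, MS and NC be told
apart on single 20 s segments of raw normalized light intensity recorded
on 18 channels (3 detectors × 3 source-pairs per detector × 2 wavelengths,
all at the 3 cm source-detector separation) sampled at 31.25 Hz?

This package implements that analysis as a tested, reusable library:

- **`nirsbci.synth`** — protocol and recording generator: balanced study
  designs (3 sessions × 32 trials → 72 MA, 72 MS, 144 NC periods),
  channel enumeration from an optode layout under the 3 cm rule, and a
  per-channel signal model (task-evoked amplitude ramp + Mayer-wave,
  respiratory and cardiac oscillations + drift, white noise and per-trial
  coupling gain/offset), including MS "non-responder" profiles.
- **`nirsbci.preprocess`** — per-trial channel standardization, linear
  detrending, segment extraction, and zero-phase low-pass filtering with a
  3rd-order Chebyshev type II design (cut-off 0.1 Hz, stop 0.5 Hz, ≤ 6 dB
  passband loss, ≥ 50 dB stopband attenuation).
- **`nirsbci.features`** — the 180-dimensional feature pool: the OLS
  regression slope of each of the 18 channels over each of 10 time
  windows (starts 0–15 s, ends 5–20 s, 5 s grid) within the segment.
- **`nirsbci.lda`** — pooled-covariance linear discriminant analysis with
  equal priors, δ_c(x) = xᵀΣ⁻¹μ_c − ½μ_cᵀΣ⁻¹μ_c + log π_c.
- **`nirsbci.ga`** — genetic-algorithm wrapper feature selection at a
  prescribed subset dimensionality (population 250, elitism 1,
  roulette-wheel selection, scattered crossover 0.7 with cardinality
  repair, uniform mutation 0.2, 30 generations) with the LDA
  resubstitution mean probability of error as fitness.
- **`nirsbci.evaluate`** — 5 × 6-fold nested cross-validation (selection
  and training strictly inside each training fold), **adjusted accuracy**
  AA = (1/k) Σⱼ PCⱼ (the k-class generalization of
  (sensitivity + specificity)/2, immune to the 2:1:1 class imbalance),
  randomized-label controls, and chance-level upper confidence limits
  (adjusted-Wald or exact binomial).

## Worked example

`python examples/04_classification_pipeline.py` simulates one default
participant, extracts features, and runs the nested CV on true and on
permuted labels (reduced schedule for speed):

```
features: (288, 180)
true labels:   mean adjusted accuracy 100.0%  per-class {'MA': 100.0, 'MS': 100.0, 'NC': 100.0}
permuted:      mean adjusted accuracy 32.6%
chance upper limit (3 classes, n=288, alpha=0.01): 40.8%
```

The planted class effects in the default synthetic participant are set
well above the noise floor, so the true-label accuracy saturates; the
permuted-label run staying at ~33% is the leakage check — feature
selection inside the CV sees only training folds, so randomized labels
cannot score above chance. `examples/03_chance_bounds.py` prints the
guessing thresholds:

```
3-class, n=288: chance point 33.3%, upper limit 40.8% (adjusted-Wald), 40.6% (exact binomial)
2-class, n=144: chance point 50.0%, upper limit 60.5% (adjusted-Wald), 60.4% (exact binomial)
```

A thin CLI wraps the same functions:

```sh
nirsbci simulate --out data/ --seed 1           # trial CSVs + labels.csv
nirsbci analyze  --data data/ --out report/     # per-participant reports
nirsbci chance 3 288 0.01                       # -> 40.8
```

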