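# Methods

## The Wendling neural mass model

The simulator implements the standard ten-dimensional Wendling model of a
hippocampal circuit: a pyramidal population coupled to an excitatory
feedback population, a slow (dendritic, GABA_A,slow) inhibitory population
and a fast (somatic, GABA_A,fast) inhibitory population. Each synaptic
pathway is a critically damped second-order kernel; population firing is
the sigmoid S(v) = 2e₀ / (1 + exp(r(v₀ − v))). Writing each kernel as the
pair ẏᵢ = yᵢ₊₅, ẏᵢ₊₅ = K·k·(input) − 2k·yᵢ₊₅ − k²·yᵢ:

| channel | (K, k) | input |
|---|---|---|
| y₀ pyramidal output PSP | (A, a) | S(y₁ − y₂ − y₃) |
| y₁ excitatory feedback PSP | (A, a) | p(t) + C₂·S(C₁·y₀) |
| y₂ slow-inhibitory PSP | (B, b) | C₄·S(C₃·y₀) |
| y₃ fast-inhibitory PSP | (G, g) | C₇·S(C₅·y₀ − C₆·y₄) |
| y₄ slow PSP on fast cells | (B, b) | S(C₃·y₀) |

The model output — the simulated EEG/LFP — is y₁ − y₂ − y₃.

Fixed parameters: a = 100 s⁻¹, b = 30 s⁻¹, g = 350 s⁻¹, C = 135 with
C₁ = C, C₂ = C₇ = 0.8C, C₃ = C₄ = 0.25C, C₅ = 0.3C, C₆ = 0.1C;
v₀ = 6 mV, e₀ = 2.5 s⁻¹, r = 0.56 mV⁻¹. The input firing rate p(t) is
drawn i.i.d. N(90, 30²) s⁻¹ per integration step. The four state types
are selected by the synaptic gains (mV):

| type | A | B | G |
|---|---|---|---|
| 1 interictal | 3.5 | 13.2 | 10.76 |
| 2 preonset | 4.6 | 20.4 | 11.48 |
| 3 onset | 7.7 | 4.3 | 15.1 |
| 4 ictal | 8.7 | 11.4 | 2.1 |

### Integration

Fixed-step Euler with one noise draw per step, initial state zero, and a
2 s burn-in discarded before the retained window. The default integration
step equals the output sampling interval (dt = 1/fs, i.e. 512 Hz): this
is the discrete formulation common to reference implementations of this
model, in which the noise sequence is part of the model definition rather
than an approximation to a continuous white-noise process (no √dt
scaling). Because the per-step noise variance is fixed, the effective
noise power delivered to the system scales inversely with the integration
rate; integrating finer than the sampling rate therefore *under-drives*
the model — it visibly suppresses the sporadic preonset spikes, which are
noise-triggered excursions. A finer internal rate remains available
(`fs_int`, with stride decimation of the band-limited output) for
stability experiments. At the default rates Euler is stable: the fastest
kernel gives g·dt ≈ 0.68, well inside the stability region of the
critically damped pair.

`simulate_type_set` integrates all segments of a state as one vectorized
ensemble, but every segment consumes its own per-segment generator
(master seed + running index), so batch results are bit-identical to
one-at-a-time simulation.

### Dynamical regimes (what the generator emulates)

- Interictal and preonset configurations possess a stable low-voltage
  equilibrium; noise produces background fluctuations, and in the
  preonset regime occasional large noise excursions trigger
  high-amplitude spikes (hundreds of Tukey-fence outlier samples per 5 s
  segment versus ~20 for interictal, the Gaussian baseline).
- The ictal configuration has a stable limit cycle: sustained rhythmic
  discharges at ≈ 8 Hz, dominating the 4–12 Hz band in every realization.
- The onset configuration has a single strongly damped equilibrium with
  the pyramidal sigmoid near saturation (output ≈ 13.5 mV); its output is
  a low-amplitude broadband fluctuation with spectral mass spread over
  roughly 0.5–16 Hz rather than a dominant 15–40 Hz rhythm. Fixed-point
  and eigenvalue analysis (and high-accuracy re-integration) confirm this
  is a property of the published gain triple under the canonical
  equations, not of the integrator: nearby configurations (e.g. G ≈ 25)
  do produce dominant 20–25 Hz oscillations. Onset segments remain
  perfectly separable in feature space — through their elevated mean,
  small variance and short line length — so classification is unaffected;
  only the textbook "dominant beta/gamma band" description of this regime
  is not reproduced.

## Features

All 11 features are computed on raw segments. Band power is the mean
Welch PSD (1 s Hann windows, 50 % overlap) over bins whose center falls
in the half-open band [lo, hi); the top band is closed at the segment's
own Nyquist frequency. Quantiles use linear interpolation (the Tukey
fences Q₁ − 1.5·IQR, Q₃ + 1.5·IQR inherit this convention). The spike
count `spikeabs` counts outlier *samples*, not merged events.
Autocorrelation is the Pearson correlation at a lag of round(0.005·fs)
samples (minimum 1); a zero-variance segment yields 0 with a warning.
Variance and the z-normalization statistics use the sample (n − 1)
convention. Z-normalization is always per dataset (one individual, or
the whole simulated set); a zero-variance feature column is mapped to
zeros with a warning.

## Prototyping and classification

PCA is fixed at four components (they carry ≈ 99 % of the variance on
simulated data); each loading column is oriented so its
largest-magnitude entry is positive, removing the sign arbitrariness so
serialized prototype sets are reproducible. k-means uses k-means++ with
50 restarts and a recorded seed. Centroid labeling assigns every
simulated segment to its nearest centroid (unweighted Euclidean distance
in the 4-dimensional score space) and takes the majority vote per
Voronoi region; vote ties go to the lower label number (warned),
duplicate-label centroids keep the larger region (index ties keep the
smaller index, warned), and empty regions are dropped — a prototype set
may therefore hold fewer than four prototypes. Segments to classify are
z-normalized with their **own** dataset's statistics before projection
with the prototype dataset's coefficients; using the prototype dataset's
statistics instead is available as an explicit choice by passing an
already-normalized matrix.

## Evaluation

Sensitivity and PPV are per-type with macro averages over the types for
which the metric is defined: a type absent from the truth contributes no
sensitivity term; a type never predicted contributes no PPV term; a type
predicted but never true yields PPV 0 (false alarms are penalized).

The surrogate null replaces the *predicted* sequence with realizations
of a discrete-time, time-homogeneous Markov chain whose transition
matrix is estimated from the true labels (uniform 0.25 for the balanced
simulated set); the classifier is not re-run. Surrogate chains start
from the stationary distribution of the estimated chain (recorded in the
result). p = (#{surrogates ≥ observed} + 1) / (n + 1), so ties count
against significance and the smallest attainable p with n = 1000 is
1/1001 ≈ 0.001. Group-level tests draw one chain per individual per
realization and compare unweighted group means. Under a null classifier
whose predictions are themselves drawn from the chain, the resulting
p-values are uniform to Kolmogorov–Smirnov tolerance.

## Preprocessing of real recordings

Centering and polarity inversion (−(x − mean)) align slice and
depth-electrode recordings with the model's output convention; the model
output itself is never inverted. "50 Hz filtering" is implemented as a
second-order IIR notch (quality 30) applied forward-backward, since the
stated purpose is line-noise removal; a low-pass reading is possible but
would discard the >64 Hz feature band. Segmentation is non-overlapping,
anchored at the first sample, dropping a trailing remainder; recordings
at other sampling rates (e.g. 1 kHz) are featurized at native rate — the
top band edge then differs, which within-dataset z-scoring absorbs.

## Problem sizes and tolerances

The package's reference experiment uses 400 segments (100 per type, 5 s,
512 Hz), 1000 surrogates, and 5 independent noise realizations in the
repeated checks; null-calibration uses 200 replicates. These sizes give
Monte-Carlo error well below the margins asserted in the tests (e.g.
chance level 0.25 ± 0.05 at n = 400; self-classification ≥ 0.95 against
an observed ≈ 0.9975).

## Known limitations

- Single channel only; no artifact rejection, montage handling or
  resampling beyond what is described.
- Segments are classified independently; no temporal smoothing of the
  label sequence, although real state sequences are strongly
  autocorrelated.
- The synthetic generator produces stationary 5 s segments per regime; it
  does not emulate mixed-type segments at state transitions, measurement
  noise, electrode drift, or inter-subject variability beyond optional
  gain jitter in the multi-subject fixture — real-data performance is
  therefore expected to be substantially below the simulated ≈ 0.99.
- The onset regime's spectral content deviates from the classical
  low-voltage-fast description, as analyzed above.
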