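# Methods

## Model

`cohdecode` decodes a continuous per-trial target signal `y(t)` (finger
position, speech amplitude envelope) from trial-aligned multichannel neural
features `x_j(t)` under a single structural assumption: **every trial of
the same condition is a realization of the same random process**. Nothing
is assumed about stationarity *within* a trial; what must be consistent
across trials is the joint second-order statistics of feature and target —
in particular the phase difference between them at each frequency.

Fitting has two stages, both estimated on training trials only:

1. **Per-feature Wiener filter.** Cross-trial spectra are estimated with a
   trial-as-window variant of Welch's method: one full-length window per
   trial, Hamming taper, zero overlap, averaged across the K training
   trials. The one-sided densities `Pxx[j,f]`, `Pyy[f]` and the complex
   cross-density `Pxy[j,f] = <conj(X_kj) Y_k>_k` give the complex coherence
   `C = Pxy / sqrt(Pxx Pyy)` (|C|² is the per-frequency squared
   correlation) and the filter `H_j = Pxy / (Pxx + ε·max_f Pxx)`. The
   relative floor ε (default 1e-8) only matters in stop-bands where the
   feature has essentially no power. `h_j` is the inverse DFT of the
   Hermitian-extended `H_j` and is real by construction; filters are
   allowed to be non-causal, and prediction is circular convolution
   (frequency-domain product) at the trial length, matching the DFT
   framing of the estimator. No taper is applied at prediction time.

2. **Spatial combination.** The filtered training features, concatenated
   across trials in time, form the design matrix of an ordinary
   least-squares regression (with an unpenalized intercept — the
   high-gamma envelope has nonzero mean, and the model's noise term
   absorbs offsets; the intercept can be disabled). Rank-deficient designs
   fall back to the minimum-norm solution with a logged warning. The
   magnitudes |b_j|, min-max normalized per model (all-equal magnitudes
   map to 0.5 by convention), are the spatial importance maps.

The whole predictor is scale-covariant: rescaling a feature rescales its
filter inversely, rescaling the target rescales the filters
proportionally; predictions are invariant to per-feature units.

### Estimator convergence

The per-bin Wiener quotient is a ratio of K-trial averages. When the
target mixes J features (the feature-level generative model), each
feature's filter estimate carries cross-feature noise and the achievable
held-out correlation on a *noiseless* realizable system follows
r ≈ 1/sqrt(1 + (J−1)/K). The property tests therefore assert r > 0.99 at
convergent settings ((J−1)/K ≈ 0.01) and monotone improvement with K,
rather than at small trial counts where the estimator has demonstrably not
converged. With forward coupling (each channel individually carries the
target, as in the raw-level generator) there is no cross-feature term and
30 trials suffice for r ≈ 0.98.

## Preprocessing

Defaults follow common ECoG practice and are all configurable
(`PreprocessConfig`): broadband band-pass 0.1–200 Hz (4th-order
Butterworth), 60 Hz notch (second-order IIR, Q = 30), common average
reference, then per electrode the low-frequency components (LFC,
0.5–40 Hz) and/or the high-frequency band envelope (HFBE: 70–170 Hz
band-pass, magnitude of the analytic signal, 40 Hz low-pass), finally
polyphase decimation to the 200 Hz analysis rate. Every filter is applied
forward–backward (`sosfiltfilt`), so a 4th-order design acts with an
8th-order magnitude response and exactly zero phase; "order" in the
configuration refers to the one-way design. Per-trial filtering uses
full-length reflection padding: the 0.1 Hz high-pass corner and the
high-Q notch settle over many seconds, far beyond `filtfilt`'s default
padding, and under-padding leaks visible edge transients into short
trials. The high band's upper edge is a configuration choice; 170 Hz is
the default, with the band fully configurable.

## Evaluation protocol

Blocked k-fold cross-validation (default k = 5) splits each condition's
trials into contiguous blocks; sizes differ by at most one (30 trials →
24 train / 6 test per fold; 18 trials → test blocks {4,4,4,3,3}). Models
are fit per condition on training blocks only; test trials are scored
individually with Pearson's r and Lin's concordance correlation
coefficient CCC = 2·cov/(var_a + var_b + Δmean²), which additionally
penalizes scale and location error (|CCC| ≤ |r| always). Per-trial scores
are aggregated by unweighted mean. A taint test asserts the leakage
guarantee: perturbing a test trial leaves the fold's fitted model
bit-identical.

**Discriminability of the spatial weights.** Observations are the
per-(condition, fold) weight-magnitude vectors. Each electrode's values
are clustered by 1-d K-means (k = number of conditions, 10 restarts,
fixed seed) and scored by between-cluster over total sum of squares; the
score ranks electrodes (ties by index). An LDA classifier on the
top-ranked electrodes — selected on training folds only — predicts the
condition of held-out weight vectors; accuracy and Cohen's kappa are
reported, and `n_selected=None` uses all electrodes.

Two calibration caveats, both verified by tests:

* 1-d K-means partitions even pure noise effectively, so the separation
  score of an uninformative electrode is high in absolute terms (~0.9 for
  20 observations in 4 clusters); the score is useful as a *ranking*, not
  as an absolute significance measure. A constant electrode scores 0.
* The correct null for the LDA stage is identical class-conditional
  *weight distributions*. Fitting per-fold models on an uncoupled target
  does **not** produce that null: same-condition models share training
  trials across folds, hence share estimation noise, and the classifier
  detects this clustering (~0.49 accuracy vs 0.2 chance in our
  measurements) even though the weights carry no task information. Any
  application of the discriminability analysis to real data should keep
  this fold-overlap bias in mind.

## Significance of coherence

The random-phase surrogate test replaces the target's per-trial windowed
DFT phases with i.i.d. uniform phases (amplitudes preserved, DC/Nyquist
kept real with random sign), recomputes |C|², and takes the empirical
(1−α) quantile over surrogates (default 1000) per bin as the threshold.
Randomizing the windowed spectrum keeps `Pyy` exactly invariant and makes
the surrogate distribution identical to the independent-signals null, so
the test is calibrated: on uncoupled white noise the per-bin rejection
rate matches α within binomial error (measured 0.052 at α = 0.05 with 500
surrogates).

Bins within the taper's main lobe of DC (two bins for the Hamming window)
deserve caution: per-trial mean offsets of strictly positive signals (the
high-gamma envelope, a flexion trace) leak into them and are trivially
coherent — the coherence there reflects the offsets, not dynamics.
Peak-localization analyses in this package therefore search above bin 2.

## Ridge-TRF baseline

The comparison baseline expands each feature with lagged copies (default
−500 ms … +500 ms in steps of one sample at the analysis rate, zero-padded
at trial edges so no samples leak between trials) and solves the ridge
problem (XᵀX + λI)β = Xᵀy with centered columns and an unpenalized
intercept. λ is selected by nested blocked CV (inner k = 4, the training
block's natural count) over the geometric grid λ_n = 1e-6 · 1.848ⁿ,
n = 0…53, spanning 1e-6 to ≈1.4e8. A literal linear reading of the
progression (λ0 · 1.848 · n) tops out near 1e-4, which contradicts the
intended 1e-6…1e8 span and the "logarithmically spaced" description, so
geometric spacing is the default; the linear variant is available behind
`spacing="linear"` for auditability. The full solution path is computed
from one SVD per inner fold. On data generated by the coherence model the
coherence decoder scores at least as well as this baseline; no claim is
made (or tested) about real recordings.

## Synthetic generators

The generators exist so every stage is testable against known ground
truth; all are driven by one integer seed and are bit-reproducible.

* **Feature level** (`simulate_feature_level`): i.i.d. standard-normal
  features; target `y = Σ_j b*_j (g*_j ⊛ x_j) + noise` with circular
  convolution, random smooth unit-norm FIRs `g*_j` (white taps smoothed by
  a Hann kernel, length 25 at 200 Hz) and distinct random weights
  (magnitudes in [0.5, 1.5], random signs). White noise is scaled so the
  realized signal-to-noise variance ratio equals the request exactly;
  `snr_db=inf` adds none. This is the model's exact generative inverse, so
  fitted contributions can be compared to `|b*|` directly.

* **Raw level** (`simulate_raw_level`): 1000 Hz "recordings" over a pink
  (1/f) background, the realistic coarse shape of neural spectra. The
  target is a quasi-periodic flexion trace: full-period Hann pulses at the
  flexion rate (default 1.5 Hz) whose cycle lengths jitter i.i.d. with 10%
  coefficient of variation and are rescaled so every trial completes the
  same number of cycles — freely paced movement within a cued window; the
  rescaling keeps per-trial means stable, and full-period pulses make the
  trace sinusoid-like so its power concentrates at the fundamental.
  Coupled channels receive the target twice: additively in the LFC band
  through a channel-specific smooth FIR, with a per-channel gain set so
  the coupled component's 0.5–40 Hz variance sits exactly `snr_db` above
  the pink background's (default 10 dB); and as amplitude modulation of a
  70–170 Hz noise carrier by a rectified filtered copy of the target
  (positive smooth kernels, per-channel RMS-normalized modulator, depth
  0.8), the way high-gamma power tracks movement. Uncoupled channels are
  pink noise only.

* **Condition sets** (`simulate_condition_set`,
  `simulate_weight_observations`): conditions share the coupling filters;
  per-condition true weights differ on a chosen number of electrodes by a
  chosen cluster separation (0 = null), exercising the ranking/LDA
  pipeline end to end or at the weight level directly.

What the generators do *not* emulate: volume conduction and
cross-electrode correlation of the background, non-stationary noise,
artifacts, harmonically rich movement traces, and the nonlinearities of
real neurovascular/neural coupling. Passing tests demonstrate internal
correctness and calibration of the method, not performance on real
recordings.

### Identifiability of spatial weights under forward coupling

On raw-level data every coupled channel individually predicts the target
well after Wiener filtering, so the spatial regressors are nearly
collinear and only the *sum* of the weights is well determined — there is
no meaningful per-channel truth direction to recover. Parameter-recovery
checks of the weight direction therefore use the feature-level generator,
where the target is a weighted mixture and the weights are identifiable;
raw-level datasets check decoding performance and coherence-peak
localization.

## Numerical choices

* Spectra are one-sided densities (per Hz, window-power normalized); the
  normalization cancels in coherence and in the Wiener quotient but keeps
  `SpectraSet` a valid PSD. Cauchy–Schwarz (|Pxy|² ≤ Pxx·Pyy) is asserted
  on every estimate.
* Transform length equals the trial length (no zero padding); `H` at DC
  and Nyquist is real automatically for real inputs.
* Analytic-exactness tests of the Wiener stage (circular delay, known FIR
  recovery to machine-level error) use the estimator's boxcar window
  option: the Hamming taper convolves the true transfer function with its
  |W|² leakage kernel (≈4-bin main lobe), a bias of order 1e-4 at trial
  length 1024 — small, but not machine precision. The default estimator
  everywhere else is the Hamming taper.
* Mixed-condition spectral pooling is refused unless the caller passes a
  single condition's trials (fit is per condition throughout).
* Sample indexing is 0-based; epochs are half-open `[start, start+len)`,
  so contiguous epochs concatenate losslessly.

## Problem sizes

Tests and the acceptance script run the pipeline at deliberately modest
sizes — 8–16 features, 12–30 trials per condition, 1–2 s trials, 10–20
seeds per calibration, 500 surrogates — chosen so each check has clear
statistical power while the whole suite completes in well under a minute
of compute for any single check. The estimators themselves are vectorized
over trials, features and surrogates and scale to realistic electrode
counts without modification.

## Known limitations

* Causal projection of the filters (needed for real-time streaming use)
  is out of scope; predictions use the whole trial.
* The per-electrode filters are condition-specific; decoding *which*
  condition an unlabeled trial belongs to is not provided.
* The mTRF baseline is the only comparison method implemented; neural-
  network and probabilistic-graphical-model baselines are not included.
* The surrogate test randomizes target phases only; alternative surrogate
  schemes (feature-phase randomization, trial shuffling) are not
  implemented.
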