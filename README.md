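# cohdecode

Coherence-based spectro-spatial filters for decoding stimulus and task
dynamics from trial-aligned multichannel neural recordings (ECoG-style
data): finger-position traces from motor cortex, speech envelopes from
auditory cortex, or any continuous per-trial target signal.

## The method

Classic stimulus-reconstruction models (lagged ridge regression / mTRF)
assume stationarity within a trial and must expand the feature set with
lagged copies of every channel. `cohdecode` instead treats **each trial as
one realization of a random process** and estimates, per electrode, the
cross-trial complex coherence between a neural feature `x_j(t)` and the
target `y(t)`:

    C_j(f) = P_xy(f) / sqrt(P_xx(f) P_yy(f))

with the spectra averaged across trials (one full-length Hamming window per
trial, zero overlap). From the same spectra a per-electrode Wiener filter

    H_j(f) = P_xy(f) / P_xx(f)

captures, at every frequency, both the gain and the phase lag between
brain feature and target — no frequency bands or lags need to be chosen by
hand. Each filtered feature `x_j * h_j` is an estimate of `y`; a spatial
least-squares stage combines them:

    y(t) = Σ_j  b_j · (x_j * h_j)(t) + n(t)

The weight magnitudes `|b_j|` index electrode importance and, clustered
per condition (K-means) and classified (LDA), reveal whether different
conditions (fingers, words) recruit different electrodes.

The package implements the full chain: preprocessing (zero-phase 4th-order
Butterworth band-pass 0.1–200 Hz, 60 Hz notch, common average reference),
feature extraction (low-frequency components 0.5–40 Hz and the Hilbert
envelope of the 70–170 Hz high-gamma band, both at 200 Hz), the
coherence/Wiener estimator, a random-phase surrogate significance test,
blocked 5-fold cross-validation scored with Pearson's r and Lin's
concordance correlation coefficient, the discriminability analysis, a
nested-CV ridge-TRF baseline (λ grid 1e-6 · 1.848^n, 54 steps), and
ground-truth synthetic generators for every level of the pipeline.

## Worked example

```python
import numpy as np
from cohdecode import (coherence, cross_spectra, cross_validate,
                       random_phase_threshold, resample_to)
from cohdecode.preprocess import preprocess_trials
from cohdecode.synthetic import simulate_raw_level

# 30 trials, 8 channels at 1000 Hz; channels carry a quasi-periodic
# finger-flexion trace (1.5 Hz) additively in the low-frequency band and
# as amplitude modulation of a high-gamma carrier, at 10 dB in-band SNR.
trials, targets, truth = simulate_raw_level(
    n_trials=30, n_channels=8, snr_db=10.0, flexion_rate_hz=1.5, seed=0)

feats = preprocess_trials(trials, bands=("LFC", "HFBE"))
y = resample_to(targets, feats.fs)

res = cross_validate(feats, y, ["flex"] * 30, k=5)
print(f"held-out r   = {res.mean_r():.3f}")
print(f"held-out CCC = {res.mean_ccc():.3f}")

C = coherence(cross_spectra(feats, y))
coh2 = np.abs(C.C) ** 2
peak = np.argmax(coh2[0, 3:]) + 3
print(f"LFC ch00 coherence peak: {C.freqs[peak]:.1f} Hz, |C|^2 = {coh2[0, peak]:.2f}")
thresh = random_phase_threshold(feats, y, alpha=0.05, n_surrogates=500, seed=0)
print(f"significant bins on ch00 (LFC): {(coh2[0] > thresh[0]).sum()} of {coh2.shape[1]}")
```

Output:

```
held-out r   = 0.986
held-out CCC = 0.983
LFC ch00 coherence peak: 1.5 Hz, |C|^2 = 0.99
significant bins on ch00 (LFC): 22 of 201
```

The decoder reconstructs the flexion trace from held-out trials with
r ≈ 0.99; the coherence spectrum peaks exactly at the designed flexion
rate, and the surrogate test marks only the narrow band around the flexion
rhythm (and its low harmonics) as significant.

A command-line interface mirrors the library:

```bash
cohdecode simulate --preset finger --seed 0 --out D.h5
cohdecode evaluate --data D.h5 --bands lfc,hfbe --k 5 --out scores.csv
cohdecode coherence-report --data D.h5 --bands lfc --out coh.csv --plot coh.png
cohdecode discriminability --data D.h5 --bands lfc --top 2 --out disc.json
```

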