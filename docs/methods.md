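# Methods

This note documents the models, parameters and numerical choices behind
pcgkit, and what the synthetic-data experiments do and do not establish.

## Signal model and synthetic generator

A phonocardiogram beat is modelled as four consecutive intervals: the first
heart sound (S1), systole, the second heart sound (S2), and diastole.  The
generator emulates only the gross acoustic structure relevant to the
pipeline:

* **S1**: 120 ms Gaussian-enveloped sum of 30 and 45 Hz tones (envelope
  sigma = duration/6, unit peak).  **S2**: 100 ms at 50 and 70 Hz.
* **Systole**: 200 ms; **diastole**: 380 ms — a ~75 bpm cycle.  Both are
  silent in a normal beat.
* **Murmur** (abnormal class): white noise band-passed to 150–400 Hz,
  normalized to unit RMS and scaled by `murmur_amplitude`, injected into
  systole only — a systolic-murmur stand-in giving one well-controlled
  abnormality axis.  The amplitude is scaled after filtering, so zero
  amplitude leaves systole exactly silent.
* **Measurement noise**: white Gaussian, sd `noise_sd`, added everywhere.
* **Jitter**: each segment duration is scaled by an independent uniform
  factor in 1 ± `jitter_fraction` per beat, breaking exact beat alignment
  the way real rhythms do.

Defaults for dataset generation are `murmur_amplitude = 0.5`,
`noise_sd = 0.05`, `jitter_fraction = 0.1` at a native rate of 2000 Hz
(which exercises the 2:1 resampling step).  `beats_per_signal` defaults to
10 so that extracting the first 9 complete beats never depends on the final
diastole being complete.  All generation is driven by
`numpy.random.default_rng` seeds; identical seeds give identical bytes on
disk.

What the generator does **not** emulate: diastolic murmurs, S3/S4, sound
splitting, respiration and friction artifacts, sensor variability, and the
acoustic diversity of real pathology.  Synthetic experiments therefore
validate the machinery (segmentation, features, protocol), not clinical
accuracy; published accuracies on real databases are not claimed
reproducible from packaged data.

## Preprocessing

Signals are resampled to 1000 Hz by polyphase rational resampling
(alias-safe, exact for the 2:1 default) and band-pass filtered to
25–400 Hz.  The filter realization is a 4th-order Butterworth applied
forward-backward (`sosfiltfilt`): zero phase, so S1/S2 onsets are not
shifted, with stop-band rejection verified to exceed 20 dB both one octave
below the low edge and near the Nyquist frequency.  No amplitude normalization is applied by default — the
log compression in the features makes scale largely irrelevant — but
unit-variance scaling is available as a switch.

## Segmentation

The package ingests external per-sample state labels (the route a trained
hidden semi-Markov segmenter would provide; the synthetic generator's
ground truth uses the same path) and also provides a simplified envelope
segmenter for clean signals:

1. Shannon-energy envelope: normalize to unit peak, compute
   −x²·ln x² (0 at x = 0), average in a 20 ms sliding window.
2. Sound lobes = regions above 0.2 × the envelope maximum, extended
   outward while the envelope stays above max(0.02 × maximum, 2 × median)
   — the hysteresis attributes a burst's quiet tails to the burst while the
   median term keeps the extension above the noise floor.  Lobes closer
   than 50 ms are merged; lobes shorter than 20 ms are dropped.
3. S1/S2 pairing: of the two alternating inter-lobe gap populations, the
   longer mean gap follows S2 (diastole is longer than systole); ties label
   the first lobe S1.  Samples between an S1 and the next S2 get state 2,
   between an S2 and the next S1 state 4; leading/trailing partial
   intervals get the consistent neighbour state.

On clean synthetic signals the segmenter agrees with ground truth on ≈97%
of samples; agreement degrades monotonically with noise and collapses when
noise or murmur energy rivals the sound lobes (Shannon energy of a
0.5-amplitude murmur is comparable to S1's).  That is why experiments on
strongly abnormal synthetic cohorts use the ground-truth/ingestion route —
mirroring the practice of treating segmentation as an external, separately
trained component.  Beat enumeration is S1-anchored: a beat starts at an S1
onset and runs through the end of the following diastole; leading partial
cycles are skipped, and signals with fewer than 9 complete beats are
excluded from classification.

## Features

Frames are 24 ms with a 6 ms hop (18 ms overlap), anchored at each
segment's onset; only frames fully inside a segment are emitted, and a
segment shorter than one frame yields a single whole-segment frame.  Each
frame is Hamming-windowed, then zero-padded to the 64-point DFT (window
before pad; at 1000 Hz a frame is 24 samples, so padding is the only
consistent reading of a 64-point transform).  Filter power is pooled as

    P[m] = 10 log10( (1/N) Σ_{k=0..N/2} |X[k]|² |H_m[k]| ),   m = 0..19,

with the triangular responses H_m entering at their **first power** — a
deliberate fidelity choice; the conventional |H|² variant is available via
`response_power=2`.  The mean weighted power is floored at 1e−12 before the
log so silent frames stay finite.  The M = 20 filter centers are
equispaced on the Mel axis over 0–400 Hz and mapped to bin indices by
k = floor(f/f_s · N) (round-to-nearest available); at this resolution
adjacent centers can share a bin, and a degenerate triangle keeps its unit
peak.  The cepstrum is the unnormalized DCT-II; the first 13 coefficients
(including C[0], the overall log-energy term) are averaged over a segment's
frames, and the four segment descriptors are concatenated in the order
S1, systole, S2, diastole — 52 values per beat.

## Classification

`PcgStrategyClassifier` is a scikit-learn estimator taking
(n_signals, n_beats, 52) arrays.  Backends: kNN (Euclidean distance, k = 3
default; k must be odd, so with two classes neighbour votes cannot tie),
SVM (polynomial kernel, degree 3, C = 1 defaults; linear and Gaussian
kernels available), and a Gini decision tree with a fixed `random_state`
for determinism.  Features are z-scored with training statistics by default
(switchable).  In ensemble mode beat *j* of every training signal trains
model *j*, each beat inheriting its signal's label — the only consistent
reading when labels exist per signal.  The majority vote is exactly
"strictly more normal beats ⇒ normal, else abnormal"; over an odd committee
it is total, and the tie-breaking direction for even committees is
conservative (abnormal).

## Evaluation protocol

Per run: draw a fresh balanced subsample of normals (uniform, without
replacement, as many as there are abnormals), pool with the abnormals, and
run stratified 10-fold cross-validation, refitting a clone of the
classifier per fold — standardization statistics are computed on training
folds only, so no test information leaks.  The four metrics are computed
per fold from the confusion counts (abnormal positive) and averaged over
folds; runs are repeated (50 by default; experiments in this repository use
10) with run *r* seeded as `master_seed + r`, and the report carries metric
means over runs with mean ± 1.96·sd/√n confidence intervals (the normal
approximation matches the symmetric intervals this protocol is usually
reported with).  Fold redraw happens every run.  Percentages are rendered
half-away-from-zero at two decimals; note that the MAcc = (Se+Sp)/2
identity is maintained on unrounded values, which can disagree with
2-decimal arithmetic on the rounded Se/Sp in the last digit.

## Problem sizes and defaults used in packaged experiments

The parameter-recovery experiment uses 100 abnormal + 100 normal synthetic
signals and 10 protocol repeats — large enough that the balanced subsample,
stratification and vote machinery are all exercised while a full run stays
in the tens of seconds.  With `murmur_amplitude = 0.5, noise_sd = 0.05` the
ensemble SVM reaches ceiling accuracy (the murmur is a strong spectral
effect); with `murmur_amplitude = 0` the classes are identically
distributed and accuracy sits inside the 95% binomial band around 0.5.

## Known limitations

* The envelope segmenter assumes two dominant sound lobes per cycle and
  clean recordings; it is not an HSMM replacement and is not evaluated
  against expert annotation.
* The synthetic abnormality axis is one systolic murmur; effect sizes on
  real data will differ, and the SVM degree/C and standardization choices
  are configuration, not reproductions of any published setting.
* MFCCs capture spectral shape only; no temporal features are included.
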