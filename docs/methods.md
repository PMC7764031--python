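# Methods notes

## Data model and preprocessing

An `EEGRecording` is a `(trial, channel, sample)` tensor in
microvolts for one subject, with unique 10–20-system channel labels,
a sampling rate, and the number of seconds of pre-trial baseline
still attached at the head of every trial.  The reference geometry is
the common emotion-study format: 32 channels at 128 Hz, 60 s trials
plus a 3 s baseline (8064 samples per trial).  Validation rejects
non-finite samples, naming the offending trial and channel, because a
single NaN silently propagates through filtering into every feature
of that trial.

Downsampling applies a zero-phase 8th-order Butterworth low-pass at
0.4 × target rate before polyphase resampling.  The cutoff leaves the
gamma band (≤ 47 Hz) intact at the 128 Hz working rate while keeping
a guard band below the new Nyquist; upsampling is refused since it
cannot add information and would silently change feature counts.

Ratings on the conventional 1–9 scale are binarized at 4.5.  The
boundary case (a rating of exactly 4.5) is mapped to the high class;
the midpoint is not otherwise defined, so the ≥ convention is
declared and tested rather than left to float luck.  On-disk
interchange uses a minimal HDF5 container (`/data` float32,
`/channel_names`, `/fs`, `/baseline_seconds`, `subject_id` attr) —
float32 keeps round-trips bit-exact — plus EDF with a sidecar trial
table for continuous recordings.

## Band–electrode features

The four analysis bands are theta 4–7, alpha 8–12, beta 13–30 and
gamma 31–47 Hz; delta is excluded because slow-wave activity is not
informative for valence/arousal work and is easily contaminated by
residual drift.  Filtering is a 4th-order Butterworth band-pass
applied forward–backward (`sosfiltfilt`), i.e. zero-phase, so that
per-second windows on the filtered signal line up with windows on the
raw signal.

Each (trial, channel, band) stream is summarized by one value per
non-overlapping one-second window; a trailing partial second is
dropped.  The default statistic is **mean band power** (mean of
squared samples).  A per-second "mean" of a zero-mean band-passed
signal would be ≈ 0 and carry no information, so mean power is the
informative reading of a per-second average; `mean_abs` and
`mean_raw` are provided for sensitivity analysis.  Instances are
(trial, second) windows that inherit their trial's binary label and
are pooled over subjects (the subject-independent protocol).
Columns are ordered band-major within channel-major order and named
`<channel>_<band>`; 32 channels × 4 bands = 128 columns.

## The reversed-correlation selector

Redundancy is measured as absolute Pearson correlation: a perfectly
anti-correlated feature is just as redundant as a perfectly
correlated one, so |r| is the default (a signed mode exists behind a
flag).  The greedy procedure is:

1. pick the column minimizing the mean |r| to all other columns;
2. while |R| < N: among unselected columns, pick the one minimizing
   the mean |r| to the selected set R.

Ties within 1e−12 resolve to the lower column index in the canonical
ordering, making the selection deterministic.  Zero-variance columns
are removed (and reported) before selection because Pearson is
undefined for them; treating them as zero-correlation would make
dead channels maximally attractive.  Labels are never an input.
Correlations are computed over instances pooled across subjects,
consistent with the pooled cross-validation protocol.

A consequence of the greedy criterion worth stating plainly: from the
second step on, only the correlation *to the selected set* matters.
In data where many feature pairs are mutually near-uncorrelated, the
later steps are decided by sampling noise among near-zero
correlations, so "the selector finds the planted features" is only a
well-posed expectation when every non-planted feature retains some
correlation with every planted one.  The synthetic generator and the
clone fixture are designed around exactly this identifiability
requirement (below).

## Evaluation protocol

Stratified k-fold (default k = 10) on instances shuffled by a seed;
the partition is a function of (instance count, k, seed, labels)
only, and every channel set inside one experiment shares it.
Data-driven selection is refit inside each training fold, so the
held-out fold never influences which columns are used.  Columns are
z-scored with training-fold statistics before the SVM — RBF distances
on raw band powers would be dominated by the largest-amplitude band —
and the SVM uses C = 1 and `gamma="scale"` (1 / (n_features × var)),
both exposed; no hyperparameter search is performed.

Channel sets are compared on per-fold accuracies with a two-sided
Welch t-test (a paired variant is available by flag); significance is
p ≤ 0.05, and the gain convention is positive = reference better, in
percentage points.  When both fold vectors are (numerically)
constant, the p-value is defined as 1 if the means agree and 0
otherwise.  Fixed literature sets carry an emotion applicability tag;
a set requested for the other emotion yields a blank comparison row
rather than a misleading number.

## Synthetic EEG generator

Each channel is a sum over bands of
`amplitude × gain(second) × band-limited unit noise`, plus a 1/f
background (exponent 1.0, amplitude 3 µV) and white sensor noise
(1 µV).  Band-limited Gaussian noise rather than pure sinusoids gives
per-second band-power features realistic within-trial variance.
Default band amplitudes are theta 4, alpha 5, beta 3, gamma 1.5 µV —
a conventional rest-like spectral profile.

Structure:

* **Redundancy groups** share one latent band waveform per band,
  mixed as `w·latent + sqrt(1−w²)·own` (default w = 0.9, variance
  preserved), yielding the correlated electrode blocks the selector
  is supposed to avoid.  The default study uses four groups of eight
  neighbouring channels.
* **Per-second envelopes**: every band component's amplitude is
  multiplied by `exp(tau · h(second))` with τ = `envelope_scale`
  (default 0.5).  Planted components get independent standard-normal
  log-gains `z_i`; all non-planted components share the common factor
  `c = Σ z_i / sqrt(n_effects)` with log-variance share
  `envelope_leak` (default 1.0).  This is the identifiability device
  discussed above: it puts a positive correlation floor between every
  non-planted feature and every planted feature while the planted
  features stay mutually uncorrelated, so the greedy selector's later
  steps have a real signal to act on instead of a noise race.
* **Planted effects** multiply one (channel, band) amplitude by
  `amplitude_ratio` on trials whose latent class for the effect's
  emotion is 1 (power ratio = ratio²).  Planted pairs are excluded
  from group waveform sharing (`decorrelate_effects`).

Ratings are drawn uniformly from [1, 4.3] (class 0) or [4.7, 9]
(class 1); the guard band around 4.5 makes label recovery exact.

**Default study conditions**, chosen once for desk scale: 2 subjects
× 10 trials × 60 s at 128 Hz with 3 s baselines — 1200 one-second
instances — and three planted valence effects at `P8_alpha`,
`AF4_gamma`, `Cz_theta`.  The effect size was calibrated once against
the brute-force greedy oracle and frozen: with amplitude ratio 2 the
three planted features, which share the valence class, become
mutually correlated at ≈ 0.2 through the class itself and the
recovery property degrades; at ratio 1.5 with `envelope_leak` = 1.0
the full planted set is recovered across seeds while 10-fold RCA(3)
accuracy stays near 0.75.  No arousal effect is planted by default,
so arousal results on default data are an honest near-chance control.

What the generator does **not** emulate: volume conduction and
referencing, artifacts (ocular, muscular), non-stationarity beyond
the per-second envelopes, inter-subject variability in spectra, or
any topographic realism.  Passing tests therefore demonstrate that
the pipeline recovers the structure it is told to plant — they say
nothing about classification rates attainable on real recordings.

### Clone-matrix fixture

`make_clone_matrix` builds clone groups (shared latent + N(0, σ)
clone noise) plus mutually decorrelated singleton columns.  The
latent/independent basis is orthogonalized after centering, so the
"independent" columns have *exactly* zero pairwise Pearson
correlation while clones keep a small nonzero correlation to
everything through their clone noise.  With merely-random independent
columns, greedy recovery of the independent set would be a coin flip
among near-zero sample correlations (the identifiability issue
above); with the engineered-orthogonal basis it is deterministic for
any σ > 0, which is what a selector fixture should be.

## Determinism and numerics

One experiment seed is split into per-stage substreams
(`numpy.random.SeedSequence.spawn`: synthesis, evaluation), so stages
can be re-run in isolation; report payloads contain no timestamps and
repeated runs are byte-identical.  Problem sizes used throughout the
test-suite and the acceptance script are the default study conditions
(1200 instances) or smaller; the oracle-equivalence suite covers 100
random matrices of 4–20 columns and 50–500 rows with mixed covariance
structures.

Known limitations: the selector's O(p²) correlation matrix is
recomputed per fold (fine at p = 128; would need caching for
high-density montages); EDF support is read-only and requires a
sidecar trial table; only binary labels and the two-emotion
valence/arousal setting are modeled.
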