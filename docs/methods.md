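# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of the package.

## Problem setting

Polysomnography records EEG (derivation C3A2 referenced to the
contralateral mastoid), two EOG channels and a submental EMG. An expert
assigns each 20- or 30-s epoch one of five stages: W, N1, N2, N3, R.
Scoring conventions differ between laboratories: one dataset style scores
20-s epochs under AASM rules, another 30-s epochs under R&K rules, where
NREM stages 3 and 4 both correspond to N3 and "movement time" (MT) exists
as a label. The package harmonizes labels (3/4 → N3; MT → majority of the
flanking epochs, tie → W, since MT epochs are artifact-dominated and wake
is the conservative fallback), converts epoch grids by maximal time
overlap (ties toward the earlier source epoch), and resamples all signals
to a common 128 Hz with polyphase anti-alias filtering (downsampling
only). High-pass differences between laboratories (0.16 vs 0.5 Hz) are
deliberately *not* equalized: classifiers should tolerate equipment
differences.

## Feature pipeline

Welch power spectral densities use non-overlapping 5-s Hann windows with
per-window mean detrending — four windows per 20-s epoch, six per 30-s
epoch — giving 0.2 Hz resolution at 128 Hz. The scaling satisfies
Parseval (integral of the PSD equals the mean square of the signal).
Spectrograms crop to 0.8–40 Hz (197 bins).

The 20 per-epoch features cover every class of marker an expert uses:
log band powers (slow oscillation 0.8–1, delta 1–4, theta 4–8, alpha
8–12, sigma 12–14, beta1 14–20, beta2 20–30 Hz), four log band ratios,
the 95 % spectral edge, log total power, the epoch amplitude range
(p99 − p1), EOG lag-0 cross-correlation after 0.3–5 Hz band-passing (eye
movements appear with opposite polarity on the two EOG channels, so this
feature goes negative during eye-movement activity), log EOG slow
(0.3–2 Hz) and fast (2–6 Hz) band powers, a rapid-eye-movement event
count (excursions of the band-passed EOG difference beyond ±25 µV), log
EMG 15–30 Hz power, and EMG power relative to its recording median. Band
edges are half-open [lo, hi) except the final 40 Hz edge; logs use
log10(x + 1e−12) so silent epochs stay finite. No epochs are excluded —
artifacts carry stage information (movement accompanies wake).

## Classifiers

**Random forest.** 500 trees, bootstrap resampling, √20 features per
split, unlimited depth, fixed seed (scikit-learn backend). Per-epoch
posteriors are tree-vote fractions; classes absent at training get
probability 0.

**HMM smoothing.** Stage bigram counts pooled over training hypnograms
with add-1 smoothing give a strictly positive 5×5 transition matrix,
initial distribution and stage priors. The decoded path is the global MAP
(Viterbi, log space) rather than per-epoch marginals, because a MAP path
is itself a valid stage sequence — the point of smoothing. Emission
scores are posterior/prior (the standard hybrid-classifier rescaling of
posteriors into likelihoods). Ties break toward the lower stage index in
(W, N1, N2, N3, R).

**Median filter.** The 3-epoch window is operationalized as: replace an
interior epoch if both neighbours agree on a different stage, otherwise
keep it; first/last epochs unchanged; single pass. This equals a true
running median whenever the window has a repeated value (every window-3
case that matters) and avoids imposing an arbitrary numeric order on the
stages.

**Feature LSTMs.** Three stacked LSTM layers (8, 16, 32 or 128 units,
uni- or bidirectional; bidirectional doubles the output width), dense
5-way head. Inputs are the 20 features or the 197-bin log spectrogram,
standardized with training-set statistics stored in the model. The
catalogue instantiates all eight unit-count × directionality
combinations; six are flagged as the published set (the published count
of six does not identify which two of the eight are excluded, so the flag
is a convention, not physics).

**CNN-LSTMs.** One convolutional block per raw channel; EOG channels get
*separate* blocks because their mutual correlation distinguishes
eye-movement types. The plain block has 11 conv layers (kernel 7, stride
1, ReLU, max-pool 2 after every second layer, widths doubling 16→64 at
each pool) followed by global average pooling, so each 2560-sample epoch
maps to one feature vector. The residual variant has an input conv plus
nine two-conv residual units (19 weight layers) at constant width 32 with
pooling after every second unit; skip connections keep gradients usable
at this depth. All widths scale with a `width_multiplier` so desk-scale
tests can run the same topology reduced. The EMG enters as one scalar
per epoch (15–30 Hz power, log-standardized) appended after the conv
features. Two bidirectional 32-unit LSTM layers with batch normalization
before, between and after produce the 5-way output. Conv hyperparameters
(kernel length, pool schedule, widths) are this package's choices — the
architecture family fixes only layer counts and the LSTM head.

**Training.** Cross-entropy loss minimized with Adam (step 1e-3, batch 32
sequences of 8/32/128 epochs; one "iteration" = 100 sampled batches by
default, reduced in the test configurations). Sequence starts are drawn
uniformly at random, so sequences may intersect and far more sequences
are available than a disjoint tiling would give. Class imbalance is
handled by inverse-frequency weighting of the loss (N1 is scarce);
switchable off. No early stopping by default — a fixed iteration count is
run, with optional best-validation checkpointing. Temporal memory is
deliberately capped at the sequence length: global night architecture
must not bias scoring of naps or pathological sleep, and the test suite
verifies outputs are bit-independent of epochs outside the window (batch
normalization uses running statistics at inference for exactly this
reason). The networks run on a small reverse-mode autodiff tape over
NumPy arrays (float64) written for this package; gradient correctness is
verified against central differences in the test suite.

**Whole-recording scoring** tiles sequences with half-window overlap and
averages probabilities before the argmax; recordings shorter than one
sequence are padded by repeating the last epoch (with a warning).

## Evaluation

Cohen's kappa is the primary metric (chance-corrected, ≤ 1, can be
negative; ≥ 0.8 is conventionally "excellent"). Per-stage kappas binarize
to stage-vs-rest. A stage absent from a recording's reference leaves that
recording's entry *undefined* — N3 is frequently never reached in MSLT
naps — and undefined entries are excluded from the stage's across-recording
mean ± sd (sample sd, n−1; recordings weighted equally). F1 per class is
reported for comparability; it is not chance-corrected.

## Synthetic data generator

The generator defines the study conditions for all tests.

**Hypnograms** come from a semi-Markov chain: geometric bout durations
with per-stage means (healthy defaults, in minutes: W 3, N1 1.2, N2 9,
N3 6.5, R 10), then a transition drawn from a weight row with the
diagonal removed. Wake exits only to N1, so nights enter sleep through
N1. Entry into R is multiplied by a sinusoidal gate of period 90 min
(positive half-wave, first opening near the end of the first hour), which
produces the NREM–REM cyclic alternation — a plain per-epoch Markov chain
cannot. Over 200 simulated nights the detected mean cycle period (REM
onset to REM onset, episodes ≥ 2 epochs, ≥ 30 min apart) lies in the
90-minute range, and stage proportions are textbook-like (N2 modal,
N1 < 15 %). The patient profile doubles inter-stage transition pressure,
halves bout durations, removes the REM gate and permits N1→R, so
fragmented sleep and sleep-onset REM (as in narcolepsy) occur; the MSLT
protocol forces wake outside five 20-min nap windows spaced 90 min apart
over a 9-h day.

**Signals** are additive: 1/f Gaussian background, quasi-sinusoidal alpha
(10 Hz) and theta (6 Hz) oscillations, band-limited 0.5–4 Hz slow-wave
noise (42 µV RMS in N3, comfortably exceeding the 75 µV peak-to-peak
scoring criterion), Poisson-arriving Hann-enveloped spindle bursts
(13 Hz) and REM sawtooth bursts (3 Hz ramp), EOG events (blinks, slow
rolling movements, rapid-eye-movement deflections) injected with
coefficient −0.9 on the opposite channel plus 0.3 EEG crosstalk, and
white-noise EMG with variance ordered W > N1 ≥ N2 ≥ N3 > R (atonia).
Every component amplitude is scaled per epoch by a mean-one lognormal
factor (σ = 0.4), and the first epoch of each bout mixes in 30 % of the
previous stage's signal. These two choices are what make the problem
realistically hard: without them a classifier is perfect and smoothing
has nothing to do; with them raw per-epoch accuracy drops to the
high-0.8 kappa range with N1 weakest and transition epochs ambiguous —
the structure reported for human inter-rater agreement.

**What the generator does not emulate:** ECG contamination and electrode
artifacts, age- or drug-dependent EEG changes, K-complexes as distinct
from spindles, respiration/position effects, inter-subject montage
variability. Passing tests therefore demonstrate that the pipeline's
machinery is correct and well-calibrated on signals with the right
spectral statistics, not that clinical-grade accuracy transfers to real
patients.

## Experiment design

Splits are subject-disjoint: subjects are shuffled under a seed and
allocated by largest-remainder rounding, so the reference design of 18
subjects × 3 nights at 70/15/15 gives exactly 36/9/9 recordings. The
mixed regime adds 19 patient recordings (whole patients) to training and
evaluates on the held-out patients plus the healthy test part. Its
reference totals (73 training, 33 evaluation) imply that *all 54* healthy
recordings train while the 9-recording healthy test part is re-used for
evaluation; the default reproduces those totals and flags the overlap
explicitly (`SplitPlan.allow_overlap`), and a strict variant
(`healthy_training="train"`, 36 + 19 = 55) keeps the healthy evaluation
subject-disjoint. Healthy-part scores under the default reading are
optimistic; the patient part, which carries the regime's conclusions, is
unaffected. Every run writes a manifest (config hash, seed, versions) and
re-running an identical config reproduces the reports bit-for-bit.

## Scale of the shipped test configurations

The test and acceptance configurations run the full algorithms at reduced
problem sizes chosen once for single-CPU execution: label recovery uses
16 one-night subjects (12 train / 4 test, full 8-h nights, 20-s epochs,
500 trees); the LSTM smoke runs 50 iterations × 20 batches on five 90-min
recordings; the CNN-LSTM overfit uses width multiplier 0.25 on two 40-min
recordings; the sequence-length study uses 2-h fragmented nights. Full-
size training (width multiplier 1, 100 batches/iteration, 54-night
datasets) uses the identical code paths.

## Known limitations

* The 20-feature set is this package's concrete instantiation of the
  published feature *categories*; the original exact list is not public.
* The HMM's published parameterization is likewise not public; bigram
  add-1 estimation with posterior/prior rescaling is the standard
  construction and is documented as such.
* The NumPy networks are exact but not fast; GPU-scale replication is out
  of scope.
* Per-stage kappa via one-vs-rest binarization is the standard
  construction consistent with per-stage reporting, but other
  constructions exist.
* The EDF codec writes/reads the plain 16-bit format with one-second
  records; EDF+ annotations are not parsed.
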