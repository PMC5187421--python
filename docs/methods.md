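# Methods

`phonrestore` analyses neural phoneme restoration: the illusion in which a
speech sound that has been completely replaced by noise is nevertheless
"heard", and — in intracranial recordings — reconstructed by auditory cortex
in real time. The package implements the full analysis chain on synthetic
recordings with planted ground truth, because patient ECoG data of this kind
are not publicly deposited.

## The generative model

The synthetic module emulates the experimental design at the spectrogram and
field-potential level; it does not attempt acoustic realism, coarticulation,
or behavioural response-time modelling.

**Stimuli.** A word-pair triplet consists of two spectrograms (32 log-spaced
bins, 200–8000 Hz, 100 frames/s, 0.8 s word) that are bitwise identical
except inside the critical-phoneme window (default 0.30–0.50 s after word
onset): `orig1` carries elevated power in a high-frequency contrast band
(3–8 kHz, a fricative-like component), `orig2` a complementary bump one
octave below. The noise version replaces the whole critical-phoneme segment
with 1/f-distributed power (power ∝ 1/f with chi-squared fluctuations),
scaled so its RMS matches the mean RMS of the two excised segments —
mirroring how such maskers are constructed from RMS-matched 1/f noise. The
default 200 ms critical phoneme is at the long end of natural phoneme
durations; it gives the restoration effect a resolvable temporal support
given the 150 ms latency below.

**Neural drive.** Each electrode's high-gamma drive is a linear
spectrotemporal (STRF) convolution of the driving spectrogram: Gaussian
log-frequency profiles with exponentially decaying temporal kernels
(~80 ms integration), unit-normalized and scaled so single-trial responses
reach a few baseline SDs — the range in which electrode-selection z
thresholds of 1–2.25 are meaningful. STG-labelled
electrodes carry STRFs — a configurable subset tuned inside the contrast
band ("effect" electrodes) — while frontal electrodes (IFG, precentral,
postcentral) carry none.

**Planted effects.** Two independent knobs:

* *Restoration* (`restoration_gain` g ∈ [0,1], `restoration_latency`
  150 ms): on noise trials the drive is mixed toward the drive evoked by the
  *perceived* original, `(1−g)·noise + g·perceived`, for response times ≥
  critical-phoneme onset + latency. Mixing operates on the drive rather
  than the stimulus because the three stimuli are identical outside the
  critical phoneme — a spectrogram-level mix after the latency point would
  be a no-op. The latency stands in for the response lag with which
  auditory cortex reflects (and restores) phoneme content.
* *Pre-stimulus bias* (`bias_amplitude`, `bias_window` = (−0.3, 0) s before
  the critical phoneme): a latent state b ∈ {+1, −1}, drawn per noise
  trial, adds a raised-cosine amplitude offset on a designated frontal
  electrode subset, and the reported percept follows the state with
  probability `percept_bias_strength` (default 0.85). The probabilistic
  link is a modelling choice; the source phenomenon is only reported as
  "classifiable", so any monotone link would do, and 0.85 keeps labels
  informative but noisy, as single-trial reports are.

**Voltage synthesis.** The drive (plus a smooth ongoing background
fluctuation, SD 0.3, ~20 ms correlation length — real high-gamma baselines
fluctuate with ongoing activity, and without this the per-trial baseline SD
is a near-constant carrier artifact and z-scores explode) modulates a
per-electrode sinusoidal carrier at a random frequency in 80–140 Hz, with
white measurement noise (SD 0.3) added, sampled at 1 kHz. Bias electrodes
are scattered across grid rows so row-wise re-referencing cannot cancel the
bias. Defaults emulate a 16×16 grid at 4 mm pitch with ~12 presentations
per stimulus version; tests and the acceptance script run reduced grids
(4×4 to 6×6) and up to 40 trials/condition, the sizes at which the planted
effects are resolvable on one CPU.

What the generator does **not** emulate: spectral shape of real speech,
electrode covariance/volume conduction, non-Gaussian artifacts, cross-trial
adaptation or priming, and any link between bias and *original* trials.
Passing tests therefore certify the statistical machinery and its
calibration, not performance on real recordings.

## Preprocessing

Channel rejection by robust z-score of log-variance (median/MAD, cutoff 5),
common average reference across electrode-grid rows (good channels only),
70–150 Hz band-pass with a symmetric (zero-phase) FIR filter whose
transition width is 10% of the band edges, Hilbert-envelope extraction, and
boxcar anti-alias decimation to 100 frames/s (preserves nonnegativity and
alignment to ±1 frame). Epochs are cut relative to word onset and z-scored
per electrode and trial against the trial's own 500 ms pre-stimulus
baseline (a pooled-baseline mode is available). A single 70–150 Hz band is
used rather than an average over sub-bands; the sub-band averaging used by
some laboratories is a configuration away but not the default.

## Restoration index

Electrodes are selected per word pair where the |orig1 − orig2| trial-mean
difference exceeds a z threshold (default 1.5, studied range 1–2.25) at any
frame between critical-phoneme onset and word offset. Per selected
electrode, frame j and percept, distances are Euclidean norms over
trial-mean traces in a 5-frame (50 ms) window centred on j:
D1 = ‖noise − orig1‖, D2 = ‖noise − orig2‖, D0 = ‖orig1 − orig2‖, and

    RI = (D2 − D1) / D0.

RI is +1 when the noise response equals the orig1 response, −1 at orig2,
0 at the midpoint, and lies in [−1, 1] by the reverse triangle inequality.
Frames with D0 = 0 are emitted as missing. Where D0 is small (outside the
response window) RI is a ratio of noise terms — bounded, but uninformative;
the group statistic handles this by baseline referencing.

Bootstrap criteria: 99% percentile CIs of the condition trial means (1,000
resamples by default), with "≠" = disjoint CIs and "=" = overlapping CIs,
evaluated for Orig1≠Orig2, (Orig1=Noise1)&(Orig1≠Noise2) and
(Orig2=Noise2)&(Orig2≠Noise1); for non-bistable pairs the clause against
the empty percept cell is dropped.

Group aggregation: bistable pairs contribute |RI_p1 − RI_p2| per
electrode/frame; non-bistable pairs the RI of the observed percept, signed
positive toward the perceived word. Each electrode's pre-critical-phoneme
mean is subtracted and each frame tested with a one-sided one-sample t test
across electrodes, Benjamini–Hochberg corrected over the 91 frames of the
−0.3…+0.6 s analysis window at 100 Hz. The baseline reference is essential:
raw |ΔRI| is nonnegative with a nonzero null mean, so a test against zero
would be vacuous; referencing also makes the test conservative at frames
where D0 is large (RI concentrates, |ΔRI| shrinks below its baseline).

## Stimulus reconstruction

Decoding filters map lagged responses (lags −300…0 ms; reconstruction at
time t uses responses from t to t+300 ms) to each spectrogram bin, fit by
ridge regression on a continuous speech-like training corpus (2–8 Hz
envelope rhythm, 1/f spectral profile) — never on the word triplets,
mirroring decoder training on separate passive-listening sessions. Corpus
responses are z-scored per electrode so the filters live in the same units
as the baseline-z-scored epochs they are applied to. The lagged design is
heavily rank-deficient (smooth envelopes make neighbouring 10 ms lag copies
nearly collinear), so the solver works through an SVD of the design matrix:
penalties act on singular values, the zero-penalty limit is the
pseudoinverse, and blocked cross-validation (5 contiguous folds, log grid
scaled to the top singular value) can select the penalty.

Epoch reconstructions are *centred*: filters are applied to the z-scored
trial-mean responses without adding the corpus-mean spectrum back. Adding
that intercept would inject a static, stimulus-independent spectral prior
into every reconstruction, which dominated region-restricted fidelity
comparisons; with centred reconstructions all metrics are computed on the
linear scale. Fidelity metrics per word pair: pairwise 2D correlations
(Pearson on the flattened freq × time matrices over the whole word — the
critical-phoneme-only variant is a parameter), a discriminative frequency
set (bins at or above the 90th percentile of the |orig1 − orig2|
critical-phoneme difference of the *true* spectrograms, ties included),
per-group critical-phoneme spectra, Euclidean distances on the
discriminative set, and a two-sided Mann–Whitney U across word pairs
comparing same-percept with cross-percept distances (skipped with a warning
below two pairs). Region-restricted variants refit the decoder on an
electrode subset (e.g. STG-only, frontal-only).

## State space

PCA on the (frames·trials) × electrodes matrix after column mean-centering
only (inputs are already in baseline-z units). Scores are reshaped back to
frames × trials; per-condition/percept mean trajectories are attached.
Component signs are fixed so the maximum-|weight| electrode is positive.
The analysis is deliberately descriptive — no inferential statistics are
attached in PC space.

## Classification

Per frame, features concatenate all electrodes over a symmetric 110 ms
window (truncated at epoch edges); a linear SVM (C = 1, identical
everywhere) is trained per leave-one-out fold. Accuracy is the fraction of
held-out trials matching the label (stimulus word for original trials,
reported percept for noise trials; chance 50%). Per-electrode squared
coefficients are averaged over the window's lag copies and across folds.
Temporal generalization trains at one window per fold and tests every frame
where a full window fits (truncated windows would change the feature
dimension; those frames are NaN).

Weight localization averages squared weights in pre (−0.3…0 s) and post
(0…0.3 s) windows around critical-phoneme onset, runs a three-way
fixed-effects ANOVA (hemisphere × location × condition, type-II sums of
squares; supra-Sylvian = IFG/precentral/postcentral, sub-Sylvian =
STG/MTG/other) per window, and Welch t tests for noise-vs-original
contrasts within location groups, Bonferroni-adjusted over the contrasts.
Degenerate all-equal weights define F = 0 and t = 0 explicitly rather than
0/0.

## Numerical and design notes

* Time is in seconds relative to word onset; frames are half-open
  `[onset, offset)`; conversions are centralized in one module.
* All randomness flows from `numpy.random.Generator` objects seeded from a
  single configured seed via `SeedSequence` spawning; identical
  configurations give byte-identical pipeline reports.
* When windows touch array bounds, distance windows truncate (both the
  implementation and its brute-force oracle define them that way).
* Classifier accuracy "above chance" in the recovery experiments means a
  one-sided binomial p-value below 0.05 after Bonferroni correction over
  the evaluated frames (a max-over-frames detector needs multiplicity
  control). Weight localization compares the pre-window mean squared
  weight on the bias electrodes directly against the mean over all other
  electrodes; under the null this comparison is not a coin flip, because
  null-classifier weights concentrate on the strongly stimulus-driven
  (high trial-variance) electrodes rather than the quiet frontal set.
* The per-timepoint classifiers run per word pair; accuracies are averaged
  across pairs afterwards.

## Known limitations

The RI formula is one admissible reading of "relative distance normalized
by the originals' separation" (the properties ±1 at the originals and an
arbitrary sign convention do not pin down a unique form). The windowed
trial-mean trace resolves the pooling ambiguity in "Euclidean distance at
each time point". Synthetic calibration results bound false-positive rates
under this generator's noise model only; heavy-tailed artifacts in real
recordings would require the (stubbed) time-segment rejection that is out
of scope here. Single-"subject" runs only: cross-subject pooling is not
modelled.
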