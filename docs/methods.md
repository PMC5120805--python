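# Methods

## Signal model and front end

Flight calls are modeled as single-note FM vocalizations of 50–150 ms
confined to 2000–11025 Hz. The front end computes a log-scaled
mel spectrogram with 40 triangular bands over that range, from a
256-sample (11.6 ms) symmetric Hann window hopped by 32 samples
(1.45 ms) at 22050 Hz, with no frame padding, so a clip of N samples
yields `1 + floor((N − 256)/32)` frames. Log compression is the
natural log of (band power + 1e-10); the floor keeps digital silence
finite. The mel dialect is configurable (`mel_style`:
Slaney-style area-normalized triangles on the power spectrum by
default, HTK optional; `spectrum`: power or magnitude) because the
dialect materially changes band weights and should be an explicit
choice, not an accident of a library default. The symmetric (rather
than periodic) Hann taper is used so that time-reversing a clip
reverses its frame sequence exactly — a property the test suite
exploits — at negligible spectral cost.

TF-patches are `patch_frames` consecutive frames flattened band-major;
patch durations quoted in milliseconds are frame multiples of the hop
(92.9 ms ↔ 64 frames, 23.2 ms ↔ 16 frames). Encoding uses a default
stride of 1 frame (maximally overlapping); codebook learning may
subsample patches to a seeded cap (default 250 000) to bound k-means
cost.

Clips shorter than the 150 ms trim target raise an error in
`trim_center` (an explicit reflect-pad option exists, off by default).
Off-rate or multichannel WAV input is canonicalized (channel-mean
downmix, polyphase resampling) rather than rejected.

## Feature learning

Whitening keeps the fewest principal components explaining 99% of the
training-patch variance and scales each to unit variance (verified on
the fit set to 1e-6 relative). Test-time patches always use
training-time parameters.

Spherical k-means is implemented exactly as the three-rule loop:
absolute-dot-product assignment (at most one non-zero per code vector,
storing the signed dot product), the damped additive update
`D := XSᵀ + D`, and column renormalization. Centroids are initialized
from a standard Normal and normalized; a single integer seed drives
initialization and patch subsampling and is stored in the codebook.
Design points the loop fixes deliberately:

- **Stopping** — the loop stops when the assigned-index vector repeats
  or after `max_iter` (default 100). An optional centroid-movement
  tolerance (`tol > 0`) replaces the assignment criterion, letting the
  damped update iterate to its fixed point (needed e.g. for k = 1,
  where assignments are trivially stable from the first sweep).
- **Empty clusters** — the additive damping leaves an unassigned
  centroid unchanged; no re-seeding by default (a `reseed_empty` flag
  exists).
- **Ties** — argmax ties break to the lowest codeword index.
- Over-complete codebooks (k larger than the dimension or the sample
  count) are supported.

## Encoding and pooling

`F = MᵀD` exactly; pooling concatenates the requested statistics in
the fixed canonical order mean → std → max, each over all k codewords
(stat-major), so serialized feature tables are portable. Standard
deviation uses the population convention (divide by m), making a
single-patch clip pool to 0 rather than NaN. Feature standardization
is per-dimension z-scoring with training-set mean/std; zero-variance
dimensions are centered and passed through with divisor 1.

## Classification

RBF-kernel SVM (scikit-learn SVC) on standardized pooled features.
The kernel width uses the `gamma="scale"` heuristic (1 / (d·var)), a
declared choice recorded in the model, since nothing in the method
pins it; multiclass decomposition is SVC's one-vs-one. Probabilities
come from Platt scaling (sigmoid calibration) fitted by internal
3-fold CV on the training portion — calibrating on the raw fit
overfits the probabilities; when a class has fewer than 2 training
instances per fold the calibrator falls back to fitting the sigmoid on
the training decision values directly. Monitoring models are trained
with equal weight per datum: under season/location mismatch the
training class balance is the only available estimate of the test
distribution.

The MFCC baseline extracts 25 coefficients per frame (orthonormal
DCT-II of a full-band 40-channel log-mel spectrogram at the same
window/hop) and pools them with a fixed, documented set of 11
statistics: min, max, median, mean, variance, skewness, kurtosis, and
mean/variance of the first and second frame differences — 275
dimensions total. Skewness/kurtosis guard zero-variance coefficients
(returning 0) so silence yields a finite, deterministic vector.

## Hyperparameter search

Grids: `d_patch ∈ {1.45, 5.8, 11.6, 23.2, 46.4, 92.9, 185.8} ms`,
`k ∈ {128, 256, 512, 1024, 2048}`, `f_stat ∈ {{mean,std}, {max},
{mean,std,max}}`, `C ∈ {1, 10, 100, 1000}` — 420 points; scored per
fold in the N-class scheme this yields 2100 validation scores.
The N-class scheme is nested: stratified 5-fold outer CV; inside each
fold a stratified 75/25 train/validation split (the validation
fraction is a declared choice) scores every grid point, the best point
refits on the full fold-train and is scored on the fold-test, and the
final score averages the five folds. The monitoring scheme runs the
same search on a single stratified 75/25 split of the training season.
Ties break toward the earliest grid point in declared order. Front-end
work is shared across the grid (whitening per patch duration, codebook
per (duration, k), one encoding pass for all three pooling sets), so
only the C axis costs an SVM fit each.

Every fitted component records the fingerprints of the clips it was
trained on; the test suite asserts fold-train/fold-test disjointness
through those fingerprints rather than trusting the splitter.

## Evaluation

Overall accuracy is trace/total of the confusion matrix; per-class
accuracy is the diagonal over row sums. ROC and PR curves enumerate
all distinct score thresholds (scikit-learn), AUC by the trapezoid
rule; both are cross-checked against brute-force threshold enumeration
in tests. Threshold selection: `default` = 0.5; `f1_train` and
`oracle` maximize f1 exactly over all distinct scores plus {0, 1} (no
grid approximation), differing only in whether training- or test-set
labels are supplied.

Detection curves count above-threshold clips per local calendar date
(ISO-8601 timestamps; the date part defines the day); the reference
curve counts expert-labeled positives the same way, so its total
equals the number of labeled positives. Curve agreement is Pearson r
with df = n − 2; a zero-variance curve is an explicit error.

SNR per clip: mean band-limited (2000–11025 Hz) STFT power over the
central 150 ms versus the remainder, `SNR_dB = 10·log10(P_call /
P_background)`; a time-domain Butterworth band-pass alternative sits
behind a flag and agrees with the spectral route to within ~2 dB on
realistic scenes. The estimate is scale-invariant. TP-vs-FN SNR
distributions are compared by the two-sample KS test with the
asymptotic two-sided p-value; SNR–confidence association is Pearson r
over the positive clips.

## Synthetic data: what it emulates, and what it does not

The generator reproduces dataset *structure*, not bioacoustic
realism: six contour families (down-sweep, up-sweep, V, inverted V,
two-peak, modulated tail) with seeded jitter on anchors and duration;
FM synthesis with a raised-cosine envelope; backgrounds of white
noise ("quiet"), pink noise ("wind"), an AM tone cluster ("insect")
and a peeper-like repeated rising note that overlaps the target call's
band — the analogue of the frog chorus that dominates field false
positives. The template detector is zero-mean normalized spectrogram
cross-correlation, rectified at 0 so scores lie in [0, 1] (the
field systems' normalization is not documented; ZNCC is the declared
choice), with local maxima above threshold 0.6 emitting centered ~1 s
clips.

Scene SNR semantics deserve care. The center-vs-rest estimator applied
to a mixed clip is bounded below by ~0 dB when the background is
stationary, because the call window itself contains background. The
mixer therefore supports two modes: `measured` (default) calibrates the
background gain in closed form so the estimator applied to the mix
returns the requested value — feasible only above that floor, raising
otherwise — and `call` interprets the request as the pure
call-to-background power ratio, which may be arbitrarily negative and
is how buried calls are generated. The closed-loop property (request
vs estimate within 0.5 dB) holds across 1–30 dB in `measured` mode.

Study conditions (the generator defaults): the N-class experiment uses
4 archetypes × 40 clips (300 ms scenes, quiet/wind, 5–25 dB, trimmed
to 150 ms) with a stratified 25% holdout. The monitoring experiment
trains on a fall-like season (90 target / 70 other-call / 140 reject
clips, quiet/wind/insect, call-mode −5..+18 dB — training clips come
from the same detectors and so also contain partially buried calls)
and tests on a 57-day spring-like season: 150 positives following a
Gaussian pulse (peak day 28, σ = 7 days), ~6 negatives per night,
peeper backgrounds appearing only in spring, positives at call-mode
−12..+15 dB so that quietness is the dominant failure factor, and 20%
of test calls drawn with doubled jitter ("unusual variants"). Problem
sizes keep the full run under a minute while leaving ~120 positive
test clips for the error-analysis statistics.

What passing these experiments does **not** show: synthetic archetypes
are far more separable than real inter-species variation (43 wild
species will not reach the synthetic accuracy), the background library
cannot stand in for real soundscape diversity, and detection-curve
correlations on synthetic seasons say nothing about absolute count
reliability in the field. The KS and correlation magnitudes of the SNR
error analysis are stochastic across seeds at this problem size; only
their sign/qualitative recovery is asserted.

## Known limitations

- No streaming spectrogram computation, denoising, augmentation, or
  neural models; the Random Forest branch of the original search is
  out of scope (the margin classifier was always selected).
- `load_clip` reads WAV only (PCM 8/16/24/32 and float); other
  containers must be converted upstream.
- The damped k-means update never re-seeds empty clusters by default,
  so with adversarial initialization some codewords may stay unused;
  this is the printed update's behavior, kept deliberately.
- Platt calibration assumes enough per-class data for internal CV;
  with fewer than ~6 clips per class probabilities are poorly
  calibrated (the fallback path is exercised but not recommended).
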