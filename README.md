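# flightcall

Machine listening for nocturnal bird-migration monitoring: unsupervised
codebook feature learning on mel-spectrogram patches, margin-based
species classification, and the evaluation machinery for both the
closed-set *N*-species problem and the open-set continuous-monitoring
problem — exercisable end to end on synthetic flight-call audio.

## The problem

Migrating songbirds emit short (~50–150 ms) frequency-modulated flight
calls, mostly at night, in the 2–11 kHz band. Remote acoustic sensors
run cheap spectrogram-template detectors that emit ~1 s clips whenever
the cross-correlation score exceeds a threshold; the vast majority of
those clips are false triggers (wind, insects, frogs, other species).
The classification task is to decide, per clip, whether it contains the
target species' flight call — and, aggregated per calendar day, to
recover the species' migration timing curve.

## The model

1. **Front end** — log-scaled mel spectrogram, 40 bands over
   2000–11025 Hz, 11.6 ms Hann window, 1.45 ms hop at 22050 Hz, sliced
   into overlapping 2-D time-frequency patches (TF-patches) of
   `d_patch` frames, flattened.
2. **Feature learning** — PCA whitening (fewest components explaining
   99% of training-set variance), then *spherical k-means*: codewords
   constrained to the unit sphere, learned by looping

   ```
   s_j(i) = D(j)ᵀx(i)  if j = argmax_l |D(l)ᵀx(i)|, else 0
   D     := X Sᵀ + D
   D(j)  := D(j) / ‖D(j)‖₂
   ```

   until the assignment vector stops changing. The k centroids form an
   over-complete dictionary D ∈ ℝ^{n×k}.
3. **Encoding** — per clip, F = MᵀD (M = whitened patches of that
   clip); each column of F is the match-score time series against one
   codeword, pooled over time by summary statistics
   (mean/std/max) into a fixed k·l vector.
4. **Classification** — features standardized with training-set
   statistics, RBF-kernel SVM, confidences by Platt scaling of the
   decision values. Hyperparameters (`d_patch`, `k`, `f_stat`, `C`) by
   nested grid search: stratified 5-fold CV for the N-class regime, a
   train/validation split for the season-mismatched monitoring regime.
5. **Evaluation** — accuracy/per-class/confusion; ROC-AUC and PR
   curves; threshold selection (default 0.5, f1-optimal on train,
   oracle); daily detection curves and their Pearson correlation with
   the expert reference; SNR error analysis with
   `SNR_dB = 10·log10(P_call / P_background)` computed from
   band-limited power in the clip's central 150 ms versus the rest,
   compared TP-vs-FN by a two-sample Kolmogorov–Smirnov test.

A synthetic generator (`flightcall.synth`) provides species-like call
archetypes, background scenes (wind, insects, a peeper-like confounder
that spectrally mimics the target call), a sensor-side template
detector, and dataset builders with exact class counts and
season-mismatched splits, so the whole pipeline runs without any
field recordings.

## Worked example

```python
from flightcall import FlightCallModel, HyperParams, PoolingSpec, synth_call
from flightcall.synth import CallArchetype

down = CallArchetype("down", "down", 7000.0, 4500.0, 100.0)
up = CallArchetype("up", "up", 4500.0, 7000.0, 100.0)
clips, labels = [], []
for i in range(8):
    for arch in (down, up):
        clips.append(synth_call(arch, seed=10 * i + (arch.species == "up")))
        labels.append(arch.species)

hp = HyperParams(d_patch_ms=23.2, k=32, f_stat=PoolingSpec(("mean", "std")), C=10.0)
res = FlightCallModel(clips, labels, hyperparams=hp).fit(seed=0)
print(res.summary())
```

prints

```
Flight-call codebook classifier
===============================================
Scenario                                 nclass
Training clips                               16
Classes                                       2
TF-patch duration (ms)                    23.20
TF-patch frames                              16
Whitened dims (99% var)                      20
Codebook size k                              32
Pooling statistics                     mean+std
Feature length k*l                           64
SVM penalty C                              10.0
Support vectors                              10
Training accuracy                        1.0000
===============================================
```

Reading the table: the 23.2 ms patch spans 16 spectrogram frames, so
each flattened patch has 40 × 16 = 640 dimensions, of which 20 whitened
components carry 99% of the variance; 32 codewords pooled with two
statistics give a 64-dimensional feature per clip, and the SVM
separates the two opposite-direction sweeps perfectly (they are
spectrally identical — only the temporal structure inside the patch
distinguishes them). `res.evaluate(clips, labels,
positive_label="down")` adds confusion, ROC-AUC and PR curves.

The same pipeline is available from the shell
(`flightcall synth|learn|encode|train|gridsearch|evaluate|monitor|summarize`),
reading CSV manifests and WAV audio and writing JSON reports.

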