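# Methods

This note documents the models and procedures implemented in `ecgfusion`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the package's numerical conventions.

## Pipeline overview

1. **I/O** (`wfdb_io`): WFDB records (text header, format-16 int16 signal,
   MIT annotation file) are read into physical units; one lead is
   selected by name (default `MLII`, the usual single-lead choice) with
   fallback to channel 0, since header naming varies across dialects.
   Annotation symbols map to the five AAMI classes — N (normal, L/RBBB,
   atrial/nodal escape), SVEB (atrial/aberrated/nodal/supraventricular
   premature), VEB (PVC, ventricular escape), F (ventricular+normal
   fusion), Q (paced, paced fusion, unclassifiable); everything else
   (rhythm marks, noise, comments) is not a beat. Records from paced
   patients are excluded by a configurable blocklist (default
   102/104/107/217, the conventional set).
2. **Preprocessing** (`preprocess`): zero-phase Butterworth bandpass
   0.5–50 Hz over the whole record, then windows `[r−144, r+180)` around
   each annotated R peak (324 samples at 360 Hz ≈ 0.9 s), then
   resampling of each window to the image side length.
3. **Encoding** (`imaging`): RP, GAF and MTF images per beat, stacked in
   fixed (RP, GAF, MTF) order along the channel axis (a height-axis
   concatenation is available for ablations).
4. **Balancing** (`balance`): optional Borderline-SMOTE on the *training*
   beats only, before encoding.
5. **Network** (`network`): residual CNN with FCA, trained with
   label-smoothing cross-entropy and Adam, best-validation-accuracy
   checkpointing.
6. **Metrics** (`metrics`): per-class one-vs-rest Acc/Se/PPV/Sp/F1 in
   percent plus overall accuracy.

The high-level `HeartbeatClassifier` / `ClassifierResults` pair wraps
steps 3–6 in a fit/results interface; the `ecgfusion` CLI wraps the whole
pipeline with a strict-keyed YAML configuration, and every command writes
its fully resolved configuration next to its outputs.

## Numerical and design choices

**Filter.** Butterworth bandpass applied forward–backward
(`sosfiltfilt`), so the R peak is not shifted relative to its annotation
and passband gain is 1. Order is configurable; the default is 6 because
the zero-phase gain of the 0.5–50 Hz design at 60 Hz is then 0.069
(sufficient mains suppression), while a 4th-order design only reaches
0.150. Gain at 10 Hz (QRS energy) is 1.000 in both.

**Resampling.** "324 samples resampled toward 224 Hz" is realised as
resampling each window to exactly the image side length (default 224, so
each image is 224×224; the scaled-down configurations use 64 or 32).
Linear interpolation on an endpoint-aligned grid is used: it preserves
constants exactly, is the identity when lengths match, and the windows
are already band-limited far below the new Nyquist rate, so no
anti-aliasing stage is needed.

**Normalization (GAF).** Min–max to `[−1,1]` by default (`[0,1]`
selectable). A constant window has no range; it maps to all zeros with a
warning rather than dividing 0/0.

**GADF variant.** Two forms are provided: `cos(φ_i − φ_j)` ("paper",
default — symmetric, unit diagonal) and the antisymmetric `sin(φ_i − φ_j)`
("standard"). Which Gramian field feeds the fusion is configurable;
default GASF.

**RP threshold.** Binary mode thresholds at ε = the 10th percentile of
the beat's own pairwise distances when no ε is given (a common recurrence
convention); an unthresholded distance mode is also available. Entrywise,
growing ε can only turn 0s into 1s.

**MTF binning.** Empirical quantile bins, default Q = 8. Bins are
left-closed (a value equal to an interior edge belongs to the upper bin,
as in `np.digitize`); duplicate quantile edges are merged with a warning.
Rows of the transition matrix with no observed outgoing transition are
set to the uniform distribution so the matrix stays row-stochastic.

**FCA.** The 2-D DCT basis is unnormalised (any constants would be
absorbed by the first gate matrix) and cached per `(H, W, u, v)` —
repeated calls return bit-identical arrays. Frequency pairs default to
the `n` lowest by `u+v` (ties by `u`, then `v`), starting at `(0,0)`:
low-frequency dominance is the stated motivation for DCT attention, and
the empirically tuned index sets used elsewhere are not recoverable.
Defaults `n = 16`, reduction 16 at full scale; `n` must divide the block
width and fit the block's spatial grid (`n ≤ H·W`). With a single
`(0,0)` pair the block is numerically identical to squeeze-and-excitation
whose squeeze is `H·W` times the channel mean — this equivalence is a
test oracle.

**Architecture.** The published description fixes the topology but not
the widths. Defaults follow standard residual-network conventions: stem
7×7/2 → 64 channels, 3×3/2 max pool; block widths (64, 128, 256, 512)
with strides (1, 2, 2, 2); 3×3 block convolutions; LeakyReLU slope 0.01;
identity shortcuts where shapes match and 1×1 projections (with BN)
elsewhere; activation after the shortcut addition (the standard residual
convention). A per-stage repeat count (default one block per stage, four
blocks total) exposes the depth ablation. Because the widths are
conventions rather than published values, the full-scale parameter count
is not expected to match any published figure.

**Training.** Label smoothing ε = 0.1 over K = 5 classes; Adam with
constant learning rate (no schedule); batch size 128; up to 80 epochs at
full scale; parameters from the epoch with the highest validation
accuracy are restored at the end. Data order, initialisation and dropout
masks all derive from a single seed, so a rerun is bit-identical. The
loss gradient for the softmax head is `(p − y′)/B` with the smoothed
target `y′`; a 1e-12 floor guards the logarithm when a probability
underflows. A non-finite loss aborts training.

The layer library (conv via im2col + GEMM, batch-norm, max/global
pooling, FCA, dropout, linear) implements explicit forward/backward
passes in float32 and was verified against finite differences in float64
(worst relative error ~4e-9 across all parameter types).

**Borderline-SMOTE.** Variant 1 of the original algorithm: a minority
point is *danger* iff, among its `m` nearest neighbours in the full set
(Euclidean, default m = 10), the majority count m′ satisfies
`m/2 ≤ m′ < m`; `m′ = m` is noise, `m′ < m/2` is safe. Synthesis
interpolates each danger seed toward one of its k = 5 nearest *minority*
neighbours with u ~ U(0,1). Defaults raise every minority class to the
majority count. Edge policies: an empty danger set falls back to seeding
from the whole minority class; a class smaller than k+1 falls back to
random duplication with a warning. Oversampling operates on the 1-D
beats before image encoding — interpolating transition-probability
images would violate their row-stochastic structure.

**Metrics.** Per class, one-vs-rest: Acc = (TP+TN)/total,
PPV = TP/(TP+FP), Se = TP/(TP+FN), F1 = 2·Se·PPV/(Se+PPV), and
Sp = TN/(TN+FP) (the standard form; only named, not printed, in the
source description), all ×100. A 0/0 ratio is reported as `nan`
("undefined") and excluded from averages; overall Acc is trace/total.
Reports print one decimal. Summary tables list N/SVEB/VEB/F by default
with Q optional; Q beats always remain in the confusion matrix.

**Data split.** Seeded and stratified per class: the test fraction is
drawn first, then the validation fraction from the remaining *training*
portion (validation never touches test data). A class too small to
appear in all three partitions stays entirely in train, with a warning.
The published per-class split counts are not derivable from a stated
procedure, so no attempt is made to match them row-for-row; fractions
are configurable (defaults 20% test, 10% of the remainder for
validation). Beats are pooled across records (intra-patient); a
record-disjoint protocol is out of scope.

## Synthetic data

The generator exists so that every stage — including WFDB round-trips —
is testable offline. Beats are sums of Gaussian bumps (P, Q, R, S, T)
over a 324-sample window with the R center at sample 144, with
class-distinct morphology: N is the textbook shape; SVEB suppresses the
P wave (presence probability 0.2) and shifts timing earlier; VEB widens
the QRS 2.5× with a deep S and no P; F averages the N and VEB templates;
Q is low-amplitude with strongly randomised morphology. Per-beat
variability: 10% multiplicative amplitude jitter, timing jitter of 1% of
the window, white noise σ = 0.02 mV (Q uses larger jitter). Records
concatenate beats with class-dependent RR intervals (ectopics premature)
and add baseline wander (0.1 mV at 0.3 Hz), powerline interference
(0.05 mV at 60 Hz, the source database's mains frequency; 50 Hz
selectable) and white noise (σ = 0.03 mV), annotating each R peak with
the class's conventional symbol.

What this emulates: class-separable single-lead morphology under the
noise types the preprocessing is designed to remove. What it does not:
inter-patient variability, rhythm context (bigeminy, AF), electrode
motion artefacts, or the heavy class imbalance and label noise of real
Holter data. Passing tests therefore demonstrate that the pipeline is
implemented correctly and can learn morphologically distinct classes;
they do not certify clinical-grade accuracy on real recordings.

"Within-class deviation" in the separability check is the mean
per-sample standard deviation; the N-vs-VEB mean-beat distance exceeds
five times that deviation under the defaults.

## Problem sizes

The test suite and `scripts/acceptance.py` use scaled-down
configurations chosen as the smallest sizes at which every contract is
meaningfully exercised: 100 random series for encoder oracles, 200
random confusion matrices for metric checks, and an end-to-end run with
300 beats per class, 64×64 images, block widths 16/32/64/128, FCA n = 4,
and 15 epochs at learning rate 3e-3 (selected on validation accuracy at
this scale; the full-scale default stays 1e-3). That run reaches ≥95%
test accuracy across seeds and trains in roughly two minutes on one CPU.

## Known limitations

- The network is CPU-oriented numpy; at the full 224×224 / 80-epoch
  scale it is correct but far slower than a GPU framework — the package
  targets method study and scaled experiments, not full-database
  training runs.
- Only WFDB signal format 16 (the relevant one) is implemented.
- Borderline-SMOTE2, ADASYN, undersampling, and the CBAM/coordinate
  attention baselines are out of scope; squeeze-and-excitation exists
  only as a test reference.
- The RP operates on the scalar series (no time-delay phase-space
  embedding), matching the encoding the rest of the pipeline expects.
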