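# Methods

## Problem and model

Sleep staging assigns one of five AASM stages (W, N1, N2, N3, REM) to each
non-overlapping 30-s epoch of a single EEG channel sampled at 100 Hz
(T = 3000 samples). When a stager trained on one dataset is applied to
another, the feature distributions differ (montage, hardware, population)
and accuracy drops — the domain-shift problem. The package implements an
adversarial unsupervised domain-adaptation network for this setting:
labeled source epochs, unlabeled target epochs.

Components:

* **Feature extractor `F`** — three blocks of Conv1d → BatchNorm →
  leaky-ReLU → MaxPool with kernels/filters (25, 32), (8, 64), (8, 128)
  and pool sizes/strides 2, 3, 3. Convolutions are stride-1 with zero
  "same" padding so pooling is the only down-sampler; the temporal length
  is 3000 → 1500 → 500 → 166 and the flattened feature is 128·166 = 21248.
* **Domain attentions `A_s`, `A_t`** — one instance per domain, *not*
  shared. Two kernel-1 convolutions M1, M2 map each position's 128-vector
  to a 16-dimensional query/key (d/8). The weight of output position y on
  input position x is the softmax over x of the un-scaled dot product
  M1(p_x)·M2(p_y); the output is the attention-weighted sum of input
  positions, folded back through a learnable scalar gate γ initialized at
  0 (so an untrained module is the identity and the gate opens during
  training). The residual gate follows the convention of the
  convolutional self-attention literature.
* **Dual classifiers `C1`, `C2`** — fully connected 21248 → 1024 → 512 → 5
  with leaky-ReLU hidden activations and a softmax output; identical
  architecture, independent initialization streams.
* **Domain discriminator `D`** — 21248 → 1024 → 512 → 2 with softmax;
  output index 1 means "source".

The discrepancy between the heads is d(p1, p2) = (1/K) Σ|p1k − p2k|,
symmetric, zero iff the rows agree, bounded by 2/K.

## Training procedure

Per mini-batch (paired source/target batches, iterators cycled to equal
length):

A. minimize source cross-entropy over G = {F, A} and C1, C2 (the
   per-head losses are averaged);
B. with G fixed (features detached), train D on the source-vs-target
   binary task; then train G to fool the fixed D by flipped-label
   cross-entropy (an explicit two-phase scheme rather than a gradient
   reversal layer);
C. with G fixed, update C1, C2 on source cross-entropy **minus** target
   discrepancy (the heads maximize disagreement subject to staying
   accurate on the source);
D. with heads and D fixed, update G to minimize the target discrepancy,
   repeated n times (default n = 4).

One Adam optimizer (lr 1e-3) per parameter group — G, C1∪C2, D — since
the steps update disjoint groups. The cross-entropy terms are evaluated
from the pre-softmax logits via log-softmax, which equals the textbook
−Σ y log p but keeps gradients alive where float32 softmax saturates to
exactly 0 or 1; probability-space helpers clamp to [1e-7, 1 − 1e-7].
Training aborts with a diagnostic naming the
step if any loss goes non-finite. The direction of the discrepancy game
(heads maximize in step C, generator minimizes in step D) follows the
maximum-classifier-discrepancy scheme; descriptions of this family of
methods sometimes transpose the two labels, so the package states its
convention here once.

Target labels can never reach a loss: `fit` strips them on entry and the
target-side loss signatures take no label argument (verified by a
poisoning test asserting bit-identical training).

Prediction averages the two heads' softmax rows and takes the argmax
(ties resolve to the lower class index). Step A runs inside every
mini-batch by default (`pretrain_each_batch`), exposed as a switch.

## Preprocessing

EDF/EDF+ reading is delegated to `mne`; hypnograms are accepted as EDF+
annotation files or a plain CSV dialect (`onset,duration,stage`). The
pipeline: 4th-order Butterworth band-pass 0.3–35 Hz applied zero-phase
(forward–backward), polyphase anti-aliased resampling to 100 Hz
(exact for rational ratios such as 250→100; upsampling is rejected),
epoching into 30-s pieces (epoch i covers samples [3000·i, 3000·(i+1)),
0-based half-open), then three label rules: drop M/? epochs, merge S3/S4
into N3, and keep wake epochs only if they *start* within 30 min of the
first/last sleep-epoch boundary (the anchoring point of the wake-trimming
window is a package decision; "lights off" is not recoverable from the
annotation file). The filter order/type and resampling algorithm are
likewise package choices — standard zero-phase EEG practice and exact
rational-rate conversion.

Sliding-window augmentation re-cuts each maximal run of k consecutive
N1 epochs (a 30k-second signal) into windows of 30 s every 25 s:
floor((30k − 30)/25) + 1 windows. Windows never cross a run boundary, so
labels stay pure; runs shorter than one window pass through unchanged.
Augmentation belongs on training data only — overlapping copies in an
evaluation split would leak signal into the metric.

## Metrics

ACC = Σ TP_i / M and MF1 = (1/K) Σ 2 P_i R_i / (P_i + R_i) with
precision/recall/F1 defined as 0 whenever their denominator is 0, so an
absent or never-predicted class counts as a 0 toward MF1 instead of being
skipped. Computation is backed by scikit-learn; the tests check it against
an independent confusion-matrix loop.

## Synthetic benchmark

The generator emulates the cross-dataset situation without data download.
Each class is a sum of band-limited noise components (white noise passed
through the package's own band-pass filter, scaled to a target RMS
amplitude in µV) over a 10 µV white-noise floor:

| stage | bands (center ± half-width, amplitude) |
|---|---|
| W | 10 ± 2 Hz, 30 µV; 20 ± 10 Hz, 10 µV |
| N1 | 5.5 ± 1.5 Hz, 15 µV |
| N2 | 5.5 ± 1.5 Hz, 20 µV; 13 ± 1 Hz, 25 µV |
| N3 | 1.25 ± 0.75 Hz, 60 µV |
| REM | 6 ± 2 Hz, 12 µV; 22 ± 4 Hz, 8 µV |

Target epochs are additionally transformed by a shift triple: amplitude
gain, added white noise SD, and a frequency offset of the prototype
bands. The default (gain 2.0, +5 µV noise, +1 Hz) was chosen once to
produce a clear but recoverable direct-transfer drop. Classes are
interleaved so the ordered 80/20 split stays balanced, and the two domains
come from independent child streams of one seeded generator, so a null
shift gives two draws of the same process.

What the generator does **not** emulate: sleep architecture (no stage
transition structure), within-night non-stationarity, artifacts, subject
variability, and realistic class imbalance. Its classes are far more
spectrally separable than real sleep EEG. Passing the adaptation tests
therefore demonstrates that the adversarial machinery aligns a
well-defined distribution shift — not that the published cross-dataset
accuracies on real polysomnography are reproduced.

## Study conditions for the self-contained experiments

The adaptation experiments in the tests and `scripts/acceptance.py` use
500 epochs per domain (100 per class), the default shift, and five
training seeds with the mean reported, at a reduced network width
(conv filters 4/8/16, FC 64/32, d_q = 2) and batch 32 for CPU-scale
runtimes. The adversarial model trains 4 epochs; the source-only
direct-transfer baseline trains 12, because it takes a single head/extractor
update per batch instead of several and the comparison is only fair when
both have reached their training-loss plateau (≲0.01 on this task).
Published-scale experiments would use the full Table widths, batch 128
and real PSG recordings; the defaults of `ModelConfig`/`TrainConfig`
remain those settings.

## Numerical choices and limitations

* All network arithmetic is float32 on a tape-based numpy autodiff engine
  (`tdsan.nn`) written for exactly the ops this model needs; gradients
  are verified against central differences in the test suite's companion
  checks. Training is single-threaded-deterministic under a fixed seed.
* BatchNorm keeps one set of running statistics shared by both domains
  (momentum 0.1). During adversarial training target batches pass through
  more often than source batches, so the running statistics tilt toward
  the target domain; this favors target-side inference (the object of the
  method) and can cost source-side eval accuracy under large shifts.
  Domain-specific BN would remove the asymmetry and is a known
  alternative; it is deliberately not implemented.
* Leaky-ReLU slope 0.1 everywhere; no dropout; fan-in uniform
  initialization; attention dot products are un-scaled (no 1/√d), exactly
  as the score definition states.
* The 80/20 split preserves epoch order (no shuffling across the
  boundary); mini-batch composition within the training split is
  shuffled per epoch under the run seed.
* Checkpoints are NPZ archives of every parameter and BN statistic plus
  the YAML-serialized config.
* No early stopping; `max_epochs` is the only stopping rule.
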