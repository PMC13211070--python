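# Methods

## Problem and model

A standard clinical ECG records 12 leads — 12 simultaneous projections of
the same cardiac electrical activity — while wearable devices typically
record one (most often lead I).  Some rhythm and morphology signatures that
are obvious in several chest leads are weak or nearly absent in lead I, so
a single-lead classifier faces an intrinsic information deficit.  This
package implements a feature-space remedy: instead of synthesizing the
missing lead waveforms, a single-lead network learns to *reconstruct the
feature representation* that a 12-lead network would have produced, and
then classifies a fusion of reconstructed and original features.

The pipeline has two phases.

**Phase 1 (teacher).**  A 12-lead extractor `E_full` plus a pooling
classifier is trained with multi-class cross-entropy on 12-lead input,
producing `F_full = E_full(X)` and `P_pre = softmax(W_pre · pool(F_full) +
b_pre)`.  After training, all teacher parameters are frozen and a SHA-256
content hash over every weight and buffer is recorded; the hash is
re-verified every subsequent epoch, so any drift aborts the run.

**Phase 2 (student).**  The student extractor (identical architecture, one
input channel) maps the chosen lead to `F_single`.  A two-layer transformer
encoder maps `F_single` to `F_rec`, trained to minimize an alignment loss
against the frozen teacher's `F_full` — by default the elementwise mean
absolute difference

    L_rec = mean |F_rec − F_full|

(the mean rather than a raw sum keeps the loss-weighting coefficient
comparable across model widths; L2, cosine, KL and Jensen–Shannon variants
are selectable, with KL fixed in the target-as-reference direction
KL(softmax F_full ‖ softmax F_rec), per token, channels as the distribution
axis, and JS in base 2 so it is bounded by 1).  A cross-attention layer
(queries from `F_rec`, keys/values from `F_single`, residual from the query
stream plus layer norm — the residual is our addition, without it early
training can collapse the fused signal) followed by one self-attention
layer yields `F_enhance`, which the classifier pools (global average ‖
global max — concatenation preserves both statistics where a sum would
merge them) and maps to class probabilities.  The training objective is

    L_total = L_rec + α · L_CE,        α = 1 by default.

α is deliberately exposed: it balances alignment against discrimination and
no canonical value exists; 1.0 treats both objectives equally and is used
throughout.

## Feature extractor

Shared by teacher and student; they differ only in input channels.

| stage | output (length, channels) |
|---|---|
| omni-scale conv + SE + stride-2 max-pool | (N/2, 192) |
| 5 × inverted-bottleneck CNN block | (N/64, 1536) |
| 4 × pre-norm transformer encoder layer | (N/64, 1536) |

* **Omni-scale stage**: parallel same-padded 1-D convolutions with kernel
  sizes {1, 3, 5, 7, 11, 13}, 32 channels each, concatenated to 192.  The
  kernel set and per-branch split are open choices (odd sizes make same
  padding exact; the spread covers sub-QRS to full-beat scales at 250 Hz).
  Squeeze-and-excitation recalibration is applied after concatenation, not
  per branch.
* **CNN block**: 1×1 expansion (×4) → depthwise k=3 stride-2 → 1×1
  compression, each conv followed by BatchNorm, ReLU and an SE gate
  (reduction 16).  Stride on the depthwise conv is the standard
  inverted-bottleneck placement; five blocks × 2 plus the initial pool give
  the ×1/64 time reduction.  No residual connections inside the block.
  Channel schedule 192 → 256 → 384 → 512 → 1024 → 1536 (monotone widening;
  only the endpoints are fixed by the stage table, the interior is config).
* **Transformer**: fixed sinusoidal positions, pre-norm layers, 8 heads,
  FFN width 4×d_model, dropout 0.1.

A `small` profile divides all widths by 8 (OS-CNN 24, blocks
32/48/64/128/192, d_model 192, 2 heads).  The time-reduction contract is
width-independent, so every shape property of the full model holds in the
small profile; correctness tests use it, and the full 1536-wide model is
exercised once per suite on the full-width shape contract.

## Numerical backend

All networks run on a compact reverse-mode autodiff engine written on
numpy (`slfr.nn`): tensors with broadcasting-aware gradients, grouped 1-D
convolution via im2col matmuls (depthwise convolutions as k fused
multiply-adds), attention, batch/layer norm, Adam, and the plateau
learning-rate schedule.  Every operation's gradient is verified against
central finite differences in the test suite.  Arrays are float64 by
default; desk-scale experiments switch to float32, which roughly halves
step time on one CPU and changes held-out metrics only in the noise.
Determinism: all weight initialization, sampling and dropout draw from
generators seeded by the run seed, so a repeated run reproduces weights
bit-for-bit (the teacher hash test relies on this).

## Preprocessing

Quality gate (drop records with NaN/Inf, "incomplete", or |amplitude| above
a configurable 20 mV limit — the anomaly threshold is not standardized, so
it is config) → zero-phase third-order Butterworth band-pass 0.05–48 Hz
(forward–backward filtering avoids phase distortion of QRS morphology;
attenuation is therefore the squared one-pass magnitude response, which the
tests verify against an independently computed frequency response) →
polyphase downsampling to 250 Hz → per-lead z-score (constant leads map to
zeros) → fixed-length standardization.  The target window (20 s for
CPSC-style material, 10 s for CODE-style; configurable) is truncated from
the leading samples or zero-padded: training records split the deficit
uniformly before/after the signal, evaluation records pad only at the end.
Because 20 s × 250 Hz = 5000 is not divisible by the model's ×1/64 time
reduction, the window is then right-padded to the next multiple of 64
(5056).  Splits are patient-level 7:1:2 by record count via greedy packing
(patients shuffled by seed, each assigned to the split with the largest
remaining deficit), so no patient spans splits.  Training batches draw from
a class-balanced sampler: class uniform, then record uniform within class,
with replacement.

## Synthetic data

The generator exists so the whole method is testable without clinical
downloads; it emulates the *structure* of the problem, not ECG physiology.

* 8 latent sources built from Gaussian-bump P/QRS/T/ST templates on a
  per-class beat grid; 12 leads are a fixed full-column-rank 12×8 linear
  mixing of the sources plus white noise and a baseline-wander sinusoid,
  scaled to a prescribed SNR (default 20 dB).
* Six classes: normal; an irregular-rhythm class (RR coefficient of
  variation 0.28 vs 0.04, absent P waves — AF-like); a wide-QRS class; a
  bradycardic class; and two classes whose only distinguishing signature
  (an ST-segment shift, a T-wave inversion) is injected exclusively into
  two "hidden" sources.  The wearable lead's mixing weights on those
  sources are scaled to 0.05, so its view of these classes is attenuated
  ~20-fold but not strictly zero: recoverable in principle, weak in
  practice.  This is the engineered single-lead information deficit.
* Patients contribute several records and carry a shared heart-rate and
  amplitude random effect; class priors are mildly imbalanced (geometric
  decay, ratio 0.82).  Same seed ⇒ byte-identical dataset.

What passing tests on this generator do **not** show: robustness to real
morphological variability, electrode artifacts, label noise, or class
taxonomies of clinical datasets.  They show that the training protocol,
supervision signal and fusion wiring behave as designed when the premise
(single lead misses recoverable information that 12 leads carry) holds.

## Desk-scale experiment sizes

The ablation study runs the full two-phase protocol at sizes one CPU
handles in minutes, as the package's own reference experiment: 60 patients
× 4 records (≈168 train / 24 validation / 48 test records after
patient-level splitting), 5 s records at 500 Hz (conditioned to 5 s at
250 Hz, padded to 1280 samples → 20 tokens), small architecture profile
with dropout 0, float32.  Teacher: 24 epochs × 8 steps of batch 8;
students: 24 epochs × 8 steps, Adam at 1e-3 (the library's full-scale
defaults — 120 epochs, batch 128, lr 1e-4 — are impractical and unconverged
at this problem size; the plateau schedule with patience 5, factor 0.5 and
floor 1e-7 is kept).  Replicates use seeds 1, 2, 3; model selection is
best validation macro-F1 (no selection rule is prescribed at full scale,
so the package fixes one).  Reported quantities are means over the
replicate seeds.  Under these conditions the frozen teacher reaches
test macro-F1 ≈ 0.78 and the single-lead baseline ≈ 0.38, so the
engineered information deficit is large and reproducible.

## Evaluation

Accuracy, macro precision/recall/F1 with the 0/0 → 0 convention for never-
predicted classes, and macro AUC as the unweighted mean of one-vs-rest
AUCs over classes present in the truth (truth-absent classes are excluded
from the AUC mean but count as 0 in the P/R/F1 means — the convention is
explicit because "macro AUC" is ambiguous in the literature).  Confusion
matrices are rows-true × columns-predicted.  Significance between two
models on the same records uses a two-sided paired bootstrap on the
accuracy difference (2000 resamples, add-one smoothing, deterministic under
seed); the bootstrap is one reasonable choice among several, not a
canonical one.

## Known limitations

* The generator's morphology is schematic; absolute macro-F1 values on it
  say nothing about clinical performance.
* At desk scale the variant ranking is a noisy, partly adverse statistic.
  The teacher-supervised variants carry the alignment term as an extra
  constraint throughout training; their benefit is tied to teacher quality
  (replicates whose teacher generalizes poorly show the supervised student
  falling *below* the unsupervised baseline), and per-seed macro-F1 moves
  by ±10 points across seeds — even across mere floating-point rounding
  changes.  Training the students 2.5× longer reproduces the same selected
  checkpoints, so this is not a step-budget artifact.  The variant
  ordering that motivates the design at full scale should therefore not be
  expected to re-emerge reliably from three desk-scale replicates on this
  generator; the ordering test documents the outcome on fixed seeds rather
  than guaranteeing it.
* The CNN-based reconstruction backend and waveform-level (GAN /
  autoencoder) baselines are out of scope; `logit_kd` is a minimal
  distillation hook, not a tuned baseline.
* The real-data adapters (CPSC-style .mat, CODE-style HDF5, WFDB) are
  untuned conveniences; the WFDB route needs the optional `wfdb` package.
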