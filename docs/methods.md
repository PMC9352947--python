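# Methods

## Problem and approach

`rp3d` classifies short multi-lead ECG recordings into four rhythm
classes — normal sinus rhythm (NSR), atrial fibrillation (AF), left
bundle branch block (LBBB) and first-degree atrioventricular block
(I-AVB) — by treating the heart as a nonlinear dynamical system
rather than a stack of 1-D waveforms. Each lead's 5-s segment is
mapped to a recurrence image, the per-lead images are stacked along
the lead axis into a 3-D volume, and a 3-D convolutional
Inception-ResNet learns texture within each recurrence plane *and*
correlation across leads.

### Recurrence images

For a scalar segment x₁…x_L, phase-space points are built by delay
embedding with dimension m and delay τ (point i is
(x_i, x_{i+τ}, …, x_{i+(m−1)τ})). The classic recurrence plot is the
binary matrix R_ij = θ(ε − ‖x_i − x_j‖) with the Heaviside convention
θ(0) = 1, so the boundary counts as recurrent and the diagonal is all
ones. The classifier input uses the *unthresholded* variant
R_ij = ‖x_i − x_j‖ (L2 norm), which keeps the full distance texture
instead of a binary silhouette. Defaults are m = 1, τ = 1 — the
matrix is then exactly the pairwise |x_i − x_j| of the raw samples —
because no embedding parameters are pinned down for this
application; both are exposed in `EmbeddingParams` since the
recurrence literature typically embeds (m 2–10, τ near the first
autocorrelation zero).

Each matrix is normalized by its own statistics — min-max to [0, 1]
or z-score to mean 0/sd 1 (z-score is the default; it gave the best
reported operating points for this family of models). Normalization
is strictly per matrix, never per volume or per dataset, so every
lead plane carries comparable contrast. Degenerate (constant)
matrices normalize to all zeros rather than NaN: a flat segment has
no recurrence texture.

A 1000-sample segment yields a 1000×1000 matrix (~4 MB float32 per
lead), which is impractical as direct network input at batch size 64.
Matrices are therefore area-average downsampled (exact block means,
symmetric by construction) to a configurable side, 128 by default and
64 in the desk-scale experiments. Area averaging was chosen over
decimation because it preserves the energy of thin recurrence lines;
pre-RP decimation of the segment is also available (`RPConfig.decimate`).
Only downsampling is supported — upsampling recurrence texture would
interpolate structure that was never measured.

### Vectorcardiogram route

As an alternative to stacking 12 lead images, the 12-lead ECG is
reduced to the 3 orthogonal Frank leads (Vx right–left, Vy
head–feet, Vz anterior–posterior) by a fixed linear map over the
eight electrically independent leads (I, II, V1–V6), cutting the
volume depth from 12 to 3 at little information cost. The default
coefficient matrix is the published Frank-synthesis regression with
the outer negation of the Vx and Vz expressions folded in. One
coefficient required judgement: the Vy lead-I term is printed in the
source as −227, four orders of magnitude outside the sub-unit range
of every other entry of this matrix family; it is implemented as
−0.227, and a sanity check rejects |c| > 10 unless explicitly
overridden (`allow_unchecked=True`). Alternative maps (Kors, inverse
Dower) can be supplied as any 3×8 matrix over the same input order.
No gain or offset is applied before the map.

### Dataset construction

The splitting pipeline mirrors the published inter-patient design on
PTB-XL-sized cohorts:

1. multi-labelled records are removed;
2. over-represented classes (NSR, AF) are subsampled to 1200 records,
   uniformly at random, seeded;
3. per class, floor(n/5) *records* are drawn as the test set — no
   subject contributes to both training and test;
4. records (resampled to 200 Hz) are cut into 5-s, 1000-sample
   windows with class-specific starts that re-balance the classes:
   NSR/AF {0}, I-AVB {0, 1000}, LBBB {0, 500, 1000} (overlapping);
5. the remaining *segments* are shuffled into floor(0.8·n) train and
   the rest validation.

The published per-class count grid (e.g. LBBB: 370 records → 1110
segments → 710/178/222 train/val/test) is reproduced exactly by this
order of operations: the test draw must happen at record level
*before* augmentation (222 = 74×3, 274 = 137×2), while the train/val
split must happen at segment level (710 = floor(0.8·888), which no
record-level split of 296 three-segment records can produce). The
source text's 1-based inclusive window ranges are internally
inconsistent ("500th to 1500th" spans 1001 samples); 0-based
half-open windows of exactly 1000 samples are used instead, since the
volume shapes require a uniform window length. Cross-validation folds
are grouped by record (all segments of a record share a fold) and
stratified by class; record grouping preserves the inter-patient
principle inside CV, a choice this package makes explicitly where the
source is silent. Fold sizes are exactly balanced when every record
contributes one segment and differ by at most the largest per-record
segment count otherwise.

### Classifier

The network operates on [1, C, H, W] volumes (one feature channel;
C = 12 or 3 leads as depth; H×W recurrence axes). The block
inventory follows the 3-D Inception-ResNet design: a stem of 1×1×1,
3×3×3, 1×1×7 and 1×7×1 convolutions with two max-pools (overall H, W
divided by 8); A blocks (1×1×1, 3×3×3 branches); B blocks (1×1×1
plus 1×1×7→1×7×1 asymmetric branch); C blocks (1×1×1 plus
1×1×3→1×3×1); reductions A and B (parallel max-pool and strided-conv
branches); head = 3-D global average pooling → dropout → dense →
softmax. Asymmetric kernels act on the two recurrence axes only; the
lead axis is mixed exclusively by 3×3×3 convolutions and is never
pooled (a 3-lead VCG volume leaves no room). Residual branches are
concatenated, linearly projected back to the trunk width and added
with scale 0.2, the standard stabilizer for this family. Batch
normalization follows every convolution, activations are ReLU,
padding is "same" inside blocks and "valid" at pools.

Per-branch filter counts and block repeats are configuration, not
architecture: only the kernel inventory of the reference design is
pinned down. `tiny_config` (stem 8/12/16, blocks 8/12/16, reductions
16/24, one repeat each, ~90 k parameters) is the desk-scale preset
used in all tests; `paper_scale_config` instantiates the same shape
at Inception-ResNet-v2-like widths (order 10⁷ parameters) without
claiming parameter-count parity with any published build.

The implementation is a self-contained NumPy layer library with
explicit backpropagation (shift-and-matmul 3-D convolution, batch
norm, non-overlapping max pooling, inverted dropout, Adam). Gradients
are verified against central finite differences on float64 block
compositions. One caveat documented by those tests: bias-free
convolutions over ReLU-clamped all-zero windows put pre-activations
exactly at the ReLU kink, where a finite difference and the (correct)
subgradient legitimately disagree; the checks nudge batch-norm betas
off zero to avoid kink hits.

### Training and evaluation

Defaults follow the reference protocol: Adam (lr 0.001, β 0.9/0.999),
batch size 64, categorical cross-entropy. Early stopping monitors
validation loss; the best-validation checkpoint is restored (the
selection rule is this package's choice; only per-fold epoch counts
are reported in the source). Runs are fully seeded — weight
initialization, shuffling and dropout derive from two integers
(model seed, train seed) — and bit-reproducible. Evaluation reports
per-class precision, recall and F1 one-vs-rest from the confusion
matrix, their unweighted macro averages, and the matrix itself;
printed metrics are rounded to 4 decimals. After cross-validation,
per-fold test reports, their mean, and the best fold (lowest
validation loss) are all reported and labelled, since which
checkpoint should face the held-out test set is otherwise ambiguous.

## Synthetic cohort generator

Real PTB-XL-scale experiments need the external database and
GPU-scale training; the package is instead exercised end to end on
a synthetic cohort whose defaults emulate the source records: 12
leads, 500 Hz, 10 s, later resampled to 200 Hz. Each beat is a sum of
Gaussian deflections (P, Q, R, S, T) on per-lead amplitude templates
(ECGSYN-style), with the four classes differing by their defining
clinical feature:

| class | defining feature | generator default |
|-------|------------------|-------------------|
| NSR   | regular RR, P present | RR CV 0.03, PR 0.16 s, QRS 0.08 s |
| AF    | irregular RR, absent P | lognormal RR with CV 0.20 (≥ 0.15 enforced), no P, 4–9 Hz fibrillatory baseline ~0.05 mV |
| LBBB  | wide, notched QRS | QRS 0.14 s (≥ 0.12 enforced), split R hump |
| I-AVB | prolonged PR | PR 0.28 s (≥ 0.20 enforced) |

Heart rate is drawn per record (72 ± 8 bpm) identically for all
classes so rate is not a confound; additive white noise defaults to
0.01 mV. Limb leads III, aVR, aVL, aVF are derived exactly from I
and II, so the electrical identities (III = II − I, aVR = −(I+II)/2)
hold to the last bit — a standing invariant of the test suite. V1–V6
carry independent amplitude templates with no torso model; that is
acceptable because no downstream stage assumes a dipole source except
the Frank-lead map, which is a fixed linear combination either way.

What the generator does *not* emulate: baseline wander, powerline
interference, electrode artifacts, ectopic beats, pathology mixtures,
inter-patient template variability beyond rate/phase/noise jitter.
Consequently the end-to-end result — the desk-scale experiment
recovers the four classes at test macro-F1 ≥ 0.90 on held-out
records — demonstrates that every stage of the pipeline is wired
correctly and that the recurrence volumes carry class information a
3-D CNN can exploit; it does not predict performance on clinical
recordings, where the reported operating points came from the real
database at full training scale. The residual errors concentrate on
the NSR/AF boundary: a single 5-s window contains only ~6 RR
intervals, a short sample from which to witness the irregularity
that defines the AF surrogate, and 20 held-out records per class
make each misread window worth half an F1 point.

No baseline-wander or powerline filtering is applied anywhere (the
source protocol states none); the resampling step is the natural hook
should one be needed.

## Problem sizes and numerical choices

* Desk-scale experiment: 100 records/class → 560 train+val and 140
  test segments, VCG mode, 64×64 recurrence images, `tiny_config`
  model, ≤ 60 epochs with early stopping (patience 10 on validation
  loss; runs typically stop near 45). This size keeps the full run
  around ten minutes on one CPU core. Area-averaged resize was
  compared against pre-RP decimation at the same 64×64 output on the
  same cohort; decimation was no better, so the default stands.
* Resampling is polyphase (500→200 Hz = ratio 2/5), output length
  round(n·target/fs), edge-padded to the rounded length when the
  rational approximation runs short.
* WFDB export uses format 16 with gain 1000 adu/mV (0.001 mV
  quantization, ±32 mV range); reads apply gain/baseline and accept
  mV or µV, refusing to guess unknown units.
* Min-max/z-score guards: constant matrices map to zeros. Softmax is
  computed with max subtraction; cross-entropy clips log(0) at 1e−12.
* Ties in argmax predictions resolve to the lowest class index.
* Seeds: cohort, split, fold, model and training seeds are all
  derived from one integer via a seed sequence, masked below 2³¹.

## Known limitations

* The recurrence matrix is O(L²) in segment length; 5-s/1000-sample
  windows are comfortable, minute-long segments are not.
* `paper_scale_config` builds and runs but is not trainable in
  reasonable time on a single CPU; no claim is made about its exact
  parameter count.
* The NumPy network trains single-threaded BLAS-bound; there is no
  GPU path, mixed precision, or data-parallel training.
* The generator's class contrasts are intentionally strong; the
  synthetic task is easier than clinical arrhythmia discrimination.
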