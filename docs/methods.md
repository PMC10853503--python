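# Methods

## The encoder

`clustervit` implements a hierarchical vision transformer whose single
classification token is replaced by a *shrinking set* of learnable [cls]
tokens. An RGB tile is cut into non-overlapping patches (row-major, 0-based
grid), each patch linearly embedded to a d-vector, with an additive learnable
positional table (bilinearly resampled when a smaller view is encoded, e.g.
a multi-crop local view). The encoder is a sequence of *stages*; stage k
consists of

1. a stack of standard pre-norm multi-head self-attention (MSA) blocks over
   the concatenation `M = [inputs; cls_k]`, where `inputs` are the patch
   tokens at stage 0 and the previous stage's output [cls] tokens afterwards,
   and `cls_k` are the stage's fresh learnable tokens; then
2. a **semantic clustering block**: a cross-attention that soft-assigns each
   input token to one of the stage's N_c [cls] tokens,

       Attn[i, j] = softmax_j( (W_p x_i) · (W_c c_j) + γ_j )

   and moves each [cls] token toward the attention-weighted **mean** of its
   assigned inputs, with a residual connection:

       c'_j = c_j + W · ( Σ_i Attn[i, j] W_v x_i / Σ_i Attn[i, j] ).

   The column-sum normalizer makes the update a weighted mean rather than a
   weighted sum, so a token's update magnitude does not depend on how many
   inputs chose it. `W_p, W_c, W_v, W` and the per-token bias γ are learnable
   and stage-specific (not shared across stages).

The stage's output is the updated [cls] set, which is strictly smaller than
its input set (the per-stage [cls] counts must be strictly decreasing; the
default schedule is 16 → 8 → 4, geometric halving from coarse to fine). The
final representation is the average of the last stage's [cls] tokens.

The assignment dot product is deliberately **unscaled** (no 1/√d factor) —
that is the clustering rule as stated; a `scaled_cluster_logits` flag enables
a 1/√d variant. The MSA blocks themselves use the conventional scaled
dot-product attention, a GELU MLP (ratio 4, 2 in the tiny preset) and
pre-layer-norm residuals.

**Attention maps.** Each stage's assignment matrix is row-stochastic. For
stage k > 0 the rows index [cls] tokens, not patches, so maps are composed
down the hierarchy by the chained product `A_0 A_1 … A_k`, which is again
row-stochastic; each column, reshaped to the patch grid and bilinearly
upsampled (align-corners off), is one token's map, and at every pixel the
maps across tokens sum to 1 (within interpolation tolerance).

**Initialization.** Linear projections use Xavier-uniform. This matters more
here than in a plain ViT: the clustering hierarchy re-roots the residual
stream at the [cls] constants every stage, so the input signal survives only
through the projections — with the common 0.02-std truncated-normal init the
signal is attenuated by roughly an order of magnitude per stage and the
pooled embedding is nearly input-independent. [cls] tokens and the positional
table use truncated normal (std 0.02); γ and all biases start at zero.

**Numerics.** The assignment softmax is shift-stabilized. In the fused
forward path the weighted mean is computed in log space: the column
normalized weights `Attn[i,j]/Σ_i Attn[i,j]` equal a softmax over inputs of
the row log-softmax of the logits, which never underflows even when a token
is avoided by every input (the explicit ratio hits 0/0 once the exponentials
underflow; training sharpens the assignments far enough for this to happen in
float32 and occasionally even in float64). The public `update_cls_tokens`
keeps the explicit formula and raises on a zero column. Training runs in
float64.

Two presets are provided: `small` (224 px tiles, patch 16, d=384, 6 heads,
MSA depths [6,4,2] — 12 blocks, ≈23.4 M parameters, deliberately on the
ViT-small footing) and `tiny` (64 px tiles, patch 8, d=64, 4 heads, stages
[8,4,2], depths [2,2,1]) for CPU-scale experiments and the test suite.

## Self-distillation training

Training follows the teacher–student self-distillation recipe: a student and
an EMA teacher share the encoder plus a 3-layer projection head (hidden →
hidden → L2-normalized bottleneck → linear map to K prototype logits; the
prototype columns are kept unit-norm and frozen during the first epoch,
standard stabilizers against early prototype collapse). Each tile yields
N_g global and N_l local random-resized crops with horizontal flips and
brightness/contrast/saturation jitter. The teacher encodes global views
only; its logits are centered by a running mean and sharpened by a low
temperature τ_t into target distributions. The loss is the cross-entropy
between each teacher-global target and each student-local prediction
(softmax at τ_s), averaged over the (g, l) pairs; averaging rather than
summing keeps magnitudes comparable across local-view counts. An opt-in
`cross_global_terms` flag adds the (g ≠ g′) global pairs, which is required
when N_l = 0 (otherwise the objective is undefined and the loss raises).
Gradients flow into the student only; the teacher follows by

    θ_t ← λ θ_t + (1 − λ) θ_s

applied elementwise after every step, and the center by
`c ← m c + (1 − m) · batch-mean(teacher logits)`. The number of local views
and the [cls]-token schedule are independent knobs.

Optimizer: AdamW (decoupled weight decay on matrices only), linear warmup
over the first 10 % of steps then cosine decay, global gradient-norm
clipping at 3. None of the optimizer settings come from a reference
experiment; they are conventional defaults.

### Desk-scale study conditions

The package's reference experiment — what the acceptance script and the
heavier tests run — is deliberately small: 500 synthetic 64-px tiles, the
tiny preset, batch 16, 5 epochs (160 steps), one CPU, roughly half a minute
per run. Several schedule constants must be *rescaled* to that regime or the
run degenerates; the full-size defaults keep the conventional values
(τ_t = 0.04, center momentum 0.9, λ cosine-ramped 0.996 → 1), while
`SSLConfig.tiny()` applies the rescalings:

* **Teacher temperature 0.01.** Sharpening is only meaningful relative to
  the teacher's centered logit spread, which for a d=64 encoder at
  initialization is ~0.01. At τ_t = 0.04 the targets are indistinguishable
  from uniform, the student's optimum is the uniform output, and the teacher
  inherits that flatness — a one-way collapse. τ_t of the same order as the
  logit spread yields sharp, tile-specific, learnable targets.
* **Constant λ = 0.996.** The cosine ramp to 1 is designed for runs long
  enough that 1/(1−λ) steps is a small fraction of training; over 160 steps
  it freezes the teacher almost immediately, after which the center erodes
  the frozen targets toward uniform.
* **Crop scales (0.7, 1.0) global / (0.15, 0.5) local.** The conventional
  (0.05, 0.4) local range is calibrated to 224-px natural images; 0.05 of a
  64-px tile is a ~14 px crop that frequently contains no nuclei at all, so
  the teacher's targets become unpredictable from the student's views.
* **Warm-started center.** The center is initialized to the teacher's mean
  logit over 32 views before the first step. Without it the first ~20 steps
  see uncentered targets dominated by a static pattern: the loss starts
  artificially low, then rises as the center converges, and the smoothed
  trace says nothing about learning.

Under these conditions the smoothed training loss (mean of the first vs.
last 10 steps) falls by 35–70 % depending on the seed, the teacher's target
entropy falls from ≈4.5 to ≈1–3 nats while its cross-view consistency rises,
and frozen-feature k-NN on held-out synthetic tiles reaches ≈85–95 %
(4 balanced classes, 25 % chance).

## Tile preprocessing

Frames are cropped on a sliding grid with stride
`tile_size × (1 − overlap)`, overlap capped at 50 %; the last row/column is
shifted inward so frame edges are covered. A tile survives iff its *tissue
coverage* — the fraction of pixels with HSV saturation > 0.07 and value
< 0.95, a standard H&E glass-background heuristic — is at least 0.70. The
filter runs before the offline dihedral augmentation (identity, rot90,
rot180, horizontal and vertical flips, deduplicated), which is distinct from
the online multi-crop augmentation above. Both thresholds are configurable.

## Synthetic tiles

The generator rasterizes histology-like tiles from four classes — dense
cellular, sparse cellular, stromal, background — by drawing a Poisson number
of dark elliptical "nuclei" (hematoxylin-purple) and thin anisotropic
"stroma" streaks (eosin-pink) over a tinted, lightly textured background,
with per-structure boolean masks and a continuous coverage score equal to
the nucleus-mask fraction (a tumor-cellularity stand-in). Classes are
separable by color and density by construction, which is what makes the
downstream-probe tests meaningful at all: a pass shows the pipeline learns
and preserves the discriminative structure the generator provides. It does
**not** show robustness to what real H&E data adds — stain variability
across labs, scanner artefacts, tissue morphology that is not an ellipse,
label noise, magnification differences — so the probe numbers here are
pipeline checks, not performance claims about real tissue.

## Evaluation protocols

All probes operate on frozen features. k-NN uses cosine similarity with an
`exp(sim/0.07)`-weighted vote, sweeping k ∈ {5, 10, 20, 50, 100} (capped at
the training-set size) and reporting the best top-1. The linear probe is
softmax regression on standardized features, full-batch gradient descent
from a zero init (hence invariant to row order), swept over learning rates.
Semi-supervised splits draw a per-class stratified sample at the requested
fraction (counts within 1 of exact proportionality; a fraction that would
give a class zero samples raises unless a flag bumps it to one); the test
split is never subsampled. Regression from features to the coverage score is
ordinary least squares, scored by test MSE and Kendall tau-b (tie-corrected).
Accuracies are reported in percent. The 2-D UMAP export (neighbors 15,
min-dist 0.1) is a qualitative convenience, not a tested surface.

## Known limitations

* **Final-stage attention maps at desk scale.** With the literal unscaled
  assignment rule, the clustering softmax is saturated by the common mode of
  its inputs: from initialization onward, all inputs at stages ≥ 1 route to
  a single [cls] token, and nothing in the distillation objective rewards
  routing diversity. Composed *final-stage* maps are therefore degenerate in
  the desk-scale runs (one token wins every pixel), and the corresponding
  acceptance check fails honestly. Stage-0 maps, by contrast, reliably
  segment structure (a dark blob's IoU ≈ 0.5 against a permutation null of
  ≈ 0.08). Diverse final-token maps are an emergent property of full-scale
  training that this package's reference experiment cannot reproduce.
* The EMA rule is the standard convex combination; training is
  single-threaded, single-device, double precision — no mixed-precision or
  distributed support.
* The semi-supervised protocol provides the split generator and frozen- or
  fine-tunable features, not a full fine-tuning schedule.
* Reproducibility is exact under a fixed seed and single-threaded BLAS;
  thread-count changes can perturb floating-point reductions.
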