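# Methods

## Problem

Individual animals with patterned coats (Holstein cattle being the canonical
case) can be re-identified from overhead or side imagery by treating the task
as retrieval: a *query* image is ranked against a *gallery* of images with
known identities, and the ranking is scored with CMC (Rank-1/Rank-5) and mAP.
`moo-reid` implements a complete retrieval pipeline of this kind — synthetic
data generation, a modified ResNet50 feature extractor, metric-learning
training, a query-adaptive matching stage, and the evaluation protocol — in
pure NumPy, including the reverse-mode autodiff core (`moo_reid.nn`) that the
models train with.

## Model

The backbone is a ResNet50 feature extractor (7x7/2 stem, 3x3/2 max-pool,
four bottleneck stages with [3, 4, 6, 3] blocks and output widths
256/512/1024/2048, global average pooling, no classifier; 23,508,032
trainable parameters in the all-standard configuration) with three
modifications:

**Dynamic bottleneck (stages 1 and 4).** Every bottleneck block in stages 1
and 4 replaces its dense 3x3 convolution with `DyConv`: three parallel
*depthwise* branches — a plain k x k (default 3x3), a 3x3 dilated at rate
d1 = 2 for local detail, and a 5x5 dilated at rate d2 = 2 for large-scale
context — fused with per-sample convex weights from a gating head (global
average pool -> linear C->3 -> softmax). All branches pad to preserve the
spatial size, so the block is a drop-in replacement; the depthwise design
keeps its parameter count (43C + 3C + 3) far below the dense 3x3's 9C^2.
After the fusion, `S2Attention` lets spatially distant pattern elements
interact: a 1x1 convolution expands the map to 3C channels, the three C-wide
slices become Q/K/V, each is average-pooled by `stride` (default 2) so
single-head scaled dot-product attention (scale 1/sqrt(C)) runs over
N = (H/stride)(W/stride) tokens, and the result is nearest-neighbour
upsampled and passed through a 1x1 output projection. Attention rows are
softmax-normalized; inputs whose H or W is not divisible by the stride are
rejected rather than padded. Stages 2-3 keep standard bottlenecks (dynamic
blocks there hurt in ablation) and can be narrowed via `width_factor_23`,
which scales only the squeezed internal channels so inter-stage interfaces
are untouched.

**NAM head (after stage 4).** Normalization-based attention derives
importance from batch-norm scale factors. Channel path: with BN output
B_out = alpha (B_in - mu)/sqrt(sigma^2 + eps) + beta, the per-channel weights
are W_a(i) = alpha_i / sum_j alpha_j and the gate is
Mc = sigmoid(W_a * BN(B_in)), applied multiplicatively. The weights are
signed exactly as written (a zero sum raises; `abs_weights` selects the
|alpha| variant). The spatial path mirrors this per pixel position
(statistics over batch x channels, trainable per-pixel scale/shift) and
composes multiplicatively with the channel gate; it is off by default, so
the NAM head contributes exactly 2C = 4,096 parameters at C = 2048 — the
delta the parameter accounting attributes to NAM.

**QAConv matcher.** Instead of comparing pooled embeddings, each gallery
image's feature map becomes a bank of L2-normalized p x p local kernels (one
per spatial position — the *class memory*). Matching correlates every kernel
with the normalized query map, keeps the maximum response over query
positions (S = H*W local scores in [-1, 1]), and converts the score vector
to one scalar through a BN -> FC(S->1) -> BN head. The head initializes to
identity normalizations and uniform positive weights, i.e. the mean local
score, and can be fitted on match/non-match pairs with a logistic loss
(`train_head`). Retrieval distance is negative QAConv similarity when the
matcher is enabled and Euclidean embedding distance otherwise. Ranking ties
break by gallery index (stable sort), making evaluation deterministic.

## Training protocol

P x K identity-balanced batches (batch 16 = 4 identities x 4 instances),
batch-hard triplet loss max(0, d_ap - d_an + m) with margin m = 0.3 on
Euclidean embedding distances, Adam with learning rate 1e-4 and first-moment
decay 0.9 ("momentum"), 80 epochs at full scale. An epoch covers
ceil(N/batch) batches. Augmentations: pad by 10 px and random-crop back,
horizontal flip (p = 0.5), random erasing (p = 0.5, area 2-20%). Input
images are scaled to [0, 1] and standardized by per-channel statistics of
the training split, which are stored in the checkpoint.

"Momentum 0.9 alongside Adam" is read as Adam's beta1; a plain momentum-SGD
mode exists behind `optimizer: sgd`.

## Synthetic data

Each identity is a fixed set of 4-9 dark elliptical patches (grayscale
20-60) on a light coat (205-240), positioned in normalized body coordinates
on an elliptical body. A render projects patch centres through a horizontal
shear+scale standing in for view angle (±60°), pastes the body on one of 4
flat-texture backgrounds, multiplies by an illumination factor in
[0.3, 1.2], optionally occludes with a gray rectangle, and adds Gaussian
pixel noise (sigma 3). Splits follow the re-identification convention,
train : gallery : query = 6:3:1 by largest remainder; `split_mode="identity"`
(default) holds out whole identities for testing and splits their images
gallery:query = 3:1, `split_mode="image"` splits every identity's images
6:3:1. Every query identity is guaranteed gallery support.

What the generator does *not* emulate: articulated pose, perspective
foreshortening beyond shear, soft shadows, motion blur, backgrounds with
structure. Passing the end-to-end check therefore demonstrates that the
pipeline learns and retrieves under controlled nuisance variation, not that
it reaches any particular accuracy on real barn imagery.

## Scaled-down end-to-end benchmark

Full-scale training is far beyond a desktop CPU, so the verifiable
end-to-end claim is made on a miniature instance
(`moo_reid.benchmark.run_reduced_benchmark`): stage widths divided by 4,
input 96 x 48, 10 identities x 12 images, identity-level split, 20 epochs
with the protocol above. Three deliberate configuration choices at this
scale:

* **S2Attention stride 1** — the reduced stage-4 maps are 3 x 2 and cannot
  be halved; stride is config-exposed and stays 2 at full scale.
* **QAConv on stage-3 maps with p = 3** — at 96 x 48 the stage-1 default
  produces 24 x 12 maps whose unit receptive fields are too generic to be
  identity-specific; stage-3 kernels with 3 x 3 patches are selective enough
  for the matcher to separate identities.
* **Frozen batch-norm statistics** (`freeze_bn=True`) — a 20-epoch run here
  is only ~100 gradient steps. BN running estimates converge within ~30
  batches regardless of the learning rate, while the weights stay near
  initialization, so live BN makes eval-mode behaviour drift away from what
  the loss optimized and the loss itself chases a moving normalization.
  With statistics frozen at their initial values the triplet loss converges
  cleanly (typically ~3.2 -> ~0.5 over the 20 epochs) and retrieval on the
  held-out identities reaches Rank-1 1.0/1.0/0.92 over seeds 0-2. Full-scale
  defaults keep live BN.

## Numerical choices

* Convolution is computed tap-by-tap with BLAS contractions; gradients are
  exact (verified against finite differences to ~1e-7).
* Batch-norm uses biased batch variance with eps = 1e-5 and momentum 0.1 for
  running estimates.
* Softmax subtracts the detached row maximum; attention uses scale
  1/sqrt(C).
* Zero-norm local patches stay zero in the class memory (no NaN).
* Degenerate inputs error loudly: even patch sizes, indivisible attention
  strides, empty galleries, query identities without gallery support, zero
  NAM scale-factor sums.
* Parameter counting covers exactly the trainable arrays (conv kernels, BN
  affine pairs, linear weights/biases); BN running statistics are buffers,
  not parameters.

## Known limitations

* The exact internal widths that would reproduce the reference ablation
  totals 16,473,629 / 19,675,421 / 19,679,517 are not recoverable from the
  published description; `parameter_report` documents the counts of this
  implementation instead of asserting those totals. The NAM delta (4,096)
  and the baseline total (23,508,032) are reproduced exactly.
* QAConv cost scales as S^2 per image pair; with full-size stage-1 maps
  (96 x 48 positions) matching is expensive, which is another reason the
  matcher runs on later stages at reduced scale.
* From-scratch training at the miniature problem size depends on the frozen
  BN regime described above; conclusions about full-scale optimization
  dynamics should not be drawn from it.
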