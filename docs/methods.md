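# Methods

This note documents the model implemented by `pcgnet`, the synthetic data it
is validated on, the numerical choices that are not obvious from the code,
and what the test suite does and does not establish.

## The segmentation network

The network maps a single-channel 2-D slice to per-pixel class probabilities
over M classes (background + M−1 structures). It is assembled from four
parts.

**Parallel encoder.** Two branches with matched output shapes and no shared
weights each produce a 4-stage feature pyramid (stage s emits C_s channels at
1/2^(s+1) of the input resolution; downsampling everywhere is patch merging —
folding each 2×2 neighbourhood into channels and projecting linearly, which
is lossless before the projection).

* The *CNN branch* stages are depth-2 nested U blocks: at constant resolution
  an internal encoder/decoder (two patch-merge descents, bilinear ascents
  with skip concatenation) is added residually to the stage input, extracting
  intra-stage multi-scale features.
* The *transformer branch* stages apply gated axial attention blocks. Axial
  attention factorises 2-D self-attention into 1-D passes along each image
  axis, reducing cost from O((HW)²) to O(HW·(H+W)). For a width pass with
  query position j and key position w in a row:

      logit(j,w) = q_j·k_w/√d + G_Q·(q_j·r_q[j,w]) + G_K·(k_w·r_k[j,w])
      y_j       = Σ_w softmax_w(logit) · (G_V1·v_w + G_V2·r_v[j,w])

  The positional tables r_q, r_k, r_v are full span×span grids of
  head-dimension vectors learned per head; G_Q, G_K, G_V1, G_V2 are learned
  scalars per head initialised at 1 (positional terms fully on). The plain
  content term q·k carries no gate, exactly as the attention rule is defined.

**Axial block locality.** One block applies the height-axis and width-axis
sub-layers to the *block input* and accumulates them residually, so a single
block's dependency set of pixel (i,j) is exactly row i ∪ column j. Feeding
the width pass the height-attended features instead would make every output
pixel depend on the entire image after one block (two hops), which
contradicts the advertised axial locality; global context still accumulates
across stacked blocks and stages. This choice is verified exhaustively by a
finite-difference probe in the test suite.

**Cascade graph fusion (CGM).** At each skip level, n "global" nodes are
built from the transformer features and n "local" nodes from the CNN
features with dilated 3×3 convolutions of increasing rates (each node sees a
different receptive field; rates are capped per level so the dilated kernel
fits the map). Intra-set edges e1 and the inter-set edge e2 are 3×3
convolutions of the sum over all ordered node pairs of α·first + β·second,
with α, β two learned scalars shared by both edge types. Because the pair
function is linear, the pair sum has the closed form n(α+β)Σ_i node_i; pairs
include i=j and are not normalised by n² (a `normalize_pairs` flag divides by
n² for numerical hygiene at large n; off by default). Messages gate each node
elementwise, M = node·(σ(e1_own) + σ(e2)), and a convolutional GRU
(3×3 kernels, update/reset gates, h' = z·h + (1−z)·candidate) updates node
states; all nodes of a set share one GRU and are processed in a single
stacked call. After t message-passing steps the 2n nodes are concatenated,
merged by a 3×3 convolution and projected 1×1 to the skip width. After two
steps every node provably depends on every node of both sets (probed by
finite differences in the suite).

**Progressive refinement decoder.** Four prediction branches, coarse to
fine. Branch i applies two conv–BN–ReLU pairs (γ_i) at a common feature
width, after concatenating the ×2-bilinear-upsampled previous feature with
that scale's fused skip, and adds the upsampled previous feature elementwise;
a 1×1 convolution (σ_i) emits class logits. The finest logits are upsampled
×2 to the input resolution. Training attaches the focal-dice loss to all four
scales (deep supervision, equal weights 1, ground truth downsampled by
nearest-neighbour striding); inference takes the argmax of the finest map
only. The plain (baseline) decoder is a standard one-shot upsample-concat-
conv path with a single output.

**Ablation variants.** `baseline` (CNN encoder, plain skips, plain decoder),
`level1` (+ progressive decoder), `level2` (attention encoder only),
`level3` (parallel encoder, concat-projection skips), `level4` (parallel +
CGM skips), `level5` (all three components).

## Losses

*Focal-dice*: l_DF = l_DSC + α·l_Focal with soft per-class confusion counts
TP(m)=Σp·g, FN(m)=Σg(1−p), FP(m)=Σ(1−g)p:

    l_DSC   = M − Σ_m TP/(TP + β·FN + η·FP),      l_Focal = −(1/N) Σ_m Σ_n g(1−p)² ln p

Defaults α=2, β=η=1. The sum runs over all classes including background (a
config flag excludes it). Natural log; probabilities are clamped at ε=1e−8
before the log, and ε is added to the dice denominator so an absent class
contributes a well-defined term. Both terms are strictly decreasing in the
true-class probability, so the compound is too (property-tested).

*Siamese stop-gradient loss*: L = ½S(p1, sg(z2)) + ½S(p2, sg(z1)) with S the
negative cosine similarity; sg blocks all gradient flow, which is what
prevents the twin branches from collapsing to a constant representation. The
autodiff contract (zero gradient through the z path, matching finite
differences with the z branch frozen) is asserted in the suite.

## Training procedures

*Contrastive pretraining* (images only, labels never read — enforced by a
tripwire test): two independent views per image from the augmentation
cluster (random resized crop 0.6–1.0, mirrors, rotation ±15°, affine jitter,
grayscale noise, intensity gain/bias), both branches encoded, deepest
features global-average-pooled and concatenated, a 3-layer batch-normalised
projector produces z and a 2-layer bottleneck predictor produces p. SGD with
momentum 0.9, weight decay 1e−4, base lr 0.05 linearly scaled by
batch/256, cosine decay. After training the MLP heads are discarded and the
encoder weights transfer into the full model (an explicit manifest partitions
transferred vs freshly initialised tensors).

*Supervised fine-tuning*: Adam (weight decay 1e−4), polynomial decay
lr·(1−e/E)^0.9, deep-supervised focal-dice, per-epoch validation mean DSC,
best-validation checkpointing. Full-scale defaults: lr 1e−4, batch 32,
150 epochs (pretraining: 50).

## Numerical substrate

No GPU framework is used: layers are pure functions over nested dicts of
float32 numpy arrays, differentiated with `autograd` (reverse mode). The 2-D
convolution is a custom primitive whose forward and both backward passes are
K² shift-and-matmul steps (BLAS) with hand-written vector-Jacobian products;
attention contractions are expressed as batched matmuls rather than einsum.
Batch normalisation uses in-trace batch statistics during training and
updates running statistics outside the trace; inference uses the running
statistics, so per-sample predictions are batch-independent. Content logits
are scaled by 1/√(head_dim) for numerical stability (the attention rule as
printed omits this; recorded as a deliberate deviation). Bilinear ×2
resampling uses half-pixel centres with replicated edges, so constant maps
stay constant. Everything is deterministic given the seed: one global seed
fans out to phantom generation, initialisation, batching and augmentation.

## Synthetic phantoms

The generator emulates the three properties of multi-site organ-at-risk CT
collections that the method is sensitive to: (a) structure sizes spanning
two orders of magnitude — default area fractions 0.04, 0.06, 0.03 (large:
brainstem/mandible/parotid-like) and 0.004, 0.002 (optic-nerve/chiasm-like,
well under 0.5% of pixels); (b) HU-like per-structure intensity bands over a
textured background with additive noise; (c) systematic cross-site intensity
shifts (gain/bias/gamma per "institution") separating the unlabeled
pretraining pool from the labeled fine-tuning split. Structures are
randomised superellipses placed without overlap; semi-axes are calibrated
from the exact superellipse area formula, and the mean realised area
fraction per structure stays within ±10% of target over 50 seeds (tested).

What the phantoms do **not** model: anatomy (shape priors, neighbouring-organ
context), CT physics (beam hardening, metal artifacts, partial-volume
effects in 3-D), annotation noise, or class co-occurrence statistics.
Passing the suite therefore demonstrates that the architecture, losses and
procedures are implemented correctly and can learn size-imbalanced
segmentation under cross-site shift — not that the reported clinical
accuracies transfer to real CT.

## Desk-scale study conditions

All heavyweight checks run on one CPU, so the study sizes are scaled down
(the architecture and procedures are unchanged):

| quantity | full-scale | desk scale |
|---|---|---|
| slice size | 512×512 | 64×64 for learnability runs; 48×48 for pretraining and smoke checks; phantom default 128 for data-level tests |
| stage channels | 32, 64, 128, 256 | 8, 16, 32, 64 |
| attention heads / stage | 4, 4, 8, 8 | 1, 1, 2, 2 (learnability); 2, 2, 2, 2 elsewhere |
| axial blocks / stage | 2 | 1 |
| CGM nodes / rates / steps | 4 / (1,2,4,8) / 2 | 2 / (1,2) / 2 |
| supervised protocol | Adam 1e−4, batch 32, 150 epochs | Adam 5e−3, batch 4, 15 epochs, BN momentum 0.8 |
| pretraining | SGD, batch 32, 50 epochs, lr 0.05·batch/256 | SGD, batch 4, 10 epochs, effective lr 0.05 |
| datasets | 223 unlabeled + 160 labeled | 50 unlabeled; 48 train / 16 val |

Two scale choices deserve justification. First, the learnability slice size
is 64, not smaller: the smallest structure's area fraction (0.002) must stay
*representable* after rasterisation — at 64² it spans ~8 pixels, still well
under 1% of the image, whereas at 48² it collapses to ~4–5 pixels and falls
below what any method can reliably segment; at the full 512² the same
fraction is ~500 pixels, so smaller desk images make the regime strictly
harder, not equivalent. Second, both optimisers run with small batches and
re-anchored learning rates: the scaled schedules contain only one to two
hundred optimisation steps, so batch 4 doubles the step count at equal
compute, the supervised learning rate rises to 5e−3, and the contrastive
learning rate keeps its full-scale *effective* value of 0.05 (the 256-sample
linear-scaling anchor would give 0.0016, which moves nothing in a 130-step
run). The batch-norm momentum is lowered to 0.8 so running statistics settle
within the short schedules, and the supervised augmentation pipeline (on by
default at full scale) is disabled — at ~180 steps it slows convergence
without improving the endpoint. With these conditions the scaled level-5 network
reaches ≈0.75 validation mean DSC over the five structures (median of seeds
0–2, large structures ≈0.97, the 16-px structure ≈0.85–0.91), and the
contrastive run reaches a final-epoch Siamese loss ≤ −0.5 without embedding
collapse.

**Desk-scale detection floor.** The smallest structure (area fraction 0.002,
~8 px at 64², and deliberately the lowest-contrast one, emulating the optic
chiasm — the hardest organ in clinical reports) is *not* detected under the
desk conditions: its DSC is 0 in every seed, doubling the epochs does not
change this, supervised augmentation does not change this, and a probability
probe shows the trained network is ~0.998 confident those pixels are
background. Two scale effects compound against it: partial-coverage
rasterisation dilutes its interior contrast from 0.15 to ≈0.10 at this size,
and a ~180-step schedule gives the optimiser little chance to discover an
8-pixel, ≈2σ blob. At the full 512² protocol the same fraction spans
hundreds of fully covered pixels. Ground truth for deep supervision is
downsampled by rarity-priority presence pooling (a coarse cell takes the
rarest class present in it) rather than stride sampling — stride sampling
deletes sub-stride structures from the coarse scales, whose branches then
actively train the network to suppress them; the two schemes coincide at
full scale where every organ spans many pixels at the coarsest map.

## Known limitations

- 2-D slices only; no volumetric context or 3-D surface distances.
- The Hausdorff metric is the classical maximum (HD95 available behind its
  own function); boundaries are mask pixels 4-connected to background.
- The full-scale (512×512, 150-epoch) protocol is expressed in the configs
  but is not practical on a single CPU; only the scaled protocol is exercised.
- GLCM heterogeneity features are diagnostics; the accompanying two-sample
  comparison (`compare_texture_distributions`) is a thin pass-through to
  scipy's Mann–Whitney U test, not a re-derivation. On absolute intensity
  scales pass a fixed `value_range`; per-image min–max quantisation removes
  exactly the gain/offset differences the diagnostic is meant to expose.
- The convolutional GRU and the edge convolutions make the CGM the most
  expensive component per parameter; `normalize_pairs` is available if large
  node counts push the edge sums into float32 saturation.
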