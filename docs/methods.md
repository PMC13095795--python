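# Methods

## Problem and model

`mvfuse` implements late multi-view fusion for fine-grained classification of
specimens photographed from three standardized viewpoints (dorsal, lateral,
ventral), in the setting of leaf-beetle taxonomy where the two target
subfamilies are diagnosed by traits living on different anatomical planes:
flea-beetle-like taxa (subfamily "A" throughout the code) by the hypertrophied
hind femur housing the metafemoral spring, visible laterally and ventrally,
and their sister lineage ("B") largely by antennal characters, visible
dorsally.

One shared CNN encoder f_θ maps every available view I_v to its final
convolutional feature map F_v = f_θ(I_v); the native classifier head of the
backbone is replaced by an identity so the encoder ends at the last conv
layer.  Global average pooling gives a per-view descriptor f_v = GAP(F_v) of
length C.  A per-view scoring head produces S_v = σ(W_v f_v + b_v); the
scores are softmax-normalized **over the available views only** into
attention weights α_v (missing views carry weight exactly 0), and the fused
descriptor

    f_fusion = Σ_v α_v f_v

feeds a dropout + linear species classifier.  Two ablation variants bracket
the attention model: `concat` (same shared encoder, fixed-order concatenation
of the f_v, zero-filled for missing views) and `baseline` (a single-stream
per-image classifier that ignores view structure).

Grad-CAM is computed at the final conv layer: channel weights
α_k^c = (1/Z) Σ_ij ∂y_c/∂A_ij^k with Z = h·w, heatmap
S_c = ReLU(Σ_k α_k^c A^k).  For fusion models the gradient flows through the
attention weights, so a view's map reflects its actual contribution to the
fused prediction.

## Design choices in ambiguous places

* **σ in the scoring head** defaults to tanh (bounded scores keep the 3-way
  softmax away from saturation); sigmoid, relu and identity are config
  options.  The subscripted W_v, b_v are honored with per-view scoring heads
  of identical shape; a `shared_scorer` flag collapses them to one head.
* **Scoring-head initialization is zero**, so training starts from exactly
  uniform attention.  In addition, the training protocol can freeze the
  scoring heads for the first `gate_warmup_epochs` epochs
  (`TrainConfig.gate_warmup_epochs`, default 0).  Without a warmup, the gate
  reliably collapses early onto the single most informative view — fused
  features then carry one view only, the other views stop receiving useful
  gradient, and accuracy pins at that view's information ceiling.  Freezing
  the gate while the encoder learns fusible features, then releasing it,
  removes the trap; after release the gate specializes correctly (on the
  benchmark it learns to suppress the uninformative lateral view to
  α ≈ 0.07).
* **Missing views**: masked out of the softmax for attention (weight exactly
  0, no gradient), zero-filled for concat.  About 15% of specimens lack one
  view, matching the completeness of realistic tri-view collections.
* **Top-20% activation selection** is read as the top 20% of pixels by value
  (threshold at the 80th percentile), which is scale-invariant; tie pixels at
  the threshold are retained and constant maps are flagged degenerate.  The
  other reading — values ≥ 0.8 after min-max normalization — is available as
  ``mode="value_threshold"``.
* **Morphological refinement** is binary opening followed by closing with a
  3×3 cross element; components smaller than 0.1% of the image are dropped;
  components are 8-connected.
* **Region recording**: a region is recorded for an image when it holds at
  least τ = 0.15 of the activated pixels; several regions may be recorded per
  image, background never.  An alternative rule records the region under each
  connected component's centroid (``rule="centroid"``).  Activation
  Rate(r) = N_r / N per (subfamily, view) subset.
* **Split protocol**: species-stratified 70/15/15 with largest-remainder
  rounding; at equal remainders the seat order is train > val > test (so 10
  specimens split 7/2/1).  The split unit is the specimen, and augmented
  derivatives always inherit their parent's partition, which eliminates
  same-specimen leakage by construction; an image-level mode exists for
  fidelity comparisons.
* **MAC accounting** counts multiply-accumulates over conv and fully
  connected layers at 224×224 with the 1000-class head attached, the
  convention under which the standard printed figures for these backbones
  (ResNet18 1.8 G, ResNet50 4.1 G, VGG16 15.5 G) are reproduced exactly;
  parameter totals match the canonical ImageNet configurations to the digit
  (e.g. ResNet50 = 25,557,032).
* **Unfreezing**: "late-stage residual blocks" is read as the final residual
  stage (`layer4`) only, with `include_penultimate` to widen it; VGG16
  unfreezes all 13 conv layers; MobileNetV2 only its final 1×1 conv block.

## Numerical engine

No GPU deep-learning framework is assumed: the package carries a small
reverse-mode automatic differentiation engine on NumPy float32 arrays
(`mvfuse.engine`) with exactly the operations the models need — im2col
convolution (grouped), max pooling, fused batch normalization with the
closed-form gradient, linear layers, the activations, dropout, and row
gather/scatter for routing incomplete triplets through one shared encoder.
All gradients are verified against central differences in the test suite.
Two implementation details matter for correctness:

* **Batch statistics cover all views jointly.**  All available images of a
  batch are encoded in one concatenated forward pass, so train-mode
  batch-norm statistics and the eval-mode running statistics describe the
  same distribution.  (Encoding views in separate forward passes gives each
  view its own batch statistics in training but blended running statistics
  at evaluation — a train/eval mismatch that destabilizes validation.)
* **Graphs are freed deterministically** after `backward()` (nodes and their
  closures form reference cycles that Python's GC reclaims too slowly for
  arrays of this size).

Training uses Adam with classic L2 weight decay, step-decay learning rate
(lr·γ^⌊(epoch−1)/step⌋, epochs 1-based), early stopping on validation top-1
(configurable to loss), and restores the best-validation checkpoint including
batch-norm buffers.  The `amp` flag emulates reduced-precision arithmetic by
quantizing batch inputs through float16; it is a performance experiment, not
a correctness dependency, and drift is bounded (checked ≤1% relative on the
fixture).  Default fine-tuning hyperparameters (lr 1e-4, weight decay 1e-4,
step 10, γ 0.1, batch 32, patience 10) are a standard transfer-learning
regime; the experiment runner repeats training over the fixed seed set
(42, 100, 2024, 7, 99) and reports mean ± sample std (n−1).

## Synthetic specimen generator

The generator is the package's study system: procedural "beetles" rendered
at 96×96 in three synchronized views with ground-truth part masks (head,
thorax, abdomen, antennae, legs).  Class information is split across views
by construction:

* subfamily A draws a hind femur 2× enlarged (lateral and ventral views);
  subfamily B draws 2.4× longer antennae (dorsal view); lateral antennae are
  drawn identically for both subfamilies, so the lateral subfamily cue is
  the femur alone;
* the species code within a subfamily is split into a dorsal sub-code
  (elytral spot pairs) and a ventral sub-code (abdominal bands), so with 4
  species per subfamily a dorsal-only or ventral-only classifier faces a 50%
  information ceiling and a lateral-only classifier a 25% ceiling, while
  dorsal+ventral can reach the oracle.

Nuisance variation emulates collection heterogeneity: per-specimen body
scale (±8%), position jitter, body-color tint, background gray level and
texture, and additive pixel noise (σ = 0.03 of full scale).  Views are
dropped at most one per specimen with probability 0.15, so the
complete-triplet rate is 0.85 exactly in expectation (independent per-view
dropping cannot reach an 85% complete rate at plausible per-view rates).
Additionally, with probability 0.25 one present view of a specimen is
captured under degraded conditions (defocus blur, contrast washout, heavy
sensor noise).  This emulates the suboptimal imaging that motivates
per-specimen view weighting in the first place: a fixed-weight fusion
(concat) must absorb the degraded view's features, while the attention gate
can detect and downweight them per specimen — the structural reason the
attention variant outperforms concatenation on this benchmark rather than
merely tying it.  Subfamily-B antennae are drawn with clubbed terminal
segments (the taxonomically salient character), giving the antennal region
enough visual mass that class-discriminative attention on it is resolvable
at the CAM's spatial granularity.

What the generator does **not** emulate: photographic texture, lighting
geometry, pose articulation, occlusion, museum-specimen damage, or
intra-species morphological variation beyond global scale and tint.  Passing
benchmark tests therefore demonstrate that the architecture orders correctly
when information is distributed across views as designed — not field
performance on real imagery.

## Benchmark protocol and problem sizes

The desk-scale benchmark uses 2 subfamilies × 4 species × 60 specimens
(480 specimens, ~1,370 images), 96×96 renders pad-resized to 32×32 model
input, the ~47k-parameter `tinycnn` reference backbone (three Conv-BN-ReLU
blocks, 16/32/96 channels, final map ⌀ input/4), and three protocol seeds
(42, 100, 2024).  The training protocol for this benchmark is Adam 3e-3,
weight decay 1e-4, γ 0.3 every 20 epochs, batch 32, max 35 epochs, patience
12, gate warmup 18 epochs (`mvfuse.evaluator.benchmark_train_config`).  The
ablation grid covers the three single-view per-image baselines, concat,
attention, and the dorsal+lateral / dorsal+ventral attention pairs.  The
standalone reproduction script (`scripts/acceptance.py`) runs the same grid
over the first two protocol seeds, a scaled-down report of the same
computation.

On a fixed dataset draw the full pipeline is deterministic, so the reported
orderings are exactly reproducible; across independent dataset draws the
attention-versus-concat gap is small (both near ceiling) and its sign can
vary, while the fusion-versus-single-view and dorsal+ventral-versus-
dorsal+lateral gaps are large and stable.

## Known limitations

* The engine is CPU/NumPy; the large backbones are practical for forward
  passes and accounting, not for full training.
* ImageNet pretraining is supported only as an explicit error path (no
  offline weights); fine-tuning experiments on real data would load local
  weight files.
* The baseline variant evaluates per image; specimen-level aggregation is
  provided as majority vote but is not the primary comparison.
* Grad-CAM maps at tinycnn's 8×8 final resolution are coarse; region
  assignment uses activated-mass fractions rather than precise boundaries
  for exactly this reason.
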