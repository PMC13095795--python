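# mvfuse

Multi-view CNN fusion with self-adaptive view attention and quantitative
Grad-CAM interpretability, for fine-grained classification of specimens
photographed from synchronized dorsal, lateral and ventral viewpoints.

## The problem

In leaf-beetle taxonomy (and fine-grained biological imaging generally), the
diagnostic traits of closely related lineages live on different anatomical
planes: flea beetles (Alticinae) are recognized by the hypertrophied hind
femur housing the metafemoral spring — a lateral/ventral character — while
their sister lineage (Galerucinae) is diagnosed largely by antennal and
dorsal-surface characters.  No single photograph suffices; a classifier must
integrate complementary views the way a taxonomist turns a specimen under
the microscope.

`mvfuse` implements that integration as late fusion over a shared encoder.
For each available view v ∈ {dorsal, lateral, ventral}:

    F_v = f_θ(I_v)                  shared CNN, final conv feature map
    f_v = GAP(F_v)                  per-view descriptor, length C
    S_v = σ(W_v f_v + b_v)          per-view attention score
    α_v = softmax over available views
    f_fusion = Σ_v α_v f_v          attention-weighted fusion
    logits = W f_fusion + b         dropout + linear species head

with a `concat` variant (fixed-order concatenation, missing views
zero-filled) and a per-image single-stream `baseline` as ablation controls.
Interpretability follows Grad-CAM at the final conv layer
(α_k^c = (1/Z)Σ_ij ∂y_c/∂A^k_ij, S^c = ReLU(Σ_k α_k^c A^k)) with a
quantification pipeline — normalize, keep the top 20% of pixels,
morphological refinement, connected components, region assignment against
part masks — that turns heatmaps into per-(subfamily, view, region)
activation rates N_r/N.

Because curated tri-view beetle collections are not freely downloadable, the
package ships a procedural specimen generator that reproduces the *structure*
of such data — two subfamilies whose discriminative traits sit in different
views, species codes split between dorsal and ventral patterns, ~85%
complete triplets, occasional degraded captures, ground-truth part masks —
so every claim the package
makes is testable end-to-end offline.  The models run on a small NumPy
autodiff engine included in the package; no GPU framework is required.

## Worked example

```bash
# 1. generate a synthetic tri-view dataset (8 species, 480 specimens)
mvfuse generate --out dataset/ --seed 0

# 2. species-stratified 70/15/15 split at specimen level
mvfuse split --manifest dataset/manifest.csv --seed 0 --out splits.json
# -> wrote splits.json {'train': 336, 'val': 72, 'test': 72}

# 3. inspect the backbone registry (parameter/MAC accounting)
mvfuse backbones
# backbone,params_M,macs_G,feature_dim,final_map,unfreeze_policy
# mobilenetv2,3.5,0.3,1280,7,mnv2_last_block
# resnet18,11.7,1.8,512,7,resnet_last_stage
# resnet50,25.6,4.1,2048,7,resnet_last_stage
# tinycnn,0.1,0.1,96,56,all
# vgg16,138.4,15.5,512,7,vgg_all_conv
```

The parameter and MAC columns are recomputed from the architecture
definitions (25.6 M / 4.1 G-MAC for ResNet50 means 25,557,032 parameters and
4.089·10⁹ multiply-accumulates for one 224×224 forward pass with the
1000-class head).

Training and evaluating the ablation grid from Python:

```python
from mvfuse.dataset_io import load_dataset, load_manifest, stratified_split
from mvfuse.evaluator import (BENCHMARK_GRID, benchmark_train_config,
                              run_ablation)

data = load_dataset("dataset/manifest.csv", input_size=32)
split = stratified_split(load_manifest("dataset/manifest.csv"), seed=0)
result = run_ablation(data, split, BENCHMARK_GRID, seeds=(42, 100, 2024),
                      train_config=benchmark_train_config(), input_size=32,
                      model_kwargs={"dropout_p": 0.2})
print(result.to_frame()[["variant", "views", "top1_mean", "top1_std",
                         "delta_acc"]])
```

With the generator seeded at 0 this prints (test top-1, mean ± sample std
over the three seeds):

| variant   | views | top-1         | Δ acc |
|-----------|-------|---------------|-------|
| baseline  | d     | 0.469 ± 0.008 | —     |
| baseline  | l     | 0.227 ± 0.022 | —     |
| baseline  | v     | 0.498 ± 0.008 | —     |
| concat    | d+l+v | 0.940 ± 0.028 | +0.44 |
| attention | d+l+v | 0.944 ± 0.000 | +0.45 |
| attention | d+l   | 0.444 ± 0.037 | −0.05 |
| attention | d+v   | 0.944 ± 0.024 | +0.45 |

Single views are pinned near their designed information ceilings (the
species code is split between dorsal spots and ventral bands, so
dorsal-only ≈ 0.5 and lateral-only ≈ 0.25 are the best achievable); fusing
views recovers the full signal, attention edges out plain concatenation, and
dorsal+ventral dominates dorsal+lateral — the orderings the architecture is
supposed to produce.  The trained attention gate suppresses the
uninformative lateral view (α ≈ 0.07 on average).  Interpretability closes
the loop:

```bash
mvfuse quantify --ckpt runs/model_seed42.npz --dataset dataset/ \
                --splits splits.json --partition test --tau 0.15
```

prints the activation-rate table; on the benchmark the "legs" rate exceeds
the "antennae" rate in subfamily-A lateral views (the model looks at the
femur bulge) and the reverse holds in subfamily-B dorsal views (it looks at
the antennae).

## Layout

| module | contents |
|---|---|
| `mvfuse.engine` | NumPy reverse-mode autodiff: conv/pool/BN/linear, Adam-ready |
| `mvfuse.dataset_io` | manifests, stratified splits, pad-resize, synchronized augmentation |
| `mvfuse.backbone_zoo` | ResNet18/50, VGG16, MobileNetV2, tinycnn; accounting; unfreezing |
| `mvfuse.multiview_model` | shared-weight encoding, view attention, fusion variants |
| `mvfuse.trainer` | Adam + step decay, early stopping, gate warmup, multi-seed runner |
| `mvfuse.evaluator` | metric suite, confusion/cross-subfamily analysis, McNemar/paired tests, ablation harness |
| `mvfuse.interpretability` | Grad-CAM, mask post-processing, activation rates, Cohen's kappa |
| `mvfuse.synthetic_specimens` | procedural tri-view specimen generator with part masks |
| `mvfuse.cli` / `mvfuse.config` | `mvfuse` command-line pipeline and YAML config schema |

See `docs/methods.md` for the model, the generator's design and its limits,
and every numerical convention.
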