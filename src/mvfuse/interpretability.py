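"""Grad-CAM computation and quantitative activation analysis.

For a class score y_c and the final convolutional feature maps A^k of one
view, channel weights are the spatially averaged gradients
alpha_k = (1/Z) sum_ij dy_c/dA^k_ij (Z = h*w), and the heatmap is
S_c = ReLU(sum_k alpha_k A^k).  The post-processing chain upsamples the map
to the input resolution, min-max normalizes it, keeps the top 20% of pixels
by value (80th-percentile threshold, ties retained), refines the binary mask
morphologically (opening then closing, 3x3 cross), and extracts 8-connected
components with bounding boxes.

Region assignment compares the refined mask against a part-label annotation:
a region is recorded when it holds at least a fraction `tau` (default 0.15)
of the activated pixels; several regions may be recorded per image, and
background is never recorded.  Activation rates aggregate the recorded
regions over (subfamily, view) subsets as N_r / N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops
from skimage.transform import resize as sk_resize

from .dataset_io import ViewTriplet
from .engine import Tensor
from .multiview_model import MultiViewClassifier
from .synthetic_specimens import REGION_LABELS

CROSS_3x3 = ndimage.generate_binary_structure(2, 1)  # 3x3 cross element


@dataclass
class Heatmap:
    values: np.ndarray  # h x w, nonnegative
    class_index: int
    view: str
    layer: str = "final_conv"

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if not np.all(np.isfinite(v)) or (v < 0).any():
            raise ValueError("heatmap must be finite and nonnegative")
        self.values = v


@dataclass
class ChannelWeights:
    alpha: np.ndarray  # per-channel weights alpha_k
    Z: int  # number of spatial positions


@dataclass
class Component:
    pixels: np.ndarray  # boolean mask of this component
    bbox: tuple  # (min_row, min_col, max_row, max_col) exclusive
    area: int


@dataclass
class ActivationMask:
    mask: np.ndarray  # binary, input resolution
    components: list = field(default_factory=list)
    degenerate: bool = False
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------


def compute_cam(model: MultiViewClassifier, triplet: ViewTriplet, view: str,
                class_c: int | None = None) -> tuple[Heatmap, ChannelWeights]:
    """Grad-CAM for one view of one triplet at the final conv layer.

    `class_c` defaults to the predicted class.  The gradient of y_c flows
    through the full fusion head (including the attention weights), so the
    map reflects the view's actual contribution to the fused prediction.
    """
    if view not in triplet.images:
        raise ValueError(f"view {view!r} not available for this specimen")
    model.eval()
    if model.variant == "baseline":
        from .multiview_model import _to_input

        logits = model.forward_images(_to_input(triplet.images[view])[None])
    else:
        logits = model.forward_triplet(triplet)
    if class_c is None:
        class_c = int(logits.data[0].argmax())
    onehot = np.zeros_like(logits.data)
    onehot[0, class_c] = 1.0
    (logits * Tensor(onehot)).sum().backward()
    key = view if view in model.last_maps else "image"
    A = model.last_maps[key]
    if A.data.ndim != 4 or A.data.shape[2] < 1:
        raise ValueError("target layer has no spatial activations")
    row = int(model._last_rows[key][0]) if key in model._last_rows else 0
    amap = A.data[row]  # (C, h, w)
    grads = A.grad[row]
    Z = amap.shape[1] * amap.shape[2]
    alpha = grads.mean(axis=(1, 2))  # (1/Z) sum_ij dy/dA
    cam = np.maximum((alpha[:, None, None] * amap).sum(axis=0), 0.0)
    return (Heatmap(cam, class_c, view), ChannelWeights(alpha, Z))


# ---------------------------------------------------------------------------
# Post-processing chain
# ---------------------------------------------------------------------------


def select_top_fraction(values: np.ndarray, frac: float = 0.2,
                        mode: str = "pixel_fraction") -> tuple[np.ndarray, bool]:
    """Retain the top-activation pixels of a (normalized) heatmap.

    ``mode="pixel_fraction"`` (default) keeps pixels at or above the
    (1-frac) percentile — on all-distinct values exactly `frac` of the
    pixels, scale-invariantly.  ``mode="value_threshold"`` keeps pixels with
    value >= 1-frac of the map's range (the alternative reading of a
    "top-20%" rule).  Tie pixels at the threshold are retained; a constant
    map (all ties) is flagged degenerate.
    """
    v = np.asarray(values, float)
    degenerate = bool(np.isclose(v.max(), v.min()))
    if mode == "pixel_fraction":
        thr = np.percentile(v, 100 * (1 - frac))
    elif mode == "value_threshold":
        thr = v.min() + (1 - frac) * (v.max() - v.min())
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return v >= thr, degenerate


def postprocess_cam(heatmap: Heatmap | np.ndarray, input_shape: tuple,
                    top_frac: float = 0.2, structure: np.ndarray = CROSS_3x3,
                    min_area_frac: float = 0.001) -> ActivationMask:
    """Upsample -> normalize -> top-20% -> opening -> closing -> components."""
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap, float)
    if values.max() <= 0:
        return ActivationMask(np.zeros(input_shape, bool),
                              provenance={"empty": "all-zero heatmap"})
    up = sk_resize(values, input_shape, order=1, preserve_range=True,
                   anti_aliasing=False)
    lo, hi = float(up.min()), float(up.max())
    norm = (up - lo) / (hi - lo) if hi > lo else np.ones_like(up)
    selected, degenerate = select_top_fraction(norm, top_frac)
    refined = ndimage.binary_opening(selected, structure=structure)
    refined = ndimage.binary_closing(refined, structure=structure)
    comps = extract_components(refined, min_area_frac=min_area_frac)
    mask = np.zeros(input_shape, bool)
    for comp in comps:
        mask |= comp.pixels
    return ActivationMask(mask, comps, degenerate,
                          provenance={"top_frac": top_frac,
                                      "morphology": "open-close 3x3 cross",
                                      "min_area_frac": min_area_frac})


def extract_components(mask: np.ndarray, min_area_frac: float = 0.001) -> list:
    """8-connected components with minimal axis-aligned bounding boxes;
    components smaller than `min_area_frac` of the image are dropped."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        return []
    min_area = max(1, int(round(min_area_frac * mask.size)))
    labeled = cc_label(mask, connectivity=2)
    out = []
    for prop in regionprops(labeled):
        if prop.area < min_area:
            continue
        out.append(Component(pixels=labeled == prop.label,
                             bbox=tuple(prop.bbox), area=int(prop.area)))
    return out


# ---------------------------------------------------------------------------
# Region assignment and activation rates
# ---------------------------------------------------------------------------


def assign_regions(mask: np.ndarray | ActivationMask, annotation: np.ndarray,
                   tau: float = 0.15, rule: str = "mass") -> set:
    """Regions activated by a refined mask; background never recorded.

    ``rule="mass"`` (default) records region r when it holds >= tau of the
    activated pixels.  ``rule="centroid"`` records the region under each
    connected component's centroid (tau is ignored).
    """
    components = mask.components if isinstance(mask, ActivationMask) else None
    if isinstance(mask, ActivationMask):
        mask = mask.mask
    mask = np.asarray(mask, bool)
    annotation = np.asarray(annotation)
    if mask.shape != annotation.shape:
        raise ValueError(
            f"mask {mask.shape} and annotation {annotation.shape} differ")
    if not mask.any():
        return set()
    if rule == "centroid":
        if components is None:
            components = extract_components(mask, min_area_frac=0.0)
        out = set()
        for comp in components:
            rows, cols = np.nonzero(comp.pixels)
            label = int(annotation[int(rows.mean().round()),
                                   int(cols.mean().round())])
            if REGION_LABELS.get(label, "background") != "background":
                out.add(REGION_LABELS[label])
        return out
    if rule != "mass":
        raise ValueError(f"unknown region-recording rule {rule!r}")
    total = mask.sum()
    out = set()
    for rid, name in REGION_LABELS.items():
        if name == "background":
            continue
        frac = np.sum(mask & (annotation == rid)) / total
        if frac >= tau:
            out.add(name)
    return out


@dataclass
class AssignmentRecord:
    specimen_id: str
    subfamily: str
    view: str
    regions: set


@dataclass
class ActivationRateTable:
    rates: dict  # (subfamily, view, region) -> rate
    counts: dict  # (subfamily, view, region) -> N_r
    totals: dict  # (subfamily, view) -> N

    def rate(self, subfamily: str, view: str, region: str) -> float:
        key = (subfamily, view)
        if key not in self.totals:
            raise KeyError(f"empty subset {key}")
        return self.rates.get((subfamily, view, region), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        regions = [n for n in REGION_LABELS.values() if n != "background"]
        for (sf, view), n in sorted(self.totals.items()):
            for region in regions:
                rows.append({"subfamily": sf, "view": view, "region": region,
                             "N": n,
                             "N_r": self.counts.get((sf, view, region), 0),
                             "rate": self.rates.get((sf, view, region), 0.0)})
        return pd.DataFrame(rows)


def activation_rates(assignments: list) -> ActivationRateTable:
    """Rate(r) = N_r / N per (subfamily, view) subset.

    N counts images in the subset, N_r images where region r was recorded;
    an image recording several regions counts once for each, so rates across
    regions may sum above 1.
    """
    totals: dict = {}
    counts: dict = {}
    for rec in assignments:
        key = (rec.subfamily, rec.view)
        totals[key] = totals.get(key, 0) + 1
        for region in rec.regions:
            k3 = key + (region,)
            counts[k3] = counts.get(k3, 0) + 1
    rates = {k: counts[k] / totals[k[:2]] for k in counts}
    return ActivationRateTable(rates, counts, totals)


def quantify_activations(model: MultiViewClassifier, dataset, ids: list,
                         annotation_loader, tau: float = 0.15,
                         class_mode: str = "predicted") -> ActivationRateTable:
    """Full interpretability pipeline over a split.

    For every available view of every listed specimen: Grad-CAM at the final
    conv layer for the predicted (or true) class, post-processing to a
    refined activation mask at annotation resolution, region assignment
    against the ground-truth part masks, then Rate = N_r / N aggregation.
    """
    assignments = []
    for sid in ids:
        triplet = dataset.triplets[sid]
        for view in model.views:
            if view not in triplet.images:
                continue
            annotation = annotation_loader(sid, view)
            cls = None if class_mode == "predicted" else triplet.label
            heat, _ = compute_cam(model, triplet, view, cls)
            act = postprocess_cam(heat, annotation.shape)
            regions = assign_regions(act, annotation, tau)
            assignments.append(AssignmentRecord(
                sid, dataset.subfamilies[triplet.subfamily], view, regions))
    return activation_rates(assignments)


# ---------------------------------------------------------------------------
# Inter-annotator agreement
# ---------------------------------------------------------------------------


@dataclass
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    degenerate: bool = False


def cohens_kappa(labels_a, labels_b) -> KappaResult:
    """Cohen's kappa with marginal-product chance agreement."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("label vectors must be equal-length and nonempty")
    cats = np.unique(np.concatenate([a, b]))
    n = a.size
    po = float(np.mean(a == b))
    pa = np.array([(a == c).mean() for c in cats])
    pb = np.array([(b == c).mean() for c in cats])
    pe = float(pa @ pb)
    if np.isclose(pe, 1.0):
        return KappaResult(float("nan"), po, pe, degenerate=True)
    return KappaResult((po - pe) / (1 - pe), po, pe)
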