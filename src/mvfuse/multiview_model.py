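"""Shared-weight multi-view classification with self-adaptive view attention.

The forward computation mirrors the late-fusion design: every available view
of a specimen is encoded by ONE shared CNN encoder into a feature map F_v,
global average pooling turns each map into a vector f_v, a per-view scoring
head produces a scalar S_v = sigma(W_v f_v + b_v), the scores are softmax
normalized OVER AVAILABLE VIEWS ONLY into attention weights alpha_v, and the
fused descriptor f_fusion = sum_v alpha_v f_v feeds a dropout + linear
classifier.

Three variants are exposed:

* ``attention`` — the full model described above;
* ``concat``   — shared-weight encoding, fixed-order concatenation of the
  f_v (missing views zero-filled), no attention;
* ``baseline`` — a single-stream per-image classifier that ignores view
  structure (each image is an independent sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone_zoo import build_encoder, get_spec
from .dataset_io import VIEWS, ViewTriplet
from .engine import (Dropout, Linear, Module, Tensor, concat, dropout,
                     gather_rows, global_avg_pool, scatter_rows)

SIGMAS = {
    "tanh": lambda t: t.tanh(),
    "sigmoid": lambda t: t.sigmoid(),
    "relu": lambda t: t.relu(),
    "identity": lambda t: t,
}

_SIGMAS_NP = {
    "tanh": np.tanh,
    "sigmoid": lambda x: 1.0 / (1.0 + np.exp(-x)),
    "relu": lambda x: np.maximum(x, 0.0),
    "identity": lambda x: x,
}


@dataclass
class ModelConfig:
    variant: str = "attention"  # {baseline, concat, attention}
    views: tuple = VIEWS
    n_classes: int = 2
    dropout_p: float = 0.5
    backbone: str = "tinycnn"
    sigma: str = "tanh"
    shared_scorer: bool = False
    input_size: int = 224
    pretrained: bool = False

    def validate(self) -> None:
        if self.variant not in ("baseline", "concat", "attention"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not self.views or any(v not in VIEWS for v in self.views):
            raise ValueError(f"views must be a nonempty subset of {VIEWS}")
        if self.sigma not in SIGMAS:
            raise ValueError(f"sigma must be one of {sorted(SIGMAS)}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")


@dataclass
class FeatureBundle:
    """Per-view feature maps F_v (C,h,w) and GAP vectors f_v (C,)."""

    maps: dict
    vectors: dict

    @property
    def views(self):
        return tuple(self.maps)


@dataclass
class AttentionWeights:
    scores: dict  # view -> scalar S_v (available views only)
    alpha: dict  # view -> weight; missing views carry exactly 0


# ---------------------------------------------------------------------------
# Functional per-triplet operations (NumPy; the batched Module mirrors them)
# ---------------------------------------------------------------------------


def encode_views(triplet: ViewTriplet, encoder: Module,
                 normalize: bool = True) -> FeatureBundle:
    """Encode every available view with the shared encoder and GAP."""
    if not triplet.images:
        raise ValueError("triplet has no available views")
    encoder.eval()
    maps, vectors = {}, {}
    for view, img in triplet.images.items():
        x = _to_input(img, normalize)
        F = encoder(Tensor(x[None])).data[0]  # (C, h, w)
        maps[view] = F
        vectors[view] = F.mean(axis=(1, 2))
    return FeatureBundle(maps, vectors)


def _to_input(img: np.ndarray, normalize: bool = True) -> np.ndarray:
    x = np.asarray(img, np.float32)
    if x.ndim == 2:
        x = x[:, :, None]
    x = x.transpose(2, 0, 1)
    if normalize:
        x = x / 127.5 - 1.0
    return x


def compute_attention(bundle: FeatureBundle, scoring_heads: dict,
                      sigma: str = "tanh") -> AttentionWeights:
    """S_v = sigma(W_v f_v + b_v); softmax over available views only."""
    if not bundle.vectors:
        raise ValueError("all views missing")
    act = _SIGMAS_NP[sigma]
    scores = {}
    for view, f in bundle.vectors.items():
        head = scoring_heads[view]
        scores[view] = float(act(head.weight.data @ f + head.bias.data)[0])
    views = list(scores)
    s = np.array([scores[v] for v in views])
    e = np.exp(s - s.max())
    a = e / e.sum()
    alpha = {v: 0.0 for v in VIEWS}
    alpha.update({v: float(w) for v, w in zip(views, a)})
    return AttentionWeights(scores=scores, alpha=alpha)


def fuse_views(bundle: FeatureBundle, weights: AttentionWeights) -> np.ndarray:
    """f_fusion = sum_v alpha_v f_v (length C)."""
    dims = {f.shape[0] for f in bundle.vectors.values()}
    if len(dims) != 1:
        raise ValueError(f"inconsistent feature dimensions {dims}")
    (C,) = dims
    out = np.zeros(C, np.float32)
    for view, f in bundle.vectors.items():
        out += weights.alpha[view] * f
    return out


def fuse_concat(bundle: FeatureBundle, view_order: tuple = VIEWS,
                feature_dim: int | None = None) -> np.ndarray:
    """Fixed-order concatenation; missing views zero-filled."""
    if feature_dim is None:
        feature_dim = next(iter(bundle.vectors.values())).shape[0]
    blocks = [bundle.vectors.get(v, np.zeros(feature_dim, np.float32))
              for v in view_order]
    return np.concatenate(blocks)


def classify(fused: np.ndarray, head: Linear, training: bool = False,
             dropout_p: float = 0.0,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """Dropout (training only) followed by the linear species head."""
    if fused.shape[-1] != head.in_features:
        raise ValueError(
            f"fused dimension {fused.shape[-1]} != head input {head.in_features}")
    x = Tensor(fused[None] if fused.ndim == 1 else fused)
    x = dropout(x, dropout_p, training, rng)
    logits = head(x).data
    return logits[0] if fused.ndim == 1 else logits


# ---------------------------------------------------------------------------
# Batched trainable model
# ---------------------------------------------------------------------------


class MultiViewClassifier(Module):
    """Batched forward over (possibly incomplete) view triplets.

    The batch format is ``images[view] -> (N,3,H,W) float32`` plus
    ``avail[view] -> (N,) bool``; the shared encoder runs only on the rows
    where a view is present, and missing views are masked out of the
    attention softmax (attention variant) or zero-filled (concat variant).
    Masked views receive exactly zero attention weight and contribute no
    gradient.
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        config.validate()
        self.config = config
        spec = get_spec(config.backbone, config.pretrained)
        self.encoder = build_encoder(spec)
        self.feature_dim = self.encoder.feature_dim
        self.variant = config.variant
        self.views = tuple(config.views)
        if self.variant == "attention":
            if config.shared_scorer:
                shared = Linear(self.feature_dim, 1)
                self.scorers = {v: shared for v in self.views}
                self._scorer_list = [shared]
            else:
                self._scorer_list = [Linear(self.feature_dim, 1) for _ in self.views]
                self.scorers = dict(zip(self.views, self._scorer_list))
            for sc in self._scorer_list:
                # zero-init gating: training starts from uniform attention
                sc.weight.data[:] = 0.0
                sc.bias.data[:] = 0.0
        head_in = self.feature_dim * (len(self.views) if self.variant == "concat" else 1)
        self.head = Linear(head_in, config.n_classes)
        self.drop = Dropout(config.dropout_p)
        self.last_maps: dict = {}  # view -> Tensor feature map of last forward
        self._last_rows: dict = {}

    # -- forward -----------------------------------------------------------
    def forward(self, images: dict, avail: dict) -> Tensor:
        n = len(next(iter(avail.values())))
        any_view = np.zeros(n, bool)
        for v in self.views:
            if v in avail:
                any_view |= np.asarray(avail[v], bool)
        if not any_view.all():
            raise ValueError(
                f"{int((~any_view).sum())} batch rows have zero available views")
        self.last_maps.clear()
        self._last_rows.clear()

        # one concatenated forward over all available (view, specimen) images:
        # batch-norm statistics then cover every view jointly, matching the
        # running statistics used at eval time
        rows_per_view = {v: np.flatnonzero(avail.get(v, np.zeros(n, bool)))
                         for v in self.views}
        stacked = np.concatenate([images[v][rows_per_view[v]]
                                  for v in self.views if len(rows_per_view[v])])
        F = self.encoder(Tensor(stacked))
        f_all = global_avg_pool(F)

        vectors = {}
        masks = {}
        offset = 0
        for v in self.views:
            rows = rows_per_view[v]
            masks[v] = np.zeros((n, 1), np.float32)
            masks[v][rows] = 1.0
            if len(rows) == 0:
                vectors[v] = Tensor(np.zeros((n, self.feature_dim), np.float32))
                continue
            self.last_maps[v] = F
            self._last_rows[v] = np.arange(offset, offset + len(rows))
            f = gather_rows(f_all, np.arange(offset, offset + len(rows)))
            vectors[v] = scatter_rows(f, rows, n)
            offset += len(rows)

        if self.variant == "baseline":
            raise ValueError(
                "baseline variant is a per-image classifier; use forward_images "
                "on a flat image batch")
        if self.variant == "concat":
            fused = concat([vectors[v] for v in self.views], axis=1)
        else:
            fused = self._attention_fuse(vectors, masks)
        return self.head(self.drop(fused))

    def _attention_fuse(self, vectors: dict, masks: dict) -> Tensor:
        act = SIGMAS[self.config.sigma]
        scores = {v: act(self.scorers[v](vectors[v])) for v in self.views}
        # masked, shift-stabilized softmax over available views
        smax = np.max(
            [s.data * masks[v] - 1e9 * (1 - masks[v]) for v, s in scores.items()],
            axis=0,
        )
        exps = {v: (scores[v] - Tensor(smax)).exp() * Tensor(masks[v])
                for v in self.views}
        denom = exps[self.views[0]]
        for v in self.views[1:]:
            denom = denom + exps[v]
        alphas = {v: exps[v] / denom for v in self.views}
        self.last_alphas = {v: a.data[:, 0].copy() for v, a in alphas.items()}
        fused = alphas[self.views[0]] * vectors[self.views[0]]
        for v in self.views[1:]:
            fused = fused + alphas[v] * vectors[v]
        return fused

    def forward_images(self, x: np.ndarray | Tensor) -> Tensor:
        """Single-stream per-image forward (the baseline configuration)."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        F = self.encoder(x)
        self.last_maps["image"] = F
        return self.head(self.drop(global_avg_pool(F)))

    # -- convenience -------------------------------------------------------
    def forward_triplet(self, triplet: ViewTriplet, normalize: bool = True) -> Tensor:
        """Batch-of-one forward; keeps the graph for Grad-CAM."""
        images, avail = {}, {}
        for v in self.views:
            present = v in triplet.images
            avail[v] = np.array([present])
            if present:
                images[v] = _to_input(triplet.images[v], normalize)[None]
        return self(images, avail)

    def predict(self, images: dict, avail: dict) -> np.ndarray:
        self.eval()
        return self(images, avail).data


def build_model(config: ModelConfig) -> MultiViewClassifier:
    return MultiViewClassifier(config)
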