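"""Optimization protocol: Adam + step decay, differentiated unfreezing,
early stopping, optional reduced-precision inputs, and the fixed multi-seed
experiment runner.

Training is fully deterministic for a fixed seed: all stochastic sources
(parameter init, shuffling, augmentation, dropout) draw from one global
generator installed by :func:`set_global_seed`, and all arithmetic is plain
single-threaded NumPy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
import numpy as np

from . import engine as eng
from .backbone_zoo import apply_unfreeze_policy
from .dataset_io import AugmentationPolicy, SpecimenDataset, SplitManifest, augment_triplet
from .engine import Tensor, softmax_cross_entropy
from .multiview_model import ModelConfig, MultiViewClassifier, _to_input, build_model

DEFAULT_SEEDS = (42, 100, 2024, 7, 99)


class NumericalError(RuntimeError):
    """Loss became non-finite during optimization."""


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-4
    step_size: int = 10  # epochs between learning-rate decays
    gamma: float = 0.1
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    amp: bool = False
    monitor: str = "val_acc"  # or "val_loss"
    seeds: tuple = DEFAULT_SEEDS
    augment: bool = False
    # epochs with the attention gate frozen at uniform weights before the
    # scoring heads train; guards against early gate collapse onto the
    # single most informative view
    gate_warmup_epochs: int = 0

    def validate(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("lr must be positive, weight_decay nonnegative")


@dataclass
class TrainRecord:
    epochs: list = field(default_factory=list)  # per-epoch dicts
    best_epoch: int = 0
    best_metric: float = -np.inf
    stop_reason: str = ""
    seed: int | None = None
    config: dict = field(default_factory=dict)

    @property
    def lr_sequence(self) -> list:
        return [e["lr"] for e in self.epochs]


def set_global_seed(seed: int) -> np.random.Generator:
    """Seed every stochastic source (init, shuffling, augmentation, dropout)."""
    rng = np.random.default_rng(int(seed))
    eng.set_rng(rng)
    return rng


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Step decay: lr * gamma^floor((epoch-1)/step_size), epochs 1-based."""
    return config.lr * config.gamma ** ((epoch - 1) // config.step_size)


class Adam:
    """Adam with classic L2 weight decay; updates only trainable parameters."""

    def __init__(self, params: list, weight_decay: float = 0.0,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None or not getattr(p, "trainable", True):
                continue
            g = p.grad + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Batch assembly
# ---------------------------------------------------------------------------


def _triplet_arrays(dataset: SpecimenDataset, ids: list, views: tuple,
                    policy: AugmentationPolicy | None = None,
                    rng: np.random.Generator | None = None) -> tuple:
    """Stack triplets into per-view image arrays + availability + labels."""
    n = len(ids)
    first = dataset.triplets[ids[0]]
    hw = next(iter(first.images.values())).shape[:2]
    images = {v: np.zeros((n, 3, *hw), np.float32) for v in views}
    avail = {v: np.zeros(n, bool) for v in views}
    labels = np.zeros(n, np.int64)
    for i, sid in enumerate(ids):
        t = dataset.triplets[sid]
        if policy is not None:
            t = augment_triplet(t, policy, rng)
        labels[i] = t.label
        for v in views:
            if v in t.images:
                images[v][i] = _to_input(t.images[v])
                avail[v][i] = True
    return images, avail, labels


def _image_arrays(dataset: SpecimenDataset, ids: list, views: tuple,
                  policy: AugmentationPolicy | None = None,
                  rng: np.random.Generator | None = None) -> tuple:
    """Flatten triplets into independent per-image samples (baseline)."""
    xs, labels, meta = [], [], []
    for sid in ids:
        t = dataset.triplets[sid]
        if policy is not None:
            t = augment_triplet(t, policy, rng)
        for v in views:
            if v in t.images:
                xs.append(_to_input(t.images[v]))
                labels.append(t.label)
                meta.append((sid, v))
    if not xs:
        raise ValueError(f"no images for views {views} in the requested split")
    return np.stack(xs), np.asarray(labels, np.int64), meta


def _quantize_amp(x: np.ndarray) -> np.ndarray:
    return x.astype(np.float16).astype(np.float32)


def predict_logits(model: MultiViewClassifier, dataset: SpecimenDataset,
                   ids: list, batch_size: int = 64) -> tuple:
    """Eval-mode logits over a split; per image for the baseline variant,
    per specimen otherwise.  Returns (logits, labels, meta)."""
    import gc

    if not ids:
        raise ValueError("no specimens in the requested split partition")
    model.eval()
    if model.variant == "baseline":
        x, labels, meta = _image_arrays(dataset, ids, model.views)
        chunks = [model.forward_images(x[i:i + batch_size]).data
                  for i in range(0, len(x), batch_size)]
        gc.collect()  # eval graphs are cyclic (closure <-> node); drop them now
        return np.concatenate(chunks), labels, meta
    images, avail, labels = _triplet_arrays(dataset, ids, model.views)
    keep = np.flatnonzero(np.any([avail[v] for v in model.views], axis=0))
    chunks = []
    for i in range(0, len(keep), batch_size):
        sel = keep[i:i + batch_size]
        chunks.append(model(
            {v: images[v][sel] for v in model.views},
            {v: avail[v][sel] for v in model.views}).data)
    meta = [(ids[int(i)], None) for i in keep]
    gc.collect()
    return np.concatenate(chunks), labels[keep], meta


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def train_model(model: MultiViewClassifier, dataset: SpecimenDataset,
                split: SplitManifest, config: TrainConfig,
                policy: AugmentationPolicy | None = None,
                unfreeze: str | None = None,
                verbose: bool = False) -> TrainRecord:
    """Optimize the model on the train partition with early stopping on the
    validation metric; the best-validation parameters are restored on exit."""
    config.validate()
    rng = eng.get_rng()
    train_ids = sorted(split.ids("train"))
    val_ids = sorted(split.ids("val"))
    train_ids = [i for i in train_ids if i in dataset.triplets]
    val_ids = [i for i in val_ids if i in dataset.triplets]
    if not train_ids:
        raise ValueError("empty training partition")

    if unfreeze is not None:
        apply_unfreeze_policy(model.encoder, unfreeze)
    optimizer = Adam(model.parameters(), weight_decay=config.weight_decay)
    aug = policy if (policy is not None and config.augment) else None

    record = TrainRecord(config=asdict(config))
    best_state = model.state_dict()
    since_best = 0
    sign = 1.0 if config.monitor == "val_acc" else -1.0

    gate_params = []
    if model.variant == "attention" and config.gate_warmup_epochs > 0:
        gate_params = [p for sc in model._scorer_list for p in sc.parameters()]
        for p in gate_params:
            p.trainable = False

    per_image = model.variant == "baseline"
    for epoch in range(1, config.max_epochs + 1):
        lr = lr_at_epoch(config, epoch)
        if gate_params and epoch == config.gate_warmup_epochs + 1:
            for p in gate_params:
                p.trainable = True
        model.train()
        order = rng.permutation(len(train_ids))
        losses, hits, count = [], 0, 0
        for start in range(0, len(order), config.batch_size):
            batch_ids = [train_ids[i] for i in order[start:start + config.batch_size]]
            if per_image:
                x, labels, _ = _image_arrays(dataset, batch_ids, model.views, aug, rng)
                if config.amp:
                    x = _quantize_amp(x)
                logits = model.forward_images(x)
            else:
                images, avail, labels = _triplet_arrays(dataset, batch_ids,
                                                        model.views, aug, rng)
                if config.amp:
                    images = {v: _quantize_amp(a) for v, a in images.items()}
                logits = model(images, avail)
            loss = softmax_cross_entropy(logits, labels)
            if not np.isfinite(loss.data):
                raise NumericalError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}")
            model.zero_grad()
            loss.backward()
            optimizer.step(lr)
            losses.append(float(loss.data) * len(labels))
            hits += int((logits.data.argmax(1) == labels).sum())
            count += len(labels)

        train_loss = sum(losses) / count
        train_acc = hits / count
        val_loss, val_acc = _evaluate_split(model, dataset, val_ids, config.batch_size)
        metric = val_acc if config.monitor == "val_acc" else val_loss
        record.epochs.append({"epoch": epoch, "lr": lr,
                              "train_loss": train_loss, "train_acc": train_acc,
                              "val_loss": val_loss, "val_acc": val_acc})
        if verbose:
            print(f"epoch {epoch:3d} lr {lr:.2e} train {train_acc:.3f} "
                  f"val {val_acc:.3f}")
        if sign * metric > sign * record.best_metric:
            record.best_metric = metric
            record.best_epoch = epoch
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                record.stop_reason = f"early_stop@{epoch}"
                break
    else:
        record.stop_reason = "max_epochs"

    model.load_state_dict(best_state)
    return record


def _evaluate_split(model: MultiViewClassifier, dataset: SpecimenDataset,
                    ids: list, batch_size: int) -> tuple:
    if not ids:
        return float("nan"), float("nan")
    logits, labels, _ = predict_logits(model, dataset, ids, batch_size)
    loss = float(softmax_cross_entropy(Tensor(logits), labels).data)
    acc = float((logits.argmax(1) == labels).mean())
    return loss, acc


# ---------------------------------------------------------------------------
# Multi-seed runner
# ---------------------------------------------------------------------------


@dataclass
class SeedRuns:
    reports: list  # (seed, MetricsReport)
    records: list  # (seed, TrainRecord)
    failures: list  # (seed, message)

    def metric_values(self, metric: str) -> np.ndarray:
        return np.array([getattr(rep, metric) for _, rep in self.reports])

    def summary(self) -> dict:
        """Mean and sample std (n-1) per metric over seeds."""
        out = {}
        for metric in ("top1", "top5", "macro_f1", "macro_precision",
                       "macro_recall", "ovr_auc"):
            vals = self.metric_values(metric)
            out[metric] = {"mean": float(np.mean(vals)),
                           "std": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
        return out


def run_seeds(model_config: ModelConfig, dataset: SpecimenDataset,
              split: SplitManifest, train_config: TrainConfig,
              seeds: tuple | None = None, unfreeze: str | None = None,
              policy: AugmentationPolicy | None = None) -> SeedRuns:
    """Independent full train/evaluate runs, one per seed."""
    from .evaluator import compute_metrics  # local import to avoid a cycle

    seeds = tuple(seeds if seeds is not None else train_config.seeds)
    if len(seeds) < 2:
        raise ValueError("need >= 2 seeds for a seed study")
    reports, records, failures = [], [], []
    test_ids = sorted(split.ids("test"))
    for seed in seeds:
        try:
            set_global_seed(seed)
            model = build_model(model_config)
            rec = train_model(model, dataset, split, train_config,
                              policy=policy, unfreeze=unfreeze)
            rec.seed = seed
            logits, labels, _ = predict_logits(model, dataset, test_ids)
            rep = compute_metrics(logits, labels, model_config.n_classes)
            reports.append((seed, rep))
            records.append((seed, rec))
        except Exception as exc:  # failed runs reported, not silently dropped
            failures.append((seed, f"{type(exc).__name__}: {exc}"))
    return SeedRuns(reports, records, failures)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: MultiViewClassifier, path, extra: dict | None = None) -> None:
    """Single-file archive: all parameter arrays + config snapshot."""
    meta = {"model_config": asdict(model.config)}
    if extra:
        meta.update(extra)
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path) -> MultiViewClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = ModelConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                         for k, v in meta["model_config"].items()})
    model = build_model(cfg)
    model.load_state_dict(state)
    return model
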