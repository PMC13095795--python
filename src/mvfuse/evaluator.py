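"""Metric suite, confusion analysis, paired significance tests, and the
ablation harness over (backbone, variant, view subset) grids.

Metric conventions: Top-k uses average-rank tie handling; precision, recall
and F1 are macro-averaged (unweighted over classes); OvR AUC is the macro
average of per-class one-vs-rest ROC areas; classes absent from the evaluated
labels are excluded from macro averages with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, roc_auc_score

from .dataset_io import SpecimenDataset, SplitManifest
from .multiview_model import ModelConfig
from .trainer import TrainConfig, run_seeds


@dataclass
class MetricsReport:
    top1: float
    top5: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    ovr_auc: float
    confusion: np.ndarray  # K x K row-normalized (rows with >=1 true sample)
    confusion_counts: np.ndarray  # K x K raw counts
    n_samples: int = 0

    def as_dict(self) -> dict:
        return {k: round(float(getattr(self, k)), 6)
                for k in ("top1", "top5", "macro_precision", "macro_recall",
                          "macro_f1", "ovr_auc")}


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def compute_metrics(logits: np.ndarray, labels: np.ndarray, n_classes: int) -> MetricsReport:
    logits = np.asarray(logits, float)
    labels = np.asarray(labels)
    if logits.ndim != 2 or logits.shape[1] != n_classes:
        raise ValueError(f"logits must be (n, {n_classes}), got {logits.shape}")
    if len(labels) != len(logits) or len(labels) == 0:
        raise ValueError("labels must be nonempty and match logits")

    # top-k membership by average rank (descending logits)
    ranks = np.vstack([rankdata(-row, method="average") for row in logits])
    true_rank = ranks[np.arange(len(labels)), labels]
    top1 = float(np.mean(true_rank <= 1))
    top5 = float(np.mean(true_rank <= min(5, n_classes)))

    present = np.unique(labels)
    if len(present) < n_classes:
        warnings.warn(
            f"{n_classes - len(present)} classes absent from labels; "
            "excluded from macro averages", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            labels, logits.argmax(1), labels=present, average="macro",
            zero_division=0)

    probs = _softmax(logits)
    aucs = []
    for c in present:
        y = labels == c
        if y.all():
            continue
        aucs.append(roc_auc_score(y, probs[:, c]))
    auc = float(np.mean(aucs)) if aucs else float("nan")

    counts = confusion_matrix(labels, logits.argmax(1), labels=np.arange(n_classes))
    row_sums = counts.sum(axis=1, keepdims=True)
    norm = np.divide(counts, row_sums, where=row_sums > 0,
                     out=np.zeros_like(counts, float))
    return MetricsReport(top1=top1, top5=top5, macro_precision=float(prec),
                         macro_recall=float(rec), macro_f1=float(f1),
                         ovr_auc=auc, confusion=norm, confusion_counts=counts,
                         n_samples=len(labels))


def cross_subfamily_error(confusion_counts: np.ndarray,
                          species_to_subfamily: dict) -> float:
    """Share of all samples predicted into a species of the other subfamily."""
    counts = np.asarray(confusion_counts)
    K = counts.shape[0]
    missing = [k for k in range(K) if k not in species_to_subfamily]
    if missing:
        raise ValueError(f"species without subfamily mapping: {missing}")
    sf = np.array([species_to_subfamily[k] for k in range(K)])
    cross = sf[:, None] != sf[None, :]
    total = counts.sum()
    return float((counts * cross).sum() / total) if total else 0.0


# ---------------------------------------------------------------------------
# Paired significance tests
# ---------------------------------------------------------------------------


@dataclass
class McNemarResult:
    statistic: float
    p_value: float
    b: int  # samples only model A got right
    c: int  # samples only model B got right
    method: str  # "chi2_cc" or "exact_binomial"
    degenerate: bool = False


def mcnemar_test(pred_a: np.ndarray, pred_b: np.ndarray,
                 labels: np.ndarray, exact_threshold: int = 25) -> McNemarResult:
    """Paired McNemar test on two models' predictions over the same samples.

    Continuity-corrected chi-square ``(|b-c|-1)^2/(b+c)`` for b+c >=
    `exact_threshold`; exact two-sided binomial otherwise.  b+c = 0 is
    reported as "no discordance" with p = 1 and a degeneracy flag.
    """
    pred_a, pred_b, labels = map(np.asarray, (pred_a, pred_b, labels))
    if not (len(pred_a) == len(pred_b) == len(labels)):
        raise ValueError("prediction/label lengths differ")
    ok_a = pred_a == labels
    ok_b = pred_b == labels
    b = int(np.sum(ok_a & ~ok_b))
    c = int(np.sum(~ok_a & ok_b))
    n = b + c
    if n == 0:
        return McNemarResult(0.0, 1.0, b, c, "none", degenerate=True)
    if n < exact_threshold:
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5))
        stat = float(min(b, c))
        return McNemarResult(stat, float(p), b, c, "exact_binomial")
    stat = (abs(b - c) - 1) ** 2 / n
    p = float(stats.chi2.sf(stat, df=1))
    return McNemarResult(float(stat), p, b, c, "chi2_cc")


def mcnemar_chi2(b: int, c: int) -> float:
    """Continuity-corrected chi-square statistic from the discordance pair."""
    if b + c == 0:
        return 0.0
    return (abs(b - c) - 1) ** 2 / (b + c)


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values (optional; raw
    p-values are reported by default across the ablation grid)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


@dataclass
class PairedSeedTests:
    t_statistic: float
    t_p: float
    wilcoxon_statistic: float
    wilcoxon_p: float
    degenerate: bool = False
    note: str = ""


def paired_seed_tests(metrics_a, metrics_b) -> PairedSeedTests:
    """Paired two-sided t and Wilcoxon signed-rank over per-seed metrics."""
    a = np.asarray(metrics_a, float)
    b = np.asarray(metrics_b, float)
    if a.shape != b.shape:
        raise ValueError("per-seed metric vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need >= 2 paired values")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        note = ("identical vectors" if np.allclose(diff, 0)
                else "zero-variance differences")
        return PairedSeedTests(0.0 if np.allclose(diff, 0) else np.inf, 1.0,
                               0.0, 1.0, degenerate=True, note=note)
    t_stat, t_p = stats.ttest_rel(a, b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            w_stat, w_p = stats.wilcoxon(a, b)
        except ValueError:
            w_stat, w_p = 0.0, 1.0
    return PairedSeedTests(float(t_stat), float(t_p), float(w_stat), float(w_p))


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------


@dataclass
class AblationResult:
    rows: list  # dicts keyed by (backbone, variant, view_subset)
    seeds: tuple
    invalid: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def row(self, backbone: str, variant: str, views: tuple) -> dict:
        key = (backbone, variant, tuple(views))
        for r in self.rows:
            if (r["backbone"], r["variant"], tuple(r["views"])) == key:
                return r
        raise KeyError(key)


def run_ablation(dataset: SpecimenDataset, split: SplitManifest,
                 grid: list, seeds: tuple, train_config: TrainConfig,
                 n_classes: int | None = None, input_size: int = 96,
                 model_kwargs: dict | None = None,
                 keep_models: bool = False) -> AblationResult:
    """Run a (backbone, variant, view_subset) grid, all cells sharing the
    same split and seed set.

    `grid` is a list of (backbone, variant, views) tuples.  Reported cells
    are mean and sample std per metric over seeds plus delta accuracy versus
    the per-image baseline of the same backbone (best single-view baseline if
    several baseline cells exist); invalid combinations are listed, not
    silently skipped.
    """
    n_classes = n_classes or dataset.n_classes
    rows, invalid = [], []
    models_by_cell = {}
    for backbone, variant, views in grid:
        try:
            cfg = ModelConfig(variant=variant, views=tuple(views),
                              n_classes=n_classes, backbone=backbone,
                              input_size=input_size, **(model_kwargs or {}))
            cfg.validate()
        except (ValueError, KeyError) as exc:
            invalid.append(((backbone, variant, tuple(views)), str(exc)))
            continue
        runs = run_seeds(cfg, dataset, split, train_config, seeds)
        if runs.failures:
            invalid.append(((backbone, variant, tuple(views)),
                            f"failed seeds: {runs.failures}"))
        summ = runs.summary()
        row = {"backbone": backbone, "variant": variant, "views": tuple(views)}
        for metric, ms in summ.items():
            row[f"{metric}_mean"] = ms["mean"]
            row[f"{metric}_std"] = ms["std"]
        row["per_seed_top1"] = list(runs.metric_values("top1"))
        rows.append(row)
        if keep_models:
            models_by_cell[(backbone, variant, tuple(views))] = runs

    # delta accuracy vs the best baseline cell of the same backbone
    for backbone in {r["backbone"] for r in rows}:
        base = [r for r in rows if r["backbone"] == backbone
                and r["variant"] == "baseline"]
        ref = max((r["top1_mean"] for r in base), default=None)
        for r in rows:
            if r["backbone"] != backbone:
                continue
            if r["variant"] == "baseline":
                r["delta_acc"] = 0.0
            else:
                r["delta_acc"] = (r["top1_mean"] - ref) if ref is not None else np.nan
    result = AblationResult(rows, tuple(seeds), invalid)
    if keep_models:
        result.models = models_by_cell  # type: ignore[attr-defined]
    return result


def save_confusion_heatmap(report: MetricsReport, path, class_names=None) -> None:
    """Render the row-normalized confusion matrix as a heatmap PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    K = report.confusion.shape[0]
    fig, ax = plt.subplots(figsize=(max(4, K * 0.5),) * 2)
    im = ax.imshow(report.confusion, vmin=0, vmax=1, cmap="viridis")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if class_names is not None:
        ax.set_xticks(range(K), class_names, rotation=90, fontsize=7)
        ax.set_yticks(range(K), class_names, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def benchmark_train_config() -> TrainConfig:
    """Training protocol for the desk-scale synthetic benchmark (tinycnn at
    32x32 input): Adam 3e-3, weight decay 1e-4, step decay x0.3 every 20
    epochs, batch 32, early stopping on validation top-1 (patience 12,
    max 35), attention gate frozen at uniform for the first 18 epochs."""
    return TrainConfig(lr=3e-3, weight_decay=1e-4, step_size=20, gamma=0.3,
                       batch_size=32, max_epochs=35, patience=12,
                       gate_warmup_epochs=18)


BENCHMARK_INPUT_SIZE = 32

#: model settings of the benchmark protocol (applies to every grid cell)
BENCHMARK_MODEL_KWARGS = {"dropout_p": 0.2}

#: Ablation grid for the synthetic benchmark: three single-view
#: per-image baselines, shared-weight concat, full attention fusion, and the
#: two dual-view attention cells whose ordering the generator controls.
BENCHMARK_GRID = [
    ("tinycnn", "baseline", ("dorsal",)),
    ("tinycnn", "baseline", ("lateral",)),
    ("tinycnn", "baseline", ("ventral",)),
    ("tinycnn", "concat", ("dorsal", "lateral", "ventral")),
    ("tinycnn", "attention", ("dorsal", "lateral", "ventral")),
    ("tinycnn", "attention", ("dorsal", "lateral")),
    ("tinycnn", "attention", ("dorsal", "ventral")),
]


def majority_vote_by_specimen(logits: np.ndarray, labels: np.ndarray,
                              meta: list) -> tuple:
    """Aggregate per-image baseline predictions to specimen level."""
    pred = logits.argmax(1)
    by_spec: dict = {}
    for p, y, (sid, _) in zip(pred, labels, meta):
        by_spec.setdefault(sid, ([], y))[0].append(p)
    spec_pred, spec_true = [], []
    for sid, (ps, y) in sorted(by_spec.items()):
        vals, cnts = np.unique(ps, return_counts=True)
        spec_pred.append(int(vals[np.argmax(cnts)]))
        spec_true.append(int(y))
    return np.asarray(spec_pred), np.asarray(spec_true)
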