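"""Multi-class evaluation statistics, focus fusion and ablation experiments.

Per-class rates are one-vs-rest: for class c, TP are samples of c predicted
c, FP are non-c predicted c, TN are non-c not predicted c, FN are c predicted
otherwise. Accuracy deltas between models are reported in percentage points
(e.g. accuracies 0.8234 vs 0.7025 differ by 12.09 points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import laplace, uniform_filter

from .errors import ConfigurationError
from .stvit_model import CLASS_ORDER

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "compute_confusion",
    "compute_metrics",
    "mean_report",
    "roc_curves",
    "fuse_zstack",
    "run_ablation",
    "ablation_report",
]


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple = CLASS_ORDER

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.class_names),) * 2:
            raise ValueError(f"confusion matrix shape {self.counts.shape} invalid")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Per-class one-vs-rest rates plus overall accuracy (and optional AUC)."""

    confusion: ConfusionMatrix
    recall: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    accuracy: float
    auc: np.ndarray | None = None
    zero_division_flags: dict = field(default_factory=dict)
    class_names: tuple = CLASS_ORDER

    def as_table(self):
        import pandas as pd

        rows = {}
        for metric in ("recall", "specificity", "precision", "f1"):
            for i, name in enumerate(self.class_names):
                rows[f"{metric}:{name}"] = getattr(self, metric)[i]
        if self.auc is not None:
            for i, name in enumerate(self.class_names):
                rows[f"auc:{name}"] = self.auc[i]
        rows["accuracy"] = self.accuracy
        return pd.Series(rows)


def compute_confusion(y_true, y_pred, n_classes: int = 3) -> ConfusionMatrix:
    """Tally (true, predicted) label pairs."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size and (min(y_true.min(), y_pred.min()) < 0 or max(y_true.max(), y_pred.max()) >= n_classes):
        raise ValueError("labels out of range")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, class_names=CLASS_ORDER[:n_classes])


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest recall/specificity/precision/F1 per class, plus accuracy.

    F1 = 2*P*R/(P+R); any zero-denominator rate is reported as 0 and flagged
    in ``zero_division_flags``.
    """
    c = cm.counts
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    k = c.shape[0]
    recall = np.zeros(k)
    specificity = np.zeros(k)
    precision = np.zeros(k)
    f1 = np.zeros(k)
    flags = {}

    def safe(num, den, key):
        if den == 0:
            flags[key] = True
            return 0.0
        return num / den

    for i in range(k):
        tp = c[i, i]
        fn = c[i].sum() - tp
        fp = c[:, i].sum() - tp
        tn = n - tp - fn - fp
        recall[i] = safe(tp, tp + fn, f"recall:{i}")
        specificity[i] = safe(tn, tn + fp, f"specificity:{i}")
        precision[i] = safe(tp, tp + fp, f"precision:{i}")
        f1[i] = safe(2 * precision[i] * recall[i], precision[i] + recall[i], f"f1:{i}")
    return MetricsReport(
        confusion=cm,
        recall=recall,
        specificity=specificity,
        precision=precision,
        f1=f1,
        accuracy=float(np.trace(c) / n),
        zero_division_flags=flags,
        class_names=cm.class_names,
    )


def mean_report(reports: list[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of fold metrics; confusions are summed for reference."""
    cm = ConfusionMatrix(sum(r.confusion.counts for r in reports), reports[0].class_names)
    aucs = [r.auc for r in reports if r.auc is not None]
    return MetricsReport(
        confusion=cm,
        recall=np.mean([r.recall for r in reports], axis=0),
        specificity=np.mean([r.specificity for r in reports], axis=0),
        precision=np.mean([r.precision for r in reports], axis=0),
        f1=np.mean([r.f1 for r in reports], axis=0),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        auc=np.mean(aucs, axis=0) if aucs else None,
        class_names=reports[0].class_names,
    )


def roc_curves(y_true, proba) -> dict:
    """One-vs-rest ROC per class by threshold sweep; AUC by the trapezoid rule.

    Equal scores are grouped (both axes step at once). Raises for a class with
    no positives or no negatives, where the AUC is undefined.
    """
    from sklearn.metrics import auc as _auc
    from sklearn.metrics import roc_curve as _roc

    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=float)
    if proba.ndim != 2 or len(y_true) != len(proba):
        raise ValueError("probability matrix must be (n_samples, n_classes)")
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    curves, aucs = [], []
    for c in range(proba.shape[1]):
        pos = y_true == c
        if pos.all() or not pos.any():
            raise ValueError(f"class {c} is degenerate (no positives or no negatives)")
        fpr, tpr, _ = _roc(pos.astype(int), proba[:, c])
        curves.append((fpr, tpr))
        aucs.append(_auc(fpr, tpr))
    return {"curves": curves, "auc": np.array(aucs)}


def fuse_zstack(images: np.ndarray, window: int = 9) -> np.ndarray:
    """Per-day focus stacking of a (T, Z, H, W) stack into (T, H, W).

    For every pixel, the z-plane with the largest local Laplacian variance
    (sharpness in a `window` x `window` neighbourhood) is selected. This is a
    documented stand-in for instrument-side z-fusion.
    """
    if hasattr(images, "images"):  # OrganoidStack
        images = images.images
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 3:
        arr = arr[None]
        squeeze = True
    else:
        squeeze = False
    t, z = arr.shape[:2]
    fused = np.empty(arr.shape[:1] + arr.shape[2:])
    for ti in range(t):
        planes = arr[ti]
        lap = np.stack([laplace(p) for p in planes])
        sharp = uniform_filter(lap**2, size=(1, window, window))
        best = sharp.argmax(axis=0)
        fused[ti] = np.take_along_axis(planes, best[None], axis=0)[0]
    return fused[0] if squeeze else fused


def run_ablation(data, model_params: dict, cfg, mode: str):
    """Cross-validated ablation experiment.

    ``temporal_D0D1`` truncates every sample to days {0, 1} before training
    and evaluation; ``no_spatial`` replaces each day's z-stack with one fused
    image and bypasses the spatial encoder (the image CLS vector feeds the
    Bi-LSTM directly). Everything else — folds, optimizer, epochs — is
    identical to the full protocol. Returns the cross-validation result.
    """
    from .training import ArrayDataset, _as_dataset, cross_validate

    ds = _as_dataset(data, model_params.get("image_size", 224))
    if mode == "temporal_D0D1":
        ds2 = ArrayDataset(ds.sample_ids, [x[:2] for x in ds.X], ds.y)
        return cross_validate(ds2, model_params, cfg)
    if mode == "no_spatial":
        fused_X = []
        for x in ds.X:
            fused = fuse_zstack(np.transpose(x, (0, 1, 4, 2, 3)).mean(axis=2))  # (T,H,W) from channel-mean
            fused_X.append(np.repeat(fused[:, None, :, :, None], 3, axis=4).astype(np.float32))
        ds2 = ArrayDataset(ds.sample_ids, fused_X, ds.y)
        params = dict(model_params, use_spatial_encoder=False)
        return cross_validate(ds2, params, cfg)
    raise ConfigurationError(f"unknown ablation mode {mode!r}")


def ablation_report(full: MetricsReport, ablated: MetricsReport) -> dict:
    """Deltas (full minus ablated) with accuracy in percentage points."""
    if full.class_names != ablated.class_names:
        raise ValueError("reports use different class orders")
    return {
        "accuracy_full": full.accuracy,
        "accuracy_ablated": ablated.accuracy,
        "accuracy_delta_pp": round((full.accuracy - ablated.accuracy) * 100.0, 10),
        "recall_delta": full.recall - ablated.recall,
        "specificity_delta": full.specificity - ablated.specificity,
        "precision_delta": full.precision - ablated.precision,
        "f1_delta": full.f1 - ablated.f1,
    }
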