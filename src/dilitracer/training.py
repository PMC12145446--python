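"""Training protocol: per-fold supervised training and K-fold cross-validation.

These functions are thin wrappers over :class:`~dilitracer.estimator.
DILITracerClassifier`; they add the dataset bookkeeping (index loading, fold
assignment, per-fold evaluation, metric averaging) specified by the
cross-validation protocol: cross-entropy loss, AdamW (lr=2e-4, batch size 6,
100 epochs by default), K=5 stratified folds so every sample is scored
exactly once, and the arithmetic mean of fold metrics as the headline result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import DatasetIndex, DiliLabel, load_stack, preprocess_stack, split_kfold
from .errors import ConfigurationError
from .estimator import DILITracerClassifier
from .evaluation import MetricsReport, compute_confusion, compute_metrics, mean_report, roc_curves

__all__ = [
    "TrainConfig",
    "ArrayDataset",
    "train_fold",
    "cross_validate",
    "CVResult",
    "DESK_MODEL_PARAMS",
    "desk_train_config",
    "make_benchmark_dataset",
]

#: desk-scale benchmark conditions: tiny encoder (D=64, L=2, k=4) on 64-px
#: frames, six z-planes sampled per step, dihedral augmentation
DESK_MODEL_PARAMS: dict = {
    "image_size": 64,
    "patch_size": 16,
    "embed_dim": 64,
    "depth": 2,
    "n_heads": 4,
    "lstm_hidden": 64,
    "train_z_planes": 6,
    "augment": "dihedral",
}


def desk_train_config(seed: int, epochs: int = 45, k: int = 5) -> "TrainConfig":
    """Training protocol used for the desk-scale benchmark runs."""
    return TrainConfig(lr=2e-4, batch_size=3, epochs=epochs, k=k, seed=seed, betas=(0.9, 0.95))


def make_benchmark_dataset(n_per_class: int, seed: int, image_size: int = 64) -> "ArrayDataset":
    """Balanced synthetic benchmark data at desk scale (phenotype defaults)."""
    from .synthetic_organoid import LABELS, SimConfig, generate_sample

    cfg = SimConfig().scaled(image_size)
    ids, X, y = [], [], []
    i = 0
    for ci, label in enumerate(LABELS):
        for _ in range(n_per_class):
            stack = generate_sample(label, cfg, seed=seed * 100_000 + i, sample_id=f"S{i:04d}")
            ids.append(stack.sample_id)
            X.append(preprocess_stack(stack, out_size=image_size))
            y.append(ci)
            i += 1
    return ArrayDataset(ids, X, y)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and cross-validation protocol."""

    lr: float = 2e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.01
    batch_size: int = 6
    epochs: int = 100
    k: int = 5
    train_fraction: float = 0.8
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.lr < 0:
            raise ConfigurationError("lr must be >= 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.k < 2:
            raise ConfigurationError("K must be >= 2")


@dataclass
class ArrayDataset:
    """In-memory dataset: aligned sample ids, stacks and labels."""

    sample_ids: list[str]
    X: list[np.ndarray]  # per-sample (T, Z, H, W, 3) float32, Z may vary
    y: list[int]  # class indices (vNo=0, vLess=1, vMost=2)

    def subset(self, ids: list[str]) -> "ArrayDataset":
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        sel = [pos[s] for s in ids]
        return ArrayDataset([self.sample_ids[i] for i in sel], [self.X[i] for i in sel], [self.y[i] for i in sel])

    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "label": [DiliLabel.from_index(i).value for i in self.y],
                "compound": "", "platform": "",
            }
        )

    @classmethod
    def from_index(cls, index: DatasetIndex, image_size: int) -> "ArrayDataset":
        ids, X, y = [], [], []
        for sid in index.sample_ids:
            stack = load_stack(index, sid)
            ids.append(sid)
            X.append(preprocess_stack(stack, out_size=image_size))
            y.append(DiliLabel.from_string(stack.label).class_index)
        return cls(ids, X, y)

    @classmethod
    def from_stacks(cls, stacks, image_size: int) -> "ArrayDataset":
        return cls(
            [s.sample_id for s in stacks],
            [preprocess_stack(s, out_size=image_size) for s in stacks],
            [DiliLabel.from_string(s.label).class_index for s in stacks],
        )


def _as_dataset(data, image_size: int) -> ArrayDataset:
    if isinstance(data, ArrayDataset):
        return data
    if isinstance(data, DatasetIndex):
        return ArrayDataset.from_index(data, image_size)
    raise TypeError("data must be an ArrayDataset or DatasetIndex")


def make_estimator(model_params: dict, cfg: TrainConfig) -> DILITracerClassifier:
    return DILITracerClassifier(
        **model_params,
        lr=cfg.lr,
        betas=cfg.betas,
        weight_decay=cfg.weight_decay,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        seed=cfg.seed,
    )


def train_fold(train_ids, model_params: dict, cfg: TrainConfig, data) -> DILITracerClassifier:
    """Train one model on the given sample ids; returns the fitted estimator
    (loss curve in ``estimator.loss_curve_``).

    Raises a stratification error when any of the three classes is absent
    from the training ids.
    """
    ds = _as_dataset(data, model_params.get("image_size", 224)).subset(list(train_ids))
    present = set(ds.y)
    if present != {0, 1, 2}:
        missing = [DiliLabel.from_index(i).value for i in sorted({0, 1, 2} - present)]
        raise ConfigurationError(f"training ids lack class(es) {missing}")
    est = make_estimator(model_params, cfg)
    est.fit(ds.X, ds.y)
    return est


@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    mean_report: MetricsReport
    predictions: pd.DataFrame  # sample_id, fold, true, pred, p0, p1, p2
    estimators: list = field(default_factory=list)


def cross_validate(
    data,
    model_params: dict,
    cfg: TrainConfig,
    keep_estimators: bool = False,
) -> CVResult:
    """Stratified K-fold cross-validation; every sample is scored exactly once.

    Per fold: train on K-1 parts, score the held-out part, compute the full
    metrics report (including one-vs-rest AUC); the summary is the arithmetic
    mean of the fold metrics.
    """
    ds = _as_dataset(data, model_params.get("image_size", 224))
    folds = split_kfold(ds.sample_table(), k=cfg.k, seed=cfg.seed, stratify=True)
    reports, rows, ests = [], [], []
    for fold_i, (train_ids, test_ids) in enumerate(folds):
        est = train_fold(train_ids, model_params, cfg, ds)
        test = ds.subset(test_ids)
        proba = est.predict_proba(test.X)
        pred = proba.argmax(axis=1)
        cm = compute_confusion(test.y, pred)
        report = compute_metrics(cm)
        try:
            report.auc = roc_curves(test.y, proba)["auc"]
        except ValueError:
            report.auc = None  # degenerate fold (a class absent)
        reports.append(report)
        for sid, t, p, pr in zip(test.sample_ids, test.y, pred, proba):
            rows.append((sid, fold_i, int(t), int(p), *map(float, pr)))
        if keep_estimators:
            ests.append(est)
    predictions = pd.DataFrame(rows, columns=["sample_id", "fold", "true", "pred", "p0", "p1", "p2"])
    return CVResult(reports, mean_report(reports), predictions, ests)
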