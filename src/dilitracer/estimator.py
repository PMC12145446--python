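"""Scikit-learn style front end for the spatiotemporal organoid classifier.

:class:`DILITracerClassifier` follows the estimator contract (``fit`` /
``predict`` / ``predict_proba``, ``get_params`` / ``set_params``, fitted
attributes with a trailing underscore), so it composes with sklearn model
selection and pipelines. ``X`` is a list of per-sample stacks — either raw
:class:`~dilitracer.synthetic_organoid.OrganoidStack` objects (preprocessed
internally) or pre-standardized arrays of shape (T, Z, H, W, 3); Z may vary
between samples.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._autograd import no_grad
from ._nn import AdamW
from .data_io import DiliLabel, preprocess_stack
from .errors import ConfigurationError
from .stvit_model import CLASS_ORDER, EncoderConfig, SpatialConfig, STViT, TemporalConfig
from .synthetic_organoid import OrganoidStack

__all__ = ["DILITracerClassifier"]


def _to_class_index(label) -> int:
    if isinstance(label, DiliLabel):
        return label.class_index
    if isinstance(label, str):
        return DiliLabel.from_string(label).class_index
    i = int(label)
    if i not in (0, 1, 2):
        raise ConfigurationError(f"class index out of range: {label!r}")
    return i


class DILITracerClassifier(BaseEstimator, ClassifierMixin):
    """Three-class DILI-severity classifier over brightfield z-stack series.

    Parameters
    ----------
    image_size, patch_size, embed_dim, depth, n_heads, pos_embed
        Image-encoder (ViT) geometry. The default dimensions are the
        desk-scale configuration (D=64, L=2, k=4) that trains in minutes on
        one CPU; scale up for production runs.
    lstm_hidden
        Hidden size of the bidirectional temporal LSTM (feature = 2x this).
    use_spatial_encoder
        When False, each day must provide exactly one (fused) image and the
        image CLS vector feeds the temporal encoder directly — the
        spatial-ablation variant.
    lr, betas, weight_decay, batch_size, epochs
        AdamW / cross-entropy training protocol. Defaults follow the
        reference protocol (lr=2e-4, batch of 6 samples, 100 epochs).
    pretrain_epochs, pretrain_frames_per_sample
        Optional masked-image-modeling warm start for the image encoder
        (regressing masked patch pixels) before supervised training; the
        desk-scale counterpart of initializing the image encoder from a
        pretrained checkpoint. 0 disables it.
    train_z_planes
        When set, each training step samples this many focal planes per
        sample (video-transformer frame sampling; the spatial encoder is
        z-permutation invariant, so the contract is unchanged). Evaluation
        always uses every plane. None uses all planes during training too.
    seed
        Seeds weight initialization and data ordering; fits are reproducible.
    """

    def __init__(
        self,
        image_size: int = 224,
        patch_size: int = 16,
        embed_dim: int = 64,
        depth: int = 2,
        n_heads: int = 4,
        pos_embed: str = "learnable_2d",
        lstm_hidden: int = 64,
        use_spatial_encoder: bool = True,
        lr: float = 2e-4,
        betas: tuple = (0.9, 0.999),
        weight_decay: float = 0.01,
        batch_size: int = 6,
        epochs: int = 100,
        pretrain_epochs: int = 0,
        pretrain_frames_per_sample: int = 8,
        train_z_planes: int | None = None,
        augment: str | None = None,
        head_norm_gain: float = 4.0,
        seed: int = 0,
        verbose: int = 0,
    ):
        self.image_size = image_size
        self.patch_size = patch_size
        self.embed_dim = embed_dim
        self.depth = depth
        self.n_heads = n_heads
        self.pos_embed = pos_embed
        self.lstm_hidden = lstm_hidden
        self.use_spatial_encoder = use_spatial_encoder
        self.lr = lr
        self.betas = betas
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.pretrain_epochs = pretrain_epochs
        self.pretrain_frames_per_sample = pretrain_frames_per_sample
        self.train_z_planes = train_z_planes
        self.augment = augment
        self.head_norm_gain = head_norm_gain
        self.seed = seed
        self.verbose = verbose

    # -- helpers -------------------------------------------------------------
    def _prepare_X(self, X) -> list[np.ndarray]:
        out = []
        for item in X:
            if isinstance(item, OrganoidStack):
                arr = preprocess_stack(item, out_size=self.image_size)
            else:
                arr = np.asarray(item, dtype=np.float32)
                if arr.ndim != 5 or arr.shape[-1] != 3:
                    raise ConfigurationError(
                        f"expected a (T, Z, H, W, 3) array per sample, got {arr.shape}"
                    )
            out.append(arr)
        return out

    def _build_model(self) -> STViT:
        enc = EncoderConfig(
            image_size=self.image_size,
            patch_size=self.patch_size,
            embed_dim=self.embed_dim,
            depth=self.depth,
            n_heads=self.n_heads,
            pos_embed=self.pos_embed,
        )
        return STViT(
            enc,
            SpatialConfig(),
            TemporalConfig(hidden_size=self.lstm_hidden),
            n_classes=3,
            seed=self.seed,
        )

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y):
        """Minimize mean cross-entropy with AdamW over `epochs` passes."""
        if self.lr < 0:
            raise ConfigurationError("lr must be >= 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        Xp = self._prepare_X(X)
        yi = np.array([_to_class_index(v) for v in y])
        if len(Xp) != len(yi):
            raise ValueError("X and y length mismatch")
        if len(Xp) == 0:
            raise ValueError("empty training set")
        self.classes_ = np.array(sorted(np.unique(yi)))
        self.class_order_ = CLASS_ORDER
        model = self._build_model()
        model.head_norm.gamma.data[:] = self.head_norm_gain
        opt = AdamW(
            model.parameters(),
            lr=self.lr,
            betas=tuple(self.betas),
            weight_decay=self.weight_decay,
        )
        rng = np.random.default_rng(self.seed)
        n = len(Xp)
        mim_curve = []
        if self.pretrain_epochs > 0:
            mim_opt = AdamW(
                model.parameters(), lr=self.lr, betas=tuple(self.betas), weight_decay=self.weight_decay
            )
            for _ in range(self.pretrain_epochs):
                total, count = 0.0, 0
                order = rng.permutation(n)
                for i in order:
                    arr = Xp[i].reshape(-1, *Xp[i].shape[2:])
                    pick = rng.choice(len(arr), size=min(self.pretrain_frames_per_sample, len(arr)), replace=False)
                    mim_opt.zero_grad()
                    loss = model.mim_batch_loss(arr[pick], rng)
                    loss.backward()
                    mim_opt.step()
                    total += float(loss.data)
                    count += 1
                mim_curve.append(total / count)
                if self.verbose:
                    print(f"mim epoch loss {mim_curve[-1]:.4f}")
        curve = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                stacks = []
                for i in batch:
                    arr = Xp[i]
                    kz = self.train_z_planes
                    if kz is not None and self.use_spatial_encoder and arr.shape[1] > kz:
                        arr = arr[:, rng.choice(arr.shape[1], size=kz, replace=False)]
                    if self.augment == "dihedral":
                        arr = np.rot90(arr, k=int(rng.integers(4)), axes=(2, 3))
                        if rng.integers(2):
                            arr = np.flip(arr, axis=2)
                        arr = np.ascontiguousarray(arr)
                    elif self.augment is not None:
                        raise ConfigurationError(f"unknown augment mode {self.augment!r}")
                    stacks.append(arr)
                opt.zero_grad()
                loss = model.batch_loss(stacks, yi[batch], use_spatial=self.use_spatial_encoder)
                loss.backward()
                if self.lr > 0:
                    opt.step()
                total += float(loss.data) * len(batch)
            curve.append(total / n)
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs}  loss {curve[-1]:.4f}")
        self.model_ = model
        self.loss_curve_ = curve
        self.mim_loss_curve_ = mim_curve
        self.n_features_in_ = None
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-sample softmax probabilities in class order (vNo, vLess, vMost)."""
        check_is_fitted(self, "model_")
        Xp = self._prepare_X(X)
        out = np.empty((len(Xp), 3))
        with no_grad():
            for start in range(0, len(Xp), max(self.batch_size, 8)):
                chunk = Xp[start : start + max(self.batch_size, 8)]
                logits = self.model_.forward_batch(chunk, use_spatial=self.use_spatial_encoder)
                out[start : start + len(chunk)] = logits.softmax(axis=-1).data
        return out

    def predict(self, X) -> np.ndarray:
        """Class indices; ties broken toward the lowest class index."""
        return self.predict_proba(X).argmax(axis=1)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        Xp = self._prepare_X(X)
        out = np.empty((len(Xp), 3))
        with no_grad():
            for i, arr in enumerate(Xp):
                out[i] = self.model_.forward_sample(arr, use_spatial=self.use_spatial_encoder).data
        return out
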