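"""Image-spatial-temporal transformer classifier for organoid z-stack series.

The network factorizes a T x Z brightfield stack the way video transformers
factorize clips:

1. **Image encoder** — a ViT: each frame is cut into P x P patches, linearly
   embedded (plus learnable positional embeddings), a learnable CLS token is
   prepended, and L pre-norm transformer blocks followed by a final layer norm
   produce the image CLS vector ``H_0``.
2. **Spatial encoder** — a two-block ViT over the Z image-CLS vectors of one
   day with its own learnable CLS token. It carries no positional embedding,
   so it is invariant to the order of focal planes (Z varies between samples).
3. **Temporal encoder** — a bidirectional LSTM over the T daily spatial CLS
   vectors; the final forward and backward hidden states are concatenated.
4. **Classification head** — a small MLP producing three logits in the fixed
   class order (vNo=0, vLess=1, vMost=2).

A masked-image-modeling mode is provided for desk-scale self-supervised
pretraining: a fraction rho of patch embeddings is replaced by a shared
learnable mask embedding ``e_[M]`` and a single fully connected layer predicts
the normalized pixel vectors of the masked patches.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._autograd import Parameter, Tensor, as_tensor, concatenate, no_grad, stack
from ._nn import AdamW, BiLSTM, LayerNorm, Linear, Module, TransformerEncoder, cross_entropy, trunc_normal
from .errors import ConfigurationError

__all__ = [
    "EncoderConfig",
    "SpatialConfig",
    "TemporalConfig",
    "MaskSet",
    "STViT",
    "patchify",
    "unpatchify",
    "sample_mask",
    "apply_mask",
    "self_attention",
    "multi_head_attention",
    "save_checkpoint",
    "load_checkpoint",
]

CLASS_ORDER = ("vNo-DILI-Concern", "vLess-DILI-Concern", "vMost-DILI-Concern")


@dataclass(frozen=True)
class EncoderConfig:
    """Image (ViT) encoder hyperparameters."""

    image_size: int = 224
    patch_size: int = 16
    embed_dim: int = 768
    depth: int = 12
    n_heads: int = 12
    in_channels: int = 3
    mlp_ratio: float = 4.0
    ln_eps: float = 1e-6
    mask_ratio: float = 0.40  # used only in masked-image-modeling mode
    pos_embed: str = "learnable_2d"  # or "none"

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ConfigurationError(
                f"embed_dim {self.embed_dim} must be divisible by n_heads {self.n_heads}"
            )
        if not 0.0 <= self.mask_ratio < 1.0:
            raise ConfigurationError(f"mask_ratio must be in [0, 1), got {self.mask_ratio}")
        if self.image_size % self.patch_size:
            raise ConfigurationError(
                f"patch size {self.patch_size} must divide image size {self.image_size}"
            )
        if self.pos_embed not in ("learnable_2d", "none"):
            raise ConfigurationError(f"unknown pos_embed {self.pos_embed!r}")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    @property
    def grid_size(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.grid_size**2

    @classmethod
    def tiny(cls, image_size: int = 224, **kw) -> "EncoderConfig":
        """Desk-scale configuration used throughout the tests."""
        return cls(image_size=image_size, embed_dim=64, depth=2, n_heads=4, **kw)


@dataclass(frozen=True)
class SpatialConfig:
    """Spatial (z-axis) encoder: fixed two-block ViT, no positional embedding."""

    depth: int = 2
    ln_eps: float = 1e-6

    def __post_init__(self):
        if self.depth != 2:
            raise ConfigurationError("the spatial encoder depth is fixed at 2")


@dataclass(frozen=True)
class TemporalConfig:
    """Temporal encoder: bidirectional LSTM over the day sequence."""

    hidden_size: int = 64
    bidirectional: bool = True
    pooling: str = "final_concat"

    def __post_init__(self):
        if not self.bidirectional:
            raise ConfigurationError("the temporal encoder is bidirectional by contract")

    @property
    def feature_size(self) -> int:
        return 2 * self.hidden_size


# ---------------------------------------------------------------------------
# patch and mask plumbing


def patchify(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Cut (..., H, W, C) into flattened non-overlapping patches.

    Returns (..., N, P*P*C) with N = H*W/P^2, patches in row-major grid order.
    Lossless: :func:`unpatchify` reproduces the input bit-exactly.
    """
    arr = np.asarray(image)
    *lead, h, w, c = arr.shape
    p = patch_size
    if h % p or w % p:
        raise ConfigurationError(f"patch size {p} does not divide image shape {(h, w)}")
    gh, gw = h // p, w // p
    arr = arr.reshape(*lead, gh, p, gw, p, c)
    arr = np.moveaxis(arr, -4, -3)  # (..., gh, gw, p, p, c)
    return arr.reshape(*lead, gh * gw, p * p * c)


def unpatchify(patches: np.ndarray, image_shape: tuple[int, int, int], patch_size: int) -> np.ndarray:
    """Inverse of :func:`patchify` for a (..., N, P*P*C) patch sequence."""
    h, w, c = image_shape
    p = patch_size
    gh, gw = h // p, w // p
    arr = np.asarray(patches)
    lead = arr.shape[:-2]
    arr = arr.reshape(*lead, gh, gw, p, p, c)
    arr = np.moveaxis(arr, -3, -4)  # (..., gh, p, gw, p, c)
    return arr.reshape(*lead, h, w, c)


@dataclass
class MaskSet:
    """A subset M of patch indices selected for corruption."""

    indices: np.ndarray  # sorted unique patch indices
    n_patches: int

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and (self.indices.min() < 0 or self.indices.max() >= self.n_patches):
            raise ValueError(
                f"mask indices out of range [0, {self.n_patches}): {self.indices}"
            )

    def __len__(self):
        return int(self.indices.size)


def sample_mask(n_patches: int, mask_ratio: float, rng: np.random.Generator) -> MaskSet:
    """Sample |M| = floor(mask_ratio * N) patch indices uniformly without replacement."""
    m = int(np.floor(mask_ratio * n_patches))
    idx = np.sort(rng.choice(n_patches, size=m, replace=False))
    return MaskSet(indices=idx, n_patches=n_patches)


def apply_mask(embedded, mask: MaskSet, mask_token):
    """Replace rows of the (N, D) embedded patch sequence listed in `mask` by
    the shared mask embedding; all other rows pass through unchanged.

    Implements the corruption rule
    ``x_i = [i in M] * e_[M] + (1 - [i in M]) * x_i``.
    Works on plain arrays or autograd tensors (gradients flow to ``e_[M]``).
    """
    x = as_tensor(embedded)
    n, d = x.shape[-2], x.shape[-1]
    token = as_tensor(mask_token)
    delta = np.zeros((n, 1))
    delta[mask.indices] = 1.0
    return x * (1.0 - delta) + token.reshape(1, d) * delta


# ---------------------------------------------------------------------------
# functional attention (the primitives behind the encoder blocks)


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def self_attention(tokens: np.ndarray, u_qkv: np.ndarray):
    """Single-head self-attention: [q, k, v] = x U_qkv, out = softmax(qk^T/sqrt(D_h)) v.

    `u_qkv` has shape (D, 3*D_h). Returns (attended tokens, attention matrix);
    every attention row sums to 1.
    """
    x = np.asarray(tokens, dtype=float)
    u = np.asarray(u_qkv, dtype=float)
    if x.shape[-1] != u.shape[0]:
        raise ConfigurationError(f"token dim {x.shape[-1]} does not match U_qkv {u.shape}")
    if u.shape[1] % 3:
        raise ConfigurationError("U_qkv second dim must be 3 * head_dim")
    dh = u.shape[1] // 3
    q, k, v = np.split(x @ u, 3, axis=-1)
    att = _softmax(q @ k.swapaxes(-1, -2) / np.sqrt(dh))
    return att @ v, att


def multi_head_attention(tokens: np.ndarray, u_qkv_heads, u_msa: np.ndarray):
    """k-head attention: concatenate per-head SA outputs and project with U_msa.

    `u_qkv_heads` is a sequence of k matrices (D, 3*D_h); `u_msa` has shape
    (k*D_h, D). Returns (tokens, list of per-head attention matrices).
    """
    outs, atts = [], []
    for u in u_qkv_heads:
        o, a = self_attention(tokens, u)
        outs.append(o)
        atts.append(a)
    cat = np.concatenate(outs, axis=-1)
    u_msa = np.asarray(u_msa, dtype=float)
    if cat.shape[-1] != u_msa.shape[0]:
        raise ConfigurationError(
            f"concatenated head dim {cat.shape[-1]} does not match U_msa {u_msa.shape}"
        )
    return cat @ u_msa, atts


# ---------------------------------------------------------------------------
# the full model


class STViT(Module):
    """The three-stage encoder plus MLP head (see module docstring)."""

    def __init__(
        self,
        encoder: EncoderConfig,
        spatial: SpatialConfig | None = None,
        temporal: TemporalConfig | None = None,
        n_classes: int = 3,
        seed: int = 0,
        dtype: str = "float32",
    ):
        self.cfg = encoder
        self.spatial_cfg = spatial or SpatialConfig()
        self.temporal_cfg = temporal or TemporalConfig()
        self.n_classes = n_classes
        self.seed = seed
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        d = encoder.embed_dim
        patch_dim = encoder.patch_size**2 * encoder.in_channels
        self.patch_embed = Linear(patch_dim, d, rng)
        self.cls_token = Parameter(trunc_normal(rng, (d,)))
        if encoder.pos_embed == "learnable_2d":
            self.pos_embed = Parameter(trunc_normal(rng, (encoder.n_patches, d)))
        else:
            self.pos_embed = None
        self.encoder = TransformerEncoder(d, encoder.depth, encoder.n_heads, rng, ln_eps=encoder.ln_eps)
        self.mask_token = Parameter(trunc_normal(rng, (d,)))
        self.mim_head = Linear(d, patch_dim, rng)
        self.spatial_cls = Parameter(trunc_normal(rng, (d,)))
        self.spatial_encoder = TransformerEncoder(
            d, self.spatial_cfg.depth, encoder.n_heads, rng, ln_eps=self.spatial_cfg.ln_eps
        )
        self.temporal = BiLSTM(d, self.temporal_cfg.hidden_size, rng)
        # normalize the spatiotemporal feature scale before the classifier,
        # mirroring the final LN the encoders apply to their outputs
        self.head_norm = LayerNorm(self.temporal_cfg.feature_size, self.cfg.ln_eps)
        self.head_fc1 = Linear(self.temporal_cfg.feature_size, d, rng)
        self.head_fc2 = Linear(d, n_classes, rng)
        for p in self.parameters():
            p.data = p.data.astype(self.dtype)

    # -- stage 1: image ------------------------------------------------------
    def embed_patches(self, images: np.ndarray) -> Tensor:
        """(..., H, W, C) -> embedded patch tokens (..., N, D), before CLS."""
        patches = patchify(np.asarray(images, dtype=self.dtype), self.cfg.patch_size)
        x = self.patch_embed(Tensor(patches))
        if self.pos_embed is not None:
            x = x + self.pos_embed
        return x

    def _prepend(self, tokens: Tensor, cls: Parameter) -> Tensor:
        *lead, n, d = tokens.shape
        cls_block = cls.reshape(*([1] * len(lead)), 1, d)
        if lead:
            cls_block = cls_block * np.ones((*lead, 1, 1), dtype=cls.data.dtype)
        return concatenate([cls_block, tokens], axis=-2)

    def encode_image(self, images: np.ndarray, return_attention: bool = False):
        """Run the ViT over one image (H, W, C) or a batch (..., H, W, C).

        Returns the image CLS vector(s) ``H_0`` of shape (..., D); with
        ``return_attention=True`` also the per-layer attention stack
        (L, ..., heads, N+1, N+1).
        """
        x = self.embed_patches(images)
        x = self._prepend(x, self.cls_token)
        y = self.encoder(x)
        h0 = y[..., 0, :]
        if return_attention:
            return h0, self.encoder.attention_stack
        return h0

    # -- stage 2: spatial (z-axis) -------------------------------------------
    def encode_spatial(self, z_cls_tokens, return_attention: bool = False):
        """Fuse the Z image-CLS vectors of one day (or a (T, Z, D) batch of days).

        Prepends the spatial CLS token, runs the two-block encoder, and
        returns token 0. No positional embedding is added, so the output is
        invariant to z-order permutations.
        """
        x = as_tensor(z_cls_tokens)
        if x.shape[-2] < 1:
            raise ValueError("encode_spatial needs at least one z-plane token")
        x = self._prepend(x, self.spatial_cls)
        y = self.spatial_encoder(x)
        s0 = y[..., 0, :]
        if return_attention:
            return s0, self.spatial_encoder.attention_stack
        return s0

    # -- stage 3: temporal ----------------------------------------------------
    def encode_temporal(self, day_tokens) -> Tensor:
        """Bi-LSTM over the ordered day sequence; concatenated final states."""
        if isinstance(day_tokens, Tensor):
            day_tokens = [day_tokens[t] for t in range(day_tokens.shape[0])]
        if len(day_tokens) == 0:
            raise ValueError("encode_temporal needs at least one day")
        return self.temporal([as_tensor(t) for t in day_tokens])

    # -- stage 4: head ---------------------------------------------------------
    def classify_features(self, feature: Tensor) -> Tensor:
        return self.head_fc2(self.head_fc1(self.head_norm(feature)).gelu())

    def forward_sample(self, stack_images: np.ndarray, use_spatial: bool = True) -> Tensor:
        """Logits for one preprocessed stack of shape (T, Z, H, W, C)."""
        t, z = stack_images.shape[:2]
        flat = stack_images.reshape(t * z, *stack_images.shape[2:])
        h0 = self.encode_image(flat)  # (T*Z, D)
        h0 = h0.reshape(t, z, self.cfg.embed_dim)
        if use_spatial:
            day_feats = self.encode_spatial(h0)  # (T, D)
        else:
            if z != 1:
                raise ConfigurationError("spatial bypass expects one fused image per day")
            day_feats = h0[:, 0, :]
        feat = self.encode_temporal(day_feats)
        return self.classify_features(feat)

    def forward_batch(self, stacks: list, use_spatial: bool = True) -> Tensor:
        """Logits (B, n_classes) for several preprocessed stacks in one pass.

        All stacks must share T (the day count); Z may vary per sample. The
        image encoder runs once over every frame of the batch; the spatial
        encoder runs per sample (batched over days); the temporal encoder and
        head run batched.
        """
        t = stacks[0].shape[0]
        if any(s.shape[0] != t for s in stacks):
            raise ConfigurationError("all stacks in a batch must share the day count T")
        flat = np.concatenate([np.asarray(s).reshape(-1, *s.shape[2:]) for s in stacks])
        h0 = self.encode_image(flat)  # (sum T*Z_i, D)
        day_feats, off = [], 0
        for s in stacks:
            z = s.shape[1]
            h = h0[off : off + t * z].reshape(t, z, self.cfg.embed_dim)
            off += t * z
            if use_spatial:
                day_feats.append(self.encode_spatial(h))  # (T, D)
            else:
                if z != 1:
                    raise ConfigurationError("spatial bypass expects one fused image per day")
                day_feats.append(h[:, 0, :])
        days = stack(day_feats, axis=0)  # (B, T, D)
        feat = self.temporal([days[:, ti, :] for ti in range(t)])  # (B, 2*hidden)
        return self.classify_features(feat)

    def batch_loss(self, stacks: list, targets, use_spatial: bool = True) -> Tensor:
        """Mean cross-entropy of a batch (equals the mean of per-sample losses)."""
        logits = self.forward_batch(stacks, use_spatial=use_spatial)
        logp = logits.log_softmax(axis=-1)
        picked = logp[np.arange(len(stacks)), np.asarray(targets, dtype=int)]
        return -picked.mean()

    def classify_forward(self, stack_images: np.ndarray, use_spatial: bool = True, return_attention: bool = False):
        """Class probabilities, logits and the attention record for one sample.

        Probabilities follow the fixed class order (vNo, vLess, vMost) and
        sum to 1. The record carries the spatial-encoder attention per day and,
        on request, the image-encoder attention of the last processed batch.
        """
        with no_grad():
            logits = self.forward_sample(stack_images, use_spatial=use_spatial)
            probs = logits.softmax(axis=-1)
        record = {
            "class_order": CLASS_ORDER,
            "spatial_attention": self.spatial_encoder.attention_stack if use_spatial else None,
        }
        if return_attention:
            record["image_attention"] = self.encoder.attention_stack
        return probs.data, logits.data, record

    # -- masked image modeling --------------------------------------------------
    def mim_corrupt_and_loss(self, image: np.ndarray, rng: np.random.Generator) -> Tensor:
        """Desk-scale masked-patch pretraining loss for one preprocessed image.

        Samples |M| = floor(rho * N) patches, replaces their embeddings by the
        shared mask token, encodes the corrupted sequence, and regresses the
        per-patch normalized pixel vectors of the masked positions with a
        single fully connected layer. The loss is the mean squared error over
        masked positions only.
        """
        if self.cfg.mask_ratio <= 0:
            raise ConfigurationError("mask_ratio must be > 0 in masked-image-modeling mode")
        patches = patchify(np.asarray(image, dtype=self.dtype), self.cfg.patch_size)
        target = patches  # the normalized (preprocessed) pixel vectors
        mask = sample_mask(self.cfg.n_patches, self.cfg.mask_ratio, rng)
        x = self.patch_embed(Tensor(patches))
        if self.pos_embed is not None:
            x = x + self.pos_embed
        x = apply_mask(x, mask, self.mask_token)
        x = self._prepend(x, self.cls_token)
        y = self.encoder(x)
        pred = self.mim_head(y[1:, :])  # drop CLS: predictions for all patches
        err = (pred[mask.indices] - target[mask.indices]) ** 2
        return err.mean()

    def mim_batch_loss(self, images: np.ndarray, rng: np.random.Generator) -> Tensor:
        """Masked-patch regression loss over a batch of frames (B, H, W, C).

        One mask draw is shared across the batch; the loss is the mean squared
        error over the masked rows of every frame.
        """
        if self.cfg.mask_ratio <= 0:
            raise ConfigurationError("mask_ratio must be > 0 in masked-image-modeling mode")
        patches = patchify(np.asarray(images, dtype=self.dtype), self.cfg.patch_size)
        target = patches  # the normalized (preprocessed) pixel vectors
        mask = sample_mask(self.cfg.n_patches, self.cfg.mask_ratio, rng)
        x = self.patch_embed(Tensor(patches))
        if self.pos_embed is not None:
            x = x + self.pos_embed
        x = apply_mask(x, mask, self.mask_token)
        x = self._prepend(x, self.cls_token)
        y = self.encoder(x)
        pred = self.mim_head(y[:, 1:, :])
        err = (pred[:, mask.indices, :] - target[:, mask.indices, :]) ** 2
        return err.mean()

    # -- loss -------------------------------------------------------------------
    def sample_loss(self, stack_images: np.ndarray, class_index: int, use_spatial: bool = True) -> Tensor:
        return cross_entropy(self.forward_sample(stack_images, use_spatial=use_spatial), class_index)

    def config_dict(self) -> dict:
        return {
            "encoder": asdict(self.cfg),
            "spatial": asdict(self.spatial_cfg),
            "temporal": asdict(self.temporal_cfg),
            "n_classes": self.n_classes,
            "seed": self.seed,
            "dtype": str(self.dtype),
            "class_order": list(CLASS_ORDER),
        }


def save_checkpoint(model: STViT, path: str | Path) -> None:
    """Single-file checkpoint: weights + full config + class-order manifest."""
    state = {f"param:{k}": v for k, v in model.state_dict().items()}
    state["config_json"] = np.frombuffer(
        json.dumps(model.config_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> STViT:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["config_json"].tobytes()).decode())
        model = STViT(
            EncoderConfig(**cfg["encoder"]),
            SpatialConfig(**cfg["spatial"]),
            TemporalConfig(**cfg["temporal"]),
            n_classes=cfg["n_classes"],
            seed=cfg["seed"],
            dtype=cfg.get("dtype", "float32"),
        )
        model.load_state_dict(
            {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
        )
    return model
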