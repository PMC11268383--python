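"""Spectral-spatial factorized-attention transformer for hypercube patches.

The image is cut into a square grid of spatial patches per wavelength band;
each band's patches go through the same linear patch embedding and share a
spatial positional embedding (plus an optional learnable band positional
embedding).  Every block applies, in order and each with pre-norm residual
form:

1. **spectral attention** — tokens attend across bands at a fixed spatial
   position (sequence length = number of bands, batched over positions);
2. **spatial attention** — tokens attend across spatial positions within a
   band (the class token joins every band's spatial sequence and its
   per-band updates are averaged);
3. a GELU feed-forward sub-layer with 4x expansion.

The class token bypasses spectral attention via its residual path.  A final
layer norm, linear head and softmax produce class probabilities.  Scores
are scaled by 1/sqrt(d_head) (the standard scaling of the attention
lineage this architecture derives from).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from . import autodiff as ad
from .autodiff import Tensor


@dataclass(frozen=True)
class ModelConfig:
    image_px: int = 224
    patch_px: int = 16
    n_bands: int = 84
    embed_dim: int = 768
    n_heads: int = 12
    depth: int = 12
    n_classes: int = 2
    mlp_ratio: int = 4
    dropout: float = 0.0
    band_pos_embed: bool = True
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_px % self.patch_px:
            raise ValueError("image_px must be divisible by patch_px")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def grid(self) -> int:
        return self.image_px // self.patch_px

    @property
    def n_tokens(self) -> int:
        return self.grid * self.grid

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads


def tiny_config(**overrides) -> ModelConfig:
    """A CPU-scale variant: 2 blocks, 64-dim embedding, 8 bands, 56 px input."""
    base = dict(
        image_px=56,
        patch_px=8,
        n_bands=8,
        embed_dim=64,
        n_heads=4,
        depth=2,
        n_classes=2,
    )
    base.update(overrides)
    return ModelConfig(**base)


def parameter_count(cfg: ModelConfig) -> int:
    """Closed-form trainable parameter count for a configuration."""
    D, P, N, B = cfg.embed_dim, cfg.patch_px, cfg.n_tokens, cfg.n_bands
    n = P * P * D + D  # patch embedding
    n += N * D + D  # spatial positional embedding + class token
    if cfg.band_pos_embed:
        n += B * D
    per_attn = 4 * (D * D + D)  # Wq, Wk, Wv, Wo with biases
    per_block = 2 * per_attn + 3 * 2 * D  # two attentions + three layer norms
    per_block += D * cfg.mlp_ratio * D + cfg.mlp_ratio * D + cfg.mlp_ratio * D * D + D
    n += cfg.depth * per_block
    n += 2 * D  # final norm
    n += D * cfg.n_classes + cfg.n_classes  # head
    return n


# ---------------------------------------------------------------------------
# Attention primitives
# ---------------------------------------------------------------------------

def scaled_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, d: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention on already-projected row matrices.

    ``attention = row_softmax(Q K^T / sqrt(d))``, ``output = attention V``.
    Works on any leading batch shape; ``d`` defaults to the feature length.
    Returns (output, attention) so attention maps can be captured for
    rollout.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if d is None:
        d = Q.shape[-1]
    scores = (Q @ np.swapaxes(K, -1, -2)) / np.sqrt(d)
    scores = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    att = e / e.sum(axis=-1, keepdims=True)
    return att @ V, att


def _init_params(cfg: ModelConfig) -> dict[str, np.ndarray]:
    """Truncated-normal (±2 sigma) initialization, seeded."""
    rng = np.random.default_rng(cfg.init_seed)

    def tn(*shape, std=0.02):
        n = int(np.prod(shape))
        samples = truncnorm.rvs(-2.0, 2.0, scale=std, size=n, random_state=rng)
        return samples.reshape(shape)

    D = cfg.embed_dim
    p: dict[str, np.ndarray] = {
        "patch_embed/W": tn(cfg.patch_px * cfg.patch_px, D),
        "patch_embed/b": np.zeros(D),
        "pos_embed": tn(cfg.n_tokens, D),
        "cls_token": tn(D),
        "norm/g": np.ones(D),
        "norm/b": np.zeros(D),
        "head/W": tn(D, cfg.n_classes),
        "head/b": np.zeros(cfg.n_classes),
    }
    if cfg.band_pos_embed:
        p["band_embed"] = tn(cfg.n_bands, D)
    for l in range(cfg.depth):
        for sub in ("spectral", "spatial"):
            for w in ("q", "k", "v", "o"):
                p[f"block{l}/{sub}/W{w}"] = tn(D, D)
                p[f"block{l}/{sub}/b{w}"] = np.zeros(D)
        for i in (1, 2, 3):
            p[f"block{l}/ln{i}/g"] = np.ones(D)
            p[f"block{l}/ln{i}/b"] = np.zeros(D)
        H = cfg.mlp_ratio * D
        p[f"block{l}/mlp/W1"] = tn(D, H)
        p[f"block{l}/mlp/b1"] = np.zeros(H)
        p[f"block{l}/mlp/W2"] = tn(H, D)
        p[f"block{l}/mlp/b2"] = np.zeros(D)
    return p


def extract_patches(images: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """(S, H, W, B) cubes -> (S, B, N, patch_px**2) flattened patch rows."""
    S, H, W, B = images.shape
    if H != cfg.image_px or W != cfg.image_px or B != cfg.n_bands:
        raise ValueError(
            f"input {images.shape[1:]} does not match config "
            f"({cfg.image_px}, {cfg.image_px}, {cfg.n_bands})"
        )
    g, P = cfg.grid, cfg.patch_px
    x = images.reshape(S, g, P, g, P, B)
    # (S, B, grid_r, grid_c, P, P) -> row-major token order
    x = x.transpose(0, 5, 1, 3, 2, 4).reshape(S, B, g * g, P * P)
    return x


class SpectralSpatialTransformer:
    """The network: parameters + forward pass (training and inference)."""

    def __init__(self, cfg: ModelConfig, params: dict[str, np.ndarray] | None = None):
        self.cfg = cfg
        self.params = params if params is not None else _init_params(cfg)

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        """Flat key -> array archive (NumPy .npz) plus the config fields."""
        import dataclasses

        meta = {f"__cfg__{k}": np.asarray(v) for k, v in dataclasses.asdict(self.cfg).items()}
        np.savez(path, **self.params, **meta)

    @classmethod
    def load(cls, path: str) -> "SpectralSpatialTransformer":
        with np.load(path) as f:
            cfg_kwargs, params = {}, {}
            for k in f.files:
                if k.startswith("__cfg__"):
                    v = f[k][()]
                    name = k[len("__cfg__") :]
                    field_type = ModelConfig.__dataclass_fields__[name].type
                    if "bool" in str(field_type):
                        cfg_kwargs[name] = bool(v)
                    elif "float" in str(field_type):
                        cfg_kwargs[name] = float(v)
                    else:
                        cfg_kwargs[name] = int(v)
                else:
                    params[k] = f[k]
        return cls(ModelConfig(**cfg_kwargs), params)

    def load_external_weights(self, mapping: dict[str, np.ndarray]) -> None:
        """Import hook for externally trained weights with matching keys/shapes."""
        for k, v in mapping.items():
            if k not in self.params:
                raise KeyError(f"unknown parameter {k!r}")
            if self.params[k].shape != np.asarray(v).shape:
                raise ValueError(f"shape mismatch for {k!r}")
            self.params[k] = np.asarray(v, dtype=float)

    # -- forward ------------------------------------------------------------

    def _mha(
        self,
        x: Tensor,
        prefix: str,
        t: dict[str, Tensor],
        capture: list | None,
        dropout_rng: np.random.Generator | None,
    ) -> Tensor:
        """Multi-head attention over axis 1 of a (batch, seq, D) tensor."""
        cfg = self.cfg
        Bt, S, D = x.shape
        h, dh = cfg.n_heads, cfg.head_dim

        def proj(name):
            y = ad.linear(x, t[f"{prefix}/W{name}"], t[f"{prefix}/b{name}"])
            return y.reshape(Bt, S, h, dh).transpose(0, 2, 1, 3)  # (Bt, h, S, dh)

        q, k, v = proj("q"), proj("k"), proj("v")
        scores = ad.matmul(q, k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        att = ad.softmax(scores, axis=-1)
        if capture is not None:
            capture.append(att.data.copy())
        out = ad.matmul(att, v)
        out = out.transpose(0, 2, 1, 3).reshape(Bt, S, D)
        out = ad.linear(out, t[f"{prefix}/Wo"], t[f"{prefix}/bo"])
        return self._dropout(out, dropout_rng)

    def _dropout(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        p = self.cfg.dropout
        if rng is None or p <= 0.0:
            return x
        mask = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask, requires_grad=False)

    def forward(
        self,
        images: np.ndarray,
        train: bool = False,
        capture: dict | None = None,
        dropout_rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Logits for a batch of cubes, shape (S, n_classes).

        ``capture``, when a dict, is filled with per-layer attention maps:
        ``capture["spectral"][l]`` has shape (S*N, heads, B, B) and
        ``capture["spatial"][l]`` has shape (S*B, heads, N+1, N+1).
        """
        cfg = self.cfg
        t = {k: Tensor(v) for k, v in self.params.items()}
        self._tensors = t
        if capture is not None:
            capture["spectral"] = []
            capture["spatial"] = []
        drop = dropout_rng if (train and cfg.dropout > 0) else None

        patches = extract_patches(np.asarray(images, dtype=float), cfg)
        S, B, N, _ = patches.shape
        D = cfg.embed_dim

        x = ad.linear(Tensor(patches, requires_grad=False), t["patch_embed/W"], t["patch_embed/b"])
        x = x + t["pos_embed"]  # broadcast over (S, B, N, D)
        if cfg.band_pos_embed:
            x = x + t["band_embed"].reshape(1, B, 1, D)
        cls = t["cls_token"].reshape(1, D) + Tensor(np.zeros((S, D)), requires_grad=False)

        for l in range(cfg.depth):
            # spectral attention: sequence axis = bands, batched over positions
            y = ad.layer_norm(x, t[f"block{l}/ln1/g"], t[f"block{l}/ln1/b"])
            y = y.transpose(0, 2, 1, 3).reshape(S * N, B, D)
            cap = capture["spectral"] if capture is not None else None
            y = self._mha(y, f"block{l}/spectral", t, cap, drop)
            y = y.reshape(S, N, B, D).transpose(0, 2, 1, 3)
            x = x + y  # class token bypasses spectral attention

            # spatial attention: class token joins every band's sequence
            clsb = cls.reshape(S, 1, 1, D) + Tensor(
                np.zeros((S, B, 1, D)), requires_grad=False
            )
            z = ad.concat([clsb, x], axis=2)  # (S, B, N+1, D)
            z = ad.layer_norm(z, t[f"block{l}/ln2/g"], t[f"block{l}/ln2/b"])
            z = z.reshape(S * B, N + 1, D)
            cap = capture["spatial"] if capture is not None else None
            z = self._mha(z, f"block{l}/spatial", t, cap, drop)
            z = z.reshape(S, B, N + 1, D)
            cls = cls + z.slice((slice(None), slice(None), 0)).mean(axis=1)
            x = x + z.slice((slice(None), slice(None), slice(1, None)))

            # feed-forward on tokens and class token jointly
            allt = ad.concat([cls.reshape(S, 1, D), x.reshape(S, B * N, D)], axis=1)
            w = ad.layer_norm(allt, t[f"block{l}/ln3/g"], t[f"block{l}/ln3/b"])
            w = ad.linear(w, t[f"block{l}/mlp/W1"], t[f"block{l}/mlp/b1"])
            w = ad.gelu(w)
            w = ad.linear(w, t[f"block{l}/mlp/W2"], t[f"block{l}/mlp/b2"])
            w = self._dropout(w, drop)
            allt = allt + w
            cls = allt.slice((slice(None), 0))
            x = allt.slice((slice(None), slice(1, None))).reshape(S, B, N, D)

        out = ad.layer_norm(cls, t["norm/g"], t["norm/b"])
        logits = ad.linear(out, t["head/W"], t["head/b"])
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("non-finite activations in classification head")
        return logits

    def predict_proba(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Softmax class probabilities in eval mode (deterministic)."""
        images = np.asarray(images, dtype=float)
        outs = []
        for i in range(0, images.shape[0], batch_size):
            logits = self.forward(images[i : i + batch_size]).data
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            outs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(outs, axis=0)

    def gradients(self) -> dict[str, np.ndarray]:
        """Parameter gradients accumulated by the last backward pass."""
        return {
            k: (t.grad if t.grad is not None else np.zeros_like(t.data))
            for k, t in self._tensors.items()
        }


def forward_classify(cube_or_batch: np.ndarray, model: SpectralSpatialTransformer) -> np.ndarray:
    """Class probabilities for one cube (H, W, B) or a batch (S, H, W, B)."""
    arr = np.asarray(cube_or_batch, dtype=float)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    probs = model.predict_proba(arr)
    return probs[0] if single else probs


def embed_patches(
    images: np.ndarray, model: SpectralSpatialTransformer
) -> tuple[np.ndarray, np.ndarray]:
    """Patch token embeddings (S, B, N, D) and the class token (S, D).

    Applies the patch projection, spatial positional embedding and (if
    enabled) band positional embedding, exactly as the forward pass does.
    """
    cfg = model.cfg
    patches = extract_patches(np.asarray(images, dtype=float), cfg)
    S, B, N, _ = patches.shape
    x = patches @ model.params["patch_embed/W"] + model.params["patch_embed/b"]
    x = x + model.params["pos_embed"]
    if cfg.band_pos_embed:
        x = x + model.params["band_embed"][None, :, None, :]
    cls = np.broadcast_to(model.params["cls_token"], (S, cfg.embed_dim)).copy()
    return x, cls
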