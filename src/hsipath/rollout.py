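"""Attention rollout: aggregate layer attentions into input-token relevance.

Per layer, head attentions are averaged and convexly mixed with the
identity (0.5 A + 0.5 I, rows renormalized) to account for residual paths;
the rollout is the ordered matrix product of these mixed maps across
layers, which stays row-stochastic.  For the factorized spectral-spatial
model, spatial attentions are rolled out per band to give one spatial map
per wavelength, and each band's map is weighted by the head-averaged
spectral attention mass that band receives, yielding a grid x band
heatmap scaled to [0, 1].
"""

from __future__ import annotations

import logging

import numpy as np

from .model import SpectralSpatialTransformer

logger = logging.getLogger(__name__)


def layer_mix(head_maps: np.ndarray) -> np.ndarray:
    """Head-average then identity-mix one layer's attention maps.

    ``head_maps``: (n_heads, S, S) row-stochastic matrices.  Returns the
    row-stochastic layer matrix ``normalize(0.5 * mean_heads + 0.5 * I)``.
    """
    head_maps = np.asarray(head_maps, dtype=float)
    if head_maps.ndim == 2:
        head_maps = head_maps[None]
    mean = head_maps.mean(axis=0)
    if mean.shape[0] != mean.shape[1]:
        raise ValueError("attention maps must be square")
    mixed = 0.5 * mean + 0.5 * np.eye(mean.shape[0])
    return mixed / mixed.sum(axis=1, keepdims=True)


def rollout(layer_mats: list[np.ndarray]) -> np.ndarray:
    """Ordered product of mixed layer matrices (layer 1 first)."""
    if not layer_mats:
        raise ValueError("need at least one layer")
    size = np.asarray(layer_mats[0]).shape
    out = np.eye(size[0])
    for m in layer_mats:
        m = np.asarray(m, dtype=float)
        if m.shape != size:
            raise ValueError(f"layer size mismatch: {m.shape} vs {size}")
        out = out @ m
    return out


def heatmap_from_rollout(
    rollout_mat: np.ndarray,
    cls_index: int,
    grid_shape: tuple[int, int],
    band_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Class-token relevance reshaped to the token grid, min-max scaled.

    ``rollout_mat`` is one spatial rollout (or a stack of per-band
    rollouts, leading axis = band); the class-token row minus its own entry
    gives per-token relevance.  Returns a (rows, cols, n_bands) heatmap in
    [0, 1]; a constant map scales to all zeros with a warning.
    """
    mats = np.asarray(rollout_mat, dtype=float)
    if mats.ndim == 2:
        mats = mats[None]
    nb = mats.shape[0]
    rows, cols = grid_shape
    maps = np.empty((rows, cols, nb))
    for b in range(nb):
        row = np.delete(mats[b, cls_index], cls_index)
        if row.size != rows * cols:
            raise ValueError("rollout size does not match token grid")
        maps[:, :, b] = row.reshape(rows, cols)
    if band_weights is not None:
        w = np.asarray(band_weights, dtype=float)
        if w.size != nb:
            raise ValueError("band weight length mismatch")
        maps = maps * w[None, None, :]
    lo, hi = maps.min(), maps.max()
    if hi - lo < 1e-15:
        logger.warning("constant rollout map; returning zeros")
        return np.zeros_like(maps)
    return (maps - lo) / (hi - lo)


def spectral_band_weights(spectral_maps: list[np.ndarray]) -> np.ndarray:
    """Per-band attention mass from the captured spectral attentions.

    For each layer the head- and query-averaged attention received by each
    band is accumulated; the final layer's distribution is returned scaled
    to unit maximum.  This is the weighting used to modulate per-band
    spatial rollouts.
    """
    last = np.asarray(spectral_maps[-1], dtype=float)  # (batch, heads, B, B)
    received = last.mean(axis=(0, 1, 2))  # average over batch, heads, queries
    return received / max(received.max(), 1e-15)


def attention_rollout(
    model: SpectralSpatialTransformer, cube: np.ndarray
) -> np.ndarray:
    """Per-band spatial attention heatmap for one input cube (H, W, B).

    Runs the model with attention capture, rolls out the spatial attention
    stream independently for each band, weights bands by their spectral
    attention mass, and returns a (grid, grid, n_bands) heatmap in [0, 1].
    """
    cfg = model.cfg
    capture: dict = {}
    model.forward(np.asarray(cube, dtype=float)[None], capture=capture)
    B, N = cfg.n_bands, cfg.n_tokens
    per_band_rollouts = np.empty((B, N + 1, N + 1))
    for b in range(B):
        mats = []
        for layer_maps in capture["spatial"]:  # (1*B, heads, N+1, N+1)
            mats.append(layer_mix(layer_maps[b]))
        per_band_rollouts[b] = rollout(mats)
    weights = spectral_band_weights(capture["spectral"])
    return heatmap_from_rollout(
        per_band_rollouts, cls_index=0, grid_shape=(cfg.grid, cfg.grid), band_weights=weights
    )
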