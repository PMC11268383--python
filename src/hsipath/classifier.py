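"""scikit-learn-style estimator facade over the spectral-spatial transformer."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .augment import TransformRanges
from .model import ModelConfig, SpectralSpatialTransformer
from .training import TrainConfig, train_model


class SpectralSpatialTransformerClassifier(BaseEstimator, ClassifierMixin):
    """Hypercube patch classifier with a fit/predict surface.

    ``X`` is an ``(n_samples, image_px, image_px, n_bands)`` array of
    transmittance cubes sharing a wavelength axis; ``y`` holds binary
    labels (any two values; mapped to ``classes_``).  Training follows the
    package's protocol (Nesterov SGD, stepped learning rate, best
    validation weighted-F1 checkpoint); a fraction of the training data is
    held out internally for checkpoint selection unless a validation set is
    passed to :meth:`fit` explicitly.

    Examples
    --------
    >>> clf = SpectralSpatialTransformerClassifier(depth=2, embed_dim=64,
    ...     n_heads=4, image_px=56, patch_px=8, n_bands=8, epochs=5)
    >>> clf.fit(X_train, y_train)          # doctest: +SKIP
    >>> clf.predict_proba(X_test)          # doctest: +SKIP
    """

    def __init__(
        self,
        image_px: int = 224,
        patch_px: int = 16,
        n_bands: int = 84,
        embed_dim: int = 768,
        n_heads: int = 12,
        depth: int = 12,
        dropout: float = 0.0,
        band_pos_embed: bool = True,
        epochs: int = 15,
        batch_size: int = 16,
        lr0: float = 1e-3,
        momentum: float = 0.9,
        lr_decay: float = 0.5,
        lr_decay_every: int = 5,
        augment: bool = False,
        augment_ranges: TransformRanges | None = None,
        val_fraction: float = 0.2,
        wavelengths: np.ndarray | None = None,
        random_state: int = 0,
    ):
        self.image_px = image_px
        self.patch_px = patch_px
        self.n_bands = n_bands
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.depth = depth
        self.dropout = dropout
        self.band_pos_embed = band_pos_embed
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.momentum = momentum
        self.lr_decay = lr_decay
        self.lr_decay_every = lr_decay_every
        self.augment = augment
        self.augment_ranges = augment_ranges
        self.val_fraction = val_fraction
        self.wavelengths = wavelengths
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------

    def _validate(self, X: np.ndarray, y: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 4:
            raise ValueError("X must be (n_samples, H, W, B)")
        expect = (self.image_px, self.image_px, self.n_bands)
        if X.shape[1:] != expect:
            raise ValueError(f"sample shape {X.shape[1:]} != configured {expect}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if y is None:
            return X
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y disagree in length")
        return X, y

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            image_px=self.image_px,
            patch_px=self.patch_px,
            n_bands=self.n_bands,
            embed_dim=self.embed_dim,
            n_heads=self.n_heads,
            depth=self.depth,
            n_classes=2,
            dropout=self.dropout,
            band_pos_embed=self.band_pos_embed,
            init_seed=self.random_state,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr0=self.lr0,
            momentum=self.momentum,
            lr_decay=self.lr_decay,
            lr_decay_every=self.lr_decay_every,
            augment=self.augment,
            augment_ranges=self.augment_ranges,
            seed=self.random_state,
        )

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = self._validate(X, y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        # per-band standardization from training statistics: removes the
        # bright-background common mode that otherwise dominates the tokens.
        # Applied inside the training loop *after* augmentation, which
        # operates on raw [0, 1] transmittance.
        self.band_mean_ = X.mean(axis=(0, 1, 2))
        self.band_std_ = np.maximum(X.std(axis=(0, 1, 2)), 1e-8)
        if self.classes_.size != 2:
            raise ValueError("binary classification only")
        if X_val is None:
            # internal patient-agnostic stratified holdout for checkpoint selection
            rng = np.random.default_rng(self.random_state)
            val_idx = []
            for c in range(2):
                idx = np.flatnonzero(y_enc == c)
                rng.shuffle(idx)
                k = max(1, int(round(self.val_fraction * idx.size)))
                val_idx.append(idx[:k])
            val_idx = np.concatenate(val_idx)
            mask = np.zeros(len(y_enc), dtype=bool)
            mask[val_idx] = True
            Xtr, ytr, Xva, yva = X[~mask], y_enc[~mask], X[mask], y_enc[mask]
        else:
            Xva, yva_raw = self._validate(X_val, np.asarray(y_val))
            yva = np.searchsorted(self.classes_, yva_raw)
            Xtr, ytr = X, y_enc
        model = SpectralSpatialTransformer(self._model_config())
        best, log = train_model(
            model,
            (Xtr, ytr),
            (Xva, yva),
            self._train_config(),
            wavelengths=self.wavelengths,
            normalize=lambda a: (a - self.band_mean_) / self.band_std_,
        )
        model.params = best
        self.model_ = model
        self.training_log_ = log
        self.best_epoch_ = int(log.attrs["best_epoch"])
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._validate(X)
        X = (X - self.band_mean_) / self.band_std_
        return self.model_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def decision_function(self, X) -> np.ndarray:
        """Score for the positive (second) class, for ROC analysis."""
        return self.predict_proba(X)[:, 1]
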