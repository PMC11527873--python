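"""Scikit-learn-style estimator wrapping the segmentation network.

``ReflexSegmenter`` exposes the network through the familiar
``fit``/``predict`` surface so it composes with sklearn model selection:

>>> seg = ReflexSegmenter(variant="proposed", channel_scale=0.25,
...                       max_epochs=20, random_state=0)
>>> seg.fit(X, y)            # X: (n, H, W, 3) in [0, 1]; y: (n, H, W) binary
>>> masks = seg.predict(X)   # (n, H, W) binary masks
>>> seg.score(X, y)          # mean Dice
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .arch import build_variant
from .losses import LossConfig
from .metrics import evaluate_dataset
from .nn import Tensor, no_grad
from .train import AugmentConfig, TrainConfig, train


class ReflexSegmenter(BaseEstimator):
    """Encoder-decoder segmenter for tiny bright targets in eye images.

    Parameters mirror the training protocol: AdamW at ``lr``, focal
    Tversky loss with (``alpha``, ``beta``, ``gamma``), early stopping
    after ``patience`` stagnant validation epochs, weights restored from
    the minimum-validation-loss epoch.  ``channel_scale`` uniformly
    shrinks the channel schedule for desk-scale work.

    Attributes set by :meth:`fit` end in an underscore: ``network_`` (the
    trained network), ``history_`` (per-epoch train/val losses),
    ``n_epochs_``, ``best_epoch_``.
    """

    def __init__(self, variant: str = "proposed", channel_scale: float = 1.0,
                 alpha: float = 0.7, beta: float = 0.3,
                 gamma: float = 4.0 / 3.0, lr: float = 1e-4,
                 batch_size: int = 8, max_epochs: int = 50,
                 patience: int = 15, weight_decay: float = 0.01,
                 augment: bool = False, threshold: float = 0.5,
                 validation_fraction: float = 0.0,
                 random_state: int | None = None):
        self.variant = variant
        self.channel_scale = channel_scale
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.weight_decay = weight_decay
        self.augment = augment
        self.threshold = threshold
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _check_xy(X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"X must be (n, H, W, 3), got {X.shape}")
        if X.min() < 0.0 or X.max() > 1.0:
            raise ValueError("X intensities must lie in [0, 1]")
        if y is None:
            return X, None
        y = np.asarray(y)
        if y.shape != X.shape[:3]:
            raise ValueError(f"y must be (n, H, W) matching X, got {y.shape}")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary masks")
        return X, y.astype(np.uint8)

    def _train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size, lr=self.lr,
            weight_decay=self.weight_decay, max_epochs=self.max_epochs,
            patience=min(self.patience, self.max_epochs),
            augment=AugmentConfig() if self.augment else None,
            loss=LossConfig(alpha=self.alpha, beta=self.beta,
                            gamma=self.gamma),
            seed=seed, channel_scale=self.channel_scale)

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None) -> "ReflexSegmenter":
        """Fit on images ``X`` and masks ``y``.

        Validation data for early stopping comes from ``(X_val, y_val)``
        if given, else from ``validation_fraction`` of the training data,
        else the training data itself (overfitting mode, useful for
        capacity checks).
        """
        X, y = self._check_xy(X, y)
        seed = 0 if self.random_state is None else int(self.random_state)
        if X_val is not None:
            X_val, y_val = self._check_xy(X_val, y_val)
            xt, yt = X, y
        elif self.validation_fraction > 0.0:
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(X))
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            xt, yt = X[tr_idx], y[tr_idx]
            X_val, y_val = X[val_idx], y[val_idx]
        else:
            xt, yt = X, y
            X_val, y_val = X, y

        self.network_ = build_variant(self.variant,
                                      channel_scale=self.channel_scale,
                                      seed=seed)
        cfg = self._train_config(seed)
        _, history = train(self.network_, (xt, yt), (X_val, y_val), cfg)
        self.history_ = history
        self.n_epochs_ = len(history["val_loss"])
        self.best_epoch_ = history["best_epoch"]
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel foreground probabilities, shape (n, H, W)."""
        check_is_fitted(self, "network_")
        X, _ = self._check_xy(X)
        self.network_.eval()
        out = []
        with no_grad():
            for lo in range(0, len(X), self.batch_size):
                xb = np.ascontiguousarray(X[lo:lo + self.batch_size])
                out.append(self.network_(Tensor(xb)).numpy()[..., 0])
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        """Binary masks at ``threshold``, shape (n, H, W)."""
        return (self.predict_proba(X) > self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean per-image Dice coefficient."""
        X, y = self._check_xy(X, y)
        preds = self.predict(X)
        return evaluate_dataset(list(preds), list(y)).dice


__all__ = ["ReflexSegmenter"]
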