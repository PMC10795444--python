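"""Scikit-learn style estimator facade over HN-Net training.

`HNNetSegmenter` exposes the network as a conventional estimator —
``fit(X, y)`` / ``predict(X)`` / ``predict_proba(X)`` with
``get_params``/``set_params`` — so it composes with sklearn model
selection utilities.  X is an array of preprocessed slices
(n_slices, H, W) with values in [0, 1]; y the matching binary masks.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .model import ModelConfig, build_model
from .training import TrainConfig, fine_tune, train

__all__ = ["HNNetSegmenter"]


class HNNetSegmenter(BaseEstimator):
    """Per-organ binary segmentation with the HN-Net architecture.

    Parameters mirror ModelConfig and TrainConfig; see those classes
    for semantics.  After ``fit`` the trained network is available as
    ``model_`` and the loss trajectory as ``history_``.
    """

    def __init__(self, input_size: int = 64, depth: int = 2,
                 base_channels: int = 4, cbam_reduction: int = 8,
                 cbam_spatial_kernel: int = 7, use_cbam: bool = True,
                 cbam_scope: str = "all", separable: bool = True,
                 learning_rate: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, lr_decay_factor: float = 0.8,
                 lr_decay_every: int = 10, epochs: int = 20,
                 batch_size: int = 8, threshold: float = 0.5,
                 random_state: int = 0):
        self.input_size = input_size
        self.depth = depth
        self.base_channels = base_channels
        self.cbam_reduction = cbam_reduction
        self.cbam_spatial_kernel = cbam_spatial_kernel
        self.use_cbam = use_cbam
        self.cbam_scope = cbam_scope
        self.separable = separable
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_every = lr_decay_every
        self.epochs = epochs
        self.batch_size = batch_size
        self.threshold = threshold
        self.random_state = random_state

    # -- config assembly -------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(input_size=self.input_size, depth=self.depth,
                           base_channels=self.base_channels,
                           cbam_reduction=self.cbam_reduction,
                           cbam_spatial_kernel=self.cbam_spatial_kernel,
                           use_cbam=self.use_cbam,
                           cbam_scope=self.cbam_scope,
                           separable=self.separable,
                           seed=self.random_state)

    def _train_config(self, epochs: int | None = None) -> TrainConfig:
        return TrainConfig(learning_rate=self.learning_rate,
                           beta1=self.beta1, beta2=self.beta2,
                           lr_decay_factor=self.lr_decay_factor,
                           lr_decay_every=self.lr_decay_every,
                           epochs=self.epochs if epochs is None else epochs,
                           batch_size=self.batch_size,
                           seed=self.random_state)

    def _validate_xy(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_slices, H, W)")
        if X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            raise ValueError(
                f"slices must be {self.input_size}x{self.input_size}, "
                f"got {X.shape[1:]}")
        if X.min() < 0 or X.max() > 1:
            raise ValueError("X must be windowed/normalized to [0, 1]")
        if y is None:
            return X, None
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError("y must match X in shape")
        if not np.isin(np.unique(y), (0, 1)).all():
            raise ValueError("y must be binary")
        return X, y.astype(np.float64)

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y):
        X, y = self._validate_xy(X, y)
        self.model_ = build_model(self._model_config())
        self.model_, self.history_ = train(
            self.model_, list(zip(X, y)), self._train_config())
        return self

    def fine_tune(self, X, y, epochs: int | None = None):
        """Continue training the fitted network on additional labeled data."""
        check_is_fitted(self, "model_")
        X, y = self._validate_xy(X, y)
        self.model_, history = fine_tune(
            self.model_, [], list(zip(X, y)), self._train_config(epochs))
        self.history_.losses.extend(history.losses)
        self.history_.learning_rates.extend(history.learning_rates)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel foreground probabilities, shape (n_slices, H, W)."""
        check_is_fitted(self, "model_")
        X, _ = self._validate_xy(X)
        self.model_.eval()
        return self.model_.forward_array(X)

    def predict(self, X) -> np.ndarray:
        """Binary masks: probabilities thresholded at `threshold`."""
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean per-slice Dice of thresholded predictions against y."""
        from .metrics import overlap_metrics
        X, y = self._validate_xy(X, y)
        pred = self.predict(X)
        return float(np.mean([overlap_metrics(p, t)[0]
                              for p, t in zip(pred, y)]))
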