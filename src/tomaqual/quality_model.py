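"""Multi-task feed-forward regression from the normalized a* feature to six
quality traits (FI, SSC, SS, TA, VC, LYC).

Architecture: scalar input → 256 → 128 → 64 → 6, ReLU hidden activations,
linear output, dropout 0.4 after each hidden layer during training only.
Targets are standardized independently per trait; training minimizes an
adaptively weighted multi-task loss Σ λ_k·MSE_k whose weights track each
task's recent error (harder tasks upweighted), renormalized to sum 6.
Training: Adam, lr 0.001, batch 16, 100 epochs by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from . import nn
from .simulate import TRAITS, TRAIT_UNITS

__all__ = [
    "DNNParams",
    "QualityVector",
    "dnn_forward",
    "adaptive_multitask_loss",
    "update_adaptive_weights",
    "QualityDNNRegressor",
]

logger = logging.getLogger(__name__)


@dataclass
class DNNParams:
    """Weights of the quality network (w_k maps layer k−1 → layer k)."""

    w1: np.ndarray
    w2: np.ndarray
    w3: np.ndarray
    w4: np.ndarray
    b1: np.ndarray
    b2: np.ndarray
    b3: np.ndarray
    b4: np.ndarray


@dataclass
class QualityVector:
    """Six quality traits with their customary units."""

    FI: float  # firmness, kg/cm²
    SSC: float  # soluble solids, °Brix
    SS: float  # soluble sugars, mg/g
    TA: float  # titratable acidity, %
    VC: float  # vitamin C, mg/g
    LYC: float  # lycopene, mg/g

    def as_array(self) -> np.ndarray:
        return np.array([self.FI, self.SSC, self.SS, self.TA, self.VC, self.LYC])


def dnn_forward(x, params: DNNParams) -> np.ndarray:
    """Inference-mode forward pass H_k = ReLU(w_k·H_{k−1}+b_k); Y = w4·H3+b4."""
    n_in = params.w1.shape[0]
    X = np.atleast_1d(np.asarray(x, dtype=float)).reshape(-1, n_in)
    relu = lambda v: np.maximum(v, 0.0)
    h1 = relu(X @ params.w1 + params.b1)
    h2 = relu(h1 @ params.w2 + params.b2)
    h3 = relu(h2 @ params.w3 + params.b3)
    y = h3 @ params.w4 + params.b4
    return y


def update_adaptive_weights(task_mse: np.ndarray, gamma: float = 0.5) -> np.ndarray:
    """λ_k ∝ MSE_k^γ, renormalized to sum to the task count.

    Harder (higher-error) tasks receive larger weights; equal errors give
    all-ones.  Zero total error leaves the weights at 1.
    """
    task_mse = np.asarray(task_mse, dtype=float)
    if not np.isfinite(task_mse).all():
        raise ValueError("non-finite task error")
    k = task_mse.size
    total = (task_mse**gamma).sum()
    if total == 0:
        return np.ones(k)
    return k * task_mse**gamma / total


def adaptive_multitask_loss(
    predictions: np.ndarray, targets: np.ndarray, weights: np.ndarray, gamma: float = 0.5
) -> tuple[float, np.ndarray]:
    """Weighted multi-task loss Σ λ_k·MSE_k and the post-update weights."""
    predictions = np.atleast_2d(predictions)
    targets = np.atleast_2d(targets)
    weights = np.asarray(weights, dtype=float)
    if predictions.shape != targets.shape or predictions.shape[1] != weights.size:
        raise ValueError("predictions, targets and weights must align")
    task_mse = ((predictions - targets) ** 2).mean(axis=0)
    loss = float((weights * task_mse).sum())
    new_weights = update_adaptive_weights(task_mse, gamma) if task_mse.sum() > 0 else weights.copy()
    return loss, new_weights


class QualityDNNRegressor(BaseEstimator, RegressorMixin):
    """Multi-task quality regressor from a_norm ∈ [0, 1].

    fit(a, Y): a is (S,) scalars, Y is (S, 6) traits in physical units.
    predict returns de-standardized traits clamped at 0 from below.
    """

    def __init__(
        self,
        hidden_sizes: tuple = (256, 128, 64),
        dropout: float = 0.4,
        gamma: float = 0.5,
        weight_smoothing: float = 0.8,
        learning_rate: float = 1e-3,
        batch_size: int = 16,
        epochs: int = 100,
        lr_decay: float = 1.0,
        lr_decay_at: float = 0.7,
        seed: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.gamma = gamma
        self.weight_smoothing = weight_smoothing
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.lr_decay = lr_decay
        self.lr_decay_at = lr_decay_at
        self.seed = seed

    def _build(self) -> None:
        rng = np.random.default_rng(self.seed)
        sizes = (1, *self.hidden_sizes, 6)
        self.dense_ = [nn.Dense(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self._dropout_rng = np.random.default_rng(self.seed + 1)
        self._shuffle_rng = np.random.default_rng(self.seed + 2)

    def _forward(self, x: np.ndarray, training: bool) -> nn.Tensor:
        h = nn.Tensor(x.reshape(-1, 1))
        for layer in self.dense_[:-1]:
            h = nn.relu(layer(h))
            if training and self.dropout > 0:
                keep = (self._dropout_rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * nn.Tensor(keep)
        return self.dense_[-1](h)

    def fit(self, X, y=None) -> "QualityDNNRegressor":
        a = np.asarray(X, dtype=float).ravel()
        Y = np.asarray(y, dtype=float)
        if Y.ndim != 2 or Y.shape != (a.size, 6) or a.size == 0:
            raise ValueError("targets must be (samples, 6) aligned with a_norm inputs")
        self.target_scaler_ = StandardScaler()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant targets give std=0 → scaled zeros
            Yz = self.target_scaler_.fit_transform(Y)
        self._build()
        optimizer = nn.Adam([p for l in self.dense_ for p in l.parameters()], lr=self.learning_rate)
        self.loss_history_ = []
        self.task_weights_ = np.ones(6)
        ema_mse = None
        n = a.size
        decay_epoch = int(self.lr_decay_at * self.epochs)
        for epoch in range(self.epochs):
            if self.lr_decay != 1.0 and epoch == decay_epoch:
                optimizer.lr = self.learning_rate * self.lr_decay
            order = self._shuffle_rng.permutation(n)
            losses = []
            epoch_sq = np.zeros(6)
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                pred = self._forward(a[idx], training=True)
                err2 = (pred - nn.Tensor(Yz[idx])) ** 2
                task_mse = err2.mean(axis=0)  # (6,)
                loss = (nn.Tensor(self.task_weights_) * task_mse).sum()
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(float(loss.data))
                epoch_sq += err2.data.sum(axis=0)
            epoch_loss = float(np.mean(losses))
            if not np.isfinite(epoch_loss):
                raise nn.TrainingDivergedError(epoch)
            epoch_mse = epoch_sq / n
            ema_mse = epoch_mse if ema_mse is None else (
                self.weight_smoothing * ema_mse + (1 - self.weight_smoothing) * epoch_mse
            )
            if ema_mse.sum() > 0:
                self.task_weights_ = update_adaptive_weights(ema_mse, self.gamma)
            self.loss_history_.append(epoch_loss)
            logger.debug("dnn epoch %d loss %.6g", epoch, epoch_loss)
        return self

    def predict(self, X) -> np.ndarray:
        """De-standardized (S, 6) trait predictions, clamped at 0."""
        check_is_fitted(self, "dense_")
        a = np.asarray(X, dtype=float).ravel()
        if ((a < 0) | (a > 1)).any():
            warnings.warn("a_norm outside [0, 1]; prediction proceeds without clamping input")
        z = self._forward(a, training=False).data
        return np.maximum(self.target_scaler_.inverse_transform(z), 0.0)

    def predict_vectors(self, X) -> list[QualityVector]:
        return [QualityVector(*row) for row in self.predict(X)]

    def dnn_params(self) -> DNNParams:
        check_is_fitted(self, "dense_")
        w = [l.W.data for l in self.dense_]
        b = [l.b.data for l in self.dense_]
        return DNNParams(w[0], w[1], w[2], w[3], b[0], b[1], b[2], b[3])

    def save(self, path) -> None:
        check_is_fitted(self, "dense_")
        state = {
            "kind": "quality_dnn",
            "config": self.get_params(),
            "weights": [l.state_list() for l in self.dense_],
            "scaler_mean": self.target_scaler_.mean_.tolist(),
            "scaler_scale": self.target_scaler_.scale_.tolist(),
            "loss_history": self.loss_history_,
            "task_weights": self.task_weights_.tolist(),
            "traits": TRAITS,
            "units": TRAIT_UNITS,
        }
        nn.save_checkpoint(path, state)

    @classmethod
    def load(cls, path) -> "QualityDNNRegressor":
        state = nn.load_checkpoint(path)
        if state.get("kind") != "quality_dnn":
            raise ValueError("incompatible checkpoint")
        model = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in state["config"].items()})
        model._build()
        for layer, st in zip(model.dense_, state["weights"]):
            layer.load_state_list(st)
        model.target_scaler_ = StandardScaler()
        model.target_scaler_.mean_ = np.asarray(state["scaler_mean"])
        model.target_scaler_.scale_ = np.asarray(state["scaler_scale"])
        model.target_scaler_.var_ = model.target_scaler_.scale_ ** 2
        model.target_scaler_.n_features_in_ = 6
        model.loss_history_ = state["loss_history"]
        model.task_weights_ = np.asarray(state["task_weights"])
        return model
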