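"""GRU-with-attention forecasting of fruit surface color fractions.

A single GRU layer encodes 24-step windows of six features (temperature,
humidity, radiation and lagged red/yellow/green fractions); query–key–value
attention over all hidden states (query = projection of the final state)
produces a context vector, followed by a ReLU fully connected layer and a
linear head with three outputs.  Raw outputs are clipped to [0, 1] and
renormalized so predictions lie on the 3-simplex.  Training: Adam, lr
0.001, batch 64, MSE over the three outputs, 150 epochs by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .preprocess import WindowedDataset

__all__ = [
    "GRUCellParams",
    "gru_cell_step",
    "AttentionParams",
    "AttentionOutput",
    "attention",
    "GRUAttentionForecaster",
    "to_simplex",
]

logger = logging.getLogger(__name__)


@dataclass
class GRUCellParams:
    w_xr: np.ndarray
    w_hr: np.ndarray
    w_xz: np.ndarray
    w_hz: np.ndarray
    w_xh: np.ndarray
    w_hh: np.ndarray
    b_r: np.ndarray
    b_z: np.ndarray
    b_h: np.ndarray


def gru_cell_step(x: np.ndarray, h_prev: np.ndarray, params: GRUCellParams) -> np.ndarray:
    """One GRU update: r, z gates then candidate; h' = z·h + (1−z)·h~."""
    x = np.asarray(x, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    if x.shape[0] != params.w_xr.shape[0] or h_prev.shape[0] != params.w_hr.shape[0]:
        raise ValueError("input/hidden sizes inconsistent with cell weights")
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    r = sig(x @ params.w_xr + h_prev @ params.w_hr + params.b_r)
    z = sig(x @ params.w_xz + h_prev @ params.w_hz + params.b_z)
    h_tilde = np.tanh(x @ params.w_xh + (r * h_prev) @ params.w_hh + params.b_h)
    return z * h_prev + (1.0 - z) * h_tilde


@dataclass
class AttentionParams:
    W_Q: np.ndarray
    W_K: np.ndarray
    W_V: np.ndarray


@dataclass
class AttentionOutput:
    weights: np.ndarray  # α, length T, ≥ 0, sums to 1
    context: np.ndarray


def attention(H: np.ndarray, params: AttentionParams) -> AttentionOutput:
    """Dot-product attention over a hidden-state sequence (T, hidden).

    q projects the final state; α = softmax over key·q scores; the context
    is the α-weighted sum of value projections.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("H must be a non-empty (T, hidden) sequence")
    q = H[-1] @ params.W_Q
    K = H @ params.W_K
    V = H @ params.W_V
    scores = K @ q
    shifted = np.exp(scores - scores.max())
    alpha = shifted / shifted.sum()
    return AttentionOutput(alpha, V.T @ alpha)


def to_simplex(raw: np.ndarray) -> np.ndarray:
    """Clip to [0, 1] and renormalize rows to sum 1 (uniform if all-zero)."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    clipped = np.clip(raw, 0.0, 1.0)
    sums = clipped.sum(axis=1, keepdims=True)
    uniform = np.full_like(clipped, 1.0 / clipped.shape[1])
    return np.where(sums > 0, clipped / np.where(sums == 0, 1.0, sums), uniform)


class GRUAttentionForecaster(BaseEstimator, RegressorMixin):
    """Next-step red/yellow/green fraction predictor.

    fit(X, Y): X is (S, T, 6) scaled windows pairing environment channels
    with lagged color fractions, Y is (S, 3) next-step fractions.
    """

    def __init__(
        self,
        hidden_size: int = 64,
        attention_dim: int = 32,
        fc_size: int = 32,
        time_steps: int = 24,
        n_features: int = 6,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        epochs: int = 150,
        seed: int = 0,
    ):
        self.hidden_size = hidden_size
        self.attention_dim = attention_dim
        self.fc_size = fc_size
        self.time_steps = time_steps
        self.n_features = n_features
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _build(self) -> None:
        rng = np.random.default_rng(self.seed)
        self.gru_ = nn.GRULayer(self.n_features, self.hidden_size, rng)
        self.attention_ = nn.Attention(self.hidden_size, self.attention_dim, rng)
        self.fc_ = nn.Dense(self.attention_dim, self.fc_size, rng)
        self.head_ = nn.Dense(self.fc_size, 3, rng)
        self._shuffle_rng = np.random.default_rng(self.seed + 1)

    def _params(self) -> list:
        return (
            self.gru_.parameters()
            + self.attention_.parameters()
            + self.fc_.parameters()
            + self.head_.parameters()
        )

    def _forward(self, batch: np.ndarray) -> nn.Tensor:
        xs = [nn.Tensor(batch[:, t, :]) for t in range(batch.shape[1])]
        hs = self.gru_.forward_sequence(xs)
        context, _ = self.attention_(hs)
        return self.head_(nn.relu(self.fc_(context)))

    def fit(self, X, y=None) -> "GRUAttentionForecaster":
        if isinstance(X, WindowedDataset):
            X, y = X.X, X.y
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y, dtype=float)
        if X.ndim != 3 or X.shape[2] != self.n_features:
            raise ValueError(f"X must be (samples, T, {self.n_features})")
        if Y.ndim != 2 or Y.shape != (X.shape[0], 3) or X.shape[0] == 0:
            raise ValueError("Y must be (samples, 3) aligned with X")
        self.n_features_in_ = X.shape[2]
        self._build()
        optimizer = nn.Adam(self._params(), lr=self.learning_rate)
        self.loss_history_ = []
        n = X.shape[0]
        for epoch in range(self.epochs):
            order = self._shuffle_rng.permutation(n)
            losses = []
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                pred = self._forward(X[idx])
                loss = ((pred - nn.Tensor(Y[idx])) ** 2).mean()
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(float(loss.data))
            epoch_loss = float(np.mean(losses))
            if not np.isfinite(epoch_loss):
                raise nn.TrainingDivergedError(epoch)
            self.loss_history_.append(epoch_loss)
            logger.debug("gru-at epoch %d loss %.6g", epoch, epoch_loss)
        return self

    def predict(self, X) -> np.ndarray:
        """Simplex-projected (red, yellow, green) predictions."""
        check_is_fitted(self, "gru_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.ndim != 3 or X.shape[2] != self.n_features_in_:
            raise ValueError("window must have shape (T, 6) or (S, T, 6)")
        out = to_simplex(self._forward(X).data)
        return out[0] if single else out

    def predict_raw(self, X) -> np.ndarray:
        """Linear-head outputs before simplex projection."""
        check_is_fitted(self, "gru_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        return self._forward(X).data

    def cell_params(self) -> GRUCellParams:
        check_is_fitted(self, "gru_")
        g = self.gru_
        return GRUCellParams(
            g.w_xr.data, g.w_hr.data, g.w_xz.data, g.w_hz.data,
            g.w_xh.data, g.w_hh.data, g.b_r.data, g.b_z.data, g.b_h.data,
        )

    def attention_params(self) -> AttentionParams:
        check_is_fitted(self, "attention_")
        a = self.attention_
        return AttentionParams(a.W_Q.data, a.W_K.data, a.W_V.data)

    def save(self, path) -> None:
        check_is_fitted(self, "gru_")
        state = {
            "kind": "gru_at",
            "config": self.get_params(),
            "weights": [
                self.gru_.state_list(),
                self.attention_.state_list(),
                self.fc_.state_list(),
                self.head_.state_list(),
            ],
            "loss_history": self.loss_history_,
        }
        nn.save_checkpoint(path, state)

    @classmethod
    def load(cls, path) -> "GRUAttentionForecaster":
        state = nn.load_checkpoint(path)
        if state.get("kind") != "gru_at":
            raise ValueError("incompatible checkpoint")
        model = cls(**state["config"])
        model.n_features_in_ = model.n_features
        model._build()
        for module, st in zip(
            (model.gru_, model.attention_, model.fc_, model.head_), state["weights"]
        ):
            module.load_state_list(st)
        model.loss_history_ = state["loss_history"]
        return model


def rollout_fractions(
    model: GRUAttentionForecaster, env_future: np.ndarray, window: np.ndarray, horizon: int
) -> np.ndarray:
    """Recursive color-fraction rollout fed with (forecast) environment rows.

    ``window`` is the seed (T, 6) history; ``env_future`` supplies the three
    environment channels for each forecast step; predicted fractions are fed
    back as the lagged color channels.  Returns (horizon, 3).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    env_future = np.asarray(env_future, dtype=float)
    if env_future.shape[0] < horizon or env_future.shape[1] != 3:
        raise ValueError("env_future must provide (>= horizon, 3) rows")
    window = np.asarray(window, dtype=float).copy()
    out = np.empty((horizon, 3))
    for step in range(horizon):
        frac = model.predict(window)
        out[step] = frac
        next_row = np.concatenate([env_future[step], frac])
        window = np.vstack([window[1:], next_row])
    return out
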