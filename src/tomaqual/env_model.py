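"""LSTM-based next-step forecasting of greenhouse temperature, humidity and
solar radiation.

Each variable has its own single-output model consuming all three scaled
features; hidden stacks follow the per-variable tuning: temperature 3 LSTM
layers × 100 units, humidity 1 × 160, radiation 2 × 64.  Training uses Adam
(lr 0.001), batch size 32, MSE loss, 150 epochs by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .preprocess import WindowedDataset

__all__ = [
    "LSTMCellParams",
    "LSTMCellState",
    "lstm_cell_step",
    "EnvLSTMForecaster",
    "ARCHITECTURES",
    "rollout",
]

logger = logging.getLogger(__name__)

#: Per-variable hidden-layer stacks (units per LSTM layer).
ARCHITECTURES = {
    "temperature": (100, 100, 100),
    "humidity": (160,),
    "radiation": (64, 64),
}


@dataclass
class LSTMCellParams:
    """Weights of one LSTM cell; each matrix acts on [H_{t−1}, X_t]."""

    W_f: np.ndarray
    W_u: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_u: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[1]


@dataclass
class LSTMCellState:
    C: np.ndarray
    H: np.ndarray


def lstm_cell_step(x: np.ndarray, state: LSTMCellState, params: LSTMCellParams) -> LSTMCellState:
    """One LSTM cell update.

    f = σ(W_f·[H,x]+b_f); u = σ(W_u·[H,x]+b_u); c~ = tanh(W_c·[H,x]+b_c);
    C' = f·C + u·c~; o = σ(W_o·[H,x]+b_o); H' = o·tanh(C').
    """
    z = np.concatenate([state.H, np.asarray(x, dtype=float)])
    if z.shape[0] != params.W_f.shape[0]:
        raise ValueError("input/hidden sizes inconsistent with cell weights")
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    f = sig(z @ params.W_f + params.b_f)
    u = sig(z @ params.W_u + params.b_u)
    c_tilde = np.tanh(z @ params.W_c + params.b_c)
    c_new = f * state.C + u * c_tilde
    o = sig(z @ params.W_o + params.b_o)
    return LSTMCellState(c_new, o * np.tanh(c_new))


class EnvLSTMForecaster(BaseEstimator, RegressorMixin):
    """Next-step forecaster for one environmental variable.

    Parameters
    ----------
    variable : which variable the single scalar output predicts; selects the
        default hidden stack from ``ARCHITECTURES``.
    hidden_layers : optional explicit stack overriding the default.
    Inputs to :meth:`fit` are windows (S, T, X) of min–max scaled features
    and scalar targets (S,); all randomness flows from ``seed``.
    """

    def __init__(
        self,
        variable: str = "temperature",
        hidden_layers: tuple | None = None,
        time_steps: int = 24,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        epochs: int = 150,
        seed: int = 0,
    ):
        self.variable = variable
        self.hidden_layers = hidden_layers
        self.time_steps = time_steps
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _resolve_stack(self) -> tuple:
        if self.hidden_layers is not None:
            stack = tuple(self.hidden_layers)
        else:
            if self.variable not in ARCHITECTURES:
                raise ValueError(f"unknown variable {self.variable!r}")
            stack = ARCHITECTURES[self.variable]
        if len(stack) == 0 or any(h <= 0 for h in stack):
            raise ValueError("hidden stack must contain positive layer sizes")
        return stack

    def _build(self, n_features: int) -> None:
        rng = np.random.default_rng(self.seed)
        stack = self._resolve_stack()
        self.layers_ = []
        n_in = n_features
        for h in stack:
            self.layers_.append(nn.LSTMLayer(n_in, h, rng))
            n_in = h
        self.head_ = nn.Dense(n_in, 1, rng)
        self._shuffle_rng = np.random.default_rng(self.seed + 1)

    def _forward(self, batch: np.ndarray) -> nn.Tensor:
        xs = [nn.Tensor(batch[:, t, :]) for t in range(batch.shape[1])]
        for layer in self.layers_:
            xs = layer.forward_sequence(xs)
        return self.head_(xs[-1])

    def _params(self) -> list:
        params = []
        for layer in self.layers_:
            params.extend(layer.parameters())
        params.extend(self.head_.parameters())
        return params

    def fit(self, X, y=None) -> "EnvLSTMForecaster":
        if isinstance(X, WindowedDataset):
            X, y = X.X, X.y
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        if X.ndim != 3:
            raise ValueError("X must be (samples, time_steps, features)")
        if X.shape[0] != y.shape[0] or X.shape[0] == 0:
            raise ValueError("X and y must be non-empty and aligned")
        if np.abs(X).max() > 2.0:
            warnings.warn("inputs look unscaled (|value| > 2); expected min–max scaled data")
        self.n_features_in_ = X.shape[2]
        self._build(self.n_features_in_)
        optimizer = nn.Adam(self._params(), lr=self.learning_rate)
        self.loss_history_ = []
        n = X.shape[0]
        for epoch in range(self.epochs):
            order = self._shuffle_rng.permutation(n)
            losses = []
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                pred = self._forward(X[idx])
                loss = ((pred - nn.Tensor(y[idx])) ** 2).mean()
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(float(loss.data))
            epoch_loss = float(np.mean(losses))
            if not np.isfinite(epoch_loss):
                raise nn.TrainingDivergedError(epoch)
            self.loss_history_.append(epoch_loss)
            logger.debug("env[%s] epoch %d loss %.6g", self.variable, epoch, epoch_loss)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "head_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.ndim != 3 or X.shape[2] != self.n_features_in_:
            raise ValueError("window must have shape (T, X) or (S, T, X)")
        if np.abs(X).max() > 2.0:
            logger.warning("prediction input looks unscaled (|value| > 2)")
        out = self._forward(X).data[:, 0]
        return out[0] if single else out

    def cell_params(self, layer: int = 0) -> LSTMCellParams:
        """Export one layer's weights for the functional single-step API."""
        check_is_fitted(self, "layers_")
        lay = self.layers_[layer]
        return LSTMCellParams(
            lay.W_f.data, lay.W_u.data, lay.W_c.data, lay.W_o.data,
            lay.b_f.data, lay.b_u.data, lay.b_c.data, lay.b_o.data,
        )

    # -- checkpointing ----------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self, "head_")
        state = {
            "kind": "env_lstm",
            "config": self.get_params(),
            "n_features_in": self.n_features_in_,
            "weights": [lay.state_list() for lay in self.layers_] + [self.head_.state_list()],
            "loss_history": self.loss_history_,
        }
        nn.save_checkpoint(path, state)

    @classmethod
    def load(cls, path) -> "EnvLSTMForecaster":
        state = nn.load_checkpoint(path)
        if state.get("kind") != "env_lstm":
            raise ValueError("incompatible checkpoint")
        model = cls(**state["config"])
        model.n_features_in_ = state["n_features_in"]
        model._build(model.n_features_in_)
        *layer_states, head_state = state["weights"]
        for lay, st in zip(model.layers_, layer_states):
            lay.load_state_list(st)
        model.head_.load_state_list(head_state)
        model.loss_history_ = state["loss_history"]
        return model


def rollout(models: dict, window: np.ndarray, horizon: int) -> np.ndarray:
    """Recursive multi-step forecast of all variables.

    ``models`` maps variable name → fitted forecaster (column order of the
    window follows the dict order).  Each step's one-step predictions are
    appended to the window and fed back.  Returns (horizon, X) scaled values.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    window = np.asarray(window, dtype=float).copy()
    names = list(models)
    if window.shape[1] != len(names):
        raise ValueError("window feature count must match number of models")
    out = np.empty((horizon, len(names)))
    for step in range(horizon):
        nxt = np.array([models[v].predict(window) for v in names])
        out[step] = nxt
        window = np.vstack([window[1:], nxt])
    return out
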