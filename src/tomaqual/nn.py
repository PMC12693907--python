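"""Minimal reverse-mode automatic differentiation and recurrent layers.

Everything the package's recurrent and feed-forward models need is built on
a small dynamic computation graph over float64 numpy arrays: elementwise
arithmetic with broadcasting, matrix products, the sigmoid/tanh/ReLU
activations, softmax, concatenation, slicing and reductions.  Gradients are
accumulated by topological-order backpropagation.  The engine is deliberately
tiny; its correctness is guarded by finite-difference gradient checks in the
test suite rather than by feature breadth.
"""

from __future__ import annotations

import json
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "softmax",
    "sigmoid",
    "tanh",
    "relu",
    "Dense",
    "LSTMLayer",
    "GRULayer",
    "Attention",
    "Adam",
    "uniform_init",
    "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    """Raised when a training loss becomes non-finite; carries the epoch index."""

    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph.

    ``requires_grad`` marks trainable leaves; interior nodes participate in
    backprop whenever any ancestor is trainable.
    """

    __slots__ = ("data", "grad", "requires_grad", "_needs_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._needs_grad = requires_grad
        self._parents: tuple = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph construction helpers --------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        out._parents = tuple(parents)
        out._needs_grad = any(p._needs_grad for p in parents)
        out._backward = backward if out._needs_grad else None
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self._needs_grad:
            self.grad = g if self.grad is None else self.grad + g

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            a._accumulate(_unbroadcast(g, a.data.shape))
            b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._node(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._node(-a.data, (a,), lambda g: a._accumulate(-g))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._node(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

        return Tensor._node(a.data / b.data, (a, b), backward)

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data**exponent

        def backward(g):
            a._accumulate(g * exponent * a.data ** (exponent - 1))

        return Tensor._node(out_data, (a,), backward)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            a._accumulate(g @ b.data.T)
            b._accumulate(a.data.T @ g)

        return Tensor._node(a.data @ b.data, (a, b), backward)

    def __getitem__(self, key):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accumulate(full)

        return Tensor._node(a.data[key], (a,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        a = self
        return Tensor._node(
            a.data.reshape(*shape), (a,), lambda g: a._accumulate(g.reshape(a.data.shape))
        )

    # -- backward pass ----------------------------------------------------
    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs from long sequences exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node._needs_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# -- activations and composites -------------------------------------------


def sigmoid(t: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-t.data))
    return Tensor._node(s, (t,), lambda g: t._accumulate(g * s * (1.0 - s)))


def tanh(t: Tensor) -> Tensor:
    th = np.tanh(t.data)
    return Tensor._node(th, (t,), lambda g: t._accumulate(g * (1.0 - th**2)))


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0
    return Tensor._node(t.data * mask, (t,), lambda g: t._accumulate(g * mask))


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        t._accumulate(s * (g - dot))

    return Tensor._node(s, (t,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


# -- layers ----------------------------------------------------------------


def uniform_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """Uniform in ±1/sqrt(fan_in), the package's seeded default initializer."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    # state (de)serialization: parameter arrays in attribute order
    def state_list(self) -> list:
        return [p.data.tolist() for p in self.parameters()]

    def load_state_list(self, state: list) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match module structure")
        for p, arr in zip(params, state):
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = arr


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(uniform_init(rng, (n_in, n_out), n_in), requires_grad=True)
        self.b = Tensor(uniform_init(rng, (n_out,), n_in), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LSTMLayer(Module):
    """One LSTM layer; each gate acts on the concatenation [H_{t-1}, X_t].

    Gate order and semantics: forget f, update u, candidate cell c~ (tanh),
    output o; C_t = f*C_{t-1} + u*c~; H_t = o * tanh(C_t).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in, self.n_hidden = n_in, n_hidden
        fan = n_in + n_hidden
        for name in ("f", "u", "c", "o"):
            setattr(self, f"W_{name}", Tensor(uniform_init(rng, (fan, n_hidden), fan), requires_grad=True))
            setattr(self, f"b_{name}", Tensor(uniform_init(rng, (n_hidden,), fan), requires_grad=True))

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = concat([h, x], axis=1)
        f = sigmoid(z @ self.W_f + self.b_f)
        u = sigmoid(z @ self.W_u + self.b_u)
        c_tilde = tanh(z @ self.W_c + self.b_c)
        c_new = f * c + u * c_tilde
        o = sigmoid(z @ self.W_o + self.b_o)
        return o * tanh(c_new), c_new

    def forward_sequence(self, xs: Sequence[Tensor]) -> list[Tensor]:
        batch = xs[0].data.shape[0]
        h = Tensor(np.zeros((batch, self.n_hidden)))
        c = Tensor(np.zeros((batch, self.n_hidden)))
        hs = []
        for x in xs:
            h, c = self.step(x, h, c)
            hs.append(h)
        return hs


class GRULayer(Module):
    """One GRU layer with separate input/recurrent matrices per gate.

    r = σ(w_xr x + w_hr h + b_r); z = σ(w_xz x + w_hz h + b_z);
    h~ = tanh(w_xh x + w_hh (r*h) + b_h); h' = z*h + (1-z)*h~.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in, self.n_hidden = n_in, n_hidden
        for name in ("r", "z", "h"):
            setattr(self, f"w_x{name}", Tensor(uniform_init(rng, (n_in, n_hidden), n_in), requires_grad=True))
            setattr(self, f"w_h{name}", Tensor(uniform_init(rng, (n_hidden, n_hidden), n_hidden), requires_grad=True))
            setattr(self, f"b_{name}", Tensor(uniform_init(rng, (n_hidden,), n_in + n_hidden), requires_grad=True))

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        r = sigmoid(x @ self.w_xr + h @ self.w_hr + self.b_r)
        z = sigmoid(x @ self.w_xz + h @ self.w_hz + self.b_z)
        h_tilde = tanh(x @ self.w_xh + (r * h) @ self.w_hh + self.b_h)
        return z * h + (1.0 - z) * h_tilde

    def forward_sequence(self, xs: Sequence[Tensor]) -> list[Tensor]:
        h = Tensor(np.zeros((xs[0].data.shape[0], self.n_hidden)))
        hs = []
        for x in xs:
            h = self.step(x, h)
            hs.append(h)
        return hs


class Attention(Module):
    """Query–key–value attention over a hidden-state sequence.

    The query is the projection of the final hidden state; keys and values
    are projections of every state.  Scores are plain dot products (no
    scaling), normalized by softmax; the context is the α-weighted sum of
    the value vectors.
    """

    def __init__(self, n_hidden: int, n_dim: int, rng: np.random.Generator):
        self.W_Q = Tensor(uniform_init(rng, (n_hidden, n_dim), n_hidden), requires_grad=True)
        self.W_K = Tensor(uniform_init(rng, (n_hidden, n_dim), n_hidden), requires_grad=True)
        self.W_V = Tensor(uniform_init(rng, (n_hidden, n_dim), n_hidden), requires_grad=True)

    def __call__(self, hs: Sequence[Tensor]) -> tuple[Tensor, Tensor]:
        q = hs[-1] @ self.W_Q  # (B, d)
        scores = []
        values = []
        for h in hs:
            k = h @ self.W_K
            values.append(h @ self.W_V)
            scores.append((k * q).sum(axis=1, keepdims=True))  # (B, 1)
        alpha = softmax(concat(scores, axis=1), axis=1)  # (B, T)
        context = None
        for t, v in enumerate(values):
            term = alpha[:, t : t + 1] * v
            context = term if context is None else context + term
        return context, alpha


class Adam:
    """Adam optimizer (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def save_checkpoint(path, state: dict) -> None:
    """Write a JSON checkpoint (config + weight lists)."""
    with open(path, "w") as fh:
        json.dump(state, fh)


def load_checkpoint(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
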