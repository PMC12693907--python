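"""Independent scalar brute-force oracles used by the test suite.

Everything here is written with explicit Python loops and ``math``
functions, deliberately sharing no code with the package's vectorized
implementations.
"""

import math


def sigmoid(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-v))


def lstm_step_scalar(x, h_prev, c_prev, W_f, W_u, W_c, W_o, b_f, b_u, b_c, b_o):
    """Element-by-element LSTM update on Python lists."""
    z = list(h_prev) + list(x)
    n_hidden = len(h_prev)

    def affine(W, b, j):
        return sum(z[i] * W[i][j] for i in range(len(z))) + b[j]

    h_new, c_new = [], []
    for j in range(n_hidden):
        f = sigmoid(affine(W_f, b_f, j))
        u = sigmoid(affine(W_u, b_u, j))
        c_t = math.tanh(affine(W_c, b_c, j))
        c = f * c_prev[j] + u * c_t
        o = sigmoid(affine(W_o, b_o, j))
        c_new.append(c)
        h_new.append(o * math.tanh(c))
    return h_new, c_new


def gru_step_scalar(x, h_prev, w_xr, w_hr, w_xz, w_hz, w_xh, w_hh, b_r, b_z, b_h):
    n_hidden = len(h_prev)

    def dot(vec, W, j):
        return sum(vec[i] * W[i][j] for i in range(len(vec)))

    h_new = []
    r = [sigmoid(dot(x, w_xr, j) + dot(h_prev, w_hr, j) + b_r[j]) for j in range(n_hidden)]
    z = [sigmoid(dot(x, w_xz, j) + dot(h_prev, w_hz, j) + b_z[j]) for j in range(n_hidden)]
    rh = [r[j] * h_prev[j] for j in range(n_hidden)]
    for j in range(n_hidden):
        h_t = math.tanh(dot(x, w_xh, j) + dot(rh, w_hh, j) + b_h[j])
        h_new.append(z[j] * h_prev[j] + (1.0 - z[j]) * h_t)
    return h_new


def attention_scalar(H, W_Q, W_K, W_V):
    """Explicit-summation attention: query from the last state."""
    T = len(H)
    d = len(W_Q[0])

    def project(vec, W):
        return [sum(vec[i] * W[i][j] for i in range(len(vec))) for j in range(d)]

    q = project(H[-1], W_Q)
    keys = [project(h, W_K) for h in H]
    values = [project(h, W_V) for h in H]
    scores = [sum(keys[t][j] * q[j] for j in range(d)) for t in range(T)]
    m = max(scores)
    exps = [math.exp(s - m) for s in scores]
    total = sum(exps)
    alpha = [e / total for e in exps]
    context = [sum(alpha[t] * values[t][j] for t in range(T)) for j in range(d)]
    return alpha, context


def dnn_forward_scalar(x, weights, biases):
    """Loop-and-sum feed-forward pass: ReLU on all but the final layer."""
    h = list(x)
    for layer, (W, b) in enumerate(zip(weights, biases)):
        out = []
        for j in range(len(b)):
            v = sum(h[i] * W[i][j] for i in range(len(h))) + b[j]
            if layer < len(weights) - 1:
                v = max(v, 0.0)
            out.append(v)
        h = out
    return h


def quantile_scalar(values, p: float) -> float:
    """Sorted-order linear-interpolation quantile."""
    v = sorted(values)
    h = (len(v) - 1) * p
    lo = math.floor(h)
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def point_in_polygon(x: float, y: float, vertices) -> bool:
    """Ray casting with an explicit on-boundary check (boundary counts inside)."""
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # boundary: collinear and within the segment's bounding box
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside
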