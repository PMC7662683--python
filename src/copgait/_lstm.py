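"""Compact NumPy LSTM for short-window sequence regression.

A single LSTM layer followed by a linear readout of the last hidden state.
Gate order in the stacked parameter matrices is (input, forget, candidate,
output).  Weights are Glorot-uniform initialized with the forget-gate bias
set to 1.0; optimization is Adam on the mean-squared error.  Everything is
float64 and driven by one Generator, so training is bit-reproducible for a
fixed seed.

Windows are processed statelessly: the hidden and cell states are reset for
every window, making predictions independent of sample order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LstmParams", "init_params", "forward", "backward", "AdamState", "adam_step"]


class LstmParams(dict):
    """Parameter container: Wx (d, 4H), Wh (H, 4H), b (4H,), Wo (H, 2), bo (2,)."""

    def copy(self) -> "LstmParams":
        return LstmParams({k: v.copy() for k, v in self.items()})


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_params(d: int, hidden: int, rng: np.random.Generator, n_out: int = 2) -> LstmParams:
    p = LstmParams()
    p["Wx"] = _glorot(rng, (d, 4 * hidden))
    p["Wh"] = _glorot(rng, (hidden, 4 * hidden))
    p["b"] = np.zeros(4 * hidden)
    p["b"][hidden : 2 * hidden] = 1.0  # forget-gate bias
    p["Wo"] = _glorot(rng, (hidden, n_out))
    p["bo"] = np.zeros(n_out)
    return p


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def forward(params: LstmParams, X: np.ndarray, cache: bool = False):
    """Run the network on windows X of shape (B, T, d).

    Returns predictions (B, n_out), plus a cache for :func:`backward` when
    requested.
    """
    B, T, d = X.shape
    H = params["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    steps = []
    for t in range(T):
        z = X[:, t, :] @ params["Wx"] + h @ params["Wh"] + params["b"]
        i = _sigmoid(z[:, 0:H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        if cache:
            steps.append((h, c, i, f, g, o, tc))
        h, c = h_new, c_new
    y = h @ params["Wo"] + params["bo"]
    if cache:
        return y, (X, steps, h)
    return y


def backward(params: LstmParams, cache, dY: np.ndarray) -> dict[str, np.ndarray]:
    """Backprop-through-time; dY is ∂loss/∂predictions, shape (B, n_out)."""
    X, steps, h_last = cache
    B, T, d = X.shape
    H = params["Wh"].shape[0]

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["Wo"] = h_last.T @ dY
    grads["bo"] = dY.sum(axis=0)

    dh = dY @ params["Wo"].T
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        h_prev, c_prev, i, f, g, o, tc = steps[t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        grads["Wx"] += X[:, t, :].T @ dz
        grads["Wh"] += h_prev.T @ dz
        grads["b"] += dz.sum(axis=0)
        dh = dz @ params["Wh"].T
        dc = dc * f
    return grads


class AdamState:
    def __init__(self, params: LstmParams, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}


def adam_step(params: LstmParams, grads: dict[str, np.ndarray], state: AdamState) -> None:
    state.t += 1
    b1, b2 = state.beta1, state.beta2
    for k in params:
        state.m[k] = b1 * state.m[k] + (1 - b1) * grads[k]
        state.v[k] = b2 * state.v[k] + (1 - b2) * grads[k] ** 2
        mhat = state.m[k] / (1 - b1**state.t)
        vhat = state.v[k] / (1 - b2**state.t)
        params[k] -= state.lr * mhat / (np.sqrt(vhat) + state.eps)
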