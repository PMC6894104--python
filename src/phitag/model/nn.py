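"""Minimal neural-network primitives with explicit backward passes.

Everything the tagger needs -- embedding tables, uni-directional LSTM
layers (composed into BiLSTMs by the caller), a linear projection,
inverted dropout and SGD with momentum -- implemented directly on numpy
arrays with hand-derived gradients.  Shapes follow the (T, B, D)
time-major convention; the word-level LSTM runs with B=1 and the
character-level LSTM batches all tokens of a sentence with a mask for
their different lengths.
"""

from __future__ import annotations

import numpy as np

Params = dict[str, np.ndarray]


def uniform_init(rng: np.random.Generator, shape: tuple[int, ...],
                 fan_in: int) -> np.ndarray:
    """Uniform initialization scaled by fan-in."""
    bound = float(np.sqrt(3.0 / max(fan_in, 1)))
    return rng.uniform(-bound, bound, size=shape)


def lstm_init(rng: np.random.Generator, d_in: int, hidden: int,
              prefix: str) -> Params:
    """LSTM parameters; gate order i, f, g, o; forget bias starts at 1."""
    b = np.zeros(4 * hidden)
    b[hidden:2 * hidden] = 1.0
    return {
        f"{prefix}.Wx": uniform_init(rng, (d_in, 4 * hidden), d_in),
        f"{prefix}.Wh": uniform_init(rng, (hidden, 4 * hidden), hidden),
        f"{prefix}.b": b,
    }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def lstm_forward(X: np.ndarray, params: Params, prefix: str,
                 mask: np.ndarray | None = None):
    """Run an LSTM over ``X`` of shape (T, B, D).

    ``mask`` (T, B) freezes the state where 0, so padded positions carry
    the last real hidden state forward.  Returns the hidden sequence
    (T, B, H) and a cache for :func:`lstm_backward`.
    """
    Wx, Wh, b = (params[f"{prefix}.Wx"], params[f"{prefix}.Wh"],
                 params[f"{prefix}.b"])
    T, B, _ = X.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.empty((T, B, H))
    cache = {"i": np.empty((T, B, H)), "f": np.empty((T, B, H)),
             "g": np.empty((T, B, H)), "o": np.empty((T, B, H)),
             "tc": np.empty((T, B, H)), "c_prev": np.empty((T, B, H)),
             "h_prev": np.empty((T, B, H))}
    for t in range(T):
        z = X[t] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache["i"][t], cache["f"][t], cache["g"][t] = i, f, g
        cache["o"][t], cache["tc"][t] = o, tc
        cache["c_prev"][t], cache["h_prev"][t] = c, h
        if mask is None:
            h, c = h_new, c_new
        else:
            m = mask[t][:, None]
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
        Hs[t] = h
    cache["X"], cache["mask"], cache["prefix"] = X, mask, prefix
    cache["Wx"], cache["Wh"] = Wx, Wh
    return Hs, cache


def lstm_backward(dHs: np.ndarray, cache,
                  grads: Params) -> np.ndarray:
    """Backprop through :func:`lstm_forward`; accumulates into *grads*.

    ``dHs`` is the gradient wrt the returned hidden sequence.  Returns
    the gradient wrt the input ``X``.
    """
    X, mask, prefix = cache["X"], cache["mask"], cache["prefix"]
    Wx, Wh = cache["Wx"], cache["Wh"]
    T, B, D = X.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dh = dHs[t] + dh_next
        dc = dc_next
        if mask is not None:
            m = mask[t][:, None]
            # gradient flowing around frozen steps goes straight to t-1
            dh_skip = (1 - m) * dh
            dc_skip = (1 - m) * dc
            dh = m * dh
            dc = m * dc
        else:
            dh_skip = dc_skip = 0.0
        i, f, g, o = (cache["i"][t], cache["f"][t], cache["g"][t],
                      cache["o"][t])
        tc = cache["tc"][t]
        c_prev, h_prev = cache["c_prev"][t], cache["h_prev"][t]
        do = dh * tc
        dc = dc + dh * o * (1 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                             dg * (1 - g * g), do * o * (1 - o)], axis=1)
        dX[t] = dz @ Wx.T
        dWx += X[t].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh_next = dz @ Wh.T + dh_skip
        dc_next = dc * f + dc_skip
    grads[f"{prefix}.Wx"] = grads.get(f"{prefix}.Wx", 0) + dWx
    grads[f"{prefix}.Wh"] = grads.get(f"{prefix}.Wh", 0) + dWh
    grads[f"{prefix}.b"] = grads.get(f"{prefix}.b", 0) + db
    return dX


def dropout_mask(rng: np.random.Generator, shape: tuple[int, ...],
                 p: float) -> np.ndarray:
    """Inverted-dropout mask: multiply by it at train time only."""
    if p <= 0:
        return np.ones(shape)
    return (rng.random(shape) >= p).astype(np.float64) / (1.0 - p)


class SGDMomentum:
    """Classical momentum SGD over a dict of parameter arrays.

    Gradients are of the *loss* (descends); values are clipped
    elementwise to ``[-clip, clip]`` before the update, applied once per
    sentence (pure SGD, batch size 1).
    """

    def __init__(self, params: Params, lr: float, momentum: float,
                 clip: float) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.clip = clip
        self.velocity: Params = {k: np.zeros_like(v)
                                 for k, v in params.items()}

    def step(self, grads: Params) -> None:
        for k, g in grads.items():
            g = np.clip(g, -self.clip, self.clip)
            v = self.velocity[k]
            v *= self.momentum
            v += g
            self.params[k] -= self.lr * v
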