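"""Recurrent building blocks on top of the autodiff engine.

All layers hold their parameters as ``Tensor`` objects with
``requires_grad=True`` and expose ``parameters()`` for the optimizer.
Masked timesteps are handled by state carry-through: at a step flagged
missing, hidden and cell states are copied from the previous step, so the
layer's output is exactly invariant to whatever values the masked input
rows contain (they are additionally zeroed upstream).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def lstm_cell(x: Tensor, h: Tensor, c: Tensor, Wx: Tensor, Wh: Tensor,
              b: Tensor) -> tuple[Tensor, Tensor]:
    """One fused LSTM step with a hand-written backward pass.

    Gate order (input, forget, cell, output). Fusing the ~20 elementwise
    primitives of a step into two tape nodes keeps the graph small enough
    for pure-numpy training; the gradient is covered by the same
    finite-difference checks as the composed ops.
    """
    H = h.data.shape[1]
    z = x.data @ Wx.data + h.data @ Wh.data + b.data
    gi = _sigmoid(z[:, :H])
    gf = _sigmoid(z[:, H:2 * H])
    gg = np.tanh(z[:, 2 * H:3 * H])
    go = _sigmoid(z[:, 3 * H:])
    c_new_d = gf * c.data + gi * gg
    tc = np.tanh(c_new_d)
    h_new_d = go * tc

    c_new = Tensor(c_new_d, _parents=(x, h, c, Wx, Wh, b))
    h_new = Tensor(h_new_d, _parents=(x, h, c_new, Wx, Wh, b))

    def _through_z(dz: np.ndarray):
        x._accum(dz @ Wx.data.T)
        h._accum(dz @ Wh.data.T)
        Wx._accum(x.data.T @ dz)
        Wh._accum(h.data.T @ dz)
        b._accum(dz.sum(axis=0))

    def bw_c(gc: np.ndarray):
        c._accum(gc * gf)
        dz = np.empty_like(z)
        dz[:, :H] = gc * gg * gi * (1.0 - gi)
        dz[:, H:2 * H] = gc * c.data * gf * (1.0 - gf)
        dz[:, 2 * H:3 * H] = gc * gi * (1.0 - gg * gg)
        dz[:, 3 * H:] = 0.0
        _through_z(dz)

    def bw_h(gh: np.ndarray):
        c_new._accum(gh * go * (1.0 - tc * tc))
        dz = np.zeros_like(z)
        dz[:, 3 * H:] = gh * tc * go * (1.0 - go)
        _through_z(dz)

    c_new._bw = bw_c
    h_new._bw = bw_h
    return h_new, c_new


class LSTMDirection:
    """A single-direction LSTM scanned over a (possibly masked) sequence.

    Gate layout in the fused weight matrices is (input, forget, cell, output).
    The forget-gate bias is initialized to 1, the usual remedy for early
    gradient vanishing in gated recurrences.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 reverse: bool = False):
        self.n_hidden = n_hidden
        self.reverse = reverse
        self.Wx = Tensor(glorot(rng, n_in, 4 * n_hidden), requires_grad=True)
        self.Wh = Tensor(glorot(rng, n_hidden, 4 * n_hidden), requires_grad=True)
        b = np.zeros(4 * n_hidden)
        b[n_hidden:2 * n_hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def parameters(self):
        return [self.Wx, self.Wh, self.b]

    def __call__(self, xs: list[Tensor], keep: np.ndarray) -> list[Tensor]:
        """Scan over timesteps.

        xs: list of (B, n_in) tensors, oldest first.
        keep: (T, B, 1) float array, 1 where the timestep is observed,
              0 where masked (state carries through unchanged).
        Returns hidden states per timestep in the original (oldest-first)
        order regardless of scan direction.
        """
        T = len(xs)
        B = xs[0].shape[0]
        H = self.n_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        order = range(T - 1, -1, -1) if self.reverse else range(T)
        out: list[Tensor | None] = [None] * T
        for t in order:
            h_new, c_new = lstm_cell(xs[t], h, c, self.Wx, self.Wh, self.b)
            k = keep[t]
            if k.all():
                h, c = h_new, c_new
            else:  # state carries through masked timesteps unchanged
                c = c_new * k + c * (1.0 - k)
                h = h_new * k + h * (1.0 - k)
            out[t] = h
        return out  # type: ignore[return-value]


class BiLSTMLayer:
    """Forward (+ optional backward) LSTM with per-timestep concatenation."""

    def __init__(self, n_in: int, n_hidden_per_dir: int, rng: np.random.Generator,
                 bidirectional: bool = True):
        self.fwd = LSTMDirection(n_in, n_hidden_per_dir, rng)
        self.bwd = (LSTMDirection(n_in, n_hidden_per_dir, rng, reverse=True)
                    if bidirectional else None)
        self.n_out = n_hidden_per_dir * (2 if bidirectional else 1)

    def parameters(self):
        ps = self.fwd.parameters()
        if self.bwd is not None:
            ps += self.bwd.parameters()
        return ps

    def __call__(self, xs: list[Tensor], keep: np.ndarray) -> list[Tensor]:
        hf = self.fwd(xs, keep)
        if self.bwd is None:
            return hf
        hb = self.bwd(xs, keep)
        return [concat([a, b], axis=1) for a, b in zip(hf, hb)]


class LayerNorm:
    """Normalization over the feature dimension, per sample and timestep."""

    def __init__(self, n: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(n), requires_grad=True)
        self.bias = Tensor(np.zeros(n), requires_grad=True)
        self.eps = eps

    def parameters(self):
        return [self.gain, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gain + self.bias


class Dropout:
    """Inverted dropout; identity when not training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator | None) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * keep


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = Tensor(glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y
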