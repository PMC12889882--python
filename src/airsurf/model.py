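"""Masked bidirectional recurrent regressor with Luong multiplicative attention.

The network stacks three bidirectional LSTM layers, each followed by layer
normalization (over the feature dimension, per timestep) and dropout. The
attention block scores every normalized hidden state h_s against the
last-timestep query h_t through a trainable bilinear form,

    score(h_t, h_s) = h_t' W h_s,

normalizes the scores with a masked softmax into weights a_{t,s}, forms the
context c_t = sum_s a_{t,s} h_s, combines it with the query as
h~_t = tanh(W_c [c_t ; h_t]), and maps h~_t through a linear head to one
PM2.5 estimate (in scaled target space) per sequence.

Missing timesteps are handled so that the output is *exactly* invariant to
whatever values a masked row stores: masked inputs are zeroed before the
first layer, recurrent states carry through masked steps unchanged, and
masked steps receive attention weight zero.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .nn import BiLSTMLayer, Dense, Dropout, LayerNorm, Tensor, concat

__all__ = [
    "AttentionTrace", "PM25SequenceModel",
    "attention_scores", "attention_weights", "context_vector", "attended_output",
]


# ---------------------------------------------------------------------------
# Standalone attention operators (numpy; mirrored inside the model's graph)
# ---------------------------------------------------------------------------

def attention_scores(h_hat_t: np.ndarray, h_hat_all: np.ndarray,
                     W: np.ndarray) -> np.ndarray:
    """Bilinear scores h_t' W h_s for every stored state.

    h_hat_t: (d,) query state; h_hat_all: (T, d); W: (d, d).
    """
    h_hat_t = np.asarray(h_hat_t, dtype=float)
    h_hat_all = np.asarray(h_hat_all, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.shape != (h_hat_t.shape[-1], h_hat_all.shape[-1]):
        raise ValueError(
            f"W shape {W.shape} inconsistent with states of dim "
            f"{h_hat_t.shape[-1]} x {h_hat_all.shape[-1]}")
    return h_hat_all @ (W.T @ h_hat_t)


def attention_weights(scores: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Masked softmax: weights over unmasked steps sum to 1, masked get 0.

    ``mask`` is True where a timestep is missing. Stabilized by
    max-subtraction, which leaves the softmax unchanged.
    """
    scores = np.asarray(scores, dtype=float)
    if mask is None:
        mask = np.zeros(scores.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise ValueError("attention needs at least one unmasked timestep")
    e = np.exp(scores - scores.max())
    e = np.where(mask, 0.0, e)
    return e / e.sum()


def context_vector(alpha: np.ndarray, h_hat_all: np.ndarray) -> np.ndarray:
    """Weighted average of the stored states: c_t = sum_s a_{t,s} h_s."""
    return np.asarray(alpha, dtype=float) @ np.asarray(h_hat_all, dtype=float)


def attended_output(c_t: np.ndarray, h_hat_t: np.ndarray,
                    W_c: np.ndarray) -> np.ndarray:
    """Combine context and query: h~_t = tanh(W_c [c_t ; h_t])."""
    z = np.concatenate([np.asarray(c_t, dtype=float), np.asarray(h_hat_t, dtype=float)])
    return np.tanh(np.asarray(W_c, dtype=float) @ z)


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

@dataclass
class AttentionTrace:
    """Per-sample introspection of the attention block."""

    h_hat: np.ndarray     # (T, d) normalized hidden states
    scores: np.ndarray    # (T,)
    alpha: np.ndarray     # (T,), sums to 1, zero on masked steps
    context: np.ndarray   # (d,)
    attended: np.ndarray  # (d,) h~_t


class PM25SequenceModel:
    """Three stacked (bi)directional LSTM layers + attention + linear head."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0xD0]).generate_state(1)[0])
        self.layers: list[BiLSTMLayer] = []
        self.norms: list[LayerNorm] = []
        self.dropout = Dropout(config.dropout_rate)
        n_in = config.n_features
        for width in config.layer_widths:
            per_dir = (width // 2 if (config.bidirectional and
                                      config.width_interpretation == "total")
                       else width)
            layer = BiLSTMLayer(n_in, per_dir, rng, bidirectional=config.bidirectional)
            self.layers.append(layer)
            self.norms.append(LayerNorm(layer.n_out))
            n_in = layer.n_out
        d = n_in
        self.W_att = Tensor(np.random.default_rng(rng.integers(2**31)).normal(
            0.0, 1.0 / np.sqrt(d), size=(d, d)), requires_grad=True)
        self.combine = Dense(2 * d, d, rng, bias=False)  # W_c of the tanh combine
        self.head = Dense(d, 1, rng)
        self.hidden_dim = d

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for layer, norm in zip(self.layers, self.norms):
            ps += layer.parameters() + norm.parameters()
        ps += [self.W_att] + self.combine.parameters() + self.head.parameters()
        return ps

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]):
        for p, w in zip(self.parameters(), weights, strict=True):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = w.astype(np.float64).copy()

    # -- forward -----------------------------------------------------------

    def forward(self, X: np.ndarray, mask: np.ndarray | None = None,
                training: bool = False) -> tuple[Tensor, Tensor]:
        """Run a batch through the network.

        X: (B, T, F) scaled features; mask: (B, T) True where the timestep
        is missing. Returns (predictions (B,) Tensor in scaled target
        space, alpha (B, T) Tensor).
        """
        X = np.asarray(X, dtype=float)
        B, T, F = X.shape
        cfg = self.config
        if T != cfg.window or F != cfg.n_features:
            raise ValueError(f"expected (B, {cfg.window}, {cfg.n_features}), got {X.shape}")
        if mask is None:
            mask = np.zeros((B, T), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.all(axis=1).any():
            raise ValueError("every sample needs at least one unmasked timestep")

        # kill any sentinel values so masked rows cannot leak
        X = np.where(mask[:, :, None], 0.0, X)
        keep = (~mask).astype(float).T[:, :, None]       # (T, B, 1)
        xs = [Tensor(X[:, t, :]) for t in range(T)]
        rng = self._dropout_rng if training else None
        for layer, norm in zip(self.layers, self.norms):
            hs = layer(xs, keep)
            # normalize/dropout all timesteps in one graph node (row-wise ops)
            stacked = concat(hs, axis=0)                 # (T*B, d)
            stacked = norm(stacked)
            if training:
                stacked = self.dropout(stacked, True, rng)
            xs = [stacked[t * B:(t + 1) * B] for t in range(T)]

        q = xs[-1]                                       # (B, d) query = last step
        qW = q @ self.W_att                              # (B, d)
        cols = [(qW * h).sum(axis=1, keepdims=True) for h in xs]
        scores = concat(cols, axis=1)                    # (B, T)
        # max-subtraction (constant w.r.t. grad) for numerical stability
        shift = scores.data.max(axis=1, keepdims=True)
        e = (scores - shift).exp() * (~mask).astype(float)
        alpha = e / e.sum(axis=1, keepdims=True)         # (B, T)
        ctx_terms = [alpha[:, s:s + 1] * xs[s] for s in range(T)]
        ctx = ctx_terms[0]
        for term in ctx_terms[1:]:
            ctx = ctx + term
        attended = self.combine(concat([ctx, q], axis=1)).tanh()
        pred = self.head(attended).reshape(-1)
        return pred, alpha

    def predict(self, X: np.ndarray, mask: np.ndarray | None = None,
                batch_size: int = 1024) -> np.ndarray:
        """Deterministic inference (dropout off), scaled target space."""
        outs = []
        for i in range(0, len(X), batch_size):
            m = None if mask is None else mask[i:i + batch_size]
            pred, _ = self.forward(X[i:i + batch_size], m, training=False)
            outs.append(pred.data)
        return np.concatenate(outs) if outs else np.empty(0)

    def forward_one(self, x: np.ndarray, mask: np.ndarray | None = None
                    ) -> tuple[float, AttentionTrace]:
        """Single-sample inference with an introspectable attention trace."""
        x = np.asarray(x, dtype=float)
        m = None if mask is None else np.asarray(mask, dtype=bool)[None, :]
        X = np.where((m[0] if m is not None else np.zeros(x.shape[0], bool))[:, None],
                     0.0, x)[None, ...]
        keep = (np.ones((x.shape[0], 1, 1)) if m is None
                else (~m).astype(float).T[:, :, None])
        xs = [Tensor(X[:, t, :]) for t in range(x.shape[0])]
        for layer, norm in zip(self.layers, self.norms):
            xs = [norm(h) for h in layer(xs, keep)]
        h_hat = np.stack([h.data[0] for h in xs])        # (T, d)
        scores = attention_scores(h_hat[-1], h_hat, self.W_att.data)
        alpha = attention_weights(scores, None if m is None else m[0])
        ctx = context_vector(alpha, h_hat)
        attended = attended_output(ctx, h_hat[-1], self.combine.W.data.T)
        y = float(attended @ self.head.W.data[:, 0] + self.head.b.data[0])
        return y, AttentionTrace(h_hat, scores, alpha, ctx, attended)

    # -- checkpointing -----------------------------------------------------

    def schema_hash(self, feature_names: list[str]) -> str:
        blob = json.dumps({"features": feature_names,
                           "widths": list(self.config.layer_widths),
                           "window": self.config.window,
                           "bidirectional": self.config.bidirectional})
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
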