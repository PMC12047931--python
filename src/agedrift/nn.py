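"""A small transformer encoder in NumPy with explicit backpropagation.

Implements the classic post-layer-norm encoder (embedding sum, multi-head
self-attention, position-wise feed-forward, residual connections) together
with a softmax cross-entropy head over masked positions and an Adam
optimizer.  Written as plain ndarray code so training is fully deterministic
given a seed; gradients are verified against central finite differences in
the test suite.

Large intermediate tensors (attention scores, FFN activations) are kept in
per-shape scratch buffers reused across batches — repeated mmap/munmap of
tens-of-megabyte temporaries otherwise dominates the runtime of a training
epoch.  Shapes follow the convention (batch, sequence, dim).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TransformerParams", "Transformer", "Adam", "softmax", "cross_entropy_grads"]

DTYPE = np.float32
LN_EPS = 1e-5


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def _softmax_inplace(x: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis, computed in place."""
    x -= np.max(x, axis=-1, keepdims=True)
    np.exp(x, out=x)
    x /= np.sum(x, axis=-1, keepdims=True)
    return x


def _linear_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return (rng.normal(0.0, scale, size=(fan_in, fan_out))).astype(DTYPE)


@dataclass
class TransformerParams:
    """Flat name -> ndarray parameter store."""

    data: dict[str, np.ndarray]

    def copy(self) -> "TransformerParams":
        return TransformerParams({k: v.copy() for k, v in self.data.items()})

    def allclose(self, other: "TransformerParams", **kw) -> bool:
        return all(np.allclose(self.data[k], other.data[k], **kw) for k in self.data)


class Transformer:
    """Post-LN transformer encoder with an untied output projection.

    The contextual embedding of a position is the final encoder hidden state
    at that position; the output head maps hidden states to logits over the
    token vocabulary and is used only for masked-token prediction, so static
    token embeddings and predictive distributions stay independent
    measurements.
    """

    def __init__(self, k: int, seq_len: int, d: int, n_layers: int, n_heads: int,
                 d_ff: int, dropout: float = 0.0, seed: int = 0):
        if d % n_heads != 0:
            raise ValueError(f"embedding dim d={d} must be divisible by n_heads={n_heads}")
        if min(k, seq_len, d, n_layers, n_heads, d_ff) < 1:
            raise ValueError("all model dimensions must be positive")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.k, self.seq_len, self.d = k, seq_len, d
        self.n_layers, self.n_heads, self.d_ff = n_layers, n_heads, d_ff
        self.d_head = d // n_heads
        self.dropout = dropout
        self._buffers: dict[tuple, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {
            "tok_emb": (rng.normal(0, 0.02, size=(k, d))).astype(DTYPE),
            "pos_emb": (rng.normal(0, 0.02, size=(seq_len, d))).astype(DTYPE),
            # small head init: an untrained model emits near-uniform predictions
            "head.W": (rng.normal(0, 0.02, size=(d, k))).astype(DTYPE),
            "head.b": np.zeros(k, dtype=DTYPE),
        }
        for i in range(n_layers):
            for name in ("q", "kk", "v", "o"):
                p[f"l{i}.{name}.W"] = _linear_init(rng, d, d)
                p[f"l{i}.{name}.b"] = np.zeros(d, dtype=DTYPE)
            p[f"l{i}.ff1.W"] = _linear_init(rng, d, d_ff)
            p[f"l{i}.ff1.b"] = np.zeros(d_ff, dtype=DTYPE)
            p[f"l{i}.ff2.W"] = _linear_init(rng, d_ff, d)
            p[f"l{i}.ff2.b"] = np.zeros(d, dtype=DTYPE)
            for ln in ("ln1", "ln2"):
                p[f"l{i}.{ln}.g"] = np.ones(d, dtype=DTYPE)
                p[f"l{i}.{ln}.b"] = np.zeros(d, dtype=DTYPE)
        self.params = TransformerParams(p)

    def free_buffers(self) -> None:
        """Release scratch buffers (they are re-created on demand).

        Call between analyses or before keeping many models alive: the
        buffers are sized per (tensor, batch size) and dominate resident
        memory for an idle model.
        """
        self._buffers.clear()

    def _buf(self, key: tuple, shape: tuple) -> np.ndarray:
        buf = self._buffers.get(key)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=DTYPE)
            self._buffers[key] = buf
        return buf

    # ------------------------------------------------------------------ fwd
    def _layer_norm_fwd(self, x, g, b):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + LN_EPS)
        xhat = xc * inv
        return g * xhat + b, (xhat, inv, g)

    @staticmethod
    def _layer_norm_bwd(dy, cache):
        xhat, inv, g = cache
        dg = (dy * xhat).sum(axis=(0, 1))
        db = dy.sum(axis=(0, 1))
        dxhat = dy * g
        m = dxhat.mean(axis=-1, keepdims=True)
        mx = (dxhat * xhat).mean(axis=-1, keepdims=True)
        dx = inv * (dxhat - m - xhat * mx)
        return dx, dg, db

    def _attn_fwd(self, x, i, p):
        B, S, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(y):  # (B,S,d) -> (B,h,S,dh)
            return np.ascontiguousarray(y.reshape(B, S, h, dh).transpose(0, 2, 1, 3))

        q = split(x @ p[f"l{i}.q.W"] + p[f"l{i}.q.b"])
        kk = split(x @ p[f"l{i}.kk.W"] + p[f"l{i}.kk.b"])
        v = split(x @ p[f"l{i}.v.W"] + p[f"l{i}.v.b"])
        A = self._buf(("A", i, B), (B, h, S, S))
        np.matmul(q, kk.transpose(0, 1, 3, 2), out=A)
        A *= DTYPE(1.0 / np.sqrt(dh))
        _softmax_inplace(A)
        ctx = (A @ v).transpose(0, 2, 1, 3).reshape(B, S, d)
        out = ctx @ p[f"l{i}.o.W"] + p[f"l{i}.o.b"]
        return out, (x, q, kk, v, A, ctx)

    def _attn_bwd(self, dout, i, p, cache, grads):
        x, q, kk, v, A, ctx = cache
        B, S, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(y):
            return y.reshape(B, S, h, dh).transpose(0, 2, 1, 3)

        def merge(y):  # (B,h,S,dh) -> (B,S,d)
            return y.transpose(0, 2, 1, 3).reshape(B, S, d)

        grads[f"l{i}.o.W"] += ctx.reshape(-1, d).T @ dout.reshape(-1, d)
        grads[f"l{i}.o.b"] += dout.sum(axis=(0, 1))
        dctx = split(dout @ p[f"l{i}.o.W"].T)
        dA = self._buf(("dA", i, B), (B, h, S, S))
        np.matmul(np.ascontiguousarray(dctx), v.transpose(0, 1, 3, 2), out=dA)
        dv = A.transpose(0, 1, 3, 2) @ np.ascontiguousarray(dctx)
        # softmax backward over the last axis, in place:
        # dS = A * (dA - sum(dA * A)); afterwards A (a scratch buffer) is junk
        tmp = self._buf(("tmp", i, B), (B, h, S, S))
        np.multiply(dA, A, out=tmp)
        rowsum = tmp.sum(axis=-1, keepdims=True)
        dA -= rowsum
        dA *= A
        dA *= DTYPE(1.0 / np.sqrt(dh))
        dq = dA @ kk
        dkk = dA.transpose(0, 1, 3, 2) @ q
        dx = np.zeros_like(x)
        for name, dproj in (("q", dq), ("kk", dkk), ("v", dv)):
            dflat = merge(np.ascontiguousarray(dproj))
            grads[f"l{i}.{name}.W"] += x.reshape(-1, d).T @ dflat.reshape(-1, d)
            grads[f"l{i}.{name}.b"] += dflat.sum(axis=(0, 1))
            dx += dflat @ p[f"l{i}.{name}.W"].T
        return dx

    def forward(self, tokens: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                n_layers_applied: int | None = None):
        """Encode token ids (B, S) into hidden states (B, S, d); returns (h, cache).

        ``n_layers_applied`` truncates the encoder stack (0 = the summed
        token+position embedding); eval-only — backward requires the full
        stack.  ``None`` applies every layer.
        """
        tokens = np.asarray(tokens)
        if tokens.ndim != 2 or tokens.shape[1] != self.seq_len:
            raise ValueError(f"expected token batch of shape (n, {self.seq_len})")
        if tokens.min() < 0 or tokens.max() >= self.k:
            raise ValueError("token id out of vocabulary range")
        n_apply = self.n_layers if n_layers_applied is None else n_layers_applied
        if not 0 <= n_apply <= self.n_layers:
            raise ValueError(f"n_layers_applied must be in [0, {self.n_layers}]")
        p = self.params.data
        x = (p["tok_emb"][tokens] + p["pos_emb"][None, :, :]).astype(DTYPE)
        use_drop = train and self.dropout > 0.0
        caches = []
        for i in range(n_apply):
            a, attn_cache = self._attn_fwd(x, i, p)
            drop1 = None
            if use_drop:
                drop1 = ((rng.random(a.shape) >= self.dropout) / (1 - self.dropout)).astype(DTYPE)
                a = a * drop1
            h1, ln1_cache = self._layer_norm_fwd(x + a, p[f"l{i}.ln1.g"], p[f"l{i}.ln1.b"])
            z = self._buf(("z", i, x.shape[0]), (x.shape[0], self.seq_len, self.d_ff))
            np.matmul(h1, p[f"l{i}.ff1.W"], out=z)
            z += p[f"l{i}.ff1.b"]
            r = self._buf(("r", i, x.shape[0]), z.shape)
            np.maximum(z, 0.0, out=r)
            f = r @ p[f"l{i}.ff2.W"] + p[f"l{i}.ff2.b"]
            drop2 = None
            if use_drop:
                drop2 = ((rng.random(f.shape) >= self.dropout) / (1 - self.dropout)).astype(DTYPE)
                f = f * drop2
            x2, ln2_cache = self._layer_norm_fwd(h1 + f, p[f"l{i}.ln2.g"], p[f"l{i}.ln2.b"])
            caches.append((attn_cache, drop1, ln1_cache, h1, z, r, drop2, ln2_cache))
            x = x2
        return x, (tokens, caches)

    def logits(self, hidden: np.ndarray) -> np.ndarray:
        p = self.params.data
        return hidden @ p["head.W"] + p["head.b"]

    # ------------------------------------------------------------------ bwd
    def backward(self, dhidden: np.ndarray, cache, grads: dict[str, np.ndarray]) -> None:
        """Accumulate parameter gradients given d(loss)/d(hidden)."""
        tokens, caches = cache
        p = self.params.data
        dx = dhidden
        for i in reversed(range(self.n_layers)):
            attn_cache, drop1, ln1_cache, h1, z, r, drop2, ln2_cache = caches[i]
            dsum2, dg2, db2 = self._layer_norm_bwd(dx, ln2_cache)
            grads[f"l{i}.ln2.g"] += dg2
            grads[f"l{i}.ln2.b"] += db2
            df = dsum2 if drop2 is None else dsum2 * drop2
            dr = self._buf(("dr", i, df.shape[0]), r.shape)
            np.matmul(df, p[f"l{i}.ff2.W"].T, out=dr)
            grads[f"l{i}.ff2.W"] += r.reshape(-1, self.d_ff).T @ df.reshape(-1, self.d)
            grads[f"l{i}.ff2.b"] += df.sum(axis=(0, 1))
            dr *= z > 0  # dz, reusing the dr buffer
            grads[f"l{i}.ff1.W"] += h1.reshape(-1, self.d).T @ dr.reshape(-1, self.d_ff)
            grads[f"l{i}.ff1.b"] += dr.sum(axis=(0, 1))
            dh1 = dsum2 + dr @ p[f"l{i}.ff1.W"].T
            dsum1, dg1, db1 = self._layer_norm_bwd(dh1, ln1_cache)
            grads[f"l{i}.ln1.g"] += dg1
            grads[f"l{i}.ln1.b"] += db1
            da = dsum1 if drop1 is None else dsum1 * drop1
            dx = dsum1 + self._attn_bwd(da, i, p, attn_cache, grads)
        # scatter-add token-embedding grads via a one-hot matmul (k is small;
        # np.add.at is an order of magnitude slower here)
        flat = tokens.reshape(-1)
        onehot = np.zeros((flat.size, self.k), dtype=DTYPE)
        onehot[np.arange(flat.size), flat] = 1.0
        grads["tok_emb"] += onehot.T @ dx.reshape(-1, self.d)
        grads["pos_emb"] += dx.sum(axis=0)

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v, dtype=np.float64) for k, v in self.params.data.items()}

    def loss_and_grads(self, tokens: np.ndarray, targets: np.ndarray, mask: np.ndarray,
                       train: bool = True, rng: np.random.Generator | None = None,
                       weights: np.ndarray | None = None):
        """Masked-token cross entropy (weighted mean over masked positions) and gradients."""
        hidden, cache = self.forward(tokens, train=train, rng=rng)
        logits = self.logits(hidden)
        loss, dlogits = cross_entropy_grads(logits, targets, mask, weights)
        grads = self.zero_grads()
        p = self.params.data
        grads["head.W"] += hidden.reshape(-1, self.d).T @ dlogits.reshape(-1, self.k)
        grads["head.b"] += dlogits.sum(axis=(0, 1))
        dhidden = dlogits @ p["head.W"].T
        self.backward(dhidden, cache, grads)
        return loss, grads


def cross_entropy_grads(logits: np.ndarray, targets: np.ndarray, mask: np.ndarray,
                        weights: np.ndarray | None = None):
    """Weighted mean cross entropy over masked positions; returns (loss, dlogits).

    ``weights`` (same shape as ``mask``) rebalances position types — e.g.
    up-weighting the few metadata positions against the hundreds of gene
    positions; ``None`` means uniform.
    """
    n_masked = int(mask.sum())
    if n_masked == 0:
        return 0.0, np.zeros_like(logits)
    probs = softmax(logits.astype(np.float64), axis=-1)
    b, s = np.nonzero(mask)
    t = targets[b, s]
    w = np.ones(len(b)) if weights is None else np.asarray(weights)[b, s].astype(np.float64)
    wsum = w.sum()
    loss = -np.sum(w * np.log(probs[b, s, t] + 1e-300)) / wsum
    dlogits = np.zeros_like(logits)
    dl = (probs[b, s] * (w / wsum)[:, None]).astype(DTYPE)
    dl[np.arange(len(b)), t] -= (w / wsum).astype(DTYPE)
    dlogits[b, s] = dl
    return float(loss), dlogits


class Adam:
    """Adam with bias correction; state keyed by parameter name."""

    def __init__(self, params: TransformerParams, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.data.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.data.items()}

    def step(self, params: TransformerParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * (g * g)
            update = self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
            params.data[k] -= update.astype(params.data[k].dtype)
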