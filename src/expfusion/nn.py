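"""Minimal numpy transformer encoder with cross-attention fusion and manual backprop.

The trunk maps a tokenized SMILES sequence plus a standardized tabular vector
(descriptors + scenario parameters) to a fused feature vector:

    tokens -> embedding + sinusoidal positions -> n_layers encoder blocks
              (multi-head self-attention, residual + layer norm,
               position-wise feed-forward, residual + layer norm)
    pooled  = masked mean over non-padding token states
    tab     = linear projection of the tabular vector to model dim
    cross   = scaled-dot attention with tab (projected) as the single query
              over the token states
    fused   = [cross | pooled | tab]            (3d;  variants may drop parts)

During stage-1 training a temporary linear head on the fused vector is
optimized by Adam on mean-squared error; afterwards the trunk is frozen and
the fused features feed an SVR head.  Everything here is plain numpy with
hand-written gradients; evaluation mode is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttentionConfig",
    "scaled_dot_attention",
    "sinusoidal_positions",
    "FusionTrunk",
    "train_trunk",
    "TrainingError",
]


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class AttentionConfig:
    """Architecture of the encoder/fusion trunk.

    model_dim is the embedding width d, key_dim = d / n_heads per head;
    ff_dim the position-wise feed-forward width; dropout applies to sublayer
    outputs during training only.
    """

    model_dim: int = 64
    n_heads: int = 2
    n_layers: int = 2
    ff_dim: int = 128
    dropout: float = 0.1
    max_len: int = 64

    def __post_init__(self) -> None:
        if min(self.model_dim, self.n_heads, self.ff_dim, self.max_len) < 1 or self.n_layers < 0:
            raise ValueError("all dimensions must be >= 1 (n_layers >= 0)")
        if self.model_dim % self.n_heads != 0:
            raise ValueError("model_dim must be divisible by n_heads")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def key_dim(self) -> int:
        return self.model_dim // self.n_heads


def scaled_dot_attention(Q, K, V, mask=None):
    """softmax(Q K^T / sqrt(d_k)) V with optional key mask (1 = attend).

    Shapes: Q (..., n_q, d_k), K (..., n_k, d_k), V (..., n_k, d_v).
    Attention rows are non-negative and sum to one.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    d_k = K.shape[-1]
    if d_k == 0:
        raise ValueError("d_k must be positive")
    if not (np.isfinite(Q).all() and np.isfinite(K).all() and np.isfinite(V).all()):
        raise ValueError("non-finite attention input")
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    if mask is not None:
        scores = np.where(np.asarray(mask)[..., None, :] > 0, scores, -1e30)
    scores -= scores.max(axis=-1, keepdims=True)
    p = np.exp(scores)
    p /= p.sum(axis=-1, keepdims=True)
    return p @ V


def sinusoidal_positions(max_len: int, d: int) -> np.ndarray:
    """Classic fixed sin/cos positional encoding table of shape (max_len, d)."""
    pos = np.arange(max_len)[:, None].astype(float)
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.zeros((max_len, d))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


def _softmax_last(x):
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


def _softmax_backward(p, grad):
    # d/ds of softmax(s): p * (grad - sum(grad * p))
    return p * (grad - (grad * p).sum(axis=-1, keepdims=True))


class _Dense:
    def __init__(self, rng, n_in, n_out, bias=True, scale=None):
        s = scale if scale is not None else np.sqrt(2.0 / (n_in + n_out))
        self.W = rng.normal(0.0, s, size=(n_in, n_out))
        self.b = np.zeros(n_out) if bias else None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b) if bias else None
        self._x = None

    def forward(self, x):
        self._x = x
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y

    def backward(self, g):
        x2 = self._x.reshape(-1, self.W.shape[0])
        g2 = g.reshape(-1, self.W.shape[1])
        self.gW += x2.T @ g2
        if self.b is not None:
            self.gb += g2.sum(axis=0)
        return g @ self.W.T

    def params(self):
        out = [(self.W, self.gW)]
        if self.b is not None:
            out.append((self.b, self.gb))
        return out


class _LayerNorm:
    def __init__(self, d, eps=1e-5):
        self.g = np.ones(d)
        self.b = np.zeros(d)
        self.gg = np.zeros_like(self.g)
        self.gb = np.zeros_like(self.b)
        self.eps = eps
        self._cache = None

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.g * xhat + self.b

    def backward(self, grad):
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.gg += (grad * xhat).sum(axis=tuple(range(grad.ndim - 1)))
        self.gb += grad.sum(axis=tuple(range(grad.ndim - 1)))
        dxhat = grad * self.g
        dx = (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        ) * inv
        return dx

    def params(self):
        return [(self.g, self.gg), (self.b, self.gb)]


class _SelfAttention:
    def __init__(self, rng, d, n_heads):
        self.d, self.h = d, n_heads
        self.dk = d // n_heads
        self.wq = _Dense(rng, d, d)
        self.wk = _Dense(rng, d, d)
        self.wv = _Dense(rng, d, d)
        self.wo = _Dense(rng, d, d)
        self._cache = None

    def _split(self, x):  # (B, L, d) -> (B, H, L, dk)
        B, L, _ = x.shape
        return x.reshape(B, L, self.h, self.dk).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (B, H, L, dk) -> (B, L, d)
        B, H, L, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, H * dk)

    def forward(self, x, mask):
        Q = self._split(self.wq.forward(x))
        K = self._split(self.wk.forward(x))
        V = self._split(self.wv.forward(x))
        s = Q @ np.swapaxes(K, -1, -2) / np.sqrt(self.dk)
        s = np.where(mask[:, None, None, :] > 0, s, -1e30)
        p = _softmax_last(s)
        o = self._merge(p @ V)
        self._cache = (Q, K, V, p)
        return self.wo.forward(o)

    def backward(self, g):
        Q, K, V, p = self._cache
        dO = self._split(self.wo.backward(g))
        dP = dO @ np.swapaxes(V, -1, -2)
        dV = np.swapaxes(p, -1, -2) @ dO
        dS = _softmax_backward(p, dP) / np.sqrt(self.dk)
        dQ = dS @ K
        dK = np.swapaxes(dS, -1, -2) @ Q
        dx = self.wq.backward(self._merge(dQ))
        dx += self.wk.backward(self._merge(dK))
        dx += self.wv.backward(self._merge(dV))
        return dx

    def params(self):
        return self.wq.params() + self.wk.params() + self.wv.params() + self.wo.params()


class _FeedForward:
    def __init__(self, rng, d, ff):
        self.lin1 = _Dense(rng, d, ff)
        self.lin2 = _Dense(rng, ff, d)
        self._h = None

    def forward(self, x):
        h = self.lin1.forward(x)
        self._h = h
        return self.lin2.forward(np.maximum(h, 0.0))

    def backward(self, g):
        g = self.lin2.backward(g)
        g = g * (self._h > 0)
        return self.lin1.backward(g)

    def params(self):
        return self.lin1.params() + self.lin2.params()


class _EncoderLayer:
    """Post-norm block: x = LN(x + SelfAttn(x)); x = LN(x + FF(x))."""

    def __init__(self, rng, d, n_heads, ff):
        self.attn = _SelfAttention(rng, d, n_heads)
        self.ln1 = _LayerNorm(d)
        self.ff = _FeedForward(rng, d, ff)
        self.ln2 = _LayerNorm(d)
        self._drop = (None, None)

    def forward(self, x, mask, dropout=0.0, rng=None):
        a = self.attn.forward(x, mask)
        m1 = m2 = None
        if dropout > 0 and rng is not None:
            m1 = (rng.random(a.shape) >= dropout) / (1 - dropout)
            a = a * m1
        h = self.ln1.forward(x + a)
        f = self.ff.forward(h)
        if dropout > 0 and rng is not None:
            m2 = (rng.random(f.shape) >= dropout) / (1 - dropout)
            f = f * m2
        self._drop = (m1, m2)
        return self.ln2.forward(h + f)

    def backward(self, g):
        m1, m2 = self._drop
        g = self.ln2.backward(g)
        gf = g if m2 is None else g * m2
        gh = g + self.ff.backward(gf)
        gh = self.ln1.backward(gh)
        ga = gh if m1 is None else gh * m1
        return gh + self.attn.backward(ga)

    def params(self):
        return self.attn.params() + self.ln1.params() + self.ff.params() + self.ln2.params()


class FusionTrunk:
    """Encoder + fusion trunk with a temporary linear head (see module docstring).

    variant: "full" (cross | pooled | tab), "no_cross_attention"
    (pooled | tab), or "tabular_only" (tab projection alone; used by the
    no-transformer ablation only for API symmetry — the ablation normally
    bypasses the trunk entirely).
    """

    VARIANTS = ("full", "no_cross_attention", "tabular_only")

    def __init__(self, vocab_size: int, n_tabular: int, config: AttentionConfig | None = None,
                 variant: str = "full", seed: int = 0):
        if variant not in self.VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.config = config or AttentionConfig()
        self.variant = variant
        self.vocab_size = vocab_size
        self.n_tabular = n_tabular
        self.seed = seed
        rng = np.random.default_rng(seed)
        d = self.config.model_dim
        self.embedding = rng.normal(0.0, 0.1, size=(vocab_size, d))
        self.g_embedding = np.zeros_like(self.embedding)
        self.posenc = sinusoidal_positions(self.config.max_len, d)
        self.layers = [
            _EncoderLayer(rng, d, self.config.n_heads, self.config.ff_dim)
            for _ in range(self.config.n_layers)
        ]
        self.tab_proj = _Dense(rng, n_tabular, d)
        self.cross_q = _Dense(rng, d, d)
        self.cross_k = _Dense(rng, d, d)
        self.cross_v = _Dense(rng, d, d)
        self.head = _Dense(rng, self.feature_dim, 1)
        self._cache = None

    @property
    def feature_dim(self) -> int:
        d = self.config.model_dim
        return {"full": 3 * d, "no_cross_attention": 2 * d, "tabular_only": d}[self.variant]

    # ---- forward -----------------------------------------------------------

    def _clip(self, ids, mask):
        L = ids.shape[1]
        if L > self.config.max_len:
            warnings.warn(
                f"sequence length {L} exceeds max_len {self.config.max_len}; truncating",
                stacklevel=2,
            )
            ids, mask = ids[:, : self.config.max_len], mask[:, : self.config.max_len]
        return ids, mask

    def features(self, ids, mask, tab, dropout=0.0, rng=None):
        """Fused feature matrix (B, feature_dim); caches intermediates for backward."""
        ids, mask = self._clip(np.asarray(ids), np.asarray(mask, dtype=float))
        tab = np.asarray(tab, dtype=float)
        B, L = ids.shape
        x = self.embedding[ids] + self.posenc[None, :L, :]
        for layer in self.layers:
            x = layer.forward(x, mask, dropout=dropout, rng=rng)
        counts = mask.sum(axis=1, keepdims=True)
        pooled = (x * mask[:, :, None]).sum(axis=1) / counts
        cache = {"ids": ids, "mask": mask, "counts": counts, "x": x}
        if self.variant == "tabular_only":
            fused = self.tab_proj.forward(tab)
            self._cache = cache
            return fused
        # "dimension alignment" of the tabular vector for concatenation is an
        # exact zero-pad to d: it preserves the tabular geometry for the SVR
        # kernel.  The learned projection serves only as the cross-attn query.
        if self.n_tabular > self.config.model_dim:
            raise ValueError("model_dim must be >= number of tabular features")
        tab_align = np.zeros((tab.shape[0], self.config.model_dim))
        tab_align[:, : self.n_tabular] = tab
        if self.variant == "no_cross_attention":
            fused = np.concatenate([pooled, tab_align], axis=1)
        else:
            tabp = self.tab_proj.forward(tab)
            q = self.cross_q.forward(tabp)[:, None, :]
            K = self.cross_k.forward(x)
            V = self.cross_v.forward(x)
            s = (q @ np.swapaxes(K, -1, -2)) / np.sqrt(self.config.model_dim)
            s = np.where(mask[:, None, :] > 0, s, -1e30)
            p = _softmax_last(s)
            cross = (p @ V)[:, 0, :]
            cache.update({"p": p, "K": K, "V": V, "q": q})
            fused = np.concatenate([cross, pooled, tab_align], axis=1)
        self._cache = cache
        return fused

    def forward(self, ids, mask, tab, dropout=0.0, rng=None):
        """Scalar prediction per row through the temporary linear head."""
        return self.head.forward(self.features(ids, mask, tab, dropout=dropout, rng=rng))[:, 0]

    # ---- backward ----------------------------------------------------------

    def backward(self, g_pred):
        """Backprop from d(loss)/d(prediction) (shape (B,)) through the trunk."""
        c = self._cache
        g_f = self.head.backward(np.asarray(g_pred)[:, None])
        d = self.config.model_dim
        mask, counts, x = c["mask"], c["counts"], c["x"]
        g_x = np.zeros_like(x)
        if self.variant == "tabular_only":
            return self.tab_proj.backward(g_f)
        if self.variant == "no_cross_attention":
            g_pooled, g_align = g_f[:, :d], g_f[:, d:]
            g_tab = g_align[:, : self.n_tabular]
        else:
            g_cross, g_pooled, g_align = g_f[:, :d], g_f[:, d : 2 * d], g_f[:, 2 * d :]
            p, K, V, q = c["p"], c["K"], c["V"], c["q"]
            g_co = g_cross[:, None, :]
            g_p = g_co @ np.swapaxes(V, -1, -2)
            g_V = np.swapaxes(p, -1, -2) @ g_co
            g_s = _softmax_backward(p, g_p) / np.sqrt(d)
            g_q = g_s @ K
            g_K = np.swapaxes(g_s, -1, -2) @ q
            g_x += self.cross_k.backward(g_K)
            g_x += self.cross_v.backward(g_V)
            g_tab = self.tab_proj.backward(self.cross_q.backward(g_q[:, 0, :]))
            g_tab = g_tab + g_align[:, : self.n_tabular]
        g_x += (g_pooled[:, None, :] * mask[:, :, None]) / counts[:, :, None]
        for layer in reversed(self.layers):
            g_x = layer.backward(g_x)
        np.add.at(self.g_embedding, c["ids"], g_x)
        return g_tab

    # ---- parameters --------------------------------------------------------

    def params(self):
        out = [(self.embedding, self.g_embedding)]
        for layer in self.layers:
            out += layer.params()
        if self.variant in ("full", "tabular_only"):
            out += self.tab_proj.params()
        if self.variant == "full":
            out += self.cross_q.params() + self.cross_k.params() + self.cross_v.params()
        out += self.head.params()
        return out

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    # ---- serialization -----------------------------------------------------

    def _named_arrays(self):
        def dense(prefix, d):
            yield f"{prefix}.W", d.W
            if d.b is not None:
                yield f"{prefix}.b", d.b

        yield "embedding", self.embedding
        for i, layer in enumerate(self.layers):
            for nm, dd in (
                ("wq", layer.attn.wq), ("wk", layer.attn.wk),
                ("wv", layer.attn.wv), ("wo", layer.attn.wo),
                ("ff1", layer.ff.lin1), ("ff2", layer.ff.lin2),
            ):
                yield from dense(f"layer{i}.{nm}", dd)
            for nm, ln in (("ln1", layer.ln1), ("ln2", layer.ln2)):
                yield f"layer{i}.{nm}.g", ln.g
                yield f"layer{i}.{nm}.b", ln.b
        yield from dense("tab_proj", self.tab_proj)
        yield from dense("cross_q", self.cross_q)
        yield from dense("cross_k", self.cross_k)
        yield from dense("cross_v", self.cross_v)
        yield from dense("head", self.head)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._named_arrays()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self._named_arrays():
            if k not in state:
                raise KeyError(f"missing trunk weight {k!r}")
            v[...] = state[k]


class _Adam:
    """Adam with decoupled weight decay (AdamW)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, beta1, beta2, eps, weight_decay
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if self.wd:
                p -= self.lr * self.wd * p
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_trunk(
    trunk: FusionTrunk,
    ids: np.ndarray,
    mask: np.ndarray,
    tab: np.ndarray,
    y: np.ndarray,
    epochs: int = 20,
    batch_size: int = 128,
    lr: float = 1e-3,
    seed: int = 0,
    weight_decay: float = 1e-4,
    modality_dropout: float = 0.0,
    sample_tokens=None,
) -> list[float]:
    """Stage-1 gradient training of trunk + temporary head on MSE; returns per-epoch loss.

    Deterministic given the seed (batch order and dropout masks are drawn
    from one generator).  ``sample_tokens(idx, rng) -> (ids, mask)``, when
    given, supplies the token batch for rows ``idx`` each step — the hook for
    randomized-SMILES augmentation, which regularizes the encoder toward
    structural rather than string-identity features.  Raises TrainingError
    naming the epoch if the loss becomes non-finite.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    n = len(y)
    opt = _Adam(trunk.params(), lr=lr, weight_decay=weight_decay)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            trunk.zero_grad()
            if sample_tokens is not None:
                ids_b, mask_b = sample_tokens(idx, rng)
            else:
                ids_b, mask_b = ids[idx], mask[idx]
            tab_b = tab[idx]
            if modality_dropout > 0:
                # blank the (standardized) tabular branch for some rows so the
                # encoder must carry chemical information on its own
                tab_b = tab_b.copy()
                tab_b[rng.random(len(idx)) < modality_dropout] = 0.0
            pred = trunk.forward(
                ids_b, mask_b, tab_b, dropout=trunk.config.dropout, rng=rng
            )
            err = pred - y[idx]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingError(f"loss diverged (non-finite) at epoch {epoch}")
            trunk.backward(2.0 * err / len(idx))
            opt.step()
            total += loss * len(idx)
        history.append(total / n)
    return history
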