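"""Minimal self-attention encoder for sequence classification, in numpy.

Architecture: token embedding + learned positional embedding, a stack of
pre-norm encoder blocks (multi-head self-attention and a GELU
feed-forward sublayer, each wrapped in residual connections), a final
layer norm, first-token pooling, and a 2-way linear head trained with
softmax cross-entropy under AdamW.

Everything runs in float64 on the CPU. Gradients are derived by hand and
checked against central finite differences in the test suite; keep any
change to the forward pass mirrored in the backward pass.

Shapes: B batch, L sequence length, d model width, h heads, k = d / h.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_LN_EPS = 1e-5
_MASK_NEG = 1e4  # large enough that exp() underflows, small enough for float64 headroom
_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def init_params(
    vocab_size: int,
    max_len: int,
    hidden: int,
    layers: int,
    heads: int,
    ff: int,
    seed: int,
) -> dict[str, np.ndarray]:
    if hidden % heads != 0:
        raise ValueError(f"hidden_size {hidden} not divisible by num_heads {heads}")
    rng = np.random.default_rng(seed)

    def w(*shape):
        return rng.normal(0.0, 0.02, size=shape)

    p: dict[str, np.ndarray] = {
        "tok_emb": w(vocab_size, hidden),
        "pos_emb": w(max_len, hidden),
        "ln_f.g": np.ones(hidden),
        "ln_f.b": np.zeros(hidden),
        "head.W": w(hidden, 2),
        "head.b": np.zeros(2),
    }
    for i in range(layers):
        pre = f"block{i}."
        p[pre + "ln1.g"] = np.ones(hidden)
        p[pre + "ln1.b"] = np.zeros(hidden)
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[pre + name] = w(hidden, hidden)
        for name in ("bq", "bk", "bv", "bo"):
            p[pre + name] = np.zeros(hidden)
        p[pre + "ln2.g"] = np.ones(hidden)
        p[pre + "ln2.b"] = np.zeros(hidden)
        p[pre + "W1"] = w(hidden, ff)
        p[pre + "b1"] = np.zeros(ff)
        p[pre + "W2"] = w(ff, hidden)
        p[pre + "b2"] = np.zeros(hidden)
    return p


def n_params(params: dict[str, np.ndarray]) -> int:
    return int(sum(v.size for v in params.values()))


def _layer_norm(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv)


def _layer_norm_grad(dy, g, cache):
    xhat, inv = cache
    dg = np.sum(dy * xhat, axis=tuple(range(dy.ndim - 1)))
    db = np.sum(dy, axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _split_heads(x, heads):
    B, L, d = x.shape
    k = d // heads
    return x.reshape(B, L, heads, k).transpose(0, 2, 1, 3)  # B,h,L,k


def _merge_heads(x):
    B, h, L, k = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, L, h * k)


def forward(
    params: dict[str, np.ndarray],
    ids: np.ndarray,
    mask: np.ndarray,
    layers: int,
    heads: int,
    return_cache: bool = False,
):
    """Logits of shape (B, 2); optionally the cache for backward."""
    B, L = ids.shape
    x = params["tok_emb"][ids] + params["pos_emb"][:L]
    key_bias = (mask[:, None, None, :] - 1.0) * _MASK_NEG  # B,1,1,L
    cache: dict = {"ids": ids, "mask": mask, "blocks": []}
    for i in range(layers):
        pre = f"block{i}."
        a, ln1_cache = _layer_norm(x, params[pre + "ln1.g"], params[pre + "ln1.b"])
        q = a @ params[pre + "Wq"] + params[pre + "bq"]
        kk = a @ params[pre + "Wk"] + params[pre + "bk"]
        v = a @ params[pre + "Wv"] + params[pre + "bv"]
        qh, kh, vh = (_split_heads(t, heads) for t in (q, kk, v))
        scale = 1.0 / np.sqrt(qh.shape[-1])
        scores = qh @ kh.transpose(0, 1, 3, 2) * scale + key_bias
        attn = softmax(scores, axis=-1)  # B,h,L,L
        ctx = attn @ vh  # B,h,L,k
        merged = _merge_heads(ctx)
        attn_out = merged @ params[pre + "Wo"] + params[pre + "bo"]
        x1 = x + attn_out
        f, ln2_cache = _layer_norm(x1, params[pre + "ln2.g"], params[pre + "ln2.b"])
        h1 = f @ params[pre + "W1"] + params[pre + "b1"]
        g1 = gelu(h1)
        ffn_out = g1 @ params[pre + "W2"] + params[pre + "b2"]
        x2 = x1 + ffn_out
        cache["blocks"].append(
            dict(a=a, ln1=ln1_cache, qh=qh, kh=kh, vh=vh, attn=attn,
                 merged=merged, x1=x1, f=f, ln2=ln2_cache, h1=h1, g1=g1,
                 scale=scale)
        )
        x = x2
    z, lnf_cache = _layer_norm(x, params["ln_f.g"], params["ln_f.b"])
    pooled = z[:, 0, :]
    logits = pooled @ params["head.W"] + params["head.b"]
    if return_cache:
        cache["lnf"] = lnf_cache
        cache["pooled"] = pooled
        cache["z_shape"] = z.shape
        return logits, cache
    return logits


def loss_and_grads(
    params: dict[str, np.ndarray],
    ids: np.ndarray,
    mask: np.ndarray,
    labels: np.ndarray,
    layers: int,
    heads: int,
    class_weights: np.ndarray | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean softmax cross-entropy and its gradient for one batch.

    labels are 0/1 class indices (1 = PASS). class_weights, if given,
    re-weights the per-example losses by true class.
    """
    B = ids.shape[0]
    logits, cache = forward(params, ids, mask, layers, heads, return_cache=True)
    probs = softmax(logits, axis=-1)
    eps = 1e-12
    per_example = -np.log(probs[np.arange(B), labels] + eps)
    if class_weights is not None:
        w = class_weights[labels]
        denom = w.sum()
        loss = float((per_example * w).sum() / denom)
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits *= (w / denom)[:, None]
    else:
        loss = float(per_example.mean())
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B

    grads: dict[str, np.ndarray] = {}
    pooled = cache["pooled"]
    grads["head.W"] = pooled.T @ dlogits
    grads["head.b"] = dlogits.sum(axis=0)
    dpooled = dlogits @ params["head.W"].T
    dz = np.zeros(cache["z_shape"])
    dz[:, 0, :] = dpooled
    dx, grads["ln_f.g"], grads["ln_f.b"] = _layer_norm_grad(
        dz, params["ln_f.g"], cache["lnf"]
    )

    for i in reversed(range(layers)):
        pre = f"block{i}."
        c = cache["blocks"][i]
        # FFN sublayer: x2 = x1 + W2·gelu(W1·f + b1) + b2
        dffn = dx  # gradient wrt ffn_out
        grads[pre + "W2"] = np.einsum("blf,bld->fd", c["g1"], dffn)
        grads[pre + "b2"] = dffn.sum(axis=(0, 1))
        dg1 = dffn @ params[pre + "W2"].T
        dh1 = dg1 * gelu_grad(c["h1"])
        grads[pre + "W1"] = np.einsum("bld,blf->df", c["f"], dh1)
        grads[pre + "b1"] = dh1.sum(axis=(0, 1))
        df = dh1 @ params[pre + "W1"].T
        dx1_ln, grads[pre + "ln2.g"], grads[pre + "ln2.b"] = _layer_norm_grad(
            df, params[pre + "ln2.g"], c["ln2"]
        )
        dx1 = dx + dx1_ln  # residual
        # attention sublayer: x1 = x + Wo·concat(attn·V) + bo
        dattn_out = dx1
        grads[pre + "Wo"] = np.einsum("bld,ble->de", c["merged"], dattn_out)
        grads[pre + "bo"] = dattn_out.sum(axis=(0, 1))
        dmerged = dattn_out @ params[pre + "Wo"].T
        dctx = _split_heads(dmerged, heads)  # B,h,L,k
        dattn = dctx @ c["vh"].transpose(0, 1, 3, 2)  # B,h,L,L
        dvh = c["attn"].transpose(0, 1, 3, 2) @ dctx
        # softmax over keys
        A = c["attn"]
        dscores = A * (dattn - np.sum(dattn * A, axis=-1, keepdims=True))
        dqh = dscores @ c["kh"] * c["scale"]
        dkh = dscores.transpose(0, 1, 3, 2) @ c["qh"] * c["scale"]
        dq = _merge_heads(dqh)
        dk = _merge_heads(dkh)
        dv = _merge_heads(dvh)
        a = c["a"]
        grads[pre + "Wq"] = np.einsum("bld,ble->de", a, dq)
        grads[pre + "Wk"] = np.einsum("bld,ble->de", a, dk)
        grads[pre + "Wv"] = np.einsum("bld,ble->de", a, dv)
        grads[pre + "bq"] = dq.sum(axis=(0, 1))
        grads[pre + "bk"] = dk.sum(axis=(0, 1))
        grads[pre + "bv"] = dv.sum(axis=(0, 1))
        da = (
            dq @ params[pre + "Wq"].T
            + dk @ params[pre + "Wk"].T
            + dv @ params[pre + "Wv"].T
        )
        dx_ln, grads[pre + "ln1.g"], grads[pre + "ln1.b"] = _layer_norm_grad(
            da, params[pre + "ln1.g"], c["ln1"]
        )
        dx = dx1 + dx_ln  # residual into the block input

    # embeddings
    ids_arr = cache["ids"]
    grads["tok_emb"] = np.zeros_like(params["tok_emb"])
    np.add.at(grads["tok_emb"], ids_arr.ravel(), dx.reshape(-1, dx.shape[-1]))
    L = ids_arr.shape[1]
    grads["pos_emb"] = np.zeros_like(params["pos_emb"])
    grads["pos_emb"][:L] = dx.sum(axis=0)
    return loss, grads


class AdamW:
    """Decoupled-weight-decay Adam. Decay applies to matrices only
    (embeddings and projection weights), never to biases or norm gains."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float,
        weight_decay: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.decay_keys = {k for k, v in params.items() if v.ndim >= 2}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            update = mhat / (np.sqrt(vhat) + self.eps)
            if k in self.decay_keys:
                update = update + self.weight_decay * params[k]
            params[k] -= self.lr * update
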