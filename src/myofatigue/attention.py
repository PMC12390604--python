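"""A small scaled dot-product attention encoder for tabular MPF features.

Each of the 6 or 12 feature dimensions becomes one token: the scalar feature
value is mapped to a ``d_model``-vector by a learned per-dimension scale and
bias plus a learned position embedding.  The encoder stacks ``n_layers``
blocks of multi-head scaled dot-product attention,

    Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V,

each followed by a position-wise feed-forward sublayer, both with residual
connections (no layer normalization -- at this width, plain residuals train
stably and keep the arithmetic transparent).  The token outputs are mean-pooled
into a fixed-length vector feeding a one-hidden-layer classification head.
Everything -- forward pass, backpropagation, and the Adam optimizer -- is
implemented directly on numpy arrays, so training is deterministic given a
seed and a fixed BLAS thread count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AttentionParams", "AttentionEncoderClassifier", "scaled_dot_product_attention", "softmax"]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def scaled_dot_product_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """softmax(Q K^T / sqrt(d_k)) V over the last two axes.

    Works for (..., S, d) stacks.  Returns (output, attention weights); the
    weight rows sum to one.
    """
    d_k = Q.shape[-1]
    if d_k == 0:
        raise ValueError("d_k must be positive")
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    weights = softmax(scores, axis=-1)
    return weights @ V, weights


@dataclass
class AttentionParams:
    """Hyperparameters of the encoder."""

    n_tokens: int
    d_model: int = 16
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 32
    head_hidden: int = 64
    n_classes: int = 6

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.d_model // self.n_heads == 0:
            raise ValueError("d_k must be positive")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


def _init_weights(params: AttentionParams, rng: np.random.Generator) -> dict[str, np.ndarray]:
    S, D, F, H = params.n_tokens, params.d_model, params.d_ff, params.head_hidden
    C = params.n_classes

    def g(*shape, scale=None):
        scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
        return rng.normal(0.0, scale, size=shape)

    w: dict[str, np.ndarray] = {
        "embed_w": rng.normal(0.0, 1.0, size=(S, D)),
        "embed_b": np.zeros((S, D)),
        "pos": rng.normal(0.0, 0.5, size=(S, D)),
        "head_w1": g(D, H),
        "head_b1": np.zeros(H),
        "head_w2": g(H, C),
        "head_b2": np.zeros(C),
    }
    for l in range(params.n_layers):
        for name in ("wq", "wk", "wv", "wo"):
            w[f"l{l}_{name}"] = g(D, D)
        w[f"l{l}_bo"] = np.zeros(D)
        w[f"l{l}_w1"] = g(D, F)
        w[f"l{l}_b1"] = np.zeros(F)
        w[f"l{l}_w2"] = g(F, D)
        w[f"l{l}_b2"] = np.zeros(D)
    return w


def _split_heads(x: np.ndarray, n_heads: int) -> np.ndarray:
    B, S, D = x.shape
    return x.reshape(B, S, n_heads, D // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    B, H, S, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, S, H * dh)


class AttentionEncoderClassifier:
    """Attention encoder + MLP head trained jointly with Adam on cross-entropy.

    The sklearn-ish surface (``fit`` / ``predict`` / ``predict_proba``) lets
    the classify module treat it like any other family; ``encode`` exposes the
    frozen pooled representation for the SVM-on-encodings family.
    """

    def __init__(
        self,
        n_classes: int = 6,
        d_model: int = 16,
        n_heads: int = 4,
        n_layers: int = 2,
        d_ff: int = 32,
        head_hidden: int = 64,
        epochs: int = 120,
        lr: float = 5e-3,
        batch_size: int = 256,
        seed: int = 0,
    ) -> None:
        self.n_classes = n_classes
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff
        self.head_hidden = head_hidden
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed
        self.params_: AttentionParams | None = None
        self.weights_: dict[str, np.ndarray] | None = None
        self.loss_curve_: list[float] = []

    # ---------------------------------------------------------------- forward

    def _forward(self, X: np.ndarray, w: dict[str, np.ndarray]) -> dict:
        """Forward pass; returns a cache of intermediates for backprop."""
        p = self.params_
        E = X[:, :, None] * w["embed_w"][None] + w["embed_b"][None] + w["pos"][None]
        cache: dict = {"X": X, "E0": E}
        H = E
        for l in range(p.n_layers):
            Q = _split_heads(H @ w[f"l{l}_wq"], p.n_heads)
            K = _split_heads(H @ w[f"l{l}_wk"], p.n_heads)
            V = _split_heads(H @ w[f"l{l}_wv"], p.n_heads)
            ctx, A = scaled_dot_product_attention(Q, K, V)
            ctx_m = _merge_heads(ctx)
            attn_out = ctx_m @ w[f"l{l}_wo"] + w[f"l{l}_bo"]
            H1 = H + attn_out
            pre = H1 @ w[f"l{l}_w1"] + w[f"l{l}_b1"]
            F = np.maximum(pre, 0.0)
            H2 = H1 + F @ w[f"l{l}_w2"] + w[f"l{l}_b2"]
            cache[f"l{l}"] = (H, Q, K, V, A, ctx_m, H1, pre, F)
            H = H2
        z = H.mean(axis=1)
        h_pre = z @ w["head_w1"] + w["head_b1"]
        h = np.maximum(h_pre, 0.0)
        logits = h @ w["head_w2"] + w["head_b2"]
        cache.update(H_final=H, z=z, h_pre=h_pre, h=h, logits=logits)
        return cache

    # --------------------------------------------------------------- backward

    def _backward(self, cache: dict, y: np.ndarray, w: dict[str, np.ndarray]) -> dict:
        p = self.params_
        B = len(y)
        probs = softmax(cache["logits"], axis=-1)
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        g: dict[str, np.ndarray] = {}
        g["head_w2"] = cache["h"].T @ dlogits
        g["head_b2"] = dlogits.sum(0)
        dh = dlogits @ w["head_w2"].T
        dh_pre = dh * (cache["h_pre"] > 0)
        g["head_w1"] = cache["z"].T @ dh_pre
        g["head_b1"] = dh_pre.sum(0)
        dz = dh_pre @ w["head_w1"].T
        S = cache["H_final"].shape[1]
        dH = np.repeat(dz[:, None, :], S, axis=1) / S

        for l in reversed(range(p.n_layers)):
            H, Q, K, V, A, ctx_m, H1, pre, F = cache[f"l{l}"]
            # feed-forward sublayer
            dH1 = dH.copy()
            g[f"l{l}_w2"] = np.einsum("bsf,bsd->fd", F, dH)
            g[f"l{l}_b2"] = dH.sum((0, 1))
            dF = dH @ w[f"l{l}_w2"].T
            dpre = dF * (pre > 0)
            g[f"l{l}_w1"] = np.einsum("bsd,bsf->df", H1, dpre)
            g[f"l{l}_b1"] = dpre.sum((0, 1))
            dH1 += dpre @ w[f"l{l}_w1"].T
            # attention sublayer
            dHres = dH1.copy()
            dattn = dH1
            g[f"l{l}_wo"] = np.einsum("bsd,bse->de", ctx_m, dattn)
            g[f"l{l}_bo"] = dattn.sum((0, 1))
            dctx_m = dattn @ w[f"l{l}_wo"].T
            dctx = _split_heads(dctx_m, p.n_heads)
            dA = dctx @ np.swapaxes(V, -1, -2)
            dV = np.swapaxes(A, -1, -2) @ dctx
            dscores = A * (dA - np.sum(dA * A, axis=-1, keepdims=True))
            scale = 1.0 / np.sqrt(p.d_head)
            dQ = dscores @ K * scale
            dK = np.swapaxes(dscores, -1, -2) @ Q * scale
            dQm, dKm, dVm = (_merge_heads(a) for a in (dQ, dK, dV))
            g[f"l{l}_wq"] = np.einsum("bsd,bse->de", H, dQm)
            g[f"l{l}_wk"] = np.einsum("bsd,bse->de", H, dKm)
            g[f"l{l}_wv"] = np.einsum("bsd,bse->de", H, dVm)
            dH = (
                dHres
                + dQm @ w[f"l{l}_wq"].T
                + dKm @ w[f"l{l}_wk"].T
                + dVm @ w[f"l{l}_wv"].T
            )

        dE = dH
        X = cache["X"]
        g["embed_w"] = np.einsum("bs,bsd->sd", X, dE)
        g["embed_b"] = dE.sum(0)
        g["pos"] = dE.sum(0)
        return g

    def _loss(self, logits: np.ndarray, y: np.ndarray) -> float:
        logp = logits - np.log(np.sum(np.exp(logits - logits.max(-1, keepdims=True)), -1, keepdims=True)) - logits.max(-1, keepdims=True)
        return float(-np.mean(logp[np.arange(len(y)), y]))

    # -------------------------------------------------------------------- fit

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AttentionEncoderClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be (n_samples, n_features)")
        self.params_ = AttentionParams(
            n_tokens=X.shape[1],
            d_model=self.d_model,
            n_heads=self.n_heads,
            n_layers=self.n_layers,
            d_ff=self.d_ff,
            head_hidden=self.head_hidden,
            n_classes=self.n_classes,
        )
        rng = np.random.default_rng(self.seed)
        w = _init_weights(self.params_, rng)
        m = {k: np.zeros_like(v) for k, v in w.items()}
        v = {k: np.zeros_like(val) for k, val in w.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(X)
        self.loss_curve_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                cache = self._forward(X[idx], w)
                epoch_loss += self._loss(cache["logits"], y[idx]) * len(idx)
                grads = self._backward(cache, y[idx], w)
                step += 1
                for k in w:
                    gk = grads[k]
                    m[k] = b1 * m[k] + (1 - b1) * gk
                    v[k] = b2 * v[k] + (1 - b2) * gk**2
                    mhat = m[k] / (1 - b1**step)
                    vhat = v[k] / (1 - b2**step)
                    w[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)
            self.loss_curve_.append(epoch_loss / n)
        self.weights_ = w
        return self

    # -------------------------------------------------------------- inference

    def _check_fitted(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.params_.n_tokens:
            raise ValueError(
                f"expected {self.params_.n_tokens} features, got shape {X.shape}"
            )
        return X

    def decision_logits(self, X: np.ndarray) -> np.ndarray:
        X = self._check_fitted(X)
        return self._forward(X, self.weights_)["logits"]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.decision_logits(X), axis=-1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.decision_logits(X), axis=-1)

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Mean-pooled encoder output (the frozen representation)."""
        X = self._check_fitted(X)
        return self._forward(X, self.weights_)["z"]
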