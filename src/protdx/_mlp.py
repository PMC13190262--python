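"""Minimal fully-connected network with GELU hidden layers, inverted dropout
and an Adam optimizer, implemented in numpy.

Architecture: input -> [Linear -> GELU -> Dropout] x L -> Linear (embedding,
no nonlinearity) -> Linear heads -> sigmoid.  The embedding is the pre-head
activation vector; the heads combine it linearly, one logit per task.

All randomness flows through an explicit Generator, so training is exactly
reproducible for a fixed seed and thread-independent (pure BLAS calls).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_INV_SQRT2 = 0.7071067811865476
_INV_SQRT2PI = 0.3989422804014327


@njit(cache=True, fastmath=True)
def _gelu_flat(x, out):  # pragma: no cover - jitted
    for i in range(x.size):
        v = x[i]
        out[i] = v * 0.5 * (1.0 + math.erf(v * _INV_SQRT2))


@njit(cache=True, fastmath=True)
def _gelu_grad_flat(x, out):  # pragma: no cover - jitted
    for i in range(x.size):
        v = x[i]
        phi = 0.5 * (1.0 + math.erf(v * _INV_SQRT2))
        out[i] = phi + v * math.exp(-0.5 * v * v) * _INV_SQRT2PI


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact GELU x * Phi(x), elementwise (jit-compiled)."""
    x = np.ascontiguousarray(x)
    out = np.empty_like(x)
    _gelu_flat(x.ravel(), out.ravel())
    return out


def gelu_grad(x: np.ndarray) -> np.ndarray:
    """d/dx of x * Phi(x) = Phi(x) + x phi(x)."""
    x = np.ascontiguousarray(x)
    out = np.empty_like(x)
    _gelu_grad_flat(x.ravel(), out.ravel())
    return out


class MLP:
    """Trunk + embedding layer + multi-task linear heads."""

    def __init__(
        self,
        n_in: int,
        hidden: tuple[int, ...],
        embedding_dim: int,
        n_tasks: int,
        dropout: float,
        rng: np.random.Generator,
    ) -> None:
        self.hidden = tuple(hidden)
        self.dropout = float(dropout)
        dims = [n_in, *hidden]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out)))
            self.b.append(np.zeros(d_out))
        self.We = rng.normal(0.0, np.sqrt(1.0 / dims[-1]), (dims[-1], embedding_dim))
        self.be = np.zeros(embedding_dim)
        self.Wo = rng.normal(0.0, np.sqrt(1.0 / embedding_dim), (embedding_dim, n_tasks))
        self.bo = np.zeros(n_tasks)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [*self.W, *self.b, self.We, self.be, self.Wo, self.bo]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        L = len(self.W)
        self.W = [p.copy() for p in params[:L]]
        self.b = [p.copy() for p in params[L:2 * L]]
        self.We, self.be, self.Wo, self.bo = (p.copy() for p in params[2 * L:])

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        dropout_override: float | None = None,
    ) -> tuple[np.ndarray, np.ndarray, dict]:
        """Returns (logits, embedding, cache)."""
        rate = self.dropout if dropout_override is None else dropout_override
        h = x
        pre, post, masks = [], [h], []
        for W, b in zip(self.W, self.b):
            z = h @ W + b
            pre.append(z)
            h = gelu(z)
            if training and rate > 0:
                assert rng is not None, "training forward pass needs a Generator"
                mask = (rng.random(h.shape) >= rate) / (1.0 - rate)
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            post.append(h)
        emb = h @ self.We + self.be
        logits = emb @ self.Wo + self.bo
        cache = {"pre": pre, "post": post, "masks": masks, "emb_in": h, "emb": emb}
        return logits, emb, cache

    def backward(self, dlogits: np.ndarray, cache: dict) -> list[np.ndarray]:
        """Gradients in the order of :meth:`parameters`."""
        emb = cache["emb"]
        h = cache["emb_in"]
        dWo = emb.T @ dlogits
        dbo = dlogits.sum(axis=0)
        demb = dlogits @ self.Wo.T
        dWe = h.T @ demb
        dbe = demb.sum(axis=0)
        dh = demb @ self.We.T
        dW = [np.empty(0)] * len(self.W)
        db = [np.empty(0)] * len(self.W)
        for li in range(len(self.W) - 1, -1, -1):
            mask = cache["masks"][li]
            if mask is not None:
                dh = dh * mask
            dz = dh * gelu_grad(cache["pre"][li])
            dW[li] = cache["post"][li].T @ dz
            db[li] = dz.sum(axis=0)
            dh = dz @ self.W[li].T
        return [*dW, *db, dWe, dbe, dWo, dbo]


class Adam:
    """Adam with decoupled weight decay on the weight matrices."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        decay_mask: list[bool] | None = None,
    ) -> None:
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.decay_mask = decay_mask or [True] * len(params)
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            update = (self.m[i] / c1) / (np.sqrt(self.v[i] / c2) + self.eps)
            if self.weight_decay and self.decay_mask[i]:
                update = update + self.weight_decay * p
            p -= self.lr * update
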