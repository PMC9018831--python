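"""Minimal dense/sparse neural-network primitives with explicit backprop.

Everything here is plain numpy/scipy so that gradients with respect to the
*input* (needed for integrated-gradients attribution) come for free from the
same backward passes that train the parameters.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "conv1d_forward",
    "conv1d_backward",
    "normalize_adjacency",
    "gcn_layer",
    "gcn_forward",
    "gcn_backward",
    "relu",
    "Adam",
]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# 1D convolution over bins ("same" padding)
# ---------------------------------------------------------------------------


def conv1d_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """out[o, i] = b[o] + sum_{c,k} W[o,c,k] * Xpad[c, i + k].

    X: (C_in, n); W: (C_out, C_in, K) with odd K; b: (C_out,).
    Returns (out, cache) where out is (C_out, n).
    """
    cout, cin, K = W.shape
    if K % 2 != 1:
        raise ValueError("kernel size must be odd for same padding")
    n = X.shape[1]
    P = K // 2
    Xp = np.zeros((cin, n + 2 * P))
    Xp[:, P : P + n] = X
    out = np.tile(b[:, None], (1, n))
    for k in range(K):
        out += W[:, :, k] @ Xp[:, k : k + n]
    return out, (Xp, W, n)


def conv1d_backward(dOut: np.ndarray, cache):
    """Gradients of a conv1d_forward call: returns (dX, dW, db)."""
    Xp, W, n = cache
    cout, cin, K = W.shape
    P = K // 2
    dW = np.empty_like(W)
    dXp = np.zeros_like(Xp)
    for k in range(K):
        dW[:, :, k] = dOut @ Xp[:, k : k + n].T
        dXp[:, k : k + n] += W[:, :, k].T @ dOut
    db = dOut.sum(axis=1)
    return dXp[:, P : P + n], dW, db


# ---------------------------------------------------------------------------
# graph convolution (symmetric-normalized, self-loops assumed present)
# ---------------------------------------------------------------------------


def normalize_adjacency(adjacency: sp.spmatrix) -> sp.csr_matrix:
    """D^{-1/2} A D^{-1/2} for a self-looped nonnegative adjacency."""
    A = sp.csr_matrix(adjacency)
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise RuntimeError("zero-degree node encountered; self-loops missing?")
    dinv = 1.0 / np.sqrt(deg)
    D = sp.diags(dinv)
    return (D @ A @ D).tocsr()


def gcn_layer(H: np.ndarray, adjacency: sp.spmatrix, W: np.ndarray, b=None) -> np.ndarray:
    """One graph-convolution step: ReLU(D^{-1/2} A D^{-1/2} H W).

    ``adjacency`` must already contain self-loops. This is the reference
    (stateless) form of the operation; the model uses the cached
    forward/backward pair below.
    """
    A_hat = normalize_adjacency(adjacency)
    out, _ = gcn_forward(H, A_hat, W, b if b is not None else np.zeros(W.shape[1]))
    return out


def gcn_forward(H: np.ndarray, A_hat: sp.csr_matrix, W: np.ndarray, b: np.ndarray):
    """out = ReLU(A_hat @ H @ W + b) with cache for backward."""
    M = A_hat @ H
    Z = M @ W + b
    out = relu(Z)
    return out, (H, A_hat, W, Z)


def gcn_backward(dOut: np.ndarray, cache):
    """Returns (dH, dW, db); exploits the symmetry of A_hat."""
    H, A_hat, W, Z = cache
    dZ = dOut * (Z > 0)
    AdZ = A_hat @ dZ          # A_hat is symmetric, so A_hat.T @ dZ == A_hat @ dZ
    dW = H.T @ AdZ
    dH = AdZ @ W.T
    db = dZ.sum(axis=0)
    return dH, dW, db


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(
        self,
        grads: dict[str, np.ndarray],
        only: set[str] | None = None,
        max_norm: float | None = None,
    ) -> None:
        """Apply one update; ``only`` restricts which parameters move and
        ``max_norm`` clips the global gradient norm (training stability)."""
        if max_norm is not None:
            keys = [k for k in grads if only is None or k in only]
            norm = np.sqrt(sum(float((grads[k] ** 2).sum()) for k in keys))
            if norm > max_norm:
                scale = max_norm / norm
                grads = {k: (g * scale if k in keys else g) for k, g in grads.items()}
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            if only is not None and k not in only:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            self.params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
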