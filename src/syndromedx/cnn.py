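"""Text CNN over token-index sequences, implemented in numpy.

Architecture: embedding layer (initialized from a trained word model,
optionally frozen) → one 1-D convolution (ReLU) → global max-pooling →
dense ReLU layer → dense output layer with softmax (multiclass) or
per-label sigmoid (multilabel).  Optimized with Adam and early stopping
on a held-out validation split.  Single-threaded and deterministic
under a fixed seed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = ["TextCNN"]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


class _Adam:
    def __init__(self, shapes, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class TextCNN:
    """Minimal convolutional text classifier on padded index sequences."""

    def __init__(
        self,
        vocab_size: int,
        embed_dim: int,
        n_outputs: int,
        mode: str = "multiclass",
        filters: int = 128,
        kernel_size: int = 3,
        dense_units: int = 128,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        epochs: int = 30,
        patience: int = 5,
        val_fraction: float = 0.1,
        trainable_embeddings: bool = True,
        seed: int = 0,
        embeddings: Optional[np.ndarray] = None,
    ):
        if mode not in ("multiclass", "multilabel"):
            raise ValueError("mode must be 'multiclass' or 'multilabel'")
        self.mode = mode
        self.kernel_size = kernel_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.val_fraction = val_fraction
        self.trainable_embeddings = trainable_embeddings
        self.n_outputs = n_outputs
        rng = np.random.default_rng(seed)
        self._rng = rng
        if embeddings is not None:
            if embeddings.shape != (vocab_size, embed_dim):
                raise ValueError(
                    f"embeddings shape {embeddings.shape} != {(vocab_size, embed_dim)}"
                )
            self.E = embeddings.astype(np.float64).copy()
        else:
            self.E = (rng.random((vocab_size, embed_dim)) - 0.5) / embed_dim
        self.E[0] = 0.0  # padding/unknown row stays zero
        kd = kernel_size * embed_dim
        self.Wc = rng.normal(0, np.sqrt(2.0 / kd), size=(kd, filters))
        self.bc = np.zeros(filters)
        self.W1 = rng.normal(0, np.sqrt(2.0 / filters), size=(filters, dense_units))
        self.b1 = np.zeros(dense_units)
        self.W2 = rng.normal(0, np.sqrt(2.0 / dense_units), size=(dense_units, n_outputs))
        self.b2 = np.zeros(n_outputs)
        self._opt = _Adam(
            [p.shape for p in (self.E, self.Wc, self.bc, self.W1, self.b1, self.W2, self.b2)],
            lr=learning_rate,
        )

    # ---- forward/backward -------------------------------------------------

    def _windows(self, emb: np.ndarray) -> np.ndarray:
        b, length, dim = emb.shape
        k = self.kernel_size
        t = length - k + 1
        return np.concatenate([emb[:, o : o + t, :] for o in range(k)], axis=2)

    def _forward(self, X: np.ndarray):
        emb = self.E[X]                      # (B, L, D)
        xw = self._windows(emb)              # (B, T, k*D)
        z = xw @ self.Wc + self.bc           # (B, T, F)
        a = np.maximum(z, 0.0)
        pool_idx = a.argmax(axis=1)          # (B, F)
        pooled = a.max(axis=1)               # (B, F)
        h1 = np.maximum(pooled @ self.W1 + self.b1, 0.0)
        logits = h1 @ self.W2 + self.b2
        probs = _softmax(logits) if self.mode == "multiclass" else _sigmoid(logits)
        return emb, xw, z, pool_idx, pooled, h1, probs

    def _pad(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] < self.kernel_size:
            pad = np.zeros((X.shape[0], self.kernel_size - X.shape[1]), dtype=X.dtype)
            X = np.concatenate([X, pad], axis=1)
        return X

    def _batch_grads(self, X: np.ndarray, Y: np.ndarray):
        b, length = X.shape
        emb, xw, z, pool_idx, pooled, h1, probs = self._forward(X)
        dlogits = (probs - Y) / b
        dW2 = h1.T @ dlogits
        db2 = dlogits.sum(axis=0)
        dh1 = (dlogits @ self.W2.T) * (h1 > 0)
        dW1 = pooled.T @ dh1
        db1 = dh1.sum(axis=0)
        dpooled = dh1 @ self.W1.T            # (B, F)
        da = np.zeros_like(z)
        n_f = z.shape[2]
        da[np.arange(b)[:, None], pool_idx, np.arange(n_f)[None, :]] = dpooled
        dz = da * (z > 0)
        t = z.shape[1]
        kd = self.Wc.shape[0]
        dWc = xw.reshape(b * t, kd).T @ dz.reshape(b * t, n_f)
        dbc = dz.sum(axis=(0, 1))
        dE = None
        if self.trainable_embeddings:
            dxw = dz @ self.Wc.T             # (B, T, k*D)
            dim = emb.shape[2]
            demb = np.zeros_like(emb)
            for o in range(self.kernel_size):
                demb[:, o : o + t, :] += dxw[:, :, o * dim : (o + 1) * dim]
            dE = np.zeros_like(self.E)
            np.add.at(dE, X, demb)
            dE[0] = 0.0
        loss = self._loss(probs, Y)
        return (dE, dWc, dbc, dW1, db1, dW2, db2), loss

    def _loss(self, probs: np.ndarray, Y: np.ndarray) -> float:
        eps = 1e-12
        if self.mode == "multiclass":
            return float(-np.mean(np.log((probs * Y).sum(axis=1) + eps)))
        return float(
            -np.mean(Y * np.log(probs + eps) + (1 - Y) * np.log(1 - probs + eps))
        )

    # ---- public API -------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TextCNN":
        """Train on index sequences ``X`` (N, L) and one-hot/binary ``y`` (N, C)."""
        X = self._pad(np.asarray(X, dtype=np.int64))
        Y = np.asarray(y, dtype=np.float64)
        if Y.ndim != 2 or Y.shape[1] != self.n_outputs:
            raise ValueError("y must be one-hot (multiclass) or binary (multilabel)")
        n = len(X)
        order = self._rng.permutation(n)
        n_val = int(round(self.val_fraction * n))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        Xtr, Ytr, Xval, Yval = X[tr_idx], Y[tr_idx], X[val_idx], Y[val_idx]
        best_loss, best_state, bad = np.inf, None, 0
        for _ in range(self.epochs):
            perm = self._rng.permutation(len(Xtr))
            for s in range(0, len(Xtr), self.batch_size):
                idx = perm[s : s + self.batch_size]
                grads, _ = self._batch_grads(Xtr[idx], Ytr[idx])
                self._opt.step(
                    [self.E, self.Wc, self.bc, self.W1, self.b1, self.W2, self.b2],
                    grads,
                )
                self.E[0] = 0.0
            if n_val:
                val_loss = self._loss(self._forward(Xval)[-1], Yval)
            else:
                val_loss = self._loss(self._forward(Xtr)[-1], Ytr)
            if val_loss < best_loss - 1e-5:
                best_loss = val_loss
                best_state = [p.copy() for p in (self.E, self.Wc, self.bc, self.W1, self.b1, self.W2, self.b2)]
                bad = 0
            else:
                bad += 1
                if bad >= self.patience:
                    break
        if best_state is not None:
            self.E, self.Wc, self.bc, self.W1, self.b1, self.W2, self.b2 = best_state
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._pad(np.asarray(X, dtype=np.int64))
        out = []
        for s in range(0, len(X), 256):
            out.append(self._forward(X[s : s + 256])[-1])
        return np.concatenate(out, axis=0)
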