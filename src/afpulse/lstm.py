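"""Minimal numpy LSTM sequence regressor (dual-path architecture).

A compact, dependency-free implementation of the history-aware
correction model: two parallel processing paths, each a stack of four
LSTM layers with five units, followed by a fully connected layer with
eight neurons per path; the two paths are concatenated and connected to
a single linear output neuron. Inputs are (n, T, D) windows of minute
features with a (n, T) validity mask; masked steps carry the recurrent
state through unchanged (the update is skipped), and the prediction is
read at the final step (the minute under analysis).

Training is full backpropagation through time with Adam and global-norm
gradient clipping, deterministic under a fixed seed. Network sizes here
are tiny (tens of units, 10 time steps), so plain numpy is fast enough
by a wide margin.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40.0, 40.0)))


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    lim = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-lim, lim, size=shape)


class LSTMLayer:
    """Single LSTM layer with skip-update masking."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.D, self.H = input_dim, hidden
        self.Wx = _glorot(rng, (input_dim, 4 * hidden))
        self.Wh = _glorot(rng, (hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray, M: np.ndarray):
        """X: (n, T, D); M: (n, T) in {0,1}. Returns (H_seq, cache)."""
        n, T, _ = X.shape
        H = self.H
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        H_seq = np.zeros((n, T, H))
        cache = []
        for t in range(T):
            x_t = X[:, t, :]
            m = M[:, t : t + 1]
            z = x_t @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_pre = f * c + i * g
            tc = np.tanh(c_pre)
            h_pre = o * tc
            h_new = m * h_pre + (1.0 - m) * h
            c_new = m * c_pre + (1.0 - m) * c
            cache.append((x_t, h, c, i, f, g, o, tc, m))
            h, c = h_new, c_new
            H_seq[:, t, :] = h
        return H_seq, cache

    def backward(self, dH_seq: np.ndarray, cache):
        """dH_seq: (n, T, H) gradients w.r.t. the post-mask hidden states.

        Returns (dX, [dWx, dWh, db]).
        """
        n, T, H = dH_seq.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.zeros((n, T, self.D))
        dh_carry = np.zeros((n, H))
        dc_carry = np.zeros((n, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc, m = cache[t]
            dh = dH_seq[:, t, :] + dh_carry
            dc = dc_carry
            # undo the masked update: gradients split between the new
            # cell/hidden values and the carried-through previous state
            dh_pre = dh * m
            dc_pre = dc * m
            dh_passthrough = dh * (1.0 - m)
            dc_passthrough = dc * (1.0 - m)
            do = dh_pre * tc
            dc_pre = dc_pre + dh_pre * o * (1.0 - tc**2)
            df = dc_pre * c_prev
            di = dc_pre * g
            dg = dc_pre * i
            dc_prev = dc_pre * f + dc_passthrough
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t, :] = dz @ self.Wx.T
            dh_carry = dz @ self.Wh.T + dh_passthrough
            dc_carry = dc_prev
        return dX, [dWx, dWh, db]


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, (d_in, d_out))
        self.b = np.zeros(d_out)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray):
        return x @ self.W + self.b

    def backward(self, x: np.ndarray, dout: np.ndarray):
        return dout @ self.W.T, [x.T @ dout, dout.sum(axis=0)]


class DualPathLSTMRegressor:
    """Two parallel LSTM stacks over feature subsets, merged at a dense head.

    Parameters
    ----------
    path_slices : index lists splitting the feature axis between paths.
    hidden : LSTM units per layer (5).
    depth : stacked LSTM layers per path (4).
    dense_units : per-path fully connected width (8).
    """

    def __init__(
        self,
        path_slices: tuple[list[int], list[int]] = ([0, 1], [2, 3, 4]),
        hidden: int = 5,
        depth: int = 4,
        dense_units: int = 8,
        lr: float = 0.01,
        epochs: int = 60,
        batch_size: int = 256,
        clip_norm: float = 5.0,
        seed: int = 0,
    ):
        self.path_slices = path_slices
        self.hidden, self.depth, self.dense_units = hidden, depth, dense_units
        self.lr, self.epochs, self.batch_size = lr, epochs, batch_size
        self.clip_norm = clip_norm
        self.seed = seed
        self._built = False

    def _build(self) -> None:
        rng = np.random.default_rng(self.seed)
        self.paths = []
        for sl in self.path_slices:
            layers = []
            d_in = len(sl)
            for _ in range(self.depth):
                layers.append(LSTMLayer(d_in, self.hidden, rng))
                d_in = self.hidden
            dense = _Dense(self.hidden, self.dense_units, rng)
            self.paths.append((layers, dense))
        self.head = _Dense(self.dense_units * len(self.path_slices), 1, rng)
        self._rng = rng
        self._built = True

    def _params(self) -> list[np.ndarray]:
        out = []
        for layers, dense in self.paths:
            for lay in layers:
                out.extend(lay.params)
            out.extend(dense.params)
        out.extend(self.head.params)
        return out

    def _forward(self, X: np.ndarray, M: np.ndarray, want_cache: bool = False):
        feats = []
        caches = []
        for (layers, dense), sl in zip(self.paths, self.path_slices):
            h = X[:, :, sl]
            path_cache = []
            for lay in layers:
                h, cache = lay.forward(h, M)
                path_cache.append(cache)
            h_last = h[:, -1, :]
            pre = dense.forward(h_last)
            act = np.maximum(pre, 0.0)
            feats.append(act)
            caches.append((path_cache, h_last, pre))
        merged = np.concatenate(feats, axis=1)
        yhat = self.head.forward(merged)[:, 0]
        if want_cache:
            return yhat, (caches, merged)
        return yhat

    def _backward(self, X, M, dyhat, fwd_cache):
        caches, merged = fwd_cache
        n, T, _ = X.shape
        grads = []
        dmerged, head_g = self.head.backward(merged, dyhat[:, None])
        offset = 0
        for (layers, dense), (path_cache, h_last, pre), sl in zip(
            self.paths, caches, self.path_slices
        ):
            k = self.dense_units
            dact = dmerged[:, offset : offset + k]
            offset += k
            dpre = dact * (pre > 0.0)
            dh_last, dense_g = dense.backward(h_last, dpre)
            dH = np.zeros((n, T, self.hidden))
            dH[:, -1, :] = dh_last
            layer_grads = []
            for lay, cache in zip(reversed(layers), reversed(path_cache)):
                dH, g = lay.backward(dH, cache)
                layer_grads.append(g)
            for g in reversed(layer_grads):
                grads.extend(g)
            grads.extend(dense_g)
        grads.extend(head_g)
        return grads

    def fit(self, X: np.ndarray, M: np.ndarray, y: np.ndarray) -> "DualPathLSTMRegressor":
        X = np.asarray(X, dtype=float)
        M = np.asarray(M, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3 or M.shape != X.shape[:2] or len(y) != len(X):
            raise ValueError("X must be (n, T, D) with matching mask and target")
        self._build()
        params = self._params()
        m_adam = [np.zeros_like(p) for p in params]
        v_adam = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(X)
        for _epoch in range(self.epochs):
            order = self._rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                xb, mb, yb = X[idx], M[idx], y[idx]
                yhat, cache = self._forward(xb, mb, want_cache=True)
                err = yhat - yb
                if not np.all(np.isfinite(err)):
                    raise FloatingPointError("non-finite training loss")
                dyhat = 2.0 * err / len(idx)
                grads = self._backward(xb, mb, dyhat, cache)
                gnorm = np.sqrt(sum(float(np.sum(g**2)) for g in grads))
                if gnorm > self.clip_norm:
                    grads = [g * (self.clip_norm / gnorm) for g in grads]
                step += 1
                for p, g, ma, va in zip(params, grads, m_adam, v_adam):
                    ma *= b1
                    ma += (1 - b1) * g
                    va *= b2
                    va += (1 - b2) * g**2
                    mhat = ma / (1 - b1**step)
                    vhat = va / (1 - b2**step)
                    p -= self.lr * mhat / (np.sqrt(vhat) + eps)
        return self

    def predict(self, X: np.ndarray, M: np.ndarray) -> np.ndarray:
        if not self._built:
            raise RuntimeError("model is not fitted")
        yhat = self._forward(np.asarray(X, dtype=float), np.asarray(M, dtype=float))
        if not np.all(np.isfinite(yhat)):
            raise FloatingPointError("non-finite predictions")
        return yhat

    def loss(self, X, M, y) -> float:
        return float(np.mean((self.predict(X, M) - np.asarray(y, dtype=float)) ** 2))
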