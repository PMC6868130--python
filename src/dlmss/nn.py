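"""A NumPy bidirectional LSTM for per-time-step sequence classification.

One bidirectional LSTM layer followed by a per-step dense softmax.  The
implementation is self-contained: forward pass, backpropagation through
time, and an Adam optimizer, all on plain ndarrays.  Sequences inside a
batch must share one length (training uses fixed windows; inference runs
one full-length trajectory at a time), which keeps the code free of
padding and masking logic.

Gate layout in the fused weight matrices is [input, forget, cell, output].
"""

from __future__ import annotations

import numpy as np

from .exceptions import ParameterError

__all__ = ["BiLSTM", "Adam", "softmax", "cross_entropy"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean per-step categorical cross-entropy."""
    p = np.take_along_axis(probs, labels[..., None], axis=-1)
    return float(-np.mean(np.log(np.maximum(p, 1e-12))))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _orthogonal(rng: np.random.Generator, shape: tuple[int, int], dtype) -> np.ndarray:
    a = rng.standard_normal(shape)
    q, r = np.linalg.qr(a if shape[0] >= shape[1] else a.T)
    q = q * np.sign(np.diag(r))
    if shape[0] < shape[1]:
        q = q.T
    return q[: shape[0], : shape[1]].astype(dtype)


class BiLSTM:
    """Bidirectional LSTM tagger: (B, T, F) features → (B, T, C) class probs."""

    def __init__(
        self,
        n_features: int,
        hidden_units: int,
        n_classes: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        if hidden_units < 1:
            raise ParameterError(f"hidden_units must be >= 1, got {hidden_units}")
        if n_classes < 2:
            raise ParameterError(f"n_classes must be >= 2, got {n_classes}")
        self.n_features = n_features
        self.hidden_units = hidden_units
        self.n_classes = n_classes
        self.dtype = dtype
        F, H, C = n_features, hidden_units, n_classes
        scale_in = 1.0 / np.sqrt(F)
        self.params: dict[str, np.ndarray] = {}
        for d in ("f", "b"):
            self.params[f"W_{d}"] = (
                rng.uniform(-scale_in, scale_in, size=(F, 4 * H)).astype(dtype)
            )
            # orthogonal recurrent weights, one block per gate
            U = np.concatenate(
                [_orthogonal(rng, (H, H), dtype) for _ in range(4)], axis=1
            )
            self.params[f"U_{d}"] = U
            b = np.zeros(4 * H, dtype=dtype)
            b[H : 2 * H] = 1.0  # forget-gate bias starts open
            self.params[f"b_{d}"] = b
        scale_out = 1.0 / np.sqrt(2 * H)
        self.params["W_out"] = rng.uniform(
            -scale_out, scale_out, size=(2 * H, C)
        ).astype(dtype)
        self.params["b_out"] = np.zeros(C, dtype=dtype)

    # ---------------- forward ----------------

    def _lstm_pass(self, X: np.ndarray, d: str):
        """Unidirectional pass over (B, T, F); returns hidden states + cache."""
        B, T, _ = X.shape
        H = self.hidden_units
        W, U, b = self.params[f"W_{d}"], self.params[f"U_{d}"], self.params[f"b_{d}"]
        h = np.zeros((B, H), dtype=self.dtype)
        c = np.zeros((B, H), dtype=self.dtype)
        pre = X.reshape(B * T, -1) @ W
        pre = pre.reshape(B, T, 4 * H) + b
        hs = np.empty((B, T, H), dtype=self.dtype)
        cache = []
        for t in range(T):
            a = pre[:, t] + h @ U
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h_prev = h
            h = o * tanh_c
            hs[:, t] = h
            cache.append((i, f, g, o, c_prev, tanh_c, h_prev))
        return hs, cache

    def forward(self, X: np.ndarray, want_cache: bool = False):
        """Class probabilities (B, T, C); optionally the BPTT cache."""
        X = np.ascontiguousarray(X, dtype=self.dtype)
        hs_f, cache_f = self._lstm_pass(X, "f")
        Xr = X[:, ::-1]
        hs_b_rev, cache_b = self._lstm_pass(Xr, "b")
        hs_b = hs_b_rev[:, ::-1]
        Hcat = np.concatenate([hs_f, hs_b], axis=-1)
        logits = Hcat @ self.params["W_out"] + self.params["b_out"]
        probs = softmax(logits.astype(np.float64))
        if not want_cache:
            return probs
        return probs, (X, Xr, hs_f, cache_f, hs_b_rev, cache_b, Hcat)

    # ---------------- backward ----------------

    def _lstm_backward(self, X: np.ndarray, dH: np.ndarray, cache, d: str):
        """BPTT through one direction; dH is (B, T, H) in that direction's time order."""
        B, T, _ = X.shape
        H = self.hidden_units
        U = self.params[f"U_{d}"]
        dW = np.zeros_like(self.params[f"W_{d}"])
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params[f"b_{d}"])
        dh_next = np.zeros((B, H), dtype=self.dtype)
        dc_next = np.zeros((B, H), dtype=self.dtype)
        da_all = np.empty((B, T, 4 * H), dtype=self.dtype)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tanh_c, h_prev = cache[t]
            dh = dH[:, t] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            da_all[:, t] = da
            dU += h_prev.T @ da
            dh_next = da @ U.T
            dc_next = dc * f
        flat_X = X.reshape(B * T, -1)
        flat_da = da_all.reshape(B * T, -1)
        dW += flat_X.T @ flat_da
        db += flat_da.sum(axis=0)
        return dW, dU, db

    def backward(self, probs: np.ndarray, labels: np.ndarray, cache):
        """Gradients of mean cross-entropy w.r.t. all parameters."""
        X, Xr, hs_f, cache_f, hs_b_rev, cache_b, Hcat = cache
        B, T, C = probs.shape
        H = self.hidden_units
        dlogits = probs.copy()
        np.put_along_axis(
            dlogits, labels[..., None], np.take_along_axis(dlogits, labels[..., None], -1) - 1.0, -1
        )
        dlogits = (dlogits / (B * T)).astype(self.dtype)
        grads: dict[str, np.ndarray] = {}
        flat_H = Hcat.reshape(B * T, 2 * H)
        flat_dl = dlogits.reshape(B * T, C)
        grads["W_out"] = flat_H.T @ flat_dl
        grads["b_out"] = flat_dl.sum(axis=0)
        dH = dlogits @ self.params["W_out"].T
        dH_f = dH[:, :, :H]
        dH_b = dH[:, ::-1, H:]  # backward direction runs on reversed time
        dW, dU, db = self._lstm_backward(X, dH_f, cache_f, "f")
        grads["W_f"], grads["U_f"], grads["b_f"] = dW, dU, db
        dW, dU, db = self._lstm_backward(Xr, dH_b, cache_b, "b")
        grads["W_b"], grads["U_b"], grads["b_b"] = dW, dU, db
        return grads

    def loss_and_grads(self, X: np.ndarray, labels: np.ndarray):
        probs, cache = self.forward(X, want_cache=True)
        loss = cross_entropy(probs, labels)
        return loss, self.backward(probs, labels, cache)

    # ---------------- persistence helpers ----------------

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(params[k], dtype=self.dtype)


class Adam:
    """Adam optimizer with global gradient-norm clipping."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 3e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        clip_norm: float | None = 5.0,
    ) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        if self.clip_norm is not None:
            norm = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values()))
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g**2
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(params[k].dtype)
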