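"""A minimal, self-contained CNN engine for 24x24 grayscale patches.

The network is deliberately small, sized for training sets of a few
hundred lesions: two 3x3 convolutional layers of 16 filters, a 2x2 max
pool, two more 3x3 convolutional layers of 32 filters, a second max pool,
then a single 64-unit dense layer flanked by 50% dropout on both sides and
a single sigmoid output giving the probability of malignancy.  All
convolutions are zero-padded ("same"), so the spatial path is
24 -> 24 -> 12 -> 12 -> 6, flattening to 6*6*32 = 1152 features.

Everything — im2col convolution, pooling, dropout, Adam, binary
cross-entropy on logits — is implemented directly on numpy arrays.  The
engine is CPU-only and fully deterministic given its seed.  The 64-unit
dense activations are exposed as the penultimate ("pre-softmax") feature
representation used for t-SNE visualization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

INPUT_SIZE = 24
DTYPE = np.float32


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer widths of the patch classifier."""

    filters_block1: int = 16
    filters_block2: int = 32
    dense_units: int = 64
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if min(self.filters_block1, self.filters_block2, self.dense_units) < 1:
            raise ValueError("layer widths must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0,1)")


# ---------------------------------------------------------------------------
# layer primitives (NHWC layout)
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    """Overflow-safe logistic function."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N,H,W,C) -> (N,H,W,9*C) of 3x3 neighborhoods, zero-padded."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((n, h, w, 9, c), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, :, k, :] = xp[:, di : di + h, dj : dj + w, :]
            k += 1
    return cols.reshape(n, h, w, 9 * c)


def _col2im(dcols: np.ndarray, c: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, h, w, _ = dcols.shape
    dcols = dcols.reshape(n, h, w, 9, c)
    dxp = np.zeros((n, h + 2, w + 2, c), dtype=dcols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, di : di + h, dj : dj + w, :] += dcols[:, :, :, k, :]
            k += 1
    return dxp[:, 1:-1, 1:-1, :]


def _pool2_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4))
    mask = xr == out[:, :, None, :, None, :]
    return out, mask


def _pool2_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n, hh, _, ww, _, c = mask.shape
    dxr = mask * dout[:, :, None, :, None, :]
    return dxr.reshape(n, hh * 2, ww * 2, c)


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            self.params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class SmallCNN:
    """The patch classifier.  Inputs are standardized 24x24 arrays."""

    def __init__(self, arch: ArchitectureSpec | None = None, seed: int = 0) -> None:
        self.arch = arch or ArchitectureSpec()
        self.seed = seed
        rng = np.random.default_rng(seed)
        f1, f2, d = self.arch.filters_block1, self.arch.filters_block2, self.arch.dense_units
        self.flat_dim = (INPUT_SIZE // 4) ** 2 * f2

        def he(fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
            return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)

        self.params: dict[str, np.ndarray] = {
            "W1": he(9, (9, f1)), "b1": np.zeros(f1, DTYPE),
            "W2": he(9 * f1, (9 * f1, f1)), "b2": np.zeros(f1, DTYPE),
            "W3": he(9 * f1, (9 * f1, f2)), "b3": np.zeros(f2, DTYPE),
            "W4": he(9 * f2, (9 * f2, f2)), "b4": np.zeros(f2, DTYPE),
            "W5": he(self.flat_dim, (self.flat_dim, d)), "b5": np.zeros(d, DTYPE),
            "W6": he(d, (d, 1)), "b6": np.zeros(1, DTYPE),
        }

    # -- forward -----------------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None):
        p = self.params
        rate = self.arch.dropout_rate
        cache: dict[str, np.ndarray] = {}

        a = x[..., None]  # (N,24,24,1)
        for i, (wk, bk) in enumerate([("W1", "b1"), ("W2", "b2")], start=1):
            cols = _im2col(a)
            z = cols @ p[wk] + p[bk]
            a = np.maximum(z, 0.0)
            cache[f"cols{i}"], cache[f"relu{i}"] = cols, a > 0
        a, cache["pmask1"] = _pool2_forward(a)
        for i, (wk, bk) in enumerate([("W3", "b3"), ("W4", "b4")], start=3):
            cols = _im2col(a)
            z = cols @ p[wk] + p[bk]
            a = np.maximum(z, 0.0)
            cache[f"cols{i}"], cache[f"relu{i}"] = cols, a > 0
        a, cache["pmask2"] = _pool2_forward(a)
        flat = a.reshape(a.shape[0], self.flat_dim)

        if train and rate > 0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            d1 = ((rng.random(flat.shape) >= rate) / (1 - rate)).astype(DTYPE)
            flat = flat * d1
            cache["drop1"] = d1
        z5 = flat @ p["W5"] + p["b5"]
        h = np.maximum(z5, 0.0)  # penultimate 64-d features
        cache["flat"], cache["relu5"], cache["features"] = flat, z5 > 0, h
        hd = h
        if train and rate > 0:
            d2 = ((rng.random(h.shape) >= rate) / (1 - rate)).astype(DTYPE)
            hd = h * d2
            cache["drop2"] = d2
        cache["hd"] = hd
        logits = (hd @ p["W6"] + p["b6"]).ravel()
        return logits, cache

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(self._check(x), train=False, rng=None)
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probability of malignancy per patch; deterministic (no dropout)."""
        return _sigmoid(self.predict_logits(x))

    def penultimate_features(self, x: np.ndarray) -> np.ndarray:
        """The 64-unit dense-layer activations (pre-softmax features)."""
        _, cache = self._forward(self._check(x), train=False, rng=None)
        return cache["features"]

    @staticmethod
    def _check(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != (INPUT_SIZE, INPUT_SIZE):
            raise ValueError(f"expected (n, {INPUT_SIZE}, {INPUT_SIZE}) input, got {x.shape}")
        return x

    # -- training ----------------------------------------------------------
    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean binary cross-entropy (on logits) and its parameter grads."""
        x = self._check(x)
        y = np.asarray(y, dtype=DTYPE)
        n = x.shape[0]
        p = self.params
        logits, cache = self._forward(x, train=True, rng=rng)
        prob = _sigmoid(logits)
        loss = float(np.mean(
            np.logaddexp(0.0, logits) - y * logits
        ))
        grads: dict[str, np.ndarray] = {}
        dlogit = ((prob - y)[:, None] / n).astype(DTYPE)  # (N,1)

        grads["W6"] = cache["hd"].T @ dlogit
        grads["b6"] = dlogit.sum(axis=0)
        dh = dlogit @ p["W6"].T
        if "drop2" in cache:
            dh = dh * cache["drop2"]
        dz5 = dh * cache["relu5"]
        grads["W5"] = cache["flat"].T @ dz5
        grads["b5"] = dz5.sum(axis=0)
        dflat = dz5 @ p["W5"].T
        if "drop1" in cache:
            dflat = dflat * cache["drop1"]

        side = INPUT_SIZE // 4
        f2 = self.arch.filters_block2
        da = dflat.reshape(n, side, side, f2)
        da = _pool2_backward(da, cache["pmask2"])
        for i, wk, bk in [(4, "W4", "b4"), (3, "W3", "b3")]:
            dz = da * cache[f"relu{i}"]
            grads[wk] = np.tensordot(cache[f"cols{i}"], dz, axes=([0, 1, 2], [0, 1, 2]))
            grads[bk] = dz.sum(axis=(0, 1, 2))
            da = _col2im(dz @ p[wk].T, p[wk].shape[0] // 9)
        da = _pool2_backward(da, cache["pmask1"])
        for i, wk, bk in [(2, "W2", "b2"), (1, "W1", "b1")]:
            dz = da * cache[f"relu{i}"]
            grads[wk] = np.tensordot(cache[f"cols{i}"], dz, axes=([0, 1, 2], [0, 1, 2]))
            grads[bk] = dz.sum(axis=(0, 1, 2))
            da = _col2im(dz @ p[wk].T, p[wk].shape[0] // 9)
        return loss, grads

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=DTYPE).copy()
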