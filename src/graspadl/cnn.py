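"""Small-grid convolutional classifier, implemented directly on NumPy.

Architecture (fixed by default, every hyperparameter overridable)::

    conv(1 -> 16, 2x2, stride 1, pad 1) + BN + ReLU + maxpool(2x2, stride 2)
    conv(16 -> 32, 2x2, stride 1, pad 1) + BN + ReLU + maxpool(2x2, stride 2)
    conv(32 -> 32, 2x2, stride 1, pad 1) + BN + ReLU
    flatten -> linear(-> n_classes), 50% dropout at the end

trained with plain SGD (lr 0.01), cross-entropy loss, 20 epochs, batches of
40.  Feature vectors are laid row-major onto the smallest near-square grid
(zero-padded tail) before entering the network.

No deep-learning framework is available in the runtime environment, so the
layers (including batch-norm statistics and full backpropagation) are
implemented here; they follow the conventional definitions, and gradients
are verified against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from graspadl.features import FeatureMatrix
from graspadl.classify import EvalResult, run_folds

__all__ = ["CnnConfig", "SmallGridCNN", "reshape_for_cnn", "train_eval_cnn"]


@dataclass(frozen=True)
class CnnConfig:
    conv_out_channels: tuple[int, int, int] = (16, 32, 32)
    kernel: int = 2
    stride: int = 1
    padding: int = 1
    pool_after_layers: tuple[int, ...] = (1, 2)
    dropout: float = 0.5
    learning_rate: float = 0.01
    epochs: int = 20
    batch_size: int = 40
    seed: int = 0
    n_classes: int = 8

    def __post_init__(self) -> None:
        if len(self.conv_out_channels) != 3:
            raise ValueError("expected three convolution layers")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("bad training hyperparameters")


def reshape_for_cnn(samples: np.ndarray) -> np.ndarray:
    """Lay feature vectors row-major onto the smallest near-square grid.

    ``h = floor(sqrt(m))``, ``w = ceil(m / h)``; the tail of the last row is
    zero-padded.  Accepts one m-vector or an (n, m) matrix; returns
    (n, 1, h, w).
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    n, m = X.shape
    if m == 0:
        raise ValueError("cannot reshape zero-length feature vectors")
    h = int(np.floor(np.sqrt(m)))
    w = int(np.ceil(m / h))
    grid = np.zeros((n, h * w))
    grid[:, :m] = X
    return grid.reshape(n, 1, h, w)


# ---------------------------------------------------------------------------
# layers


class _Conv2d:
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        fan_in = c_in * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.W = rng.uniform(-bound, bound, size=(c_out, fan_in))
        self.b = rng.uniform(-bound, bound, size=c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def describe(self) -> str:
        return f"conv({self.c_in}->{self.c_out}, {self.k}x{self.k}, stride {self.stride}, pad {self.pad})"

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        B, C, H, W = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        sw = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]  # B,C,Ho,Wo,k,k
        cols = sw.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * k * k, Ho * Wo)
        return cols, (B, C, H, W, Ho, Wo)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols, shape = self._im2col(x)
        B, C, H, W, Ho, Wo = shape
        out = np.einsum("oc,bcl->bol", self.W, cols) + self.b[None, :, None]
        self._cache = (cols, shape)
        return out.reshape(B, self.c_out, Ho, Wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (B, C, H, W, Ho, Wo) = self._cache
        d = dout.reshape(B, self.c_out, Ho * Wo)
        self.dW = np.einsum("bol,bcl->oc", d, cols)
        self.db = d.sum(axis=(0, 2))
        dcols = np.einsum("oc,bol->bcl", self.W, d)  # B, C*k*k, L
        p, k, s = self.pad, self.k, self.stride
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
        dcols = dcols.reshape(B, C, k, k, Ho, Wo)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + Ho * s : s, j : j + Wo * s : s] += dcols[:, :, i, j]
        return dxp[:, :, p : p + H, p : p + W]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _BatchNorm2d:
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros(c)
        self.dbeta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.eps, self.momentum = eps, momentum

    def describe(self) -> str:
        return f"batchnorm({len(self.gamma)})"

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        mean_d = dout.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dx = (dout * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return g * (dout - mean_d - xhat * mean_dx)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class _ReLU:
    def describe(self) -> str:
        return "relu"

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class _MaxPool2d:
    """2x2 max pooling with stride 2; trailing odd row/column dropped."""

    def describe(self) -> str:
        return "maxpool(2x2, stride 2)"

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, W = x.shape
        if H < 2 or W < 2:
            raise ValueError(f"spatial size {H}x{W} too small for 2x2 pooling")
        Ho, Wo = H // 2, W // 2
        xc = x[:, :, : Ho * 2, : Wo * 2].reshape(B, C, Ho, 2, Wo, 2)
        out = xc.max(axis=(3, 5))
        self._cache = (x.shape, xc, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        shape, xc, out = self._cache
        mask = xc == out[:, :, :, None, :, None]
        # split gradient evenly among tied maxima to keep the map well defined
        counts = mask.sum(axis=(3, 5), keepdims=True)
        d = mask * (dout[:, :, :, None, :, None] / counts)
        B, C, H, W = shape
        Ho, Wo = H // 2, W // 2
        dx = np.zeros(shape)
        dx[:, :, : Ho * 2, : Wo * 2] = d.reshape(B, C, Ho * 2, Wo * 2)
        return dx

    def params(self):
        return []


class _Flatten:
    def describe(self) -> str:
        return "flatten"

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self):
        return []


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_out, n_in))
        self.b = rng.uniform(-bound, bound, size=n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def describe(self) -> str:
        return f"linear({self.W.shape[1]}->{self.W.shape[0]})"

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _Dropout:
    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def describe(self) -> str:
        return f"dropout({self.p})"

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []


# ---------------------------------------------------------------------------
# network


class SmallGridCNN:
    """Three conv blocks + linear head on a single-channel feature grid."""

    def __init__(self, input_hw: tuple[int, int], cfg: CnnConfig = CnnConfig()):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        h, w = input_hw
        if h < 1 or w < 1:
            raise ValueError("input grid must be at least 1x1")
        layers: list = []
        c_in = 1
        for i, c_out in enumerate(cfg.conv_out_channels, start=1):
            layers.append(_Conv2d(c_in, c_out, cfg.kernel, cfg.stride, cfg.padding, self.rng))
            h = (h + 2 * cfg.padding - cfg.kernel) // cfg.stride + 1
            w = (w + 2 * cfg.padding - cfg.kernel) // cfg.stride + 1
            layers.append(_BatchNorm2d(c_out))
            layers.append(_ReLU())
            if i in cfg.pool_after_layers:
                if h < 2 or w < 2:
                    raise ValueError(
                        f"grid shrank to {h}x{w} before pool {i}; feature vector too short"
                    )
                layers.append(_MaxPool2d())
                h, w = h // 2, w // 2
            c_in = c_out
        layers.append(_Flatten())
        layers.append(_Linear(c_in * h * w, cfg.n_classes, self.rng))
        layers.append(_Dropout(cfg.dropout, self.rng))
        self.layers = layers

    def describe(self) -> list[str]:
        return [layer.describe() for layer in self.layers]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def sgd_step(self, lr: float) -> None:
        for layer in self.layers:
            for p, g in layer.params():
                p -= lr * g

    @staticmethod
    def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        B = len(y)
        loss = -np.mean(np.log(probs[np.arange(B), y] + 1e-300))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        return float(loss), dlogits / B

    def fit(self, X: np.ndarray, y: np.ndarray) -> list[float]:
        """Train with seeded shuffling; returns per-epoch mean losses."""
        cfg = self.cfg
        n = X.shape[0]
        losses = []
        for _ in range(cfg.epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = self.forward(X[idx], train=True)
                loss, dlogits = self.cross_entropy(logits, y[idx])
                self.backward(dlogits)
                self.sgd_step(cfg.learning_rate)
                epoch_loss += loss * len(idx)
            losses.append(epoch_loss / n)
        return losses

    def predict(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        preds = []
        for start in range(0, X.shape[0], batch_size):
            logits = self.forward(X[start : start + batch_size], train=False)
            preds.append(np.argmax(logits, axis=1))  # ties -> lowest class index
        return np.concatenate(preds)


def train_eval_cnn(
    fm: FeatureMatrix,
    folds: np.ndarray,
    cfg: CnnConfig = CnnConfig(),
) -> EvalResult:
    """K-fold evaluation of the CNN; standardization fitted per training fold,
    feature vectors reshaped to grids, one freshly seeded network per fold."""

    def fit_predict(X_train, y_train, X_test, fold_idx):
        Xtr = reshape_for_cnn(X_train)
        Xte = reshape_for_cnn(X_test)
        fold_cfg = CnnConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * fold_idx})
        net = SmallGridCNN(Xtr.shape[2:], fold_cfg)
        net.fit(Xtr, np.asarray(y_train))
        return net.predict(Xte)

    config = {"model": "cnn", **{k: v for k, v in cfg.__dict__.items()}}
    return run_folds(fm, folds, fit_predict, config)
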