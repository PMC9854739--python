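"""Desk-scale trainer backends for hyperparameter-tuning experiments.

Both backends are small, deterministic numpy models trained by minibatch
SGD with momentum, an L2 penalty and a piecewise learning-rate schedule
(the rate is multiplied by ``RateDropFactor`` every
``LearnRateDropPeriod`` epochs).  They exist so that every tunable
training option — ``InitialLearnRate``, ``MiniBatchSize``, ``MaxEpochs``,
``Momentum``, ``L2Regularization``, ``RateDropFactor``,
``LearnRateDropPeriod`` — has a real, observable effect on validation
accuracy while a single fitness evaluation stays in the tens of
milliseconds on one CPU.

* ``linear`` — regularized logistic regression on average-pooled pixel
  features; the default backend for optimization runs and tests.
* ``cnn`` — a tiny convolutional network (two 3x3 conv blocks with
  max-pooling, one dense sigmoid output) on inputs pooled to 32x32,
  implemented with im2col; epochs are capped at 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["TrainerContract", "pooled_features", "train_and_score", "LinearModel", "TinyCNN"]


@dataclass
class TrainerContract:
    """Which backend to use and the budget it must respect."""

    backend: str = "linear"  # "linear" or "cnn"
    max_epochs: int | None = None
    max_samples: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("linear", "cnn"):
            raise ValueError(f"unknown trainer backend {self.backend!r}")


def pooled_features(images: np.ndarray, out_size: int = 8) -> np.ndarray:
    """Mean- and max-pool (n, h, w) images to (n, 2*out_size**2) flat features.

    The mean channel captures overall tissue intensity; the max channel
    makes a small bright focal structure linearly detectable wherever it
    falls in the grid.
    """
    n, h, w = images.shape
    if h % out_size or w % out_size:
        crop_h, crop_w = h - h % out_size, w - w % out_size
        images = images[:, :crop_h, :crop_w]
        h, w = crop_h, crop_w
    fh, fw = h // out_size, w // out_size
    blocks = images.reshape(n, out_size, fh, out_size, fw)
    mean_pool = blocks.mean(axis=(2, 4)).reshape(n, -1)
    max_pool = blocks.max(axis=(2, 4)).reshape(n, -1)
    flat = images.reshape(n, -1)
    top = np.sort(flat, axis=1)[:, -max(flat.shape[1] // 100, 1) :].mean(axis=1)
    summary = np.column_stack([flat.mean(axis=1), flat.max(axis=1), top])
    return np.concatenate([mean_pool, max_pool, summary], axis=1)


def _epoch_lr(base: float, epoch: int, drop_factor: float, drop_period: int) -> float:
    """Piecewise schedule: multiply the rate by drop_factor every drop_period epochs."""
    return base * drop_factor ** (epoch // max(int(drop_period), 1))


def _minibatches(n: int, batch: int, rng: np.random.Generator, shuffle: bool):
    order = rng.permutation(n) if shuffle else np.arange(n)
    for start in range(0, n, batch):
        yield order[start : start + batch]


class LinearModel:
    """Logistic regression on pooled pixels, trained by momentum SGD."""

    def __init__(self, hyper: dict, seed: int = 0, max_epochs: int | None = None):
        self.hyper = dict(hyper)
        self.seed = seed
        self.max_epochs = max_epochs
        self.w: np.ndarray | None = None
        self.b: float = 0.0
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    def _features(self, images: np.ndarray) -> np.ndarray:
        x = pooled_features(images)
        if self._mu is None:
            self._mu = x.mean(axis=0)
            self._sd = x.std(axis=0) + 1e-8
        return (x - self._mu) / self._sd

    def fit(self, images: np.ndarray, labels: np.ndarray) -> "LinearModel":
        rng = np.random.default_rng(self.seed)
        x = self._features(images)
        y = np.asarray(labels, dtype=float)
        n, d = x.shape
        lr0 = float(self.hyper["InitialLearnRate"])
        batch = int(self.hyper["MiniBatchSize"])
        epochs = int(self.hyper["MaxEpochs"])
        if self.max_epochs is not None:
            epochs = min(epochs, self.max_epochs)
        mom = float(self.hyper["Momentum"])
        l2 = float(self.hyper["L2Regularization"])
        drop = float(self.hyper["RateDropFactor"])
        period = int(self.hyper["LearnRateDropPeriod"])
        shuffle = self.hyper.get("Shuffle", "every-epoch") == "every-epoch"

        self.w = np.zeros(d)
        self.b = 0.0
        vw, vb = np.zeros(d), 0.0
        for epoch in range(epochs):
            lr = _epoch_lr(lr0, epoch, drop, period)
            for idx in _minibatches(n, batch, rng, shuffle):
                xb, yb = x[idx], y[idx]
                z = xb @ self.w + self.b
                p = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
                err = p - yb
                gw = xb.T @ err / len(idx) + l2 * self.w
                gb = float(err.mean())
                vw = mom * vw - lr * gw
                vb = mom * vb - lr * gb
                self.w += vw
                self.b += vb
                if not (np.all(np.isfinite(self.w)) and math.isfinite(self.b)):
                    raise FloatingPointError("training diverged to non-finite weights")
        return self

    def predict(self, images: np.ndarray) -> np.ndarray:
        x = self._features(images)
        return (x @ self.w + self.b > 0).astype(int)


# ---------------------------------------------------------------------------
# tiny convolutional network (im2col)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(n, c, h, w) -> (n, out_h*out_w, c*k*k) patch matrix for valid 3x3 conv."""
    n, c, h, w = x.shape
    oh, ow = h - k + 1, w - k + 1
    s0, s1, s2, s3 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, oh, ow, k, k), strides=(s0, s1, s2, s3, s2, s3)
    )
    return patches.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)


class _ConvLayer:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (c_in * k * k))
        self.w = rng.standard_normal((c_out, c_in * k * k)) * scale
        self.b = np.zeros(c_out)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._in_shape = x.shape
        self._cols = _im2col(x, self.k)  # (n, P, c*k*k)
        out = self._cols @ self.w.T + self.b  # (n, P, c_out)
        oh = h - self.k + 1
        return out.transpose(0, 2, 1).reshape(n, self.c_out, oh, oh)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c_out, oh, ow = grad.shape
        g = grad.reshape(n, c_out, oh * ow).transpose(0, 2, 1)  # (n, P, c_out)
        # upstream grad already carries the 1/batch loss normalization
        self.gw = np.einsum("npo,npk->ok", g, self._cols)
        self.gb = g.sum(axis=(0, 1))
        gcols = g @ self.w  # (n, P, c*k*k)
        # scatter patch gradients back (col2im)
        _, c, h, w = self._in_shape
        gx = np.zeros(self._in_shape)
        gcols = gcols.reshape(n, oh, ow, c, self.k, self.k)
        for di in range(self.k):
            for dj in range(self.k):
                gx[:, :, di : di + oh, dj : dj + ow] += gcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return gx

    def sgd(self, lr: float, mom: float, l2: float) -> None:
        self.vw = mom * self.vw - lr * (self.gw + l2 * self.w)
        self.vb = mom * self.vb - lr * self.gb
        self.w += self.vw
        self.b += self.vb


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    oh, ow = h // 2, w // 2
    blocks = (
        x[:, :, : oh * 2, : ow * 2]
        .reshape(n, c, oh, 2, ow, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, oh, ow, 4)
    )
    arg = blocks.argmax(axis=-1)
    return blocks.max(axis=-1), arg


def _maxpool2_backward(grad: np.ndarray, arg: np.ndarray, in_shape: tuple) -> np.ndarray:
    n, c, h, w = in_shape
    oh, ow = h // 2, w // 2
    gx = np.zeros((n, c, oh, ow, 4))
    np.put_along_axis(gx, arg[..., None], grad[..., None], axis=-1)
    gx = (
        gx.reshape(n, c, oh, ow, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, oh * 2, ow * 2)
    )
    out = np.zeros(in_shape)
    out[:, :, : oh * 2, : ow * 2] = gx
    return out


class TinyCNN:
    """Two conv blocks + dense sigmoid head on 32x32 inputs (epochs capped at 10)."""

    EPOCH_CAP = 10

    def __init__(self, hyper: dict, seed: int = 0, max_epochs: int | None = None):
        self.hyper = dict(hyper)
        self.seed = seed
        cap = self.EPOCH_CAP if max_epochs is None else min(max_epochs, self.EPOCH_CAP)
        self.max_epochs = cap

    @staticmethod
    def _inputs(images: np.ndarray) -> np.ndarray:
        n, h, w = images.shape
        if h != 32:
            factor = h // 32
            if factor >= 1 and h % 32 == 0:
                images = images.reshape(n, 32, factor, 32, factor).mean(axis=(2, 4))
            else:
                raise ValueError("cnn backend expects image sides that pool to 32")
        return images[:, None, :, :]  # (n, 1, 32, 32)

    def fit(self, images: np.ndarray, labels: np.ndarray) -> "TinyCNN":
        rng = np.random.default_rng(self.seed)
        x_all = self._inputs(images)
        y_all = np.asarray(labels, dtype=float)
        n = len(y_all)
        lr0 = float(self.hyper["InitialLearnRate"])
        batch = int(self.hyper["MiniBatchSize"])
        epochs = min(int(self.hyper["MaxEpochs"]), self.max_epochs)
        mom = float(self.hyper["Momentum"])
        l2 = float(self.hyper["L2Regularization"])
        drop = float(self.hyper["RateDropFactor"])
        period = int(self.hyper["LearnRateDropPeriod"])
        shuffle = self.hyper.get("Shuffle", "every-epoch") == "every-epoch"

        self.conv1 = _ConvLayer(1, 8, 3, rng)   # 32 -> 30 -> pool 15
        self.conv2 = _ConvLayer(8, 16, 3, rng)  # 15 -> 13 -> pool 6
        d_flat = 16 * 6 * 6
        self.wd = rng.standard_normal(d_flat) * math.sqrt(1.0 / d_flat)
        self.bd = 0.0
        vwd, vbd = np.zeros(d_flat), 0.0

        for epoch in range(epochs):
            lr = _epoch_lr(lr0, epoch, drop, period)
            for idx in _minibatches(n, batch, rng, shuffle):
                xb, yb = x_all[idx], y_all[idx]
                # forward
                c1 = self.conv1.forward(xb)
                r1 = np.maximum(c1, 0.0)
                p1, arg1 = _maxpool2(r1)
                c2 = self.conv2.forward(p1)
                r2 = np.maximum(c2, 0.0)
                p2, arg2 = _maxpool2(r2)
                flat = p2.reshape(len(idx), -1)
                z = flat @ self.wd + self.bd
                prob = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
                # backward (mean logistic loss)
                err = (prob - yb) / len(idx)
                gwd = flat.T @ err + l2 * self.wd
                gbd = float(err.sum())
                gflat = np.outer(err, self.wd).reshape(p2.shape)
                g2 = _maxpool2_backward(gflat, arg2, r2.shape) * (c2 > 0)
                g1 = self.conv2.backward(g2)
                g1 = _maxpool2_backward(g1, arg1, r1.shape) * (c1 > 0)
                self.conv1.backward(g1)
                self.conv2.sgd(lr, mom, l2)
                self.conv1.sgd(lr, mom, l2)
                vwd = mom * vwd - lr * gwd
                vbd = mom * vbd - lr * gbd
                self.wd += vwd
                self.bd += vbd
                if not np.all(np.isfinite(self.wd)):
                    raise FloatingPointError("training diverged to non-finite weights")
        return self

    def predict(self, images: np.ndarray) -> np.ndarray:
        x = self._inputs(images)
        c1 = np.maximum(self.conv1.forward(x), 0.0)
        p1, _ = _maxpool2(c1)
        c2 = np.maximum(self.conv2.forward(p1), 0.0)
        p2, _ = _maxpool2(c2)
        z = p2.reshape(len(images), -1) @ self.wd + self.bd
        return (z > 0).astype(int)


def train_and_score(
    hyper: dict,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    eval_images: np.ndarray,
    eval_labels: np.ndarray,
    contract: TrainerContract,
) -> float:
    """Train the contracted backend and return accuracy on the eval split."""
    if contract.max_samples is not None and len(train_labels) > contract.max_samples:
        train_images = train_images[: contract.max_samples]
        train_labels = train_labels[: contract.max_samples]
    cls = LinearModel if contract.backend == "linear" else TinyCNN
    model = cls(hyper, seed=contract.seed, max_epochs=contract.max_epochs)
    model.fit(train_images, train_labels)
    pred = model.predict(eval_images)
    return float((pred == eval_labels).mean())
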