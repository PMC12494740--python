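"""A small convolutional network implemented directly on numpy.

Architecture (fixed topology, configurable widths):

    conv(3x3, F1, pad 1) -> ReLU -> maxpool(2, stride 2)
    -> conv(3x3, F2, pad 1) -> ReLU -> maxpool(2, stride 2)
    -> flatten -> FC(512) -> ReLU -> FC(n_classes)

Spectral channels enter as the input feature channels, so reducing the
spectral dimension changes only the first convolution's input arithmetic.
Convolutions use im2col matrix products; pooling halves each spatial axis
(odd trailing rows/columns are dropped). Training uses softmax cross-entropy
with a hand-written Adam optimiser, so runs are bit-deterministic given the
seed. Everything is float64: these models are tiny and exactness is worth
more here than throughput.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["CNNSpec", "SmallCNN", "Adam", "softmax_cross_entropy"]


@dataclass(frozen=True)
class CNNSpec:
    """Widths of the two-conv / two-FC classification network.

    ``in_channels`` is the spectral channel count after band selection;
    kernel 3, pool 2/stride 2 and a 512-node hidden FC layer are fixed.
    """

    in_channels: int
    n_classes: int
    spatial: tuple[int, int]
    conv_filters: tuple[int, int] = (16, 32)
    fc_hidden: int = 512

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.n_classes < 2:
            raise ValidationError("need in_channels >= 1 and n_classes >= 2")
        if min(self.spatial) < 4:
            raise ValidationError(
                f"spatial extent {self.spatial} too small for two 2x2 pool stages"
            )

    @property
    def pooled_spatial(self) -> tuple[int, int]:
        y, x = self.spatial
        return (y // 2 // 2, x // 2 // 2)

    @property
    def flatten_size(self) -> int:
        py, px = self.pooled_spatial
        return py * px * self.conv_filters[1]

    @property
    def n_parameters(self) -> int:
        f1, f2 = self.conv_filters
        return (
            (self.in_channels * 9 + 1) * f1
            + (f1 * 9 + 1) * f2
            + (self.flatten_size + 1) * self.fc_hidden
            + (self.fc_hidden + 1) * self.n_classes
        )


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patches for a stride-1 'same' convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # view: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int],
            k: int = 3, pad: int = 1) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back to the image."""
    n, c, h, w = shape
    d = dcols.reshape(n, h, w, c, k, k)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di:di + h, dj:dj + w] += d[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return dxp[:, :, pad:pad + h, pad:pad + w]


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-300)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class SmallCNN:
    """The two-conv / two-FC network with explicit forward/backward passes."""

    def __init__(self, spec: CNNSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        c, (f1, f2) = spec.in_channels, spec.conv_filters

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        self.params: dict[str, np.ndarray] = {
            "W1": he((f1, c * 9), c * 9), "b1": np.zeros(f1),
            "W2": he((f2, f1 * 9), f1 * 9), "b2": np.zeros(f2),
            "W3": he((spec.flatten_size, spec.fc_hidden), spec.flatten_size),
            "b3": np.zeros(spec.fc_hidden),
            "W4": he((spec.fc_hidden, spec.n_classes), spec.fc_hidden),
            "b4": np.zeros(spec.n_classes),
        }
        self._cache: dict[str, np.ndarray] = {}

    # -- forward -----------------------------------------------------------

    def _conv(self, x, W, b, tag):
        n, _, h, w = x.shape
        cols = _im2col(x)
        out = cols @ W.T + b
        self._cache[f"cols{tag}"] = cols
        self._cache[f"xshape{tag}"] = x.shape
        return out.reshape(n, h, w, W.shape[0]).transpose(0, 3, 1, 2)

    def _pool(self, x, tag):
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        r = x[:, :, :ho * 2, :wo * 2]
        r = r.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        idx = r.argmax(axis=-1)
        self._cache[f"poolidx{tag}"] = idx
        self._cache[f"poolshape{tag}"] = x.shape
        return np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """``x``: (N, spectral channels, H, W) -> (N, n_classes) logits."""
        cache = self._cache if train else {}
        saved, self._cache = self._cache, cache

        a1 = self._conv(x, self.params["W1"], self.params["b1"], "1")
        r1 = np.maximum(a1, 0.0)
        p1 = self._pool(r1, "1")
        a2 = self._conv(p1, self.params["W2"], self.params["b2"], "2")
        r2 = np.maximum(a2, 0.0)
        p2 = self._pool(r2, "2")
        flat = p2.reshape(x.shape[0], -1)
        h1 = flat @ self.params["W3"] + self.params["b3"]
        rh = np.maximum(h1, 0.0)
        logits = rh @ self.params["W4"] + self.params["b4"]

        cache.update(a1=a1, p1=p1, a2=a2, p2shape=p2.shape, flat=flat, h1=h1, rh=rh)
        if not train:
            self._cache = saved
        return logits

    # -- backward ----------------------------------------------------------

    def _conv_back(self, dout, W, tag):
        n, f, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, f)
        cols = self._cache[f"cols{tag}"]
        dW = dflat.T @ cols
        db = dflat.sum(axis=0)
        dcols = dflat @ W
        return _col2im(dcols, self._cache[f"xshape{tag}"]), dW, db

    def _pool_back(self, dout, tag):
        n, c, h, w = self._cache[f"poolshape{tag}"]
        ho, wo = h // 2, w // 2
        idx = self._cache[f"poolidx{tag}"]
        dr = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w))
        dx[:, :, :ho * 2, :wo * 2] = (
            dr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho * 2, wo * 2)
        )
        return dx

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every parameter (after a train forward)."""
        c = self._cache
        grads: dict[str, np.ndarray] = {}
        grads["W4"] = c["rh"].T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        drh = dlogits @ self.params["W4"].T
        dh1 = drh * (c["h1"] > 0)
        grads["W3"] = c["flat"].T @ dh1
        grads["b3"] = dh1.sum(axis=0)
        dflat = dh1 @ self.params["W3"].T
        dp2 = dflat.reshape(c["p2shape"])
        dr2 = self._pool_back(dp2, "2")
        da2 = dr2 * (c["a2"] > 0)
        dp1, dW2, db2 = self._conv_back(da2, self.params["W2"], "2")
        grads["W2"], grads["b2"] = dW2, db2
        dr1 = self._pool_back(dp1, "1")
        da1 = dr1 * (c["a1"] > 0)
        _, dW1, db1 = self._conv_back(da1, self.params["W1"], "1")
        grads["W1"], grads["b1"] = dW1, db1
        return grads

    # -- state -------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Class predictions for a batch of inputs (no caching)."""
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(self.forward(x[i:i + batch_size], train=False).argmax(axis=1))
        return np.concatenate(out)


class Adam:
    """Adam with bias correction; the learning rate is set per step by the caller."""

    def __init__(self, params: dict[str, np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
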