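"""Minimal numpy neural-network kernels for small 2D/3D residual networks.

All tensors are ``(N, C, D, H, W)`` float32; 2D networks are expressed as 3D
networks with a singleton depth axis and depth-1 kernels, which keeps a single
convolution implementation for both families.  Convolutions use
``sliding_window_view`` + einsum in the forward pass and an offset-loop
scatter in the backward pass: exact gradients, adequate speed at the patch
sizes used here (9 x 9 spatial, tens of bands), no external frameworks.

Conventions match the usual residual-network recipe: convolutions carry no
bias when followed by batch norm, "same" padding of k // 2 per axis, output
sizes floored at 1 along the spectral axis so deep stacks remain valid on
shallow volumes.
"""

from __future__ import annotations

import numpy as np

from .exceptions import SizeError

__all__ = [
    "Param", "Layer", "Conv3d", "BatchNorm", "ReLU", "MaxPool3d",
    "GlobalAvgPool", "Linear", "Sequential", "Parallel", "Residual",
    "Network", "Adam", "SGD", "softmax", "cross_entropy",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def __call__(self, x, train=True):
        return self.forward(x, train)


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(u) for u in v)
    if len(t) != 3:
        raise SizeError(f"expected a 3-tuple, got {v!r}")
    return t


class Conv3d(Layer):
    """3-D convolution, no bias (batch norm always follows in these nets)."""

    def __init__(self, in_channels: int, out_channels: int, kernel, stride=1,
                 rng: np.random.Generator | None = None, name: str = ""):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        fan_in = in_channels * int(np.prod(self.kernel))
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (out_channels, in_channels, *self.kernel))
        self.weight = Param(w, name + ".weight")
        self._cache = None

    def _pads(self, shape) -> tuple[int, int, int]:
        # "same" padding, raised where the volume is shallower than the kernel
        pads = []
        for size, k in zip(shape, self.kernel):
            p = k // 2
            if size + 2 * p < k:
                p = -(-(k - size) // 2)
            pads.append(p)
        return tuple(pads)

    def forward(self, x, train=True):
        if x.ndim != 5 or x.shape[1] != self.in_channels:
            raise SizeError(
                f"conv expects (N, {self.in_channels}, D, H, W), got {x.shape}")
        pads = self._pads(x.shape[2:])
        pd, ph, pw = pads
        padded = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        win = np.lib.stride_tricks.sliding_window_view(
            padded, self.kernel, axis=(2, 3, 4))
        sd, sh, sw = self.stride
        win = win[:, :, ::sd, ::sh, ::sw]          # (N, C, od, oh, ow, kd, kh, kw)
        n, c, od, oh, ow = win.shape[:5]
        # im2col + one sgemm per conv is much faster than einsum here
        xmat = np.ascontiguousarray(
            win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(n * od * oh * ow, -1)
        wmat = self.weight.value.reshape(self.out_channels, -1)
        out = (xmat @ wmat.T).reshape(n, od, oh, ow, self.out_channels)
        self._cache = (xmat, (n, c, od, oh, ow), padded.shape, pads, x.shape)
        return np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))

    def backward(self, gy):
        xmat, (n, c, od, oh, ow), padded_shape, pads, x_shape = self._cache
        o = self.out_channels
        gymat = np.ascontiguousarray(gy.transpose(0, 2, 3, 4, 1)).reshape(-1, o)
        self.weight.grad += (gymat.T @ xmat).reshape(self.weight.value.shape)
        wmat = self.weight.value.reshape(o, -1)
        gcols = (gymat @ wmat).reshape(n, od, oh, ow, c, *self.kernel)
        gxp = np.zeros(padded_shape, dtype=np.float32)
        sd, sh, sw = self.stride
        kd, kh, kw = self.kernel
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    gxp[:, :,
                        i: i + sd * od: sd,
                        j: j + sh * oh: sh,
                        k: k + sw * ow: sw] += gcols[..., i, j, k].transpose(
                            0, 4, 1, 2, 3)
        pd, ph, pw = pads
        _, _, D, H, Wd = x_shape
        return gxp[:, :, pd:pd + D, ph:ph + H, pw:pw + Wd]

    def params(self):
        return [self.weight]


class BatchNorm(Layer):
    """Batch normalization over (N, D, H, W) per channel."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = ""):
        self.gamma = Param(np.ones(channels), name + ".gamma")
        self.beta = Param(np.zeros(channels), name + ".beta")
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x, train=True):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        shape = (1, -1, 1, 1, 1)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        self._cache = (xhat, invstd, x.shape)
        return (self.gamma.value.reshape(shape) * xhat
                + self.beta.value.reshape(shape)).astype(np.float32)

    def backward(self, gy):
        xhat, invstd, x_shape = self._cache
        axes = (0, 2, 3, 4)
        n_eff = gy.size // gy.shape[1]
        shape = (1, -1, 1, 1, 1)
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = self.gamma.value.reshape(shape)
        sum_gy = gy.sum(axis=axes, keepdims=True)
        sum_gy_xhat = (gy * xhat).sum(axis=axes, keepdims=True)
        gx = (g * invstd.reshape(shape) / n_eff) * (
            n_eff * gy - sum_gy - xhat * sum_gy_xhat)
        return gx.astype(np.float32)

    def params(self):
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, gy):
        return np.where(self._mask, gy, 0.0).astype(np.float32)


class MaxPool3d(Layer):
    """Max pooling with padding (window - 1) // 2; window clamped to the input."""

    def __init__(self, window, stride=None):
        self.window = _triple(window)
        self.stride = _triple(stride) if stride is not None else self.window

    def forward(self, x, train=True):
        n, c = x.shape[:2]
        dims = x.shape[2:]
        pads = tuple((k - 1) // 2 for k in self.window)
        eff = tuple(min(k, d + 2 * p)
                    for k, d, p in zip(self.window, dims, pads))
        padded = np.pad(x, ((0, 0), (0, 0)) + tuple((p, p) for p in pads),
                        constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(padded, eff, axis=(2, 3, 4))
        sd, sh, sw = self.stride
        win = win[:, :, ::sd, ::sh, ::sw]
        flat = win.reshape(*win.shape[:5], -1)
        self._arg = flat.argmax(axis=-1)
        out = flat.max(axis=-1).astype(np.float32)
        self._cache = (padded.shape, eff, x.shape, pads)
        return out

    def backward(self, gy):
        padded_shape, eff, x_shape, pads = self._cache
        gxp = np.zeros(padded_shape, dtype=np.float32)
        n, c, od, oh, ow = gy.shape
        sd, sh, sw = self.stride
        odi, ohi, owi = np.unravel_index(self._arg, eff)
        nn_, cc, dd, hh, ww = np.indices((n, c, od, oh, ow), sparse=False)
        np.add.at(gxp, (nn_, cc, dd * sd + odi, hh * sh + ohi, ww * sw + owi), gy)
        pd, ph, pw = pads
        _, _, D, H, W = x_shape
        return gxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W]


class GlobalAvgPool(Layer):
    """Mean over all spatial/spectral positions -> (N, C)."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4)).astype(np.float32)

    def backward(self, gy):
        n, c, d, h, w = self._shape
        scale = 1.0 / (d * h * w)
        return (np.broadcast_to(gy[:, :, None, None, None],
                                self._shape) * scale).astype(np.float32)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, name: str = ""):
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.weight = Param(rng.uniform(-limit, limit,
                                        (out_features, in_features)),
                            name + ".weight")
        self.bias = Param(np.zeros(out_features), name + ".bias")

    def forward(self, x, train=True):
        self._x = x
        return (x @ self.weight.value.T + self.bias.value).astype(np.float32)

    def backward(self, gy):
        self.weight.grad += gy.T @ self._x
        self.bias.grad += gy.sum(axis=0)
        return (gy @ self.weight.value).astype(np.float32)

    def params(self):
        return [self.weight, self.bias]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Parallel(Layer):
    """Run children on the same input and concatenate outputs along channels."""

    def __init__(self, *children: Layer):
        self.children = list(children)

    def forward(self, x, train=True):
        outs = [child.forward(x, train) for child in self.children]
        self._widths = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, gy):
        gx = None
        start = 0
        for child, w in zip(self.children, self._widths):
            g = child.backward(gy[:, start:start + w])
            gx = g if gx is None else gx + g
            start += w
        return gx

    def params(self):
        return [p for child in self.children for p in child.params()]


class Residual(Layer):
    """y = ReLU(main(x) + shortcut(x)); shortcut None means identity."""

    def __init__(self, main: Layer, shortcut: Layer | None = None):
        self.main = main
        self.shortcut = shortcut

    def forward(self, x, train=True):
        y = self.main.forward(x, train)
        s = self.shortcut.forward(x, train) if self.shortcut is not None else x
        out = y + s
        self._mask = out > 0
        return np.where(self._mask, out, 0.0).astype(np.float32)

    def backward(self, gy):
        gy = np.where(self._mask, gy, 0.0).astype(np.float32)
        gx = self.main.backward(gy)
        if self.shortcut is not None:
            gx = gx + self.shortcut.backward(gy)
        else:
            gx = gx + gy
        return gx

    def params(self):
        ps = self.main.params()
        if self.shortcut is not None:
            ps = ps + self.shortcut.params()
        return ps


class Network(Sequential):
    """A full classifier: layer stack plus its input contract.

    ``is3d`` networks take patches as single-channel ``(N, 1, B, S, S)``
    volumes; 2-D networks take them as B-channel ``(N, B, 1, S, S)`` images.
    :meth:`predict_proba` accepts patches in dataset layout ``(N, S, S, B)``.
    """

    def __init__(self, layers, is3d: bool, in_channels: int, n_classes: int,
                 name: str = "network"):
        super().__init__(*layers)
        self.is3d = is3d
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.name = name

    def patches_to_input(self, patches: np.ndarray) -> np.ndarray:
        if patches.ndim != 4:
            raise SizeError(f"patches must be (N, S, S, B), got {patches.shape}")
        x = patches.transpose(0, 3, 1, 2).astype(np.float32)  # (N, B, S, S)
        return x[:, None] if self.is3d else x[:, :, None]

    def logits(self, patches: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(self.patches_to_input(patches), train)

    def predict_proba(self, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
        probs = []
        for start in range(0, len(patches), batch_size):
            probs.append(softmax(self.logits(patches[start:start + batch_size])))
        return np.concatenate(probs, axis=0)

    def predict(self, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class ids in 1..K."""
        return self.predict_proba(patches, batch_size).argmax(axis=1) + 1

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits; y in 0..K-1."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), y] + eps).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class SGD:
    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.params, self._v):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v


class Adam:
    def __init__(self, params: list[Param], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self._t += 1
        bc1 = 1.0 - self.b1 ** self._t
        bc2 = 1.0 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
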