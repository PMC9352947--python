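"""Minimal 3-D CNN layer library (NumPy, explicit backprop).

Tensors are ``[N, C, D, H, W]``; here D indexes the stacked ECG/VCG
leads and H, W are the two recurrence-image axes. Convolution is
im2col + matmul; every layer caches what its backward pass needs and
exposes ``parameters()`` as (name, value, grad) triples for the
optimizer. ``training`` toggles batch-norm statistics and dropout.

Only what the recurrence-volume classifier needs is implemented:
conv3d (arbitrary kernels/strides, same/valid padding), batch norm,
ReLU, non-overlapping max pooling, global average pooling, dropout,
dense — plus the Sequential container.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv3d", "BatchNorm3d", "ReLU", "MaxPool3d",
    "GlobalAvgPool3d", "Dropout", "Flatten", "Dense", "Sequential",
]


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, int):
        return (v, v, v)
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected 3 ints, got {v!r}")
    return t


class Layer:
    """Base layer: stateless unless it declares parameters."""

    trainable: bool = True
    name: str = ""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self):
        """Yield (name, value, grad) triples for trainable params."""
        return iter(())

    def set_rng(self, rng: np.random.Generator) -> None:
        pass


class Conv3d(Layer):
    """3-D convolution over [N, C, D, H, W] via im2col.

    ``padding`` is "same" (TF convention, output = ceil(size/stride))
    or "valid". Weights are He-initialized; pass ``zero_init=True``
    for an all-zero layer (used by the zero-logit prediction head).
    """

    def __init__(self, c_in: int, c_out: int, kernel, stride=1,
                 padding: str = "same", bias: bool = True,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32, zero_init: bool = False, name: str = ""):
        self.c_in, self.c_out = c_in, c_out
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        if padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid', got {padding!r}")
        self.padding = padding
        self.name = name or f"conv{self.kernel}"
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = c_in * int(np.prod(self.kernel))
        if zero_init:
            self.w = np.zeros((c_out, c_in, *self.kernel), dtype=dtype)
        else:
            self.w = (rng.standard_normal((c_out, c_in, *self.kernel))
                      * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype) if bias else None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b) if bias else None
        self._cache = None

    def _pad_amounts(self, shape):
        pads = []
        for size, k, s in zip(shape, self.kernel, self.stride):
            if self.padding == "same":
                out = -(-size // s)
                total = max((out - 1) * s + k - size, 0)
                pads.append((total // 2, total - total // 2))
            else:
                if size < k:
                    raise ValueError(
                        f"{self.name}: input extent {size} smaller than kernel "
                        f"{k} with valid padding — spatial dims collapsed")
                pads.append((0, 0))
        return pads

    def _offsets(self):
        kd, kh, kw = self.kernel
        for a in range(kd):
            for b in range(kh):
                for c in range(kw):
                    yield a, b, c

    def _slice(self, a, b, c, do, ho, wo):
        sd, sh, sw = self.stride
        return (slice(None), slice(None),
                slice(a, a + do * sd, sd),
                slice(b, b + ho * sh, sh),
                slice(c, c + wo * sw, sw))

    def forward(self, x, training=False):
        # Shift-and-matmul: one (C_out x C_in) GEMM per kernel offset on
        # a strided slice of the padded input — much cheaper than a full
        # im2col gather for the small kernels used here.
        n, c, d, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"{self.name}: expected {self.c_in} input channels, got {c}")
        pads = self._pad_amounts((d, h, w))
        xp = np.pad(x, ((0, 0), (0, 0), *pads)) if any(p != (0, 0) for p in pads) else x
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        do = (xp.shape[2] - kd) // sd + 1
        ho = (xp.shape[3] - kh) // sh + 1
        wo = (xp.shape[4] - kw) // sw + 1
        if min(do, ho, wo) < 1:
            raise ValueError(f"{self.name}: output spatial dims collapsed to "
                             f"({do},{ho},{wo}) for input ({d},{h},{w})")
        acc = np.zeros((self.c_out, n, do, ho, wo), dtype=x.dtype)
        flat = acc.reshape(self.c_out, -1)
        for a, b, cc in self._offsets():
            xs = xp[self._slice(a, b, cc, do, ho, wo)]
            flat += self.w[:, :, a, b, cc] @ xs.reshape(n, c, -1).transpose(
                1, 0, 2).reshape(c, -1)
        out = np.ascontiguousarray(acc.transpose(1, 0, 2, 3, 4))
        if self.b is not None:
            out += self.b.reshape(1, -1, 1, 1, 1)
        self._cache = (xp, pads, (n, do, ho, wo))
        return out

    def backward(self, grad):
        xp, pads, (n, do, ho, wo) = self._cache
        p = do * ho * wo
        # [C_out, N*P] gradient matrix, contiguous once.
        g2 = np.ascontiguousarray(grad.transpose(1, 0, 2, 3, 4)).reshape(
            self.c_out, n * p)
        if self.b is not None:
            self.gb[...] = g2.sum(axis=1)
        dxp = np.zeros(xp.shape, dtype=grad.dtype)
        for a, b, cc in self._offsets():
            sl = self._slice(a, b, cc, do, ho, wo)
            xs = xp[sl].reshape(n, self.c_in, p).transpose(1, 0, 2).reshape(
                self.c_in, n * p)
            self.gw[:, :, a, b, cc] = g2 @ xs.T
            dxs = (self.w[:, :, a, b, cc].T @ g2).reshape(
                self.c_in, n, do, ho, wo).transpose(1, 0, 2, 3, 4)
            dxp[sl] += dxs
        (pd0, pd1), (ph0, ph1), (pw0, pw1) = pads
        return dxp[:, :, pd0:dxp.shape[2] - pd1, ph0:dxp.shape[3] - ph1,
                   pw0:dxp.shape[4] - pw1]

    def parameters(self):
        if self.trainable:
            yield (f"{self.name}.w", self.w, self.gw)
            if self.b is not None:
                yield (f"{self.name}.b", self.b, self.gb)


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32, name: str = ""):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.name = name or "bn"
        self._cache = None

    def forward(self, x, training=False):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * mean)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        shape = (1, -1, 1, 1, 1)
        xhat = (x - mean.reshape(shape)) / std.reshape(shape)
        self._cache = (xhat, std, training)
        return self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)

    def backward(self, grad):
        xhat, std, training = self._cache
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        self.ggamma[...] = (grad * xhat).sum(axis=axes)
        self.gbeta[...] = grad.sum(axis=axes)
        g = grad * self.gamma.reshape(shape)
        if not training:
            return g / std.reshape(shape)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        return (g - g.mean(axis=axes).reshape(shape)
                - xhat * (g * xhat).sum(axis=axes).reshape(shape) / m
                ) / std.reshape(shape)

    def parameters(self):
        if self.trainable:
            yield (f"{self.name}.gamma", self.gamma, self.ggamma)
            yield (f"{self.name}.beta", self.beta, self.gbeta)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool3d(Layer):
    """Non-overlapping max pooling (stride = kernel, valid padding).

    Trailing samples that do not fill a window are dropped.
    """

    def __init__(self, kernel=(1, 2, 2), name: str = ""):
        self.kernel = _triple(kernel)
        self.name = name or f"maxpool{self.kernel}"

    def forward(self, x, training=False):
        n, c, d, h, w = x.shape
        kd, kh, kw = self.kernel
        do, ho, wo = d // kd, h // kh, w // kw
        if min(do, ho, wo) < 1:
            raise ValueError(f"{self.name}: input ({d},{h},{w}) smaller than "
                             f"pool window {self.kernel} — spatial dims collapsed")
        xc = x[:, :, :do * kd, :ho * kh, :wo * kw]
        win = xc.reshape(n, c, do, kd, ho, kh, wo, kw)
        win = win.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, do, ho, wo, kd * kh * kw)
        self._arg = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, grad):
        n, c, d, h, w = self._in_shape
        kd, kh, kw = self.kernel
        do, ho, wo = d // kd, h // kh, w // kw
        dwin = np.zeros((n, c, do, ho, wo, kd * kh * kw), dtype=grad.dtype)
        np.put_along_axis(dwin, self._arg[..., None], grad[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dwin = dwin.reshape(n, c, do, ho, wo, kd, kh, kw).transpose(
            0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, do * kd, ho * kh, wo * kw)
        dx[:, :, :do * kd, :ho * kh, :wo * kw] = dwin
        return dx


class GlobalAvgPool3d(Layer):
    """[N, C, D, H, W] -> [N, C] mean over all spatial axes."""

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad):
        n, c, d, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None, None],
                               self._in_shape).copy() / (d * h * w)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. The RNG is injected by
    the model so training runs are reproducible from one seed."""

    def __init__(self, rate: float, name: str = "dropout"):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.name = name
        self.rng = np.random.default_rng(0)
        self._mask = None

    def set_rng(self, rng):
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng=None, dtype=np.float32,
                 zero_init: bool = False, name: str = "dense"):
        rng = rng if rng is not None else np.random.default_rng(0)
        if zero_init:
            self.w = np.zeros((c_out, c_in), dtype=dtype)
        else:
            self.w = (rng.standard_normal((c_out, c_in))
                      * np.sqrt(2.0 / c_in)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.name = name

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad):
        self.gw[...] = grad.T @ self._x
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.w

    def parameters(self):
        if self.trainable:
            yield (f"{self.name}.w", self.w, self.gw)
            yield (f"{self.name}.b", self.b, self.gb)


class Sequential(Layer):
    def __init__(self, *layers: Layer, name: str = "seq"):
        self.layers = list(layers)
        self.name = name

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        for layer in self.layers:
            yield from layer.parameters()

    def set_rng(self, rng):
        for layer in self.layers:
            layer.set_rng(rng)
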