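"""Minimal numpy neural-network layer library with manual backpropagation.

Implements exactly the pieces a small residual image classifier needs:
2-D convolution (im2col), batch normalization, ReLU, max pooling, global
average pooling, a linear head, residual basic blocks, and Adam.  Forward
passes cache what the matching backward pass needs; gradients accumulate on
``Param.grad`` and are consumed by :class:`Adam`.

Everything is deterministic given the ``numpy.random.Generator`` used at
construction time; there is no hidden global state.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _im2col(x, kh, kw, stride, pad):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, ho, wo, kh, kw),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    # (n*ho*wo, c*kh*kw)
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw
    )
    return cols, ho, wo


def _col2im(dcols, xshape, kh, kw, stride, pad, ho, wo):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dview = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dview[
                :, :, :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k×k convolution, stride/pad, no bias (always followed by batch norm)."""

    def __init__(self, cin, cout, k, stride=1, pad=None, rng=None, dtype=np.float32):
        self.k, self.stride = k, stride
        self.pad = (k // 2) if pad is None else pad
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, std, size=(cout, cin, k, k)).astype(dtype))
        self._cache = None

    def params(self):
        return [self.w]

    def forward(self, x, train=False):
        cols, ho, wo = _im2col(x, self.k, self.k, self.stride, self.pad)
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        y = cols @ wmat.T
        n = x.shape[0]
        y = y.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        self._cache = (x.shape, cols, ho, wo)
        return np.ascontiguousarray(y)

    def backward(self, dy):
        xshape, cols, ho, wo = self._cache
        n = xshape[0]
        cout = dy.shape[1]
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        self.w.grad += (dy_mat.T @ cols).reshape(self.w.value.shape)
        dcols = dy_mat @ self.w.value.reshape(cout, -1)
        return _col2im(dcols, xshape, self.k, self.k, self.stride, self.pad, ho, wo)


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv[None, :, None, None]
        if not train:
            return g * dy
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dy_mean = dy.mean(axis=(0, 2, 3))[None, :, None, None]
        proj = (dy * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return g * (dy - dy_mean - xhat * proj)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    def __init__(self, k=2, stride=None, pad=0):
        self.k, self.stride, self.pad = k, stride or k, pad

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = x.reshape(n * c, 1, h, w)
        if self.pad:
            xr = np.pad(
                xr,
                ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)),
                constant_values=-np.inf,
            )
        s = xr.strides
        ho = (xr.shape[2] - self.k) // self.stride + 1
        wo = (xr.shape[3] - self.k) // self.stride + 1
        view = np.lib.stride_tricks.as_strided(
            xr,
            shape=(n * c, ho, wo, self.k, self.k),
            strides=(s[0], s[2] * self.stride, s[3] * self.stride, s[2], s[3]),
            writeable=False,
        )
        flat = view.reshape(n * c, ho, wo, self.k * self.k)
        self._arg = flat.argmax(axis=3)
        y = np.take_along_axis(flat, self._arg[..., None], axis=3)[..., 0]
        self._xshape = (n, c, h, w)
        return y.reshape(n, c, ho, wo)

    def backward(self, dy):
        n, c, h, w = self._xshape
        ho, wo = dy.shape[2], dy.shape[3]
        dxp = np.zeros((n * c, h + 2 * self.pad, w + 2 * self.pad), dtype=dy.dtype)
        dyf = dy.reshape(n * c, ho, wo)
        ki = self._arg // self.k
        kj = self._arg % self.k
        rows = (np.arange(ho) * self.stride)[None, :, None] + ki
        cols = (np.arange(wo) * self.stride)[None, None, :] + kj
        idx0 = np.arange(n * c)[:, None, None]
        np.add.at(dxp, (idx0, rows, cols), dyf)
        if self.pad:
            dxp = dxp[:, self.pad : self.pad + h, self.pad : self.pad + w]
        return dxp.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, cin, cout, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(1.0 / cin)
        self.w = Param(rng.normal(0.0, std, size=(cout, cin)).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class BasicBlock(Layer):
    """Two 3×3 conv+BN with a shortcut; the shortcut projects (1×1 conv+BN)
    when the channel count or stride changes."""

    def __init__(self, cin, cout, stride=1, rng=None, dtype=np.float32):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(cout, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(cout, dtype=dtype)
        self.project = stride != 1 or cin != cout
        if self.project:
            self.conv_sc = Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng, dtype=dtype)
            self.bn_sc = BatchNorm2d(cout, dtype=dtype)

    def params(self):
        ps = (
            self.conv1.params()
            + self.bn1.params()
            + self.conv2.params()
            + self.bn2.params()
        )
        if self.project:
            ps += self.conv_sc.params() + self.bn_sc.params()
        return ps

    def forward(self, x, train=False):
        out = self.bn1.forward(self.conv1.forward(x, train), train)
        out = self.relu1.forward(out, train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        sc = x
        if self.project:
            sc = self.bn_sc.forward(self.conv_sc.forward(x, train), train)
        y = out + sc
        self._out_mask = y > 0
        return y * self._out_mask

    def backward(self, dy):
        dy = dy * self._out_mask
        d_main = self.conv2.backward(self.bn2.backward(dy))
        d_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(d_main)))
        if self.project:
            d_sc = self.conv_sc.backward(self.bn_sc.backward(dy))
        else:
            d_sc = dy
        return d_main + d_sc


class ResidualCNN:
    """Residual classifier: stem → residual stages → GAP → linear logits.

    The output of the last residual stage (post-ReLU) is the "final
    convolutional feature maps" handle used by Grad-CAM: after a forward
    pass it is stored in :attr:`feature_maps_`, and
    :meth:`grad_features` backpropagates a logit cotangent through the
    head only, returning d(logits·dlogits)/d(features).
    """

    def __init__(
        self,
        in_channels: int,
        num_classes: int,
        stem_channels: int,
        stem_kernel: int,
        stem_stride: int,
        stem_pool: int,
        stage_channels: tuple[int, ...],
        blocks_per_stage: tuple[int, ...],
        stage_strides: tuple[int, ...],
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        self.dtype = dtype
        body: list[Layer] = [
            Conv2d(in_channels, stem_channels, stem_kernel, stride=stem_stride, rng=rng, dtype=dtype),
            BatchNorm2d(stem_channels, dtype=dtype),
            ReLU(),
        ]
        if stem_pool:
            body.append(MaxPool2d(k=stem_pool, stride=2, pad=stem_pool // 2 if stem_pool > 2 else 0))
        cin = stem_channels
        for cout, nblocks, stride in zip(stage_channels, blocks_per_stage, stage_strides):
            for b in range(nblocks):
                body.append(BasicBlock(cin, cout, stride=stride if b == 0 else 1, rng=rng, dtype=dtype))
                cin = cout
        self.body = body
        self.gap = GlobalAvgPool()
        self.fc = Linear(cin, num_classes, rng=rng, dtype=dtype)
        self.n_features = cin
        self.feature_maps_: np.ndarray | None = None

    # -- plumbing ---------------------------------------------------------
    def params(self) -> list[Param]:
        ps: list[Param] = []
        for layer in self.body:
            ps += layer.params()
        return ps + self.fc.params()

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.params()):
            state[f"param_{i}"] = p.value
        bn_id = 0
        for layer in self._bn_layers():
            state[f"bn_{bn_id}_mean"] = layer.running_mean
            state[f"bn_{bn_id}_var"] = layer.running_var
            bn_id += 1
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"param_{i}"]
        bn_id = 0
        for layer in self._bn_layers():
            layer.running_mean[...] = state[f"bn_{bn_id}_mean"]
            layer.running_var[...] = state[f"bn_{bn_id}_var"]
            bn_id += 1

    def _bn_layers(self):
        for layer in self.body:
            if isinstance(layer, BatchNorm2d):
                yield layer
            elif isinstance(layer, BasicBlock):
                yield layer.bn1
                yield layer.bn2
                if layer.project:
                    yield layer.bn_sc

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        for layer in self.body:
            x = layer.forward(x, train)
        self.feature_maps_ = x
        pooled = self.gap.forward(x, train)
        return self.fc.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.grad_features(dlogits)
        for layer in reversed(self.body):
            d = layer.backward(d)
        return d

    def grad_features(self, dlogits: np.ndarray) -> np.ndarray:
        """Gradient of ``sum(logits * dlogits)`` w.r.t. the final feature maps."""
        d = self.fc.backward(np.asarray(dlogits, dtype=self.dtype))
        return self.gap.backward(d)

    def recalibrate_bn(self, batches) -> None:
        """Reset batch-norm running statistics to the average batch
        statistics over ``batches`` (an iterable of input tensors).

        With only a few hundred optimizer steps the momentum-tracked running
        stats lag the weights badly enough to wreck inference-mode outputs;
        one clean pass at the end fixes them.
        """
        bns = list(self._bn_layers())
        saved = [bn.momentum for bn in bns]
        for i, xb in enumerate(batches, start=1):
            for bn in bns:
                bn.momentum = 1.0 / i  # running average over batches
            self.forward(xb, train=True)
        for bn, mom in zip(bns, saved):
            bn.momentum = mom


class Adam:
    def __init__(self, params: list[Param], lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
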