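"""A small numpy neural-network engine: strided convolutions, dense layers,
ReLU, softmax cross-entropy and Adam.

Convolutions are decomposed over kernel offsets: one strided slice and one
small matmul per offset, in both the forward and backward passes, which
keeps temporaries output-sized instead of materializing im2col matrices.
Everything runs in float32.  The engine supports exactly what
the reduction networks in :mod:`perinet.nets` need — N-dimensional strided
convolution, flatten, fully connected layers — and is deliberately minimal.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ConvNd",
    "ReLU",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def _tuplify(v, ndim: int) -> tuple[int, ...]:
    if np.isscalar(v):
        return (int(v),) * ndim
    t = tuple(int(x) for x in v)
    if len(t) != ndim:
        raise ValueError(f"expected {ndim} values, got {t}")
    return t


class ConvNd:
    """N-dimensional convolution (cross-correlation) with stride and padding.

    Weights have shape ``(out_channels, in_channels, *kernel)``; inputs are
    channels-first ``(B, C, *spatial)``.  Internally the layer works
    channels-last and decomposes the convolution into one strided
    slice-and-matmul per kernel offset, which keeps temporaries small (one
    output-sized block per offset) instead of materializing a full im2col
    matrix.  ``needs_input_grad=False`` (e.g. for the first layer of a
    network) skips the input-gradient pass entirely.
    """

    def __init__(self, in_channels, out_channels, kernel, stride, padding, ndim, rng,
                 needs_input_grad=True):
        self.ndim = int(ndim)
        self.kernel = _tuplify(kernel, ndim)
        self.stride = _tuplify(stride, ndim)
        self.padding = _tuplify(padding, ndim)
        self.needs_input_grad = bool(needs_input_grad)
        fan_in = in_channels * int(np.prod(self.kernel))
        # He initialization for ReLU networks
        self.W = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels) + self.kernel
        ).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self._cache = None

    def out_shape(self, spatial) -> tuple[int, ...]:
        shape = []
        for d, k, s, p in zip(spatial, self.kernel, self.stride, self.padding):
            o = (d + 2 * p - k) // s + 1
            if o < 1:
                raise ValueError(
                    f"spatial dim {d} collapses below 1 under kernel {k}, "
                    f"stride {s}, padding {p}"
                )
            shape.append(o)
        return tuple(shape)

    def _phase_split(self, xp: np.ndarray) -> dict:
        """Split the padded input by stride phase along each spatial axis.

        A kernel offset ``a`` decomposes as ``a = s*t + r``; the slice it
        reads from the padded input is then a unit-stride window of the
        contiguous phase array ``r``, which makes the per-offset copies
        plain row memcpys instead of strided gathers.
        """
        phases = {}
        for r in np.ndindex(*self.stride):
            sl = tuple(slice(r[a], None, self.stride[a]) for a in range(self.ndim))
            phases[r] = np.ascontiguousarray(xp[(slice(None),) + sl])
        return phases

    def _phase_view(self, phases: dict, kidx, out_sp) -> np.ndarray:
        r = tuple(a % s for a, s in zip(kidx, self.stride))
        t = tuple(a // s for a, s in zip(kidx, self.stride))
        sl = tuple(slice(ti, ti + o) for ti, o in zip(t, out_sp))
        return phases[r][(slice(None),) + sl]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C = x.shape[:2]
        out_sp = self.out_shape(x.shape[2:])
        # channels-last, zero-padded copy of the input
        pad = [(0, 0)] + [(p, p) for p in self.padding] + [(0, 0)]
        xl = np.ascontiguousarray(np.moveaxis(x, 1, -1))
        xp = np.pad(xl, pad) if any(self.padding) else xl
        phases = self._phase_split(xp)
        y = np.zeros((B,) + out_sp + (self.W.shape[0],), dtype=np.float32)
        for kidx in np.ndindex(*self.kernel):
            wk = self.W[(slice(None), slice(None)) + kidx]  # (out_c, C)
            xs = self._phase_view(phases, kidx, out_sp)  # (B, *out, C)
            y += np.tensordot(xs, wk, axes=([-1], [1]))
        y += self.b
        if train:
            self._cache = (phases, xp.shape, x.shape, out_sp)
        return np.ascontiguousarray(np.moveaxis(y, -1, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        phases, xp_shape, x_shape, out_sp = self._cache
        dyl = np.ascontiguousarray(np.moveaxis(dy, 1, -1))  # (B, *out, out_c)
        self.db = dyl.reshape(-1, dyl.shape[-1]).sum(axis=0)
        self.dW = np.zeros_like(self.W)
        sum_axes = tuple(range(self.ndim + 1))  # batch + spatial
        dphases = (
            {r: np.zeros_like(p) for r, p in phases.items()}
            if self.needs_input_grad
            else None
        )
        for kidx in np.ndindex(*self.kernel):
            xs = self._phase_view(phases, kidx, out_sp)
            widx = (slice(None), slice(None)) + kidx
            # dW[:, :, kidx] = sum_{b, out} dy[b, out, :] (x) x[b, out_slice, :]
            self.dW[widx] = np.tensordot(dyl, xs, axes=(sum_axes, sum_axes))
            if dphases is not None:
                wk = self.W[widx]  # (out_c, C)
                self._phase_view(dphases, kidx, out_sp)[...] += np.tensordot(
                    dyl, wk, axes=([-1], [0])
                )
        self._cache = None
        if dphases is None:
            return None
        dxp = np.empty(xp_shape, dtype=np.float32)
        for r, dp in dphases.items():
            sl = tuple(slice(r[a], None, self.stride[a]) for a in range(self.ndim))
            dxp[(slice(None),) + sl] = dp
        if any(self.padding):
            core = (
                (slice(None),)
                + tuple(slice(p, p + d) for p, d in zip(self.padding, x_shape[2:]))
                + (slice(None),)
            )
            dxp = dxp[core]
        return np.ascontiguousarray(np.moveaxis(dxp, -1, 1))

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]

    def set_params(self, values):
        self.W, self.b = values[0].copy(), values[1].copy()


class ReLU:
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []

    def grads(self):
        return []

    def set_params(self, values):
        pass


class Flatten:
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []

    def grads(self):
        return []

    def set_params(self, values):
        pass


class Dense:
    def __init__(self, in_features, out_features, rng):
        self.W = rng.normal(
            0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features)
        ).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        dx = dy @ self.W
        self._x = None
        return dx

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]

    def set_params(self, values):
        self.W, self.b = values[0].copy(), values[1].copy()


class Sequential:
    """A plain layer stack with explicit forward/backward."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for _, p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state) -> None:
        it = iter(state)
        for layer in self.layers:
            n = len(layer.params())
            if n:
                layer.set_params([next(it) for _ in range(n)])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    B = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    ll = -np.log(np.clip(p[np.arange(B), labels], 1e-12, None))
    dlogits = p.copy()
    dlogits[np.arange(B), labels] -= 1.0
    return float(ll.mean()), (dlogits / B).astype(np.float32)


class Adam:
    """Adam with (coupled) weight decay: decay is added to the gradient."""

    def __init__(self, params, lr=1e-6, weight_decay=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            g = g.astype(np.float32)
            if self.weight_decay:
                g = g + self.weight_decay * p
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
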