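"""Minimal 3D convolutional network core in numpy.

Implements exactly the pieces a desk-scale 3D U-Net needs — 3x3x3 and 1x1x1
convolutions (im2col + BLAS matmul), instance normalization with learnable
affine, ReLU, 2x max pooling, 2x nearest-neighbour upsampling, softmax
cross-entropy and Adam — each with an explicit backward pass. Everything is
float32 and deterministic: weights are initialized from a seeded Generator
and no threading or fused kernels introduce run-to-run variation.

Tensors are channels-last, ``(N, D, H, W, C)``: the im2col matrix is then a
plain concatenation of shifted views whose reshape into the GEMM operand is
free, which is what makes CPU training tractable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet3D", "Adam", "softmax_cross_entropy", "softmax"]

_OFFSETS = [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]


def _im2col(x):
    """(N, D, H, W, C) -> (N*V, 27*C): zero-padded 3x3x3 neighborhoods,
    offset-major / channel-minor columns."""
    n, d, h, w, c = x.shape
    xp = np.zeros((n, d + 2, h + 2, w + 2, c), dtype=x.dtype)
    xp[:, 1:-1, 1:-1, 1:-1, :] = x
    cols = np.concatenate(
        [xp[:, dz : dz + d, dy : dy + h, dx : dx + w, :] for dz, dy, dx in _OFFSETS], axis=-1
    )
    return cols.reshape(n * d * h * w, 27 * c)


class Conv3x3:
    """Same-padded 3x3x3 convolution, He-initialized.

    Weight layout: ``W[c_out, k * c_in + c]`` with k the flattened 3x3x3
    offset; the full reverse of the offset axis equals the per-axis spatial
    flip, which the input-gradient computation relies on.
    """

    def __init__(self, c_in, c_out, rng, needs_input_grad=True):
        std = np.sqrt(2.0 / (c_in * 27))
        self.W = rng.normal(0.0, std, size=(c_out, 27 * c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out
        self.needs_input_grad = needs_input_grad
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        n, d, h, w, c = x.shape
        cols = _im2col(x)
        out = cols @ self.W.T + self.b
        if train:
            self._cols, self._shape = cols, (n, d, h, w, c)
        return out.reshape(n, d, h, w, self.c_out)

    def backward(self, g):
        n, d, h, w, c = self._shape
        gcol = g.reshape(n * d * h * w, self.c_out)
        self.dW += gcol.T @ self._cols
        self.db += gcol.sum(axis=0)
        if not self.needs_input_grad:  # first network layer: dx is unused
            self._cols = None
            return None
        # grad wrt input = convolution of g with spatially-flipped, transposed kernels
        W3 = self.W.reshape(self.c_out, 27, self.c_in)[:, ::-1, :]
        W2 = np.ascontiguousarray(W3.transpose(2, 1, 0)).reshape(self.c_in, 27 * self.c_out)
        dx = _im2col(g) @ W2.T
        self._cols = None
        return dx.reshape(n, d, h, w, self.c_in)


class Conv1x1:
    def __init__(self, c_in, c_out, rng):
        std = np.sqrt(2.0 / c_in)
        self.W = rng.normal(0.0, std, size=(c_out, c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, g):
        flat_g = g.reshape(-1, g.shape[-1])
        flat_x = self._x.reshape(-1, self._x.shape[-1])
        self.dW += flat_g.T @ flat_x
        self.db += flat_g.sum(axis=0)
        self._x = None
        return g @ self.W


class InstanceNorm:
    """Per-sample, per-channel normalization over spatial axes with a
    learnable per-channel affine (gamma, beta)."""

    eps = 1e-5

    def __init__(self, channels):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train=True):
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        s = np.sqrt(var + self.eps)
        y = (x - mu) / s
        if train:
            self._y, self._s = y, s
        return self.gamma * y + self.beta

    def backward(self, g):
        y, s = self._y, self._s
        self.dgamma += (g * y).sum(axis=(0, 1, 2, 3))
        self.dbeta += g.sum(axis=(0, 1, 2, 3))
        gy = g * self.gamma
        gm = gy.mean(axis=(1, 2, 3), keepdims=True)
        gym = (gy * y).mean(axis=(1, 2, 3), keepdims=True)
        dx = (gy - gm - y * gym) / s
        self._y = self._s = None
        return dx


class ReLU:
    def params(self):
        return []

    def forward(self, x, train=True):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, g):
        dx = g * self._mask
        self._mask = None
        return dx


class MaxPool2:
    def params(self):
        return []

    def forward(self, x, train=True):
        n, d, h, w, c = x.shape
        blocks = np.stack(
            [x[:, i::2, j::2, k::2, :] for i in (0, 1) for j in (0, 1) for k in (0, 1)], axis=-1
        )
        out = blocks.max(axis=-1)
        if train:
            self._argmax = blocks.argmax(axis=-1)
            self._shape = (n, d, h, w, c)
        return out

    def backward(self, g):
        n, d, h, w, c = self._shape
        flat = np.zeros((n, d // 2, h // 2, w // 2, c, 8), dtype=g.dtype)
        np.put_along_axis(flat, self._argmax[..., None], g[..., None], axis=-1)
        out = np.zeros((n, d, h, w, c), dtype=g.dtype)
        for idx, (i, j, k) in enumerate([(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]):
            out[:, i::2, j::2, k::2, :] = flat[..., idx]
        self._argmax = None
        return out


class UpNearest2:
    def params(self):
        return []

    def forward(self, x, train=True):
        return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)

    def backward(self, g):
        n, d, h, w, c = g.shape
        return (
            g.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4, 6))
        )


class ConvBlock:
    """Two (conv -> instance norm -> ReLU) stages."""

    def __init__(self, c_in, c_out, rng, needs_input_grad=True):
        self.layers = [
            Conv3x3(c_in, c_out, rng, needs_input_grad),
            InstanceNorm(c_out),
            ReLU(),
            Conv3x3(c_out, c_out, rng),
            InstanceNorm(c_out),
            ReLU(),
        ]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class UNet3D:
    """Encoder-decoder with skip connections.

    ``n_levels`` encoder blocks (features double per level, 2x max-pool
    downsampling), a bottleneck block, a mirrored decoder (2x nearest
    upsampling, skip concatenation) and a final 1x1x1 convolution to
    ``out_classes`` logits. Input/output are channels-last ``(N, D, H, W, C)``.
    """

    def __init__(self, n_levels, in_channels, base_features, out_classes, seed):
        rng = np.random.default_rng(seed)
        self.n_levels = n_levels
        self.dtype = np.dtype(np.float32)
        self.enc, self.pools = [], []
        c = in_channels
        for i in range(n_levels):
            f = base_features * 2**i
            self.enc.append(ConvBlock(c, f, rng, needs_input_grad=(i > 0)))
            self.pools.append(MaxPool2())
            c = f
        fb = base_features * 2**n_levels
        self.bottleneck = ConvBlock(c, fb, rng)
        self.ups, self.dec = [], []
        c_deep = fb
        for i in reversed(range(n_levels)):
            f = base_features * 2**i
            self.ups.append(UpNearest2())
            self.dec.append(ConvBlock(c_deep + f, f, rng))
            c_deep = f
        self.final = Conv1x1(c_deep, out_classes, rng)

    def params(self):
        ps = []
        for blk in self.enc:
            ps += blk.params()
        ps += self.bottleneck.params()
        for blk in self.dec:
            ps += blk.params()
        ps += self.final.params()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def forward(self, x, train=True):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._skip_channels = []
        for i, (up, blk) in enumerate(zip(self.ups, self.dec)):
            h = up.forward(h, train)
            skip = skips[self.n_levels - 1 - i]
            self._skip_channels.append(h.shape[-1])
            h = np.concatenate([h, skip], axis=-1)
            h = blk.forward(h, train)
        return self.final.forward(h, train)

    def backward(self, g):
        g = self.final.backward(g)
        skip_grads = [None] * self.n_levels
        for i in reversed(range(len(self.dec))):
            g = self.dec[i].backward(g)
            c_up = self._skip_channels[i]
            g_up, g_skip = g[..., :c_up], g[..., c_up:]
            level = self.n_levels - 1 - i
            skip_grads[level] = g_skip
            g = self.ups[i].backward(np.ascontiguousarray(g_up))
        g = self.bottleneck.backward(g)
        for level in reversed(range(self.n_levels)):
            g = self.pools[level].backward(g)
            g = g + skip_grads[level]
            g = self.enc[level].backward(g)
        return g

    def zero_grad(self):
        for _, grad in self.params():
            grad[...] = 0

    def cast(self, dtype):
        """Cast all weights/grads (float64 is used by the gradient tests)."""
        self.dtype = np.dtype(dtype)
        for blk in self.enc + [self.bottleneck] + self.dec:
            for l in blk.layers:
                if hasattr(l, "W"):
                    l.W = l.W.astype(dtype)
                    l.b = l.b.astype(dtype)
                    l.dW = np.zeros_like(l.W)
                    l.db = np.zeros_like(l.b)
                elif hasattr(l, "gamma"):
                    l.gamma = l.gamma.astype(dtype)
                    l.beta = l.beta.astype(dtype)
                    l.dgamma = np.zeros_like(l.gamma)
                    l.dbeta = np.zeros_like(l.beta)
        f = self.final
        f.W, f.b = f.W.astype(dtype), f.b.astype(dtype)
        f.dW, f.db = np.zeros_like(f.W), np.zeros_like(f.b)
        return self

    def get_weights(self):
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights):
        own = self.params()
        if len(weights) != len(own):
            raise ValueError("weight list length mismatch")
        for (p, _), w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


def softmax(logits):
    """Softmax over the class axis (last axis)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, targets):
    """Mean voxelwise cross-entropy and its gradient wrt logits.

    logits: (N, D, H, W, K); targets: (N, D, H, W) integer class ids.
    """
    p = softmax(logits.astype(np.float64))
    k = logits.shape[-1]
    onehot = np.eye(k, dtype=np.float64)[targets]
    nvox = targets.size
    loss = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum() / nvox)
    grad = ((p - onehot) / nvox).astype(logits.dtype)
    return loss, grad


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
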