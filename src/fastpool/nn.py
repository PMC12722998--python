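"""Minimal convolutional network in numpy.

Implements exactly what frame-pooled window classification needs: strided 2-D
convolution (im2col via stride tricks, col2im via k*k vectorized adds), ReLU,
global average pooling, a linear head, Kaiming initialization, Adam, and a
softmax cross-entropy loss. Everything is float32 and deterministic under a
seeded ``numpy.random.Generator``.

The channel-patching entry points live here too: ``kaiming_conv`` draws an
n-input-channel first layer from scratch, and ``inflate_first_conv`` adapts a
3-channel (RGB) source kernel to n channels by mean-replication scaled by 3/n,
which preserves the layer's linear response on gray (channel-constant) inputs.
"""

from __future__ import annotations

import numpy as np

SUPPORTED_ARCHITECTURES = ("tiny_cnn", "efficientnet_b0", "efficientnet_b2")


class UnsupportedArchitectureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# initialization and first-conv patching

def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int) -> np.ndarray:
    """He/Kaiming normal draw: std = sqrt(2 / fan_in), for ReLU networks."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def inflate_first_conv(source_weight: np.ndarray, in_channels: int) -> np.ndarray:
    """Adapt an RGB first-conv kernel (F, 3, k, k) to n input channels.

    Each output filter's new kernel is the mean of its three source channel
    kernels, replicated across all n channels and multiplied by 3/n. For a
    channel-constant input this reproduces the source layer's response to the
    corresponding gray RGB image exactly (linearity of convolution), and it
    preserves the expected activation magnitude for uncorrelated channels.
    """
    source_weight = np.asarray(source_weight, dtype=np.float32)
    if source_weight.ndim != 4 or source_weight.shape[1] != 3:
        raise ValueError("source weight must have shape (F, 3, k, k)")
    if in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    mean = source_weight.mean(axis=1, keepdims=True)  # (F, 1, k, k)
    return np.repeat(mean, in_channels, axis=1) * (3.0 / in_channels)


# ---------------------------------------------------------------------------
# layers

class Conv2d:
    """Strided 2-D convolution with symmetric zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, padding: int = 0,
                 rng: np.random.Generator | None = None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        rng = rng or np.random.default_rng(0)
        self.weight = kaiming_normal(rng, (out_channels, in_channels,
                                           kernel_size, kernel_size), fan_in)
        self.bias = np.zeros(out_channels, dtype=np.float32)
        self._cache = None

    @property
    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, st, p = self.kernel_size, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (B, C, H', W', k, k) view, subsampled at the stride
        cols = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        cols = cols[:, :, ::st, ::st]
        out = np.tensordot(cols, self.weight, axes=([1, 4, 5], [1, 2, 3]))
        out = np.transpose(out, (0, 3, 1, 2)) + self.bias[None, :, None, None]
        if train:
            self._cache = (x, cols)
        # keep float64 inputs in float64 (linearity checks); training is float32
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray, need_dx: bool = True):
        x_pad, cols = self._cache
        k, st, p = self.kernel_size, self.stride, self.padding
        self.dbias = dout.sum(axis=(0, 2, 3)).astype(np.float32)
        # dW[f,c,i,j] = sum_{b,h,w} dout[b,f,h,w] * cols[b,c,h,w,i,j]
        self.dweight = np.tensordot(dout, cols, axes=([0, 2, 3], [0, 2, 3])
                                    ).astype(np.float32)
        if not need_dx:
            return None
        # dcols[b,h,w,c,i,j] = sum_f dout[b,f,h,w] * W[f,c,i,j]
        dcols = np.tensordot(np.transpose(dout, (0, 2, 3, 1)), self.weight,
                             axes=([3], [0]))
        oh, ow = dout.shape[2], dout.shape[3]
        dx = np.zeros_like(x_pad, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + oh * st:st, j:j + ow * st:st] += np.transpose(
                    dcols[:, :, :, :, i, j], (0, 3, 1, 2))
        if p:
            dx = dx[:, :, p:-p, p:-p]
        return dx


class BatchNorm2d:
    """Per-channel batch normalization with running statistics for eval.

    Stabilizes from-scratch training of small networks on weak-contrast cues;
    deterministic given a fixed batch order.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return (self.gamma[None, :, None, None] * xhat
                + self.beta[None, :, None, None]).astype(np.float32)

    def backward(self, dout, need_dx=True):
        xhat, inv, shape = self._cache
        b, c, h, w = shape
        m = b * h * w
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.dbeta = dout.sum(axis=(0, 2, 3)).astype(np.float32)
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True))
        return dx.astype(np.float32)

    # running stats must survive checkpointing alongside learnables
    def extra_state(self):
        return {"running_mean": self.running_mean,
                "running_var": self.running_var}


class ReLU:
    params: list = []

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout, need_dx=True):
        return dout * self._mask


class GlobalAvgPool:
    params: list = []

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout, need_dx=True):
        b, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               self._shape).astype(np.float32)


class GlobalAvgMaxPool:
    """Concatenated global average and global max pooling (2c features).

    The max branch keeps small localized cues — an anechoic pocket covers only
    a few cells of the final feature map — from being diluted by averaging.
    """

    params: list = []

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        flat = x.reshape(b, c, h * w)
        if train:
            self._argmax = flat.argmax(axis=2)
            self._shape = x.shape
        return np.concatenate([flat.mean(axis=2), flat.max(axis=2)], axis=1)

    def backward(self, dout, need_dx=True):
        b, c, h, w = self._shape
        davg, dmax = dout[:, :c], dout[:, c:]
        dx = np.broadcast_to(davg[:, :, None] / (h * w), (b, c, h * w)).copy()
        bi, ci = np.meshgrid(np.arange(b), np.arange(c), indexing="ij")
        dx[bi, ci, self._argmax] += dmax
        return dx.reshape(self._shape).astype(np.float32)


class Linear:
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = kaiming_normal(rng, (in_features, out_features), in_features)
        self.bias = np.zeros(out_features, dtype=np.float32)

    @property
    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.weight + self.bias

    def backward(self, dout, need_dx=True):
        self.dweight = (self._x.T @ dout).astype(np.float32)
        self.dbias = dout.sum(axis=0).astype(np.float32)
        return dout @ self.weight.T


# ---------------------------------------------------------------------------
# the backbone

class TinyCNN:
    """Three stride-2 conv blocks, global average pooling, 2-logit head.

    Small enough to train on a CPU in seconds yet expressive enough to detect
    an anechoic pocket in pooled windows. The first convolution carries the
    channel patch: ``in_channels`` equals the pooled window size n. Inputs in
    [0, 1] are centered to [-1, 1] inside the network; the pooling head
    concatenates global average and global max so localized cues survive.
    """

    def __init__(self, in_channels: int, seed: int = 0, widths=(16, 32, 64)):
        if in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.widths = tuple(widths)
        c1, c2, c3 = self.widths
        self.layers = [
            Conv2d(in_channels, c1, 3, stride=2, padding=1, rng=rng),
            BatchNorm2d(c1), ReLU(),
            Conv2d(c1, c2, 3, stride=2, padding=1, rng=rng),
            BatchNorm2d(c2), ReLU(),
            Conv2d(c2, c3, 3, stride=2, padding=1, rng=rng),
            BatchNorm2d(c3), ReLU(),
            GlobalAvgMaxPool(),
            Linear(2 * c3, 2, rng=rng),
        ]

    @property
    def first_conv(self) -> Conv2d:
        return self.layers[0]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = (np.asarray(x, dtype=np.float32) - 0.5) * 2.0
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for idx in range(len(self.layers) - 1, -1, -1):
            grad = self.layers[idx].backward(grad, need_dx=idx > 0)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, _ in layer.params:
                yield f"layer{li}.{name}", layer, name

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {key: getattr(layer, name).copy()
                 for key, layer, name in self.parameters()}
        for li, layer in enumerate(self.layers):
            if hasattr(layer, "extra_state"):
                for name, value in layer.extra_state().items():
                    state[f"layer{li}.{name}"] = value.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.parameters():
            setattr(layer, name, np.asarray(state[key], dtype=np.float32).copy())
        for li, layer in enumerate(self.layers):
            if hasattr(layer, "extra_state"):
                for name in layer.extra_state():
                    setattr(layer, name,
                            np.asarray(state[f"layer{li}.{name}"],
                                       dtype=np.float32).copy())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    """Mean 2-class cross-entropy and the gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, model: TinyCNN, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(getattr(layer, n))
                  for k, layer, n in model.parameters()}
        self.v = {k: np.zeros_like(getattr(layer, n))
                  for k, layer, n in model.parameters()}

    def step(self) -> None:
        self.t += 1
        for key, layer, name in self.model.parameters():
            grad = getattr(layer, "d" + name)
            m = self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * grad
            v = self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * grad * grad
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            param = getattr(layer, name)
            param -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(param.dtype)


def build_backbone(architecture: str, in_channels: int, init: str,
                   seed: int = 0, source_first_conv: np.ndarray | None = None
                   ) -> TinyCNN:
    """Build a channel-patched backbone.

    ``init='kaiming_scratch'`` draws every weight by Kaiming initialization
    under ``seed``. ``init='pretrained_inflate'`` requires an RGB source
    first-conv kernel (F, 3, k, k) and installs its mean-replicated, 3/n-scaled
    inflation as the first layer; deeper layers have no source here, so only
    the first-layer transfer is performed.

    Only ``tiny_cnn`` is materialized as a runnable network; the EfficientNet
    variants need a pretrained-model zoo and are rejected with a clear error.
    """
    if architecture not in SUPPORTED_ARCHITECTURES:
        raise UnsupportedArchitectureError(
            f"unknown architecture {architecture!r}; supported: "
            f"{SUPPORTED_ARCHITECTURES}")
    if architecture != "tiny_cnn":
        raise UnsupportedArchitectureError(
            f"{architecture} requires a pretrained CNN model zoo, which this "
            "installation does not ship; use 'tiny_cnn'")
    if init not in ("kaiming_scratch", "pretrained_inflate"):
        raise ValueError(f"unknown init mode {init!r}")
    model = TinyCNN(in_channels, seed=seed)
    if init == "pretrained_inflate":
        if source_first_conv is None:
            raise ValueError(
                "pretrained_inflate needs source_first_conv weights; tiny_cnn "
                "has no pretrained source of its own")
        inflated = inflate_first_conv(source_first_conv, in_channels)
        fc = model.first_conv
        if inflated.shape[0] != fc.out_channels or inflated.shape[2] != fc.kernel_size:
            raise ValueError(
                f"source kernel shape {inflated.shape} does not match the "
                f"first conv ({fc.out_channels} filters, k={fc.kernel_size})")
        fc.weight = inflated
    return model
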