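"""A 3D U-Net for binary volumetric segmentation, implemented in NumPy.

The network is the canonical encoder/decoder U-Net with skip connections:
five resolution levels, two 3x3x3 convolutions per level (10 encoder convs
with 4 max-poolings in between), feature maps doubling after every pooling,
and a decoder of four 2x2x2 nearest-neighbour up-samplings each followed by
two convolutions, closed by a 1x1x1 output convolution with a sigmoid —
nine decoder convolutions in total. It is fully convolutional: any input
whose axes are divisible by 2^(levels-1) = 16 maps to an output of the same
shape, and the parameter count depends only on the configuration.

Forward and backward passes are hand-written (im2col-style windowed
tensordots), which keeps the desk-scale configurations used in this package
(base_filters 4–16, inputs around 48^3) tractable on a single CPU core.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _conv


class ShapeError(ValueError):
    """Input shape incompatible with the network's pooling pyramid."""


class IncompatibleWeightsError(ValueError):
    """Weight set does not match the network configuration."""


@dataclasses.dataclass(frozen=True)
class UNetConfig:
    base_filters: int = 16
    levels: int = 5
    in_channels: int = 1
    kernel: tuple[int, int, int] = (3, 3, 3)
    pool: tuple[int, int, int] = (2, 2, 2)
    #: per-channel instance normalization after every hidden convolution —
    #: the standard choice for batch-size-1 volumetric segmentation. Besides
    #: conditioning, it keeps activation scales bounded, which prevents the
    #: irrecoverable all-background collapse Dice-loss training can hit when
    #: an over-segmentation overshoot saturates the sigmoid
    instance_norm: bool = True
    #: initial output-conv bias: the logit of the expected foreground
    #: fraction. Starting the sigmoid near the class prior suppresses the
    #: large early-training oscillations of Dice-loss optimization
    output_bias: float = -2.0

    @property
    def divisor(self) -> int:
        return 2 ** (self.levels - 1)

    def filters(self, level: int) -> int:
        return self.base_filters * 2 ** level


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class _Conv3d:
    """3x3x3 (or 1x1x1) same-padding convolution, optionally followed by
    per-channel instance normalization, with leaky-ReLU or identity
    activation.

    The activation is leaky (slope 0.01 on the negative side) rather than a
    hard ReLU: with batch-size-1 Dice-loss training a loss spike can push a
    small network into an all-dead-ReLU state from which the saturated
    sigmoid cannot recover; the leaky slope keeps a gradient path alive.
    """

    NORM_EPS = 1e-5
    LEAKY_ALPHA = np.float32(0.01)

    def __init__(self, name, cin, cout, ksize, rng, relu=True, norm=False):
        self.name = name
        self.ksize = ksize
        self.relu = relu
        self.norm = norm
        k3 = ksize ** 3
        self.w = _glorot_uniform(rng, (cout, cin, ksize, ksize, ksize),
                                 fan_in=cin * k3, fan_out=cout * k3)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        if norm:
            self.gamma = np.ones(cout, dtype=np.float32)
            self.beta = np.zeros(cout, dtype=np.float32)
            self.dgamma = np.zeros_like(self.gamma)
            self.dbeta = np.zeros_like(self.beta)
        self._cache = None

    def forward(self, x, train=False):
        if self.ksize == 1:
            y = np.tensordot(self.w[:, :, 0, 0, 0], x, axes=([1], [0]))
            y += self.b[:, None, None, None]
        else:
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
            if _conv.HAVE_NUMBA:
                y = np.empty((self.w.shape[0],) + x.shape[1:], dtype=np.float32)
                _conv.conv3d_forward(xp, self.w, self.b, y)
            else:
                win = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))
                y = np.tensordot(self.w, win, axes=([1, 2, 3, 4], [0, 4, 5, 6]))
                y += self.b[:, None, None, None]
        xhat = istd = None
        if self.norm:
            mu = y.mean(axis=(1, 2, 3), keepdims=True)
            var = y.var(axis=(1, 2, 3), keepdims=True)
            istd = 1.0 / np.sqrt(var + self.NORM_EPS)
            xhat = ((y - mu) * istd).astype(np.float32)
            y = self.gamma[:, None, None, None] * xhat \
                + self.beta[:, None, None, None]
        if self.relu:
            y = np.where(y > 0, y, self.LEAKY_ALPHA * y)
        if train:
            self._cache = (x, y if self.relu else None, xhat, istd)
        return y.astype(np.float32, copy=False)

    def backward(self, g):
        x, y_relu, xhat, istd = self._cache
        if self.relu:
            # post-activation sign equals pre-activation sign for leaky ReLU
            g = g * np.where(y_relu > 0, np.float32(1.0), self.LEAKY_ALPHA)
        if self.norm:
            self.dgamma += (g * xhat).sum(axis=(1, 2, 3))
            self.dbeta += g.sum(axis=(1, 2, 3))
            gh = g * self.gamma[:, None, None, None]
            m1 = gh.mean(axis=(1, 2, 3), keepdims=True)
            m2 = (gh * xhat).mean(axis=(1, 2, 3), keepdims=True)
            g = (gh - m1 - xhat * m2) * istd
        g = np.ascontiguousarray(g, dtype=np.float32)
        if self.ksize == 1:
            self.db += g.sum(axis=(1, 2, 3))
            self.dw[:, :, 0, 0, 0] += np.tensordot(g, x, axes=([1, 2, 3], [1, 2, 3]))
            dx = np.tensordot(self.w[:, :, 0, 0, 0].T, g, axes=([1], [0]))
        elif _conv.HAVE_NUMBA:
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
            _conv.conv3d_backward_dw(xp, g, self.dw, self.db)
            # dx is the correlation of the padded upstream gradient with the
            # spatially flipped, channel-transposed kernel: reuse the forward
            # kernel for it.
            gp = np.pad(g, ((0, 0), (1, 1), (1, 1), (1, 1)))
            wf = np.ascontiguousarray(
                self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
            dx = np.empty_like(x)
            _conv.conv3d_forward(gp, wf, np.zeros(x.shape[0], dtype=np.float32), dx)
        else:
            self.db += g.sum(axis=(1, 2, 3))
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
            win = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))
            self.dw += np.tensordot(g, win, axes=([1, 2, 3], [1, 2, 3]))
            gp = np.pad(g, ((0, 0), (1, 1), (1, 1), (1, 1)))
            gwin = sliding_window_view(gp, (3, 3, 3), axis=(1, 2, 3))
            wf = self.w[:, :, ::-1, ::-1, ::-1]
            dx = np.tensordot(wf, gwin, axes=([0, 2, 3, 4], [0, 4, 5, 6]))
        self._cache = None
        return dx.astype(np.float32, copy=False)

    def param_names(self):
        names = ["w", "b"]
        if self.norm:
            names += ["gamma", "beta"]
        return names

    def n_params(self):
        return sum(getattr(self, a).size for a in self.param_names())


class _MaxPool2:
    def __init__(self):
        self._cache = None

    def forward(self, x, train=False):
        c, nx, ny, nz = x.shape
        xr = (x.reshape(c, nx // 2, 2, ny // 2, 2, nz // 2, 2)
               .transpose(0, 1, 3, 5, 2, 4, 6)
               .reshape(c, nx // 2, ny // 2, nz // 2, 8))
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, idx)
        return y

    def backward(self, g):
        shape, idx = self._cache
        c, nx, ny, nz = shape
        gr = np.zeros((c, nx // 2, ny // 2, nz // 2, 8), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        dx = (gr.reshape(c, nx // 2, ny // 2, nz // 2, 2, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3, 6)
                .reshape(c, nx, ny, nz))
        self._cache = None
        return dx


def _upsample2(x):
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_backward(g):
    c, nx, ny, nz = g.shape
    return g.reshape(c, nx // 2, 2, ny // 2, 2, nz // 2, 2).sum(axis=(2, 4, 6))


class UNet3D:
    """Seedable fully convolutional 3D U-Net with hand-written backprop."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        self.frozen: set[str] = set()
        rng = np.random.default_rng(seed)
        L = config.levels
        norm = config.instance_norm
        self.enc = []
        cin = config.in_channels
        for l in range(L):
            f = config.filters(l)
            c1 = _Conv3d(f"enc{l}_conv1", cin, f, 3, rng, norm=norm)
            c2 = _Conv3d(f"enc{l}_conv2", f, f, 3, rng, norm=norm)
            self.enc.append((c1, c2))
            cin = f
        self.pools = [_MaxPool2() for _ in range(L - 1)]
        self.dec = []
        for l in range(L - 2, -1, -1):
            f = config.filters(l)
            f_up = config.filters(l + 1)
            c1 = _Conv3d(f"dec{l}_conv1", f_up + f, f, 3, rng, norm=norm)
            c2 = _Conv3d(f"dec{l}_conv2", f, f, 3, rng, norm=norm)
            self.dec.append((l, c1, c2))
        self.out_conv = _Conv3d("out_conv", config.base_filters, 1, 1, rng, relu=False)
        self.out_conv.b[:] = config.output_bias

    # -- structure -----------------------------------------------------
    def _layers(self):
        for c1, c2 in self.enc:
            yield c1
            yield c2
        for _l, c1, c2 in self.dec:
            yield c1
            yield c2
        yield self.out_conv

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self._layers())

    # -- forward / backward -------------------------------------------
    def _check_shape(self, x):
        if x.ndim != 3:
            raise ShapeError(f"expected a 3D volume, got shape {x.shape}")
        d = self.config.divisor
        if any(s % d for s in x.shape):
            raise ShapeError(f"input shape {x.shape} not divisible by {d} on every axis")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Probability map in (0, 1), same shape as the input volume."""
        self._check_shape(x)
        h = x.astype(np.float32, copy=False)[None]  # (1, X, Y, Z)
        skips = []
        for l, (c1, c2) in enumerate(self.enc):
            h = c2.forward(c1.forward(h, train), train)
            if l < self.config.levels - 1:
                skips.append(h)
                h = self.pools[l].forward(h, train)
        self._skip_channels = []
        for l, c1, c2 in self.dec:
            h = _upsample2(h)
            skip = skips[l]
            self._skip_channels.append(skip.shape[0])
            h = np.concatenate([h, skip], axis=0)
            h = c2.forward(c1.forward(h, train), train)
        z = self.out_conv.forward(h, train)
        prob = 1.0 / (1.0 + np.exp(-np.clip(z[0], -60.0, 60.0)))
        if train:
            self._prob = prob
        return prob

    predict = forward

    def backward(self, dprob: np.ndarray) -> None:
        """Accumulate parameter gradients from dLoss/dprobability."""
        p = self._prob
        g = (dprob * p * (1.0 - p)).astype(np.float32)[None]
        g = self.out_conv.backward(g)
        skip_grads = {}
        for (l, c1, c2), n_skip in zip(reversed(self.dec),
                                       reversed(self._skip_channels)):
            g = c1.backward(c2.backward(g))
            g, g_skip = g[:-n_skip], g[-n_skip:]
            skip_grads[l] = g_skip
            g = _upsample2_backward(g)
        for l in range(self.config.levels - 1, -1, -1):
            c1, c2 = self.enc[l]
            if l < self.config.levels - 1:
                g = self.pools[l].backward(g)
                g = g + skip_grads[l]
            g = c1.backward(c2.backward(g))

    def zero_grad(self):
        for layer in self._layers():
            for attr in layer.param_names():
                getattr(layer, "d" + attr)[...] = 0

    # -- weights -------------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self._layers():
            for attr in layer.param_names():
                out[f"{layer.name}/{attr}"] = getattr(layer, attr).copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for layer in self._layers():
            for attr in layer.param_names():
                key = f"{layer.name}/{attr}"
                if key not in weights:
                    raise IncompatibleWeightsError(f"missing weight {key}")
                val = np.asarray(weights[key], dtype=np.float32)
                if val.shape != getattr(layer, attr).shape:
                    raise IncompatibleWeightsError(
                        f"{key}: shape {val.shape} != {getattr(layer, attr).shape}"
                    )
                setattr(layer, attr, val.copy())


def build_network(config: UNetConfig, seed: int = 0) -> UNet3D:
    """Build a U-Net with Glorot-uniform initial weights drawn from ``seed``."""
    return UNet3D(config, seed)


def expected_param_count(config: UNetConfig) -> int:
    """Closed-form parameter count of the configured architecture.

    Each hidden convolution contributes kernel weights plus bias, and — when
    instance normalization is enabled — a per-channel scale and shift pair.
    """
    k3 = int(np.prod(config.kernel))
    norm = 2 if config.instance_norm else 0
    total = 0
    cin = config.in_channels
    for l in range(config.levels):
        f = config.filters(l)
        total += (cin * k3 + 1 + norm) * f + (f * k3 + 1 + norm) * f
        cin = f
    for l in range(config.levels - 2, -1, -1):
        f, f_up = config.filters(l), config.filters(l + 1)
        total += ((f_up + f) * k3 + 1 + norm) * f + (f * k3 + 1 + norm) * f
    total += (config.base_filters + 1) * 1
    return total


# ---------------------------------------------------------------------------
# Dice loss

DICE_EPS = 1e-6


def soft_dice(pred: np.ndarray, target: np.ndarray, eps: float = DICE_EPS) -> float:
    """Soft Dice similarity DS = (2 sum(p t) + eps) / (sum p + sum t + eps)."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = pred.astype(np.float64)
    t = target.astype(np.float64)
    return float((2.0 * (p * t).sum() + eps) / (p.sum() + t.sum() + eps))


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = DICE_EPS) -> float:
    """Dice loss L = 1 - DS, in [0, 1]."""
    return 1.0 - soft_dice(pred, target, eps)


def dice_loss_grad(pred: np.ndarray, target: np.ndarray, eps: float = DICE_EPS):
    """(loss, dLoss/dpred) for the soft Dice loss."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = pred.astype(np.float64)
    t = target.astype(np.float64)
    inter = (p * t).sum()
    denom = p.sum() + t.sum() + eps
    ds = (2.0 * inter + eps) / denom
    grad = -(2.0 * t * denom - (2.0 * inter + eps)) / denom ** 2
    return float(1.0 - ds), grad.astype(np.float32)


# ---------------------------------------------------------------------------
# Weight persistence and transfer

def save_weights(weights: dict[str, np.ndarray], path) -> None:
    np.savez_compressed(path, **weights)


def load_weights(path) -> dict[str, np.ndarray]:
    with np.load(path) as npz:
        return {k: npz[k].copy() for k in npz.files}


def weight_manifest(weights: dict[str, np.ndarray]) -> dict:
    """Framework-neutral manifest: layer names, shapes, content hashes."""
    entries = {}
    for name in sorted(weights):
        arr = np.ascontiguousarray(weights[name], dtype=np.float32)
        entries[name] = {
            "shape": list(arr.shape),
            "sha256": hashlib.sha256(arr.tobytes()).hexdigest(),
        }
    return entries


def save_manifest(weights: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        json.dump(weight_manifest(weights), fh, indent=1)


def transfer_init(
    target: UNet3D, source: dict[str, np.ndarray], freeze: set[str] | None = None
) -> UNet3D:
    """Initialize ``target`` from a trained weight set (transfer learning).

    Works across stage resolutions because the network is fully convolutional;
    layers named in ``freeze`` are excluded from subsequent gradient updates.
    The default is to fine-tune everything.
    """
    target.set_weights(source)
    target.frozen = set(freeze or ())
    known = {layer.name for layer in target._layers()}
    unknown = target.frozen - known
    if unknown:
        raise IncompatibleWeightsError(f"unknown frozen layers: {sorted(unknown)}")
    return target


class Adam:
    """Adam optimizer over a network's layers, honouring frozen layers."""

    def __init__(self, net: UNet3D, lr: float = 5e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for layer in net._layers():
            for attr in layer.param_names():
                key = f"{layer.name}/{attr}"
                self.m[key] = np.zeros_like(getattr(layer, attr))
                self.v[key] = np.zeros_like(getattr(layer, attr))

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for layer in self.net._layers():
            if layer.name in self.net.frozen:
                continue
            for attr in layer.param_names():
                gattr = "d" + attr
                key = f"{layer.name}/{attr}"
                g = getattr(layer, gattr)
                self.m[key] = b1 * self.m[key] + (1 - b1) * g
                self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
                param = getattr(layer, attr)
                param -= self.lr * corr * self.m[key] / (np.sqrt(self.v[key]) + self.eps)
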