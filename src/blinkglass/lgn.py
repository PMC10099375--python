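"""The Lightweight Glass Network (LGN).

A compact hourglass-style convolutional network that regresses six eyelid
keypoints from a near-eye grayscale image via per-keypoint Gaussian probability
maps ("heatmaps").  The network is small enough to train on a CPU: layers and
backpropagation are implemented directly on numpy float32 arrays, with the
convolutions expressed as one BLAS matmul per kernel offset.

Contents, in the order the method runs:

* ``KeypointSet`` / ``HeatmapStack`` containers and the heatmap codec
  (:func:`encode_heatmaps`, :func:`decode_keypoints`);
* minimal trainable layers (conv + batch-norm + ReLU modules, 2x max-pool,
  2x nearest-neighbour upsampling) and the two-branch residual block whose
  lower branch runs at half resolution;
* the :class:`LGN` model: a stem that halves the input resolution followed by
  nested residual blocks (an hourglass of configurable order) and a 1x1
  regression head emitting one map per keypoint;
* the mean-squared heatmap loss and a momentum-SGD optimizer.

Coordinate convention: 0-based ``(row, col)`` pixel centres everywhere.
Heatmaps live on a grid of half the input resolution by default.
"""

from __future__ import annotations

import io
import json
import zlib
from dataclasses import dataclass

import numpy as np

N_KEYPOINTS = 6

__all__ = [
    "N_KEYPOINTS",
    "KeypointSet",
    "HeatmapStack",
    "encode_heatmaps",
    "decode_keypoints",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "NearestUp2",
    "Sequential",
    "conv_module",
    "ResidualBlock",
    "residual_block",
    "LGN",
    "mse_heatmap_loss",
    "mse_heatmap_loss_grad",
    "SGD",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Keypoints and heatmaps
# ---------------------------------------------------------------------------


@dataclass
class KeypointSet:
    """Six ordered eyelid landmarks in image coordinates.

    Order convention: temporal corner, nasal corner, two upper-lid points
    (temporal to nasal), two lower-lid points (temporal to nasal).

    Attributes
    ----------
    points : (6, 2) float array of (row, col) coordinates.
    valid : (6,) bool array; a point decoded from an all-zero probability map
        is flagged invalid.
    """

    points: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.shape != (N_KEYPOINTS, 2):
            raise ValueError(
                f"expected {N_KEYPOINTS} (row, col) keypoints, got shape {self.points.shape}"
            )
        if self.valid is None:
            self.valid = np.ones(N_KEYPOINTS, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (N_KEYPOINTS,):
                raise ValueError("valid mask must have shape (6,)")

    @property
    def all_valid(self) -> bool:
        return bool(self.valid.all())

    def eye_width(self) -> float:
        """Corner-to-corner distance in pixels."""
        return float(np.hypot(*(self.points[0] - self.points[1])))


@dataclass
class HeatmapStack:
    """Per-keypoint probability maps of shape (6, H_h, H_w), values >= 0."""

    maps: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps)
        if self.maps.ndim != 3 or self.maps.shape[0] != N_KEYPOINTS:
            raise ValueError(
                f"heatmap stack must have shape (6, H, W), got {self.maps.shape}"
            )

    @property
    def map_size(self) -> tuple[int, int]:
        return self.maps.shape[1], self.maps.shape[2]


def _as_maps(hm: HeatmapStack | np.ndarray) -> np.ndarray:
    return hm.maps if isinstance(hm, HeatmapStack) else np.asarray(hm)


def encode_heatmaps(
    kps: KeypointSet,
    sigma: float = 2.0,
    map_size: tuple[int, int] = (64, 64),
    image_size: tuple[int, int] = (128, 128),
) -> HeatmapStack:
    """Encode keypoints as ground-truth Gaussian probability maps.

    Each map holds a 2-D Gaussian of standard deviation ``sigma`` (in heatmap
    pixels) centred on the keypoint's position scaled into heatmap
    coordinates and rounded to the nearest grid cell, so the peak value is
    exactly 1.0 and sits at a unique cell.

    Raises
    ------
    ValueError
        If ``sigma <= 0`` or any keypoint lies outside the image.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    H, W = image_size
    Hh, Hw = map_size
    pts = kps.points
    if (
        (pts[:, 0] < 0).any()
        or (pts[:, 0] > H - 1).any()
        or (pts[:, 1] < 0).any()
        or (pts[:, 1] > W - 1).any()
    ):
        raise ValueError("keypoint outside image bounds")
    sr = Hh / H
    sc = Hw / W
    rows = np.arange(Hh, dtype=np.float64)
    cols = np.arange(Hw, dtype=np.float64)
    maps = np.empty((N_KEYPOINTS, Hh, Hw), dtype=np.float64)
    for i in range(N_KEYPOINTS):
        r0 = int(np.clip(np.rint(pts[i, 0] * sr), 0, Hh - 1))
        c0 = int(np.clip(np.rint(pts[i, 1] * sc), 0, Hw - 1))
        dr2 = (rows - r0) ** 2
        dc2 = (cols - c0) ** 2
        maps[i] = np.exp(-(dr2[:, None] + dc2[None, :]) / (2.0 * sigma**2))
    return HeatmapStack(maps)


def decode_keypoints(
    hm: HeatmapStack | np.ndarray,
    image_size: tuple[int, int] = (128, 128),
) -> KeypointSet:
    """Decode keypoints as the argmax of each probability map.

    The argmax location is rescaled to image coordinates.  Ties are broken by
    the lowest row-major index; an all-zero map yields an invalid keypoint
    (flagged in ``valid``, coordinates NaN).
    """
    maps = _as_maps(hm)
    if maps.shape[0] != N_KEYPOINTS:
        raise ValueError("expected 6 maps")
    Hh, Hw = maps.shape[1], maps.shape[2]
    H, W = image_size
    pts = np.empty((N_KEYPOINTS, 2), dtype=np.float64)
    valid = np.ones(N_KEYPOINTS, dtype=bool)
    for i in range(N_KEYPOINTS):
        m = maps[i]
        if not np.any(m):
            pts[i] = np.nan
            valid[i] = False
            continue
        flat = int(np.argmax(m))  # lowest row-major index on ties
        r, c = divmod(flat, Hw)
        pts[i, 0] = r * (H / Hh)
        pts[i, 1] = c * (W / Hw)
    # NaN coordinates are outside the (6,2) finite contract; keep them but
    # skip bounds validation by constructing directly.
    ks = KeypointSet.__new__(KeypointSet)
    ks.points = pts
    ks.valid = valid
    return ks


# ---------------------------------------------------------------------------
# Minimal trainable layers (numpy float32, explicit backprop)
# ---------------------------------------------------------------------------


class Param:
    """A trainable tensor with its gradient and momentum buffer."""

    __slots__ = ("value", "grad", "velocity")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k same-padding convolution, stride 1.

    The forward/backward passes loop over the k*k kernel offsets, each offset
    contributing one (C_out, C_in) @ (C_in, B*H*W) matmul, which keeps the
    arithmetic inside BLAS without materializing an im2col buffer.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Param(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.bias = Param(np.zeros(cout))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        p = self.pad
        if p:
            xp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
            xp[:, :, p : p + H, p : p + W] = x
        else:
            xp = np.ascontiguousarray(x, dtype=np.float32)
        self._xp = xp if train else None
        self._in_shape = (B, C, H, W)
        out = np.empty((B, self.cout, H * W), dtype=np.float32)
        out[:] = self.bias.value[None, :, None]
        Wk = self.weight.value
        for ky in range(self.k):
            for kx in range(self.k):
                xs = xp[:, :, ky : ky + H, kx : kx + W].reshape(B, C, H * W)
                out += np.matmul(Wk[:, :, ky, kx], xs)
        return out.reshape(B, self.cout, H, W)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._xp is None:
            raise RuntimeError("backward called without a train-mode forward")
        B, C, H, W = self._in_shape
        xp = self._xp
        df = np.ascontiguousarray(dout, dtype=np.float32).reshape(B, self.cout, H * W)
        self.bias.grad += df.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        Wk = self.weight.value
        for ky in range(self.k):
            for kx in range(self.k):
                xs = xp[:, :, ky : ky + H, kx : kx + W].reshape(B, C, H * W)
                self.weight.grad[:, :, ky, kx] += np.tensordot(
                    df, xs, axes=([0, 2], [0, 2])
                )
                dxp[:, :, ky : ky + H, kx : kx + W] += np.matmul(
                    Wk[:, :, ky, kx].T, df
                ).reshape(B, C, H, W)
        p = self.pad
        self._xp = None
        if p:
            return dxp[:, :, p : p + H, p : p + W]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._cache = (xhat, inv)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
            self._cache = None
        return (
            self.gamma.value[None, :, None, None] * xhat
            + self.beta.value[None, :, None, None]
        ).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a train-mode forward")
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dout * g
        # standard batch-norm backward
        dx = (
            inv[None, :, None, None]
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            )
        )
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0 if train else None
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2.  Requires even spatial dimensions."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("spatial dimensions must be even for 2x2 pooling")
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        patches = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
        idx = patches.argmax(axis=-1)
        out = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._in_shape = (B, C, H, W)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        dpatches = np.zeros((B, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(dpatches, self._idx[..., None], dout[..., None], axis=-1)
        dx = (
            dpatches.reshape(B, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, H, W)
        )
        return dx


class NearestUp2(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = dout.shape
        return (
            dout.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5)).astype(np.float32)
        )


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


def conv_module(cin: int, cout: int, rng: np.random.Generator, k: int = 3) -> Sequential:
    """One convolutional module: 3x3 conv + batch norm + ReLU."""
    return Sequential(Conv2d(cin, cout, k=k, rng=rng), BatchNorm2d(cout), ReLU())


class ResidualBlock(Layer):
    """Two-branch residual module.

    The upper branch passes the input through three convolutional modules at
    full resolution; the lower branch max-pools to half resolution, applies
    three convolutional modules (optionally followed by a nested inner
    module), and is brought back to full resolution by nearest-neighbour
    upsampling.  The branch outputs are added pixel-wise, so the output
    spatial size equals the input spatial size and the channel count equals
    ``cout``.  Spatial dimensions must be even.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        rng: np.random.Generator | None = None,
        inner: Layer | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        self.upper = Sequential(
            conv_module(cin, cout, rng),
            conv_module(cout, cout, rng),
            conv_module(cout, cout, rng),
        )
        lower_layers: list[Layer] = [
            MaxPool2(),
            conv_module(cin, cout, rng),
            conv_module(cout, cout, rng),
            conv_module(cout, cout, rng),
        ]
        if inner is not None:
            lower_layers.append(inner)
        lower_layers.append(NearestUp2())
        self.lower = Sequential(*lower_layers)

    def params(self) -> list[Param]:
        return self.upper.params() + self.lower.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        H, W = x.shape[2], x.shape[3]
        if H % 2 or W % 2:
            raise ValueError("residual block requires even spatial dimensions")
        return self.upper.forward(x, train=train) + self.lower.forward(x, train=train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.upper.backward(dout) + self.lower.backward(dout)


def residual_block(
    x: np.ndarray, out_channels: int, seed: int = 0
) -> np.ndarray:
    """Apply a freshly initialized two-branch residual block to ``x``.

    Convenience wrapper over :class:`ResidualBlock` (inference mode, weights
    seeded by ``seed``); the class is what the network composes.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        out = residual_block(x[None], out_channels, seed=seed)
        return out[0]
    rng = np.random.default_rng(seed)
    block = ResidualBlock(x.shape[1], out_channels, rng=rng)
    return block.forward(x, train=False)


# ---------------------------------------------------------------------------
# The LGN model
# ---------------------------------------------------------------------------


class LGN:
    """Hourglass keypoint regressor for near-eye images.

    A stem convolution halves the input resolution; the feature extraction
    trunk is a nest of residual blocks (``depth`` levels, each nesting one
    more block in its lower branch, so the innermost features are at
    1/2^depth of the heatmap scale); a regression head maps the fused
    features to one probability map per eyelid keypoint at half the input
    resolution.

    Parameters
    ----------
    input_size : side of the square grayscale input, pixels.
    depth : hourglass order (number of nested residual blocks).
    width : channel count used throughout the trunk.
    sigma : Gaussian standard deviation used when encoding training targets,
        in heatmap pixels (stored so checkpoints are self-describing).
    seed : weight initialization seed.
    """

    def __init__(
        self,
        input_size: int = 128,
        depth: int = 4,
        width: int = 12,
        n_keypoints: int = N_KEYPOINTS,
        sigma: float = 2.0,
        seed: int = 0,
    ):
        if input_size % (2 ** (depth + 1)) != 0:
            raise ValueError(
                f"input_size {input_size} not divisible by 2^(depth+1) = {2 ** (depth + 1)}"
            )
        self.input_size = input_size
        self.depth = depth
        self.width = width
        self.n_keypoints = n_keypoints
        self.sigma = sigma
        self.seed = seed
        rng = np.random.default_rng(seed)
        w = width
        self.stem = Sequential(conv_module(1, w, rng), MaxPool2())
        inner: Layer | None = None
        for _ in range(depth):
            inner = ResidualBlock(w, w, rng=rng, inner=inner)
        assert inner is not None
        self.trunk = inner
        out_conv = Conv2d(w, n_keypoints, k=1, rng=rng)
        # zero-init the regression conv so initial maps are flat: keeps the
        # first SGD steps small enough for the fixed 1e-3 learning rate
        out_conv.weight.value[...] = 0.0
        self.head = Sequential(conv_module(w, w, rng), out_conv)
        self.net = Sequential(self.stem, self.trunk, self.head)

    # -- inference / training passes -----------------------------------

    @property
    def heatmap_size(self) -> tuple[int, int]:
        s = self.input_size // 2
        return (s, s)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Run a batch of preprocessed frames; returns (B, 6, H/2, W/2) maps."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != self.input_size or x.shape[3] != self.input_size:
            raise ValueError(
                f"expected {self.input_size}x{self.input_size} input, got "
                f"{x.shape[2]}x{x.shape[3]}"
            )
        if x.shape[1] != 1:
            raise ValueError("LGN expects single-channel input")
        out = self.net.forward(x, train=train)
        if not np.isfinite(out).all():
            raise FloatingPointError("non-finite values in network output")
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)

    def params(self) -> list[Param]:
        return self.net.params()

    def num_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- serialization --------------------------------------------------

    def config(self) -> dict:
        return {
            "input_size": self.input_size,
            "depth": self.depth,
            "width": self.width,
            "n_keypoints": self.n_keypoints,
            "sigma": self.sigma,
            "seed": self.seed,
        }

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params()):
            arrays[f"param_{i}"] = p.value
        for i, bn in enumerate(self._batchnorms()):
            arrays[f"bn_mean_{i}"] = bn.running_mean
            arrays[f"bn_var_{i}"] = bn.running_var
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.asarray(arrays[f"param_{i}"], dtype=np.float32)
            p.grad = np.zeros_like(p.value)
            p.velocity = np.zeros_like(p.value)
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.asarray(arrays[f"bn_mean_{i}"], dtype=np.float32)
            bn.running_var = np.asarray(arrays[f"bn_var_{i}"], dtype=np.float32)

    def _batchnorms(self) -> list[BatchNorm2d]:
        found: list[BatchNorm2d] = []

        def walk(layer: Layer) -> None:
            if isinstance(layer, BatchNorm2d):
                found.append(layer)
            elif isinstance(layer, Sequential):
                for l in layer.layers:
                    walk(l)
            elif isinstance(layer, ResidualBlock):
                walk(layer.upper)
                walk(layer.lower)

        walk(self.net)
        return found


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------


def mse_heatmap_loss(pred: HeatmapStack | np.ndarray, gt: HeatmapStack | np.ndarray) -> float:
    """Mean-squared heatmap loss.

    For a single stack: the squared pixel differences are summed over each
    map and averaged over the N=6 keypoints.  For batched input (B, 6, H, W)
    the per-sample losses are averaged over the batch.  Zero iff the stacks
    are equal.
    """
    p = _as_maps(pred).astype(np.float64)
    g = _as_maps(gt).astype(np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if p.ndim == 3:
        return float(np.sum((p - g) ** 2) / p.shape[0])
    if p.ndim == 4:
        return float(np.sum((p - g) ** 2) / (p.shape[0] * p.shape[1]))
    raise ValueError("expected (6, H, W) or (B, 6, H, W)")


def mse_heatmap_loss_grad(pred: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Gradient of :func:`mse_heatmap_loss` with respect to ``pred`` (batched)."""
    B, N = pred.shape[0], pred.shape[1]
    return (2.0 / (B * N)) * (pred - gt).astype(np.float32)


class SGD:
    """Stochastic gradient descent with momentum and gradient-norm clipping.

    The global gradient norm is clipped to ``max_grad_norm`` before the
    momentum update; set it to None to disable.  Clipping guards the fixed
    learning-rate schedule against occasional large heatmap-loss gradients.
    """

    def __init__(
        self,
        params: list[Param],
        lr: float,
        momentum: float = 0.9,
        max_grad_norm: float | None = None,
    ):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.max_grad_norm = max_grad_norm

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        if self.max_grad_norm is not None:
            total = np.sqrt(
                sum(float((p.grad.astype(np.float64) ** 2).sum()) for p in self.params)
            )
            if total > self.max_grad_norm:
                scale = np.float32(self.max_grad_norm / total)
                for p in self.params:
                    p.grad *= scale
        for p in self.params:
            p.velocity = self.momentum * p.velocity + p.grad
            p.value = p.value - self.lr * p.velocity


# ---------------------------------------------------------------------------
# Checkpoint I/O
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: LGN, extra: dict | None = None) -> None:
    """Serialize model weights plus an embedded config block to one file."""
    arrays = model.state_arrays()
    payload = {"config": model.config(), "extra": extra or {}}
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with open(path, "wb") as fh:
        header = json.dumps(payload).encode()
        fh.write(len(header).to_bytes(8, "little"))
        fh.write(header)
        fh.write(zlib.compress(buf.getvalue(), level=1))


def load_checkpoint(path) -> tuple[LGN, dict]:
    """Restore an :class:`LGN` and the extra metadata stored with it."""
    with open(path, "rb") as fh:
        hlen = int.from_bytes(fh.read(8), "little")
        payload = json.loads(fh.read(hlen).decode())
        raw = zlib.decompress(fh.read())
    arrays = dict(np.load(io.BytesIO(raw)))
    model = LGN(**payload["config"])
    model.load_state_arrays(arrays)
    return model, payload.get("extra", {})
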