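"""A small, fully size-configurable U-Net implemented in numpy.

Encoder-decoder with skip connections: per encoder stage two 3x3
same-padding convolutions each followed by ReLU, then 2x2 stride-2 max
pooling; the decoder mirrors each stage with nearest-neighbor 2x
upsampling, a 3x3 convolution halving the channels, concatenation with
the same-level encoder output, and two further convolutions; a final
1x1 convolution maps the first-stage width to the class logits.
Softmax over the class axis yields per-pixel probabilities.

Forward and backward passes are written directly on float32 arrays
(im2col + BLAS matmul), which keeps a tiny variant trainable on one CPU
core and makes every result bit-reproducible under a seed.  Weights use
He initialization: zero-mean Gaussian with variance 2/N where N is the
fan-in (kernel area x input channels); biases start at zero.

Internally activations are channels-last ``(B, H, W, C)``; the public
``predict`` surface speaks ``(C, H, W)`` probability maps.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class SizeError(ValueError):
    pass


@dataclass
class UNetConfig:
    in_channels: int = 3
    num_classes: int = 3
    depth: int = 4
    #: channel widths: one per encoder stage plus the bottleneck
    widths: tuple[int, ...] = (32, 64, 128, 256, 512)
    #: convolutions per encoder stage (VGG-style presets use 3 in deep
    #: stages); None = 2 everywhere
    convs_per_stage: tuple[int, ...] | None = None
    #: pooling/upsampling factor of the bottleneck stage (4 enables the
    #: "4x4 max-pooling and 4x upsample at the bottom" variant)
    bottleneck_factor: int = 2
    encoder_preset: str = "plain"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if len(self.widths) != self.depth + 1:
            raise ValueError(
                f"widths must have depth+1={self.depth + 1} entries, got {len(self.widths)}"
            )
        if any(a >= b for a, b in zip(self.widths, self.widths[1:])):
            raise ValueError("widths must be strictly increasing along the encoder")
        if self.convs_per_stage is not None and len(self.convs_per_stage) != self.depth:
            raise ValueError("convs_per_stage must have one entry per encoder stage")
        if self.bottleneck_factor not in (2, 4):
            raise ValueError("bottleneck_factor must be 2 or 4")

    @property
    def size_multiple(self) -> int:
        return 2 ** (self.depth - 1) * self.bottleneck_factor

    @classmethod
    def tiny(cls, in_channels: int = 1, num_classes: int = 3) -> "UNetConfig":
        """Depth-3 preset (widths 8/16/32/64) for 64x64 CPU experiments."""
        return cls(in_channels=in_channels, num_classes=num_classes, depth=3,
                   widths=(8, 16, 32, 64))

    @classmethod
    def vgg16(cls, in_channels: int = 3, num_classes: int = 3) -> "UNetConfig":
        """Encoder laid out like the first 12 convolutions of VGG16
        (2+2+3+3 convs at widths 64/128/256/512, plus the bottleneck);
        pretrained weights can be loaded from an external file."""
        return cls(in_channels=in_channels, num_classes=num_classes, depth=4,
                   widths=(64, 128, 256, 512, 1024), convs_per_stage=(2, 2, 3, 3),
                   encoder_preset="vgg16-first-12")


# ---------------------------------------------------------------------------
# layers


class Conv2D:
    """Same-padding convolution with a k x k kernel (k odd)."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, name: str = ""):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.name = name
        self.W = np.zeros((k * k * in_ch, out_ch), dtype=np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._col: np.ndarray | None = None
        self._shape: tuple | None = None

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.k * self.k * self.in_ch
        std = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, size=self.W.shape).astype(np.float32)
        self.b = np.zeros(self.out_ch, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, c = x.shape
        k, p = self.k, self.k // 2
        if k == 1:
            col = x.reshape(b * h * w, c)
        else:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (B,H,W,C,k,k)
            col = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
                b * h * w, k * k * c
            )
        y = col @ self.W + self.b
        if train:
            self._col = col
            self._shape = (b, h, w, c)
        return y.reshape(b, h, w, self.out_ch)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        k, p = self.k, self.k // 2
        dy2 = dy.reshape(b * h * w, self.out_ch)
        self.gW += self._col.T @ dy2
        self.gb += dy2.sum(axis=0)
        dcol = dy2 @ self.W.T
        self._col = None
        if k == 1:
            return dcol.reshape(b, h, w, c)
        dcol = dcol.reshape(b, h, w, k, k, c)
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcol[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :]

    def zero_grad(self) -> None:
        self.gW[:] = 0
        self.gb[:] = 0


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool:
    def __init__(self, factor: int = 2):
        self.f = factor

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, c = x.shape
        f = self.f
        xr = x.reshape(b, h // f, f, w // f, f, c)
        win = xr.transpose(0, 1, 3, 5, 2, 4).reshape(b, h // f, w // f, c, f * f)
        idx = win.argmax(axis=-1)
        y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = (b, h, w, c)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        f = self.f
        flat = np.zeros((b, h // f, w // f, c, f * f), dtype=np.float32)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        dx = flat.reshape(b, h // f, w // f, c, f, f).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(b, h, w, c)


class UpsampleNearest:
    def __init__(self, factor: int = 2):
        self.f = factor

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(self.f, axis=1).repeat(self.f, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = dy.shape
        f = self.f
        return dy.reshape(b, h // f, f, w // f, f, c).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# the network


class UNet:
    def __init__(self, config: UNetConfig):
        self.config = config
        d = config.depth
        widths = config.widths
        convs = config.convs_per_stage or tuple([2] * d)
        self.enc_stages: list[list] = []
        in_ch = config.in_channels
        for s in range(d):
            stage = []
            for c in range(convs[s]):
                stage.append(Conv2D(in_ch, widths[s], 3, name=f"enc{s}_conv{c}"))
                stage.append(ReLU())
                in_ch = widths[s]
            self.enc_stages.append(stage)
        self.pools = [
            MaxPool(config.bottleneck_factor if s == d - 1 else 2) for s in range(d)
        ]
        self.bottleneck = [
            Conv2D(widths[d - 1], widths[d], 3, name="bot_conv0"), ReLU(),
            Conv2D(widths[d], widths[d], 3, name="bot_conv1"), ReLU(),
        ]
        self.dec_stages: list[dict] = []
        up_in = widths[d]
        for s in reversed(range(d)):
            stage = {
                "up": UpsampleNearest(config.bottleneck_factor if s == d - 1 else 2),
                "reduce": Conv2D(up_in, widths[s], 3, name=f"dec{s}_reduce"),
                "relu0": ReLU(),
                "convs": [
                    Conv2D(2 * widths[s], widths[s], 3, name=f"dec{s}_conv0"), ReLU(),
                    Conv2D(widths[s], widths[s], 3, name=f"dec{s}_conv1"), ReLU(),
                ],
            }
            self.dec_stages.append(stage)
            up_in = widths[s]
        self.head = Conv2D(widths[0], config.num_classes, 1, name="head")

    # -- parameter plumbing

    def conv_layers(self) -> list[Conv2D]:
        out = []
        for stage in self.enc_stages:
            out.extend(l for l in stage if isinstance(l, Conv2D))
        out.extend(l for l in self.bottleneck if isinstance(l, Conv2D))
        for stage in self.dec_stages:
            out.append(stage["reduce"])
            out.extend(l for l in stage["convs"] if isinstance(l, Conv2D))
        out.append(self.head)
        return out

    def parameters(self):
        for layer in self.conv_layers():
            yield layer, "W"
            yield layer, "b"

    def zero_grad(self) -> None:
        for layer in self.conv_layers():
            layer.zero_grad()

    def num_parameters(self) -> int:
        return sum(l.W.size + l.b.size for l in self.conv_layers())

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for l in self.conv_layers():
            out.extend([l.W.copy(), l.b.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for l in self.conv_layers():
            l.W = np.asarray(next(it), dtype=np.float32).reshape(l.W.shape).copy()
            l.b = np.asarray(next(it), dtype=np.float32).reshape(l.b.shape).copy()

    # -- passes

    def check_size(self, h: int, w: int) -> None:
        m = self.config.size_multiple
        if h % m or w % m:
            raise SizeError(
                f"input size {h}x{w} must be a multiple of {m} for depth "
                f"{self.config.depth} (bottleneck factor {self.config.bottleneck_factor})"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (B, H, W, C_in) float32 -> logits (B, H, W, num_classes)."""
        x = np.asarray(x, dtype=np.float32)
        self.check_size(x.shape[1], x.shape[2])
        skips = []
        for stage, pool in zip(self.enc_stages, self.pools):
            for layer in stage:
                x = layer.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for layer in self.bottleneck:
            x = layer.forward(x, train)
        for stage, skip in zip(self.dec_stages, reversed(skips)):
            x = stage["up"].forward(x, train)
            x = stage["relu0"].forward(stage["reduce"].forward(x, train), train)
            x = np.concatenate([x, skip], axis=-1)
            for layer in stage["convs"]:
                x = layer.forward(x, train)
        if train:
            self._skip_channels = [s.shape[-1] for s in skips]
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for stage in reversed(self.dec_stages):
            for layer in reversed(stage["convs"]):
                dx = layer.backward(dx)
            c = dx.shape[-1] // 2
            dx, dskip = dx[..., :c], dx[..., c:]
            dskips.append(dskip)
            dx = stage["reduce"].backward(stage["relu0"].backward(dx))
            dx = stage["up"].backward(dx)
        for layer in reversed(self.bottleneck):
            dx = layer.backward(dx)
        # dskips were collected shallow-to-deep; the encoder unwinds deep-to-shallow
        for stage, pool, dskip in zip(reversed(self.enc_stages),
                                      reversed(self.pools), reversed(dskips)):
            dx = pool.backward(dx)
            dx = dx + dskip
            for layer in reversed(stage):
                dx = layer.backward(dx)


def build_unet(config: UNetConfig) -> UNet:
    return UNet(config)


def init_weights(model: UNet, seed: int) -> UNet:
    """He-normal initialization of every convolution, biases zero,
    reproducible under ``seed``."""
    rng = np.random.default_rng(seed)
    for layer in model.conv_layers():
        layer.init(rng)
    return model


# ---------------------------------------------------------------------------
# inference


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def prepare_input(img: np.ndarray, in_channels: int) -> np.ndarray:
    """uint8 image (H, W) or (H, W, C) -> float32 (H, W, in_channels)
    scaled to [0, 1]."""
    arr = np.asarray(img, dtype=np.float32) / 255.0
    if arr.ndim == 2:
        arr = arr[..., None]
    if arr.shape[-1] == 1 and in_channels > 1:
        arr = np.repeat(arr, in_channels, axis=-1)
    if arr.shape[-1] != in_channels:
        raise ValueError(f"expected {in_channels} channels, got {arr.shape[-1]}")
    return arr


def predict(model: UNet, img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Segment one image.

    Returns ``(prob, mask)`` where ``prob`` has shape (classes, H, W)
    with per-pixel probabilities summing to 1, and ``mask`` is the
    per-pixel argmax (ties broken toward the lower class index).
    """
    x = prepare_input(img, model.config.in_channels)[None]
    logits = model.forward(x, train=False)[0]
    prob = softmax(logits, axis=-1)
    mask = prob.argmax(axis=-1).astype(np.uint8)
    return prob.transpose(2, 0, 1), mask


def predict_batch(model: UNet, imgs: list[np.ndarray], batch: int = 8) -> list[np.ndarray]:
    """Argmax masks for a list of same-sized images."""
    masks = []
    for i in range(0, len(imgs), batch):
        x = np.stack([prepare_input(im, model.config.in_channels) for im in imgs[i:i + batch]])
        logits = model.forward(x, train=False)
        masks.extend(np.argmax(logits, axis=-1).astype(np.uint8))
    return masks


def describe(model: UNet) -> str:
    """Layer table and parameter count."""
    lines = [f"{'layer':<14}{'kernel':>8}{'in':>6}{'out':>6}{'params':>10}"]
    for l in model.conv_layers():
        lines.append(f"{l.name:<14}{l.k:>6}x{l.k}{l.in_ch:>6}{l.out_ch:>6}"
                     f"{l.W.size + l.b.size:>10}")
    lines.append(f"total parameters: {model.num_parameters()}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: UNet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    arrays = {}
    for i, l in enumerate(model.conv_layers()):
        arrays[f"W{i}"] = l.W
        arrays[f"b{i}"] = l.b
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path) -> UNet:
    with np.load(Path(path)) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        for key in ("widths", "convs_per_stage"):
            if cfg.get(key) is not None:
                cfg[key] = tuple(cfg[key])
        model = UNet(UNetConfig(**cfg))
        for i, l in enumerate(model.conv_layers()):
            l.W = data[f"W{i}"].astype(np.float32)
            l.b = data[f"b{i}"].astype(np.float32)
    return model


def load_external_encoder_weights(model: UNet, path: str | Path) -> UNet:
    """Load externally supplied pretrained encoder weights (e.g. a VGG16
    conversion) into the encoder convolutions, in layer order.  The file
    is a .npz with arrays W0,b0,W1,b1,... matching each encoder conv's
    (k*k*in_ch, out_ch) / (out_ch,) shapes."""
    enc = []
    for stage in model.enc_stages:
        enc.extend(l for l in stage if isinstance(l, Conv2D))
    with np.load(Path(path)) as data:
        for i, l in enumerate(enc):
            if f"W{i}" not in data:
                break
            l.W = np.asarray(data[f"W{i}"], dtype=np.float32).reshape(l.W.shape)
            l.b = np.asarray(data[f"b{i}"], dtype=np.float32).reshape(l.b.shape)
    return model
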