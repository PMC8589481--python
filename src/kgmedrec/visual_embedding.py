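"""Small residual convolutional encoder for toy grayscale medical images.

The building block is the residual unit

    y_l     = h(x_l) + F(x_l, W_l)
    x_{l+1} = f(y_l)

with f = ReLU, F a two-stage conv-normalize-activate residual function and
h either the identity (identity block) or a strided 1x1 projection
(convolutional block).  Because the shortcut is additive, a stack of
zero-residual identity units is an exact identity on nonnegative inputs,
and the gradient of a loss w.r.t. any lower layer contains an additive
identity term — signal and gradient flow through the depth without
attenuation.

The full encoder follows the familiar small-ResNet recipe: stem
convolution, batch normalization, ReLU, max-pooling, then stages of one
convolutional block plus identity blocks, global average pooling and a
dense output layer.  Normalization uses batch statistics while training
and frozen running statistics in evaluation mode, so evaluation encoding
is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, conv2d, maxpool2d

__all__ = [
    "BatchNorm2d", "ResidualBlock", "ResNetConfig", "ImageEncoder",
    "identity_block", "conv_block", "residual_unit", "encode_image",
]


def _he_uniform(rng, shape, fan_in):
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, shape)


class BatchNorm2d:
    """Per-channel normalization; batch stats in training, running in eval."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor.param(np.ones((1, channels, 1, 1)))
        self.beta = Tensor.param(np.zeros((1, channels, 1, 1)))
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        if train:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            xn = (x - mu) * (var + self.eps) ** -0.5
        else:
            xn = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps))
        return xn * self.gamma + self.beta

    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class ResidualBlock:
    """Residual unit: ReLU(h(x) + F(x, W)); F = conv-BN-ReLU-conv-BN."""

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 projection: bool = False, seed: int = 0):
        if not projection and (in_channels != out_channels or stride != 1):
            raise ValueError("identity shortcut requires matching shape")
        rng = np.random.default_rng(seed)
        k = 3
        self.stride = stride
        self.conv1_w = Tensor.param(_he_uniform(rng, (out_channels, in_channels, k, k),
                                                in_channels * k * k))
        self.conv1_b = Tensor.param(np.zeros(out_channels))
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2_w = Tensor.param(_he_uniform(rng, (out_channels, out_channels, k, k),
                                                out_channels * k * k))
        self.conv2_b = Tensor.param(np.zeros(out_channels))
        self.bn2 = BatchNorm2d(out_channels)
        self.projection = projection
        if projection:
            self.proj_w = Tensor.param(_he_uniform(rng, (out_channels, in_channels, 1, 1),
                                                   in_channels))
            self.proj_b = Tensor.param(np.zeros(out_channels))
            self.proj_bn = BatchNorm2d(out_channels)

    def residual(self, x: Tensor, train: bool = False) -> Tensor:
        y = conv2d(x, self.conv1_w, self.conv1_b, stride=self.stride, pad=1)
        y = self.bn1(y, train).relu()
        y = conv2d(y, self.conv2_w, self.conv2_b, stride=1, pad=1)
        return self.bn2(y, train)

    def shortcut(self, x: Tensor, train: bool = False) -> Tensor:
        if not self.projection:
            return x
        return self.proj_bn(conv2d(x, self.proj_w, self.proj_b,
                                   stride=self.stride, pad=0), train)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return (self.shortcut(x, train) + self.residual(x, train)).relu()

    def zero_residual(self) -> "ResidualBlock":
        """Zero F's final stage so the block is the (ReLU'd) shortcut."""
        self.conv2_w.data[...] = 0.0
        self.conv2_b.data[...] = 0.0
        self.bn2.gamma.data[...] = 1.0
        self.bn2.beta.data[...] = 0.0
        return self

    def params(self) -> list[Tensor]:
        out = [self.conv1_w, self.conv1_b, self.conv2_w, self.conv2_b]
        out += self.bn1.params() + self.bn2.params()
        if self.projection:
            out += [self.proj_w, self.proj_b] + self.proj_bn.params()
        return out


def identity_block(channels: int, seed: int = 0) -> ResidualBlock:
    """Shape-preserving residual unit with identity shortcut."""
    return ResidualBlock(channels, channels, stride=1, projection=False, seed=seed)


def conv_block(in_channels: int, out_channels: int, stride: int = 2,
               seed: int = 0) -> ResidualBlock:
    """Residual unit whose shortcut is a strided 1x1 projection."""
    return ResidualBlock(in_channels, out_channels, stride=stride,
                         projection=True, seed=seed)


def residual_unit(x: np.ndarray | Tensor, block: ResidualBlock,
                  train: bool = False) -> Tensor:
    """Apply one residual unit to a (B, C, H, W) feature map."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    return block(x, train)


@dataclass
class ResNetConfig:
    stem_channels: int = 8
    # (out_channels, stride, n_identity_blocks) per stage
    stages: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(8, 1, 1), (16, 2, 1)])
    feature_dim: int = 32
    seed: int = 0


class ImageEncoder:
    """Stem conv -> BN -> ReLU -> maxpool -> residual stages -> GAP -> dense."""

    MIN_SIZE = 8

    def __init__(self, config: ResNetConfig | None = None):
        self.config = config or ResNetConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.stem_w = Tensor.param(_he_uniform(rng, (cfg.stem_channels, 1, 3, 3), 9))
        self.stem_b = Tensor.param(np.zeros(cfg.stem_channels))
        self.stem_bn = BatchNorm2d(cfg.stem_channels)
        self.blocks: list[ResidualBlock] = []
        in_ch = cfg.stem_channels
        for si, (ch, stride, n_id) in enumerate(cfg.stages):
            self.blocks.append(conv_block(in_ch, ch, stride=stride,
                                          seed=cfg.seed + 10 * si + 1))
            for b in range(n_id):
                self.blocks.append(identity_block(ch, seed=cfg.seed + 10 * si + 2 + b))
            in_ch = ch
        self.head_w = Tensor.param(_he_uniform(rng, (in_ch, cfg.feature_dim), in_ch))
        self.head_b = Tensor.param(np.zeros(cfg.feature_dim))

    def forward(self, x: Tensor, train: bool = False) -> Tensor:
        y = conv2d(x, self.stem_w, self.stem_b, stride=1, pad=1)
        y = self.stem_bn(y, train).relu()
        y = maxpool2d(y, 2)
        for block in self.blocks:
            y = block(y, train)
        pooled = y.mean(axis=(2, 3))              # global average pool (B, C)
        return pooled @ self.head_w + self.head_b

    def encode_batch(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """Encode (B, H, W) grayscale images to (B, feature_dim)."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        b, h, w = images.shape
        if h < self.MIN_SIZE or w < self.MIN_SIZE:
            raise ValueError(f"image {h}x{w} below receptive minimum {self.MIN_SIZE}")
        if h % 2 or w % 2:
            raise ValueError("image dimensions must be even for pooling")
        return self.forward(Tensor(images[:, None]), train=train).data

    def params(self) -> list[Tensor]:
        out = [self.stem_w, self.stem_b] + self.stem_bn.params()
        for b in self.blocks:
            out += b.params()
        return out + [self.head_w, self.head_b]


def encode_image(image: np.ndarray, model: ImageEncoder) -> np.ndarray:
    """Deterministic evaluation-mode feature vector for one 2-D image."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a single 2-D grayscale image")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    return model.encode_batch(image[None])[0]


def encode_images(images: dict[str, np.ndarray], model: ImageEncoder,
                  ) -> tuple[dict[str, np.ndarray], dict]:
    """Encode an id->image map; returns vectors plus a metadata header."""
    keys = list(images)
    if not keys:
        return {}, {"dim": model.config.feature_dim}
    batch = model.encode_batch(np.stack([images[k] for k in keys]))
    return ({k: batch[i] for i, k in enumerate(keys)},
            {"dim": model.config.feature_dim})
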