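"""Residual classification networks for the 3-class seedling problem.

Two architectures are provided:

``build_transfer_net``
    The standard 18-layer residual classification backbone (7×7 stem,
    3×3 max pool, four stages of two basic blocks at 64/128/256/512
    channels, projection shortcuts on channel change) with the usual
    1000-way head replaced by a 3-way fully connected layer. Its
    trainable parameter count is 11,178,051.

``build_custom_net``
    A compact variant: 3×3/16 stem at stride 3 and four two-block stages
    at 32/64/128/256 channels, with strides chosen so the stage output
    sizes on a 224×224 input are 74, 25, 9, 5 and 3. Projection shortcuts
    are used wherever the channel count or resolution changes.

Both use bias-free convolutions followed by batch normalisation, and end
with global average pooling into the fully connected head. Class order of
the 3 logits follows ``evaluation.LABELS``: (healthy, unhealthy, none).
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    conv_output_size,
    count_parameters,
)

__all__ = ["BasicBlock", "ResNet", "build_transfer_net", "build_custom_net", "count_parameters"]

NUM_CLASSES = 3


class BasicBlock(Module):
    """Two 3×3 conv/BN pairs with an additive shortcut.

    The shortcut is the identity when shape is preserved, otherwise a
    1×1 projection convolution (with BN) at the block stride.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, 3, stride=1, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)
        self.relu2 = ReLU()
        if stride != 1 or in_channels != out_channels:
            self.downsample: Sequential | None = Sequential(
                Conv2d(in_channels, out_channels, 1, stride=stride, padding=0, rng=rng),
                BatchNorm2d(out_channels),
            )
        else:
            self.downsample = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        identity = self.downsample(x) if self.downsample is not None else x
        out = self.bn1(self.conv1(x))
        out = self.relu1(out)
        out = self.bn2(self.conv2(out))
        return self.relu2(out + identity)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu2.backward(grad)
        # the sum node fans the gradient into both branches
        d_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(grad)))))
        d_short = self.downsample.backward(grad) if self.downsample is not None else grad
        return d_main + d_short


class ResNet(Module):
    """Stem + residual stages + global average pool + linear head."""

    def __init__(
        self,
        stem_channels: int,
        stem_kernel: int,
        stem_stride: int,
        stem_padding: int,
        stem_pool: bool,
        stage_channels: tuple[int, ...],
        stage_strides: tuple[int, ...],
        blocks_per_stage: int = 2,
        num_classes: int = NUM_CLASSES,
        seed: int = 0,
    ) -> None:
        super().__init__()
        rng = np.random.default_rng(seed)
        self.stem_conv = Conv2d(3, stem_channels, stem_kernel, stem_stride, stem_padding, rng=rng)
        self.stem_bn = BatchNorm2d(stem_channels)
        self.stem_relu = ReLU()
        self.pool = MaxPool2d(3, 2, 1) if stem_pool else None
        self._stem_geom = (stem_kernel, stem_stride, stem_padding, stem_pool)
        blocks: list[BasicBlock] = []
        in_ch = stem_channels
        self._stage_strides = tuple(stage_strides)
        self._stage_channels = tuple(stage_channels)
        self._blocks_per_stage = blocks_per_stage
        for ch, stride in zip(stage_channels, stage_strides):
            for b in range(blocks_per_stage):
                blocks.append(BasicBlock(in_ch, ch, stride if b == 0 else 1, rng))
                in_ch = ch
        self.blocks = blocks
        self.gap = GlobalAvgPool()
        self.fc = Linear(in_ch, num_classes, rng=rng)
        self.num_classes = num_classes

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected input of shape (N, 3, H, W), got {x.shape}")
        out = self.stem_relu(self.stem_bn(self.stem_conv(x)))
        if self.pool is not None:
            out = self.pool(out)
        for block in self.blocks:
            out = block(out)
        return self.fc(self.gap(out))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.gap.backward(self.fc.backward(grad))
        for block in reversed(self.blocks):
            grad = block.backward(grad)
        if self.pool is not None:
            grad = self.pool.backward(grad)
        return self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(grad)))

    def stage_output_sizes(self, input_size: int = 224) -> tuple[int, ...]:
        """Spatial size after the stem and after each stage (analytic)."""
        k, s, p, pooled = self._stem_geom
        size = conv_output_size(input_size, k, s, p)
        sizes = [size]
        if pooled:
            size = conv_output_size(size, 3, 2, 1)
        for stride in self._stage_strides:
            size = conv_output_size(size, 3, stride, 1)
            sizes.append(size)
        return tuple(sizes)


def build_transfer_net(num_classes: int = NUM_CLASSES, seed: int = 0) -> ResNet:
    """Standard 18-layer residual backbone with a ``num_classes``-way head.

    With the default 3-way head the trainable parameter count is exactly
    11,178,051. (Pretrained weights are a user-supplied option; fresh
    initialisation is used by default.)
    """
    return ResNet(
        stem_channels=64,
        stem_kernel=7,
        stem_stride=2,
        stem_padding=3,
        stem_pool=True,
        stage_channels=(64, 128, 256, 512),
        stage_strides=(1, 2, 2, 2),
        num_classes=num_classes,
        seed=seed,
    )


def build_custom_net(num_classes: int = NUM_CLASSES, seed: int = 0) -> ResNet:
    """Compact residual network with stage output sizes 74/25/9/5/3."""
    return ResNet(
        stem_channels=16,
        stem_kernel=3,
        stem_stride=3,
        stem_padding=0,
        stem_pool=False,
        stage_channels=(32, 64, 128, 256),
        stage_strides=(3, 3, 2, 2),
        num_classes=num_classes,
        seed=seed,
    )
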