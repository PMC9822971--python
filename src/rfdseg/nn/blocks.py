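"""Parameterized building blocks for the segmentation network."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: children and parameters are discovered by attribute scan."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        """Non-trainable state (batch-norm running stats), for checkpoints."""
        arrays: list[np.ndarray] = []
        for value in self.__dict__.values():
            if isinstance(value, Module):
                arrays.extend(value.state_arrays())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        arrays.extend(item.state_arrays())
        return arrays


class Conv3d(Module):
    """Same-padding stride-1 3-D convolution with He-normal init."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k**3
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k, k)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.weight, self.bias)


class BatchNorm3d(Module):
    def __init__(self, channels: int):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ag.batchnorm(
            x, self.gamma, self.beta, self.running_mean, self.running_var, training
        )

    def state_arrays(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]


class Dense(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, cout)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.weight), self.bias)


class ResidualDoubleConv(Module):
    """Two 3x3x3 conv + BN + ReLU layers with a residual connection from the
    block input (1x1x1 projection when channel counts differ)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv3d(cin, cout, 3, rng)
        self.bn1 = BatchNorm3d(cout)
        self.conv2 = Conv3d(cout, cout, 3, rng)
        self.bn2 = BatchNorm3d(cout)
        self.proj = Conv3d(cin, cout, 1, rng) if cin != cout else None

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        y = ag.relu(self.bn1(self.conv1(x), training))
        y = self.bn2(self.conv2(y), training)
        shortcut = self.proj(x) if self.proj is not None else x
        return ag.relu(ag.add(y, shortcut))


class DualAttention(Module):
    """Channel squeeze-and-gate plus spatial gate applied to skip features
    before they are fused with the upsampled decoder path."""

    def __init__(self, channels: int, rng: np.random.Generator):
        hidden = max(channels // 4, 4)
        self.fc1 = Dense(channels, hidden, rng)
        self.fc2 = Dense(hidden, channels, rng)
        self.spatial = Conv3d(channels, 1, 1, rng)

    def __call__(self, skip: Tensor, training: bool) -> Tensor:
        z = ag.global_avg_pool(skip)  # (N, C)
        cgate = ag.sigmoid(self.fc2(ag.relu(self.fc1(z))))
        n, c = cgate.shape
        cgate = ag.reshape(cgate, (n, c, 1, 1, 1))
        sgate = ag.sigmoid(self.spatial(skip))  # (N, 1, D, H, W)
        return ag.mul(ag.mul(skip, cgate), sgate)


class AttentionRefinement(Module):
    """Hybrid-kernel context block: parallel 3x3x3 and 5x5x5 convolutions
    concatenated into ``feature_maps`` channels."""

    def __init__(self, cin: int, feature_maps: int, rng: np.random.Generator):
        half = feature_maps // 2
        self.branch3 = Conv3d(cin, half, 3, rng)
        self.branch5 = Conv3d(cin, feature_maps - half, 5, rng)
        self.bn = BatchNorm3d(feature_maps)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        y = ag.concat([self.branch3(x), self.branch5(x)], axis=1)
        return ag.relu(self.bn(y, training))
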