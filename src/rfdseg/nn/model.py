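"""Configurable 3-D encoder-decoder with residual blocks, dual attention,
attention refinement and deep supervision.

Encoder stages are residual double-conv blocks whose channel count doubles
with each 2x downsampling, from ``base_channels`` (16 by default) capped at
``max_channels`` (128). The decoder mirrors the encoder with nearest
upsampling; skip features pass through a dual attention block (channel +
spatial gates) before fusion. Every decoder stage except the last emits a
deep-supervision probability head upsampled to full resolution. A final
attention-refinement block (parallel 3x3x3 / 5x5x5 "hybrid kernel"
convolutions concatenated into ``attention_feature_maps`` maps) precedes the
two-conv classifier that outputs a per-voxel probability field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ValidationError
from . import autograd as ag
from .autograd import Tensor
from .blocks import (
    AttentionRefinement,
    BatchNorm3d,
    Conv3d,
    DualAttention,
    Module,
    ResidualDoubleConv,
)

__all__ = ["NetworkConfig", "SegNet3D", "build_network"]


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    num_classes: int = 4
    base_channels: int = 16
    max_channels: int = 128
    depth: int = 4
    patch_size: tuple[int, int, int] = (64, 64, 64)
    use_dual_attention: bool = True
    use_attention_refinement: bool = True
    use_deep_supervision: bool = True
    attention_feature_maps: int = 16

    def __post_init__(self) -> None:
        if self.depth < 1 or self.num_classes < 2:
            raise ValidationError("depth >= 1 and num_classes >= 2 required")
        f = 2 ** (self.depth - 1)
        if any(s % f != 0 for s in self.patch_size):
            raise ValidationError(
                f"patch_size {self.patch_size} must be divisible by {f}"
            )

    @property
    def channels(self) -> list[int]:
        """Encoder channel sequence, doubling and clamped at max_channels."""
        return [
            min(self.base_channels * 2**i, self.max_channels)
            for i in range(self.depth)
        ]


class SegNet3D(Module):
    def __init__(self, config: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        ch = config.channels
        d = config.depth
        k = config.num_classes

        self.encoders = [
            ResidualDoubleConv(config.in_channels if i == 0 else ch[i - 1], ch[i], rng)
            for i in range(d)
        ]
        self.decoders = [
            ResidualDoubleConv(ch[i + 1] + ch[i], ch[i], rng) for i in range(d - 1)
        ]
        self.attentions = (
            [DualAttention(ch[i], rng) for i in range(d - 1)]
            if config.use_dual_attention
            else []
        )
        # one supervision head per decoder stage except the shallowest
        self.ds_heads = (
            [Conv3d(ch[i], k, 1, rng) for i in range(1, d - 1)]
            if config.use_deep_supervision
            else []
        )

        head_in = ch[0]
        self.refinement = None
        if config.use_attention_refinement:
            self.refinement = AttentionRefinement(
                ch[0], config.attention_feature_maps, rng
            )
            head_in = config.attention_feature_maps
        self.head_conv1 = Conv3d(head_in, head_in, 3, rng)
        self.head_bn1 = BatchNorm3d(head_in)
        self.head_conv2 = Conv3d(head_in, head_in, 3, rng)
        self.head_bn2 = BatchNorm3d(head_in)
        self.classifier = Conv3d(head_in, k, 1, rng)

    def forward(self, x: Tensor, training: bool = False):
        """Returns (probs, deep_supervision_probs): the main per-voxel class
        probability field and the list of auxiliary head fields, all at the
        input resolution and row-stochastic over the class axis."""
        cfg = self.config
        skips = []
        cur = x
        for i, enc in enumerate(self.encoders):
            cur = enc(cur, training)
            if i < cfg.depth - 1:
                skips.append(cur)
                cur = ag.maxpool2(cur)

        ds_probs = []
        for i in range(cfg.depth - 2, -1, -1):
            up = ag.upsample2(cur)
            skip = skips[i]
            if cfg.use_dual_attention:
                skip = self.attentions[i](skip, training)
            cur = self.decoders[i](ag.concat([up, skip], axis=1), training)
            if cfg.use_deep_supervision and i >= 1:
                logits = self.ds_heads[i - 1](cur)
                for _ in range(i):
                    logits = ag.upsample2(logits)
                ds_probs.append(ag.softmax_channels(logits))

        feat = cur
        if self.refinement is not None:
            feat = self.refinement(feat, training)
        feat = ag.relu(self.head_bn1(self.head_conv1(feat), training))
        feat = ag.relu(self.head_bn2(self.head_conv2(feat), training))
        probs = ag.softmax_channels(self.classifier(feat))
        return probs, ds_probs

    def predict_probs(self, volume: np.ndarray) -> np.ndarray:
        """Eval-mode forward of a single (D, H, W) patch -> (k, D, H, W)."""
        x = Tensor(volume[None, None].astype(np.float64))
        probs, _ = self.forward(x, training=False)
        return probs.data[0]


def build_network(config: NetworkConfig, seed: int = 0) -> SegNet3D:
    return SegNet3D(config, seed=seed)


def save_checkpoint(model: SegNet3D, path, extra: dict | None = None) -> None:
    """Save weights + running stats + config (npz); parameters are stored
    in the deterministic attribute-scan order."""
    import json as _json
    from dataclasses import asdict

    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    arrays.update(
        {f"state_{i}": a for i, a in enumerate(model.state_arrays())}
    )
    meta = {"config": asdict(model.config), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(
        _json.dumps(meta).encode(), dtype=np.uint8
    ), **arrays)


def load_checkpoint(path) -> SegNet3D:
    import json as _json

    with np.load(path) as data:
        meta = _json.loads(bytes(data["__meta__"].tobytes()).decode())
        cfg_dict = meta["config"]
        cfg_dict["patch_size"] = tuple(cfg_dict["patch_size"])
        model = SegNet3D(NetworkConfig(**cfg_dict))
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"param_{i}"]
        for i, a in enumerate(model.state_arrays()):
            a[...] = data[f"state_{i}"]
    return model
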