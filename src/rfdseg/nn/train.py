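"""Training (mini-batch SGD with momentum) and sliding-window inference.

The optimizer follows the published recipe: momentum 0.9, L2 weight decay
1e-4, global gradient-norm clipping at the configured threshold, initial
learning rate 1e-3 with step drops to 0.1x at the configured iterations.
The composite loss is built through the autograd graph with exactly the
formulas of :mod:`rfdseg.nn.losses`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..errors import ValidationError
from . import autograd as ag
from .autograd import Tensor
from .losses import LossWeights, inverse_frequency_weights
from .model import SegNet3D

__all__ = ["TrainConfig", "train", "predict", "one_hot"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 1e-4
    grad_clip: float = 0.005
    lr_drop_points: tuple[int, ...] = (1000, 2500)
    lr_drop_factor: float = 0.1
    batch_size: int = 1
    iterations: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size < 1 or self.iterations < 1:
            raise ValidationError("lr, batch_size, iterations must be positive")


def one_hot(mask: np.ndarray, num_classes: int) -> np.ndarray:
    """(..., ) int mask -> (k, ...) one-hot float field."""
    out = np.zeros((num_classes,) + mask.shape)
    for c in range(num_classes):
        out[c] = mask == c
    return out


class SGD:
    """SGD with momentum, decoupled-from-loss L2 penalty and global
    gradient-norm clipping."""

    def __init__(self, params: Sequence[Tensor], config: TrainConfig):
        self.params = list(params)
        self.config = config
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def lr_at(self, iteration: int) -> float:
        drops = sum(1 for p in self.config.lr_drop_points if iteration >= p)
        return self.config.lr * self.config.lr_drop_factor**drops

    def step(self, iteration: int) -> float:
        cfg = self.config
        grads = [
            (p.grad if p.grad is not None else np.zeros_like(p.data))
            + cfg.weight_decay * p.data
            for p in self.params
        ]
        norm = float(np.sqrt(sum((g**2).sum() for g in grads)))
        if cfg.grad_clip and norm > cfg.grad_clip:
            scale = cfg.grad_clip / norm
            grads = [g * scale for g in grads]
        lr = self.lr_at(iteration)
        for p, v, g in zip(self.params, self.velocity, grads):
            v *= cfg.momentum
            v -= lr * g
            p.data += v
            p.zero_grad()
        return norm


def _graph_total_loss(
    probs: Tensor,
    ds_probs: list[Tensor],
    gold: np.ndarray,
    lw: LossWeights,
    class_weights: np.ndarray,
) -> Tensor:
    k = gold.shape[1]
    n_vox = gold.size / k
    reduce_axes = (0,) + tuple(range(2, gold.ndim))
    wshape = (1, k) + (1,) * (gold.ndim - 2)

    inter = ag.tsum(ag.mul(probs, gold), axis=reduce_axes)
    total = ag.add(ag.tsum(probs, axis=reduce_axes), gold.sum(axis=reduce_axes))
    dice_terms = ag.div(ag.add(ag.mul(inter, 2.0), lw.epsilon), ag.add(total, lw.epsilon))
    l_dsc = ag.add(ag.mul(ag.tmean(dice_terms), -1.0), 1.0)

    logp = ag.log(probs, floor=1e-12)
    l_ce = ag.mul(ag.tsum(ag.mul(logp, gold)), -1.0 / n_vox)

    loss = ag.add(ag.mul(l_dsc, lw.kappa), ag.mul(l_ce, lw.gamma))
    if lw.lam > 0 and ds_probs:
        wg = gold * class_weights.reshape(wshape)
        l_max_terms = [
            ag.mul(ag.tsum(ag.mul(ag.log(h, floor=1e-12), wg)), -1.0 / n_vox)
            for h in ds_probs
        ]
        l_max = l_max_terms[0]
        for t in l_max_terms[1:]:
            l_max = ag.add(l_max, t)
        loss = ag.add(loss, ag.mul(l_max, lw.lam / len(l_max_terms)))
    return loss


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    grad_norm: list[float] = field(default_factory=list)


def _sample_patch(
    volume: np.ndarray,
    mask: np.ndarray,
    patch: tuple[int, int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    pads = [max(0, p - s) for p, s in zip(patch, volume.shape)]
    if any(pads):
        pad = [(0, p) for p in pads]
        volume = np.pad(volume, pad, mode="edge")
        mask = np.pad(mask, pad, mode="edge")
    starts = [
        int(rng.integers(0, s - p + 1)) for s, p in zip(volume.shape, patch)
    ]
    sl = tuple(slice(st, st + p) for st, p in zip(starts, patch))
    return volume[sl], mask[sl]


def train(
    model: SegNet3D,
    volumes: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    discretizer=None,
    tc: TrainConfig = TrainConfig(),
    lw: LossWeights = LossWeights(),
) -> TrainHistory:
    """Train in place on (volume, mask) pairs; returns the loss history.

    ``discretizer`` (a fitted :class:`~rfdseg.ga.VolumeDiscretization`)
    is applied to each volume before training, realizing the
    discretization-as-pre-module design. Fully seeded and deterministic.
    """
    if len(volumes) == 0 or len(volumes) != len(masks):
        raise ValidationError("need a non-empty, aligned set of volumes and masks")
    cfg = model.config
    k = cfg.num_classes
    rng = np.random.default_rng(tc.seed)

    if discretizer is not None:
        volumes = [discretizer.apply(v) for v in volumes]
    else:
        volumes = [np.asarray(v, dtype=np.float64) / 255.0 for v in volumes]

    opt = SGD(model.parameters(), tc)
    history = TrainHistory()

    for it in range(tc.iterations):
        xs, gs = [], []
        for _ in range(tc.batch_size):
            vi = int(rng.integers(0, len(volumes)))
            v, m = _sample_patch(volumes[vi], masks[vi], cfg.patch_size, rng)
            xs.append(v[None])
            gs.append(one_hot(m, k))
        x = Tensor(np.stack(xs))
        gold = np.stack(gs)
        cw = (
            np.asarray(lw.class_weights, dtype=np.float64)
            if lw.class_weights is not None
            else inverse_frequency_weights(gold.transpose(1, 0, 2, 3, 4))
        )
        probs, ds_probs = model.forward(x, training=True)
        loss = _graph_total_loss(probs, ds_probs, gold, lw, cw)
        loss.backward()
        norm = opt.step(it)
        history.loss.append(float(loss.data))
        history.lr.append(opt.lr_at(it))
        history.grad_norm.append(norm)
    return history


def predict(
    model: SegNet3D,
    volume: np.ndarray,
    discretizer=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window inference: (probability field (k, D, H, W), label mask).

    Windows of the model's patch size tile the volume (tail windows overlap);
    overlapping probabilities are averaged and renormalized, the mask is the
    per-voxel argmax with ties broken toward the lower class index. Volumes
    smaller than the patch are edge-padded and cropped back.
    """
    if discretizer is not None:
        vol = discretizer.apply(volume)
    else:
        vol = np.asarray(volume, dtype=np.float64) / 255.0

    patch = model.config.patch_size
    orig_shape = vol.shape
    pads = [max(0, p - s) for p, s in zip(patch, vol.shape)]
    if any(pads):
        vol = np.pad(vol, [(0, p) for p in pads], mode="edge")

    k = model.config.num_classes
    acc = np.zeros((k,) + vol.shape)
    cnt = np.zeros(vol.shape)

    def starts(size: int, p: int) -> list[int]:
        ss = list(range(0, size - p + 1, p))
        if ss[-1] != size - p:
            ss.append(size - p)
        return ss

    for sd in starts(vol.shape[0], patch[0]):
        for sh in starts(vol.shape[1], patch[1]):
            for sw in starts(vol.shape[2], patch[2]):
                sl = (
                    slice(sd, sd + patch[0]),
                    slice(sh, sh + patch[1]),
                    slice(sw, sw + patch[2]),
                )
                acc[(slice(None),) + sl] += model.predict_probs(vol[sl])
                cnt[sl] += 1.0
    probs = acc / cnt[None]
    probs /= probs.sum(axis=0, keepdims=True)
    crop = tuple(slice(0, s) for s in orig_shape)
    probs = probs[(slice(None),) + crop]
    return probs, probs.argmax(axis=0)
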