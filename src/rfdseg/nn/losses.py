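"""Composite segmentation loss: soft Dice + cross entropy + deep supervision.

The total training objective is

    L_total = kappa * L_DSC + gamma * L_CE + lambda * L_max,

where L_DSC is the soft multi-class Dice loss with per-class spatial
aggregation, L_CE the unweighted voxel-mean cross entropy of the main head,
and L_max the class-weighted cross entropy of the deep-supervision heads.
Defaults kappa, gamma, lambda = 1, 1, 0.5. The class axis is axis 0 for the
plain-array API here (a (k,) vector is one voxel); the training loop applies
the identical formulas through the autograd graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from ..errors import StructuralError, ValidationError

__all__ = ["LossWeights", "weighted_ce", "dsc_loss", "total_loss"]

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class LossWeights:
    """Hyperparameters of the composite loss.

    kappa, gamma, lam : weights of the Dice, cross-entropy and
        deep-supervision terms. class_weights : per-class weights of the
        deep-supervision cross entropy (None -> inverse frequency in the
        training batch, normalized to mean 1). epsilon : Dice smoothing.
    """

    kappa: float = 1.0
    gamma: float = 1.0
    lam: float = 0.5
    class_weights: Optional[tuple[float, ...]] = None
    epsilon: float = 1e-5

    def __post_init__(self) -> None:
        if min(self.kappa, self.gamma, self.lam) < 0:
            raise ValidationError("loss weights must be non-negative")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")


def _flatten(probs: np.ndarray, gold: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=np.float64)
    gold = np.asarray(gold, dtype=np.float64)
    if probs.shape != gold.shape:
        raise StructuralError(f"probs shape {probs.shape} != gold shape {gold.shape}")
    k = probs.shape[0]
    return probs.reshape(k, -1), gold.reshape(k, -1)


def weighted_ce(
    probs: np.ndarray, gold: np.ndarray, weights: Optional[Sequence[float]] = None
) -> float:
    """Class-weighted cross entropy -sum_i w_i g_i log p_i, voxel-averaged."""
    p, g = _flatten(probs, gold)
    k = p.shape[0]
    w = np.ones(k) if weights is None else np.asarray(weights, dtype=np.float64)
    if w.shape != (k,):
        raise StructuralError(f"expected {k} class weights, got {w.shape}")
    logp = np.log(np.maximum(p, _PROB_FLOOR))
    return float(-(w[:, None] * g * logp).sum(axis=0).mean())


def dsc_loss(probs: np.ndarray, gold: np.ndarray, epsilon: float = 1e-5) -> float:
    """Soft Dice loss 1 - (1/k) sum_i (2 <g_i, p_i> + eps) / (sum(g_i + p_i) + eps),
    with inner products and sums taken over the spatial domain per class."""
    p, g = _flatten(probs, gold)
    inter = (g * p).sum(axis=1)
    total = (g + p).sum(axis=1)
    return float(1.0 - ((2.0 * inter + epsilon) / (total + epsilon)).mean())


def total_loss(
    probs: np.ndarray,
    deep_supervision_probs: Union[np.ndarray, Sequence[np.ndarray], None],
    gold: np.ndarray,
    lw: LossWeights = LossWeights(),
) -> float:
    """kappa*L_DSC(main) + gamma*L_CE(main) + lambda*L_max(supervision heads).

    Multiple deep-supervision heads (each already upsampled to the gold
    resolution) contribute the mean of their weighted cross entropies.
    """
    loss = lw.kappa * dsc_loss(probs, gold, lw.epsilon)
    loss += lw.gamma * weighted_ce(probs, gold, None)
    if lw.lam > 0 and deep_supervision_probs is not None:
        heads = (
            [deep_supervision_probs]
            if isinstance(deep_supervision_probs, np.ndarray)
            else list(deep_supervision_probs)
        )
        if heads:
            w = lw.class_weights
            loss += lw.lam * float(
                np.mean([weighted_ce(h, gold, w) for h in heads])
            )
    return float(loss)


def inverse_frequency_weights(gold_onehot: np.ndarray) -> np.ndarray:
    """Per-class inverse-frequency weights, normalized to mean 1.

    Classes absent from the batch get the weight of the rarest present
    class so that a spurious prediction of an absent class is still
    penalized at the 'rare class' level.
    """
    k = gold_onehot.shape[0]
    freq = gold_onehot.reshape(k, -1).sum(axis=1)
    total = freq.sum()
    w = np.where(freq > 0, total / np.maximum(freq, 1.0), 0.0)
    if (w == 0).any():
        w[w == 0] = w[w > 0].max() if (w > 0).any() else 1.0
    return w / w.mean()
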