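"""Fuzzy c-means memberships of pixels to segmentation-region categories.

One-dimensional FCM on pixel brightness with fuzzifier m = 2: the membership
of pixel i to category j is

    u_ij = 1 / sum_k ((x_i - c_j) / (x_i - c_k))^2

and centers are updated as c_j = sum_i u_ij^2 x_i / sum_i u_ij^2, alternating
until max_ij |u_ij^{t+1} - u_ij^t| < eps or the iteration cap is reached.

Because memberships depend only on brightness, the solver groups pixels by
unique value and weights by multiplicity — numerically identical to the naive
per-pixel iteration but O(#unique) per step instead of O(N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .decision_table import DecisionTable
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "FcmConfig",
    "MembershipMatrix",
    "compute_memberships",
    "update_centers",
    "run_fcm",
]


@dataclass(frozen=True)
class FcmConfig:
    """Solver settings.

    epsilon : termination threshold on the max membership change per sweep.
    max_iter : hard iteration cap.
    init : "quantile" (deterministic, centers at the (j+0.5)/M quantiles)
           or "random" (seeded draw of M distinct observed values).
    """

    epsilon: float = 1e-5
    max_iter: int = 300
    init: str = "quantile"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.init not in ("quantile", "random"):
            raise ValidationError(f"unknown init {self.init!r}")


@dataclass(frozen=True)
class MembershipMatrix:
    """Fuzzy memberships of every pixel to every category.

    u : (N, M) row-stochastic matrix; rows of equal-brightness pixels are
        identical. centers : (M,) final class-center brightness values.
    """

    u: np.ndarray
    centers: np.ndarray
    iterations: int
    converged: bool

    @property
    def num_classes(self) -> int:
        return self.u.shape[1]


def compute_memberships(values: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Membership rows for ``values`` given fixed centers (fuzzifier 2).

    Values coinciding with one or more centers get membership 1 split
    equally among the coincident centers (the m=2 singular limit).
    """
    values = np.asarray(values, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.float64)
    if values.size == 0:
        raise ValidationError("empty values")
    if centers.ndim != 1 or len(centers) < 2:
        raise ValidationError("need at least two centers")
    if len(np.unique(centers)) != len(centers):
        raise ValidationError("centers must be pairwise distinct")

    d2 = (values[:, None] - centers[None, :]) ** 2  # (N, M)
    singular = d2 == 0.0
    u = np.empty_like(d2)

    with np.errstate(divide="ignore"):
        inv = 1.0 / d2
    # u_ij = (1/d_ij^2) / sum_k (1/d_ik^2), the algebraic rearrangement of
    # 1 / sum_k (d_ij/d_ik)^2 that is safe when some d_ik are huge.
    regular = ~singular.any(axis=1)
    u[regular] = inv[regular] / inv[regular].sum(axis=1, keepdims=True)
    if not regular.all():
        rows = ~regular
        u[rows] = singular[rows] / singular[rows].sum(axis=1, keepdims=True)
    return u


def update_centers(
    values: np.ndarray, u: np.ndarray, counts: Optional[np.ndarray] = None
) -> np.ndarray:
    """Center update c_j = sum_i u_ij^2 x_i / sum_i u_ij^2.

    ``counts`` weights each row by its pixel multiplicity (grouped mode).
    """
    values = np.asarray(values, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    w = u**2 if counts is None else (u**2) * np.asarray(counts, dtype=np.float64)[:, None]
    denom = w.sum(axis=0)
    dead = np.flatnonzero(denom == 0.0)
    if dead.size:
        raise DegenerateInputError(
            f"cluster column(s) {dead.tolist()} have zero total membership"
        )
    return (w * values[:, None]).sum(axis=0) / denom


def _init_centers(
    values: np.ndarray, counts: np.ndarray, m: int, config: FcmConfig
) -> np.ndarray:
    pixels = np.repeat(values, counts)
    if config.init == "random":
        rng = np.random.default_rng(config.seed)
        return np.sort(rng.choice(values, size=m, replace=False))
    q = (np.arange(m) + 0.5) / m
    centers = np.quantile(pixels, q)
    if len(np.unique(centers)) == m:
        return centers
    # heavily repeated values can collapse quantiles: fall back to evenly
    # spaced distinct observed values
    idx = np.linspace(0, len(values) - 1, m).round().astype(int)
    return values[idx]


def run_fcm(table: DecisionTable, config: FcmConfig = FcmConfig()) -> MembershipMatrix:
    """Iterate FCM on a decision table until converged (Lloyd-style sweeps).

    Operates on the unique brightness values weighted by their pixel counts,
    then broadcasts the converged rows back to all N pixels.
    """
    m = table.num_classes
    values, inverse, counts = np.unique(
        table.brightness, return_inverse=True, return_counts=True
    )
    if len(values) < m:
        raise DegenerateInputError(
            f"{len(values)} distinct brightness values < {m} classes"
        )

    centers = _init_centers(values, counts, m, config)
    u = compute_memberships(values, centers)
    iterations = 0
    converged = False
    for _ in range(config.max_iter):
        centers = update_centers(values, u, counts)
        u_next = compute_memberships(values, centers)
        iterations += 1
        delta = np.abs(u_next - u).max()
        u = u_next
        if delta < config.epsilon:
            converged = True
            break

    return MembershipMatrix(
        u=u[inverse], centers=centers, iterations=iterations, converged=converged
    )


def fcm_objective(values: np.ndarray, u: np.ndarray, centers: np.ndarray) -> float:
    """The m=2 FCM objective sum_ij u_ij^2 (x_i - c_j)^2 (diagnostic)."""
    values = np.asarray(values, dtype=np.float64)
    d2 = (values[:, None] - centers[None, :]) ** 2
    return float((u**2 * d2).sum())
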