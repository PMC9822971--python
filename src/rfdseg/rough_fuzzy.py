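"""Rough-fuzzy approximation of segmentation categories under a discretization.

A discretization scheme (a selected subset of candidate breakpoints) induces
an equivalence relation on pixels: two pixels are indistinguishable when
their brightness falls in the same interval (and, in per-slice mode, they lie
in the same slice). Each category j is a fuzzy set A_j given by the FCM
membership column; its rough-fuzzy lower and upper approximations at pixel x
are the inf and sup of A_j over the equivalence class of x. With sigma-count
cardinalities card(F) = sum_x F(x), the approximation precision of category j
is card(lower_j)/card(upper_j) and the average approximate precision

    eta_bar = (1/M) sum_j card(lower_j) / card(upper_j)

is the data-quality half of the discretization fitness: finer schemes have
higher eta_bar (1 when every interval holds a single brightness value),
coarser schemes save breakpoints at the price of approximation precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .decision_table import CandidateBreakpointSet, DecisionTable
from .errors import StructuralError
from .fcm import MembershipMatrix

__all__ = [
    "DiscretizationScheme",
    "RoughFuzzyApproximation",
    "interval_index",
    "approximate",
    "data_inconsistency",
]


@dataclass(frozen=True)
class DiscretizationScheme:
    """Binary selection over a candidate breakpoint set.

    ``selected[i]`` keeps candidate ``candidates.values[i]`` as a cut.
    k selected cuts partition the line into k+1 half-open intervals
    (-inf, s_1], (s_1, s_2], ..., (s_k, +inf).
    """

    candidates: CandidateBreakpointSet
    selected: np.ndarray

    def __post_init__(self) -> None:
        sel = np.asarray(self.selected, dtype=bool)
        if sel.shape != (self.candidates.n,):
            raise StructuralError(
                f"selected has length {sel.shape}, expected ({self.candidates.n},)"
            )
        object.__setattr__(self, "selected", sel)

    @property
    def n(self) -> int:
        """Number of candidate breakpoints (chromosome length, N_CB)."""
        return self.candidates.n

    @property
    def num_selected(self) -> int:
        """Number of kept breakpoints (N_DS)."""
        return int(self.selected.sum())

    @property
    def cuts(self) -> np.ndarray:
        return self.candidates.values[self.selected]

    @classmethod
    def empty(cls, candidates: CandidateBreakpointSet) -> "DiscretizationScheme":
        return cls(candidates, np.zeros(candidates.n, dtype=bool))

    @classmethod
    def full(cls, candidates: CandidateBreakpointSet) -> "DiscretizationScheme":
        return cls(candidates, np.ones(candidates.n, dtype=bool))


@dataclass(frozen=True)
class RoughFuzzyApproximation:
    """Lower/upper membership fields and the derived precision summary.

    lower, upper : (M, N) — inf/sup of each category's membership over each
    pixel's equivalence class. card_lower, card_upper : (M,) sigma-counts.
    precision : (M,) per-category approximation precision; eta_bar : their
    mean (pixel-weighted across slices in per-slice mode).
    """

    lower: np.ndarray
    upper: np.ndarray
    card_lower: np.ndarray
    card_upper: np.ndarray
    precision: np.ndarray
    eta_bar: float


def interval_index(
    value: Union[float, np.ndarray], scheme: DiscretizationScheme
) -> Union[int, np.ndarray]:
    """Index of the interval containing ``value``: the number of selected
    breakpoints strictly below it (a cut s separates v <= s from v > s)."""
    cuts = scheme.cuts
    idx = np.searchsorted(cuts, value, side="left")
    if np.isscalar(value) or np.ndim(value) == 0:
        return int(idx)
    return idx


def _membership_array(u: Union[MembershipMatrix, np.ndarray]) -> np.ndarray:
    return u.u if isinstance(u, MembershipMatrix) else np.asarray(u, dtype=np.float64)


def _scope_stats(
    values: np.ndarray, u: np.ndarray, cuts: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Grouped inf/sup and sigma-counts for one scope (slice or volume).

    Returns (lower, upper) per pixel (N, M) plus (card_lower, card_upper,
    precision) per class, computed by grouping pixels into intervals over
    the sorted unique values — never by a pairwise O(N^2) scan.
    """
    uniq, inverse = np.unique(values, return_inverse=True)
    # representative membership row per unique value (rows of equal
    # brightness are identical by construction)
    first = np.full(len(uniq), len(values), dtype=np.int64)
    np.minimum.at(first, inverse, np.arange(len(values)))
    u_uniq = u[first]
    counts = np.bincount(inverse, minlength=len(uniq)).astype(np.float64)

    interval = np.searchsorted(cuts, uniq, side="left")
    starts = np.flatnonzero(np.r_[True, np.diff(interval) > 0])
    group_of_uniq = np.cumsum(np.r_[False, np.diff(interval) > 0])

    g_min = np.minimum.reduceat(u_uniq, starts, axis=0)
    g_max = np.maximum.reduceat(u_uniq, starts, axis=0)
    g_cnt = np.add.reduceat(counts, starts)

    card_lower = (g_min * g_cnt[:, None]).sum(axis=0)
    card_upper = (g_max * g_cnt[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(card_upper > 0.0, card_lower / card_upper, 1.0)

    lower = g_min[group_of_uniq][inverse]
    upper = g_max[group_of_uniq][inverse]
    return lower, upper, card_lower, card_upper, precision


def approximate(
    u: Union[MembershipMatrix, np.ndarray],
    table: DecisionTable,
    scheme: DiscretizationScheme,
) -> RoughFuzzyApproximation:
    """Rough-fuzzy lower/upper approximations of every category fuzzy set.

    In per-slice mode equivalence classes never cross slices; per-class
    precision and eta_bar are then pixel-weighted means of the per-slice
    values, and the sigma-count cardinalities are summed over slices.
    """
    um = _membership_array(u)
    if um.shape[0] != len(table):
        raise StructuralError(
            f"membership rows ({um.shape[0]}) != table pixels ({len(table)})"
        )
    m = um.shape[1]
    n = len(table)
    cuts = scheme.cuts

    lower = np.empty((n, m))
    upper = np.empty((n, m))
    card_lower = np.zeros(m)
    card_upper = np.zeros(m)
    precision = np.zeros(m)
    eta_acc = 0.0

    for sid in table.slice_ids():
        idx = table.pixels_of(sid if table.per_slice else None)
        lo, up, cl, cu, prec = _scope_stats(table.brightness[idx], um[idx], cuts)
        lower[idx] = lo
        upper[idx] = up
        card_lower += cl
        card_upper += cu
        w = len(idx) / n
        precision += w * prec
        eta_acc += w * float(prec.mean())

    return RoughFuzzyApproximation(
        lower=lower.T,
        upper=upper.T,
        card_lower=card_lower,
        card_upper=card_upper,
        precision=precision,
        eta_bar=eta_acc,
    )


def eta_bar(
    u: Union[MembershipMatrix, np.ndarray],
    table: DecisionTable,
    scheme: DiscretizationScheme,
) -> float:
    """Average approximate precision of the scheme (scalar shortcut)."""
    return approximate(u, table, scheme).eta_bar


def data_inconsistency(table: DecisionTable, scheme: DiscretizationScheme) -> float:
    """Fraction of pixels whose equivalence class mixes gold-standard labels.

    0 means the discretized brightness still determines the label everywhere;
    1 means every pixel shares an interval with a differently-labeled pixel.
    """
    cuts = scheme.cuts
    bad = 0.0
    for sid in table.slice_ids():
        idx = table.pixels_of(sid if table.per_slice else None)
        uniq, inverse, counts = np.unique(
            table.brightness[idx], return_inverse=True, return_counts=True
        )
        lab = np.zeros((len(uniq), table.num_classes))
        np.add.at(lab, (inverse, table.labels[idx]), 1.0)
        interval = np.searchsorted(cuts, uniq, side="left")
        starts = np.flatnonzero(np.r_[True, np.diff(interval) > 0])
        g_lab = np.add.reduceat(lab, starts, axis=0)
        g_cnt = np.add.reduceat(counts.astype(np.float64), starts)
        mixed = (g_lab > 0).sum(axis=1) > 1
        bad += float(g_cnt[mixed].sum())
    return bad / len(table)


# ---------------------------------------------------------------------------
# Compact per-scope representation used by the GA fitness loop.


@dataclass(frozen=True)
class ScopeCompact:
    """Unique brightness values of one scope with counts, membership rows
    and per-label pixel counts — the sufficient statistics for eta_bar and
    data_inconsistency under any scheme."""

    values: np.ndarray  # (U,) sorted unique
    counts: np.ndarray  # (U,) float
    u: np.ndarray  # (U, M)
    label_counts: np.ndarray  # (U, M) pixels of each label per value
    n_pixels: int


def compact_scopes(
    table: DecisionTable, u: Union[MembershipMatrix, np.ndarray]
) -> list[ScopeCompact]:
    um = _membership_array(u)
    out = []
    for sid in table.slice_ids():
        idx = table.pixels_of(sid if table.per_slice else None)
        vals = table.brightness[idx]
        uniq, inverse, counts = np.unique(vals, return_inverse=True, return_counts=True)
        first = np.full(len(uniq), len(idx), dtype=np.int64)
        np.minimum.at(first, inverse, np.arange(len(idx)))
        lab = np.zeros((len(uniq), table.num_classes))
        np.add.at(lab, (inverse, table.labels[idx]), 1.0)
        out.append(
            ScopeCompact(
                values=uniq,
                counts=counts.astype(np.float64),
                u=um[idx][first],
                label_counts=lab,
                n_pixels=len(idx),
            )
        )
    return out


def scope_eta_bar(compact: ScopeCompact, cuts: np.ndarray) -> float:
    """eta_bar of one scope under the given cut values."""
    interval = np.searchsorted(cuts, compact.values, side="left")
    starts = np.flatnonzero(np.r_[True, np.diff(interval) > 0])
    g_min = np.minimum.reduceat(compact.u, starts, axis=0)
    g_max = np.maximum.reduceat(compact.u, starts, axis=0)
    g_cnt = np.add.reduceat(compact.counts, starts)
    card_lower = (g_min * g_cnt[:, None]).sum(axis=0)
    card_upper = (g_max * g_cnt[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(card_upper > 0.0, card_lower / card_upper, 1.0)
    return float(precision.mean())


def scope_inconsistency(compact: ScopeCompact, cuts: np.ndarray) -> float:
    """Mixed-label pixel count of one scope under the given cuts."""
    interval = np.searchsorted(cuts, compact.values, side="left")
    starts = np.flatnonzero(np.r_[True, np.diff(interval) > 0])
    g_lab = np.add.reduceat(compact.label_counts, starts, axis=0)
    g_cnt = np.add.reduceat(compact.counts, starts)
    mixed = (g_lab > 0).sum(axis=1) > 1
    return float(g_cnt[mixed].sum())
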