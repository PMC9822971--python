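"""Genetic-algorithm search for discretization breakpoints.

Chromosomes are binary strings over the candidate breakpoint set (bit i = 1
keeps candidate i as a cut). The fitness of a scheme balances parsimony
against rough-fuzzy approximation precision:

    Fitness = alpha * (N_CB - N_DS) / N_CB + beta * eta_bar,

with alpha + beta = 1: the first term rewards dropping breakpoints, the
second rewards schemes whose intervals approximate the category fuzzy sets
tightly. The GA uses tournament selection, single-point crossover, per-bit
mutation and elitism, with the empty and all-selected chromosomes injected
into the initial population so the result is never worse than either limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .decision_table import (
    CandidateBreakpointSet,
    DecisionTable,
    build_decision_table,
    extract_candidate_breakpoints,
)
from .errors import ValidationError
from .fcm import FcmConfig, MembershipMatrix, run_fcm
from .rough_fuzzy import (
    DiscretizationScheme,
    compact_scopes,
    data_inconsistency,
    eta_bar,
    scope_eta_bar,
)

__all__ = [
    "GAConfig",
    "GAResult",
    "fitness",
    "evolve",
    "apply_scheme",
    "discretize",
    "VolumeDiscretization",
]


@dataclass(frozen=True)
class GAConfig:
    """Search settings; alpha/beta are the fitness weights (must sum to 1)."""

    alpha: float = 0.5
    beta: float = 0.5
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: Optional[float] = None  # None -> 1/n per bit
    tournament_size: int = 2
    elitism: int = 1
    fitness_target: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValidationError("alpha, beta must be non-negative and sum to 1")
        if self.population_size < 1 or self.generations < 1:
            raise ValidationError("population_size and generations must be >= 1")
        if self.population_size < self.elitism:
            raise ValidationError("population_size must be >= elitism")
        if not (0.0 <= self.crossover_rate <= 1.0):
            raise ValidationError("crossover_rate must lie in [0, 1]")


@dataclass
class GAResult:
    best_scheme: DiscretizationScheme
    best_fitness: float
    eta_bar: float
    history: list[float]
    generations_run: int
    stopped_early: bool


def fitness(
    scheme: DiscretizationScheme,
    u: Union[MembershipMatrix, np.ndarray],
    table: DecisionTable,
    alpha: float = 0.5,
    beta: float = 0.5,
) -> float:
    """Fitness = alpha*(N_CB - N_DS)/N_CB + beta*eta_bar(scheme)."""
    if alpha < 0 or beta < 0 or abs(alpha + beta - 1.0) > 1e-12:
        raise ValidationError("alpha, beta must be non-negative and sum to 1")
    n_cb = scheme.n
    parsimony = (n_cb - scheme.num_selected) / n_cb
    return alpha * parsimony + beta * eta_bar(u, table, scheme)


class _FitnessCache:
    """Evaluates chromosomes on the compact sufficient statistics, with
    memoization keyed by the chromosome bits (eta_bar dominates cost)."""

    def __init__(
        self,
        table: DecisionTable,
        u: Union[MembershipMatrix, np.ndarray],
        candidates: CandidateBreakpointSet,
        alpha: float,
        beta: float,
    ) -> None:
        self.scopes = compact_scopes(table, u)
        self.weights = np.array([s.n_pixels for s in self.scopes], dtype=np.float64)
        self.weights /= self.weights.sum()
        self.candidates = candidates
        self.alpha = alpha
        self.beta = beta
        self._memo: dict[bytes, float] = {}

    def __call__(self, bits: np.ndarray) -> tuple[float, float]:
        """Returns (fitness, eta_bar); eta_bar breaks exact fitness ties in
        favour of the scheme with higher approximation precision."""
        key = np.packbits(bits).tobytes()
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        cuts = self.candidates.values[bits]
        eta = sum(
            w * scope_eta_bar(s, cuts) for w, s in zip(self.weights, self.scopes)
        )
        n = self.candidates.n
        fit = self.alpha * (n - int(bits.sum())) / n + self.beta * eta
        self._memo[key] = (fit, eta)
        return (fit, eta)


def evolve(
    table: DecisionTable,
    u: Union[MembershipMatrix, np.ndarray],
    candidates: CandidateBreakpointSet,
    config: GAConfig = GAConfig(),
) -> GAResult:
    """Run the seeded GA and return the best scheme ever seen.

    The history records the global best fitness after each generation and is
    therefore non-decreasing; with the empty and all-selected chromosomes in
    the initial population the result is never worse than either.
    """
    n = candidates.n
    rng = np.random.default_rng(config.seed)
    p_mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / n
    evaluate = _FitnessCache(table, u, candidates, config.alpha, config.beta)

    pop = rng.random((config.population_size, n)) < 0.5
    pop[0] = False  # empty scheme
    if config.population_size > 1:
        pop[1] = True  # all-selected scheme
    scores = [evaluate(c) for c in pop]  # (fitness, eta_bar) pairs
    fits = np.array([s[0] for s in scores])

    best_idx = int(np.lexsort((np.array([s[1] for s in scores]), fits))[-1])
    best_bits = pop[best_idx].copy()
    best_score = scores[best_idx]
    history: list[float] = []
    stopped_early = False
    gens = 0

    for gen in range(config.generations):
        gens = gen + 1
        history.append(best_score[0])
        if config.fitness_target is not None and best_score[0] >= config.fitness_target:
            stopped_early = True
            break

        children = [best_bits.copy() for _ in range(config.elitism)]
        while len(children) < config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population_size, config.tournament_size)
                parents.append(pop[contenders[fits[contenders].argmax()]].copy())
            a, b = parents
            if n >= 2 and rng.random() < config.crossover_rate:
                point = int(rng.integers(1, n))
                a[point:], b[point:] = b[point:].copy(), a[point:].copy()
            for child in (a, b):
                flip = rng.random(n) < p_mut
                child[flip] = ~child[flip]
                if len(children) < config.population_size:
                    children.append(child)
        pop = np.array(children)
        scores = [evaluate(c) for c in pop]
        fits = np.array([s[0] for s in scores])
        idx = int(np.lexsort((np.array([s[1] for s in scores]), fits))[-1])
        if scores[idx] > best_score:
            best_score = scores[idx]
            best_bits = pop[idx].copy()
        history[-1] = best_score[0]

    scheme = DiscretizationScheme(candidates, best_bits)
    return GAResult(
        best_scheme=scheme,
        best_fitness=best_score[0],
        eta_bar=eta_bar(u, table, scheme),
        history=history,
        generations_run=gens,
        stopped_early=stopped_early,
    )


def apply_scheme(
    image: np.ndarray,
    scheme: DiscretizationScheme,
    encoding: str = "interval_mean",
    table: Optional[DecisionTable] = None,
) -> np.ndarray:
    """Replace every pixel by its interval's representative value.

    encoding:
      - "index": the interval index itself (0, 1, ...).
      - "midpoint": midpoint between the bounding cuts (outer intervals use
        the extreme candidate values as bounds).
      - "interval_mean" (default): mean observed brightness of the interval
        in the fitting ``table``, rescaled to [0, 1] by the table's declared
        value range — the representation fed to the network.
    """
    image = np.asarray(image, dtype=np.float64)
    idx = np.searchsorted(scheme.cuts, image, side="left")
    k = scheme.num_selected

    if encoding == "index":
        return idx.astype(np.float64)

    cand = scheme.candidates.values
    bounds = np.concatenate([[cand[0]], scheme.cuts, [cand[-1]]])
    midpoints = (bounds[:-1] + bounds[1:]) / 2.0

    if encoding == "midpoint":
        return midpoints[idx]
    if encoding != "interval_mean":
        raise ValidationError(f"unknown encoding {encoding!r}")
    if table is None:
        raise ValidationError("interval_mean encoding requires the fitting table")

    tab_idx = np.searchsorted(scheme.cuts, table.brightness, side="left")
    sums = np.bincount(tab_idx, weights=table.brightness, minlength=k + 1)
    counts = np.bincount(tab_idx, minlength=k + 1)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), midpoints)
    lo, hi = table.value_range
    span = hi - lo if hi > lo else 1.0
    return (means[idx] - lo) / span


# ---------------------------------------------------------------------------
# Volume-level orchestration


def _interval_representatives(
    scheme: DiscretizationScheme, table: DecisionTable
) -> np.ndarray:
    """Rescaled mean observed brightness per interval ((k+1,) for k cuts);
    empty intervals fall back to the cut midpoint."""
    k = scheme.num_selected
    cand = scheme.candidates.values
    bounds = np.concatenate([[cand[0]], scheme.cuts, [cand[-1]]])
    midpoints = (bounds[:-1] + bounds[1:]) / 2.0
    tab_idx = np.searchsorted(scheme.cuts, table.brightness, side="left")
    sums = np.bincount(tab_idx, weights=table.brightness, minlength=k + 1)
    counts = np.bincount(tab_idx, minlength=k + 1)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), midpoints)
    lo, hi = table.value_range
    span = hi - lo if hi > lo else 1.0
    return (means - lo) / span


@dataclass
class VolumeDiscretization:
    """Result of discretizing a volume: one scheme per scope.

    In per-slice mode scope i is slice i and totals follow the per-slice
    accounting (candidate counts and selected counts summed over slices).
    A saved instance reloads without the fitting tables; the per-interval
    representative values are carried in the JSON.
    """

    schemes: list[DiscretizationScheme]
    interval_means: list[np.ndarray]
    per_slice: bool
    alpha: float
    beta: float
    seed: int
    scope_fitness: list[float]
    scope_eta: list[float]
    scope_pixels: list[int]
    eta_bar: float
    data_inconsistency: float
    membership_iterations: int = 0
    results: Optional[list[GAResult]] = None

    @property
    def total_candidates(self) -> int:
        return sum(s.n for s in self.schemes)

    @property
    def total_selected(self) -> int:
        return sum(s.num_selected for s in self.schemes)

    def _apply_scope(
        self, data: np.ndarray, i: int, encoding: str
    ) -> np.ndarray:
        scheme = self.schemes[i]
        if encoding == "interval_mean":
            idx = np.searchsorted(scheme.cuts, data, side="left")
            return self.interval_means[i][idx]
        return apply_scheme(data, scheme, encoding)

    def apply(self, volume: np.ndarray, encoding: str = "interval_mean") -> np.ndarray:
        volume = np.asarray(volume, dtype=np.float64)
        if not self.per_slice:
            return self._apply_scope(volume, 0, encoding)
        if volume.ndim != 3 or volume.shape[0] != len(self.schemes):
            raise ValidationError(
                f"per-slice discretization with {len(self.schemes)} schemes "
                f"cannot apply to volume of shape {volume.shape}"
            )
        out = np.empty_like(volume)
        for i in range(volume.shape[0]):
            out[i] = self._apply_scope(volume[i], i, encoding)
        return out

    def to_dict(self) -> dict:
        return {
            "per_slice": self.per_slice,
            "alpha": self.alpha,
            "beta": self.beta,
            "seed": self.seed,
            "eta_bar": self.eta_bar,
            "data_inconsistency": self.data_inconsistency,
            "total_candidates": self.total_candidates,
            "total_selected": self.total_selected,
            "scopes": [
                {
                    "candidates": s.candidates.values.tolist(),
                    "selected": s.selected.astype(int).tolist(),
                    "fitness": f,
                    "eta_bar": e,
                    "n_pixels": n,
                    "interval_means": m.tolist(),
                }
                for s, f, e, n, m in zip(
                    self.schemes,
                    self.scope_fitness,
                    self.scope_eta,
                    self.scope_pixels,
                    self.interval_means,
                )
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeDiscretization":
        schemes = [
            DiscretizationScheme(
                CandidateBreakpointSet(np.asarray(s["candidates"], dtype=np.float64)),
                np.asarray(s["selected"], dtype=bool),
            )
            for s in d["scopes"]
        ]
        return cls(
            schemes=schemes,
            interval_means=[
                np.asarray(s["interval_means"], dtype=np.float64) for s in d["scopes"]
            ],
            per_slice=d["per_slice"],
            alpha=d["alpha"],
            beta=d["beta"],
            seed=d["seed"],
            scope_fitness=[s["fitness"] for s in d["scopes"]],
            scope_eta=[s["eta_bar"] for s in d["scopes"]],
            scope_pixels=[s["n_pixels"] for s in d["scopes"]],
            eta_bar=d["eta_bar"],
            data_inconsistency=d["data_inconsistency"],
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "VolumeDiscretization":
        return cls.from_dict(json.loads(Path(path).read_text()))


def discretize(
    image: np.ndarray,
    mask: np.ndarray,
    num_classes: int,
    mode: str = "per_slice",
    fcm_config: FcmConfig = FcmConfig(),
    ga_config: GAConfig = GAConfig(),
) -> VolumeDiscretization:
    """Full discretization pipeline: decision table -> FCM -> GA per scope.

    Memberships are computed once on the raw brightness of the whole input
    (fuzzification precedes the breakpoint search); in per-slice mode the GA
    then runs independently per slice on that slice's candidates, with the
    per-scope seed derived from the base seed.
    """
    table = build_decision_table(image, mask, num_classes, mode=mode)
    membership = run_fcm(table, fcm_config)

    schemes, results, means, incons, npix = [], [], [], [], []
    scope_list = table.slice_ids() if table.per_slice else [None]
    for i, sid in enumerate(scope_list):
        idx = table.pixels_of(sid if table.per_slice else None)
        sub = DecisionTable(
            brightness=table.brightness[idx],
            labels=table.labels[idx],
            num_classes=table.num_classes,
            value_range=table.value_range,
            provenance={**table.provenance, "scope": None if sid is None else int(sid)},
        )
        candidates = extract_candidate_breakpoints(table, sid if table.per_slice else None)
        cfg = GAConfig(
            **{
                **ga_config.__dict__,
                "seed": (ga_config.seed + 1009 * i) % (2**31 - 1),
            }
        )
        res = evolve(sub, membership.u[idx], candidates, cfg)
        schemes.append(res.best_scheme)
        results.append(res)
        means.append(_interval_representatives(res.best_scheme, sub))
        incons.append(data_inconsistency(sub, res.best_scheme))
        npix.append(len(sub))

    w = np.asarray(npix, dtype=np.float64)
    w /= w.sum()
    return VolumeDiscretization(
        schemes=schemes,
        interval_means=means,
        per_slice=table.per_slice,
        alpha=ga_config.alpha,
        beta=ga_config.beta,
        seed=ga_config.seed,
        scope_fitness=[r.best_fitness for r in results],
        scope_eta=[r.eta_bar for r in results],
        scope_pixels=npix,
        eta_bar=float((w * np.array([r.eta_bar for r in results])).sum()),
        data_inconsistency=float((w * np.asarray(incons)).sum()),
        membership_iterations=membership.iterations,
        results=results,
    )
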