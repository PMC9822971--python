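import itertools

import numpy as np
import pytest

from rfdseg.decision_table import CandidateBreakpointSet
from rfdseg.errors import ValidationError
from rfdseg.ga import GAConfig, apply_scheme, evolve, fitness
from rfdseg.rough_fuzzy import DiscretizationScheme

from conftest import random_membership, random_table


def exhaustive_best(table, u, candidates, alpha=0.5, beta=0.5):
    best = None
    for bits in itertools.product([False, True], repeat=candidates.n):
        scheme = DiscretizationScheme(candidates, np.array(bits))
        f = fitness(scheme, u, table, alpha, beta)
        if best is None or f > best[0]:
            best = (f, bits)
    return best


class TestFitness:
    def test_hand_worked_values(self, worked_example):
        table, u, candidates = worked_example
        cut10 = DiscretizationScheme(candidates, np.array([True, False]))
        empty = DiscretizationScheme.empty(candidates)
        full = DiscretizationScheme.full(candidates)
        assert fitness(cut10, u, table) == pytest.approx(0.75)
        assert fitness(empty, u, table) == pytest.approx(0.5868055555, abs=1e-9)
        assert fitness(full, u, table) == pytest.approx(0.5)

    def test_all_selected_fitness_equals_beta(self):
        rng = np.random.default_rng(0)
        table = random_table(rng, n=60, m=3)
        u = random_membership(rng, table.brightness, 3)
        cand = CandidateBreakpointSet(np.unique(table.brightness))
        for alpha in (0.0, 0.3, 0.7):
            f = fitness(DiscretizationScheme.full(cand), u, table, alpha, 1 - alpha)
            assert f == pytest.approx(1 - alpha)

    def test_weights_must_sum_to_one(self, worked_example):
        table, u, candidates = worked_example
        with pytest.raises(ValidationError):
            fitness(DiscretizationScheme.empty(candidates), u, table, 0.5, 0.6)

    def test_fitness_in_unit_interval(self):
        rng = np.random.default_rng(5)
        table = random_table(rng, n=50, m=2, n_values=8)
        u = random_membership(rng, table.brightness, 2)
        cand = CandidateBreakpointSet(np.unique(table.brightness))
        for _ in range(20):
            sel = rng.random(cand.n) < rng.random()
            f = fitness(DiscretizationScheme(cand, sel), u, table)
            assert 0.0 <= f <= 1.0


class TestEvolve:
    @pytest.mark.parametrize("seed", [0, 7, 42])
    def test_recovers_known_optimum_from_any_seed(self, worked_example, seed):
        table, u, candidates = worked_example
        res = evolve(table, u, candidates, GAConfig(seed=seed, generations=10,
                                                    population_size=12))
        assert res.best_scheme.selected.tolist() == [True, False]
        assert res.best_fitness == pytest.approx(0.75)

    def test_parsimony_only_returns_empty_scheme(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, n=40, m=2, n_values=9)
        u = random_membership(rng, table.brightness, 2)
        cand = CandidateBreakpointSet(np.unique(table.brightness))
        res = evolve(table, u, cand, GAConfig(alpha=1.0, beta=0.0, seed=0,
                                              generations=5, population_size=10))
        assert res.best_scheme.num_selected == 0
        assert res.best_fitness == pytest.approx(1.0)

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(2)
        table = random_table(rng, n=60, m=3, n_values=10)
        u = random_membership(rng, table.brightness, 3)
        cand = CandidateBreakpointSet(np.unique(table.brightness))
        cfg = GAConfig(seed=17, generations=15, population_size=16)
        r1 = evolve(table, u, cand, cfg)
        r2 = evolve(table, u, cand, cfg)
        assert np.array_equal(r1.best_scheme.selected, r2.best_scheme.selected)
        assert r1.history == r2.history

    def test_history_monotone_and_bounded_by_limits(self):
        rng = np.random.default_rng(3)
        table = random_table(rng, n=70, m=3, n_values=11)
        u = random_membership(rng, table.brightness, 3)
        cand = CandidateBreakpointSet(np.unique(table.brightness))
        res = evolve(table, u, cand, GAConfig(seed=5, generations=20,
                                              population_size=14))
        assert all(b >= a for a, b in zip(res.history, res.history[1:]))
        assert res.best_fitness == res.history[-1]
        f_empty = fitness(DiscretizationScheme.empty(cand), u, table)
        f_full = fitness(DiscretizationScheme.full(cand), u, table)
        assert res.best_fitness >= max(f_empty, f_full) - 1e-12

    def test_fitness_target_stops_early(self, worked_example):
        table, u, candidates = worked_example
        res = evolve(table, u, candidates,
                     GAConfig(seed=0, generations=50, population_size=12,
                              fitness_target=0.7))
        assert res.stopped_early
        assert res.generations_run < 50

    def test_never_exceeds_exhaustive_optimum(self):
        rng = np.random.default_rng(11)
        for seed in range(5):
            table = random_table(rng, n=50, m=2, n_values=8)
            u = random_membership(rng, table.brightness, 2)
            cand = CandidateBreakpointSet(np.unique(table.brightness))
            res = evolve(table, u, cand, GAConfig(seed=seed, generations=30,
                                                  population_size=20))
            best_f, _ = exhaustive_best(table, u, cand)
            assert res.best_fitness <= best_f + 1e-12


class TestApplyScheme:
    def test_index_encoding(self):
        cand = CandidateBreakpointSet(np.array([10.0, 20.0]))
        scheme = DiscretizationScheme(cand, np.array([True, False]))
        out = apply_scheme(np.array([5.0, 10.0, 15.0]), scheme, "index")
        assert out.tolist() == [0.0, 0.0, 1.0]

    def test_all_selected_interval_mean_is_affine_rescale(self, worked_example):
        table, _, candidates = worked_example
        scheme = DiscretizationScheme.full(candidates)
        img = np.array([10.0, 20.0, 10.0])
        out = apply_scheme(img, scheme, "interval_mean", table)
        assert np.allclose(out, img / 255.0)

    def test_empty_scheme_interval_mean_is_global_mean(self, worked_example):
        table, _, candidates = worked_example
        scheme = DiscretizationScheme.empty(candidates)
        out = apply_scheme(np.array([10.0, 20.0]), scheme, "interval_mean", table)
        assert np.allclose(out, 15.0 / 255.0)

    def test_interval_mean_without_table_rejected(self, worked_example):
        _, _, candidates = worked_example
        with pytest.raises(ValidationError):
            apply_scheme(np.array([1.0]), DiscretizationScheme.empty(candidates),
                         "interval_mean")

    def test_output_constant_within_equivalence_classes(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 50, (8, 8)).astype(float)
        vals = np.unique(img)
        cand = CandidateBreakpointSet(vals)
        sel = rng.random(cand.n) < 0.5
        scheme = DiscretizationScheme(cand, sel)
        out = apply_scheme(img, scheme, "midpoint")
        idx = np.searchsorted(scheme.cuts, img, side="left")
        for i in np.unique(idx):
            assert len(np.unique(out[idx == i])) == 1
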