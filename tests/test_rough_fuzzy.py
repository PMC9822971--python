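import numpy as np
import pytest

from rfdseg.decision_table import CandidateBreakpointSet, DecisionTable
from rfdseg.errors import StructuralError
from rfdseg.rough_fuzzy import (
    DiscretizationScheme,
    approximate,
    data_inconsistency,
    interval_index,
)

from conftest import random_membership, random_table


def pairwise_oracle(u, table, scheme):
    """Brute-force O(N^2) reference: for each pixel scan all pixels in its
    equivalence class ((same interval) and (same slice in per-slice mode))."""
    n, m = u.shape
    cuts = scheme.cuts
    interval = np.searchsorted(cuts, table.brightness, side="left")
    sid = table.slice_id if table.slice_id is not None else np.zeros(n, int)
    lower = np.empty((n, m))
    upper = np.empty((n, m))
    for i in range(n):
        same = (interval == interval[i]) & (sid == sid[i])
        lower[i] = u[same].min(axis=0)
        upper[i] = u[same].max(axis=0)
    return lower.T, upper.T


def oracle_eta(u, table, scheme):
    lower, upper = pairwise_oracle(u, table, scheme)
    sid = table.slice_id if table.slice_id is not None else np.zeros(len(table), int)
    etas, weights = [], []
    for s in np.unique(sid):
        sel = sid == s
        cl = lower[:, sel].sum(axis=1)
        cu = upper[:, sel].sum(axis=1)
        prec = np.where(cu > 0, cl / np.maximum(cu, 1e-300), 1.0)
        etas.append(prec.mean())
        weights.append(sel.sum())
    return float(np.average(etas, weights=weights))


class TestIntervalIndex:
    def test_boundary_value_closes_its_interval(self):
        cand = CandidateBreakpointSet(np.array([10.0]))
        scheme = DiscretizationScheme.full(cand)
        assert interval_index(10.0, scheme) == 0
        assert interval_index(11.0, scheme) == 1

    def test_counts_cuts_strictly_below(self):
        cand = CandidateBreakpointSet(np.array([10.0, 20.0, 30.0]))
        scheme = DiscretizationScheme.full(cand)
        assert interval_index(25.0, scheme) == 2

    def test_vectorized_matches_scalar(self):
        cand = CandidateBreakpointSet(np.array([5.0, 15.0]))
        scheme = DiscretizationScheme(cand, np.array([True, True]))
        vals = np.array([1.0, 5.0, 6.0, 15.0, 99.0])
        idx = interval_index(vals, scheme)
        assert idx.tolist() == [interval_index(float(v), scheme) for v in vals]


class TestApproximate:
    def test_hand_worked_single_interval(self, worked_example):
        table, u, candidates = worked_example
        ap = approximate(u, table, DiscretizationScheme.empty(candidates))
        assert np.allclose(ap.precision, [0.8 / 3.6, 0.4 / 3.2])
        assert ap.eta_bar == pytest.approx(0.1736111111, abs=1e-9)
        # inf/sup over the single class
        assert np.allclose(ap.lower[0], 0.2) and np.allclose(ap.upper[0], 0.9)

    def test_separating_cut_gives_exact_approximation(self, worked_example):
        table, u, candidates = worked_example
        scheme = DiscretizationScheme(candidates, np.array([True, False]))
        ap = approximate(u, table, scheme)
        assert np.allclose(ap.lower, ap.upper)
        assert ap.eta_bar == pytest.approx(1.0)

    def test_all_selected_scheme_is_exact(self):
        rng = np.random.default_rng(2)
        table = random_table(rng, n=80, m=3)
        u = random_membership(rng, table.brightness, 3)
        cand = CandidateBreakpointSet(np.unique(table.brightness))
        ap = approximate(u, table, DiscretizationScheme.full(cand))
        assert ap.eta_bar == pytest.approx(1.0)

    def test_fuzzy_set_between_its_approximations(self):
        rng = np.random.default_rng(4)
        table = random_table(rng, n=150, m=4)
        u = random_membership(rng, table.brightness, 4)
        cand = CandidateBreakpointSet(np.unique(table.brightness))
        sel = rng.random(cand.n) < 0.4
        ap = approximate(u, table, DiscretizationScheme(cand, sel))
        assert (ap.lower <= u.T + 1e-12).all()
        assert (ap.upper >= u.T - 1e-12).all()
        assert (ap.card_lower <= ap.card_upper + 1e-12).all()
        assert ap.eta_bar == pytest.approx(float(ap.precision.mean()))

    @pytest.mark.parametrize("seed", range(5))
    def test_grouped_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng, n=120, m=3, n_values=10)
        u = random_membership(rng, table.brightness, 3)
        cand = CandidateBreakpointSet(np.unique(table.brightness))
        sel = rng.random(cand.n) < 0.5
        scheme = DiscretizationScheme(cand, sel)
        ap = approximate(u, table, scheme)
        lo_ref, up_ref = pairwise_oracle(u, table, scheme)
        assert np.allclose(ap.lower, lo_ref, atol=1e-12)
        assert np.allclose(ap.upper, up_ref, atol=1e-12)
        assert ap.eta_bar == pytest.approx(oracle_eta(u, table, scheme), abs=1e-12)

    def test_per_slice_classes_do_not_cross_slices(self):
        # two slices with identical brightness but different memberships
        # would be merged in whole-volume mode; per-slice keeps them apart
        brightness = np.array([10.0, 10.0, 10.0, 10.0])
        table = DecisionTable(
            brightness=brightness,
            labels=np.array([0, 0, 1, 1]),
            num_classes=2,
            value_range=(0.0, 255.0),
            slice_id=np.array([0, 0, 1, 1]),
        )
        u = np.array([[0.9, 0.1], [0.9, 0.1], [0.2, 0.8], [0.2, 0.8]])
        cand = CandidateBreakpointSet(np.array([10.0]))
        ap = approximate(u, table, DiscretizationScheme.empty(cand))
        # each slice is internally constant (memberships only need to be a
        # function of brightness within a slice), so approximation is exact
        assert ap.eta_bar == pytest.approx(1.0)

    def test_misaligned_lengths_rejected(self, worked_example):
        table, u, candidates = worked_example
        with pytest.raises(StructuralError):
            approximate(u[:2], table, DiscretizationScheme.empty(candidates))


class TestRefinementMonotonicity:
    @pytest.mark.parametrize("seed", range(4))
    def test_eta_increases_under_refinement(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng, n=100, m=3, n_values=14)
        u = random_membership(rng, table.brightness, 3)
        cand = CandidateBreakpointSet(np.unique(table.brightness))
        coarse = rng.random(cand.n) < 0.3
        fine = coarse | (rng.random(cand.n) < 0.4)  # superset selection
        ap_c = approximate(u, table, DiscretizationScheme(cand, coarse))
        ap_f = approximate(u, table, DiscretizationScheme(cand, fine))
        assert (ap_f.lower >= ap_c.lower - 1e-12).all()
        assert (ap_f.upper <= ap_c.upper + 1e-12).all()
        assert ap_f.eta_bar >= ap_c.eta_bar - 1e-12


class TestDataInconsistency:
    def test_pure_separation_is_consistent(self, worked_example):
        table, _, candidates = worked_example
        scheme = DiscretizationScheme(candidates, np.array([True, False]))
        assert data_inconsistency(table, scheme) == 0.0

    def test_single_interval_mixes_everything(self, worked_example):
        table, _, candidates = worked_example
        assert data_inconsistency(table, DiscretizationScheme.empty(candidates)) == 1.0

    def test_identical_values_different_labels_irreducible(self):
        table = DecisionTable(
            brightness=np.array([10.0, 10.0]),
            labels=np.array([0, 1]),
            num_classes=2,
            value_range=(0.0, 255.0),
        )
        cand = CandidateBreakpointSet(np.array([10.0]))
        assert data_inconsistency(table, DiscretizationScheme.full(cand)) == 1.0

    def test_non_increasing_under_refinement(self):
        rng = np.random.default_rng(6)
        table = random_table(rng, n=100, m=2, n_values=10)
        cand = CandidateBreakpointSet(np.unique(table.brightness))
        for _ in range(10):
            coarse = rng.random(cand.n) < 0.3
            fine = coarse | (rng.random(cand.n) < 0.5)
            d_c = data_inconsistency(table, DiscretizationScheme(cand, coarse))
            d_f = data_inconsistency(table, DiscretizationScheme(cand, fine))
            assert d_f <= d_c + 1e-12
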