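"""CPM protocol: edge selection, network strengths, LOOCV, permutations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eegcpm.cpm import (
    cpm_loocv,
    edge_behavior_correlation,
    network_strength,
    permutation_test,
    select_edges,
)


@pytest.fixture
def random_edges(rng):
    return rng.uniform(0, 1, size=(30, 40))


class TestEdgeCorrelation:
    def test_edge_identical_to_behavior_has_r_one(self, rng):
        y = rng.normal(size=20)
        X = np.column_stack([y, rng.normal(size=20)])
        r, p = edge_behavior_correlation(X, y)
        assert r[0] == pytest.approx(1.0)
        assert p[0] < 1e-10

    def test_independent_edge_r_small_at_n_75(self, rng):
        y = rng.normal(size=75)
        X = rng.normal(size=(75, 200))
        r, _ = edge_behavior_correlation(X, y)
        assert np.mean(np.abs(r) < 0.23) > 0.9  # ~95% of null draws

    def test_constant_edge_never_selected(self, rng):
        y = rng.normal(size=12)
        X = np.column_stack([np.full(12, 0.4), rng.normal(size=12)])
        r, p = edge_behavior_correlation(X, y)
        assert r[0] == 0.0 and p[0] == 1.0

    def test_partial_correlation_absorbs_covariate(self, rng):
        age = rng.uniform(18, 30, size=40)
        y = age.copy()  # behavior fully explained by the covariate
        X = rng.normal(size=(40, 15)) + 0.5 * age[:, None]
        r, _ = edge_behavior_correlation(X, y, covariate=age)
        assert np.max(np.abs(r)) < 1e-8

    def test_partial_correlation_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        y = rng.normal(size=25)
        age = rng.uniform(18, 30, size=25)
        X = rng.normal(size=(25, 3))
        r, p = edge_behavior_correlation(X, y, covariate=age)
        for k in range(3):
            frame = pd.DataFrame({"x": X[:, k], "y": y, "age": age})
            ref = pingouin.partial_corr(frame, x="x", y="y", covar="age")
            assert r[k] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
            assert p[k] == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_constant_behavior_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            edge_behavior_correlation(rng.normal(size=(10, 4)), np.ones(10))


class TestSelection:
    def test_matches_manual_enumeration(self):
        r = np.array([0.8, -0.7, 0.1, -0.2, 0.5])
        p = np.array([0.01, 0.03, 0.9, 0.2, 0.04])
        pos, neg = select_edges(r, p, threshold=0.05)
        assert list(pos) == [True, False, False, False, True]
        assert list(neg) == [False, True, False, False, False]

    def test_all_insignificant_gives_empty_masks(self):
        pos, neg = select_edges(np.array([0.5, -0.5]), np.array([1.0, 1.0]))
        assert not pos.any() and not neg.any()

    def test_stricter_threshold_selects_subset(self, rng):
        r = rng.uniform(-1, 1, size=200)
        p = rng.uniform(0, 1, size=200)
        pos05, neg05 = select_edges(r, p, 0.05)
        pos01, neg01 = select_edges(r, p, 0.01)
        assert not (pos01 & ~pos05).any()
        assert not (neg01 & ~neg05).any()

    def test_masks_disjoint(self, rng):
        r = rng.uniform(-1, 1, size=100)
        p = rng.uniform(0, 0.1, size=100)
        pos, neg = select_edges(r, p)
        assert not (pos & neg).any()


class TestNetworkStrength:
    def test_empty_masks_give_zero(self):
        v = np.array([0.1, 0.2, 0.3])
        empty = np.zeros(3, dtype=bool)
        assert network_strength(v, empty, empty) == (0.0, 0.0, 0.0)

    def test_single_positive_edge(self):
        v = np.array([0.4, 0.9])
        pos = np.array([True, False])
        neg = np.zeros(2, dtype=bool)
        assert network_strength(v, pos, neg) == (pytest.approx(0.4), 0.0, pytest.approx(0.4))

    def test_matches_manual_addition(self):
        v = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        pos = np.array([True, False, True, True, False])
        neg = np.array([False, True, False, False, True])
        s = network_strength(v, pos, neg)
        assert s == (pytest.approx(0.8), pytest.approx(0.7), pytest.approx(0.8 - 0.7))

    @given(perm=st.permutations(list(range(6))))
    def test_invariant_to_edge_ordering(self, perm):
        v = np.array([0.1, 0.5, 0.2, 0.9, 0.3, 0.7])
        pos = np.array([1, 0, 1, 0, 0, 1], dtype=bool)
        neg = np.array([0, 1, 0, 0, 1, 0], dtype=bool)
        perm = np.array(perm)
        base = network_strength(v, pos, neg)
        permuted = network_strength(v[perm], pos[perm], neg[perm])
        assert permuted == pytest.approx(base)


class TestLoocv:
    def test_noiseless_linear_effect_recovered(self, rng):
        X = rng.uniform(0, 1, size=(24, 12))
        y = 3.0 * X[:, 4] + 1.0  # behavior is exactly one edge
        run = cpm_loocv(X, y, threshold=0.05)
        assert run["combined"].r > 0.95
        assert run["positive"].r > 0.95

    def test_fold_masks_match_per_fold_recomputation(self, random_edges, rng):
        y = rng.normal(size=30)
        run = cpm_loocv(random_edges, y, threshold=0.2)
        for s in range(30):
            train = np.delete(np.arange(30), s)
            r, p = edge_behavior_correlation(random_edges[train], y[train])
            pos, neg = select_edges(r, p, 0.2)
            np.testing.assert_array_equal(run.pos_masks[s], pos)
            np.testing.assert_array_equal(run.neg_masks[s], neg)

    def test_left_out_subject_cannot_leak_into_its_fold(self, random_edges, rng):
        y = rng.normal(size=30)
        run = cpm_loocv(random_edges, y, threshold=0.2)
        for s in (0, 13, 29):
            y_mod = y.copy()
            y_mod[s] += 100.0  # wildly perturb only the held-out subject
            mod = cpm_loocv(random_edges, y_mod, threshold=0.2)
            np.testing.assert_array_equal(run.pos_masks[s], mod.pos_masks[s])
            np.testing.assert_array_equal(run.neg_masks[s], mod.neg_masks[s])

    def test_all_null_edges_can_yield_no_prediction(self, rng):
        X = np.tile(rng.uniform(0, 1, size=12), (12, 1))  # constant columns
        y = rng.normal(size=12)
        run = cpm_loocv(X, y)
        assert run["combined"].no_prediction
        assert np.isnan(run["combined"].r)

    def test_independent_covariate_changes_little(self, rng):
        # n large enough that one near-threshold edge flipping in or out of
        # the selection cannot move the LOOCV correlation much
        X = rng.uniform(0, 1, size=(100, 20))
        y = 2.0 * X[:, 3] + rng.normal(0, 0.3, size=100)
        cov = rng.uniform(18, 30, size=100)  # independent of everything
        plain = cpm_loocv(X, y)["combined"].r
        controlled = cpm_loocv(X, y, covariate=cov)["combined"].r
        assert controlled == pytest.approx(plain, abs=0.15)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            cpm_loocv(rng.uniform(size=(4, 6)), rng.normal(size=4))

    def test_constant_scores_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            cpm_loocv(rng.uniform(size=(8, 6)), np.ones(8))


class TestPermutation:
    def test_strong_effect_attains_p_zero_under_strict_convention(self, rng):
        X = rng.uniform(0, 1, size=(24, 12))
        y = 3.0 * X[:, 4] + 1.0
        run = cpm_loocv(X, y)
        p = permutation_test(X, y, run, n_perm=50, seed=0)
        assert p["combined"] == 0.0

    def test_plus_one_estimator_never_returns_zero(self, rng):
        X = rng.uniform(0, 1, size=(24, 12))
        y = 3.0 * X[:, 4] + 1.0
        run = cpm_loocv(X, y)
        p = permutation_test(X, y, run, n_perm=50, seed=0, plus_one=True)
        assert p["combined"] == pytest.approx(1 / 51)

    def test_null_network_keeps_nan_p(self, rng):
        X = np.tile(rng.uniform(0, 1, size=12), (12, 1))
        y = rng.normal(size=12)
        run = cpm_loocv(X, y)
        p = permutation_test(X, y, run, n_perm=20, seed=0)
        assert np.isnan(p["combined"])

    def test_result_reproducible_for_fixed_seed(self, random_edges, rng):
        y = rng.normal(size=30)
        run = cpm_loocv(random_edges, y, threshold=0.2)
        p1 = permutation_test(random_edges, y, run, n_perm=40, seed=5)
        p2 = permutation_test(random_edges, y, run, n_perm=40, seed=5)
        assert p1 == p2

    def test_nonpositive_n_perm_rejected(self, random_edges, rng):
        y = rng.normal(size=30)
        run = cpm_loocv(random_edges, y)
        with pytest.raises(ValueError):
            permutation_test(random_edges, y, run, n_perm=0)
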