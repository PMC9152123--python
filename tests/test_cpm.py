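import numpy as np
import pytest
from scipy import stats

from cpmnet import cpm
from helpers import naive_loocv_predictions


class TestCorrelateEdges:
    def test_matches_scipy_pearsonr_oracle(self, rng):
        x = rng.normal(size=(12, 40))
        y = rng.normal(size=12)
        r, p = cpm.correlate_edges(x, y)
        for e in range(40):
            re, pe = stats.pearsonr(x[:, e], y)
            assert r[e] == pytest.approx(re, abs=1e-12)
            assert p[e] == pytest.approx(pe, abs=1e-12)

    def test_perfect_positive_and_negative_correlation(self, rng):
        y = rng.normal(size=10)
        x = np.column_stack([y, -y, rng.normal(size=10)])
        r, p = cpm.correlate_edges(x, y)
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(-1.0)
        assert p[0] == 0.0 and p[1] == 0.0

    def test_constant_edge_gets_r0_p1(self, rng):
        x = rng.normal(size=(10, 3))
        x[:, 1] = 4.2
        r, p = cpm.correlate_edges(x, rng.normal(size=10))
        assert r[1] == 0.0 and p[1] == 1.0

    def test_threshold_boundary_p_at_n45(self):
        """r = 0.38 at n = 45 sits almost exactly on the p = 0.01 boundary."""
        n, r0 = 45, 0.38
        t = r0 * np.sqrt((n - 2) / (1 - r0**2))
        p_oracle = 2 * stats.t.sf(t, n - 2)  # brute-force t-CDF evaluation
        assert p_oracle == pytest.approx(0.0100, abs=5e-4)
        # construct data with that exact correlation and check our p agrees
        rng = np.random.default_rng(1)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        az = (a - a.mean()) / a.std()
        bz = b - b.mean()
        bz -= (bz @ az) / n * az
        bz /= bz.std()
        edge = r0 * az + np.sqrt(1 - r0**2) * bz
        _, p = cpm.correlate_edges(edge[:, None], az)
        assert p[0] == pytest.approx(p_oracle, abs=1e-10)

    def test_constant_scores_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            cpm.correlate_edges(rng.normal(size=(8, 4)), np.ones(8))


class TestSelectEdges:
    def test_limit_threshold_selects_everything_by_sign(self, rng):
        x = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        r, p = cpm.correlate_edges(x, y)
        sel = cpm.select_edges(r, p, 1 - 1e-12)
        assert sel.positive.size + sel.negative.size == 30
        assert np.all(r[sel.positive] > 0)
        assert np.all(r[sel.negative] < 0)

    def test_tie_at_threshold_excluded(self):
        r = np.array([0.5, -0.5, 0.5])
        p = np.array([0.01, 0.005, 0.0099])
        sel = cpm.select_edges(r, p, 0.01)
        assert sel.positive.tolist() == [2]
        assert sel.negative.tolist() == [1]

    def test_selection_nested_across_thresholds(self, rng):
        x = rng.normal(size=(25, 60))
        y = rng.normal(size=25)
        r, p = cpm.correlate_edges(x, y)
        prev_pos = prev_neg = None
        for t in cpm.DEFAULT_THRESHOLD_GRID:
            sel = cpm.select_edges(r, p, t)
            if prev_pos is not None:
                assert set(prev_pos) <= set(sel.positive)
                assert set(prev_neg) <= set(sel.negative)
            prev_pos, prev_neg = sel.positive, sel.negative

    def test_invalid_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            cpm.select_edges(np.zeros(3), np.ones(3), 1.5)


class TestSummedStrengthAndModel:
    def test_empty_selection_sums_to_zero(self):
        sel = cpm.EdgeSelection(
            positive=np.array([], dtype=int), negative=np.array([], dtype=int),
            r=np.zeros(5), p=np.ones(5), threshold=0.01,
        )
        pos, neg = cpm.summed_strength(np.arange(5.0), sel)
        assert pos == 0.0 and neg == 0.0

    def test_small_arithmetic_case(self):
        sel = cpm.EdgeSelection(
            positive=np.array([0, 2]), negative=np.array([1]),
            r=np.zeros(3), p=np.ones(3), threshold=0.01,
        )
        pos, neg = cpm.summed_strength(np.array([0.3, -0.1, 0.2]), sel)
        assert pos == pytest.approx(0.5)
        assert neg == pytest.approx(-0.1)

    def test_matches_masked_brute_force(self, rng):
        x = rng.normal(size=(6, 50))
        pos = np.sort(rng.choice(50, size=7, replace=False))
        rest = np.setdiff1d(np.arange(50), pos)
        neg = np.sort(rng.choice(rest, size=5, replace=False))
        sel = cpm.EdgeSelection(positive=pos, negative=neg,
                                r=np.zeros(50), p=np.ones(50), threshold=0.01)
        ps, ns = cpm.summed_strength(x, sel)
        for s in range(6):
            assert ps[s] == pytest.approx(sum(x[s, e] for e in pos), abs=1e-12)
            assert ns[s] == pytest.approx(sum(x[s, e] for e in neg), abs=1e-12)

    def test_exact_linear_recovery_with_constant_negative(self, rng):
        pos = rng.normal(size=30)
        neg = np.zeros(30)
        y = 3.0 + 2.5 * pos
        m = cpm.fit_model(pos, neg, y)
        assert m.b_pos == pytest.approx(2.5, abs=1e-8)
        assert m.b_neg is None
        assert m.intercept == pytest.approx(3.0, abs=1e-8)

    def test_constant_target(self, rng):
        m = cpm.fit_model(rng.normal(size=10), rng.normal(size=10), np.full(10, 7.0))
        assert cpm.predict(m, 1.3, -0.4) == pytest.approx(7.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        pos = rng.normal(size=15)
        neg = rng.normal(size=15)
        y = rng.normal(size=15)
        m = cpm.fit_model(pos, neg, y)
        a = np.column_stack([np.ones(15), pos, neg])
        beta = np.linalg.solve(a.T @ a, a.T @ y)
        assert [m.intercept, m.b_pos, m.b_neg] == pytest.approx(beta.tolist(), abs=1e-9)

    def test_both_features_constant_falls_back_to_mean(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = cpm.fit_model(np.zeros(4), np.zeros(4), y)
        assert m.fallback_mean
        assert cpm.predict(m, 0.0, 0.0) == pytest.approx(2.5)


class TestLoocv:
    def test_one_fold_per_subject(self, fes_data):
        x, y = fes_data
        fit = cpm.loocv(x, y)
        assert fit.n_folds == len(y)
        assert fit.predicted_scores.shape == y.shape
        assert np.all(np.isfinite(fit.predicted_scores))

    def test_matches_naive_reimplementation(self, rng):
        """Optimized LOOCV equals a from-scratch naive version to 1e-10."""
        x = rng.normal(size=(12, 190))
        y = rng.normal(loc=20, scale=5, size=12)
        fit = cpm.loocv(x, y, threshold=0.05)
        naive = naive_loocv_predictions(x, y, 0.05)
        np.testing.assert_allclose(fit.predicted_scores, naive, atol=1e-10)

    def test_held_out_score_cannot_leak(self, fes_data):
        x, y = fes_data
        k = 3
        y2 = y.copy()
        y2[k] += 11.0
        fit_a = cpm.loocv(x, y)
        fit_b = cpm.loocv(x, y2)
        assert fit_a.predicted_scores[k] == fit_b.predicted_scores[k]

    def test_separate_mode_reports_both_models(self, fes_data):
        x, y = fes_data
        fit = cpm.loocv(x, y, mode="separate")
        assert fit.predicted_scores_neg is not None
        assert np.isfinite(fit.accuracy_r_neg)

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            cpm.loocv(rng.normal(size=(4, 10)), rng.normal(size=4))


class TestPermutationTest:
    def test_fixed_seed_is_deterministic(self, fes_data):
        x, y = fes_data
        a = cpm.permutation_test(x, y, n_perm=25, seed=42)
        b = cpm.permutation_test(x, y, n_perm=25, seed=42)
        assert np.array_equal(a.null_r, b.null_r)
        assert a.p_value == b.p_value

    def test_add_one_estimator(self, fes_data):
        x, y = fes_data
        res = cpm.permutation_test(x, y, n_perm=30, seed=0)
        expected = (1 + np.sum(res.null_r >= res.observed_r)) / 31
        assert res.p_value == pytest.approx(expected)
        assert 0 < res.p_value <= 1

    def test_observed_above_every_null_gives_minimum_p(self, fes_data):
        x, y = fes_data
        res = cpm.permutation_test(x, y, n_perm=30, seed=1)
        if np.all(res.null_r < res.observed_r):
            assert res.p_value == pytest.approx(1 / 31)
        else:  # formula still honoured
            assert res.p_value > 1 / 31


class TestThresholdSweep:
    def test_default_grid_has_ten_models(self, fes_data):
        x, y = fes_data
        table = cpm.threshold_sweep(x, y)
        assert len(table) == 10
        assert table["threshold"].tolist() == list(cpm.DEFAULT_THRESHOLD_GRID)

    def test_singleton_grid_matches_loocv(self, fes_data):
        x, y = fes_data
        table = cpm.threshold_sweep(x, y, thresholds=[0.01])
        assert len(table) == 1
        assert table.loc[0, "accuracy_r"] == pytest.approx(
            cpm.loocv(x, y, threshold=0.01).accuracy_r
        )

    def test_duplicate_thresholds_rejected(self, fes_data):
        x, y = fes_data
        with pytest.raises(ValueError, match="duplicate"):
            cpm.threshold_sweep(x, y, thresholds=[0.01, 0.01])


class TestConsensus:
    def test_matches_brute_force_intersection(self, rng):
        x = rng.normal(size=(12, 100))
        y = rng.normal(size=12)
        fit = cpm.loocv(x, y, threshold=0.2)
        cons = cpm.consensus_networks(fit, x)
        pos_sets = [set(s.positive.tolist()) for s in fit.fold_selections]
        neg_sets = [set(s.negative.tolist()) for s in fit.fold_selections]
        assert set(cons.positive.tolist()) == set.intersection(*pos_sets)
        assert set(cons.negative.tolist()) == set.intersection(*neg_sets)

    def test_consensus_networks_disjoint(self, fes_data):
        x, y = fes_data
        fit = cpm.loocv(x, y, threshold=0.1)
        cons = cpm.consensus_networks(fit, x)
        assert not set(cons.positive.tolist()) & set(cons.negative.tolist())

    def test_edge_missing_in_one_fold_is_excluded(self, fes_data):
        x, y = fes_data
        fit = cpm.loocv(x, y, threshold=0.1)
        cons = cpm.consensus_networks(fit, x)
        union = set()
        for s in fit.fold_selections:
            union |= set(s.positive.tolist())
        dropped = union - set(cons.positive.tolist())
        for e in dropped:
            assert any(e not in s.positive for s in fit.fold_selections)

    def test_weights_are_subject_means(self, rng):
        x = rng.normal(size=(10, 50))
        y = rng.normal(size=10)
        fit = cpm.loocv(x, y, threshold=0.3)
        cons = cpm.consensus_networks(fit, x)
        for e, w in zip(cons.positive, cons.positive_weights):
            assert w == pytest.approx(x[:, e].mean())

    def test_union_mode_is_superset(self, fes_data):
        x, y = fes_data
        fit = cpm.loocv(x, y, threshold=0.05)
        inter = cpm.consensus_networks(fit, x)
        union = cpm.consensus_union(fit, x)
        assert set(inter.positive.tolist()) <= set(union.positive.tolist())
        assert not set(union.positive.tolist()) & set(union.negative.tolist())
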