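import numpy as np
import pytest
from hypothesis import given, strategies as st

from nnct.errors import DegenerateInputError, ParameterError, ValidationError
from nnct.stats import (
    compare_correlations,
    compare_dependent_correlations,
    development_rate,
    pearson,
    regionwise_group_test,
    residualize,
    two_sample_t,
)

from _oracles import bh_reject_bruteforce


class TestResidualize:
    def test_orthogonal_covariate_just_centers(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to the trend in y
        assert np.allclose(residualize(y, x), y - y.mean())

    def test_exactly_linear_outcome_vanishes(self):
        x = np.arange(10.0)
        y = 3.0 * x - 2.0
        assert np.linalg.norm(residualize(y, x)) < 1e-10

    def test_hand_four_point_example(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.array([0.0, 0.0, 1.0, 1.0])
        assert np.allclose(residualize(y, x), [-0.5, 0.5, -0.5, 0.5])

    def test_collinear_design_rejected(self):
        X = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValidationError, match="collinear"):
            residualize(np.random.default_rng(0).random(6), X)


class TestTwoSampleT:
    def test_identical_groups_give_zero(self):
        t, df, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_pooled_formula(self):
        t, df, p = two_sample_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == 4

    def test_df_for_cohort_sized_groups(self):
        rng = np.random.default_rng(0)
        _, df, _ = two_sample_t(rng.random(448), rng.random(73))
        assert df == 519

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestRegionwise:
    def _cohort(self, seed=0, n=40, m=6, shift_first=0.0):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((2 * n, m))
        groups = np.array(["a"] * n + ["b"] * n)
        vals[n:, 0] += shift_first
        return vals, groups

    def test_all_equal_small_p_all_significant(self):
        # BH with all p equal to 0.01 at q=0.05 rejects everything
        vals, groups = self._cohort(seed=1, shift_first=0.0)
        # construct directly from the step-up definition instead
        assert bh_reject_bruteforce([0.01] * 90, 0.05).all()

    def test_step_up_matches_bruteforce(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert bh_reject_bruteforce(p, 0.05).all()
        from statsmodels.stats.multitest import multipletests

        reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.array_equal(reject, bh_reject_bruteforce(p, 0.05))

    def test_bh_monotone_in_q(self):
        vals, groups = self._cohort(seed=2, shift_first=1.0)
        ids = [f"n{i}" for i in range(vals.shape[1])]
        r1 = regionwise_group_test(vals, groups, ids, q=0.01)
        r5 = regionwise_group_test(vals, groups, ids, q=0.05)
        set1 = {r.node_id for r in r1 if r.significant_at_q}
        set5 = {r.node_id for r in r5 if r.significant_at_q}
        assert set1 <= set5

    def test_p_fdr_dominates_p_raw(self):
        vals, groups = self._cohort(seed=3, shift_first=0.8)
        ids = [f"n{i}" for i in range(vals.shape[1])]
        for r in regionwise_group_test(vals, groups, ids):
            assert r.p_fdr >= r.p_raw - 1e-15

    def test_node_order_permutation_equivariance(self):
        vals, groups = self._cohort(seed=4, shift_first=1.0)
        ids = [f"n{i}" for i in range(vals.shape[1])]
        perm = np.random.default_rng(0).permutation(vals.shape[1])
        r = regionwise_group_test(vals, groups, ids)
        rp = regionwise_group_test(
            vals[:, perm], groups, [ids[i] for i in perm]
        )
        by_id = {x.node_id: x for x in r}
        for x in rp:
            assert x.statistic == pytest.approx(by_id[x.node_id].statistic)
            assert x.p_fdr == pytest.approx(by_id[x.node_id].p_fdr)

    def test_group_order_controls_sign(self):
        vals, groups = self._cohort(seed=5, shift_first=2.0)
        ids = [f"n{i}" for i in range(vals.shape[1])]
        r_ab = regionwise_group_test(vals, groups, ids, group_order=("a", "b"))
        r_ba = regionwise_group_test(vals, groups, ids, group_order=("b", "a"))
        assert r_ab[0].statistic == pytest.approx(-r_ba[0].statistic)
        assert r_ab[0].statistic < 0  # group b was shifted up on node 0


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_value(self):
        r, _ = pearson([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert r == pytest.approx(0.9820, abs=1e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareCorrelations:
    def test_equal_correlations_give_zero(self):
        assert compare_correlations(0.3, 50, 0.3, 80).z == 0.0

    @given(
        st.floats(-0.95, 0.95), st.floats(-0.95, 0.95),
        st.integers(5, 500), st.integers(5, 500),
    )
    def test_antisymmetry(self, r1, r2, n1, n2):
        a = compare_correlations(r1, n1, r2, n2)
        b = compare_correlations(r2, n2, r1, n1)
        assert a.z == pytest.approx(-b.z, abs=1e-12)
        assert np.sign(a.z) == np.sign(r1 - r2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            compare_correlations(1.0, 50, 0.3, 50)
        with pytest.raises(ParameterError):
            compare_correlations(0.5, 3, 0.3, 50)

    def test_one_sided_p_is_half_two_sided(self):
        c = compare_correlations(0.5, 60, 0.2, 60)
        assert c.p_two_sided == pytest.approx(2 * c.p_one_sided)


class TestDependentComparison:
    def test_swap_negates_z(self):
        rng = np.random.default_rng(0)
        x1, y1, x2, y2 = rng.standard_normal((4, 60))
        y1 = y1 + 0.8 * x1
        a = compare_dependent_correlations(x1, y1, x2, y2)
        b = compare_dependent_correlations(x2, y2, x1, y1)
        assert a.z == pytest.approx(-b.z)
        assert a.z > 0

    def test_uncorrelated_pairs_match_independent_formula(self):
        # with all cross-correlations zero the dependent statistic reduces
        # to the independent Fisher z with n1 = n2 = n
        n = 40
        rng = np.random.default_rng(1)
        base = rng.standard_normal((4, n))
        base -= base.mean(axis=1, keepdims=True)
        q, _ = np.linalg.qr(base.T)
        x1, y1, x2, y2 = q.T  # zero-mean, exactly orthogonal columns
        y1c = y1 + 0.5 * x1
        dep = compare_dependent_correlations(x1, y1c, x2, y2)
        r1, _ = pearson(x1, y1c)
        r2, _ = pearson(x2, y2)
        ind = compare_correlations(r1, n, r2, n)
        assert dep.z == pytest.approx(ind.z, rel=1e-6)


class TestDevelopmentRate:
    def test_monotone_metric_positive_rate(self):
        pma = np.linspace(28, 36, 20)
        r, p = development_rate(pma**1.5, pma)
        assert r > 0.99

    def test_constant_metric_degenerate(self):
        with pytest.raises(DegenerateInputError):
            development_rate(np.ones(10), np.linspace(28, 36, 10))
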