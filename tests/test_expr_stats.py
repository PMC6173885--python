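import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from regcircuit import (
    GeneSet,
    ValidationError,
    bh_adjust,
    correlation_matrix,
    enrichment_test,
    grand_mean_center,
    pearson_ci,
    pfaffl_ratio,
    proportion_test,
    reallocation_test,
)

from oracles import bh_step_up, fisher_two_sided, hypergeom_upper_tail


class TestPfaffl:
    def test_no_change(self):
        assert pfaffl_ratio(2.0, 0.0, 2.0, 0.0) == 1.0

    def test_simple_doubling(self):
        assert pfaffl_ratio(2.0, 2.0, 2.0, 1.0) == 2.0

    def test_unequal_efficiencies(self):
        assert pfaffl_ratio(1.9, 3.0, 2.0, 1.0) == pytest.approx(1.9 ** 3 / 2.0)
        assert pfaffl_ratio(1.9, 3.0, 2.0, 1.0) == pytest.approx(3.4295, abs=1e-4)

    def test_non_positive_efficiency_rejected(self):
        with pytest.raises(ValidationError):
            pfaffl_ratio(0.0, 1.0, 2.0, 1.0)

    @given(
        e_t=st.floats(1.2, 2.2),
        e_r=st.floats(1.2, 2.2),
        d_t=st.floats(-5, 5),
        d_r=st.floats(-5, 5),
    )
    def test_log_linearity(self, e_t, e_r, d_t, d_r):
        ratio = pfaffl_ratio(e_t, d_t, e_r, d_r)
        assert np.log(ratio) == pytest.approx(
            d_t * np.log(e_t) - d_r * np.log(e_r), abs=1e-9
        )


class TestReallocationTest:
    def test_identical_groups(self):
        ct_t = [20.0, 20.0, 20.0, 20.0, 20.0, 20.0]
        ct_r = [22.0, 22.0, 22.0, 22.0, 22.0, 22.0]
        groups = ["c"] * 3 + ["t"] * 3
        res = reallocation_test(ct_t, ct_r, groups, "c", "t")
        assert res.ratio == pytest.approx(1.0)
        assert res.p == 1.0
        assert res.exhaustive and res.n_reallocations == 20

    def test_exhaustive_agrees_with_large_sampled(self):
        rng = np.random.default_rng(0)
        n = 6  # per group; C(12,6) = 924 distinct reallocations
        ct_t = np.concatenate([rng.normal(20, 0.3, n), rng.normal(19, 0.3, n)])
        ct_r = rng.normal(22, 0.3, 2 * n)
        groups = ["c"] * n + ["t"] * n
        exact = reallocation_test(ct_t, ct_r, groups, "c", "t", n_perm=2000)
        assert exact.exhaustive
        sampled = reallocation_test(ct_t, ct_r, groups, "c", "t", n_perm=800,
                                    rng_seed=7)
        assert not sampled.exhaustive
        assert sampled.p == pytest.approx(exact.p, abs=0.05)
        assert sampled.ratio == exact.ratio

    def test_p_floor_and_ceiling(self):
        rng = np.random.default_rng(1)
        ct_t = np.concatenate([rng.normal(25, 0.1, 3), rng.normal(18, 0.1, 3)])
        ct_r = np.full(6, 22.0)
        groups = ["c"] * 3 + ["t"] * 3
        res = reallocation_test(ct_t, ct_r, groups, "c", "t")
        # mirror allocations tie on |log ratio|, so the floor is 2/20
        assert 2 / 20 <= res.p <= 1.0

    def test_degenerate_group_errors(self):
        with pytest.raises(ValidationError):
            reallocation_test([20, 20, 20], [22, 22, 22], ["c", "t", "t"], "c", "t")

    def test_type_i_error_calibration(self):
        """Null rejection rate at alpha=.05 sits in the 95% binomial band.

        5 samples per group, exhaustive 252 reallocations per dataset,
        1,000 null datasets.
        """
        rng = np.random.default_rng(99)
        n_sim, n = 1000, 5
        rejections = 0
        for _ in range(n_sim):
            ct_t = rng.normal(20, 0.5, 2 * n)
            ct_r = rng.normal(22, 0.5, 2 * n)
            groups = ["c"] * n + ["t"] * n
            res = reallocation_test(ct_t, ct_r, groups, "c", "t")
            if res.p <= 0.05:
                rejections += 1
        rate = rejections / n_sim
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_sim)
        assert 0.05 - half <= rate <= 0.05 + half


class TestCorrelationMatrix:
    def test_perfect_self_correlation(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.normal(size=(2, 10)), index=["a", "b"])
        corr = correlation_matrix(values)
        assert corr.r.loc["a", "a"] == 1.0
        assert corr.lo.loc["a", "a"] == corr.hi.loc["a", "a"] == 1.0

    def test_known_ci_width(self):
        lo, hi = pearson_ci(0.6, 15)
        assert lo == pytest.approx(0.127, abs=1e-3)
        assert hi == pytest.approx(0.851, abs=1e-3)

    def test_zero_correlation_not_significant(self):
        x = np.arange(16.0)
        y = (x - x.mean()) ** 2  # even function of centered x: exactly r = 0
        values = pd.DataFrame([x, y], index=["a", "b"])
        corr = correlation_matrix(values)
        r = corr.r.loc["a", "b"]
        assert abs(r) < 1e-12
        assert not corr.significant.loc["a", "b"]
        assert corr.lo.loc["a", "b"] == pytest.approx(-corr.hi.loc["a", "b"])

    def test_significance_flag_equals_ci_excludes_zero(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.normal(size=(6, 15)),
                              index=[f"g{i}" for i in range(6)])
        values.iloc[1] = values.iloc[0] * 2 + rng.normal(0, 0.3, 15)
        corr = correlation_matrix(values)
        for a in values.index:
            for b in values.index:
                if not corr.valid.loc[a, b]:
                    continue
                excludes = corr.lo.loc[a, b] > 0 or corr.hi.loc[a, b] < 0
                assert bool(corr.significant.loc[a, b]) == bool(excludes)
        # symmetry and unit diagonal
        assert np.allclose(corr.r.to_numpy(), corr.r.to_numpy().T, equal_nan=True)
        assert np.allclose(np.diag(corr.r.to_numpy()), 1.0)

    def test_zero_variance_flagged(self):
        values = pd.DataFrame(
            [[1.0] * 8, np.arange(8.0)], index=["flat", "g"]
        )
        corr = correlation_matrix(values)
        assert not corr.valid.loc["flat", "g"]
        assert np.isnan(corr.r.loc["flat", "g"])
        assert not corr.significant.loc["flat", "g"]

    def test_pairwise_complete_n(self):
        values = pd.DataFrame(
            [[1.0, 2, 3, 4, 5, 6], [2.0, 4, 5, 8, np.nan, 11]],
            index=["a", "b"],
        )
        corr = correlation_matrix(values)
        assert corr.n.loc["a", "b"] == 5

    def test_too_few_samples_rejected(self):
        values = pd.DataFrame([[1.0, 2, 3]], index=["a"])
        with pytest.raises(ValidationError):
            correlation_matrix(values)


class TestGrandMeanCenter:
    def test_constant_gene_all_zero(self):
        m = pd.DataFrame({"g1": [5.0], "g2": [5.0], "g3": [5.0]}, index=["x"])
        out = grand_mean_center(m, pseudocount=1.0)
        assert np.allclose(out.to_numpy(), 0.0)

    def test_symmetric_split_base2(self):
        m = pd.DataFrame({"lo": [2.0], "hi": [8.0]}, index=["x"])
        out = grand_mean_center(m, pseudocount=0.0, base=2.0)
        assert out.loc["x", "lo"] == -1.0
        assert out.loc["x", "hi"] == 1.0

    @given(st.integers(0, 2 ** 32 - 1))
    def test_rows_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.uniform(0, 100, size=(5, 4)))
        out = grand_mean_center(m)
        assert np.allclose(out.sum(axis=1), 0.0, atol=1e-9)


class TestEnrichment:
    def test_category_equals_background(self):
        bg = GeneSet.from_iterable("bg", [f"g{i}" for i in range(10)])
        hits = GeneSet.from_iterable("hits", ["g0", "g1", "g2"])
        res = enrichment_test(hits, bg, bg)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_tail_matches_direct_summation(self):
        bg = GeneSet.from_iterable("bg", [f"g{i}" for i in range(20)])
        hits = GeneSet.from_iterable("hits", [f"g{i}" for i in range(5)])
        cat = GeneSet.from_iterable("cat", [f"g{i}" for i in range(2, 8)])
        res = enrichment_test(hits, cat, bg)
        overlap = len(hits.members & cat.members)
        assert overlap == 3
        assert res.p == pytest.approx(
            hypergeom_upper_tail(20, 6, 5, overlap), rel=1e-12
        )

    def test_fold_is_observed_over_expected(self):
        bg = GeneSet.from_iterable("bg", [f"g{i}" for i in range(20)])
        hits = GeneSet.from_iterable("hits", [f"g{i}" for i in range(5)])
        cat = GeneSet.from_iterable("cat", [f"g{i}" for i in range(4)] + ["g10", "g11"])
        res = enrichment_test(hits, cat, bg)
        assert res.fold == pytest.approx(4 / (5 * 6 / 20))

    def test_subset_violation_rejected(self):
        bg = GeneSet.from_iterable("bg", ["a", "b"])
        with pytest.raises(ValidationError):
            enrichment_test(GeneSet.from_iterable("h", ["zz"]),
                            GeneSet.from_iterable("c", ["a"]), bg)


class TestBhAdjust:
    def test_hand_computed_example(self):
        q = bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(q, [0.03, 0.03, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_step_up_oracle_and_bounds(self, ps):
        q = bh_adjust(ps)
        assert np.allclose(q, bh_step_up(ps), atol=1e-12)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert (q <= 1 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestProportionTest:
    def test_balanced_table(self):
        assert proportion_test([[10, 10], [10, 10]]) == pytest.approx(1.0)

    def test_fisher_matches_enumeration_oracle(self):
        table = [[12, 5], [7, 15]]
        assert proportion_test(table) == pytest.approx(
            fisher_two_sided(table), rel=1e-9
        )

    def test_chi2_matches_hand_formula(self):
        table = np.array([[20, 30, 10], [25, 15, 20]])
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row * col / table.sum()
        stat = ((table - expected) ** 2 / expected).sum()
        from scipy.stats import chi2

        p_hand = chi2.sf(stat, df=2)
        assert proportion_test(table) == pytest.approx(p_hand, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            proportion_test([[0, 0], [1, 2]])
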