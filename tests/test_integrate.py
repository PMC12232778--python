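import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdmr.integrate import (compare_groups,
                               correlate_methylation_expression,
                               dmr_methylation, filter_expression_genes,
                               merge_gene_dmrs, stratified_expression_test)
from methdmr.intervals import GenomicInterval
from methdmr.io_formats import ExpressionMatrix


def _iv(s, e):
    return GenomicInterval("chr1", s, e)


class TestMergeGeneDmrs:
    def test_largest_member_represents_overlap_group(self):
        merged = merge_gene_dmrs([_iv(100, 600), _iv(350, 700)])
        assert len(merged) == 1
        assert (merged[0].representative.start,
                merged[0].representative.end) == (100, 600)
        assert (merged[0].union.start, merged[0].union.end) == (100, 700)

    def test_non_overlapping_stay_independent(self):
        merged = merge_gene_dmrs([_iv(100, 200), _iv(300, 400)])
        assert len(merged) == 2

    def test_transitive_closure_of_overlap(self):
        # A overlaps B, B overlaps C, A does not overlap C
        a, b, c = _iv(100, 300), _iv(250, 500), _iv(450, 460)
        merged = merge_gene_dmrs([c, a, b])
        assert len(merged) == 1
        assert set(merged[0].members) == {a, b, c}
        assert merged[0].representative == b  # width 250 is largest

    def test_width_tie_prefers_smaller_start(self):
        merged = merge_gene_dmrs([_iv(200, 300), _iv(150, 250)])
        assert merged[0].representative.start == 150

    def test_idempotent_and_order_invariant(self, rng):
        ivs = [_iv(int(s), int(s) + int(w))
               for s, w in zip(rng.integers(0, 5000, 30),
                               rng.integers(10, 400, 30))]
        once = merge_gene_dmrs(ivs)
        shuffled = list(ivs)
        rng.shuffle(shuffled)
        assert merge_gene_dmrs(shuffled) == once
        again = merge_gene_dmrs([m.representative for m in once])
        assert [m.representative for m in again] \
            == [m.representative for m in once]


class TestCorrelation:
    def test_exact_linear_relation(self):
        x = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        res = correlate_methylation_expression(x, 2 * x + 1)
        assert res.pearson_r == pytest.approx(1.0)
        res = correlate_methylation_expression(x, -x)
        assert res.pearson_r == pytest.approx(-1.0)

    def test_matches_longhand_formula(self, rng):
        idx = [f"s{i}" for i in range(10)]
        x = pd.Series(rng.uniform(0, 1, 10), index=idx)
        y = pd.Series(rng.normal(5, 2, 10), index=idx)
        res = correlate_methylation_expression(x, y)
        n = 10
        sx, sy = x.sum(), y.sum()
        sxy = (x * y).sum()
        sxx, syy = (x ** 2).sum(), (y ** 2).sum()
        r = ((n * sxy - sx * sy)
             / np.sqrt((n * sxx - sx ** 2) * (n * syy - sy ** 2)))
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert res.pearson_r == pytest.approx(r, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        idx = [f"s{i}" for i in range(12)]
        x = pd.Series(rng.uniform(0, 1, 12), index=idx)
        y = pd.Series(rng.normal(0, 1, 12), index=idx)
        r0 = correlate_methylation_expression(x, y).pearson_r
        r1 = correlate_methylation_expression(x * 3 + 2, y * 0.5 + 7).pearson_r
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_zero_variance_reported_na(self):
        x = pd.Series([0.5] * 5, index=list("abcde"))
        y = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        res = correlate_methylation_expression(x, y)
        assert res.reason == "zero_variance"
        assert np.isnan(res.pearson_r)

    def test_too_few_samples_rejected(self):
        x = pd.Series([0.1, 0.9], index=["a", "b"])
        with pytest.raises(ValueError, match=">= 3"):
            correlate_methylation_expression(x, x)

    def test_count_weighted_dmr_methylation(self):
        frac = dmr_methylation(np.array([5.0, 0.0]), np.array([10.0, 0.0]))
        assert frac[0] == 0.5 and np.isnan(frac[1])


class TestCompareGroups:
    def test_identical_groups_nonparametric_p_one(self):
        v = np.array([1.0, 1, 1, 1, 1])
        res = compare_groups({"a": v, "b": v})
        assert res.test_name == "mann-whitney"
        assert res.p_value == pytest.approx(1.0)
        assert "constant_group" in res.flags

    def test_normal_data_takes_t_branch(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        res = compare_groups({"a": a, "b": b})
        assert res.test_name == "t-test"

    def test_type_i_error_in_binomial_band(self, rng):
        reject = 0
        reps = 1000
        for _ in range(reps):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0, 1, 12)
            if compare_groups({"a": a, "b": b}).p_value < 0.05:
                reject += 1
        # 99% binomial band around 0.05 at 1000 replicates
        lo, hi = stats.binom.ppf([0.005, 0.995], reps, 0.05)
        assert lo <= reject <= hi

    def test_three_group_anova_with_bonferroni_posthoc(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        c = rng.normal(1.0, 1, 30)   # planted 1-SD shift
        res = compare_groups({"a": a, "b": b, "c": c})
        assert res.test_name == "anova"
        assert res.p_value < 0.05
        ph = res.posthoc.set_index(["group_a", "group_b"])
        assert ph.loc[("a", "c"), "p_bonferroni"] < 0.05
        assert ph.loc[("b", "c"), "p_bonferroni"] < 0.05
        assert (res.posthoc["p_bonferroni"]
                >= res.posthoc["p_value"] - 1e-12).all()

    def test_skewed_data_takes_nonparametric_branch(self, rng):
        a = rng.exponential(1.0, 40) ** 3
        b = rng.exponential(1.0, 40) ** 3
        res = compare_groups({"a": a, "b": b})
        assert res.test_name in ("mann-whitney",)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n < 3"):
            compare_groups({"a": [1.0, 2], "b": [1.0, 2, 3]})


class TestStratifiedExpression:
    def test_degenerate_k_rejected(self):
        s = pd.Series([0.1, 0.9], index=["a", "b"])
        with pytest.raises(ValueError):
            stratified_expression_test(s, s, k=1)

    def test_sign_recovery_with_negative_slope(self, rng):
        idx = [f"s{i:02d}" for i in range(30)]
        meth = pd.Series(rng.uniform(0, 1, 30), index=idx)
        expr = pd.Series(10 - 4 * meth + rng.normal(0, 0.3, 30), index=idx)
        res = stratified_expression_test(meth, expr, k=10)
        assert res.p_value < 0.05
        # low-methylation arm should express more
        order = sorted(idx, key=lambda s: (-meth[s], s))
        assert expr[order[-10:]].mean() > expr[order[:10]].mean()

    def test_null_p_values_uniform(self, rng):
        idx = [f"s{i:02d}" for i in range(24)]
        pvals = []
        for _ in range(500):
            meth = pd.Series(rng.uniform(0, 1, 24), index=idx)
            expr = pd.Series(rng.normal(0, 1, 24), index=idx)
            pvals.append(stratified_expression_test(meth, expr, k=6).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestExpressionFilter:
    def _matrix(self, counts_rows):
        counts = pd.DataFrame(counts_rows)
        values = pd.DataFrame(np.ones_like(counts, dtype=float),
                              index=counts.index, columns=counts.columns)
        return ExpressionMatrix(values, counts)

    def test_nineteen_supporting_samples_excluded(self):
        row = [10] * 19 + [9] * 11
        expr = self._matrix(pd.DataFrame([row], index=["g1"]))
        kept = filter_expression_genes(expr)
        assert "g1" not in kept.values.index

    def test_boundary_twenty_samples_kept(self):
        row = [10] * 20
        expr = self._matrix(pd.DataFrame([row], index=["g1"]))
        kept = filter_expression_genes(expr)
        assert list(kept.values.index) == ["g1"]

    def test_matches_brute_force_double_loop(self, rng):
        counts = pd.DataFrame(rng.integers(0, 30, size=(40, 25)),
                              index=[f"g{i}" for i in range(40)])
        expr = self._matrix(counts)
        kept = set(filter_expression_genes(expr).values.index)
        expect = set()
        for g in counts.index:
            n_ok = 0
            for c in counts.columns:
                if counts.loc[g, c] >= 10:
                    n_ok += 1
            if n_ok >= 20:
                expect.add(g)
        assert kept == expect
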