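"""Statistical battery: t-tests, effect sizes, Holm variants, mixed rmANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from minf.reference_data import GROUP_SUMMARY, PAIRED_SUMMARY
from minf.stats import (
    assumption_checks,
    d_from_t_paired,
    holm_adjust,
    independent_ttest,
    paired_ttest,
    rm_anova_mixed,
)


class TestPairedT:
    def test_symmetric_null(self):
        res = paired_ttest([2.0, 0.0], [1.0, 1.0], alternative="two-sided")
        assert res.t == 0.0 and res.p == 1.0

    def test_hand_expanded_formula(self):
        a, b = np.array([3.0, 5.0, 7.0]), np.array([1.0, 2.0, 3.0])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        res = paired_ttest(a, b, alternative="two-sided")
        assert res.t == pytest.approx(t_hand, rel=1e-12)
        ref = sps.ttest_rel(a, b)  # independent implementation
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_one_sided_p_below_point001_at_t5(self):
        rng = np.random.default_rng(8)
        b = rng.standard_normal(17)
        # construct a pair whose difference yields t = 5.185
        d = rng.standard_normal(17)
        d = (d - d.mean()) / d.std(ddof=1)
        d = d + 5.185 / np.sqrt(17)
        res = paired_ttest(b + d, b, alternative="greater")
        assert res.t == pytest.approx(5.185, abs=1e-9)
        assert res.p < 0.001
        assert res.df == 16

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [0.0, 1.0])

    def test_one_sided_ci_upper_infinite(self):
        res = paired_ttest([3.0, 5.0, 7.0], [1.0, 2.0, 3.0])
        assert res.ci[1] == np.inf and np.isfinite(res.ci[0])


class TestEffectSizes:
    @pytest.mark.parametrize("row", list(PAIRED_SUMMARY.itertuples()),
                             ids=lambda r: f"block{r.block}")
    def test_paired_d_from_reported_t(self, row):
        expected = {1: 1.258, 2: 0.980, 3: 0.954}[row.block]
        assert round(d_from_t_paired(row.t, row.n), 3) == expected

    def test_null_t_gives_null_d(self):
        assert d_from_t_paired(0.0, 17) == 0.0


class TestIndependentT:
    @pytest.mark.parametrize("row,expected_t,expected_d", [
        (0, 0.948, 0.325), (1, -1.064, -0.365), (2, -0.226, -0.078),
    ])
    def test_group_summaries_reproduce_reported_values(self, row, expected_t,
                                                       expected_d):
        r = GROUP_SUMMARY.iloc[row]
        res = independent_ttest(mean1=r.mean_doc, sd1=r.sd_doc, n1=int(r.n),
                                mean2=r.mean_qr, sd2=r.sd_qr, n2=int(r.n))
        assert round(res.t, 3) == expected_t
        assert round(res.d, 3) == expected_d
        assert res.df == 32

    def test_equal_means_give_zero_t(self):
        res = independent_ttest(mean1=5.0, sd1=1.0, n1=10,
                                mean2=5.0, sd2=3.0, n2=10)
        assert res.t == 0.0

    def test_raw_samples_match_scipy(self, rng):
        a, b = rng.standard_normal(12) + 0.4, rng.standard_normal(15)
        res = independent_ttest(a=a, b=b)
        ref = sps.ttest_ind(a, b)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)
        assert res.df == 25

    def test_mean_difference_ci_matches_summary_route(self, rng):
        a, b = rng.standard_normal(10) + 1, rng.standard_normal(10)
        res = independent_ttest(a=a, b=b)
        res2 = independent_ttest(mean1=a.mean(), sd1=a.std(ddof=1), n1=10,
                                 mean2=b.mean(), sd2=b.std(ddof=1), n2=10)
        assert res.ci == pytest.approx(res2.ci, rel=1e-12)


class TestHolm:
    def test_reported_smallest_p_adjusts_to_0885(self):
        raw = [0.350, 0.295, 0.822]
        for variant in ("standard", "raw-multiplier"):
            adj = holm_adjust(raw, variant)
            assert round(adj[1], 3) == 0.885

    def test_variants_on_reported_pvalues(self):
        raw = [0.350, 0.295, 0.822]
        assert np.allclose(np.round(holm_adjust(raw, "standard"), 3),
                           [0.885, 0.885, 0.885])
        assert np.allclose(np.round(holm_adjust(raw, "raw-multiplier"), 3),
                           [0.700, 0.885, 0.822])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.123])[0] == 0.123

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=8))
    def test_standard_variant_monotone_and_capped(self, pvals):
        adj = holm_adjust(pvals, "standard")
        assert (adj <= 1.0).all() and (adj >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestRmAnova:
    @staticmethod
    def long_table(y, groups=None):
        n, k = y.shape
        rows = []
        for i in range(n):
            for j in range(k):
                rows.append(dict(participant=f"s{i:02d}", block=j + 1,
                                 value=y[i, j]))
                if groups is not None:
                    rows[-1]["group"] = groups[i]
        return pd.DataFrame(rows)

    def test_k2_equals_squared_paired_t(self, rng):
        y = rng.standard_normal((12, 2))
        res = rm_anova_mixed(self.long_table(y))[0]
        t = paired_ttest(y[:, 0], y[:, 1], alternative="two-sided", ci=False)
        assert res.F == pytest.approx(t.t**2, rel=1e-10)
        assert res.p == pytest.approx(t.p, rel=1e-10)
        assert res.gg_epsilon == 1.0

    def test_hand_computed_tableau(self):
        # 3 subjects x 3 blocks; sums of squares expanded by hand
        y = np.array([[1.0, 2.0, 3.0],
                      [2.0, 4.0, 6.0],
                      [3.0, 6.0, 9.0]])
        grand = 4.0
        ss_total = ((y - grand) ** 2).sum()                       # 52
        ss_subj = 3 * (((np.array([2., 4., 6.]) - grand) ** 2).sum())   # 24
        ss_block = 3 * (((np.array([2., 4., 6.]) - grand) ** 2).sum())  # 24
        ss_err = ss_total - ss_subj - ss_block                    # 4
        f_hand = (ss_block / 2) / (ss_err / 4)                    # 12
        res = rm_anova_mixed(self.long_table(y))[0]
        assert res.F == pytest.approx(f_hand, rel=1e-12)
        assert res.eta_squared == pytest.approx(ss_block / ss_total, rel=1e-12)

    def test_mixed_design_matches_pingouin(self, rng):
        import pingouin as pg

        y = rng.standard_normal((16, 3)) + np.array([0.0, 0.3, 0.5])
        groups = np.array(["a"] * 8 + ["b"] * 8)
        y[8:] += 0.4
        tbl = self.long_table(y, groups)
        ours = {r.term: r for r in rm_anova_mixed(tbl)}
        ref = pg.mixed_anova(data=tbl, dv="value", within="block",
                             subject="participant", between="group")
        ref = ref.set_index("Source")
        pcol = "p_unc" if "p_unc" in ref.columns else "p-unc"
        assert ours["group"].F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert ours["block"].F == pytest.approx(ref.loc["block", "F"], rel=1e-9)
        assert ours["block*group"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)
        assert ours["block"].p == pytest.approx(ref.loc["block", pcol],
                                                rel=1e-9)

    def test_within_only_epsilon_matches_pingouin(self, rng):
        import pingouin as pg

        y = rng.standard_normal((10, 4))
        tbl = self.long_table(y)
        res = rm_anova_mixed(tbl)[0]
        eps = pg.epsilon(tbl, dv="value", within="block",
                         subject="participant", correction="gg")
        assert res.gg_epsilon == pytest.approx(float(eps), rel=1e-9)
        spher = pg.sphericity(tbl, dv="value", within="block",
                              subject="participant")
        assert res.mauchly_W == pytest.approx(float(spher.W), rel=1e-9)
        # pingouin applies a second-order Box correction to the chi-square
        # approximation; ours is the first-order textbook form
        assert res.mauchly_p == pytest.approx(float(spher.pval), rel=0.05)

    def test_unbalanced_table_rejected(self, rng):
        tbl = self.long_table(rng.standard_normal((5, 3))).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova_mixed(tbl)

    def test_null_pvalues_uniform(self, rng):
        # moderate-scale calibration: zero block effect -> p ~ Uniform(0,1)
        pvals = []
        for _ in range(400):
            y = rng.standard_normal((8, 3)) + rng.standard_normal((8, 1))
            pvals.append(rm_anova_mixed(self.long_table(y))[0].p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestAssumptionChecks:
    def test_equal_spread_levene_zero(self):
        out = assumption_checks([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["levene_stat"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            assumption_checks([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_shapiro_size_calibrated(self, rng):
        # normal data, n=50: rejection rate at alpha=.05 is 0.05 +- 0.02
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.standard_normal(50)
            if sps.shapiro(x).pvalue < 0.05:
                rejections += 1
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_levene_detects_doubled_spread(self, rng):
        hits = 0
        for _ in range(200):
            a = rng.standard_normal(100)
            b = rng.standard_normal(100) * 2.0
            if assumption_checks(a, b)["levene_p"] < 0.05:
                hits += 1
        assert hits / 200 >= 0.80
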