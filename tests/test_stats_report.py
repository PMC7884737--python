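import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from hemowave.errors import PairingError, StatisticsError
from hemowave.stats_report import (
    build_report,
    correlation_from_r,
    pearson_correlation,
    spearman_correlation,
    wilcoxon_paired,
)


def brute_force_signed_rank_p(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    observed_plus = ranks[d > 0].sum()
    total = ranks.sum()
    t_obs = min(observed_plus, total - observed_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=len(ranks)):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if w_plus <= t_obs or w_plus >= total - t_obs:
            count += 1
    return count / 2 ** len(ranks)


class TestWilcoxonPaired:
    def test_monotone_n7_reproduces_asymptotic_p(self):
        """All post > pre with n=7: T=0, z=-14/sqrt(35), p=0.018 at 3 d.p."""
        pre = [3.1, 2.8, 4.0, 3.3, 3.9, 3.5, 3.6]
        post = [9.0, 25.1, 12.7, 30.2, 11.1, 14.8, 8.4]
        res = wilcoxon_paired(pre, post)
        assert res.w_statistic == 0.0
        assert round(res.p_two_sided, 3) == 0.018

    def test_matches_scipy_normal_approximation(self, rng):
        pre = rng.normal(10, 2, 9)
        post = pre + rng.normal(0.5, 1.5, 9)
        res = wilcoxon_paired(pre, post)
        ref = sps.wilcoxon(post, pre, correction=False, method="approx")
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_mode_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            pre = rng.normal(10, 2, 8)
            post = pre + rng.normal(0.8, 1.2, 8)
            exact = wilcoxon_paired(pre, post, method="exact").p_two_sided
            assert exact == pytest.approx(brute_force_signed_rank_p(post - pre))

    def test_exact_vs_asymptotic_for_uniform_signs(self):
        pre = np.arange(1.0, 8.0)
        post = pre + np.arange(1.0, 8.0)
        exact = wilcoxon_paired(pre, post, method="exact").p_two_sided
        asym = wilcoxon_paired(pre, post).p_two_sided
        assert exact == pytest.approx(2 / 128)
        assert round(asym, 3) == 0.018

    def test_symmetric_in_pre_post(self, rng):
        pre = rng.normal(0, 1, 7)
        post = pre + rng.normal(0.3, 1, 7)
        assert wilcoxon_paired(pre, post).p_two_sided == pytest.approx(
            wilcoxon_paired(post, pre).p_two_sided
        )

    def test_all_zero_differences_undefined(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        with pytest.raises(StatisticsError):
            wilcoxon_paired(x, x)

    def test_significance_rank_agreement_exact_vs_asymptotic(self, rng):
        """Across fixtures, exact and asymptotic p order effects the same way."""
        fixtures = []
        for shift in (0.2, 0.8, 2.0):
            pre = rng.normal(10, 1, 8)
            fixtures.append((pre, pre + rng.normal(shift, 0.5, 8)))
        exact = [wilcoxon_paired(a, b, method="exact").p_two_sided for a, b in fixtures]
        asym = [wilcoxon_paired(a, b).p_two_sided for a, b in fixtures]
        assert np.argsort(exact).tolist() == np.argsort(asym).tolist()

    def test_type_i_error_near_nominal_under_null(self):
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            d = rng.normal(0, 1, 7)
            if wilcoxon_paired(np.zeros(7), d).p_two_sided < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.08


class TestPearsonCorrelation:
    @pytest.mark.parametrize("r,expected", [(0.707, 0.038), (0.724, 0.033)])
    def test_one_sided_p_from_reported_r(self, r, expected):
        res = correlation_from_r(r, 7)
        assert round(res.p_one_sided, 3) == expected

    def test_two_sided_is_twice_one_sided(self, rng):
        x = rng.normal(0, 1, 10)
        y = 0.5 * x + rng.normal(0, 1, 10)
        res = pearson_correlation(x, y)
        assert res.p_two_sided == pytest.approx(2 * res.p_one_sided)

    def test_matches_scipy_two_sided(self, rng):
        x = rng.normal(0, 1, 12)
        y = 0.6 * x + rng.normal(0, 0.8, 12)
        res = pearson_correlation(x, y)
        ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, rel=1e-9)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    def test_perfect_correlation_flagged_degenerate(self):
        x = np.arange(8.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.degenerate and res.p_one_sided == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(StatisticsError):
            pearson_correlation(np.ones(6), np.arange(6.0))

    def test_spearman_is_pearson_on_ranks(self, rng):
        x = rng.normal(0, 1, 15)
        y = np.exp(x) + rng.normal(0, 0.1, 15)
        res = spearman_correlation(x, y)
        ref = sps.spearmanr(x, y)
        assert res.r == pytest.approx(ref.statistic, rel=1e-9)


class TestBuildReport:
    @staticmethod
    def metrics_frame(n=7, post_shift=5.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            base = rng.normal(10, 1)
            rows.append({"subject_id": f"s{i}", "condition": "baseline",
                         "stiff": base, "other": rng.normal(0, 1)})
            rows.append({"subject_id": f"s{i}", "condition": "after_evar",
                         "stiff": base + post_shift + rng.normal(0, 0.1),
                         "other": rng.normal(0, 1)})
        return pd.DataFrame(rows)

    def test_enforced_monotone_metric_yields_p_018(self):
        report = build_report(self.metrics_frame())
        row = report["paired"].set_index("metric").loc["stiff"]
        assert round(row["p_value"], 3) == 0.018

    def test_se_column_is_sd_over_sqrt_n(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "a", "b", "c"],
                "condition": ["baseline"] * 3 + ["after_evar"] * 3,
                "m": [1.0, 2.0, 3.0, 2.0, 3.0, 4.0],
            }
        )
        report = build_report(df)
        row = report["paired"].iloc[0]
        assert row["se_baseline"] == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))
        assert row["mean_after_evar"] == pytest.approx(3.0)

    def test_missing_condition_names_subject(self):
        df = self.metrics_frame()
        df = df[~((df.subject_id == "s3") & (df.condition == "after_evar"))]
        with pytest.raises(PairingError, match="s3"):
            build_report(df)

    def test_single_subject_rejected(self):
        df = self.metrics_frame(n=1)
        with pytest.raises(PairingError):
            build_report(df)

    def test_correlation_table_uses_post_rows(self):
        df = self.metrics_frame(n=8, seed=2)
        report = build_report(df, correlation_target="stiff")
        table = report["correlations"].set_index("parameter")
        post = df[df.condition == "after_evar"]
        ref = pearson_correlation(post["other"], post["stiff"])
        assert table.loc["other", "R"] == pytest.approx(ref.r)
        assert table.loc["other", "p_value"] == pytest.approx(ref.p_one_sided)
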