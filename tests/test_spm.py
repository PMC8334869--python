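"""1-D SPM: statistic fields, RFT thresholds, clusters, post hocs."""

import numpy as np
import pytest
from scipy import stats

from torsiongait import rft
from torsiongait.exceptions import SignalError
from torsiongait.spm import (
    Cluster,
    SPMCanonicalCorrelation,
    SPMPairedHotelling,
    SPMResults,
    cca_spm,
    hotelling_paired_spm,
    posthoc_components,
    regression_spm,
    report_filter,
    smooth_gaussian_fields,
)


@pytest.fixture(scope="module")
def smooth_data():
    rng = np.random.default_rng(99)
    Y = smooth_gaussian_fields(rng, 25, 101, 3, 18.0)
    x = rng.normal(16.0, 10.0, size=25)
    return Y, x


# ---------------------------------------------------------------------------
# statistic fields against independent oracles
# ---------------------------------------------------------------------------

class TestStatisticOracles:
    def test_k1_cca_equals_squared_pearson(self, smooth_data):
        Y, x = smooth_data
        r2 = SPMCanonicalCorrelation(Y[:, :, :1], x).canonical_r2()
        pear = np.array(
            [np.corrcoef(x, Y[:, q, 0])[0, 1] ** 2 for q in range(101)]
        )
        assert np.allclose(r2, pear, atol=1e-12)

    def test_regression_t_matches_statsmodels(self, smooth_data):
        import statsmodels.api as sm

        Y, x = smooth_data
        res = regression_spm(Y[:, :, 0], x)
        for q in (0, 33, 67, 100):
            ols = sm.OLS(Y[:, q, 0], sm.add_constant(x)).fit()
            assert res.statistic_field[q] == pytest.approx(ols.tvalues[1],
                                                           abs=1e-9)

    def test_cca_r2_is_multiple_correlation(self, smooth_data):
        import statsmodels.api as sm

        Y, x = smooth_data
        r2 = SPMCanonicalCorrelation(Y, x).canonical_r2()
        for q in (10, 55, 90):
            ols = sm.OLS(x, sm.add_constant(Y[:, q, :])).fit()
            assert r2[q] == pytest.approx(ols.rsquared, abs=1e-10)

    def test_hotelling_t2_matches_pingouin(self, smooth_data):
        pg = pytest.importorskip("pingouin")
        Y, x = smooth_data
        rng = np.random.default_rng(3)
        B = Y + 0.3 * smooth_gaussian_fields(rng, 25, 101, 3, 18.0) + 0.2
        res = SPMPairedHotelling(Y, B).fit()
        for q in (5, 50, 95):
            ref = pg.multivariate_ttest(Y[:, q, :] - B[:, q, :])
            t2_ref = ref["F"].iloc[0] * 3 * 24 / (25 - 3)
            assert res.statistic_field[q] == pytest.approx(t2_ref, rel=1e-9)

    def test_affine_invariance(self, smooth_data):
        Y, x = smooth_data
        a = cca_spm(Y, x).statistic_field
        b = cca_spm(Y * np.array([2.0, -3.0, 0.5]) + 1.0, 5.0 * x - 80.0
                    ).statistic_field
        assert np.allclose(a, b, atol=1e-8)

    def test_perfect_fit_flagged_infinite(self):
        x = np.arange(10.0)
        Y = np.tile(x[:, None], (1, 101))
        res = regression_spm(Y, x)
        assert np.isinf(res.statistic_field).all()
        assert res.has_suprathreshold

    def test_degenerate_inputs_rejected(self, smooth_data):
        Y, x = smooth_data
        with pytest.raises(ValueError):
            regression_spm(Y[:, :, 0], np.zeros_like(x))
        with pytest.raises(ValueError):
            cca_spm(Y[:4], x[:4])  # n <= k + 2
        with pytest.raises(ValueError):
            hotelling_paired_spm(Y, Y[:, :, :2])


# ---------------------------------------------------------------------------
# smoothness estimation
# ---------------------------------------------------------------------------

class TestFWHM:
    def test_known_smoothness_recovered(self):
        ests = [
            rft.estimate_fwhm(
                smooth_gaussian_fields(np.random.default_rng(i), 37, 101, None, 20.0)
            )
            for i in range(100)
        ]
        assert abs(np.mean(ests) - 20.0) / 20.0 < 0.15

    def test_white_noise_gives_small_fwhm(self):
        R = np.random.default_rng(0).normal(size=(50, 101))
        assert rft.estimate_fwhm(R) < 3.0

    def test_replication_invariance(self, smooth_data):
        Y, _ = smooth_data
        R = Y[:, :, 0]
        assert rft.estimate_fwhm(np.vstack([R, R])) == pytest.approx(
            rft.estimate_fwhm(R), rel=1e-12
        )

    def test_constant_residuals_rejected(self):
        with pytest.raises(SignalError):
            rft.estimate_fwhm(np.ones((10, 101)))


# ---------------------------------------------------------------------------
# RFT thresholds
# ---------------------------------------------------------------------------

class TestThresholds:
    @pytest.mark.parametrize("stat,df", [("t", 35), ("chi2", 3), ("F", (3, 33))])
    def test_threshold_decreases_with_smoothness(self, stat, df):
        us = [
            rft.critical_threshold(0.05, stat, df, rft.resel_count(101, fwhm))
            for fwhm in (5.0, 10.0, 20.0, 50.0)
        ]
        assert all(a > b for a, b in zip(us[:-1], us[1:]))

    def test_infinite_smoothness_limit_is_pointwise_quantile(self):
        """With constant-in-time fields the family-wise threshold reduces
        to the single-node t quantile."""
        rng = np.random.default_rng(5)
        base = rng.normal(size=(30, 1))
        Y = np.tile(base, (1, 101)) + 1e-9 * rng.normal(size=(30, 101))
        res = regression_spm(Y, rng.normal(size=30), alpha=0.05, two_tailed=True)
        assert res.critical == pytest.approx(stats.t.isf(0.025, 28), abs=1e-3)

    def test_fwe_pvalue_at_threshold_equals_alpha(self):
        resels = rft.resel_count(101, 20.0)
        for stat, df in [("t", 30), ("chi2", 3), ("gauss", ())]:
            u = rft.critical_threshold(0.05, stat, df, resels)
            assert rft.fwe_pvalue(u, stat, df, resels) == pytest.approx(
                0.05, abs=1e-9
            )

    def test_cluster_pvalues_are_probabilities(self, smooth_data):
        Y, x = smooth_data
        rng = np.random.default_rng(8)
        effect = np.zeros(101)
        effect[40:60] = 1.0
        Yb = Y[:, :, 0] + 0.4 * np.outer(x - x.mean(), effect)
        res = regression_spm(Yb, x)
        for c in res.clusters:
            assert 0.0 < c.p_value <= 1.0
            assert c.p_value <= res.alpha + 1e-12  # suprathreshold at level alpha


# ---------------------------------------------------------------------------
# Hotelling paired
# ---------------------------------------------------------------------------

class TestPairedHotelling:
    def test_identical_fields_give_zero_statistic(self, smooth_data):
        Y, _ = smooth_data
        res = hotelling_paired_spm(Y, Y.copy())
        assert np.allclose(np.nan_to_num(res.statistic_field, posinf=0.0), 0.0,
                           atol=1e-9) or not res.clusters
        assert res.clusters == [] or all(np.isnan(c.p_value) for c in res.clusters)

    def test_noiseless_offset_diverges(self, smooth_data):
        Y, _ = smooth_data
        res = hotelling_paired_spm(Y, Y + np.array([0.5, 0.0, 0.0]))
        # zero paired variance: divergent statistic (inf or limited only
        # by floating-point cancellation) at every node, all flagged
        assert (np.isinf(res.statistic_field) | (res.statistic_field > 1e12)).all()
        assert res.has_suprathreshold
        assert res.significant_nodes().all()

    def test_detects_systematic_shift(self, smooth_data):
        Y, _ = smooth_data
        rng = np.random.default_rng(12)
        B = Y + 0.25 * smooth_gaussian_fields(rng, 25, 101, 3, 18.0)
        B = B + np.array([0.8, 0.0, -0.5])
        res = hotelling_paired_spm(Y, B)
        assert res.has_suprathreshold


# ---------------------------------------------------------------------------
# post hocs and reporting
# ---------------------------------------------------------------------------

class TestPosthocAndReporting:
    def test_k1_posthoc_identical_to_regression(self, smooth_data):
        Y, x = smooth_data
        a = posthoc_components(Y[:, :, :1], x, alpha=0.05)[0]
        b = regression_spm(Y[:, :, 0], x, alpha=0.05)
        assert np.allclose(a.statistic_field, b.statistic_field)
        assert a.critical == pytest.approx(b.critical, abs=1e-12)

    def test_k3_uses_bonferroni_alpha(self, smooth_data):
        Y, x = smooth_data
        out = posthoc_components(Y, x, alpha=0.05)
        assert len(out) == 3
        for r in out:
            assert r.alpha == pytest.approx(0.05 / 3)

    def test_thresholds_grow_with_component_count(self, smooth_data):
        Y, x = smooth_data
        crits = []
        for k in (1, 2, 3):
            crits.append(posthoc_components(Y[:, :, :k], x)[0].critical)
        assert crits[0] < crits[1] < crits[2]

    def _result_with_clusters(self, clusters):
        return SPMResults(
            stat_name="t", statistic_field=np.zeros(101), dof=(30,), fwhm=20.0,
            resels=5.0, critical=3.0, clusters=clusters, alpha=0.05,
        )

    def test_report_filter_extent_rule(self):
        res = self._result_with_clusters(
            [Cluster(10.0, 12.0, 0.01),  # extent 2 -> dropped
             Cluster(40.0, 43.0, 0.02),  # extent 3 -> kept
             Cluster(60.0, 60.5, 0.03)]
        )
        out = report_filter(res, min_extent=2.0)
        assert [(c.start, c.end) for c in out.clusters] == [(40.0, 43.0)]

    def test_report_filter_empty_input(self):
        out = report_filter(self._result_with_clusters([]))
        assert out.clusters == []

    def test_summary_mentions_clusters(self, smooth_data):
        Y, x = smooth_data
        effect = np.zeros(101)
        effect[30:70] = 1.0
        res = regression_spm(Y[:, :, 0] + 0.5 * np.outer(x - x.mean(), effect), x)
        text = res.summary()
        assert "SPM{t}" in text and "critical" in text
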