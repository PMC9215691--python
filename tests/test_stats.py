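"""Rank-sum conventions, Holm, bootstrap effect sizes, ROC, band power."""

import numpy as np
import pytest
from scipy import stats as sps_stats

from ictonet import (
    EEGSegment,
    FunctionalNetwork,
    bootstrap_median_diff,
    holm,
    node_strength,
    ranksum,
    ranksum_exact_p,
    ranksum_from_summary,
    relative_band_power,
    roc_metrics,
)
from ictonet.stats import _ranksum_null_distribution


class TestRanksum:
    def test_u_statistic_matches_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 20, 15).astype(float)  # with ties
        y = rng.integers(0, 20, 12).astype(float)
        res = ranksum(x, y, tail="two-sided")
        u_scipy = sps_stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        assert res.U_mw == pytest.approx(u_scipy)

    def test_small_sample_null_distribution_enumeration(self):
        # all C(4,2)=6 assignments of ranks {1..4} to group 1
        dist = _ranksum_null_distribution(2, 2)
        assert dist == {3: 1, 4: 1, 5: 2, 6: 1, 7: 1}
        # P(W <= 3) = 1/6 for the minimal configuration x={1,2}, y={3,4}
        assert sum(c for w, c in dist.items() if w <= 3) / 6 == pytest.approx(1 / 6)

    def test_small_samples_use_exact_mode_matching_scipy(self):
        # auto mode enumerates the exact null for small tie-free samples;
        # scipy's exact Mann-Whitney is the independent oracle
        rng = np.random.default_rng(1)
        for n1 in range(2, 6):
            for n2 in range(2, 6):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                p_pkg = ranksum(x, y, tail="two-sided").p
                p_ref = sps_stats.mannwhitneyu(
                    x, y, alternative="two-sided", method="exact"
                ).pvalue
                assert p_pkg == pytest.approx(p_ref, abs=1e-12)

    def test_normal_approximation_quality_degrades_gracefully(self):
        # the continuity-corrected normal approximation stays within 0.09 of
        # the exact p even at the smallest configurations
        rng = np.random.default_rng(14)
        for n1, n2 in [(2, 2), (3, 3), (4, 4), (5, 5)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            for tail in ("right", "two-sided"):
                p_norm = ranksum(x, y, tail=tail, method="normal").p
                p_exact = ranksum_exact_p(x, y, tail=tail)
                assert abs(p_norm - p_exact) < 0.09

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ranksum([], [1.0])

    def test_degenerate_centre_two_sided(self):
        # W at its null mean: continuity-corrected z is 0 and p is 1
        z, p = ranksum_from_summary(611, 26, 20, tail="two-sided")
        assert z == 0.0
        assert p == 1.0

    def test_infeasible_summary_rejected(self):
        with pytest.raises(ValueError, match="feasible"):
            ranksum_from_summary(100, 26, 20)


class TestHolm:
    def test_two_family_worked_example(self):
        # raw one-sided p-values recovered from the published rank sums
        p_o2 = ranksum_from_summary(724, 26, 20, "right")[1]
        p_o1 = ranksum_from_summary(652, 26, 20, "right")[1]
        corrected = holm([p_o2, p_o1])
        assert corrected[0] == pytest.approx(0.013, abs=5e-4)
        assert corrected[1] == pytest.approx(0.18, abs=5e-3)

    def test_textbook_example(self):
        np.testing.assert_allclose(holm([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm([0.3]), [0.3])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=12)
        _, ref, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm(p), ref)

    def test_bounds_and_monotonicity(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=8)
        adj = holm(p)
        assert np.all(adj >= p)
        assert np.all(adj <= np.minimum(len(p) * p, 1.0))


class TestBootstrapMedianDiff:
    def test_pure_shift_recovered(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=30)
        x = y + 5
        res = bootstrap_median_diff(x, y, n_boot=1000, seed=0)
        assert res.median_diff == pytest.approx(5.0)
        assert res.ci_low <= 5.0 <= res.ci_high

    def test_identical_samples_cover_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=25)
        res = bootstrap_median_diff(x, x, n_boot=1000, seed=1)
        assert res.median_diff == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(1, 1, 26), rng.normal(0, 1, 20)
        a = bootstrap_median_diff(x, y, n_boot=500, seed=7)
        b = bootstrap_median_diff(x, y, n_boot=500, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_coverage_of_true_median_difference(self):
        # normal(1,1) n=26 vs normal(0,1) n=20: true median difference is 1
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 100
        for k in range(n_rep):
            x = rng.normal(1, 1, 26)
            y = rng.normal(0, 1, 20)
            res = bootstrap_median_diff(x, y, n_boot=1000, seed=k)
            hits += res.ci_low <= 1.0 <= res.ci_high
        assert hits / n_rep >= 0.85

    def test_degenerate_sample_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="percentile"):
            res = bootstrap_median_diff(
                np.ones(10), np.zeros(10), n_boot=200, seed=9
            )
        assert res.median_diff == 1.0
        assert res.method == "percentile"


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10), np.ones(10)].astype(bool)
        res = roc_metrics(scores, labels)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        assert roc_metrics(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_identity_with_pairwise_comparison_auc(self):
        rng = np.random.default_rng(11)
        pos = rng.integers(0, 10, 30).astype(float)  # ties included
        neg = rng.integers(0, 10, 25).astype(float)
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(30), np.zeros(25)].astype(bool)
        auc = roc_metrics(scores, labels).auc
        naive = np.mean(
            (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        )
        assert auc == pytest.approx(naive)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        assert roc_metrics(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_metrics(np.arange(5.0), np.ones(5, dtype=bool))


class TestBandPower:
    def _seg(self, data, fs=250.0):
        return EEGSegment(data=np.atleast_2d(data), fs=fs, channel_labels=("O1",))

    def test_pure_tone_concentrates_power(self):
        fs = 250.0
        t = np.arange(int(fs * 20)) / fs
        x = np.sin(2 * np.pi * 8 * t) + 1e-3 * np.random.default_rng(0).normal(
            size=t.size
        )
        assert relative_band_power(self._seg(x), (6, 9), "O1") >= 0.95

    def test_white_noise_matches_bandwidth_ratio(self):
        rng = np.random.default_rng(1)
        vals = [
            relative_band_power(
                self._seg(rng.normal(size=5000)), (6, 9), "O1"
            )
            for _ in range(20)
        ]
        assert np.mean(vals) == pytest.approx(3 / 44, rel=0.15)

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(2)
        v = relative_band_power(self._seg(rng.normal(size=2000)), (7.5, 12.5), "O1")
        assert 0.0 <= v <= 1.0

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            relative_band_power(
                self._seg(np.random.default_rng(3).normal(size=1000), fs=100.0),
                (40, 60), "O1",
            )


class TestNodeStrength:
    def _net(self, w, labels):
        return FunctionalNetwork(weights=w, lags=np.zeros_like(w),
                                 channel_labels=labels)

    def test_empty_network_zero(self):
        net = self._net(np.zeros((3, 3)), ("O1", "O2", "CZ"))
        assert node_strength(net, "O1") == 0.0

    def test_single_edge_counts_in_and_out(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        net = self._net(w, ("O1", "O2", "CZ"))
        assert node_strength(net, "O1") == 1.0

    def test_invariant_under_relabeling_others(self):
        rng = np.random.default_rng(13)
        w = np.triu(rng.uniform(0, 1, (4, 4)), 1)
        w = w + w.T
        net = self._net(w, ("O1", "a", "b", "c"))
        perm = [0, 2, 3, 1]
        net2 = self._net(w[np.ix_(perm, perm)],
                         tuple(net.channel_labels[i] for i in perm))
        assert node_strength(net, "O1") == pytest.approx(
            node_strength(net2, "O1")
        )

    def test_unknown_channel_rejected(self):
        net = self._net(np.zeros((2, 2)), ("O1", "O2"))
        with pytest.raises(KeyError):
            node_strength(net, "XX")


class TestPublishedConventions:
    """The exact conventions are pinned by published worked examples."""

    @pytest.mark.parametrize(
        "w, tail, z_expected, p_expected",
        [
            (556, "right", -1.23, 0.89),
            (652, "right", 0.90, None),
            (724, "right", 2.49, None),
            (568, "two-sided", -0.94, 0.35),
            (633, "two-sided", 0.48, None),
            (689, "two-sided", 1.72, None),
        ],
    )
    def test_printed_z_and_p(self, w, tail, z_expected, p_expected):
        z, p = ranksum_from_summary(w, 26, 20, tail)
        assert round(z, 2) == z_expected
        if p_expected is not None:
            assert round(p, 2) == p_expected

    def test_auc_from_rank_sum_identity(self):
        u = 724 - 26 * 27 / 2
        assert round(u / (26 * 20), 2) == 0.72
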