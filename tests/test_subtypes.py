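import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.datasets import make_blobs
from sklearn.metrics import adjusted_rand_score

from omicsurv.subtypes import (
    anova_f_oneway,
    bh_adjust,
    choose_k_silhouette,
    differential_expression,
    differential_methylation,
    kaplan_meier,
    kmeans_cluster,
    logrank_test,
    size_factors,
    survival_feature_set,
)
from omicsurv.survival import CoxFit


def _fit(coefs):
    return CoxFit(pd.Series(coefs), alpha=0.5, lambda_=0.1, lambda_path=np.array([0.1]))


class TestSurvivalFeatureSet:
    def test_nonzero_columns_returned(self):
        fit = _fit({"c1": 0.0, "c2": 0.3, "c3": 0.0, "c4": -0.1})
        assert survival_feature_set(fit) == ["c2", "c4"]

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="lambda"):
            survival_feature_set(_fit({"c1": 0.0, "c2": 0.0}))


class TestKMeans:
    def test_separable_blobs_recovered(self):
        X, y = make_blobs(n_samples=120, centers=2, cluster_std=0.5, random_state=3)
        labels = kmeans_cluster(X, 2, seed=0)
        assert adjusted_rand_score(y, labels) == 1.0

    def test_deterministic(self):
        X, _ = make_blobs(n_samples=80, centers=3, random_state=1)
        np.testing.assert_array_equal(kmeans_cluster(X, 3, seed=5), kmeans_cluster(X, 3, seed=5))

    def test_near_zero_wss_when_k_near_n(self, rng):
        X = rng.normal(size=(12, 2)) * 10
        labels = kmeans_cluster(X, 11, seed=0, n_restarts=5)
        wss = sum(
            ((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum()
            for c in np.unique(labels)
        )
        assert wss < 0.25 * ((X - X.mean(axis=0)) ** 2).sum()

    def test_labels_ordered_by_size(self, rng):
        X = np.vstack([rng.normal(0, 0.3, size=(60, 2)), rng.normal(8, 0.3, size=(20, 2))])
        labels = kmeans_cluster(X, 2, seed=0)
        assert (labels == 0).sum() > (labels == 1).sum()

    def test_invalid_k(self, rng):
        with pytest.raises(ValueError):
            kmeans_cluster(rng.normal(size=(10, 2)), 1)


class TestSilhouette:
    def test_two_blobs_select_k2(self):
        X, _ = make_blobs(n_samples=100, centers=2, cluster_std=0.6, random_state=2)
        k, profile = choose_k_silhouette(X, seed=0, n_restarts=5)
        assert k == 2
        assert set(profile) == set(range(2, 11))

    def test_three_blobs_select_k3(self):
        X, _ = make_blobs(n_samples=120, centers=3, cluster_std=0.3, random_state=1)
        k, _ = choose_k_silhouette(X, seed=0, n_restarts=5)
        assert k == 3

    def test_single_gaussian_low_separation_warns(self, rng, caplog):
        import logging

        X = rng.normal(size=(80, 5))
        with caplog.at_level(logging.WARNING):
            _, profile = choose_k_silhouette(X, seed=0, n_restarts=5)
        assert max(profile.values()) < 0.3
        assert "low cluster separation" in caplog.text

    def test_needs_enough_patients(self, rng):
        with pytest.raises(ValueError):
            choose_k_silhouette(rng.normal(size=(8, 2)))


class TestKaplanMeier:
    def test_no_censoring_steps(self):
        curves = kaplan_meier([1, 2, 3, 4], [True] * 4)
        np.testing.assert_allclose(curves[0]["survival"], [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_one(self):
        curves = kaplan_meier([1, 2, 3], [False] * 3)
        assert curves[0].empty  # no event times -> estimator stays at 1

    def test_hand_worked_six_patients(self):
        # times {1, 2+, 3, 4, 5+, 6}: S = 5/6, 5/8, 5/12, 0
        time = [1, 2, 3, 4, 5, 6]
        event = [True, False, True, True, False, True]
        curve = kaplan_meier(time, event)[0]
        np.testing.assert_allclose(
            curve["survival"], [5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 2 / 3, 0.0],
            atol=1e-12,
        )
        assert list(curve["n_at_risk"]) == [6, 4, 3, 1]

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        time = rng.integers(1, 30, size=50).astype(float)
        curve = kaplan_meier(time, np.ones(50, dtype=bool))[0]
        for t, s in zip(curve["time"], curve["survival"]):
            np.testing.assert_allclose(s, (time > t).mean(), atol=1e-12)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        time = np.array([3.0, 5.0, 7.0, 9.0] * 2)
        event = np.array([True, True, False, True] * 2)
        labels = np.array([0] * 4 + [1] * 4)
        stat, p = logrank_test(time, event, labels)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_lifelines_on_toy(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        time = rng.exponential(100, size=40)
        event = rng.random(40) < 0.7
        labels = (rng.random(40) < 0.5).astype(int)
        if event[labels == 0].sum() == 0 or event[labels == 1].sum() == 0:
            pytest.skip("degenerate draw")
        stat, p = logrank_test(time, event, labels)
        ref = ll_logrank(time[labels == 0], time[labels == 1],
                         event[labels == 0], event[labels == 1])
        assert stat == pytest.approx(ref.test_statistic, abs=1e-10)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_label_swap_invariant(self, rng):
        time = rng.exponential(50, size=60)
        event = rng.random(60) < 0.6
        labels = (rng.random(60) < 0.4).astype(int)
        s1, _ = logrank_test(time, event, labels)
        s2, _ = logrank_test(time, event, 1 - labels)
        assert s1 == pytest.approx(s2, abs=1e-10)

    def test_null_calibration(self, rng):
        rejections = 0
        sims = 1000
        for _ in range(sims):
            time = rng.exponential(100, size=60)
            event = rng.random(60) < 0.7
            labels = (rng.random(60) < 0.5).astype(int)
            try:
                _, p = logrank_test(time, event, labels)
            except ValueError:
                continue
            rejections += p < 0.05
        assert abs(rejections / sims - 0.05) < 0.02

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [False, False], [0, 1])


class TestBH:
    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(1000):
            p = rng.uniform(size=int(rng.integers(2, 40)))
            ours = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_monotone_and_above_raw(self, rng):
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestANOVA:
    def test_f_equals_t_squared(self, rng):
        for _ in range(50):
            a = rng.normal(size=12)
            b = rng.normal(0.5, 1.0, size=15)
            f, p_f = anova_f_oneway([a, b])
            t, p_t = stats.ttest_ind(a, b, equal_var=True)
            assert f == pytest.approx(t**2, abs=1e-10)
            assert p_f == pytest.approx(p_t, abs=1e-12)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(size=10), rng.normal(size=12), rng.normal(1, 1, size=9)]
        f, p = anova_f_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def _nb_counts(rng, mu, disp, size):
    lam = rng.gamma(1.0 / disp, mu * disp, size=size)
    return rng.poisson(lam)


class TestDifferentialExpression:
    def test_identical_groups_nothing_significant(self, rng):
        block = _nb_counts(rng, 100.0, 0.2, size=(30, 50))
        counts = pd.DataFrame(np.vstack([block, block]),
                              columns=[f"g{i}" for i in range(50)])
        labels = np.array([0] * 30 + [1] * 30)
        res = differential_expression(counts, labels)
        np.testing.assert_allclose(res["log2_fc"], 0.0, atol=1e-12)
        assert not res["significant"].any()

    def test_planted_fourfold_gene_recovered(self, rng):
        fcs = []
        for rep in range(5):
            n = 50
            mu = np.full(200, 80.0)
            g1 = np.vstack([_nb_counts(rng, mu * np.where(np.arange(200) == 0, 4.0, 1.0),
                                       0.15, size=(1, 200)) for _ in range(n)])
            g2 = np.vstack([_nb_counts(rng, mu, 0.15, size=(1, 200)) for _ in range(n)])
            counts = pd.DataFrame(np.vstack([g1, g2]), columns=[f"g{i}" for i in range(200)])
            labels = np.array([0] * n + [1] * n)
            res = differential_expression(counts, labels)
            assert res["significant"].iloc[0]
            fcs.append(res["log2_fc"].iloc[0])
        # size-factor normalization absorbs a little of the planted effect
        assert abs(np.mean(fcs) - 2.0) < 0.3

    def test_all_null_fdr_controlled(self, rng):
        n = 40
        counts = pd.DataFrame(
            _nb_counts(rng, 60.0, 0.2, size=(2 * n, 2000)),
            columns=[f"g{i}" for i in range(2000)],
        )
        labels = np.array([0] * n + [1] * n)
        res = differential_expression(counts, labels)
        assert res["significant"].mean() <= 0.01

    def test_all_zero_gene_excluded(self, rng):
        counts = pd.DataFrame(_nb_counts(rng, 50.0, 0.2, size=(20, 10)),
                              columns=[f"g{i}" for i in range(10)])
        counts["g3"] = 0
        labels = np.array([0] * 10 + [1] * 10)
        res = differential_expression(counts, labels)
        assert not res.loc["g3", "tested"]
        assert np.isnan(res.loc["g3", "p"])

    def test_group_size_guard(self, rng):
        counts = pd.DataFrame(_nb_counts(rng, 50.0, 0.2, size=(3, 5)))
        counts.columns = [str(c) for c in counts.columns]
        with pytest.raises(ValueError):
            differential_expression(counts, np.array([0, 0, 1]))

    def test_size_factors_recover_depth(self, rng):
        base = _nb_counts(rng, 200.0, 0.05, size=(20, 500)).astype(float)
        depth = rng.uniform(0.5, 2.0, size=20)
        counts = base * depth[:, None]
        sf = size_factors(counts)
        ratio = sf / depth
        assert ratio.std() / ratio.mean() < 0.05


class TestDifferentialMethylation:
    def _annotation(self, probes, genes):
        return pd.DataFrame(
            {
                "probe_id": probes,
                "gene_id": genes,
                "in_cpg_island": True,
                "upstream_of_tss": True,
                "distance_upstream_tss": 100,
            }
        )

    def test_identical_groups_zero_difference(self, rng):
        block = rng.uniform(0.2, 0.8, size=(25, 10))
        beta = pd.DataFrame(np.vstack([block, block]),
                            columns=[f"p{i}" for i in range(10)])
        annot = self._annotation(beta.columns, [f"gene{i % 5}" for i in range(10)])
        labels = np.array([0] * 25 + [1] * 25)
        res = differential_methylation(beta, labels, annot)
        np.testing.assert_allclose(res["mean_m_diff"], 0.0, atol=1e-12)

    def test_single_probe_gene_identity(self, rng):
        from omicsurv.preprocess import beta_to_m

        beta = pd.DataFrame(rng.uniform(0.3, 0.7, size=(20, 2)), columns=["p0", "p1"])
        annot = self._annotation(["p0", "p1"], ["gA", "gB"])
        labels = np.array([0] * 10 + [1] * 10)
        res = differential_methylation(beta, labels, annot)
        m = beta_to_m(beta["p0"])
        expected = m[:10].mean() - m[10:].mean()
        assert res.loc["gA", "mean_m_diff"] == pytest.approx(expected, abs=1e-12)

    def test_planted_m_shift_recovered(self, rng):
        diffs = []
        for rep in range(5):
            n = 50
            z = rng.normal(0, 0.3, size=(2 * n, 20))
            z[:n, :4] += 1.0 / np.log2(np.e)  # +1 M-value shift on gene g0's probes
            beta = pd.DataFrame(1 / (1 + np.exp(-z)), columns=[f"p{i}" for i in range(20)])
            annot = self._annotation(beta.columns, [f"g{i // 4}" for i in range(20)])
            labels = np.array([0] * n + [1] * n)
            res = differential_methylation(beta, labels, annot)
            assert res.loc["g0", "significant"]
            diffs.append(res.loc["g0", "mean_m_diff"])
        assert abs(np.mean(diffs) - 1.0) < 0.2

    def test_unannotated_probe_raises(self, rng):
        beta = pd.DataFrame(rng.uniform(0.3, 0.7, size=(10, 2)), columns=["p0", "px"])
        annot = self._annotation(["p0"], ["gA"])
        with pytest.raises(ValueError):
            differential_methylation(beta, np.array([0] * 5 + [1] * 5), annot)
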