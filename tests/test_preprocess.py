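import logging

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy import stats

from omicsurv.datamodel import EmptyModalityError
from omicsurv.preprocess import (
    ClinicalEncoder,
    Scaler,
    beta_to_m,
    compute_tumor_volume,
    filter_features_by_missingness,
    filter_methylation_probes,
    filter_patients_by_followup,
    fit_preprocess,
)
from omicsurv.simulate import SimulationConfig, generate_dataset


def _matrix(columns):
    return pd.DataFrame(columns, index=[f"P{i}" for i in range(10)])


class TestMissingnessFilter:
    def test_thirty_percent_removed(self):
        col = [np.nan, 0.0, np.nan, 4, 5, 6, 7, 8, 9, 10]  # 3/10 zero-or-missing
        mat = _matrix({"bad": col, "good": range(1, 11)})
        out = filter_features_by_missingness(mat)
        assert list(out.columns) == ["good"]

    def test_exactly_twenty_percent_retained(self):
        col = [np.nan, 0.0] + list(range(1, 9))  # exactly 2/10
        mat = _matrix({"edge": col})
        out = filter_features_by_missingness(mat)
        assert list(out.columns) == ["edge"]

    def test_enumerated_counts(self):
        # per-feature zero/missing counts {0, 1, 2, 3, 10} of 10 patients
        cols = {}
        for i, k in enumerate([0, 1, 2, 3, 10]):
            col = [0.0] * k + list(range(1, 11 - k))
            cols[f"f{i}"] = col
        out = filter_features_by_missingness(_matrix(cols))
        assert list(out.columns) == ["f0", "f1", "f2"]

    def test_order_preserved(self):
        mat = _matrix({"b": range(1, 11), "a": range(1, 11)})
        assert list(filter_features_by_missingness(mat).columns) == ["b", "a"]

    def test_all_removed_raises(self):
        mat = _matrix({"x": [0.0] * 10})
        with pytest.raises(EmptyModalityError, match="mrna"):
            filter_features_by_missingness(mat, name="mrna")


class TestFollowupFilter:
    def _dataset(self, times):
        n = len(times)
        cfg = SimulationConfig(
            n_patients=n,
            features_per_modality={"mrna": 5, "mirna": 5, "lncrna": 5, "methylation": 5},
            seed=1,
        )
        ds, _ = generate_dataset(cfg)
        ds.survival["time_days"] = np.asarray(times, dtype=float)
        return ds

    def test_zero_and_one_day_removed(self):
        ds = self._dataset([0.0, 1.0, 2.0, 500.0])
        out = filter_patients_by_followup(ds)
        assert list(out.survival["time_days"]) == [2.0, 500.0]

    def test_identity_when_all_long(self):
        ds = self._dataset([10.0, 20.0, 30.0, 40.0])
        out = filter_patients_by_followup(ds)
        assert out.n_patients == 4

    def test_planted_short_followups_removed_everywhere(self):
        cfg = SimulationConfig(
            n_patients=100,
            features_per_modality={"mrna": 10, "mirna": 5, "lncrna": 5, "methylation": 10},
            frac_short_followup=0.07,
            seed=2,
        )
        ds, _ = generate_dataset(cfg)
        assert (ds.survival["time_days"] <= 1).sum() == 7
        out = filter_patients_by_followup(ds)
        assert out.n_patients == 93
        for mat in out.modalities.values():
            assert mat.shape[0] == 93
        assert len(out.clinical) == 93
        assert len(out.cohort) == 93
        out.validate()


class TestScaler:
    def test_train_column_to_unit(self):
        train = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        s = Scaler().fit(train)
        np.testing.assert_allclose(s.transform(train)["x"], [-np.sqrt(1.5), 0, np.sqrt(1.5)])
        # population SD convention: sd of {1,2,3} is sqrt(2/3)
        np.testing.assert_allclose(s.sd["x"], np.sqrt(2.0 / 3.0))

    def test_train_mean_zero_var_one(self, rng):
        train = pd.DataFrame(rng.normal(5, 3, size=(50, 4)))
        train.columns = [str(c) for c in train.columns]
        z = Scaler().fit(train).transform(train)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.var(axis=0, ddof=0), 1, atol=1e-12)

    def test_value_at_train_mean_maps_to_zero(self):
        train = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        s = Scaler().fit(train)
        test = pd.DataFrame({"x": [2.0]})
        assert s.transform(test)["x"].iloc[0] == 0.0

    def test_roundtrip(self, rng):
        train = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        test = pd.DataFrame(rng.normal(size=(10, 5)), columns=list("abcde"))
        s = Scaler().fit(train)
        back = s.inverse_transform(s.transform(test))
        np.testing.assert_allclose(back.to_numpy(), test.to_numpy(), atol=1e-10)

    def test_missing_imputed_with_train_median(self):
        train = pd.DataFrame({"x": [1.0, 2.0, 9.0]})
        s = Scaler().fit(train)
        test = pd.DataFrame({"x": [np.nan]})
        # imputed to train median 2.0 then z-scored
        expected = (2.0 - train["x"].mean()) / train["x"].std(ddof=0)
        np.testing.assert_allclose(s.transform(test)["x"].iloc[0], expected)

    def test_zero_variance_dropped_and_logged(self, caplog):
        train = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with caplog.at_level(logging.WARNING):
            s = Scaler().fit(train)
        assert list(s.columns) == ["y"]
        assert "zero-variance" in caplog.text

    def test_serialization_roundtrip(self, tmp_path, rng):
        train = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        s = Scaler().fit(train)
        s.to_json(tmp_path / "scaler.json")
        s2 = Scaler.from_json(tmp_path / "scaler.json")
        test = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        assert_frame_equal(s.transform(test), s2.transform(test))

    def test_leakage_freedom(self, rng):
        train = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        s1 = Scaler().fit(train)
        s2 = Scaler().fit(train)  # "test" data never enters fit by signature
        pd.testing.assert_series_equal(s1.mean, s2.mean)


def _annotation(probes, island, upstream, dist):
    return pd.DataFrame(
        {
            "probe_id": probes,
            "gene_id": [f"g{i}" for i in range(len(probes))],
            "in_cpg_island": island,
            "upstream_of_tss": upstream,
            "distance_upstream_tss": dist,
        }
    )


class TestMethylationFilter:
    def test_missing_probe_removed_regardless_of_annotation(self):
        beta = pd.DataFrame(
            {"p1": [0.5, np.nan, 0.5, np.nan], "p2": [0.4] * 4},
            index=list("abcd"),
        )  # p1: 50% missing
        annot = _annotation(["p1", "p2"], [True, True], [True, True], [100, 100])
        out = filter_methylation_probes(beta, annot)
        assert list(out.columns) == ["p2"]

    def test_1500_inclusive_1501_excluded(self):
        beta = pd.DataFrame({"p1": [0.5] * 4, "p2": [0.4] * 4}, index=list("abcd"))
        annot = _annotation(["p1", "p2"], [True, True], [True, True], [1500, 1501])
        out = filter_methylation_probes(beta, annot)
        assert list(out.columns) == ["p1"]

    def test_downstream_excluded(self):
        beta = pd.DataFrame({"p1": [0.5] * 4, "p2": [0.4] * 4}, index=list("abcd"))
        annot = _annotation(["p1", "p2"], [True, True], [True, False], [100, 100])
        assert list(filter_methylation_probes(beta, annot).columns) == ["p1"]

    def test_top_variance_oracle(self, rng):
        n, p, k = 50, 200, 60
        sds = rng.uniform(0.01, 0.2, size=p)
        vals = 0.5 + rng.normal(size=(n, p)) * sds
        beta = pd.DataFrame(np.clip(vals, 0.01, 0.99), columns=[f"p{i}" for i in range(p)])
        annot = _annotation(beta.columns, [True] * p, [True] * p, [10] * p)
        out = filter_methylation_probes(beta, annot, top_variance=k)
        expected = set(beta.columns[np.argsort(-beta.var(axis=0, ddof=0).to_numpy())[:k]])
        assert set(out.columns) == expected

    def test_fewer_survivors_than_cap_all_kept(self):
        beta = pd.DataFrame(np.random.default_rng(0).uniform(0.2, 0.8, (10, 5)),
                            columns=[f"p{i}" for i in range(5)])
        annot = _annotation(beta.columns, [True] * 5, [True] * 5, [10] * 5)
        assert filter_methylation_probes(beta, annot, top_variance=1000).shape[1] == 5

    def test_filter_order_is_pinned(self):
        # adversarial fixture: the highest-variance probe fails missingness.
        # Running variance first would keep it and drop the in-scope survivor.
        rng = np.random.default_rng(1)
        p_loud = np.clip(0.5 + rng.normal(0, 0.3, 10), 0.01, 0.99)
        p_loud[:3] = np.nan  # 30% missing
        p_quiet = np.clip(0.5 + rng.normal(0, 0.05, 10), 0.01, 0.99)
        beta = pd.DataFrame({"loud": p_loud, "quiet": p_quiet})
        annot = _annotation(["loud", "quiet"], [True, True], [True, True], [10, 10])
        out = filter_methylation_probes(beta, annot, top_variance=1)
        assert list(out.columns) == ["quiet"]
        # permuted order (variance before missingness) picks the other probe
        var = beta.var(axis=0, ddof=0)
        variance_first = beta.loc[:, [var.idxmax()]]
        assert list(variance_first.columns) == ["loud"]


class TestBetaToM:
    def test_half_maps_to_zero(self):
        assert beta_to_m(0.5) == 0.0

    def test_closed_form(self):
        np.testing.assert_allclose(beta_to_m(0.8), 2.0, atol=1e-12)

    def test_monotone(self, rng):
        b = np.sort(rng.uniform(0.01, 0.99, 100))
        assert (np.diff(beta_to_m(b)) > 0).all()

    def test_clamping_handles_boundaries(self):
        m = beta_to_m(np.array([0.0, 1.0]))
        assert np.isfinite(m).all()

    def test_logit_normal_betas_give_gaussian_m(self, rng):
        mu, sigma = 0.3, 0.8
        z = rng.normal(mu, sigma, size=10_000)
        beta = 1.0 / (1.0 + np.exp(-z))
        m = beta_to_m(beta)
        # M = z * log2(e) exactly, so mean/SD recover and normality holds
        np.testing.assert_allclose(m.mean(), mu * np.log2(np.e), atol=0.03)
        np.testing.assert_allclose(m.std(), sigma * np.log2(np.e), atol=0.03)
        assert stats.normaltest(m).pvalue > 0.01


class TestClinicalEncoding:
    def _clinical(self, n=40, seed=0):
        cfg = SimulationConfig(
            n_patients=n,
            features_per_modality={"mrna": 5, "mirna": 5, "lncrna": 5, "methylation": 5},
            seed=seed,
        )
        ds, _ = generate_dataset(cfg)
        return ds.clinical

    def test_tumor_volume_is_product(self):
        df = pd.DataFrame(
            {"tumor_dim1_cm": [1.0], "tumor_dim2_cm": [1.0], "tumor_dim3_cm": [0.5]}
        )
        assert compute_tumor_volume(df).iloc[0] == 0.5

    def test_stage_3a_is_ordinal_3(self):
        clin = self._clinical()
        clin.loc[clin.index[0], "pathological_stage"] = "Stage 3A"
        enc = ClinicalEncoder().fit(clin)
        out = enc.transform(clin)
        assert out.loc[clin.index[0], "pathological_stage"] == 3.0

    def test_no_missing_no_missing_activations(self):
        clin = self._clinical().dropna()
        enc = ClinicalEncoder().fit(clin)
        out = enc.transform(clin)
        miss_cols = [c for c in out.columns if c.endswith("__missing__")]
        assert miss_cols and (out[miss_cols].sum() == 0).all()

    def test_unknown_level_maps_to_missing_and_logs(self, caplog):
        clin = self._clinical().dropna()
        enc = ClinicalEncoder().fit(clin)
        other = clin.copy()
        other.loc[other.index[0], "sex"] = "Unrecorded"
        with caplog.at_level(logging.WARNING):
            out = enc.transform(other)
        assert out.loc[other.index[0], "sex=__missing__"] == 1.0
        assert "unknown level" in caplog.text

    def test_continuous_zscored_with_train_stats(self):
        clin = self._clinical(n=60)
        enc = ClinicalEncoder().fit(clin)
        out = enc.transform(clin)
        assert abs(out["age"].mean()) < 1e-10


class TestDatasetPreprocess:
    def test_alignment_preserved(self, small_dataset):
        ds, _ = small_dataset
        state = fit_preprocess(ds, top_variance=200)
        mats = {
            name: state.scalers[name].transform(ds.modalities[name])
            for name in state.scalers
        }
        for mat in mats.values():
            assert mat.index.equals(ds.patient_ids)

    def test_fit_uses_train_only(self, small_dataset):
        ds, _ = small_dataset
        train = ds.subset_patients(ds.patient_ids[:100])
        state1 = fit_preprocess(train, top_variance=200)
        # perturbing non-training patients cannot change the fitted state
        ds2 = ds.copy()
        for name in ds2.modalities:
            ds2.modalities[name].iloc[100:] = 999.0
        state2 = fit_preprocess(ds2.subset_patients(ds2.patient_ids[:100]), top_variance=200)
        for name in state1.scalers:
            pd.testing.assert_series_equal(state1.scalers[name].mean, state2.scalers[name].mean)
            assert state1.kept_features[name] == state2.kept_features[name]
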