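"""Patient aggregation, group testing, stepwise selection, LOPO k-NN, ROC."""

import numpy as np
import pandas as pd
import pytest

from qusmap.cohort_stats import (aggregate_patient, knn_lopo, mwu_test,
                                 roc_auc, significance_tier, stepwise_lda)


def _long_table(pid="P1", label="benign", planes=((1.0, 2.0),)):
    rows = []
    for i, (mbf_mean, mbf_contrast) in enumerate(planes):
        rows.append({"patient_id": pid, "label": label, "plane": i,
                     "parameter": "MBF", "mean": mbf_mean,
                     "contrast": mbf_contrast, "correlation": 0.5,
                     "energy": 0.2, "homogeneity": 0.8, "ace": 1.0})
    return pd.DataFrame(rows)


def _feature_frame(rng, n_per_class, n_features=4, shift=0.0, index_offset=0):
    X = rng.standard_normal((2 * n_per_class, n_features))
    X[n_per_class:, :] += shift
    cols = [f"MBF_{k}" for k in ("mean", "contrast", "correlation", "energy")][:n_features]
    df = pd.DataFrame(X, columns=cols)
    df["label"] = ["benign"] * n_per_class + ["malignant"] * n_per_class
    df.index = [f"P{index_offset + i:03d}" for i in range(2 * n_per_class)]
    return df


class TestAggregation:
    def test_single_plane_is_identity(self):
        v = aggregate_patient(_long_table(planes=((1.5, 3.0),)))
        assert v["MBF_mean"] == 1.5
        assert v["MBF_contrast"] == 3.0

    def test_two_planes_average(self):
        v = aggregate_patient(_long_table(planes=((1.0, 2.0), (3.0, 4.0))))
        assert v["MBF_mean"] == 2.0
        assert v["MBF_contrast"] == 3.0

    def test_plane_order_irrelevant(self):
        a = aggregate_patient(_long_table(planes=((1.0, 2.0), (5.0, 0.0))))
        b = aggregate_patient(_long_table(planes=((5.0, 0.0), (1.0, 2.0))))
        pd.testing.assert_series_equal(a, b)

    def test_missing_plane_value_skipped(self):
        t = _long_table(planes=((1.0, 2.0), (3.0, 4.0)))
        t.loc[1, "contrast"] = np.nan
        v = aggregate_patient(t)
        assert v["MBF_contrast"] == 2.0


class TestMannWhitney:
    def test_exact_p_for_disjoint_triples(self):
        u, p = mwu_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        _, p = mwu_test([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_swap_symmetry(self):
        x, y = [1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0]
        u1, p1 = mwu_test(x, y)
        u2, p2 = mwu_test(y, x)
        assert u1 + u2 == len(x) * len(y)
        assert p1 == pytest.approx(p2)

    def test_tiers(self):
        assert significance_tier(0.03) == "*"
        assert significance_tier(0.004) == "**"
        assert significance_tier(0.0004) == "***"
        assert significance_tier(0.2) == ""


class TestStepwiseLDA:
    def test_dominant_feature_selected_first(self):
        rng = np.random.default_rng(1)
        df = _feature_frame(rng, 15, shift=0.0)
        df["MBF_contrast"] = np.where(df["label"] == "malignant", 5.0, 0.0) \
            + 0.1 * rng.standard_normal(len(df))
        model = stepwise_lda(df)
        assert model.selected[0] == "MBF_contrast"

    def test_duplicate_feature_never_co_selected(self):
        rng = np.random.default_rng(2)
        df = _feature_frame(rng, 15, shift=0.0)
        sig = np.where(df["label"] == "malignant", 2.0, 0.0) \
            + rng.standard_normal(len(df))
        df["MBF_mean"] = sig
        df["MBF_contrast"] = sig  # exact duplicate
        model = stepwise_lda(df)
        assert not {"MBF_mean", "MBF_contrast"} <= set(model.selected)

    def test_infinite_entry_threshold_gives_empty_model(self):
        rng = np.random.default_rng(3)
        df = _feature_frame(rng, 10, shift=2.0)
        model = stepwise_lda(df, f_enter=np.inf)
        assert model.empty
        assert model.selected == []

    def test_coefficients_sorted_by_contribution(self):
        rng = np.random.default_rng(4)
        df = _feature_frame(rng, 20, shift=1.5)
        model = stepwise_lda(df)
        mags = model.coefficients.abs().to_numpy()
        assert (np.diff(mags) <= 1e-12).all()


class TestKnnLopo:
    def test_separable_clusters_classified_perfectly(self):
        rng = np.random.default_rng(5)
        df = _feature_frame(rng, 20, shift=6.0)
        res = knn_lopo(df, k=5)
        assert res.sensitivity == 100.0
        assert res.specificity == 100.0
        assert res.accuracy == 100.0
        assert res.auc == 1.0

    def test_nearest_duplicate_wins_at_k1(self):
        df = _feature_frame(np.random.default_rng(6), 5, shift=0.0)
        df.iloc[0, :4] = df.iloc[5, :4]  # benign P000 duplicates malignant P005
        res = knn_lopo(df, k=1)
        assert res.predictions.loc["P000", "predicted"] == "malignant"

    def test_permuted_labels_score_at_chance(self):
        """Label permutation destroys the class signal.

        Leave-one-out k-NN is slightly pessimistic at chance (removing the
        held-out patient tilts the training class balance against it), so
        the mean permuted accuracy sits a little below 50%; it must stay in
        a band around chance and never rediscover the true structure.
        """
        rng = np.random.default_rng(7)
        accs = []
        base = _feature_frame(rng, 10, shift=3.0)
        for _ in range(200):
            df = base.copy()
            df["label"] = rng.permutation(df["label"].to_numpy())
            if df["label"].nunique() < 2:
                continue
            accs.append(knn_lopo(df, k=5).accuracy)
        assert abs(np.mean(accs) - 50.0) < 8.0
        assert np.mean(accs) < 60.0  # far below the true-label accuracy (100%)

    def test_even_k_rejected(self):
        df = _feature_frame(np.random.default_rng(8), 10)
        with pytest.raises(ValueError, match="odd"):
            knn_lopo(df, k=4)

    def test_patient_order_invariance(self):
        rng = np.random.default_rng(9)
        df = _feature_frame(rng, 8, shift=1.0)
        res1 = knn_lopo(df, k=3)
        res2 = knn_lopo(df.sample(frac=1, random_state=0), k=3)
        pd.testing.assert_frame_equal(res1.predictions.sort_index(),
                                      res2.predictions.sort_index())


class TestRocAuc:
    def test_perfect_ranking(self):
        auc, _ = roc_auc([0.9, 0.8, 0.1, 0.2], ["malignant", "malignant",
                                                "benign", "benign"])
        assert auc == 1.0

    def test_exchangeable_scores(self):
        auc, _ = roc_auc([0.6, 0.4, 0.6, 0.4], [1, 0, 0, 1])
        assert auc == 0.5

    def test_pairwise_enumeration_example(self):
        # malignant {3, 1}, benign {2, 0}: 3 wins, 1 loss of 4 pairs
        auc, _ = roc_auc([3, 1, 2, 0], [1, 1, 0, 0])
        assert auc == pytest.approx(3 / 4)

    def test_rank_auc_equals_trapezoidal_roc_area(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            scores = rng.choice([0.0, 0.2, 0.4, 0.6, 0.8, 1.0], size=30)
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                continue
            auc, roc = roc_auc(scores, labels)
            trapz = np.trapezoid(roc["tpr"], roc["fpr"])
            assert auc == pytest.approx(trapz, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        scores = rng.standard_normal(50)
        labels = rng.integers(0, 2, size=50)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores))


class TestFeatureStats:
    def test_holm_correction_optional_and_monotone(self):
        from qusmap.cohort_stats import feature_stats

        rng = np.random.default_rng(12)
        df = _feature_frame(rng, 12, shift=1.5)
        plain = feature_stats(df, candidates=tuple(df.columns[:4]))
        assert "p_holm" not in plain.columns
        adj = feature_stats(df, candidates=tuple(df.columns[:4]), holm=True)
        assert (adj["p_holm"] >= adj["p"] - 1e-15).all()
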