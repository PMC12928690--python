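"""Feature standardization, resampling (NearMiss-1 / SMOTE) and CV harness."""

import numpy as np
import pandas as pd
import pytest

from cardioresp import ml
from conftest import make_feature_table


def _table(cols: dict, labels=None):
    frame = pd.DataFrame(cols)
    if labels is None:
        labels = [0, 1] * (len(frame) // 2) + [0] * (len(frame) % 2)
    return ml.FeatureTable(frame, pd.Series(labels, index=frame.index))


class TestZscore:
    def test_three_point_column(self):
        t = _table({"a": [1.0, 2.0, 3.0]})
        out = ml.zscore_normalize(t)
        np.testing.assert_allclose(out.frame["a"].to_numpy(), [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        t = _table({"a": [1.0, 2.0, 3.0, 7.0]})
        once = ml.zscore_normalize(t)
        twice = ml.zscore_normalize(once)
        np.testing.assert_allclose(once.frame.to_numpy(), twice.frame.to_numpy(), atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        t = _table({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = ml.zscore_normalize(t)
        assert list(out.frame.columns) == ["a"]
        assert "b" in out.provenance["dropped_columns"]

    def test_single_row_rejected(self):
        t = ml.FeatureTable(pd.DataFrame({"a": [1.0]}), pd.Series([0]))
        with pytest.raises(ValueError):
            ml.zscore_normalize(t)


class TestCorrelationFilter:
    def test_duplicate_column_dropped(self):
        t = _table({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        out = ml.correlation_filter(t)
        assert list(out.frame.columns) == ["a"]

    def test_orthogonal_columns_kept(self):
        t = _table({"a": [1.0, -1.0, 1.0, -1.0], "b": [1.0, 1.0, -1.0, -1.0]})
        out = ml.correlation_filter(t)
        assert list(out.frame.columns) == ["a", "b"]

    def test_exact_threshold_pair_retained(self):
        # constructed so r is exactly 4/5: boundary is strict
        a = np.array([2.0, 1.0, 0.0, -1.0, -2.0])
        b = 4 * a + 3 * np.array([1.0, -2.0, 0.0, 2.0, -1.0])
        t = _table({"a": a, "b": b}, labels=[0, 1, 0, 1, 0])
        assert abs(t.frame.corr().loc["a", "b"] - 0.8) < 1e-12
        out = ml.correlation_filter(t, threshold=0.8)
        assert list(out.frame.columns) == ["a", "b"]


class TestNearMiss1:
    def test_study_counts_18_11_to_22(self, imbalanced_table):
        out = ml.nearmiss1(imbalanced_table, k=3)
        assert len(out.frame) == 22
        assert (out.labels == 1).sum() == 11 and (out.labels == 0).sum() == 11

    def test_already_balanced_unchanged(self):
        t = make_feature_table(5, 5, seed=1)
        out = ml.nearmiss1(t, k=3)
        pd.testing.assert_frame_equal(out.frame, t.frame)

    def test_one_dimensional_toy_against_enumeration(self):
        # majority {0, 1, 10}, minority {0.1, 0.9}: keeping 2 majority rows
        # closest (mean distance to k=2 nearest minority) must keep {0, 1}
        frame = pd.DataFrame({"x": [0.0, 1.0, 10.0, 0.1, 0.9]})
        labels = pd.Series([1, 1, 1, 0, 0])
        out = ml.nearmiss1(ml.FeatureTable(frame, labels), k=2)
        kept_majority = sorted(out.frame.loc[out.labels == 1, "x"])
        assert kept_majority == [0.0, 1.0]

    def test_k_exceeding_minority_rejected(self, imbalanced_table):
        with pytest.raises(ValueError, match="k="):
            ml.nearmiss1(imbalanced_table, k=12)

    def test_brute_force_distance_oracle(self):
        # independent enumeration of the NearMiss-1 criterion
        t = make_feature_table(8, 4, n_features=3, seed=2)
        k = 2
        x, y = t.x, t.y
        maj, mino = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        scores = []
        for i in maj:
            d = sorted(np.linalg.norm(x[i] - x[j]) for j in mino)
            scores.append(np.mean(d[:k]))
        expected = set(maj[np.argsort(scores, kind="stable")[: mino.size]])
        out = ml.nearmiss1(t, k=k)
        kept = set(np.flatnonzero(t.frame.index.isin(out.frame.index) & (t.y == 1)))
        assert kept == expected


class TestSmote:
    def test_study_counts_18_11_to_36(self, imbalanced_table):
        out = ml.smote(imbalanced_table, k=5, seed=0)
        assert len(out.frame) == 36
        assert out.provenance["n_synthetic"] == 7
        assert (out.labels == 0).sum() == 18

    def test_synthetic_rows_on_minority_segments(self, imbalanced_table):
        out = ml.smote(imbalanced_table, k=5, seed=3)
        minority = imbalanced_table.frame[imbalanced_table.labels == 0].to_numpy()
        synth_rows = out.frame.loc[out.frame.index.str.startswith("smote_")].to_numpy()
        for z in synth_rows:
            on_segment = False
            for i in range(minority.shape[0]):
                for j in range(minority.shape[0]):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    nz = np.flatnonzero(np.abs(d) > 1e-12)
                    if nz.size == 0:
                        continue
                    u = (z[nz[0]] - minority[i, nz[0]]) / d[nz[0]]
                    if 0 <= u <= 1 and np.allclose(z, minority[i] + u * d, atol=1e-9):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_seed_determinism(self, imbalanced_table):
        a = ml.smote(imbalanced_table, seed=11)
        b = ml.smote(imbalanced_table, seed=11)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_minority_too_small_rejected(self):
        t = make_feature_table(8, 4, seed=0)
        with pytest.raises(ValueError, match="minority"):
            ml.smote(t, k=5)


class TestMetrics:
    def test_perfect_classifier(self):
        m = ml.metrics_from_confusion(10, 0, 10, 0)
        assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall", "specificity", "f1"))

    def test_printed_confusion_example(self):
        m = ml.metrics_from_confusion(9, 1, 6, 5)
        assert m["recall"] == pytest.approx(0.900, abs=5e-4)
        assert m["specificity"] == pytest.approx(0.545, abs=5e-4)
        assert m["precision"] == pytest.approx(0.643, abs=5e-4)
        assert m["f1"] == pytest.approx(0.750, abs=5e-4)

    def test_undefined_precision_reported_missing(self):
        m = ml.metrics_from_confusion(0, 10, 10, 0)
        assert m["recall"] == 0.0
        assert m["precision"] is None

    def test_accuracy_identity_from_confusion(self):
        tp, fn, tn, fp = 7, 3, 5, 2
        m = ml.metrics_from_confusion(tp, fn, tn, fp)
        p, n = tp + fn, tn + fp
        assert m["accuracy"] == pytest.approx((m["recall"] * p + m["specificity"] * n) / (p + n))


class TestRunExperiment:
    @pytest.mark.parametrize("classifier", ["logreg", "svm_linear", "svm_rbf"])
    def test_separable_cohort_perfect_metrics(self, classifier):
        t = make_feature_table(15, 10, n_features=3, seed=0, separation=8.0)
        t.frame.columns = ["hrv_lf", "hrv_hf", "hrv_lf_hf"]
        cfg = ml.ExperimentConfig(feature_set="hrv", classifier=classifier, seed=0)
        rep = ml.run_experiment(t, cfg)
        for metric in ("accuracy", "precision", "recall", "specificity", "f1", "auc"):
            assert rep.mean[metric] == pytest.approx(1.0)

    def test_label_permutation_null_auc(self):
        rng = np.random.default_rng(0)
        aucs = []
        for rep_i in range(10):
            t = make_feature_table(15, 10, n_features=3, seed=100 + rep_i, separation=0.0)
            t.frame.columns = ["hrv_lf", "hrv_hf", "hrv_lf_hf"]
            perm = rng.permutation(len(t.labels))
            t = ml.FeatureTable(t.frame, pd.Series(t.y[perm], index=t.frame.index))
            rep = ml.run_experiment(t, ml.ExperimentConfig(feature_set="hrv", seed=rep_i))
            aucs.append(rep.mean["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_seeded_determinism(self):
        t = make_feature_table(15, 10, n_features=3, seed=1, separation=1.0)
        t.frame.columns = ["hrv_lf", "hrv_hf", "hrv_lf_hf"]
        cfg = ml.ExperimentConfig(feature_set="hrv", balancing="smote", seed=5)
        a, b = ml.run_experiment(t, cfg), ml.run_experiment(t, cfg)
        assert a.mean == b.mean and a.sd == b.sd and a.confusions == b.confusions

    def test_balancing_equalizes_classes_inside_cv(self):
        t = make_feature_table(18, 11, n_features=3, seed=2, separation=1.0)
        t.frame.columns = ["hrv_lf", "hrv_hf", "hrv_lf_hf"]
        for bal, expected_n in (("nearmiss1", 22), ("smote", 36)):
            rep = ml.run_experiment(t, ml.ExperimentConfig(feature_set="hrv", balancing=bal, seed=0))
            total = sum(sum(c) for c in rep.confusions)
            assert total == expected_n

    def test_foldwise_clean_mode_runs(self):
        t = make_feature_table(18, 11, n_features=3, seed=3, separation=2.0)
        t.frame.columns = ["hrv_lf", "hrv_hf", "hrv_lf_hf"]
        rep = ml.run_experiment(
            t, ml.ExperimentConfig(feature_set="hrv", balancing="smote", seed=0, foldwise=True)
        )
        assert rep.mean["auc"] is not None

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ml.ExperimentConfig(feature_set="nope")
        with pytest.raises(ValueError):
            ml.ExperimentConfig(balancing="undersample")
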