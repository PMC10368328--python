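"""CV engine correctness: scikit-learn oracle, chance levels, statistics."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.preprocessing import StandardScaler

from convscreen import (
    CVConfig,
    compare_metric_distributions,
    encode_alignment,
    fit_standardized_logistic,
    full_data_coefficients,
    majority_class_fraction,
    misclassification_by_group,
    permuted_label_cv,
    repeated_subsample_cv,
)
from convscreen.cv import CVSummary, METRICS


def _sklearn_split_fit(X, y, train):
    scaler = StandardScaler().fit(X[train])
    clf = LogisticRegression(C=1.0, max_iter=5000, tol=1e-10)
    clf.fit(scaler.transform(X[train]), y[train])
    prob = clf.predict_proba(scaler.transform(X[~train]))[:, 1]
    return clf, prob


class TestEngineVsSklearn:
    """The vectorized multi-split solver must match per-split scikit-learn fits."""

    def test_metrics_match_per_split_sklearn(self, random_xy):
        X, y = random_xy
        config = CVConfig(n_iterations=10, master_seed=3, tolerance=1e-7)
        cv = repeated_subsample_cv(X, y, config)
        for m in range(config.n_iterations):
            test = cv.test_mask[m]
            _, prob = _sklearn_split_fit(X, y, ~test)
            yt, pt = y[test], prob >= 0.5
            assert cv.metrics["accuracy"][m] == pytest.approx(
                accuracy_score(yt, pt), abs=1e-9)
            assert cv.metrics["auroc"][m] == pytest.approx(
                roc_auc_score(yt, prob), abs=1e-6)
            assert cv.metrics["precision"][m] == pytest.approx(
                precision_score(yt, pt, zero_division=0), abs=1e-9)
            assert cv.metrics["recall"][m] == pytest.approx(
                recall_score(yt, pt, zero_division=0), abs=1e-9)
            assert cv.metrics["f1"][m] == pytest.approx(
                f1_score(yt, pt, zero_division=0), abs=1e-9)

    def test_full_data_coefficients_match_sklearn(self, random_xy):
        X, y = random_xy
        coefs = full_data_coefficients(X, y, CVConfig(master_seed=0))
        scaler = StandardScaler().fit(X)
        ref = LogisticRegression(C=1.0, max_iter=5000, tol=1e-10).fit(
            scaler.transform(X), y)
        assert np.abs(coefs - ref.coef_.ravel()).max() < 1e-5

    def test_fitted_model_predicts_like_sklearn(self, random_xy):
        X, y = random_xy
        model = fit_standardized_logistic(X, y)
        scaler = StandardScaler().fit(X)
        ref = LogisticRegression(C=1.0, max_iter=5000, tol=1e-10).fit(
            scaler.transform(X), y)
        assert np.abs(
            model.predict_proba(X) - ref.predict_proba(scaler.transform(X))[:, 1]
        ).max() < 1e-5


class TestRepeatedSubsampleCV:
    def test_deterministic_under_seed(self, random_xy):
        X, y = random_xy
        config = CVConfig(n_iterations=15, master_seed=4)
        a = repeated_subsample_cv(X, y, config)
        b = repeated_subsample_cv(X, y, config)
        for m in METRICS:
            assert np.array_equal(a.metrics[m], b.metrics[m])

    def test_seed_context_changes_splits(self, random_xy):
        X, y = random_xy
        config = CVConfig(n_iterations=15, master_seed=4)
        a = repeated_subsample_cv(X, y, config, seed_context=(1, 0))
        b = repeated_subsample_cv(X, y, config, seed_context=(2, 0))
        assert not np.array_equal(a.test_mask, b.test_mask)

    def test_splits_do_not_depend_on_features(self, random_xy):
        X, y = random_xy
        config = CVConfig(n_iterations=15, master_seed=4)
        a = repeated_subsample_cv(X, y, config)
        b = repeated_subsample_cv(np.flip(X, axis=1) + 7.0, y, config)
        assert np.array_equal(a.test_mask, b.test_mask)

    def test_test_fraction_respected(self, random_xy):
        X, y = random_xy
        config = CVConfig(n_iterations=5, master_seed=1, test_fraction=0.3)
        cv = repeated_subsample_cv(X, y, config)
        assert (cv.test_mask.sum(axis=1) == round(0.3 * len(y))).all()

    def test_both_classes_in_every_portion(self, random_xy):
        X, y = random_xy
        cv = repeated_subsample_cv(X, y, CVConfig(n_iterations=40, master_seed=2))
        for m in range(40):
            assert len(np.unique(y[cv.test_mask[m]])) == 2
            assert len(np.unique(y[~cv.test_mask[m]])) == 2

    def test_signal_beats_noise(self):
        rng = np.random.default_rng(0)
        n = 60
        y = (np.arange(n) % 2).astype(np.int8)
        signal = np.column_stack([y + 0.0, rng.random(n)])
        noise = rng.random((n, 2))
        config = CVConfig(n_iterations=30, master_seed=6)
        acc_sig = repeated_subsample_cv(signal, y, config).mean("accuracy")
        acc_noise = repeated_subsample_cv(noise, y, config).mean("accuracy")
        assert acc_sig > 0.95
        assert acc_noise < 0.75

    def test_feature_matrix_input_uses_labels(self, tiny_dataset, fast_config):
        alignments, _ = tiny_dataset
        fm = encode_alignment(alignments["sigA"])
        cv = repeated_subsample_cv(fm, config=fast_config)
        assert cv.sample_ids == fm.sample_ids
        assert cv.mean("accuracy") > 0.8

    def test_plain_array_requires_y(self, random_xy):
        X, _ = random_xy
        with pytest.raises(ValueError, match="y is required"):
            repeated_subsample_cv(X, None, CVConfig(n_iterations=2))

    def test_single_class_rejected(self, random_xy):
        X, _ = random_xy
        with pytest.raises(ValueError, match="both classes"):
            repeated_subsample_cv(X, np.zeros(len(X), dtype=int),
                                  CVConfig(n_iterations=2))


class TestPermutedLabelCV:
    def test_deterministic(self, random_xy):
        X, y = random_xy
        config = CVConfig(n_iterations=10, master_seed=9)
        a = permuted_label_cv(X, y, config)
        b = permuted_label_cv(X, y, config)
        assert np.array_equal(a.metrics["accuracy"], b.metrics["accuracy"])

    def test_modes_differ_and_single_is_one_permutation(self, random_xy):
        X, y = random_xy
        config = CVConfig(n_iterations=10, master_seed=9)
        per = permuted_label_cv(X, y, config, mode="per-iteration")
        single = permuted_label_cv(X, y, config, mode="single")
        assert not np.array_equal(per.metrics["accuracy"],
                                  single.metrics["accuracy"])

    def test_unknown_mode(self, random_xy):
        X, y = random_xy
        with pytest.raises(ValueError, match="mode"):
            permuted_label_cv(X, y, CVConfig(n_iterations=2), mode="bogus")

    def test_destroys_signal(self):
        n = 60
        y = (np.arange(n) % 2).astype(np.int8)
        X = np.column_stack([y + 0.0, y + 0.0])
        config = CVConfig(n_iterations=30, master_seed=3)
        true_acc = repeated_subsample_cv(X, y, config).mean("accuracy")
        null_acc = permuted_label_cv(X, y, config).mean("accuracy")
        assert true_acc == 1.0
        assert null_acc < 0.75


class TestCompareMetricDistributions:
    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        a, b = rng.random(30), rng.random(30) + 0.2
        res = compare_metric_distributions(a, b, m=3)
        t, p = stats.ttest_ind(a, b)
        assert res.t_statistic == pytest.approx(float(t))
        assert res.p_raw == pytest.approx(float(p))
        assert res.p_adjusted == pytest.approx(min(1.0, 3 * float(p)))

    def test_one_sided_greater(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        a, b = rng.random(30) + 0.3, rng.random(30)
        res = compare_metric_distributions(a, b, alternative="greater")
        t, p = stats.ttest_ind(a, b, alternative="greater")
        assert res.p_raw == pytest.approx(float(p))
        # the reversed direction is non-significant by construction
        rev = compare_metric_distributions(b, a, alternative="greater")
        assert rev.p_raw > 0.5

    def test_zero_variance_equal_means(self):
        res = compare_metric_distributions([1.0, 1.0], [1.0, 1.0])
        assert res.p_raw == 1.0 and not res.significant

    def test_zero_variance_different_means(self):
        res = compare_metric_distributions([1.0, 1.0], [0.0, 0.0])
        assert res.p_raw == 0.0 and res.significant
        down = compare_metric_distributions([0.0, 0.0], [1.0, 1.0],
                                            alternative="greater")
        assert down.p_raw == 1.0 and not down.significant

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            compare_metric_distributions([], [1.0])

    def test_bad_alternative(self):
        with pytest.raises(ValueError, match="alternative"):
            compare_metric_distributions([1.0], [0.5], alternative="sideways")


class TestGroupMisclassification:
    def test_pooled_rates_hand_case(self):
        # 2 iterations x 4 samples; groups g1=(0,1), g2=(2,3)
        y = np.array([0, 1, 0, 1])
        predictions = np.array(
            [[0, 1, 1, 1],    # sample 2 wrong
             [1, 1, 0, 0]])   # samples 0 and 3 wrong
        test_mask = np.array(
            [[True, True, True, False],
             [True, False, True, True]])
        summary = CVSummary(
            metrics={m: np.zeros(2) for m in METRICS},
            test_mask=test_mask,
            predictions=predictions.astype(bool),
        )
        table = misclassification_by_group(
            summary, ["g1", "g1", "g2", "g2"], y)
        g1 = table[table["group"] == "g1"].iloc[0]
        g2 = table[table["group"] == "g2"].iloc[0]
        # g1: 3 test appearances, 1 error (sample 0 in iter 2)
        assert g1["appearances"] == 3 and g1["errors"] == 1
        assert g1["rate"] == pytest.approx(1 / 3)
        # g2: 3 test appearances, 2 errors
        assert g2["appearances"] == 3 and g2["errors"] == 2
        assert g2["rate"] == pytest.approx(2 / 3)

    def test_never_tested_group_is_nan(self):
        y = np.array([0, 1, 1])
        summary = CVSummary(
            metrics={m: np.zeros(1) for m in METRICS},
            test_mask=np.array([[True, True, False]]),
            predictions=np.array([[False, True, True]]),
        )
        table = misclassification_by_group(summary, ["a", "a", "lonely"], y)
        lonely = table[table["group"] == "lonely"].iloc[0]
        assert np.isnan(lonely["rate"])


def test_majority_class_fraction():
    assert majority_class_fraction([0, 0, 1]) == pytest.approx(2 / 3)
    assert majority_class_fraction([0] * 58 + [1] * 76) == pytest.approx(76 / 134)
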