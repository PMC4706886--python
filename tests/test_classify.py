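"""SVM training, cross-validated evaluation, and system comparison."""

import numpy as np
import pytest
from scipy import stats

from eegmem import (
    LabeledDataset,
    SVMConfig,
    balanced_subset,
    compare_systems,
    evaluate_cv,
    fold_accuracies,
    repeated_cv,
    train_svm,
)
from eegmem.errors import InputError, ParameterError

SMALL_CFG = SVMConfig(C_grid=(0.1, 1.0, 10.0), gamma_grid=(0.01, 0.1), inner_folds=3)


def blobs(n_per_class, sep, n_features=5, seed=0):
    """Two Gaussian blobs separated by `sep` SDs along every feature."""
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    x1 = rng.normal(sep, 1.0, size=(n_per_class, n_features))
    y = np.r_[np.zeros(n_per_class), np.ones(n_per_class)].astype(int)
    return LabeledDataset(np.vstack([x0, x1]), y)


class TestTrainSvm:
    def test_separable_blobs_perfect_training_accuracy(self):
        data = blobs(20, sep=6.0)
        model = train_svm(data, SMALL_CFG, seed=0)
        assert np.mean(model.predict(data.features) == data.labels) == 1.0

    def test_predictions_are_binary(self):
        data = blobs(10, sep=1.0)
        pred = train_svm(data, SMALL_CFG, seed=0).predict(data.features)
        assert set(pred) <= {0, 1}

    def test_permuted_labels_near_chance_inner_cv(self):
        rng = np.random.default_rng(3)
        data = blobs(50, sep=3.0, seed=3)
        shuffled = LabeledDataset(data.features, rng.permutation(data.labels))
        model = train_svm(shuffled, SMALL_CFG, seed=3)
        assert 0.35 <= model.best_score_ <= 0.65

    def test_tie_break_prefers_smaller_c_then_gamma(self):
        # constant features: every grid point scores identically
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        data = LabeledDataset(np.ones((20, 3)), y)
        model = train_svm(data, SMALL_CFG, seed=0)
        assert model.best_params_ == {"svc__C": 0.1, "svc__gamma": 0.01}

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            train_svm(
                LabeledDataset(np.zeros((6, 2)), np.zeros(6, dtype=int)), SMALL_CFG
            )


class TestEvaluateCv:
    def test_separable_data_high_accuracy(self):
        res = evaluate_cv(blobs(30, sep=6.0), folds=10, cfg=SMALL_CFG, seed=1)
        assert len(res.fold_accuracies) == 10
        assert res.mean_accuracy >= 95.0
        assert res.mean_auc >= 0.95

    def test_shuffled_labels_chance_level(self):
        rng = np.random.default_rng(5)
        data = blobs(50, sep=4.0, seed=5)
        shuffled = LabeledDataset(data.features, rng.permutation(data.labels))
        res = evaluate_cv(shuffled, folds=10, cfg=SMALL_CFG, seed=5)
        assert 40.0 <= res.mean_accuracy <= 60.0

    def test_determinism(self):
        data = blobs(20, sep=1.5)
        a = evaluate_cv(data, folds=5, cfg=SMALL_CFG, seed=9)
        b = evaluate_cv(data, folds=5, cfg=SMALL_CFG, seed=9)
        assert a == b

    def test_no_leakage_with_many_noise_features(self):
        """Per-fold selection + standardization must stay at chance on
        label-permuted data even when features vastly outnumber samples."""
        rng = np.random.default_rng(12)
        x = rng.normal(size=(100, 600))
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)[rng.permutation(100)]
        res = evaluate_cv(
            LabeledDataset(x, y),
            folds=10,
            cfg=SMALL_CFG,
            seed=12,
            n_selected_features=50,
        )
        assert 40.0 <= res.mean_accuracy <= 60.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError):
            evaluate_cv(blobs(5, sep=1.0), folds=10, cfg=SMALL_CFG)

    def test_result_statistics_recomputable(self):
        res = evaluate_cv(blobs(20, sep=2.0), folds=5, cfg=SMALL_CFG, seed=2)
        assert res.mean_accuracy == pytest.approx(np.mean(res.fold_accuracies))
        assert res.sd_accuracy == pytest.approx(np.std(res.fold_accuracies, ddof=1))
        assert all(0 <= a <= 100 for a in res.fold_accuracies)
        assert all(0 <= a <= 1 for a in res.fold_aucs)


class TestBalancedSubset:
    def test_exact_balance(self):
        data = blobs(120, sep=1.0)
        sub = balanced_subset(data, 100, seed=0)
        assert len(sub) == 200
        assert int(sub.labels.sum()) == 100

    def test_minimal_subset(self):
        sub = balanced_subset(blobs(5, sep=1.0), 1, seed=0)
        assert sorted(sub.labels) == [0, 1]

    def test_insufficient_samples(self):
        with pytest.raises(InputError):
            balanced_subset(blobs(5, sep=1.0), 6, seed=0)


class TestRepeatedCv:
    def test_shape_r_by_folds(self):
        data = blobs(15, sep=5.0)
        results = repeated_cv(data, repeats=3, folds=5, cfg=SMALL_CFG, seed=4)
        assert len(results) == 3
        accs = fold_accuracies(results)
        assert accs.shape == (15,)
        # repeats reshuffle folds, so runs are not all identical
        assert len({r.seed for r in results}) == 3


class TestCompareSystems:
    def test_identical_samples(self):
        res = compare_systems([95.0, 96.0, 97.0], [95.0, 96.0, 97.0])
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_identical_constant_samples(self):
        res = compare_systems([100.0, 100.0], [100.0, 100.0])
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_closed_form_oracle(self):
        """Pooled-variance t computed by hand for (1..5) vs (2..6)."""
        a, b = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
        res = compare_systems(a, b)
        # means 3, 4; sample variances 2.5 each; pooled SE = sqrt(2.5*(1/5+1/5)) = 1
        assert res.t_statistic == pytest.approx(-1.0)
        assert res.p_value == pytest.approx(2 * stats.t.sf(1.0, df=8))
        assert (res.mean_a, res.mean_b) == (3.0, 4.0)
        assert res.sd_a == pytest.approx(np.sqrt(2.5))

    def test_type_i_error_rate(self):
        """Same-distribution samples reject at ~alpha under the t-test."""
        rng = np.random.default_rng(77)
        rejections = sum(
            compare_systems(rng.normal(size=25), rng.normal(size=25)).p_value < 0.05
            for _ in range(1000)
        )
        assert 30 <= rejections <= 70

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            compare_systems([1.0], [1.0, 2.0])
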