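"""Feature selection, classifiers, metrics and the two evaluation protocols."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirrortrail.classify import (
    CLASSIFIER_ROSTER,
    ClassifierSpec,
    ConfusionMatrix,
    auc,
    confusion_metrics,
    evaluate_holdout,
    evaluate_loo,
    select_features,
    train_and_score,
)
from mirrortrail.errors import DegenerateInputError, InvalidArgumentError
from mirrortrail.records import FEATURE_GROUPS, FEATURE_NAMES


def labelled_frame(rng, n_per_class, separation):
    """Separable toy features: group-structured shift on three columns."""
    n = 2 * n_per_class
    data = rng.normal(size=(n, len(FEATURE_NAMES)))
    y = np.repeat([0, 1], n_per_class)
    for col in ("TMT ICT median", "S GWS p pf", "LF RP time std"):
        data[y == 1, FEATURE_NAMES.index(col)] += separation
    return pd.DataFrame(data, columns=FEATURE_NAMES), y


class TestSelectFeatures:
    def test_mode_18_all_in_canonical_order(self):
        rng = np.random.default_rng(0)
        f, y = labelled_frame(rng, 10, 1.0)
        assert select_features(f, y, 18) == tuple(FEATURE_NAMES)

    def test_mode_3_one_per_group(self):
        rng = np.random.default_rng(1)
        f, y = labelled_frame(rng, 16, 3.0)
        chosen = select_features(f, y, 3)
        assert len(chosen) == 3
        assert chosen[0] in FEATURE_GROUPS["TMT"]
        assert chosen[1] in FEATURE_GROUPS["Solo"]
        assert chosen[2] in FEATURE_GROUPS["LF"]
        # the shifted columns dominate their groups at this separation
        assert chosen == ("TMT ICT median", "S GWS p pf", "LF RP time std")

    def test_mode_2_skips_solo(self):
        rng = np.random.default_rng(2)
        f, y = labelled_frame(rng, 16, 3.0)
        chosen = select_features(f, y, 2)
        assert len(chosen) == 2
        assert not any(c in FEATURE_GROUPS["Solo"] for c in chosen)

    def test_tie_resolves_to_earlier_feature(self):
        n = 8
        y = np.repeat([0, 1], n)
        data = np.zeros((2 * n, len(FEATURE_NAMES)))
        # two TMT features with identical perfect separation
        for col in ("TMT ICT std", "TMT ICT median"):
            data[y == 1, FEATURE_NAMES.index(col)] = 1.0
        f = pd.DataFrame(data, columns=FEATURE_NAMES)
        chosen = select_features(f, y, 3)
        assert chosen[0] == "TMT ICT std"  # earlier in canonical order

    def test_single_class_rejected(self):
        rng = np.random.default_rng(3)
        f, _ = labelled_frame(rng, 4, 0.0)
        with pytest.raises(DegenerateInputError):
            select_features(f, np.zeros(8, int), 3)


class TestTrainAndScore:
    @pytest.mark.parametrize("kind", ["knn", "naive_bayes", "svm", "bagged_trees",
                                      "linear_discriminant"])
    def test_separable_toy_perfect_accuracy(self, kind):
        rng = np.random.default_rng(4)
        train = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.repeat([0, 1], 20)
        test = np.vstack([rng.normal(-3, 0.3, (5, 2)), rng.normal(3, 0.3, (5, 2))])
        pred, scores = train_and_score(ClassifierSpec(kind), train, y, test)
        np.testing.assert_array_equal(pred, np.repeat([0, 1], 5))
        assert auc(scores, np.repeat([0, 1], 5)) == 1.0

    def test_knn_self_query_is_nearest(self):
        rng = np.random.default_rng(5)
        train = rng.normal(size=(12, 3))
        y = np.arange(12) % 2
        pred, _ = train_and_score(ClassifierSpec("knn", k=1), train, y, train)
        np.testing.assert_array_equal(pred, y)

    def test_gaussian_nb_threshold_at_midpoint(self):
        # equal variances and priors: the Bayes boundary is the midpoint
        rng = np.random.default_rng(6)
        m0, m1, sd = -1.0, 2.0, 0.5
        train = np.concatenate([rng.normal(m0, sd, 400), rng.normal(m1, sd, 400)])
        y = np.repeat([0, 1], 400)
        grid = np.linspace(m0, m1, 601).reshape(-1, 1)
        pred, _ = train_and_score(ClassifierSpec("naive_bayes"), train.reshape(-1, 1),
                                  y, grid)
        boundary = grid[np.argmax(pred == 1), 0]
        assert boundary == pytest.approx((m0 + m1) / 2, abs=0.05)


class TestMetrics:
    def test_printed_holdout_style_matrix(self):
        m = confusion_metrics(ConfusionMatrix(tn=8, fp=0, tp=6, fn=2))
        assert m["accuracy"] == pytest.approx(0.875)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == 1.0
        assert m["precision"] == 1.0

    def test_pooled_loo_style_matrix(self):
        m = confusion_metrics(ConfusionMatrix(tn=27, fp=5, tp=26, fn=6))
        assert round(m["accuracy"], 2) == 0.83
        assert round(m["sensitivity"], 2) == 0.81
        assert round(m["specificity"], 2) == 0.84
        assert round(m["precision"], 2) == 0.84

    def test_all_correct(self):
        m = confusion_metrics(ConfusionMatrix(tn=5, fp=0, tp=5, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominator_flagged_nan(self):
        m = confusion_metrics(ConfusionMatrix(tn=10, fp=0, tp=0, fn=0))
        assert np.isnan(m["sensitivity"]) and np.isnan(m["precision"])


class TestAUC:
    def test_perfect_and_reversed(self):
        y = [0, 0, 1, 1]
        assert auc([0.1, 0.2, 0.8, 0.9], y) == 1.0
        assert auc([0.9, 0.8, 0.2, 0.1], y) == 0.0

    def test_hand_computed_with_tie_free_overlap(self):
        # pos scores 0.9, 0.4 vs neg 0.6: one win, one loss of two pairs
        assert auc([0.6, 0.9, 0.4], [0, 1, 1]) == 0.5

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = np.round(rng.normal(size=50), 1)  # induce ties
        assert auc(s, y) == pytest.approx(roc_auc_score(y, s))

    @given(st.floats(0.1, 10.0))
    @settings(derandomize=True, max_examples=20)
    def test_monotone_transform_invariance(self, scale):
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1], 10)
        s = rng.normal(size=20)
        assert auc(np.exp(scale * s), y) == pytest.approx(auc(s, y))

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            auc([0.1, 0.2], [1, 1])


class TestProtocols:
    def test_holdout_separable_perfect(self):
        rng = np.random.default_rng(9)
        f, y = labelled_frame(rng, 16, 6.0)
        s = evaluate_holdout(f, y, CLASSIFIER_ROSTER["LD3"], n_folds=30, seed=1)
        assert s.medians["accuracy"] == 1.0
        assert s.centiles_low["accuracy"] == 1.0

    def test_holdout_determinism(self):
        rng = np.random.default_rng(10)
        f, y = labelled_frame(rng, 12, 1.0)
        a = evaluate_holdout(f, y, CLASSIFIER_ROSTER["kNN3"], n_folds=20, seed=3)
        b = evaluate_holdout(f, y, CLASSIFIER_ROSTER["kNN3"], n_folds=20, seed=3)
        assert a.medians == b.medians
        assert a.centiles_low == b.centiles_low and a.centiles_high == b.centiles_high

    def test_holdout_centiles_bracket_median(self):
        rng = np.random.default_rng(11)
        f, y = labelled_frame(rng, 12, 1.0)
        s = evaluate_holdout(f, y, CLASSIFIER_ROSTER["NB"], n_folds=50, seed=4)
        for m in s.medians:
            assert s.centiles_low[m] <= s.medians[m] <= s.centiles_high[m]

    def test_holdout_stratified_sizes(self):
        rng = np.random.default_rng(12)
        f, y = labelled_frame(rng, 12, 1.0)
        s = evaluate_holdout(f, y, CLASSIFIER_ROSTER["LD3"], n_folds=5,
                             per_class_holdout=3, seed=5)
        for fold in s.folds:
            assert len(fold.test_indices) == 6
            assert np.sum(y[fold.test_indices]) == 3
            assert fold.confusion.total == 6

    def test_label_permutation_null_auc(self):
        rng = np.random.default_rng(13)
        f, y = labelled_frame(rng, 16, 2.0)
        y_perm = rng.permutation(y)
        s = evaluate_holdout(f, y_perm, CLASSIFIER_ROSTER["LD3"], n_folds=200, seed=6)
        assert 0.4 <= s.medians["auc"] <= 0.6

    def test_loo_separating_feature_perfect(self):
        n = 10
        y = np.repeat([0, 1], n)
        data = np.zeros((2 * n, len(FEATURE_NAMES)))
        data[:, 0] = np.where(y == 1, 5.0, -5.0) + np.linspace(0, 0.1, 2 * n)
        f = pd.DataFrame(data, columns=FEATURE_NAMES)
        s = evaluate_loo(f, y, CLASSIFIER_ROSTER["LD3"])
        assert s.pooled_confusion.fp == 0 and s.pooled_confusion.fn == 0
        assert s.pooled_metrics["auc"] == 1.0

    def test_loo_confusion_totals(self):
        rng = np.random.default_rng(14)
        f, y = labelled_frame(rng, 8, 1.0)
        s = evaluate_loo(f, y, CLASSIFIER_ROSTER["NB"])
        assert s.pooled_confusion.total == len(y)

    def test_recovery_monotone_in_separation(self):
        rng = np.random.default_rng(15)
        aucs = []
        for sep in (0.0, 1.0, 3.0):
            f, y = labelled_frame(np.random.default_rng(16), 16, sep)
            s = evaluate_holdout(f, y, CLASSIFIER_ROSTER["LD3"], n_folds=60, seed=7)
            aucs.append(s.medians["auc"])
        assert aucs[0] <= aucs[1] <= aucs[2]


class TestNoLeakage:
    def test_fold_choices_recomputable_from_training_indices(self):
        # scaling parameters and selected features must be pure functions of
        # the training rows
        from mirrortrail.classify import zscore_fit

        rng = np.random.default_rng(17)
        f, y = labelled_frame(rng, 12, 1.5)
        s = evaluate_holdout(f, y, CLASSIFIER_ROSTER["LD3"], n_folds=25, seed=8)
        for fold in s.folds:
            train_f = f.iloc[fold.train_indices]
            selected = select_features(train_f, y[fold.train_indices], 3)
            assert selected == fold.selected_features
            mean, std = zscore_fit(train_f[list(selected)].to_numpy(float))
            np.testing.assert_array_equal(mean, fold.scaler_mean)
            np.testing.assert_array_equal(std, fold.scaler_std)
            assert np.intersect1d(fold.train_indices, fold.test_indices).size == 0
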