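"""Fold construction, metrics, and cross-validated training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from laughpd import (
    ClassifierSpec,
    ConfigError,
    DataError,
    LaughFeatureVector,
    make_folds,
    mcc_from_confusion,
    roc_auc,
    train_eval,
)

NAMES = tuple(f"f{i}" for i in range(8))


def _vectors(n_per_class, shift, seed, subjects_per_class=None):
    rng = np.random.default_rng(seed)
    subjects_per_class = subjects_per_class or n_per_class
    out = []
    for cls, mu in (("healthy", 0.0), ("pd", shift)):
        for i in range(n_per_class):
            out.append(
                LaughFeatureVector(
                    mu + rng.standard_normal(8),
                    NAMES,
                    subject_id=f"{cls}-{i % subjects_per_class}",
                    class_label=cls,
                )
            )
    return out


class TestMakeFolds:
    def test_round_robin_counting(self):
        plan = make_folds([f"s{i}" for i in range(20)], k=10, seed=0)
        counts = np.bincount(list(plan.fold_of_group.values()), minlength=10)
        assert np.all(counts == 2)

    def test_k1_rejected(self):
        with pytest.raises(ConfigError):
            make_folds(["a", "b", "c"], k=1)

    def test_fewer_groups_than_folds_rejected(self):
        with pytest.raises(ConfigError):
            make_folds(["a", "b"], k=3)

    def test_duplicated_records_never_straddle_folds(self):
        groups = [f"s{i}" for i in range(12)] * 5  # 5 records per subject
        plan = make_folds(groups, k=4, seed=1)
        folds = plan.record_folds(np.array(groups))
        for subject in set(groups):
            mask = np.array(groups) == subject
            assert len(set(folds[mask])) == 1


class TestMCC:
    def test_reference_confusion_value(self):
        # TPR 0.84 / TNR 0.82 on a balanced 100+100 sample
        assert mcc_from_confusion(84, 18, 82, 16) == pytest.approx(0.66, abs=0.005)

    def test_perfect_and_random(self):
        assert mcc_from_confusion(50, 0, 50, 0) == 1.0
        assert mcc_from_confusion(25, 25, 25, 25) == 0.0

    def test_degenerate_marginal_is_zero(self):
        assert mcc_from_confusion(0, 0, 10, 10) == 0.0

    @given(st.tuples(*[st.integers(0, 200)] * 4))
    @settings(max_examples=50, derandomize=True)
    def test_class_swap_symmetry_and_sklearn_agreement(self, counts):
        tp, fp, tn, fn = counts
        assert mcc_from_confusion(tp, fp, tn, fn) == pytest.approx(
            mcc_from_confusion(tn, fn, tp, fp), abs=1e-12
        )
        y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
        y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
        if len(set(y_true)) == 2 and len(set(y_pred)) == 2:
            assert mcc_from_confusion(tp, fp, tn, fn) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12
            )


class TestRocAuc:
    def test_scores_equal_labels(self):
        _, auc = roc_auc([0, 1, 0, 1], [False, True, False, True])
        assert auc == 1.0

    def test_all_scores_identical(self):
        points, auc = roc_auc(np.ones(10), np.arange(10) % 2 == 0)
        assert auc == pytest.approx(0.5)

    def test_matches_mann_whitney_concordance(self, rng):
        scores = np.round(rng.standard_normal(200), 1)  # force ties
        labels = rng.random(200) < 0.4
        _, auc = roc_auc(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        conc = np.mean((pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :]))
        assert auc == pytest.approx(conc, abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_score_negation_maps_auc(self, rng):
        scores = rng.standard_normal(100)
        labels = rng.random(100) < 0.5
        _, auc = roc_auc(scores, labels)
        _, auc_neg = roc_auc(-scores, labels)
        assert auc_neg == pytest.approx(1 - auc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([1.0, 2.0], [True, True])


class TestTrainEval:
    @pytest.mark.parametrize("family", ["rf", "knn", "svm"])
    def test_separable_clusters_are_perfect(self, family):
        vs = _vectors(30, shift=20.0, seed=0)
        report = train_eval(vs, ClassifierSpec(family, seed=0), k_folds=5)
        assert report.ar_percent == 100.0
        assert report.mcc == 1.0
        assert report.auc == 1.0

    def test_permuted_labels_are_null(self):
        rng = np.random.default_rng(4)
        vs = _vectors(100, shift=3.0, seed=1)
        labels = [v.class_label for v in vs]
        rng.shuffle(labels)
        shuffled = [
            LaughFeatureVector(v.values, v.names, subject_id=f"s{i}", class_label=lab)
            for i, (v, lab) in enumerate(zip(vs, labels))
        ]
        report = train_eval(shuffled, ClassifierSpec("knn", knn_k=5, seed=2), k_folds=5)
        se = 100 * 0.5 / np.sqrt(len(vs))
        assert abs(report.ar_percent - 50.0) < 3 * se + 5
        assert abs(report.auc - 0.5) < 0.1

    def test_affine_feature_transform_invariance(self):
        # training-fold standardization absorbs any affine map of the columns
        vs = _vectors(40, shift=1.0, seed=3)
        scaled = [
            LaughFeatureVector(
                3.0 * v.values + 7.0, v.names, subject_id=v.subject_id,
                class_label=v.class_label,
            )
            for v in vs
        ]
        spec = ClassifierSpec("knn", knn_k=3, seed=5)
        r1 = train_eval(vs, spec, k_folds=4)
        r2 = train_eval(scaled, spec, k_folds=4)
        assert r1.ar_percent == r2.ar_percent
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)

    def test_ar_consistent_with_confusion(self):
        vs = _vectors(50, shift=1.0, seed=6)
        r = train_eval(vs, ClassifierSpec("rf", rf_trees=30, seed=1), k_folds=5)
        assert r.ar_percent == pytest.approx(100 * (r.tp + r.tn) / r.n_records)
        assert r.tp_rate + r.fn_rate == pytest.approx(1.0)
        assert r.tn_rate + r.fp_rate == pytest.approx(1.0)

    def test_single_class_training_split_rejected(self):
        vs = _vectors(4, shift=1.0, seed=7)
        healthy_only = [v for v in vs if v.class_label == "healthy"]
        with pytest.raises(DataError):
            train_eval(healthy_only, ClassifierSpec("knn", seed=0), k_folds=2)

    def test_nonfinite_features_rejected(self):
        vs = _vectors(10, shift=1.0, seed=8)
        bad = LaughFeatureVector(
            np.full(8, np.nan), NAMES, subject_id="x", class_label="pd"
        )
        with pytest.raises(DataError):
            train_eval(vs + [bad], ClassifierSpec("knn", seed=0), k_folds=3)
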