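"""Confusion-matrix metrics, ROC, and the cross-validated classifier suite."""

import numpy as np
import pandas as pd
import pytest
from sklearn import metrics as skm

from gaitent import (
    CLASSIFIER_NAMES,
    ConfusionMatrix,
    EvalConfig,
    FEATURE_COLUMNS,
    Metrics,
    compute_metrics,
    roc_curve,
    train_evaluate,
)

# printed single-fold matrices for the top classifiers (diseased positive)
SVM_MATRIX = ConfusionMatrix(tn=30, fp=0, fn=3, tp=27)
KNN_MATRIX = ConfusionMatrix(tn=28, fp=2, fn=2, tp=28)


def _feature_frame(X, y):
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    df.insert(0, "label", y)
    return df


def _separable(n_per_class=15, seed=0):
    rng = np.random.default_rng(seed)
    healthy = rng.normal(-4.0, 0.3, size=(n_per_class, 16))
    diseased = rng.normal(4.0, 0.3, size=(n_per_class, 16))
    X = np.vstack([healthy, diseased])
    y = ["healthy"] * n_per_class + ["diseased"] * n_per_class
    return _feature_frame(X, y)


class TestComputeMetrics:
    def test_printed_svm_matrix(self):
        m = compute_metrics(SVM_MATRIX)
        assert round(100 * m.accuracy, 1) == 95.0
        assert m.sensitivity == pytest.approx(27 / 30)
        assert m.specificity == pytest.approx(1.0)

    def test_printed_knn_matrix(self):
        assert round(100 * compute_metrics(KNN_MATRIX).accuracy, 1) == 93.3

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(tn=10, fp=0, fn=0, tp=10))
        assert (m.accuracy, m.f1, m.mcc) == (1.0, 1.0, 1.0)

    def test_matches_sklearn_oracle(self, rng):
        for _ in range(50):
            tn, fp, fn, tp = rng.integers(0, 30, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            cm = ConfusionMatrix(int(tn), int(fp), int(fn), int(tp))
            y_true = ["diseased"] * (tp + fn) + ["healthy"] * (tn + fp)
            y_pred = (
                ["diseased"] * tp + ["healthy"] * fn + ["healthy"] * tn + ["diseased"] * fp
            )
            m = compute_metrics(cm)
            assert m.accuracy == pytest.approx(skm.accuracy_score(y_true, y_pred), abs=1e-12)
            if 2 * tp + fp + fn > 0:
                assert m.f1 == pytest.approx(
                    skm.f1_score(y_true, y_pred, pos_label="diseased"), abs=1e-12
                )
            if min(tp + fp, tn + fn) > 0:
                assert m.mcc == pytest.approx(
                    skm.matthews_corrcoef(
                        [1 if t == "diseased" else 0 for t in y_true],
                        [1 if t == "diseased" else 0 for t in y_pred],
                    ),
                    abs=1e-12,
                )

    def test_undefined_ratios_flagged(self):
        m = compute_metrics(ConfusionMatrix(tn=5, fp=5, fn=0, tp=0))
        assert "sensitivity" in m.undefined and np.isnan(m.sensitivity)
        assert "mcc" in m.undefined and np.isnan(m.mcc)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 1)


class TestRoc:
    def test_perfect_ranking(self):
        labels = ["healthy"] * 5 + ["diseased"] * 5
        *_, auc = roc_curve(np.arange(10), labels)
        assert auc == 1.0

    def test_reversed_scores_complement(self, rng):
        labels = np.where(rng.random(100) < 0.5, "diseased", "healthy")
        scores = rng.normal(size=100) + (labels == "diseased")
        *_, auc = roc_curve(scores, labels)
        *_, auc_rev = roc_curve(-scores, labels)
        assert auc_rev == pytest.approx(1 - auc, abs=1e-12)

    def test_null_scores_near_half(self, rng):
        labels = np.where(rng.random(2000) < 0.5, "diseased", "healthy")
        *_, auc = roc_curve(rng.normal(size=2000), labels)
        assert 0.45 < auc < 0.55

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.9], ["healthy", "healthy"])


class TestTrainEvaluate:
    def test_separable_clusters_perfect_for_all(self):
        report = train_evaluate(_separable(), EvalConfig(k=5, rng_seed=0))
        for name in CLASSIFIER_NAMES:
            rep = report.per_classifier[name]
            assert rep.mean_accuracy == 1.0, name
            assert rep.metrics.mcc == 1.0, name

    def test_deterministic_given_seed(self):
        df = _separable(seed=3)
        df[FEATURE_COLUMNS] += np.random.default_rng(1).normal(0, 4, df[FEATURE_COLUMNS].shape)
        cfg = EvalConfig(k=5, rng_seed=11, classifiers=("svm_gaussian", "neural_net_wide"))
        r1, r2 = train_evaluate(df, cfg), train_evaluate(df, cfg)
        for name in cfg.classifiers:
            assert r1.per_classifier[name].fold_accuracies == r2.per_classifier[name].fold_accuracies
            assert r1.per_classifier[name].auc == r2.per_classifier[name].auc

    def test_holdout_split_sizes(self):
        df = _separable(n_per_class=30)
        cfg = EvalConfig(scheme="holdout", holdout_fraction=0.25, rng_seed=0,
                         classifiers=("logistic_regression",))
        report = train_evaluate(df, cfg)
        cm = report.per_classifier["logistic_regression"].fold_matrices[0]
        assert cm.total == 15  # 25% of 60 subjects

    def test_imputes_missing_features(self):
        df = _separable()
        df.loc[df.index[:4], "S0_te"] = np.nan
        report = train_evaluate(df, EvalConfig(k=5, classifiers=("logistic_regression",)))
        assert report.per_classifier["logistic_regression"].mean_accuracy == 1.0

    def test_stratification_guard(self):
        df = _separable(n_per_class=4)
        with pytest.raises(ValueError, match="reduce k"):
            train_evaluate(df, EvalConfig(k=10))

    def test_label_permutation_near_chance(self, rng):
        """Permuting labels destroys the signal: mean CV accuracy ~ 50%."""
        df = _separable(n_per_class=15, seed=5)
        accs = []
        for rep in range(10):
            shuffled = df.copy()
            shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
            report = train_evaluate(
                shuffled, EvalConfig(k=5, rng_seed=rep, classifiers=("svm_gaussian",))
            )
            accs.append(report.per_classifier["svm_gaussian"].mean_accuracy)
        assert 0.35 < np.mean(accs) < 0.65

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            EvalConfig(classifiers=("svm_linear",))
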