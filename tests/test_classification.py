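"""SVM cross-validation, confusion metrics, AUC, and MRMR ranking."""

import numpy as np
import pandas as pd
import pytest

from hipgait.config import ClassifierConfig
from hipgait.classification import (confusion_metrics, roc_auc,
                                    train_and_crossvalidate,
                                    rank_features_mrmr, resolve_kernel_scale)


def _blob_table(rng, n=200, sep=6.0, n_features=4):
    """Two spherical Gaussian blobs separated by `sep` pooled SDs."""
    half = n // 2
    x = np.vstack([rng.normal(0.0, 1.0, (half, n_features)),
                   rng.normal(sep / np.sqrt(n_features), 1.0,
                              (half, n_features))])
    cols = ["stride_length_m", "stride_time_s", "cadence_spm", "speed_mps"]
    table = pd.DataFrame(x, columns=cols[:n_features])
    table["label"] = ["healthy"] * half + ["patient"] * half
    table["subject_id"] = [f"s{i % 20}" for i in range(n)]
    return table


class TestConfusionMetrics:
    def test_worked_example(self):
        m = confusion_metrics(tp=90, tn=80, fp=20, fn=10)
        assert m["accuracy"] == pytest.approx(85.0)
        assert m["sensitivity"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(80.0)

    def test_perfect_classifier(self):
        m = confusion_metrics(tp=30, tn=70, fp=0, fn=0)
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 100.0

    def test_matches_formula_oracle(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = rng.integers(0, 50, 4)
            if tp + tn + fp + fn == 0:
                continue
            m = confusion_metrics(int(tp), int(tn), int(fp), int(fn))
            assert m["accuracy"] == pytest.approx(
                (tn + tp) / (tp + tn + fp + fn) * 100, abs=1e-10)
            if tp + fn:
                assert m["sensitivity"] == pytest.approx(
                    tp / (tp + fn) * 100, abs=1e-10)
            if tn + fp:
                assert m["specificity"] == pytest.approx(
                    tn / (tn + fp) * 100, abs=1e-10)

    def test_undefined_denominators_flagged(self):
        m = confusion_metrics(tp=0, tn=5, fp=3, fn=0)
        assert m["sensitivity"] is None
        assert "sensitivity_undefined" in m["flags"]


def _auc_paircount(scores, labels):
    """Exhaustive pair counting: P(score_pos > score_neg) + 0.5 ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfectly_separated(self):
        auc, pts = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_hand_case(self):
        auc, _ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_matches_paircount_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 40))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(size=n), 1)  # force ties
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(_auc_paircount(scores, labels),
                                        abs=1e-10)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, 300)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_label_independent_scores_near_half(self, rng):
        aucs = [roc_auc(rng.normal(size=200), rng.integers(0, 2, 200))[0]
                for _ in range(30)]
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestTrainAndCrossvalidate:
    def test_separable_blobs_high_accuracy(self, rng):
        for seed in range(5):
            table = _blob_table(np.random.default_rng(seed), n=200, sep=6.0)
            rep = train_and_crossvalidate(
                table, "set1", ClassifierConfig(n_folds=5, seed=seed))
            assert rep.accuracy >= 99.0
            assert rep.auc >= 0.999

    def test_counts_sum_to_samples_and_each_seen_once(self, rng):
        table = _blob_table(rng, n=150, sep=2.0)
        rep = train_and_crossvalidate(table, "set1",
                                      ClassifierConfig(n_folds=6, seed=0))
        assert rep.tp + rep.tn + rep.fp + rep.fn == len(table)
        assert sum(f.n_val for f in rep.per_fold) == len(table)

    def test_metrics_equal_recount_of_pooled_folds(self, rng):
        table = _blob_table(rng, n=120, sep=1.5)
        rep = train_and_crossvalidate(table, "set1",
                                      ClassifierConfig(n_folds=4, seed=3))
        tp = sum(f.tp for f in rep.per_fold)
        tn = sum(f.tn for f in rep.per_fold)
        fp = sum(f.fp for f in rep.per_fold)
        fn = sum(f.fn for f in rep.per_fold)
        assert (tp, tn, fp, fn) == (rep.tp, rep.tn, rep.fp, rep.fn)
        assert rep.accuracy == pytest.approx(
            100 * (tp + tn) / len(table), abs=1e-10)

    def test_permuted_labels_near_majority_rate(self):
        accs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            table = _blob_table(r, n=200, sep=3.0)
            table["label"] = r.permutation(table["label"].values)
            rep = train_and_crossvalidate(
                table, "set1", ClassifierConfig(n_folds=5, seed=seed))
            accs.append(rep.accuracy)
        majority = 50.0
        assert abs(np.mean(accs) - majority) < 5.0

    def test_reproducible_under_fixed_seed(self, rng):
        table = _blob_table(rng, n=100, sep=2.0)
        cfg = ClassifierConfig(n_folds=4, seed=9)
        a = train_and_crossvalidate(table, "set1", cfg)
        b = train_and_crossvalidate(table, "set1", cfg)
        assert a.to_jsonable() == b.to_jsonable()

    def test_too_many_folds_advises_fewer(self, rng):
        table = _blob_table(rng, n=20, sep=2.0)
        with pytest.raises(ValueError, match="fewer folds|n_folds"):
            train_and_crossvalidate(table, "set1",
                                    ClassifierConfig(n_folds=12, seed=0))

    def test_kernel_scale_fixed_value_respected(self, rng):
        table = _blob_table(rng, n=100, sep=4.0)
        cfg = ClassifierConfig(n_folds=4, seed=1, kernel_scale=2.5)
        rep = train_and_crossvalidate(table, "set1", cfg)
        assert all(f.kernel_scale == 2.5 for f in rep.per_fold)

    def test_auto_kernel_scale_is_median_pairwise_distance(self, rng):
        x = rng.normal(size=(60, 3))
        from scipy.spatial.distance import pdist
        assert resolve_kernel_scale(x, "auto") == pytest.approx(
            np.median(pdist(x)))


class TestMRMR:
    def test_informative_feature_ranked_first(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            n = 200
            label = r.integers(0, 2, n)
            table = pd.DataFrame(
                {f"noise_{i}": r.normal(size=n) for i in range(9)})
            table["signal"] = label + 0.1 * r.normal(size=n)
            table["label"] = np.where(label, "patient", "healthy")
            ranking = rank_features_mrmr(
                table, features=[c for c in table.columns if c != "label"])
            if ranking[0][0] == "signal":
                hits += 1
        assert hits >= 95

    def test_single_feature(self, rng):
        table = pd.DataFrame({"f": rng.normal(size=50),
                              "label": ["healthy", "patient"] * 25})
        assert rank_features_mrmr(table, features=["f"])[0][0] == "f"

    def test_duplicate_feature_penalized_below_weaker_independent(self):
        r = np.random.default_rng(4)
        n = 400
        label = r.integers(0, 2, n)
        strong = label + 0.2 * r.normal(size=n)
        weak = label + 1.2 * r.normal(size=n)
        table = pd.DataFrame({
            "strong": strong, "strong_copy": strong + 1e-9 * r.normal(size=n),
            "weak_independent": weak,
            "label": np.where(label, "patient", "healthy")})
        ranking = [f for f, _ in rank_features_mrmr(
            table, features=["strong", "strong_copy", "weak_independent"])]
        assert ranking[0] == "strong"
        assert ranking.index("weak_independent") < ranking.index("strong_copy")

    def test_constant_feature_ranked_last(self, rng):
        table = pd.DataFrame({
            "informative": np.r_[np.zeros(50), np.ones(50)]
            + 0.1 * rng.normal(size=100),
            "flat": np.ones(100),
            "label": ["healthy"] * 50 + ["patient"] * 50})
        ranking = rank_features_mrmr(table, features=["flat", "informative"])
        assert ranking[-1] == ("flat", 0.0)
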