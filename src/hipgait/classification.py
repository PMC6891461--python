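"""RBF-SVM gait classification with cross-validation, plus MRMR ranking.

The classifier follows the study protocol: Gaussian RBF kernel, box
constraint (C) 1.7, features standardized, stratified 12-fold
cross-validation with predictions pooled across validation folds into one
confusion matrix. "Kernel scale auto" is resolved as the median pairwise
Euclidean distance between standardized training samples of each fold
(gamma = 1 / scale^2). Standardization statistics come from the training
portion of each fold only, so no information leaks into validation.

Accuracy, sensitivity and specificity are percentages of the pooled
confusion counts; AUC is the Mann-Whitney rank statistic on the pooled
decision scores (ties averaged), equivalent to trapezoidal ROC integration.

Feature importance is ranked with a greedy minimum-redundancy
maximum-relevance (MRMR) mutual-information difference criterion on
equal-frequency-binned features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold
from sklearn.svm import SVC

from .config import ClassifierConfig
from .features import SET1_COLUMNS, SET2_COLUMNS, FEATURE_COLUMNS

__all__ = [
    "ClassifierReport",
    "confusion_metrics",
    "roc_auc",
    "train_and_crossvalidate",
    "rank_features_mrmr",
    "resolve_kernel_scale",
]


@dataclass
class FoldResult:
    fold: int
    n_val: int
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    kernel_scale: float


@dataclass
class ClassifierReport:
    """Pooled cross-validation results of one SVM run."""

    feature_subset: str
    features: list[str]
    positive_class: str
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auc: float
    per_fold: list[FoldResult]
    n_samples: int
    config: dict = field(default_factory=dict)
    roc_points: list[tuple[float, float]] = field(default_factory=list, repr=False)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["per_fold"] = [asdict(f) for f in self.per_fold]
        d["roc_points"] = [list(p) for p in self.roc_points]
        return d


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """ACC/SEN/SPEC in percent from pooled confusion counts.

    ACC = (TN + TP) / (TP + TN + FP + FN) * 100
    SEN = TP / (TP + FN) * 100
    SPEC = TN / (TN + FP) * 100

    Sensitivity/specificity are ``None`` (flagged) when their denominator is
    zero.
    """
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    out = {"accuracy": 100.0 * (tn + tp) / total,
           "sensitivity": None, "specificity": None, "flags": []}
    if tp + fn > 0:
        out["sensitivity"] = 100.0 * tp / (tp + fn)
    else:
        out["flags"].append("sensitivity_undefined")
    if tn + fp > 0:
        out["specificity"] = 100.0 * tn / (tn + fp)
    else:
        out["flags"].append("specificity_undefined")
    return out


def roc_auc(scores, labels, positive_class=1
            ) -> tuple[float, list[tuple[float, float]]]:
    """AUC via the rank (Mann-Whitney) statistic, ties averaged.

    Returns the AUC and the ROC curve as (FPR, TPR) points swept over all
    distinct score thresholds.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_pos = pos[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    # keep the last point of each tied-score block
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    points = [(0.0, 0.0)] + [
        (fps[i] / n_neg, tps[i] / n_pos) for i in np.flatnonzero(distinct)]
    return float(auc), points


def resolve_kernel_scale(x_standardized: np.ndarray, kernel_scale,
                         rng: np.random.Generator | None = None,
                         max_pairs_n: int = 2000) -> float:
    """'auto' kernel scale: median pairwise distance on standardized data."""
    if not isinstance(kernel_scale, str):
        if kernel_scale <= 0:
            raise ValueError("kernel_scale must be positive")
        return float(kernel_scale)
    if kernel_scale != "auto":
        raise ValueError("kernel_scale must be 'auto' or a positive scalar")
    x = np.asarray(x_standardized, float)
    if len(x) > max_pairs_n:
        rng = rng or np.random.default_rng(0)
        x = x[rng.choice(len(x), size=max_pairs_n, replace=False)]
    d = pdist(x)
    d = d[d > 0]
    if len(d) == 0:
        return 1.0
    return float(np.median(d))


def _select_features(feature_subset) -> list[str]:
    if isinstance(feature_subset, str):
        mapping = {"set1": SET1_COLUMNS, "set2": SET2_COLUMNS,
                   "all": FEATURE_COLUMNS}
        if feature_subset not in mapping:
            raise ValueError("feature_subset must be set1|set2|all or a list")
        return list(mapping[feature_subset])
    return list(feature_subset)


def train_and_crossvalidate(table: pd.DataFrame, feature_subset="all",
                            config: ClassifierConfig | None = None
                            ) -> ClassifierReport:
    """Cross-validated RBF-SVM on a labeled feature table.

    Every sample is predicted exactly once, by the model of the fold that
    held it out; the pooled predictions form the confusion matrix and the
    pooled decision scores the ROC/AUC. Requires both classes in every
    training fold (reduce ``n_folds`` otherwise).
    """
    config = config or ClassifierConfig()
    config.validate()
    features = _select_features(feature_subset)
    x = table[features].to_numpy(float)
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    y = (table["label"] == config.positive_class).to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present for classification")
    counts = np.bincount(y.astype(int))
    if counts.min() < config.n_folds:
        raise ValueError(
            f"need >= n_folds={config.n_folds} samples per class; "
            f"got {counts.min()} — use fewer folds")

    if config.group_by_subject:
        splitter = StratifiedGroupKFold(n_splits=config.n_folds, shuffle=True,
                                        random_state=config.seed)
        splits = splitter.split(x, y, groups=table["subject_id"])
    else:
        splitter = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                                   random_state=config.seed)
        splits = splitter.split(x, y)

    n = len(y)
    pred = np.zeros(n, bool)
    score = np.zeros(n, float)
    seen = np.zeros(n, bool)
    per_fold: list[FoldResult] = []
    rng = np.random.default_rng(config.seed)
    for fold_idx, (tr, va) in enumerate(splits):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(
                f"fold {fold_idx}: a class is absent from the training "
                "portion — use fewer folds")
        x_tr, x_va = x[tr], x[va]
        if config.standardize:
            mu = x_tr.mean(axis=0)
            sd = x_tr.std(axis=0)
            sd[sd == 0] = 1.0
            x_tr = (x_tr - mu) / sd
            x_va = (x_va - mu) / sd
        scale = resolve_kernel_scale(x_tr, config.kernel_scale, rng=rng)
        clf = SVC(C=config.box_constraint, kernel="rbf", gamma=1.0 / scale**2)
        clf.fit(x_tr, y[tr])
        p = clf.predict(x_va)
        s = clf.decision_function(x_va)
        pred[va], score[va], seen[va] = p, s, True
        ftp = int(np.sum(p & y[va]))
        ftn = int(np.sum(~p & ~y[va]))
        ffp = int(np.sum(p & ~y[va]))
        ffn = int(np.sum(~p & y[va]))
        per_fold.append(FoldResult(
            fold=fold_idx, n_val=len(va), tp=ftp, tn=ftn, fp=ffp, fn=ffn,
            accuracy=100.0 * (ftp + ftn) / len(va), kernel_scale=scale))
    assert seen.all(), "cross-validation must predict every sample once"

    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    metrics = confusion_metrics(tp, tn, fp, fn)
    auc, roc_points = roc_auc(score, y, positive_class=True)
    return ClassifierReport(
        feature_subset=(feature_subset if isinstance(feature_subset, str)
                        else "custom"),
        features=features, positive_class=config.positive_class,
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=metrics["accuracy"], sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"], auc=auc, per_fold=per_fold,
        n_samples=n, config={
            "box_constraint": config.box_constraint,
            "kernel_scale": config.kernel_scale,
            "standardize": config.standardize,
            "n_folds": config.n_folds,
            "group_by_subject": config.group_by_subject,
            "seed": config.seed,
        },
        roc_points=roc_points)


def _equal_frequency_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize a continuous feature into <= n_bins quantile bins."""
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, values, side="right")


def rank_features_mrmr(table: pd.DataFrame, features: list[str] | None = None,
                       label_column: str = "label", n_bins: int = 10
                       ) -> list[tuple[str, float]]:
    """Greedy MRMR feature ranking with the MI-difference criterion.

    Relevance is the mutual information I(feature; label); redundancy is the
    mean MI between a candidate and the already-selected features.
    Continuous features are discretized into equal-frequency bins before MI
    estimation. Constant features carry zero relevance and are appended last
    in column order; ties break deterministically on column order. Returns
    (feature, score-at-selection) in ranked order.
    """
    if features is None:
        features = [c for c in FEATURE_COLUMNS if c in table.columns]
    if len(features) < 1:
        raise ValueError("need at least one feature")
    labels = table[label_column].to_numpy()
    if len(np.unique(labels)) < 2 and len(features) > 1:
        raise ValueError("both classes must be present for MRMR")

    binned = {}
    constant = []
    varying = []
    for f in features:
        v = table[f].to_numpy(float)
        if np.all(v == v[0]):
            constant.append(f)
            continue
        binned[f] = _equal_frequency_bins(v, n_bins)
        varying.append(f)

    relevance = {f: mutual_info_score(labels, binned[f]) for f in varying}
    selected: list[tuple[str, float]] = []
    remaining = list(varying)
    pair_mi: dict[tuple[str, str], float] = {}

    while remaining:
        best_f, best_score = None, -np.inf
        for f in remaining:
            if selected:
                red = np.mean([
                    pair_mi.setdefault(
                        (f, s), mutual_info_score(binned[f], binned[s]))
                    for s, _ in selected])
            else:
                red = 0.0
            sc = relevance[f] - red
            if sc > best_score + 1e-15:
                best_f, best_score = f, sc
        selected.append((best_f, float(best_score)))
        remaining.remove(best_f)

    selected.extend((f, 0.0) for f in constant)
    return selected
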