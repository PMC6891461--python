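"""Feature- and waveform-validation statistics against a paired reference.

Per-cycle feature values measured by two systems are compared with RMSE and
MAE aggregated per subject, then averaged across subjects with SD and a
t-based 95% confidence interval; Pearson r and r^2 are pooled over all
cycles. Waveforms are compared with the range-of-motion error (ROME) and
the Kadaba within-condition coefficient of multiple correlation (CMC):

    CMC = sqrt(1 - [sum_pt (Y_pt - Ybar_t)^2 / (T (P - 1))]
                 / [sum_pt (Y_pt - Ybar)^2 / (P T - 1)])

for P waveforms of T points. When the variance ratio exceeds 1 the root is
imaginary and the CMC is reported as undefined with a reason code, never
clamped. Group differences are assessed with a two-sample t-test
(pooled-variance by default) plus a chi-square goodness-of-fit normality
check per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import SET1_COLUMNS, SET2_COLUMNS
from .segmentation import GaitCycle

__all__ = [
    "PairedErrorStats",
    "CMCResult",
    "GroupComparison",
    "paired_error_stats",
    "rome",
    "cmc",
    "compare_groups",
    "validate_feature_tables",
]


@dataclass
class PairedErrorStats:
    """Cohort-aggregated paired-error statistics for one feature."""

    rmse_mean: float
    rmse_sd: float
    rmse_ci: tuple[float, float] | None
    mae_mean: float
    mae_sd: float
    mae_ci: tuple[float, float] | None
    r: float
    r_squared: float
    n_subjects: int
    n_cycles: int
    per_subject: pd.DataFrame = field(repr=False, default=None)
    ci_method: str = "t"
    flags: tuple[str, ...] = ()

    def to_jsonable(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("rmse_mean", "rmse_sd", "mae_mean", "mae_sd", "r", "r_squared",
              "n_subjects", "n_cycles", "ci_method")}
        d["rmse_ci"] = list(self.rmse_ci) if self.rmse_ci else None
        d["mae_ci"] = list(self.mae_ci) if self.mae_ci else None
        d["flags"] = list(self.flags)
        return d


@dataclass
class CMCResult:
    value: float | None
    defined: bool
    reason: str | None = None


@dataclass
class GroupComparison:
    t_statistic: float
    p_value: float
    normal_a: bool | None
    normal_b: bool | None
    equal_var: bool

    def to_jsonable(self) -> dict:
        return {"t": self.t_statistic, "p": self.p_value,
                "normal_a": self.normal_a, "normal_b": self.normal_b,
                "equal_var": self.equal_var}


def _mean_ci(values: np.ndarray, level: float = 0.95
             ) -> tuple[float, float, tuple[float, float] | None]:
    mean = float(np.mean(values))
    n = len(values)
    if n < 2:
        return mean, float("nan"), None
    sd = float(np.std(values, ddof=1))
    half = stats.t.ppf(0.5 + level / 2, n - 1) * sd / math.sqrt(n)
    return mean, sd, (mean - half, mean + half)


def paired_error_stats(values_a, values_b, subject_ids,
                       ci_level: float = 0.95) -> PairedErrorStats:
    """RMSE/MAE per subject, aggregated across subjects; pooled r and r^2.

    ``values_a`` / ``values_b`` are paired per-cycle values (e.g. the same
    feature from two measurement systems); ``subject_ids`` assigns each pair
    to a subject. With fewer than two subjects the SD and CI are undefined
    and flagged.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    subjects = np.asarray(subject_ids)
    if not (len(a) == len(b) == len(subjects)):
        raise ValueError("paired values and subject ids must share length")
    if len(a) == 0:
        raise ValueError("no paired values")
    err = a - b
    df = pd.DataFrame({"subject": subjects, "err": err})
    grouped = df.groupby("subject", sort=True)["err"]
    per_subject = pd.DataFrame({
        "rmse": grouped.apply(lambda e: float(np.sqrt(np.mean(e ** 2)))),
        "mae": grouped.apply(lambda e: float(np.mean(np.abs(e)))),
        "n_cycles": grouped.size(),
    })
    flags: list[str] = []
    rmse_mean, rmse_sd, rmse_ci = _mean_ci(per_subject["rmse"].values, ci_level)
    mae_mean, mae_sd, mae_ci = _mean_ci(per_subject["mae"].values, ci_level)
    if len(per_subject) < 2:
        flags.append("single_subject_no_ci")
    if np.std(a) == 0 or np.std(b) == 0:
        r = float("nan")
        flags.append("zero_variance_r_undefined")
    else:
        r = float(stats.pearsonr(a, b).statistic)
    return PairedErrorStats(
        rmse_mean=rmse_mean, rmse_sd=rmse_sd, rmse_ci=rmse_ci,
        mae_mean=mae_mean, mae_sd=mae_sd, mae_ci=mae_ci,
        r=r, r_squared=r * r if np.isfinite(r) else float("nan"),
        n_subjects=len(per_subject), n_cycles=len(a),
        per_subject=per_subject, flags=tuple(flags))


def rome(cycle_a, cycle_b) -> float:
    """Range-of-motion error between two paired cycles (deg): |ROM_a - ROM_b|."""
    a = cycle_a.values if isinstance(cycle_a, GaitCycle) else np.asarray(cycle_a, float)
    b = cycle_b.values if isinstance(cycle_b, GaitCycle) else np.asarray(cycle_b, float)
    if a.shape != b.shape:
        raise ValueError("paired cycles must share length")
    return float(abs((a.max() - a.min()) - (b.max() - b.min())))


def cmc(waveforms) -> CMCResult:
    """Kadaba within-condition coefficient of multiple correlation.

    ``waveforms`` is a (P, T) array of P equal-length waveforms (typically a
    measurement/reference cycle pair). Returns an undefined-flagged result
    when the between-waveform variance exceeds the total variance (imaginary
    root) or when the total variance is zero.
    """
    y = np.atleast_2d(np.asarray(waveforms, float))
    p, t = y.shape
    if p < 2:
        raise ValueError("need at least two waveforms")
    ybar_t = y.mean(axis=0)
    ybar = y.mean()
    num = np.sum((y - ybar_t) ** 2) / (t * (p - 1))
    den = np.sum((y - ybar) ** 2) / (p * t - 1)
    if den == 0:
        return CMCResult(None, False, "zero_total_variance")
    ratio = num / den
    if ratio > 1.0:
        return CMCResult(None, False, "negative_variance_ratio")
    return CMCResult(float(np.sqrt(1.0 - ratio)), True)


def _chi2_normality(values: np.ndarray, alpha: float = 0.05) -> bool | None:
    """Chi-square goodness-of-fit of a sample against a fitted normal.

    Sturges binning on the sample range, tail bins merged until every
    expected count is >= 5; degrees of freedom = bins - 1 - 2 (mean and SD
    estimated). Returns None when too few usable bins remain.
    """
    v = np.asarray(values, float)
    n = len(v)
    if n < 8 or np.std(v, ddof=1) == 0:
        return None
    mu, sd = v.mean(), v.std(ddof=1)
    k = int(np.ceil(np.log2(n))) + 1
    edges = np.linspace(v.min(), v.max(), k + 1)
    observed, _ = np.histogram(v, bins=edges)
    # open-ended tails for the expected counts
    cdf = stats.norm.cdf(edges, mu, sd)
    cdf[0], cdf[-1] = 0.0, 1.0
    expected = n * np.diff(cdf)

    obs, exp = list(observed), list(expected)
    # merge small-expectation bins inward from both ends
    i = 0
    while i < len(exp) - 1:
        if exp[i] < 5:
            exp[i + 1] += exp[i]
            obs[i + 1] += obs[i]
            del exp[i], obs[i]
        else:
            i += 1
    while len(exp) > 1 and exp[-1] < 5:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        del exp[-1], obs[-1]
    if len(exp) < 4:  # dof = k - 3 must be >= 1
        return None
    chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
    dof = len(exp) - 3
    p = float(stats.chi2.sf(chi2, dof))
    return p >= alpha


def compare_groups(values_a, values_b, equal_var: bool = True,
                   alpha: float = 0.05) -> GroupComparison:
    """Two-sample independent t-test plus per-group normality flags."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        t_stat, p = 0.0, 1.0
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        t_statistic=t_stat, p_value=p,
        normal_a=_chi2_normality(a, alpha), normal_b=_chi2_normality(b, alpha),
        equal_var=equal_var)


def validate_feature_tables(table_measured: pd.DataFrame,
                            table_reference: pd.DataFrame,
                            features: list[str] | None = None) -> dict:
    """Full feature-validation report between two paired feature tables.

    The tables must describe the same retained cycles (same subject/cycle
    keys, e.g. truth-channel vs reference-channel extractions of one
    cohort). Per feature: paired error statistics over all cycles, plus a
    between-group comparison of the per-subject RMSEs.
    """
    if features is None:
        features = SET1_COLUMNS + SET2_COLUMNS
    key = ["subject_id", "cycle_index"]
    merged = table_measured.merge(table_reference, on=key,
                                  suffixes=("_m", "_r"))
    if len(merged) != len(table_measured) or len(merged) != len(table_reference):
        raise ValueError("feature tables do not describe the same cycles")
    report: dict = {"features": {}, "ci_method": "t"}
    labels = merged["label_m"]
    for feat in features:
        pes = paired_error_stats(merged[f"{feat}_m"], merged[f"{feat}_r"],
                                 merged["subject_id"])
        entry = pes.to_jsonable()
        # group difference in per-subject RMSE (healthy vs patient)
        subj_label = merged.groupby("subject_id", sort=True)["label_m"].first()
        rmse = pes.per_subject["rmse"]
        a = rmse[subj_label == "patient"].values
        b = rmse[subj_label == "healthy"].values
        if len(a) >= 2 and len(b) >= 2:
            entry["group_test"] = compare_groups(a, b).to_jsonable()
        else:
            entry["group_test"] = None
        report["features"][feat] = entry
    report["n_cycles"] = int(len(merged))
    report["labels"] = {lab: int((labels == lab).sum())
                        for lab in sorted(labels.unique())}
    return report
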