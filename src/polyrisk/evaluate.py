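"""Discrimination analysis for risk scores on the testing set.

Association of a score with case status is tested nonparametrically
(Wilcoxon rank-sum with midranks); discrimination is the Mann-Whitney AUC
(ties count one half, so the AUC equals the probability that a random case
outscores a random control); and paired AUCs over the same subjects are
compared with the DeLong placement-value covariance estimator.  Heavy ties
are the norm for a score built from a handful of SNPs — a three-SNP score
takes at most 27 distinct values — which is why every statistic here uses
midrank/half-tie conventions rather than assuming continuous scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CASE, CohortDataset
from .grs import GRSProfile

_EXACT_N_MAX = 20


def wilcoxon_rank_sum(
    scores_cases: np.ndarray, scores_controls: np.ndarray
) -> tuple[float, float]:
    """Rank-sum test of stochastic ordering between the two groups.

    Returns (case rank-sum statistic, two-sided p).  When the combined
    sample size is at most 20 and there are no ties the p-value is exact
    by enumeration; otherwise a normal approximation with midranks, tie
    correction, and a continuity correction toward the null is used, so
    identical samples give p = 1 exactly.
    """
    x = np.asarray(scores_cases, dtype=float)
    y = np.asarray(scores_controls, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = float(ranks[:n1].sum())

    has_ties = np.unique(combined).size < combined.size
    if n1 + n2 <= _EXACT_N_MAX and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return w, float(res.pvalue)

    mu = n1 * (n2 + n1 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:  # all observations tied
        return w, 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)  # continuity correction never crosses the null
    return w, float(min(2 * stats.norm.sf(z), 1.0))


def auc_mann_whitney(
    scores_cases: np.ndarray, scores_controls: np.ndarray
) -> float:
    """AUC as the normalized Mann-Whitney U: P(case > control) + P(tie)/2."""
    x = np.asarray(scores_cases, dtype=float)
    y = np.asarray(scores_controls, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    u = r1 - x.size * (x.size + 1) / 2.0
    return float(u / (x.size * y.size))


def _placements(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """(AUC, case placements V10, control placements V01) for one marker."""
    # V10_i = fraction of controls below case i (ties half)
    cmp = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return float(cmp.mean()), v10, v01


@dataclass(frozen=True)
class ROCComparison:
    """Paired AUC comparison by the DeLong covariance estimator."""

    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p_two_sided: float
    degenerate: bool = False


def delong_compare(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
) -> ROCComparison:
    """Compare the AUCs of two markers measured on the same subjects.

    ``labels`` is boolean/0-1 with 1 marking cases.  Variances and the
    covariance come from the empirical covariance of placement values
    (structural components) across cases and across controls.  If the
    variance of the AUC difference is zero the comparison is degenerate:
    equal AUCs give p = 1, unequal AUCs are returned flagged.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    lab = np.asarray(labels).astype(bool)
    if a.shape != b.shape or a.shape != lab.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned")
    if lab.all() or not lab.any():
        raise ValueError("both groups must be non-empty")

    m = int(lab.sum())
    n = int((~lab).sum())
    auc_a, v10_a, v01_a = _placements(a[lab], a[~lab])
    auc_b, v10_b, v01_b = _placements(b[lab], b[~lab])

    def _cov(u, v):
        if u.size < 2:
            return 0.0
        return float(np.cov(u, v, ddof=1)[0, 1])

    s10 = np.array(
        [[_cov(v10_a, v10_a), _cov(v10_a, v10_b)], [_cov(v10_b, v10_a), _cov(v10_b, v10_b)]]
    )
    s01 = np.array(
        [[_cov(v01_a, v01_a), _cov(v01_a, v01_b)], [_cov(v01_b, v01_a), _cov(v01_b, v01_b)]]
    )
    s = s10 / m + s01 / n
    var_a, var_b, cov_ab = s[0, 0], s[1, 1], s[0, 1]
    var_diff = var_a + var_b - 2 * cov_ab

    if var_diff <= 0:
        if np.isclose(auc_a, auc_b):
            return ROCComparison(auc_a, auc_b, var_a, var_b, cov_ab, 0.0, 1.0)
        return ROCComparison(
            auc_a, auc_b, var_a, var_b, cov_ab, np.nan, np.nan, degenerate=True
        )
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(min(2 * stats.norm.sf(abs(z)), 1.0))
    return ROCComparison(auc_a, auc_b, var_a, var_b, cov_ab, float(z), p)


def roc_coordinates(
    scores_cases: np.ndarray, scores_controls: np.ndarray
) -> pd.DataFrame:
    """Empirical ROC curve (FPR, TPR) at every distinct threshold."""
    x = np.asarray(scores_cases, dtype=float)
    y = np.asarray(scores_controls, dtype=float)
    thresholds = np.unique(np.concatenate([x, y]))[::-1]
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for t in thresholds:
        rows.append(
            {
                "threshold": t,
                "fpr": float((y >= t).mean()),
                "tpr": float((x >= t).mean()),
            }
        )
    return pd.DataFrame(rows)


def combined_model_scores(
    ds: CohortDataset, grs: list[GRSProfile]
) -> tuple[np.ndarray, np.ndarray]:
    """Linear predictor of a logistic fit of status on log-GRS + e4 carriage.

    Returns (scores, labels) aligned to subjects having both a score and an
    APOE genotype.  The fit runs on the evaluation cohort itself, the
    standard way ROC overlays combine a score with an established marker.
    Fit failures propagate as ValueError.
    """
    by_id = {p.subject_id: p.grs for p in grs}
    scores, e4, labels = [], [], []
    for s in ds.subjects:
        if s.subject_id in by_id and s.e4_carrier is not None:
            scores.append(np.log(by_id[s.subject_id]))
            e4.append(float(s.e4_carrier))
            labels.append(1.0 if s.status == CASE else 0.0)
    if not scores:
        raise ValueError("no subjects with both a GRS and APOE genotype")
    X = sm.add_constant(np.column_stack([scores, e4]), prepend=True, has_constant="add")
    y = np.array(labels)
    fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    if not fit.mle_retvals.get("converged", False):
        raise ValueError("combined-model logistic fit did not converge")
    return np.asarray(X @ fit.params), y


def evaluate_scores(
    scores_cases: np.ndarray, scores_controls: np.ndarray
) -> dict[str, float]:
    """Summary block used by the stratified report: means, medians, p, AUC."""
    x = np.asarray(scores_cases, dtype=float)
    y = np.asarray(scores_controls, dtype=float)
    _, p = wilcoxon_rank_sum(x, y)
    return {
        "n_cases": x.size,
        "n_controls": y.size,
        "mean_cases": float(x.mean()),
        "mean_controls": float(y.mean()),
        "median_cases": float(np.median(x)),
        "median_controls": float(np.median(y)),
        "wilcoxon_p": p,
        "auc": auc_mann_whitney(x, y),
    }


def stratified_evaluation(
    ds: CohortDataset, grs: list[GRSProfile], label: str = "GRS"
) -> pd.DataFrame:
    """Pooled and APOE-e4-stratified score/outcome association table.

    One row for the whole evaluation set, one per e4 stratum (carriers and
    non-carriers; subjects without APOE genotype appear only in the pooled
    row).  A stratum lacking cases or controls is kept as a flagged row
    rather than dropped; a stratum where either arm has fewer than two
    subjects is flagged low-n (its rank test is unreliable) but still
    reported.
    """
    by_id = {p.subject_id: p.grs for p in grs}

    def _arms(subjects):
        x = [by_id[s.subject_id] for s in subjects if s.status == CASE and s.subject_id in by_id]
        y = [by_id[s.subject_id] for s in subjects if s.status != CASE and s.subject_id in by_id]
        return np.array(x), np.array(y)

    strata = [
        ("pooled", ds.subjects),
        ("e4_carriers", [s for s in ds.subjects if s.e4_carrier is True]),
        ("e4_non_carriers", [s for s in ds.subjects if s.e4_carrier is False]),
    ]
    rows = []
    for name, subjects in strata:
        x, y = _arms(subjects)
        row = {"score": label, "stratum": name, "flag": ""}
        if x.size == 0 or y.size == 0:
            row.update(
                n_cases=x.size, n_controls=y.size, flag="empty_arm",
                mean_cases=np.nan, mean_controls=np.nan,
                median_cases=np.nan, median_controls=np.nan,
                wilcoxon_p=np.nan, auc=np.nan,
            )
        else:
            row.update(evaluate_scores(x, y))
            if min(x.size, y.size) < 2:
                row["flag"] = "low_n"
        rows.append(row)
    return pd.DataFrame(rows)
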