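"""Per-SNP additive-model logistic regression with covariate adjustment.

Each SNP is tested by regressing case/control status on risk-allele dosage
(0/1/2) plus covariates, by maximum likelihood.  Two covariate models are
supported: sex + age, and sex + age + APOE e4 carrier status (0/1).  The
dosage coefficient gives the allelic odds ratio; confidence intervals and
p-values are Wald-based, matching the OR (95% CI) presentation convention
of replication studies.  Subjects with a missing dosage or covariate are
excluded listwise per SNP.  No multiple-testing correction is applied —
candidate-SNP replication uses a per-SNP alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CASE, CohortDataset

MODEL_SEX_AGE = "sex_age"
MODEL_SEX_AGE_APOE = "sex_age_apoe"
_MODEL_COVARIATES = {
    MODEL_SEX_AGE: ("sex", "age"),
    MODEL_SEX_AGE_APOE: ("sex", "age", "apoe_e4"),
}
# coefficients beyond this magnitude indicate (quasi-)complete separation
_SEPARATION_BETA = 15.0
_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    model: str
    allelic_or: float
    ci95: tuple[float, float]
    p_wald: float
    n_used: int
    allele_freq_cases: float
    allele_freq_controls: float
    flag: str | None = None  # e.g. "separation", "non_convergence", "monomorphic"

    @property
    def ok(self) -> bool:
        return self.flag is None


def _design(
    ds: CohortDataset, snp_idx: int, covariates: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Listwise-complete (X, y, dosage) arrays for one SNP."""
    dos = ds.dosages[:, snp_idx]
    y = ds.status_mask(CASE).astype(float)
    cols = [dos]
    for cov in covariates:
        if cov == "sex":
            cols.append(np.array([1.0 if s.sex == "female" else 0.0 for s in ds.subjects]))
        elif cov == "age":
            cols.append(np.array([s.age_years for s in ds.subjects]))
        elif cov == "apoe_e4":
            cols.append(
                np.array(
                    [
                        np.nan if s.e4_carrier is None else float(s.e4_carrier)
                        for s in ds.subjects
                    ]
                )
            )
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    X = np.column_stack(cols)
    ok = ~np.isnan(X).any(axis=1)
    X = X[ok]
    # a covariate constant across the analyzed subjects is collinear with
    # the intercept and carries no information: drop it
    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.unique(X[:, j]).size > 1
    ]
    X = sm.add_constant(X[:, keep], prepend=True, has_constant="add")
    return X, y[ok], dos[ok]


def _allele_freq(dos: np.ndarray) -> float:
    called = dos[~np.isnan(dos)]
    return float(called.sum() / (2 * called.size)) if called.size else np.nan


def fit_additive_logistic(
    ds: CohortDataset,
    snp_id: str,
    covariates: tuple[str, ...] | str = MODEL_SEX_AGE,
) -> AssociationResult:
    """Fit status ~ dosage + covariates; return the allelic OR with Wald CI.

    ``covariates`` may be a model name (``"sex_age"`` / ``"sex_age_apoe"``)
    or an explicit tuple drawn from {"sex", "age", "apoe_e4"}.  Separation
    and non-convergence are returned as flagged results rather than raised;
    a monomorphic SNP (no dosage variation among usable subjects) is an
    error.
    """
    if isinstance(covariates, str):
        model_name = covariates
        covariates = _MODEL_COVARIATES[covariates]
    else:
        covariates = tuple(covariates)
        model_name = next(
            (k for k, v in _MODEL_COVARIATES.items() if v == covariates), "custom"
        )
    j = ds.variant_index(snp_id)
    X, y, dos_used = _design(ds, j, covariates)
    n_used = int(y.size)

    case_mask = ds.status_mask(CASE)
    freq_cases = _allele_freq(ds.dosages[case_mask, j])
    freq_controls = _allele_freq(ds.dosages[~case_mask, j])

    if np.unique(dos_used).size < 2:
        raise ValueError(f"SNP {snp_id} is monomorphic among usable subjects")

    flag = None
    beta = se = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
        beta = fit.params[1]
        se = fit.bse[1]
        if not fit.mle_retvals.get("converged", False):
            flag = "non_convergence"
        elif np.abs(fit.params).max() > _SEPARATION_BETA:
            flag = "separation"
        elif not np.isfinite(se):
            flag = "separation"
    except Exception:
        flag = "non_convergence"

    if flag is None:
        or_hat = float(np.exp(beta))
        ci = (float(np.exp(beta - _Z975 * se)), float(np.exp(beta + _Z975 * se)))
        z = beta / se
        p = float(2 * stats.norm.sf(abs(z)))
        p = min(max(p, np.finfo(float).tiny), 1.0)
    else:
        or_hat, ci, p = np.nan, (np.nan, np.nan), np.nan

    return AssociationResult(
        snp_id=snp_id,
        model=model_name,
        allelic_or=or_hat,
        ci95=ci,
        p_wald=p,
        n_used=n_used,
        allele_freq_cases=freq_cases,
        allele_freq_controls=freq_controls,
        flag=flag,
    )


def association_table(
    ds: CohortDataset,
    models: tuple[str, ...] = (MODEL_SEX_AGE, MODEL_SEX_AGE_APOE),
) -> list[AssociationResult]:
    """One result per retained SNP per covariate model, in genomic order.

    Flagged fits (separation, non-convergence) are kept in the table with
    their reason rather than dropped.
    """
    order = sorted(
        range(ds.n_variants),
        key=lambda j: (_chrom_key(ds.variants[j].chromosome), ds.variants[j].position),
    )
    results = []
    for j in order:
        for model in models:
            results.append(fit_additive_logistic(ds, ds.variants[j].snp_id, model))
    return results


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def select_significant(
    results: list[AssociationResult], alpha: float = 0.05, model: str = MODEL_SEX_AGE
) -> list[str]:
    """SNPs with Wald p < alpha under the named model, in genomic order."""
    if not results:
        raise ValueError("no association results supplied")
    return [
        r.snp_id
        for r in results
        if r.model == model and r.ok and r.p_wald < alpha
    ]


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "model": r.model,
                "allelic_or": r.allelic_or,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "p_wald": r.p_wald,
                "n_used": r.n_used,
                "allele_freq_cases": r.allele_freq_cases,
                "allele_freq_controls": r.allele_freq_controls,
                "flag": r.flag or "",
            }
            for r in results
        ]
    )
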