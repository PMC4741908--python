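"""Subject- and SNP-level genotype quality control.

Filters mirror the conventions of candidate-SNP replication studies:
subjects with a genotype missing rate above 20% are dropped first, then
SNPs are dropped for (in order of precedence) complete genotyping failure,
missing rate above 5%, minor allele frequency below 0.01 in either arm, or
departure from Hardy-Weinberg equilibrium among controls at p < 0.001 by
the exact conditional test.  All thresholds are strict inequalities in the
removal direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CASE, CONTROL, CohortDataset


@dataclass(frozen=True)
class QCThresholds:
    subject_missing_max: float = 0.20
    snp_missing_max: float = 0.05
    maf_min: float = 0.01
    hwe_p_min: float = 0.001

    def __post_init__(self) -> None:
        for name in ("subject_missing_max", "snp_missing_max", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")


@dataclass
class QCReport:
    """What was removed and why, plus the per-SNP statistics behind it."""

    removed_subjects: list[tuple[str, str]] = field(default_factory=list)
    removed_snps: list[tuple[str, str]] = field(default_factory=list)
    snp_stats: pd.DataFrame | None = None

    def write_tsv(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["removed_subjects"] = out_dir / "qc_removed_subjects.tsv"
        pd.DataFrame(self.removed_subjects, columns=["subject_id", "reason"]).to_csv(
            paths["removed_subjects"], sep="\t", index=False
        )
        paths["removed_snps"] = out_dir / "qc_removed_snps.tsv"
        pd.DataFrame(self.removed_snps, columns=["snp_id", "reason"]).to_csv(
            paths["removed_snps"], sep="\t", index=False
        )
        if self.snp_stats is not None:
            paths["snp_stats"] = out_dir / "qc_snp_stats.tsv"
            self.snp_stats.to_csv(paths["snp_stats"], sep="\t", index=False)
        return paths


def subject_missing_rate(ds: CohortDataset, subject_id: str) -> float:
    """Fraction of this subject's variant calls that are missing."""
    if ds.n_variants == 0:
        raise ValueError("cohort has no variants")
    i = ds.subject_index(subject_id)
    return float(np.isnan(ds.dosages[i]).mean())


def filter_subjects(
    ds: CohortDataset, th: QCThresholds = QCThresholds()
) -> tuple[CohortDataset, QCReport]:
    """Drop subjects whose missing rate strictly exceeds the threshold."""
    rates = np.isnan(ds.dosages).mean(axis=1) if ds.n_variants else np.zeros(ds.n_subjects)
    keep = rates <= th.subject_missing_max
    report = QCReport(
        removed_subjects=[
            (ds.subjects[i].subject_id, "missing_rate")
            for i in np.flatnonzero(~keep)
        ]
    )
    return ds.subset(subject_idx=np.flatnonzero(keep)), report


def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Given genotype counts (``n1`` heterozygotes), conditions on the allele
    counts and sums the probabilities of all heterozygote counts no more
    probable than the observed one.  Probabilities follow the exact
    sampling distribution of heterozygote counts given allele counts
    (Levene/Haldane); the enumeration uses the standard stable recurrence.
    Returns p in (0, 1]; p = 1 when the observed count is modal or the
    configuration is the only one possible (e.g. monomorphic SNPs).
    """
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("all genotype counts are zero")
    # rare (minor) allele count; the distribution is symmetric in the labels
    n_rare = 2 * n2 + n1
    if n_rare > n:  # ensure n_rare is the minor allele count
        n_rare = 2 * n - n_rare

    if n_rare == 0:
        return 1.0

    # possible heterozygote counts share the parity of the rare allele count
    het_min = n_rare % 2
    het_max = n_rare if n_rare <= n else 2 * n - n_rare  # == n_rare here
    hets = np.arange(het_min, het_max + 1, 2)

    # unnormalized probabilities via the ratio
    # P(h+2)/P(h) = (n_rare-h)(2n-n_rare-h) / ((h+2)(h+1)) with hom counts
    # rare_hom = (n_rare-h)/2, common_hom = n - h - rare_hom
    probs = np.empty(hets.size)
    probs[0] = 1.0
    for k in range(hets.size - 1):
        h = hets[k]
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        probs[k + 1] = probs[k] * 4.0 * rare_hom * common_hom / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()

    observed = n1
    p_obs = probs[(hets == observed)][0]
    # tiny relative slack so float ties count as "no more probable"
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _arm_stats(dos: np.ndarray) -> tuple[int, int, int]:
    """Genotype counts (n0, n1, n2) from a dosage vector, ignoring missing."""
    called = dos[~np.isnan(dos)]
    n0 = int((called == 0).sum())
    n1 = int((called == 1).sum())
    n2 = int((called == 2).sum())
    return n0, n1, n2


def _maf(n0: int, n1: int, n2: int) -> float:
    n = n0 + n1 + n2
    if n == 0:
        return np.nan
    p = (2 * n2 + n1) / (2 * n)
    return min(p, 1 - p)


def filter_snps(
    ds: CohortDataset, th: QCThresholds = QCThresholds()
) -> tuple[CohortDataset, QCReport]:
    """Drop SNPs failing call-rate, per-arm MAF or control HWE criteria.

    A SNP failing several criteria is reported once, with the first
    triggering reason in the precedence order genotyping_failure >
    missing_rate > maf > hwe; the retained set does not depend on the
    order.
    """
    case_mask = ds.status_mask(CASE)
    ctrl_mask = ds.status_mask(CONTROL)
    if not case_mask.any() or not ctrl_mask.any():
        raise ValueError("both case and control arms are required for SNP QC")

    removed: list[tuple[str, str]] = []
    stats_rows = []
    keep = []
    for j, v in enumerate(ds.variants):
        dos = ds.dosages[:, j]
        n_called = int((~np.isnan(dos)).sum())
        call_rate = n_called / ds.n_subjects
        miss_rate = 1.0 - call_rate

        c0, c1, c2 = _arm_stats(dos[case_mask])
        t0, t1, t2 = _arm_stats(dos[ctrl_mask])
        maf_cases = _maf(c0, c1, c2)
        maf_controls = _maf(t0, t1, t2)
        hwe_p = hwe_exact_test(t0, t1, t2) if (t0 + t1 + t2) > 0 else np.nan

        reason = None
        if n_called == 0:
            reason = "genotyping_failure"
        elif miss_rate > th.snp_missing_max:
            reason = "missing_rate"
        elif (np.isnan(maf_cases) or maf_cases < th.maf_min) or (
            np.isnan(maf_controls) or maf_controls < th.maf_min
        ):
            reason = "maf"
        elif not np.isnan(hwe_p) and hwe_p < th.hwe_p_min:
            reason = "hwe"

        stats_rows.append(
            {
                "snp_id": v.snp_id,
                "call_rate": call_rate,
                "maf_cases": maf_cases,
                "maf_controls": maf_controls,
                "hwe_p_controls": hwe_p,
                "removed_reason": reason or "",
            }
        )
        if reason is None:
            keep.append(j)
        else:
            removed.append((v.snp_id, reason))

    report = QCReport(removed_snps=removed, snp_stats=pd.DataFrame(stats_rows))
    return ds.subset(variant_idx=keep), report


def run_qc(
    ds: CohortDataset, th: QCThresholds = QCThresholds()
) -> tuple[CohortDataset, QCReport]:
    """Subject filter followed by SNP filter; merged report."""
    ds1, rep_subj = filter_subjects(ds, th)
    ds2, rep_snp = filter_snps(ds1, th)
    return ds2, QCReport(
        removed_subjects=rep_subj.removed_subjects,
        removed_snps=rep_snp.removed_snps,
        snp_stats=rep_snp.snp_stats,
    )
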