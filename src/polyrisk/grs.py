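"""Multiplicative genetic risk score normalized to the population average.

The score follows the Pharoah construction: (1) take each SNP's allelic
odds ratio estimated in the discovery set; (2) expand it to genotypic odds
ratios (1, OR, OR^2) under a multiplicative model; (3) divide by the mean
genotypic OR under the reference genotype frequencies, so each genotype
carries a risk *relative to the population average* and the per-SNP
expectation is exactly 1; (4) multiply the relative risks across SNPs.
A score of 1.0 therefore means average population risk, independent of how
many SNPs enter the score.

The modified score drops SNPs whose signal is not independent of APOE:
those losing significance once APOE e4 carriage is adjusted for, and those
in strong LD with the recoded APOE locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import MODEL_SEX_AGE, MODEL_SEX_AGE_APOE, AssociationResult
from .cohort import CohortDataset, FrequencyTable


@dataclass(frozen=True)
class SnpRisk:
    snp_id: str
    allelic_or: float
    genotypic_or: tuple[float, float, float]
    genotype_freqs: tuple[float, float, float]
    relative_risks: tuple[float, float, float]


@dataclass
class RiskTable:
    """Per-SNP normalized genotype relative risks."""

    rows: dict[str, SnpRisk]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "snp_id": r.snp_id,
                    "allelic_or": r.allelic_or,
                    "or0": r.genotypic_or[0],
                    "or1": r.genotypic_or[1],
                    "or2": r.genotypic_or[2],
                    "f0": r.genotype_freqs[0],
                    "f1": r.genotype_freqs[1],
                    "f2": r.genotype_freqs[2],
                    "r0": r.relative_risks[0],
                    "r1": r.relative_risks[1],
                    "r2": r.relative_risks[2],
                }
                for r in self.rows.values()
            ]
        )


@dataclass(frozen=True)
class GRSProfile:
    subject_id: str
    grs: float
    snps_used: tuple[str, ...]
    n_missing_imputed: int


def genotypic_or_from_allelic(allelic_or: float) -> tuple[float, float, float]:
    """(1, OR, OR^2): per-genotype odds ratios under the multiplicative model."""
    if not allelic_or > 0:
        raise ValueError(f"allelic OR must be positive, got {allelic_or}")
    return (1.0, float(allelic_or), float(allelic_or) ** 2)


def relative_risks(
    genotypic_or: tuple[float, float, float],
    genotype_freqs: tuple[float, float, float],
) -> tuple[float, float, float]:
    """Normalize genotypic ORs so the population-mean risk is exactly 1.

    With mean risk mu = sum_g f_g * or_g, each genotype's relative risk is
    or_g / mu, hence sum_g f_g * r_g = 1 identically.
    """
    f = np.asarray(genotype_freqs, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"genotype frequencies sum to {f.sum()}, not 1")
    ors = np.asarray(genotypic_or, dtype=float)
    mu = float(f @ ors)
    return tuple(float(x) for x in ors / mu)


def build_risk_table(
    assoc: list[AssociationResult],
    freqs: FrequencyTable,
    snp_ids: list[str],
    model: str = MODEL_SEX_AGE,
) -> RiskTable:
    """Risk table for the given SNPs from their discovery-set allelic ORs.

    ORs are taken from the sex+age-adjusted model by default (the score is
    built before any APOE consideration).  Every SNP must have both a
    usable association result and a reference frequency entry.
    """
    if not snp_ids:
        raise ValueError("cannot build a risk score from an empty SNP set")
    by_snp = {r.snp_id: r for r in assoc if r.model == model and r.ok}
    rows: dict[str, SnpRisk] = {}
    for snp in snp_ids:
        if snp not in by_snp:
            raise KeyError(f"no usable discovery association result for {snp!r}")
        if snp not in freqs.entries:
            raise KeyError(f"no reference frequency entry for {snp!r}")
        g_or = genotypic_or_from_allelic(by_snp[snp].allelic_or)
        g_f = freqs.genotype_freqs(snp)
        rows[snp] = SnpRisk(
            snp_id=snp,
            allelic_or=by_snp[snp].allelic_or,
            genotypic_or=g_or,
            genotype_freqs=g_f,
            relative_risks=relative_risks(g_or, g_f),
        )
    return RiskTable(rows)


def compute_grs(ds: CohortDataset, table: RiskTable) -> list[GRSProfile]:
    """Per-subject product of genotype relative risks over the table's SNPs.

    A missing genotype contributes a factor of 1.0 — the population-average
    risk — so subjects are never dropped and the expectation of the score
    stays at 1 under the reference distribution.
    """
    cols = {snp: ds.variant_index(snp) for snp in table.snp_ids}
    profiles = []
    snps_used = tuple(table.snp_ids)
    for i, subj in enumerate(ds.subjects):
        score = 1.0
        n_imputed = 0
        for snp, j in cols.items():
            d = ds.dosages[i, j]
            if np.isnan(d):
                n_imputed += 1
            else:
                score *= table.rows[snp].relative_risks[int(d)]
        profiles.append(
            GRSProfile(
                subject_id=subj.subject_id,
                grs=score,
                snps_used=snps_used,
                n_missing_imputed=n_imputed,
            )
        )
    return profiles


def grs_frame(profiles: list[GRSProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": p.subject_id,
                "grs": p.grs,
                "n_missing_imputed": p.n_missing_imputed,
            }
            for p in profiles
        ]
    )


def modified_grs_snps(
    assoc_both_models: list[AssociationResult],
    ld: pd.DataFrame,
    alpha: float = 0.05,
    r2_threshold: float = 0.2,
) -> list[str]:
    """APOE-independent subset of the discovery-significant SNPs.

    Starting from SNPs significant under the sex+age model, drop any that
    (a) are no longer significant once APOE e4 carriage is adjusted for, or
    (b) sit in strong LD (r2 >= threshold) with the recoded APOE locus.
    ``ld`` is the frame from :func:`polyrisk.ld.ld_screen`; SNPs absent
    from it are treated as unlinked.
    """
    base = [
        r.snp_id
        for r in assoc_both_models
        if r.model == MODEL_SEX_AGE and r.ok and r.p_wald < alpha
    ]
    apoe_adjusted = {
        r.snp_id: r
        for r in assoc_both_models
        if r.model == MODEL_SEX_AGE_APOE
    }
    r2_by_snp = dict(zip(ld["snp_id"], ld["r2"])) if len(ld) else {}
    kept = []
    for snp in base:
        adj = apoe_adjusted.get(snp)
        if adj is None or not adj.ok or adj.p_wald >= alpha:
            continue
        if r2_by_snp.get(snp, 0.0) >= r2_threshold:
            continue
        kept.append(snp)
    return kept
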