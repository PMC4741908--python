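"""Two-locus linkage disequilibrium from unphased genotypes.

Haplotype frequencies for a pair of biallelic loci are estimated from
genotype dosages by expectation-maximization (the classical Hill
gene-counting scheme): the only phase-ambiguous class is the double
heterozygote, whose two resolutions are apportioned by their current
haplotype-frequency products each iteration.  D, D' and r-squared are
derived from the converged frequencies.  The APOE locus participates after
biallelic recoding — e2 and e3 collapse to one allele, e4 is the other —
so LD between a SNP and APOE is a routine two-locus computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDataset, SubjectRecord


@dataclass(frozen=True)
class LDResult:
    """Converged haplotype frequencies and the LD statistics they imply.

    ``haplotype_freqs`` orders the four haplotypes as (AB, Ab, aB, ab)
    where A/B are the counted (risk) alleles at the two loci.  D' is
    reported as an absolute value; only r-squared feeds downstream
    decisions.
    """

    locus_a: str
    locus_b: str
    haplotype_freqs: tuple[float, float, float, float]
    D: float
    D_prime: float
    r2: float
    n_used: int
    n_iter: int
    log_likelihood: float

    @property
    def allele_freq_a(self) -> float:
        return self.haplotype_freqs[0] + self.haplotype_freqs[1]

    @property
    def allele_freq_b(self) -> float:
        return self.haplotype_freqs[0] + self.haplotype_freqs[2]


def apoe_as_biallelic(subjects: Sequence[SubjectRecord]) -> np.ndarray:
    """APOE genotypes as e4-allele dosage (0/1/2; NaN where ungenotyped)."""
    return np.array(
        [np.nan if s.e4_count is None else float(s.e4_count) for s in subjects]
    )


def _genotype_table(dos_a: np.ndarray, dos_b: np.ndarray) -> np.ndarray:
    """3x3 joint genotype count table over pairwise-complete subjects."""
    table = np.zeros((3, 3))
    for i in range(3):
        ai = dos_a == i
        for j in range(3):
            table[i, j] = np.sum(ai & (dos_b == j))
    return table


def _hap_log_likelihood(h: np.ndarray, table: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype table under
    random mating with haplotype frequencies h = (AB, Ab, aB, ab)."""
    pAB, pAb, paB, pab = h
    # genotype probability for (i copies of A, j copies of B)
    g = np.empty((3, 3))
    g[2, 2] = pAB**2
    g[2, 1] = 2 * pAB * pAb
    g[2, 0] = pAb**2
    g[1, 2] = 2 * pAB * paB
    g[1, 1] = 2 * (pAB * pab + pAb * paB)
    g[1, 0] = 2 * pAb * pab
    g[0, 2] = paB**2
    g[0, 1] = 2 * paB * pab
    g[0, 0] = pab**2
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(table > 0, table * np.log(np.maximum(g, 1e-300)), 0.0).sum()
    return float(ll)


def em_haplotype_freqs(
    dos_a: np.ndarray,
    dos_b: np.ndarray,
    locus_a: str = "A",
    locus_b: str = "B",
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LDResult:
    """Estimate haplotype frequencies and LD for two dosage vectors.

    Subjects missing either locus are dropped pairwise.  Initialization is
    at linkage equilibrium (product of observed allele frequencies);
    convergence is on the maximum absolute haplotype-frequency change.
    When the data contain no double heterozygotes the first M-step already
    equals the closed-form haplotype count and the loop exits immediately.
    """
    dos_a = np.asarray(dos_a, dtype=float)
    dos_b = np.asarray(dos_b, dtype=float)
    ok = ~(np.isnan(dos_a) | np.isnan(dos_b))
    a, b = dos_a[ok], dos_b[ok]
    n = int(a.size)
    if n < 2:
        raise ValueError("need at least 2 subjects with both loci called")
    pA = a.sum() / (2 * n)
    pB = b.sum() / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic locus: r2 undefined")

    table = _genotype_table(a, b)
    n_dh = table[1, 1]  # double heterozygotes: the ambiguous class

    # known haplotype contributions from the eight unambiguous cells
    # cell (i,j): i copies of A, j copies of B -> haplotypes are determined
    # except at (1,1)
    base = np.zeros(4)  # AB, Ab, aB, ab
    base[0] = 2 * table[2, 2] + table[2, 1] + table[1, 2]
    base[1] = 2 * table[2, 0] + table[2, 1] + table[1, 0]
    base[2] = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    base[3] = 2 * table[0, 0] + table[0, 1] + table[1, 0]

    h = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: split double heterozygotes between AB/ab and Ab/aB phases
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        denom = cis + trans
        w = 0.5 if denom == 0 else cis / denom
        counts = base.copy()
        counts[0] += n_dh * w
        counts[3] += n_dh * w
        counts[1] += n_dh * (1 - w)
        counts[2] += n_dh * (1 - w)
        new_h = counts / (2 * n)
        delta = np.abs(new_h - h).max()
        h = new_h
        if delta < tol:
            break

    pA_hat = h[0] + h[1]
    pB_hat = h[0] + h[2]
    D = h[0] - pA_hat * pB_hat
    if D >= 0:
        d_max = min(pA_hat * (1 - pB_hat), (1 - pA_hat) * pB_hat)
    else:
        d_max = min(pA_hat * pB_hat, (1 - pA_hat) * (1 - pB_hat))
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    denom = pA_hat * (1 - pA_hat) * pB_hat * (1 - pB_hat)
    r2 = D**2 / denom if denom > 0 else 0.0

    return LDResult(
        locus_a=locus_a,
        locus_b=locus_b,
        haplotype_freqs=tuple(float(x) for x in h),
        D=float(D),
        D_prime=float(min(d_prime, 1.0)),
        r2=float(min(r2, 1.0)),
        n_used=n,
        n_iter=n_iter,
        log_likelihood=_hap_log_likelihood(h, table),
    )


def ld_screen(
    ds: CohortDataset,
    target: np.ndarray,
    snp_ids: Sequence[str],
    r2_threshold: float = 0.2,
    target_name: str = "APOE",
) -> pd.DataFrame:
    """r-squared of each SNP against a target dosage vector.

    A SNP is flagged when r2 >= ``r2_threshold`` (inclusive, the usual
    tag-SNP convention).  Returns a frame with columns snp_id, r2, flagged,
    n_used, D_prime.
    """
    rows = []
    for snp in snp_ids:
        res = em_haplotype_freqs(
            ds.dosage_vector(snp), target, locus_a=snp, locus_b=target_name
        )
        rows.append(
            {
                "snp_id": snp,
                "r2": res.r2,
                "flagged": res.r2 >= r2_threshold,
                "n_used": res.n_used,
                "D_prime": res.D_prime,
            }
        )
    return pd.DataFrame(rows, columns=["snp_id", "r2", "flagged", "n_used", "D_prime"])
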