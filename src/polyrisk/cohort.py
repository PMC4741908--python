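"""Cohort containers and text I/O for case-control SNP genotype data.

The central object is :class:`CohortDataset`: a list of subjects, a list of
biallelic variants, and a subjects x variants dosage matrix counting copies
of each variant's *risk allele* (0/1/2, ``NaN`` for missing).  Orienting
dosages to the reported risk allele means an odds ratio above 1 from the
association stage replicates the source GWAS direction.

Two on-disk dialects are supported:

``tsv``
    Three tab-separated files — phenotypes (one row per subject), variants
    (one row per SNP) and a subjects x SNPs dosage table with ``NA`` for
    missing.  Native format of the simulator; convenient for inspection.
``plink_text``
    Whitespace-separated PLINK pedigree text (``.ped``/``.map``, ``0 0``
    missing genotype) for interoperability, written alongside the phenotype
    and variant TSVs (the ``.map`` file cannot carry gene labels or risk
    allele orientation, so the variant TSV remains the orientation source).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
_APOE_ALLELES = ("e2", "e3", "e4")
_AMBIGUOUS_PAIRS = {frozenset("AT"), frozenset("CG")}


@dataclass(frozen=True)
class SubjectRecord:
    """One study subject.

    ``age_years`` follows the recruitment convention of frequency-matched
    case-control dementia studies: age at onset for cases, age at
    examination for controls.  ``apoe_alleles`` is the unordered pair of
    apolipoprotein-E alleles (``e2``/``e3``/``e4``) when genotyped.
    """

    subject_id: str
    status: str
    sex: str
    age_years: float
    mmse: int | None = None
    apoe_alleles: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.status not in (CASE, CONTROL):
            raise ValueError(f"status must be 'case' or 'control', got {self.status!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not 18 < self.age_years < 120:
            raise ValueError(f"age_years {self.age_years} outside (18, 120)")
        if self.mmse is not None and not 0 <= self.mmse <= 30:
            raise ValueError(f"mmse {self.mmse} outside 0-30")
        if self.apoe_alleles is not None:
            pair = tuple(sorted(self.apoe_alleles))
            if len(pair) != 2 or any(a not in _APOE_ALLELES for a in pair):
                raise ValueError(f"invalid apoe_alleles {self.apoe_alleles!r}")
            object.__setattr__(self, "apoe_alleles", pair)

    @property
    def e4_carrier(self) -> bool | None:
        """True iff at least one APOE allele is e4; None when ungenotyped."""
        if self.apoe_alleles is None:
            return None
        return "e4" in self.apoe_alleles

    @property
    def e4_count(self) -> int | None:
        if self.apoe_alleles is None:
            return None
        return sum(a == "e4" for a in self.apoe_alleles)


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP with its reported risk allele orientation."""

    snp_id: str
    chromosome: str
    position: int
    gene_label: str
    risk_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"{self.snp_id}: position must be positive (1-based)")
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: risk and other allele identical")
        for a in (self.risk_allele, self.other_allele):
            if a not in "ACGT":
                raise ValueError(f"{self.snp_id}: allele {a!r} not a nucleotide")

    @property
    def strand_ambiguous(self) -> bool:
        """A/T and C/G SNPs cannot be strand-resolved from alleles alone."""
        return frozenset((self.risk_allele, self.other_allele)) in _AMBIGUOUS_PAIRS


@dataclass
class CohortDataset:
    """Subjects, variants and the risk-allele dosage matrix binding them.

    ``dosages`` is float64 with entries in {0, 1, 2} and ``NaN`` for
    missing calls; rows follow ``subjects``, columns follow ``variants``.
    """

    subjects: list[SubjectRecord]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.subjects), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id")
        snps = [v.snp_id for v in self.variants]
        if len(set(snps)) != len(snps):
            raise ValueError("duplicate snp_id")

    # -- basic accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    def variant_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown snp_id {snp_id!r}") from None

    def subject_index(self, subject_id: str) -> int:
        try:
            return self.subject_ids.index(subject_id)
        except ValueError:
            raise KeyError(f"unknown subject_id {subject_id!r}") from None

    def status_mask(self, status: str) -> np.ndarray:
        return np.array([s.status == status for s in self.subjects])

    def dosage_vector(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(snp_id)]

    def subset(
        self,
        subject_idx: Sequence[int] | np.ndarray | None = None,
        variant_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "CohortDataset":
        si = np.arange(self.n_subjects) if subject_idx is None else np.asarray(subject_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return CohortDataset(
            subjects=[self.subjects[i] for i in si],
            variants=[self.variants[j] for j in vi],
            dosages=self.dosages[np.ix_(si, vi)].copy(),
        )

    def subject_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "status": s.status,
                    "sex": s.sex,
                    "age_years": s.age_years,
                    "mmse": s.mmse,
                    "apoe": "/".join(s.apoe_alleles) if s.apoe_alleles else None,
                    "e4_carrier": s.e4_carrier,
                }
            )
        return pd.DataFrame(rows)

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "snp_id": v.snp_id,
                    "chromosome": v.chromosome,
                    "position": v.position,
                    "gene_label": v.gene_label,
                    "risk_allele": v.risk_allele,
                    "other_allele": v.other_allele,
                }
                for v in self.variants
            ]
        )


@dataclass
class FrequencyTable:
    """Per-SNP risk-allele and genotype frequencies in a reference population.

    Plays the role of an external reference panel (e.g. HapMap CHB) for the
    risk-score normalization.  ``entries`` maps snp_id to
    ``(p, f0, f1, f2)`` where ``p`` is the risk-allele frequency and ``f_g``
    the frequency of the g-copy genotype.
    """

    entries: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for snp, (p, f0, f1, f2) in self.entries.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{snp}: allele frequency {p} outside [0,1]")
            if abs(f0 + f1 + f2 - 1.0) > 1e-9:
                raise ValueError(f"{snp}: genotype frequencies sum to {f0 + f1 + f2}")

    @classmethod
    def from_hwe(cls, allele_freqs: dict[str, float]) -> "FrequencyTable":
        """Expand risk-allele frequencies to genotype frequencies under HWE."""
        return cls(
            {
                snp: (p, (1 - p) ** 2, 2 * p * (1 - p), p**2)
                for snp, p in allele_freqs.items()
            }
        )

    def genotype_freqs(self, snp_id: str) -> tuple[float, float, float]:
        p, f0, f1, f2 = self.entries[snp_id]
        return (f0, f1, f2)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        frame = pd.DataFrame(
            [(snp, *vals) for snp, vals in self.entries.items()],
            columns=["snp_id", "p", "f0", "f1", "f2"],
        )
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FrequencyTable":
        frame = pd.read_csv(path, sep="\t")
        return cls(
            {
                str(r.snp_id): (float(r.p), float(r.f0), float(r.f1), float(r.f2))
                for r in frame.itertuples()
            }
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _format_optional(value) -> str:
    return "NA" if value is None else str(value)


def _write_phenotypes(ds: CohortDataset, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("subject_id\tstatus\tsex\tage_years\tmmse\tapoe\n")
        for s in ds.subjects:
            apoe = "/".join(s.apoe_alleles) if s.apoe_alleles else "NA"
            fh.write(
                f"{s.subject_id}\t{s.status}\t{s.sex}\t{s.age_years!r}\t"
                f"{_format_optional(s.mmse)}\t{apoe}\n"
            )


def _read_phenotypes(path: Path) -> list[SubjectRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    subjects = []
    for r in frame.itertuples():
        apoe = None if r.apoe == "NA" else tuple(r.apoe.split("/"))
        mmse = None if r.mmse == "NA" else int(r.mmse)
        subjects.append(
            SubjectRecord(
                subject_id=r.subject_id,
                status=r.status,
                sex=r.sex,
                age_years=float(r.age_years),
                mmse=mmse,
                apoe_alleles=apoe,
            )
        )
    return subjects


_VARIANT_COLUMNS = [
    "snp_id", "chromosome", "position", "gene_label", "risk_allele", "other_allele"
]


def _write_variants(ds: CohortDataset, path: Path) -> None:
    frame = ds.variant_frame()
    if frame.empty:
        frame = pd.DataFrame(columns=_VARIANT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def _read_variants(path: Path) -> list[VariantRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return [
        VariantRecord(
            snp_id=r.snp_id,
            chromosome=r.chromosome,
            position=int(r.position),
            gene_label=r.gene_label,
            risk_allele=r.risk_allele,
            other_allele=r.other_allele,
        )
        for r in frame.itertuples()
    ]


def write_cohort(
    ds: CohortDataset, out_dir: str | Path, dialect: str = "tsv"
) -> dict[str, Path]:
    """Write a cohort to ``out_dir``; returns the paths written.

    The inverse of :func:`read_cohort`: reading the files back reproduces
    the dataset exactly for both dialects.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": out_dir / "phenotypes.tsv",
        "variants": out_dir / "variants.tsv",
    }
    _write_phenotypes(ds, paths["phenotypes"])
    _write_variants(ds, paths["variants"])

    if dialect == "tsv":
        paths["genotypes"] = out_dir / "genotypes.tsv"
        with paths["genotypes"].open("w") as fh:
            fh.write("subject_id\t" + "\t".join(ds.snp_ids) + "\n")
            for i, s in enumerate(ds.subjects):
                cells = [
                    "NA" if np.isnan(d) else str(int(d)) for d in ds.dosages[i]
                ]
                fh.write(s.subject_id + "\t" + "\t".join(cells) + "\n")
    elif dialect == "plink_text":
        paths["genotypes"] = out_dir / "cohort.ped"
        paths["map"] = out_dir / "cohort.map"
        with paths["map"].open("w") as fh:
            for v in ds.variants:
                fh.write(f"{v.chromosome}\t{v.snp_id}\t0\t{v.position}\n")
        with paths["genotypes"].open("w") as fh:
            for i, s in enumerate(ds.subjects):
                sex_code = "1" if s.sex == "male" else "2"
                pheno = "2" if s.status == CASE else "1"
                fields = [s.subject_id, s.subject_id, "0", "0", sex_code, pheno]
                for j, v in enumerate(ds.variants):
                    d = ds.dosages[i, j]
                    if np.isnan(d):
                        fields += ["0", "0"]
                    elif d == 2:
                        fields += [v.risk_allele, v.risk_allele]
                    elif d == 1:
                        fields += [v.risk_allele, v.other_allele]
                    else:
                        fields += [v.other_allele, v.other_allele]
                fh.write(" ".join(fields) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return paths


def read_cohort(
    phenotype_path: str | Path,
    variant_path: str | Path,
    genotype_path: str | Path,
    dialect: str = "tsv",
) -> CohortDataset:
    """Read a cohort, orienting all dosages as risk-allele counts.

    In ``plink_text`` the genotype file is a ``.ped``; alleles are resolved
    against the variant table's risk/other alleles, half-missing calls
    become missing (counted, logged), and an allele matching neither
    orientation allele is a hard error naming the SNP.
    """
    subjects = _read_phenotypes(Path(phenotype_path))
    variants = _read_variants(Path(variant_path))
    for v in variants:
        if v.strand_ambiguous:
            logger.warning(
                "SNP %s has strand-ambiguous alleles %s/%s; no strand flipping "
                "is attempted",
                v.snp_id,
                v.risk_allele,
                v.other_allele,
            )

    n, m = len(subjects), len(variants)
    dosages = np.full((n, m), np.nan)
    if dialect == "tsv":
        frame = pd.read_csv(
            Path(genotype_path), sep="\t", dtype=str, keep_default_na=False
        )
        frame = frame.set_index("subject_id")
        sid = [s.subject_id for s in subjects]
        frame = frame.loc[sid, [v.snp_id for v in variants]]
        values = frame.to_numpy()
        for i in range(n):
            for j in range(m):
                cell = values[i, j]
                if cell != "NA":
                    dosages[i, j] = int(cell)
    elif dialect == "plink_text":
        by_id = {}
        n_half_missing = 0
        with Path(genotype_path).open() as fh:
            for line in fh:
                fields = line.split()
                if not fields:
                    continue
                iid = fields[1]
                if iid in by_id:
                    raise ValueError(f"duplicated subject_id {iid!r} in ped file")
                alleles = fields[6:]
                if len(alleles) != 2 * m:
                    raise ValueError(
                        f"subject {iid}: expected {2 * m} alleles, got {len(alleles)}"
                    )
                row = np.full(m, np.nan)
                for j, v in enumerate(variants):
                    a, b = alleles[2 * j], alleles[2 * j + 1]
                    if a == "0" or b == "0":
                        if (a, b) != ("0", "0"):
                            n_half_missing += 1
                        continue
                    d = 0
                    for al in (a, b):
                        if al == v.risk_allele:
                            d += 1
                        elif al != v.other_allele:
                            raise ValueError(
                                f"SNP {v.snp_id}: allele {al!r} matches neither "
                                f"risk ({v.risk_allele}) nor other "
                                f"({v.other_allele}) allele"
                            )
                    row[j] = d
                by_id[iid] = row
        if n_half_missing:
            logger.warning(
                "%d half-missing genotype calls set to missing", n_half_missing
            )
        for i, s in enumerate(subjects):
            if s.subject_id not in by_id:
                raise ValueError(f"subject {s.subject_id!r} absent from ped file")
            dosages[i] = by_id[s.subject_id]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return CohortDataset(subjects=subjects, variants=variants, dosages=dosages)


# ---------------------------------------------------------------------------
# discovery / testing split
# ---------------------------------------------------------------------------

def split_discovery_testing(
    ds: CohortDataset, fraction: float, seed: int
) -> tuple[CohortDataset, CohortDataset]:
    """Random split stratified by case/control status.

    Within each arm the subjects are shuffled with a seeded generator and
    the first ``floor(fraction * n_arm)`` go to the first part, so the two
    parts partition the cohort and each arm deviates from ``fraction`` by
    less than one subject.  The same seed always yields the same split.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0,1), got {fraction}")
    n_cases = int(ds.status_mask(CASE).sum())
    n_controls = ds.n_subjects - n_cases
    if n_cases < 2 or n_controls < 2:
        raise ValueError("need at least 2 cases and 2 controls to split")

    rng = np.random.default_rng(seed)
    part_one: list[int] = []
    for status in (CASE, CONTROL):
        idx = np.flatnonzero(ds.status_mask(status))
        rng.shuffle(idx)
        k = int(np.floor(fraction * idx.size))
        part_one.extend(idx[:k].tolist())
    mask = np.zeros(ds.n_subjects, dtype=bool)
    mask[part_one] = True
    return ds.subset(np.flatnonzero(mask)), ds.subset(np.flatnonzero(~mask))


# ---------------------------------------------------------------------------
# descriptive summary
# ---------------------------------------------------------------------------

def _mean_sd(values: Iterable[float]) -> tuple[float, float]:
    arr = np.array([v for v in values if v is not None and not np.isnan(v)])
    if arr.size == 0:
        return (np.nan, np.nan)
    return (float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else np.nan)


def summarize_cohort(ds: CohortDataset, early_onset_cutoff: float = 65.0) -> pd.DataFrame:
    """Descriptive characteristics per arm with case/control group tests.

    Quantitative characteristics (age, MMSE) are compared by two-sample
    t-test, categorical ones (sex, APOE e4 carriage) by chi-square;
    percentages use non-missing denominators.  Among cases an early-onset
    row (age at onset below ``early_onset_cutoff``) is reported.
    """
    cases = [s for s in ds.subjects if s.status == CASE]
    controls = [s for s in ds.subjects if s.status == CONTROL]
    if not cases or not controls:
        raise ValueError("both arms must be non-empty to summarize")

    rows = []

    def add(metric, case_val, control_val, p=np.nan):
        rows.append(
            {"metric": metric, "cases": case_val, "controls": control_val, "p_value": p}
        )

    add("n", len(cases), len(controls))

    # sex
    f_case = sum(s.sex == "female" for s in cases)
    f_ctrl = sum(s.sex == "female" for s in controls)
    table = np.array(
        [[f_case, len(cases) - f_case], [f_ctrl, len(controls) - f_ctrl]]
    )
    p_sex = stats.chi2_contingency(table, correction=False)[1] if table.min() >= 0 else np.nan
    add("female_n", f_case, f_ctrl, p_sex)
    add("female_pct", 100 * f_case / len(cases), 100 * f_ctrl / len(controls))

    # age (onset for cases, examination for controls — recruitment convention)
    age_case = [s.age_years for s in cases]
    age_ctrl = [s.age_years for s in controls]
    p_age = stats.ttest_ind(age_case, age_ctrl, equal_var=False).pvalue
    m, sd = _mean_sd(age_case)
    m2, sd2 = _mean_sd(age_ctrl)
    add("age_mean", m, m2, p_age)
    add("age_sd", sd, sd2)

    early = sum(s.age_years < early_onset_cutoff for s in cases)
    add("early_onset_n", early, np.nan)
    add("early_onset_pct", 100 * early / len(cases), np.nan)

    # MMSE
    mmse_case = [s.mmse for s in cases if s.mmse is not None]
    mmse_ctrl = [s.mmse for s in controls if s.mmse is not None]
    if mmse_case and mmse_ctrl:
        p_mmse = stats.ttest_ind(mmse_case, mmse_ctrl, equal_var=False).pvalue
    else:
        p_mmse = np.nan
    m, sd = _mean_sd([float(v) for v in mmse_case]) if mmse_case else (np.nan, np.nan)
    m2, sd2 = _mean_sd([float(v) for v in mmse_ctrl]) if mmse_ctrl else (np.nan, np.nan)
    add("mmse_mean", m, m2, p_mmse)
    add("mmse_sd", sd, sd2)

    # APOE e4 carriage
    e4_case = [s.e4_carrier for s in cases if s.e4_carrier is not None]
    e4_ctrl = [s.e4_carrier for s in controls if s.e4_carrier is not None]
    n4_case, n4_ctrl = sum(e4_case), sum(e4_ctrl)
    if e4_case and e4_ctrl:
        table = np.array(
            [
                [n4_case, len(e4_case) - n4_case],
                [n4_ctrl, len(e4_ctrl) - n4_ctrl],
            ]
        )
        p_e4 = stats.chi2_contingency(table, correction=False)[1]
        add("e4_carrier_n", n4_case, n4_ctrl, p_e4)
        add("e4_carrier_pct", 100 * n4_case / len(e4_case), 100 * n4_ctrl / len(e4_ctrl))
    else:
        add("e4_carrier_n", np.nan, np.nan)
        add("e4_carrier_pct", np.nan, np.nan)

    return pd.DataFrame(rows).set_index("metric")
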