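import numpy as np
import pytest

from polyrisk.cohort import CohortDataset, SubjectRecord, VariantRecord

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


def build_cohort(
    n_cases: int,
    n_controls: int,
    n_snps: int,
    seed: int = 0,
    missing_rate: float = 0.0,
    maf_low: float = 0.1,
    maf_high: float = 0.9,
    with_apoe: bool = True,
) -> CohortDataset:
    """Random but seed-deterministic cohort for structural tests."""
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_cases + n_controls):
        status = "case" if i < n_cases else "control"
        apoe = None
        if with_apoe and rng.random() > 0.05:
            apoe = tuple(rng.choice(["e2", "e3", "e4"], size=2, p=[0.1, 0.75, 0.15]))
        subjects.append(
            SubjectRecord(
                subject_id=f"s{i:04d}",
                status=status,
                sex="female" if rng.random() < 0.5 else "male",
                age_years=float(rng.uniform(45, 90)),
                mmse=int(rng.integers(0, 31)) if rng.random() > 0.1 else None,
                apoe_alleles=apoe,
            )
        )
    variants = []
    for j in range(n_snps):
        risk, other = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        variants.append(
            VariantRecord(
                snp_id=f"rs{1000 + j}",
                chromosome=str(1 + j % 22),
                position=int(1000 + 17 * j),
                gene_label=f"GENE{j}",
                risk_allele=risk,
                other_allele=other,
            )
        )
    p = rng.uniform(maf_low, maf_high, size=n_snps)
    dosages = rng.binomial(2, p, size=(len(subjects), n_snps)).astype(float)
    if missing_rate > 0:
        dosages[rng.random(dosages.shape) < missing_rate] = np.nan
    return CohortDataset(subjects=subjects, variants=variants, dosages=dosages)


def assert_cohorts_equal(a: CohortDataset, b: CohortDataset) -> None:
    assert a.subjects == b.subjects
    assert a.variants == b.variants
    np.testing.assert_array_equal(a.dosages, b.dosages)


@pytest.fixture
def tiny_cohort() -> CohortDataset:
    return build_cohort(5, 6, 3, seed=42, missing_rate=0.1)
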