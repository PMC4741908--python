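import numpy as np
import pytest

from polyrisk.cohort import (
    CohortDataset,
    FrequencyTable,
    SubjectRecord,
    VariantRecord,
    read_cohort,
    split_discovery_testing,
    summarize_cohort,
    write_cohort,
)

from conftest import assert_cohorts_equal, build_cohort


class TestRecords:
    def test_e4_carrier_derived_from_alleles(self):
        s = SubjectRecord("s1", "case", "male", 70.0, apoe_alleles=("e3", "e4"))
        assert s.e4_carrier is True and s.e4_count == 1
        s2 = SubjectRecord("s2", "control", "female", 70.0, apoe_alleles=("e2", "e3"))
        assert s2.e4_carrier is False
        assert SubjectRecord("s3", "case", "male", 70.0).e4_carrier is None

    @pytest.mark.parametrize("age", [17.0, 120.0, 10.0])
    def test_age_bounds(self, age):
        with pytest.raises(ValueError):
            SubjectRecord("s1", "case", "male", age)

    def test_variant_validation(self):
        with pytest.raises(ValueError):
            VariantRecord("rs1", "1", 100, "G", "A", "A")
        with pytest.raises(ValueError):
            VariantRecord("rs1", "1", 0, "G", "A", "G")
        assert VariantRecord("rs1", "1", 5, "G", "A", "T").strand_ambiguous
        assert not VariantRecord("rs1", "1", 5, "G", "A", "G").strand_ambiguous

    def test_dataset_rejects_bad_entries(self):
        subj = [SubjectRecord("s1", "case", "male", 70.0)]
        var = [VariantRecord("rs1", "1", 5, "G", "A", "G")]
        with pytest.raises(ValueError):
            CohortDataset(subj, var, np.array([[3.0]]))
        with pytest.raises(ValueError):
            CohortDataset(subj * 2, var, np.array([[1.0], [1.0]]))


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["tsv", "plink_text"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip_identity(self, tmp_path, dialect, seed):
        ds = build_cohort(4, 5, 3, seed=seed, missing_rate=0.15)
        paths = write_cohort(ds, tmp_path, dialect)
        back = read_cohort(
            paths["phenotypes"], paths["variants"], paths["genotypes"], dialect
        )
        assert_cohorts_equal(ds, back)

    @pytest.mark.parametrize("dialect", ["tsv", "plink_text"])
    def test_empty_variant_list(self, tmp_path, dialect):
        ds = build_cohort(2, 2, 0, seed=0)
        paths = write_cohort(ds, tmp_path, dialect)
        back = read_cohort(
            paths["phenotypes"], paths["variants"], paths["genotypes"], dialect
        )
        assert back.n_variants == 0 and back.n_subjects == 4

    def test_ped_dosage_conventions(self, tmp_path):
        """'A A' with risk allele A is dosage 2; '0 0' is missing."""
        ds = build_cohort(1, 1, 2, seed=3)
        ds.dosages[:] = [[2.0, np.nan], [0.0, 1.0]]
        paths = write_cohort(ds, tmp_path, "plink_text")
        text = paths["genotypes"].read_text().splitlines()
        v0, v1 = ds.variants
        assert text[0].split()[6:8] == [v0.risk_allele, v0.risk_allele]
        assert text[0].split()[8:10] == ["0", "0"]
        back = read_cohort(
            paths["phenotypes"], paths["variants"], paths["genotypes"], "plink_text"
        )
        np.testing.assert_array_equal(back.dosages, ds.dosages)

    def test_tsv_missing_is_na(self, tmp_path):
        ds = build_cohort(1, 1, 1, seed=3)
        ds.dosages[0, 0] = np.nan
        paths = write_cohort(ds, tmp_path, "tsv")
        assert "NA" in paths["genotypes"].read_text()

    def test_foreign_allele_is_hard_error_naming_snp(self, tmp_path):
        ds = build_cohort(1, 1, 1, seed=3)
        paths = write_cohort(ds, tmp_path, "plink_text")
        ped = paths["genotypes"].read_text().split()
        ped[6] = "T" if ds.variants[0].risk_allele != "T" else "C"
        bad = tmp_path / "bad.ped"
        # rewrite the single-subject line with the corrupted allele
        lines = paths["genotypes"].read_text().splitlines()
        f0 = lines[0].split()
        f0[6] = ped[6]
        bad.write_text(" ".join(f0) + "\n" + lines[1] + "\n")
        with pytest.raises(ValueError, match=ds.variants[0].snp_id):
            read_cohort(paths["phenotypes"], paths["variants"], bad, "plink_text")

    def test_duplicate_subject_in_ped_is_error(self, tmp_path):
        ds = build_cohort(1, 1, 1, seed=3)
        paths = write_cohort(ds, tmp_path, "plink_text")
        lines = paths["genotypes"].read_text().splitlines()
        (tmp_path / "dup.ped").write_text("\n".join([lines[0], lines[0]]) + "\n")
        with pytest.raises(ValueError, match="duplicated"):
            read_cohort(
                paths["phenotypes"], paths["variants"], tmp_path / "dup.ped", "plink_text"
            )


class TestSplit:
    def test_partition_and_stratum_balance(self):
        ds = build_cohort(459, 751, 2, seed=5)
        one, two = split_discovery_testing(ds, 0.5, seed=11)
        assert sorted(one.subject_ids + two.subject_ids) == sorted(ds.subject_ids)
        assert not set(one.subject_ids) & set(two.subject_ids)
        c1 = int(one.status_mask("case").sum())
        c2 = int(two.status_mask("case").sum())
        assert sorted([c1, c2]) == [229, 230]
        assert sorted([one.n_subjects - c1, two.n_subjects - c2]) == [375, 376]

    def test_deterministic_given_seed(self):
        ds = build_cohort(10, 12, 2, seed=5)
        a1, b1 = split_discovery_testing(ds, 0.4, seed=99)
        a2, b2 = split_discovery_testing(ds, 0.4, seed=99)
        assert a1.subject_ids == a2.subject_ids and b1.subject_ids == b2.subject_ids
        a3, _ = split_discovery_testing(ds, 0.4, seed=100)
        assert a1.subject_ids != a3.subject_ids  # overwhelmingly likely

    def test_minimal_split(self):
        ds = build_cohort(2, 2, 1, seed=5)
        one, two = split_discovery_testing(ds, 0.5, seed=0)
        for part in (one, two):
            assert int(part.status_mask("case").sum()) == 1
            assert part.n_subjects == 2

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_bounds(self, fraction):
        ds = build_cohort(3, 3, 1, seed=5)
        with pytest.raises(ValueError):
            split_discovery_testing(ds, fraction, seed=0)


class TestSummary:
    def test_percentages_consistent_with_counts(self):
        ds = build_cohort(40, 60, 2, seed=8)
        table = summarize_cohort(ds)
        for col in ("cases", "controls"):
            pct_rows = [m for m in table.index if m.endswith("_pct")]
            vals = table.loc[pct_rows, col].dropna()
            assert ((vals >= 0) & (vals <= 100)).all()
        n_f = sum(s.sex == "female" for s in ds.subjects if s.status == "case")
        assert table.loc["female_n", "cases"] == n_f
        assert table.loc["female_pct", "cases"] == pytest.approx(100 * n_f / 40)

    def test_all_missing_mmse_reported_missing(self):
        ds = build_cohort(5, 5, 1, seed=9)
        ds.subjects = [
            SubjectRecord(s.subject_id, s.status, s.sex, s.age_years, None, s.apoe_alleles)
            for s in ds.subjects
        ]
        table = summarize_cohort(ds)
        assert np.isnan(table.loc["mmse_mean", "cases"])

    def test_empty_arm_is_error(self):
        ds = build_cohort(3, 3, 1, seed=9)
        cases_only = ds.subset(np.flatnonzero(ds.status_mask("case")))
        with pytest.raises(ValueError):
            summarize_cohort(cases_only)


class TestFrequencyTable:
    def test_hwe_expansion_and_roundtrip(self, tmp_path):
        ft = FrequencyTable.from_hwe({"rs1": 0.2, "rs2": 0.5})
        p, f0, f1, f2 = ft.entries["rs1"]
        assert (f0, f1, f2) == pytest.approx((0.64, 0.32, 0.04))
        ft.write_tsv(tmp_path / "f.tsv")
        back = FrequencyTable.read_tsv(tmp_path / "f.tsv")
        for snp in ft.entries:
            assert back.entries[snp] == pytest.approx(ft.entries[snp])

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            FrequencyTable({"rs1": (0.2, 0.5, 0.5, 0.5)})
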