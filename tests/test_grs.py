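import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyrisk.assoc import AssociationResult, MODEL_SEX_AGE, MODEL_SEX_AGE_APOE
from polyrisk.cohort import FrequencyTable
from polyrisk.grs import (
    build_risk_table,
    compute_grs,
    genotypic_or_from_allelic,
    modified_grs_snps,
    relative_risks,
)
from polyrisk.simulate import default_config, simulate_cohort

from conftest import build_cohort


def _result(snp, model, odds, p):
    lo, hi = odds * 0.8, odds * 1.25
    return AssociationResult(
        snp_id=snp, model=model, allelic_or=odds, ci95=(min(lo, hi), max(lo, hi)),
        p_wald=p, n_used=100, allele_freq_cases=0.2, allele_freq_controls=0.15,
    )


class TestGenotypicOR:
    @pytest.mark.parametrize(
        "allelic,expected",
        [(2.0, (1, 2, 4)), (1.0, (1, 1, 1)), (0.5, (1, 0.5, 0.25))],
    )
    def test_multiplicative_expansion(self, allelic, expected):
        assert genotypic_or_from_allelic(allelic) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            genotypic_or_from_allelic(bad)


class TestRelativeRisks:
    def test_worked_example(self):
        # OR (1,2,4) with HWE frequencies at p=0.2: mean risk 1.44
        r = relative_risks((1, 2, 4), (0.64, 0.32, 0.04))
        assert r == pytest.approx((1 / 1.44, 2 / 1.44, 4 / 1.44), abs=1e-9)

    def test_null_score(self):
        assert relative_risks((1, 1, 1), (0.2, 0.5, 0.3)) == pytest.approx((1, 1, 1))

    def test_degenerate_frequency(self):
        assert relative_risks((1, 3, 9), (1.0, 0.0, 0.0)) == pytest.approx((1, 3, 9))

    @given(
        st.floats(min_value=0.05, max_value=0.95),
        st.floats(min_value=0.1, max_value=5.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_population_mean_risk_is_one(self, p, odds):
        f = ((1 - p) ** 2, 2 * p * (1 - p), p**2)
        r = relative_risks(genotypic_or_from_allelic(odds), f)
        assert sum(fg * rg for fg, rg in zip(f, r)) == pytest.approx(1.0, abs=1e-9)
        if odds > 1:
            assert r[0] < r[1] < r[2]
        elif odds < 1:
            assert r[0] > r[1] > r[2]


class TestRiskTable:
    def _assoc(self):
        return [
            _result("rs1", MODEL_SEX_AGE, 1.5, 0.01),
            _result("rs2", MODEL_SEX_AGE, 2.0, 0.001),
        ]

    def test_builds_per_snp_rows(self):
        freqs = FrequencyTable.from_hwe({"rs1": 0.3, "rs2": 0.1})
        table = build_risk_table(self._assoc(), freqs, ["rs1", "rs2"])
        assert table.snp_ids == ["rs1", "rs2"]
        row = table.rows["rs2"]
        assert row.genotypic_or == pytest.approx((1, 2, 4))

    def test_missing_frequency_entry_names_snp(self):
        freqs = FrequencyTable.from_hwe({"rs1": 0.3})
        with pytest.raises(KeyError, match="rs2"):
            build_risk_table(self._assoc(), freqs, ["rs1", "rs2"])

    def test_empty_snp_set_is_error(self):
        with pytest.raises(ValueError):
            build_risk_table(self._assoc(), FrequencyTable({}), [])


class TestComputeGRS:
    def _setup(self, n_snps=3, seed=0):
        ds = build_cohort(10, 10, n_snps, seed=seed)
        assoc = [
            _result(snp, MODEL_SEX_AGE, odds, 0.01)
            for snp, odds in zip(ds.snp_ids, (1.5, 2.0, 0.8))
        ]
        freqs = FrequencyTable.from_hwe({s: 0.2 + 0.1 * i for i, s in enumerate(ds.snp_ids)})
        return ds, assoc, freqs

    def test_missing_dosage_imputed_as_average_risk(self):
        ds, assoc, freqs = self._setup()
        table = build_risk_table(assoc, freqs, ds.snp_ids)
        ds.dosages[0, :] = np.nan
        profiles = compute_grs(ds, table)
        assert profiles[0].grs == 1.0
        assert profiles[0].n_missing_imputed == 3

    def test_multiplicative_over_disjoint_snp_sets(self):
        ds, assoc, freqs = self._setup()
        full = build_risk_table(assoc, freqs, ds.snp_ids)
        part_a = build_risk_table(assoc, freqs, ds.snp_ids[:1])
        part_b = build_risk_table(assoc, freqs, ds.snp_ids[1:])
        g_full = compute_grs(ds, full)
        g_a = compute_grs(ds, part_a)
        g_b = compute_grs(ds, part_b)
        for f, a, b in zip(g_full, g_a, g_b):
            assert f.grs == pytest.approx(a.grs * b.grs, rel=1e-12)

    def test_order_invariance(self):
        ds, assoc, freqs = self._setup()
        fwd = build_risk_table(assoc, freqs, ds.snp_ids)
        rev = build_risk_table(assoc, freqs, ds.snp_ids[::-1])
        for f, r in zip(compute_grs(ds, fwd), compute_grs(ds, rev)):
            assert f.grs == pytest.approx(r.grs, rel=1e-12)

    def test_null_table_gives_unit_scores(self):
        ds, _, freqs = self._setup()
        assoc = [_result(s, MODEL_SEX_AGE, 1.0, 0.5) for s in ds.snp_ids]
        table = build_risk_table(assoc, freqs, ds.snp_ids)
        assert all(p.grs == pytest.approx(1.0) for p in compute_grs(ds, table))

    def test_modal_genotype_below_average_for_risk_alleles(self):
        """With p < 0.5 and OR > 1 the common homozygote carries less than
        average risk, so an all-reference subject scores below 1."""
        ds, assoc, freqs = self._setup()
        table = build_risk_table(assoc, freqs, ds.snp_ids[:2])  # ORs 1.5, 2.0
        ds.dosages[1, :] = 0.0
        profile = compute_grs(ds, table)[1]
        assert profile.grs < 1.0

    def test_case_mean_exceeds_control_mean_under_true_effects(self):
        cfg = default_config(n_cases=400, n_controls=400, seed=12, missing_rate=0.0)
        ds, truth = simulate_cohort(cfg)
        causal = [s.snp_id for s in cfg.snps if s.allelic_or > 1]
        assoc = [
            _result(snp, MODEL_SEX_AGE, next(s.allelic_or for s in cfg.snps if s.snp_id == snp), 0.01)
            for snp in causal
        ]
        freqs = FrequencyTable.from_hwe(
            {s.snp_id: s.risk_allele_freq for s in cfg.snps if s.snp_id in causal}
        )
        table = build_risk_table(assoc, freqs, causal)
        profiles = compute_grs(ds, table)
        grs = np.array([p.grs for p in profiles])
        case = ds.status_mask("case")
        assert grs[case].mean() > grs[~case].mean()


class TestModifiedSelection:
    def _ld(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "r2", "flagged", "n_used", "D_prime"])

    def test_drops_apoe_dependent_and_linked_snps(self):
        results = []
        # six discovery-significant SNPs
        for snp in ("rs_a", "rs_b", "rs_c", "rs_d", "rs_e", "rs_f"):
            results.append(_result(snp, MODEL_SEX_AGE, 1.5, 0.01))
        # after APOE adjustment two lose significance
        apoe_p = {"rs_a": 0.01, "rs_b": 0.02, "rs_c": 0.03, "rs_d": 0.30, "rs_e": 0.60, "rs_f": 0.01}
        for snp, p in apoe_p.items():
            results.append(_result(snp, MODEL_SEX_AGE_APOE, 1.4, p))
        ld = self._ld([("rs_f", 0.48, True, 600, 0.8), ("rs_a", 0.05, False, 600, 0.2)])
        kept = modified_grs_snps(results, ld, alpha=0.05, r2_threshold=0.2)
        assert kept == ["rs_a", "rs_b", "rs_c"]

    def test_identity_when_nothing_is_apoe_related(self):
        results = [
            _result("rs_a", MODEL_SEX_AGE, 1.5, 0.01),
            _result("rs_a", MODEL_SEX_AGE_APOE, 1.5, 0.01),
        ]
        assert modified_grs_snps(results, self._ld([]), 0.05, 0.2) == ["rs_a"]

    def test_all_related_yields_empty_and_downstream_error(self):
        results = [
            _result("rs_a", MODEL_SEX_AGE, 1.5, 0.01),
            _result("rs_a", MODEL_SEX_AGE_APOE, 1.5, 0.50),
        ]
        kept = modified_grs_snps(results, self._ld([]), 0.05, 0.2)
        assert kept == []
        with pytest.raises(ValueError):
            build_risk_table(results, FrequencyTable({}), kept)
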