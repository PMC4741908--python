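import numpy as np
import pytest
from scipy.special import comb
from sklearn.metrics import roc_auc_score, roc_curve

from polyrisk.evaluate import (
    auc_mann_whitney,
    combined_model_scores,
    delong_compare,
    roc_coordinates,
    stratified_evaluation,
    wilcoxon_rank_sum,
)
from polyrisk.grs import GRSProfile
from polyrisk.simulate import default_config, simulate_cohort

from _oracles import auc_pairwise, delong_brute_force, wilcoxon_exact_pvalue
from conftest import build_cohort


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 5.0] * 10)
        _, p = wilcoxon_rank_sum(x, x.copy())
        assert p == 1.0

    def test_all_tied_constant_scores(self):
        _, p = wilcoxon_rank_sum(np.ones(30), np.ones(40))
        assert p == 1.0

    def test_complete_separation_exact_p(self):
        cases = np.arange(11, 21, dtype=float)
        controls = np.arange(1, 11, dtype=float)
        _, p = wilcoxon_rank_sum(cases, controls)
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        cases = rng.normal(1.0, 1.0, 7)
        controls = rng.normal(0.0, 1.0, 8)
        _, p = wilcoxon_rank_sum(cases, controls)
        assert p == pytest.approx(wilcoxon_exact_pvalue(cases, controls), abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0.5, 1, 40), rng.normal(0, 1, 60)
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum(np.array([]), np.array([1.0]))


class TestAUC:
    def test_perfect_separation(self):
        assert auc_mann_whitney(np.array([3.0, 4.0]), np.array([1.0, 2.0])) == 1.0

    def test_all_ties_half(self):
        assert auc_mann_whitney(np.ones(5), np.ones(7)) == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_pairwise_and_sklearn_oracles(self, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(0.5, 1, 25), 1)  # rounding induces ties
        y = np.round(rng.normal(0.0, 1, 35), 1)
        ours = auc_mann_whitney(x, y)
        assert ours == pytest.approx(auc_pairwise(x, y), abs=1e-12)
        labels = np.r_[np.ones(25), np.zeros(35)]
        assert ours == pytest.approx(roc_auc_score(labels, np.r_[x, y]), abs=1e-12)

    def test_equals_trapezoidal_roc_area(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(1, 1, 30), rng.normal(0, 1, 40)
        fpr, tpr, _ = roc_curve(np.r_[np.ones(30), np.zeros(40)], np.r_[x, y])
        assert auc_mann_whitney(x, y) == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 30)
        assert auc_mann_whitney(x, y) + auc_mann_whitney(-x, -y) == pytest.approx(1.0)

    def test_roc_coordinates_consistent(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(1, 1, 15), rng.normal(0, 1, 20)
        coords = roc_coordinates(x, y)
        assert coords.fpr.iloc[0] == 0.0 and coords.tpr.iloc[-1] == 1.0
        assert coords.fpr.is_monotonic_increasing


class TestDeLong:
    def test_identical_markers_compare_equal(self):
        rng = np.random.default_rng(5)
        s = rng.normal(0, 1, 50)
        labels = rng.random(50) < 0.4
        labels[0], labels[1] = True, False
        res = delong_compare(s, s.copy(), labels)
        assert res.z == 0.0 and res.p_two_sided == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_instance_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        a = np.round(rng.normal(0, 1, n), 1)
        b = np.round(rng.normal(0, 1, n), 1)
        labels = np.array([True, True, True, False, False, False, False, True])
        res = delong_compare(a, b, labels)
        auc_a, auc_b, var_a, var_b, cov_ab = delong_brute_force(a, b, labels)
        assert res.auc_a == pytest.approx(auc_a, abs=1e-12)
        assert res.auc_b == pytest.approx(auc_b, abs=1e-12)
        assert res.var_a == pytest.approx(var_a, abs=1e-12)
        assert res.var_b == pytest.approx(var_b, abs=1e-12)
        assert res.cov_ab == pytest.approx(cov_ab, abs=1e-12)

    def test_self_covariance_equals_variance(self):
        rng = np.random.default_rng(6)
        s = rng.normal(0, 1, 60)
        labels = np.r_[np.ones(25), np.zeros(35)].astype(bool)
        res = delong_compare(s, s.copy(), labels)
        assert res.cov_ab == pytest.approx(res.var_a, rel=1e-12)
        assert res.var_a >= 0 and res.var_b >= 0
        assert abs(res.cov_ab) <= np.sqrt(res.var_a * res.var_b) + 1e-15

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.5, 1, 80)
        b = rng.normal(0.2, 1, 80)
        labels = np.r_[np.ones(30), np.zeros(50)].astype(bool)
        r1 = delong_compare(a, b, labels)
        r2 = delong_compare(np.exp(a), b**3, labels)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided, rel=1e-12)

    def test_misaligned_inputs_error(self):
        with pytest.raises(ValueError):
            delong_compare(np.ones(3), np.ones(4), np.array([True, False, True]))


class TestCombinedAndStratified:
    def _cohort_with_grs(self, seed=13, n=300):
        cfg = default_config(n_cases=n, n_controls=n, seed=seed, missing_rate=0.0)
        ds, _ = simulate_cohort(cfg)
        rng = np.random.default_rng(seed + 1)
        # score correlated with both the causal genotypes and status
        causal = [s.snp_id for s in cfg.snps if s.allelic_or > 1]
        base = sum(ds.dosage_vector(snp) for snp in causal)
        grs = np.exp(0.3 * base + rng.normal(0, 0.1, ds.n_subjects))
        profiles = [
            GRSProfile(s.subject_id, float(g), tuple(causal), 0)
            for s, g in zip(ds.subjects, grs)
        ]
        return ds, profiles

    def test_combined_beats_components_on_fit_data(self):
        ds, profiles = self._cohort_with_grs()
        scores, labels = combined_model_scores(ds, profiles)
        auc_combined = auc_mann_whitney(scores[labels == 1], scores[labels == 0])
        by_id = {p.subject_id: p.grs for p in profiles}
        kept = [s for s in ds.subjects if s.e4_carrier is not None and s.subject_id in by_id]
        g = np.array([by_id[s.subject_id] for s in kept])
        e4 = np.array([float(s.e4_carrier) for s in kept])
        lab = np.array([s.status == "case" for s in kept])
        auc_grs = auc_mann_whitney(g[lab], g[~lab])
        auc_apoe = auc_mann_whitney(e4[lab], e4[~lab])
        assert auc_combined >= max(auc_grs, auc_apoe) - 0.01

    def test_uninformative_markers_auc_near_half(self):
        ds = build_cohort(300, 300, 1, seed=14)
        rng = np.random.default_rng(15)
        profiles = [
            GRSProfile(s.subject_id, float(np.exp(rng.normal(0, 0.2))), (), 0)
            for s in ds.subjects
        ]
        scores, labels = combined_model_scores(ds, profiles)
        auc = auc_mann_whitney(scores[labels == 1], scores[labels == 0])
        assert abs(auc - 0.5) < 0.08

    def test_strata_partition_the_pooled_set(self):
        ds, profiles = self._cohort_with_grs(seed=16)
        table = stratified_evaluation(ds, profiles)
        pooled = table[table.stratum == "pooled"].iloc[0]
        carriers = table[table.stratum == "e4_carriers"].iloc[0]
        non = table[table.stratum == "e4_non_carriers"].iloc[0]
        assert pooled.n_cases == carriers.n_cases + non.n_cases
        assert pooled.n_controls == carriers.n_controls + non.n_controls

    def test_true_effect_shows_in_both_strata(self):
        ds, profiles = self._cohort_with_grs(seed=17, n=400)
        table = stratified_evaluation(ds, profiles)
        assert (table.auc > 0.5).all()

    def test_single_case_stratum_flagged_not_dropped(self):
        ds = build_cohort(1, 30, 1, seed=18, with_apoe=False)
        # give everyone APOE so strata are defined; one case, a carrier
        import dataclasses

        subjects = [
            dataclasses.replace(
                s, apoe_alleles=("e3", "e4") if i < 10 or s.status == "case" else ("e3", "e3")
            )
            for i, s in enumerate(ds.subjects)
        ]
        ds = dataclasses.replace(ds, subjects=subjects)
        profiles = [
            GRSProfile(s.subject_id, 1.0 + 0.01 * i, (), 0)
            for i, s in enumerate(ds.subjects)
        ]
        table = stratified_evaluation(ds, profiles)
        carriers = table[table.stratum == "e4_carriers"].iloc[0]
        assert carriers.flag == "low_n"
        assert not np.isnan(carriers.auc)
        non = table[table.stratum == "e4_non_carriers"].iloc[0]
        assert non.flag == "empty_arm"
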