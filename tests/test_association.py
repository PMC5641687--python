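import warnings

import numpy as np
import pandas as pd
import pytest

from latgen import synthetic as syn
from latgen.association import (add_genetic_factor, associate_all,
                                extreme_group_analysis, fdr_adjust,
                                fit_cross_sectional, fit_latent_change,
                                genetic_factor_scores)
from latgen.sem import IdentificationError, SemModelSpec


def brute_force_bh(p, m):
    """Independent step-up oracle: adj_i = min_{k: rank_k >= rank_i}
    (m * p_(k) / k), straight from the definition."""
    p = np.asarray(p, float)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty_like(sorted_p)
    for i in range(len(p)):
        candidates = [m * sorted_p[k] / (k + 1) for k in range(i, len(p))]
        adj_sorted[i] = min(1.0, min(candidates))
    out = np.empty_like(adj_sorted)
    out[order] = adj_sorted
    return out


class TestFdr:
    def test_published_family(self):
        # family of 12: two smallest raw p-values 0.003 and 0.007
        p = [0.003, 0.007, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
             0.95, 0.99]
        adj = fdr_adjust(p, family_size=12)
        assert round(adj[0], 3) == 0.036
        assert round(adj[1], 3) == 0.042

    def test_single_test_unchanged(self):
        assert fdr_adjust([0.02])[0] == pytest.approx(0.02)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.random(12)
            assert np.allclose(fdr_adjust(p), brute_force_bh(p, 12),
                               atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        p = rng.random(20)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(fdr_adjust(p), adj, atol=1e-12)

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError, match="family_size"):
            fdr_adjust([0.1, 0.2, 0.3], family_size=2)

    def test_monotone_and_dominating(self):
        rng = np.random.default_rng(5)
        p = rng.random(12)
        adj = fdr_adjust(p, family_size=12)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestGeneticFactor:
    def test_two_snps_under_identified(self):
        spec = SemModelSpec(observed=["a", "b"], latents=[])
        with pytest.raises(IdentificationError, match="3 SNP"):
            add_genetic_factor(spec, ["a", "b"])

    def test_male_loading_recovery(self):
        from latgen.polychoric import compute_poly_stats
        from latgen.sem import fit_dwls
        cfg = syn.power_template(effect_variance=0.0, n=20000, seed=61)
        coh = syn.generate_full_study(cfg)
        stats = compute_poly_stats(coh.geno.calls)
        spec = SemModelSpec(observed=list(coh.geno.snp_ids), latents=[])
        add_genetic_factor(spec, list(coh.geno.snp_ids))
        fit = fit_dwls(spec, stats, compute_baseline=False)
        truth = dict(zip(coh.geno.snp_ids, [0.989, 0.989, 0.984]))
        for snp in coh.geno.snp_ids:
            assert fit.std_beta[f"std_lam:{snp}~G"][0] == pytest.approx(
                truth[snp], abs=0.02)

    def test_weak_ld_still_identified(self):
        from latgen.polychoric import compute_poly_stats
        from latgen.sem import fit_dwls
        cfg = syn.power_template(effect_variance=0.0, n=20000, seed=62)
        cfg.male.snp_loadings = np.array([0.45, 0.45, 0.45])
        coh = syn.generate_full_study(cfg)
        stats = compute_poly_stats(coh.geno.calls)
        spec = SemModelSpec(observed=list(coh.geno.snp_ids), latents=[])
        add_genetic_factor(spec, list(coh.geno.snp_ids))
        fit = fit_dwls(spec, stats, compute_baseline=False)
        assert fit.converged
        for snp in coh.geno.snp_ids:
            assert fit.std_beta[f"std_lam:{snp}~G"][0] == pytest.approx(
                0.45, abs=0.06)


class TestStructuralModels:
    @pytest.fixture(scope="class")
    def effect_cohort(self):
        cfg = syn.default_config(
            n_male=20000, n_female=0, traits=("extraversion",),
            beta_cross={"extraversion": -0.167},
            beta_change={"extraversion": 0.197},
            invariance="strict", seed=63)
        return syn.generate_full_study(cfg)

    def test_cross_sectional_recovers_effect(self, effect_cohort):
        rows, fit = fit_cross_sectional(effect_cohort.geno,
                                        effect_cohort.items,
                                        "extraversion", "male")
        t1 = rows[rows["phenotype"] == "t1"].iloc[0]
        assert t1["std_beta"] == pytest.approx(-0.167, abs=0.04)
        assert fit.converged
        assert t1["ci_low"] <= t1["std_beta"] <= t1["ci_high"]

    def test_latent_change_recovers_effect(self, effect_cohort):
        rows, est, fit = fit_latent_change(effect_cohort.geno,
                                           effect_cohort.items,
                                           "extraversion", "male")
        assert rows.iloc[0]["std_beta"] == pytest.approx(0.197, abs=0.05)
        assert est.change_var > 0
        assert abs(est.change_mean) < 0.1

    def test_reparameterization_identity(self, effect_cohort):
        """Cross-sectional and latent-difference parameterizations give
        identical discrepancy and test statistics."""
        _, fit_cs = fit_cross_sectional(effect_cohort.geno,
                                        effect_cohort.items,
                                        "extraversion", "male")
        _, _, fit_lc = fit_latent_change(effect_cohort.geno,
                                         effect_cohort.items,
                                         "extraversion", "male")
        assert fit_cs.df == fit_lc.df
        assert fit_cs._F_min == pytest.approx(fit_lc._F_min, abs=1e-6)
        assert fit_cs.chi2 == pytest.approx(fit_lc.chi2, abs=1e-4)

    def test_null_effect_near_zero(self):
        cfg = syn.power_template(effect_variance=0.0, n=8000, seed=64)
        coh = syn.generate_full_study(cfg)
        rows, _ = fit_cross_sectional(coh.geno, coh.items, "extraversion",
                                      "male")
        assert abs(rows.iloc[0]["std_beta"]) < 0.05

    def test_no_change_generator_triggers_heywood_guard(self):
        cfg = syn.default_config(n_male=10000, n_female=0,
                                 traits=("extraversion",),
                                 invariance="strict", seed=65)
        cfg.male.cross_wave_corr["extraversion"] = 0.9999
        coh = syn.generate_full_study(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows, est, fit = fit_latent_change(coh.geno, coh.items,
                                               "extraversion", "male")
        assert est.change_var < 0.05


class TestExtremeGroups:
    def test_group_sizes(self):
        cfg = syn.power_template(effect_variance=0.028, n=1160, seed=66)
        coh = syn.generate_full_study(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = extreme_group_analysis(coh.geno, coh.items,
                                          "extraversion", "male",
                                          fraction=0.30)
        assert rows.iloc[0]["n_group"] == 696  # 2 x round(0.30 * 1160)

    def test_group_contrast_matches_truth_oracle(self):
        """The estimated group coefficient agrees with the latent-truth
        correlation between the realized group indicator and the generating
        wave-1 factor (independent oracle from the truth record).

        Note: with three binary SNPs the male genetic scores take at most 8
        distinct values, so the 30% tails are completed by tie-breaking
        within a genotype pattern; the contrast is therefore attenuated
        relative to selection on a continuous score."""
        cfg = syn.power_template(effect_variance=0.09, n=20000, seed=201)
        coh = syn.generate_full_study(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = genetic_factor_scores(coh.geno, "male")
            ext = extreme_group_analysis(coh.geno, coh.items,
                                         "extraversion", "male")
        b_ext = ext[ext["phenotype"] == "t1_extreme"].iloc[0]["std_beta"]
        order = pd.DataFrame({"score": scores}).sort_values(
            ["score"], kind="stable").index
        k = int(round(len(order) * 0.30))
        sel = list(order[:k]) + list(order[-k:])
        group = np.array([0.0] * k + [1.0] * k)
        eta = coh.truth["male"].loc[sel, "extraversion_t1"].to_numpy()
        oracle = np.corrcoef(group, eta)[0, 1]
        assert b_ext == pytest.approx(oracle, abs=0.05)
        assert b_ext > 0.15  # informative contrast for a 0.3 effect

    def test_zero_effect_near_zero(self):
        cfg = syn.power_template(effect_variance=0.0, n=1160, seed=67)
        coh = syn.generate_full_study(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = extreme_group_analysis(coh.geno, coh.items,
                                          "extraversion", "male")
        assert abs(rows.iloc[0]["std_beta"]) < 0.15

    def test_scores_monotone_in_dosage_sum(self):
        cfg = syn.power_template(effect_variance=0.0, n=2000, seed=68)
        coh = syn.generate_full_study(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = genetic_factor_scores(coh.geno, "male")
        total = coh.geno.calls.sum(axis=1).loc[scores.index]
        by_total = scores.groupby(total).mean()
        assert by_total.is_monotonic_increasing


class TestAssociateAll:
    def test_family_structure_and_fdr(self):
        cfg = syn.default_config(n_male=400, n_female=400, seed=69)
        coh = syn.generate_full_study(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = associate_all(coh.geno, coh.items, family_size=12)
        assert len(table) == 12  # 2 sexes x 2 traits x 3 phenotypes
        assert np.all(table["fdr_p"] >= table["p"] - 1e-12)
        assert np.all(table["ci_low"] <= table["std_beta"])
        assert np.all(table["std_beta"] <= table["ci_high"])
        order = np.argsort(table["p"].to_numpy())
        assert np.all(np.diff(table["fdr_p"].to_numpy()[order]) >= -1e-12)
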