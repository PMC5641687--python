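import warnings

import numpy as np
import pandas as pd
import pytest

from latgen import synthetic as syn
from latgen.polychoric import compute_poly_stats
from latgen.sem import (IdentificationError, SemModelSpec, chi2_diff_test,
                        fit_dwls, fit_indices, fixed_at, free,
                        parse_model_text)

# published fit rows (chi2, df, n, printed RMSEA): the RMSEA formula must
# reproduce every row to three decimals
FIT_ROWS = [
    (808.683, 303, 1160, 0.038),
    (878.578, 311, 1160, 0.040),
    (814.835, 313, 1160, 0.037),
    (971.144, 326, 1160, 0.041),
    (1054.311, 303, 1180, 0.046),
    (1116.822, 311, 1180, 0.047),
    (1041.822, 313, 1180, 0.044),
    (1245.856, 326, 1180, 0.049),
]


def one_factor_spec(items, identification="unit_variance"):
    spec = SemModelSpec(observed=list(items), latents=["f"])
    if identification == "unit_variance":
        spec.psi[("f", "f")] = fixed_at(1.0)
        for it in items:
            spec.loadings[(it, "f")] = free()
    else:  # reference loading fixed at 1, factor variance free
        spec.psi[("f", "f")] = free(0.5)
        for i, it in enumerate(items):
            spec.loadings[(it, "f")] = fixed_at(1.0) if i == 0 else free()
    return spec


@pytest.fixture(scope="module")
def binary_six_stats():
    cfg = syn.default_config(n_male=2000, n_female=0,
                             traits=("extraversion",), invariance="strict",
                             seed=31)
    coh = syn.generate_full_study(cfg)
    return compute_poly_stats(coh.items.wide("t1")[syn.EXTRAVERSION_ITEMS])


class TestFitIndices:
    @pytest.mark.parametrize("chi2,df,n,rmsea", FIT_ROWS)
    def test_rmsea_reproduces_published_rows(self, chi2, df, n, rmsea):
        got, _, _ = fit_indices(chi2, df, n, baseline_chi2=10 * chi2,
                                baseline_df=df)
        assert round(got, 3) == rmsea

    def test_perfect_fit_limits(self):
        rmsea, cfi, tli = fit_indices(100.0, 100, 500, 4000.0, 120)
        assert rmsea == 0.0
        assert cfi == 1.0
        assert tli >= 1.0

    def test_saturated_undefined(self):
        with pytest.raises(ValueError, match="saturated"):
            fit_indices(0.0, 0, 100, 10.0, 5)


class TestFitDwls:
    def test_saturated_model_zero_chi2(self, binary_six_stats):
        # free correlations for every pair: q == m -> chi2 ~ 0, df = 0
        items = binary_six_stats.names
        spec = SemModelSpec(observed=list(items),
                            latents=[f"L{i}" for i in range(len(items))])
        for it, lat in zip(items, spec.latents):
            spec.loadings[(it, lat)] = fixed_at(1.0)
            spec.theta[it] = fixed_at(0.0)
            spec.psi[(lat, lat)] = fixed_at(1.0)
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                spec.psi[(spec.latents[a], spec.latents[b])] = free(0.1)
        # free correlations + free thresholds exhaust the statistics
        fit = fit_dwls(spec, binary_six_stats, compute_baseline=False)
        assert fit.df == 0
        assert fit.chi2 < 1e-4

    def test_overparameterized_rejected(self, binary_six_stats):
        items = binary_six_stats.names
        spec = SemModelSpec(observed=list(items),
                            latents=[f"f{i}" for i in range(8)])
        for i, lat in enumerate(spec.latents):
            spec.psi[(lat, lat)] = fixed_at(1.0)
            for it in items:
                spec.loadings[(it, lat)] = free()
        with pytest.raises(IdentificationError):
            fit_dwls(spec, binary_six_stats)

    def test_df_bookkeeping_matches_brute_force(self, binary_six_stats):
        items = binary_six_stats.names
        spec = one_factor_spec(items)
        fit = fit_dwls(spec, binary_six_stats, compute_baseline=False)
        n_stats = len(binary_six_stats.s)
        free_params = 6 + 6  # loadings + thresholds
        assert fit.df == n_stats - free_params

    def test_loading_recovery_large_n(self):
        cfg = syn.default_config(n_male=20000, n_female=0,
                                 traits=("extraversion",),
                                 invariance="strict", seed=32)
        coh = syn.generate_full_study(cfg)
        stats = compute_poly_stats(
            coh.items.wide("t1")[syn.EXTRAVERSION_ITEMS])
        fit = fit_dwls(one_factor_spec(stats.names), stats,
                       compute_baseline=False)
        truth = [0.417, 0.428, 0.626, 0.689, 0.286, 0.239]
        for it, lam in zip(stats.names, truth):
            assert fit.std_beta[f"std_lam:{it}~f"][0] == pytest.approx(
                lam, abs=0.03)

    def test_reparameterization_invariance(self, binary_six_stats):
        fit_a = fit_dwls(one_factor_spec(binary_six_stats.names),
                         binary_six_stats, compute_baseline=False)
        fit_b = fit_dwls(one_factor_spec(binary_six_stats.names,
                                         "reference"),
                         binary_six_stats, compute_baseline=False)
        assert fit_a.df == fit_b.df
        assert fit_a._F_min == pytest.approx(fit_b._F_min, abs=1e-6)
        assert fit_a.chi2 == pytest.approx(fit_b.chi2, abs=1e-4)

    def test_predictor_sign_flip_negates_beta(self):
        cfg = syn.power_template(effect_variance=0.028, n=4000, seed=33)
        coh = syn.generate_full_study(cfg)
        items = syn.EXTRAVERSION_ITEMS
        from latgen.association import build_single_wave_spec
        df = coh.items.wide("t1")[items].join(coh.geno.calls)
        fit = fit_dwls(build_single_wave_spec(items, list(coh.geno.snp_ids)),
                       compute_poly_stats(df), compute_baseline=False)
        flipped = df.copy()
        for snp in coh.geno.snp_ids:
            flipped[snp] = 1 - flipped[snp]
        fit2 = fit_dwls(build_single_wave_spec(items,
                                               list(coh.geno.snp_ids)),
                        compute_poly_stats(flipped), compute_baseline=False)
        b1 = fit.std_beta["std_b:eta1~G"][0]
        b2 = fit2.std_beta["std_b:eta1~G"][0]
        assert b2 == pytest.approx(-b1, abs=0.01)

    def test_standardized_loadings_bounded(self, binary_six_stats):
        fit = fit_dwls(one_factor_spec(binary_six_stats.names),
                       binary_six_stats, compute_baseline=False)
        for key, (val, se) in fit.std_beta.items():
            assert abs(val) <= 1.0
            assert se >= 0


class TestDifferenceTest:
    @staticmethod
    def _equality_specs(items):
        """Free model vs model constraining loadings equal in pairs."""
        spec_free = one_factor_spec(items)
        spec_eq = SemModelSpec(observed=list(items), latents=["f"])
        spec_eq.psi[("f", "f")] = fixed_at(1.0)
        for i, it in enumerate(items):
            spec_eq.loadings[(it, "f")] = free(label=f"pair{i // 2}")
        return spec_eq, spec_free

    def test_identical_specs_zero(self, binary_six_stats):
        spec = one_factor_spec(binary_six_stats.names)
        fit1 = fit_dwls(spec, binary_six_stats, compute_baseline=False)
        fit2 = fit_dwls(one_factor_spec(binary_six_stats.names),
                        binary_six_stats, compute_baseline=False)
        stat, dfd, p = chi2_diff_test(fit1, fit2)
        assert stat == 0.0 and dfd == 0 and p == 1.0

    def test_non_nested_rejected(self, binary_six_stats):
        items = binary_six_stats.names
        spec_a = one_factor_spec(items)
        # trades a free loading for a residual covariance: neither model's
        # free-parameter set contains the other's
        spec_b = one_factor_spec(items)
        spec_b.loadings[(items[0], "f")] = fixed_at(0.5)
        spec_b.theta_cov[(items[0], items[1])] = free()
        fit_a = fit_dwls(spec_a, binary_six_stats, compute_baseline=False)
        fit_b = fit_dwls(spec_b, binary_six_stats, compute_baseline=False)
        with pytest.raises(ValueError, match="not nested"):
            chi2_diff_test(fit_b, fit_a)

    def test_null_moment_calibration(self):
        """Under true equality constraints the scaled difference statistic
        has approximately its nominal chi-square mean."""
        lam = np.array([0.5, 0.5, 0.6, 0.6, 0.7, 0.7])
        tau = np.zeros(6)
        rng = np.random.default_rng(40)
        stats_list = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(300):
                eta = rng.standard_normal(800)
                liab = lam * eta[:, None] + np.sqrt(1 - lam ** 2) \
                    * rng.standard_normal((800, 6))
                df = pd.DataFrame((liab > tau).astype(float),
                                  columns=[f"i{k}" for k in range(6)])
                st = compute_poly_stats(df)
                spec_eq, spec_free = self._equality_specs(st.names)
                f_eq = fit_dwls(spec_eq, st, compute_baseline=False)
                f_free = fit_dwls(spec_free, st, compute_baseline=False)
                stat, dfd, _ = chi2_diff_test(f_eq, f_free)
                stats_list.append((stat, dfd))
        dfd = stats_list[0][1]
        assert dfd == 3
        mean_stat = np.mean([s for s, _ in stats_list])
        assert mean_stat == pytest.approx(dfd, rel=0.10)

    def test_power_against_violated_equality(self):
        """A 0.3 loading-equality violation is detected reliably."""
        lam = np.array([0.35, 0.65, 0.6, 0.6, 0.7, 0.7])  # pair0 violated
        tau = np.zeros(6)
        rng = np.random.default_rng(41)
        rejections = 0
        reps = 100
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(reps):
                eta = rng.standard_normal(1160)
                liab = lam * eta[:, None] + np.sqrt(1 - lam ** 2) \
                    * rng.standard_normal((1160, 6))
                df = pd.DataFrame((liab > tau).astype(float),
                                  columns=[f"i{k}" for k in range(6)])
                st = compute_poly_stats(df)
                spec_eq, spec_free = self._equality_specs(st.names)
                f_eq = fit_dwls(spec_eq, st, compute_baseline=False)
                f_free = fit_dwls(spec_free, st, compute_baseline=False)
                stat, dfd, p = chi2_diff_test(f_eq, f_free)
                if p < 0.05:
                    rejections += 1
        assert rejections / reps > 0.8


class TestModelText:
    def test_parse_by_on_with(self):
        spec = parse_model_text(
            "f by a, b, c; g by d, e@0.5; f on g; a with d",
            observed=["a", "b", "c", "d", "e"])
        assert set(spec.latents) == {"f", "g"}
        assert ("a", "f") in spec.loadings
        assert spec.loadings[("e", "g")].fixed
        assert ("f", "g") in spec.regressions
        assert ("a", "d") in spec.theta_cov

    def test_equality_labels(self):
        spec = parse_model_text("f by a=l1, b=l1, c",
                                observed=["a", "b", "c"])
        assert spec.loadings[("a", "f")].label == "l1"
        assert spec.loadings[("b", "f")].label == "l1"

    def test_unknown_statement(self):
        with pytest.raises(ValueError, match="cannot parse"):
            parse_model_text("f loads a", observed=["a"])
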