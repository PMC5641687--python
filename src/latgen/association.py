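"""Latent-genetic-factor association models.

The genetic predictor G is a latent factor measured by three X-linked SNP
indicators (binary in hemizygous males, three-category ordinal in diploid
females).  Phenotypes are latent personality factors measured by binary
items at two waves under strict measurement invariance.  Two structural
parameterizations are provided:

* cross-sectional: wave-1 and wave-2 trait factors regressed on G;
* latent change: the wave-2 factor is defined as wave-1 factor plus a
  latent difference score (autoregressive path fixed to 1, wave-2 residual
  variance fixed to 0), and the difference score is regressed on G.

The two are one-to-one reparameterizations and fit identically.  Analyses
are sex-stratified throughout; p-values across the test family are
adjusted by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import (FEMALE, MALE, WAVES, GenotypeTable,
                         ItemResponseTable, apply_analytic_filter)
from .polychoric import compute_mixed_stats, compute_poly_stats
from .sem import (FitResult, IdentificationError, SemModelSpec, fit_dwls,
                  fixed_at, free)

log = logging.getLogger(__name__)

__all__ = [
    "ChangeEstimates", "add_genetic_factor", "build_cross_sectional_spec",
    "build_latent_change_spec", "build_single_wave_spec",
    "build_observed_predictor_spec", "analysis_frame",
    "fit_cross_sectional", "fit_latent_change", "fdr_adjust",
    "genetic_factor_scores", "extreme_group_analysis", "associate_all",
]


@dataclass
class ChangeEstimates:
    change_mean: float
    change_var: float
    trait: str = ""

    def __post_init__(self) -> None:
        if self.change_var < 0:
            raise ValueError("latent change variance cannot be negative")


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------

def add_genetic_factor(spec: SemModelSpec, snps: list[str],
                       name: str = "G") -> SemModelSpec:
    """Attach the latent genetic factor: free loadings for each SNP
    indicator, variance fixed to 1.  Needs >= 3 indicators to be identified
    on its own."""
    if len(snps) < 3:
        raise IdentificationError(
            f"latent genetic factor needs >= 3 SNP indicators, got "
            f"{len(snps)} (with a fixed variance and free loadings the "
            f"2-indicator factor is under-identified)")
    if name not in spec.latents:
        spec.latents.insert(0, name)
    spec.psi[(name, name)] = fixed_at(1.0)
    for snp in snps:
        spec.loadings[(snp, name)] = free()
    return spec


def build_single_wave_spec(items: list[str], snps: list[str]
                           ) -> SemModelSpec:
    """Single-wave latent association model: trait factor from binary items,
    regressed on the latent genetic factor."""
    spec = SemModelSpec(observed=list(items) + list(snps), latents=["eta1"])
    add_genetic_factor(spec, snps)
    for it in items:
        spec.loadings[(it, "eta1")] = free()
    spec.regressions[("eta1", "G")] = free()
    spec.unit_variance.add("eta1")
    return spec


def _measurement_two_wave(spec: SemModelSpec, items: list[str],
                          invariance: str = "strict") -> None:
    """Shared two-wave measurement block: loadings and thresholds equal
    across waves, cross-wave correlated residuals, wave-2 residual
    variances fixed at 1 (strict) or free (strong)."""
    for it in items:
        spec.loadings[(f"{it}_t1", "eta1")] = free(label=f"l_{it}")
        spec.loadings[(f"{it}_t2", "eta2")] = free(label=f"l_{it}")
        spec.thresholds[f"{it}_t1"] = (free(label=f"t_{it}"),)
        spec.thresholds[f"{it}_t2"] = (free(label=f"t_{it}"),)
        spec.theta_cov[(f"{it}_t1", f"{it}_t2")] = free()
        if invariance == "strong":
            spec.theta[f"{it}_t2"] = free(1.0)


def build_cross_sectional_spec(items: list[str], snps: list[str]
                               ) -> SemModelSpec:
    """Two-wave cross-sectional association model: wave-1 and wave-2 trait
    factors (strict-invariant measurement) both regressed on G."""
    observed = ([f"{i}_t1" for i in items] + [f"{i}_t2" for i in items]
                + list(snps))
    spec = SemModelSpec(observed=observed, latents=["eta1", "eta2"])
    add_genetic_factor(spec, snps)
    _measurement_two_wave(spec, items)
    spec.regressions[("eta1", "G")] = free()
    spec.regressions[("eta2", "G")] = free()
    spec.psi[("eta2", "eta2")] = free(1.0)
    spec.psi[("eta1", "eta2")] = free(0.5)
    spec.alpha["eta2"] = free()
    spec.unit_variance.add("eta1")
    return spec


def build_latent_change_spec(items: list[str], snps: list[str]
                             ) -> SemModelSpec:
    """Latent difference score model: eta2 = eta1 + delta with the
    autoregressive path fixed at 1 and zero wave-2 residual variance; both
    eta1 and the change score delta are regressed on G; the change mean is
    a free latent mean."""
    observed = ([f"{i}_t1" for i in items] + [f"{i}_t2" for i in items]
                + list(snps))
    spec = SemModelSpec(observed=observed,
                        latents=["eta1", "delta", "eta2"])
    add_genetic_factor(spec, snps)
    _measurement_two_wave(spec, items)
    spec.regressions[("eta2", "eta1")] = fixed_at(1.0)
    spec.regressions[("eta2", "delta")] = fixed_at(1.0)
    spec.psi[("eta2", "eta2")] = fixed_at(0.0)
    spec.regressions[("eta1", "G")] = free()
    spec.regressions[("delta", "G")] = free()
    spec.psi[("delta", "delta")] = free(0.8)
    spec.psi[("eta1", "delta")] = free(-0.4)
    spec.alpha["delta"] = free()
    spec.unit_variance.add("eta1")
    return spec


def build_observed_predictor_spec(items: list[str], predictor: str
                                  ) -> SemModelSpec:
    """Latent trait factor regressed on an observed (numeric) predictor —
    the single-SNP dosage analysis and the extreme-group analysis."""
    spec = SemModelSpec(observed=list(items) + [predictor],
                        latents=["X", "eta1"])
    spec.loadings[(predictor, "X")] = fixed_at(1.0)
    spec.theta[predictor] = fixed_at(0.0)
    spec.psi[("X", "X")] = fixed_at(1.0)
    for it in items:
        spec.loadings[(it, "eta1")] = free()
    spec.regressions[("eta1", "X")] = free()
    spec.unit_variance.add("eta1")
    return spec


# ---------------------------------------------------------------------------
# data assembly
# ---------------------------------------------------------------------------

def analysis_frame(geno: GenotypeTable, items: ItemResponseTable,
                   trait_items: list[str], sex: str,
                   two_wave: bool = True) -> pd.DataFrame:
    """Sex-stratified analysis table: item columns (suffixed by wave when
    two waves are used) followed by SNP dosage columns."""
    present = set(geno.sex.unique())
    if len(present) > 1:
        geno = geno.stratum(sex)
    elif present != {sex}:
        raise ValueError(f"genotype table contains no {sex} samples")
    ids = [s for s in geno.sample_ids]
    cols = {}
    w1 = items.wide("t1").reindex(ids)
    if two_wave:
        w2 = items.wide("t2").reindex(ids)
        for it in trait_items:
            cols[f"{it}_t1"] = w1[it].to_numpy(float)
        for it in trait_items:
            cols[f"{it}_t2"] = w2[it].to_numpy(float)
    else:
        for it in trait_items:
            cols[it] = w1[it].to_numpy(float)
    for snp in geno.snp_ids:
        cols[snp] = geno.calls[snp].to_numpy(float)
    return pd.DataFrame(cols, index=ids)


def _wald_row(fit: FitResult, key: str, label: dict) -> dict:
    b, se = fit.param(key)
    std_key = "std_" + key
    sb, sse = fit.std_beta.get(std_key, (b, se))
    z = b / se if se > 0 else np.nan
    p = 2 * norm.sf(abs(z))
    return dict(label, std_beta=sb, se=sse, ci_low=sb - 1.96 * sse,
                ci_high=sb + 1.96 * sse, p=float(p))


def fit_cross_sectional(geno: GenotypeTable, items: ItemResponseTable,
                        trait: str, sex: str,
                        prefiltered: bool = False
                        ) -> tuple[pd.DataFrame, FitResult]:
    """Cross-sectional association of both wave factors with G; returns one
    result row per wave plus the full fit."""
    if not prefiltered:
        geno, items, _ = apply_analytic_filter(geno, items)
    t_items = items.items_for(trait)
    df = analysis_frame(geno, items, t_items, sex)
    spec = build_cross_sectional_spec(t_items, geno.snp_ids)
    stats = compute_poly_stats(df)
    fit = fit_dwls(spec, stats)
    rows = [
        _wald_row(fit, "b:eta1~G",
                  {"sex": sex, "trait": trait, "phenotype": "t1"}),
        _wald_row(fit, "b:eta2~G",
                  {"sex": sex, "trait": trait, "phenotype": "t2"}),
    ]
    return pd.DataFrame(rows), fit


def fit_latent_change(geno: GenotypeTable, items: ItemResponseTable,
                      trait: str, sex: str, prefiltered: bool = False
                      ) -> tuple[pd.DataFrame, ChangeEstimates, FitResult]:
    """Latent-change association: the change score regressed on G, with the
    estimated change mean and variance."""
    if not prefiltered:
        geno, items, _ = apply_analytic_filter(geno, items)
    t_items = items.items_for(trait)
    df = analysis_frame(geno, items, t_items, sex)
    spec = build_latent_change_spec(t_items, geno.snp_ids)
    stats = compute_poly_stats(df)
    fit = fit_dwls(spec, stats)
    row = _wald_row(fit, "b:delta~G",
                    {"sex": sex, "trait": trait, "phenotype": "change"})
    lam, psi_lat, mu_lat, *_ = fit._model._structure(fit._theta)
    di = fit._model.lat_idx["delta"]
    change = ChangeEstimates(change_mean=float(mu_lat[di]),
                             change_var=float(max(psi_lat[di, di], 0.0)),
                             trait=trait)
    return pd.DataFrame([row]), change, fit


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def fdr_adjust(p_values, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``family_size`` may exceed the number of supplied p-values (tests not
    listed are implicitly non-significant); it cannot be smaller.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = family_size if family_size is not None else len(p)
    if m < len(p):
        raise ValueError("family_size smaller than the number of tests")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# genetic factor scores and the extreme-group sensitivity analysis
# ---------------------------------------------------------------------------

def genetic_factor_scores(geno: GenotypeTable, sex: str,
                          grid: int = 201) -> pd.Series:
    """Posterior-mean genetic factor scores under the fitted probit
    measurement model of G (3 SNP indicators, factor variance 1)."""
    sub = geno.stratum(sex)
    snps = sub.snp_ids
    df = sub.calls.dropna()
    stats = compute_poly_stats(df)
    spec = SemModelSpec(observed=list(snps), latents=[])
    add_genetic_factor(spec, list(snps))
    fit = fit_dwls(spec, stats, compute_baseline=False)
    g = np.linspace(-4.5, 4.5, grid)
    logpost = np.tile(norm.logpdf(g), (len(df), 1))
    for vi, snp in enumerate(snps):
        lam = fit.estimates[f"lam:{snp}~G"]
        taus = np.array([fit.estimates[f"tau:{snp}:{c}"]
                         for c in range(len(stats.thresholds[vi]))])
        # category probabilities on the theta scale (residual sd 1)
        cum = norm.cdf(taus[:, None] - lam * g[None, :])      # K-1 x grid
        probs = np.vstack([cum, np.ones((1, grid))]) \
            - np.vstack([np.zeros((1, grid)), cum])
        probs = np.clip(probs, 1e-12, 1.0)
        codes = np.searchsorted(np.unique(df[snp].to_numpy()),
                                df[snp].to_numpy())
        logpost += np.log(probs[codes, :])
    w = np.exp(logpost - logpost.max(axis=1, keepdims=True))
    scores = (w * g[None, :]).sum(axis=1) / w.sum(axis=1)
    return pd.Series(scores, index=df.index, name="g_score")


def extreme_group_analysis(geno: GenotypeTable, items: ItemResponseTable,
                           trait: str, sex: str, fraction: float = 0.30,
                           prefiltered: bool = False) -> pd.DataFrame:
    """Top-vs-bottom genetic-score group comparison.

    Samples are ranked by posterior-mean genetic factor scores (ties broken
    deterministically by sample id); the top and bottom ``fraction`` form a
    binary group indicator which replaces G as the predictor of the wave-1
    and wave-2 trait factors.
    """
    if not prefiltered:
        geno, items, _ = apply_analytic_filter(geno, items)
    sub = geno.stratum(sex)
    scores = genetic_factor_scores(geno, sex)
    order = pd.DataFrame({"score": scores}).sort_values(
        ["score"], kind="stable").index
    k = int(round(len(order) * fraction))
    bottom = list(order[:k])
    top = list(order[-k:])
    log.info("extreme groups: %d per tail of %d (fraction %.2f)",
             k, len(order), fraction)
    t_items = items.items_for(trait)
    frame = analysis_frame(sub, items, t_items, sex)
    sel = frame.loc[bottom + top].copy()
    sel["group"] = [0.0] * len(bottom) + [1.0] * len(top)
    item_cols = [c for c in sel.columns if c not in set(sub.snp_ids) | {"group"}]
    data = sel[item_cols + ["group"]]
    stats = compute_mixed_stats(data, numeric=["group"])
    # two-wave measurement with the observed group indicator as predictor
    spec = SemModelSpec(observed=list(data.columns),
                        latents=["X", "eta1", "eta2"])
    spec.loadings[("group", "X")] = fixed_at(1.0)
    spec.theta["group"] = fixed_at(0.0)
    spec.psi[("X", "X")] = fixed_at(1.0)
    _measurement_two_wave(spec, t_items)
    spec.regressions[("eta1", "X")] = free()
    spec.regressions[("eta2", "X")] = free()
    spec.psi[("eta2", "eta2")] = free(1.0)
    spec.psi[("eta1", "eta2")] = free(0.5)
    spec.alpha["eta2"] = free()
    spec.unit_variance.add("eta1")
    fit = fit_dwls(spec, stats)
    rows = [
        _wald_row(fit, "b:eta1~X", {"sex": sex, "trait": trait,
                                    "phenotype": "t1_extreme",
                                    "n_group": 2 * k}),
        _wald_row(fit, "b:eta2~X", {"sex": sex, "trait": trait,
                                    "phenotype": "t2_extreme",
                                    "n_group": 2 * k}),
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full association sweep
# ---------------------------------------------------------------------------

def associate_all(geno: GenotypeTable, items: ItemResponseTable,
                  traits=("extraversion", "neuroticism"),
                  sexes=(MALE, FEMALE), family_size: int = 12
                  ) -> pd.DataFrame:
    """All genetic association tests (sex x trait x {t1, t2, change}) with
    BH-FDR adjustment over the declared family."""
    geno, items, _ = apply_analytic_filter(geno, items)
    rows = []
    for sex in sexes:
        if (geno.sex == sex).sum() == 0:
            continue
        for trait in traits:
            cs, _ = fit_cross_sectional(geno, items, trait, sex,
                                        prefiltered=True)
            ch, est, _ = fit_latent_change(geno, items, trait, sex,
                                           prefiltered=True)
            ch["change_mean"] = est.change_mean
            ch["change_var"] = est.change_var
            rows.extend([cs, ch])
    out = pd.concat(rows, ignore_index=True)
    out["fdr_p"] = fdr_adjust(out["p"].to_numpy(), family_size=family_size)
    return out
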