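"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-wave study of binary personality items with
three X-linked SNPs in strong mutual LD:

* SNP genotypes arise either from a fitted maximum-entropy haplotype
  distribution (``generate_snps``: target MAFs and pairwise allelic r), or
  from a latent genetic factor whose standardized SNP-liability loadings
  mirror the analysis model (``generate_full_study``).
* Binary items follow a liability-threshold model: item = 1 iff
  lambda * eta + eps > tau, with standard-normal residuals and optional
  cross-wave residual correlation for repeated items.
* Genetic effects are injected on the wave-1 factor (``beta_cross``) and on
  the standardized latent change score (``beta_change``); variance explained
  equals beta^2 on the standardized scale.

Default parameter values encode the published cohort structure (male
n=1160 / female n=1180; MAFs 0.22-0.30; pairwise LD r 0.52-0.79; item
loadings 0.24-0.90; endorsement rates 0.17-0.76; cross-wave latent
correlations ~0.48-0.59).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtri

from .data_model import (FEMALE, MALE, WAVES, GenotypeTable,
                         ItemResponseTable, SnpMeta)

__all__ = [
    "StratumParams", "SimConfig", "SyntheticCohort",
    "default_config", "power_template",
    "fit_maxent_haplotypes", "generate_snps", "generate_items",
    "generate_full_study",
]

SNP_IDS = ("rs3788862", "rs5906957", "rs979606")

# --- published cohort structure (genotype side) ----------------------------
MAF = {MALE: np.array([0.300, 0.240, 0.300]),
       FEMALE: np.array([0.280, 0.220, 0.290])}
LD_R = {MALE: np.array([[1.00, 0.68, 0.75],
                        [0.68, 1.00, 0.52],
                        [0.75, 0.52, 1.00]]),
        FEMALE: np.array([[1.00, 0.70, 0.79],
                          [0.70, 1.00, 0.56],
                          [0.79, 0.56, 1.00]])}
SNP_LOADINGS = {MALE: np.array([0.989, 0.989, 0.984]),
                FEMALE: np.array([0.968, 0.968, 0.959])}

# --- measurement model (item side): loadings and endorsement rates ---------
EXTRAVERSION_ITEMS = [f"E{i}" for i in range(1, 7)]
NEUROTICISM_ITEMS = [f"N{i}" for i in range(1, 7)]

LOADINGS = {
    (MALE, "extraversion", "t1"): [0.417, 0.428, 0.626, 0.689, 0.286, 0.239],
    (MALE, "extraversion", "t2"): [0.514, 0.527, 0.724, 0.779, 0.363, 0.306],
    (MALE, "neuroticism", "t1"): [0.676, 0.520, 0.518, 0.571, 0.808, 0.879],
    (MALE, "neuroticism", "t2"): [0.720, 0.568, 0.566, 0.619, 0.841, 0.902],
    (FEMALE, "extraversion", "t1"): [0.392, 0.520, 0.660, 0.742, 0.296, 0.284],
    (FEMALE, "extraversion", "t2"): [0.447, 0.581, 0.717, 0.792, 0.341, 0.328],
    (FEMALE, "neuroticism", "t1"): [0.620, 0.571, 0.576, 0.549, 0.859, 0.885],
    (FEMALE, "neuroticism", "t2"): [0.656, 0.608, 0.613, 0.586, 0.879, 0.902],
}
ENDORSEMENT = {
    (MALE, "extraversion", "t1"): [0.306, 0.340, 0.305, 0.172, 0.318, 0.321],
    (MALE, "extraversion", "t2"): [0.200, 0.405, 0.265, 0.232, 0.445, 0.318],
    (MALE, "neuroticism", "t1"): [0.547, 0.456, 0.712, 0.494, 0.627, 0.649],
    (MALE, "neuroticism", "t2"): [0.506, 0.521, 0.584, 0.410, 0.596, 0.637],
    (FEMALE, "extraversion", "t1"): [0.437, 0.291, 0.451, 0.218, 0.332, 0.358],
    (FEMALE, "extraversion", "t2"): [0.322, 0.397, 0.443, 0.256, 0.411, 0.342],
    (FEMALE, "neuroticism", "t1"): [0.224, 0.355, 0.637, 0.340, 0.504, 0.427],
    (FEMALE, "neuroticism", "t2"): [0.205, 0.361, 0.572, 0.269, 0.538, 0.481],
}

# factor order (trait, wave); correlations from the fitted strict model
FACTOR_CORR = {
    MALE: {("extraversion", "extraversion"): 0.592,
           ("neuroticism", "neuroticism"): 0.526,
           ("extraversion_t1", "neuroticism_t1"): -0.220,
           ("extraversion_t1", "neuroticism_t2"): -0.221,
           ("extraversion_t2", "neuroticism_t1"): -0.077,
           ("extraversion_t2", "neuroticism_t2"): -0.169},
    FEMALE: {("extraversion", "extraversion"): 0.565,
             ("neuroticism", "neuroticism"): 0.479,
             ("extraversion_t1", "neuroticism_t1"): -0.279,
             ("extraversion_t1", "neuroticism_t2"): -0.248,
             ("extraversion_t2", "neuroticism_t1"): -0.189,
             ("extraversion_t2", "neuroticism_t2"): -0.312},
}


class FeasibilityError(ValueError):
    """MAF/LD targets admit no valid haplotype distribution."""


@dataclass
class StratumParams:
    """Generator parameters for one sex stratum."""

    sex: str
    n: int
    snp_ids: tuple[str, ...] = SNP_IDS
    snp_mafs: np.ndarray = None
    snp_ld_r: np.ndarray = None
    snp_loadings: np.ndarray = None
    traits: tuple[str, ...] = ("extraversion", "neuroticism")
    item_ids: dict = None
    loadings: dict = None      # (trait, wave) -> array
    thresholds: dict = None    # (trait, wave) -> array, probit scale
    cross_wave_corr: dict = None   # trait -> latent corr between waves
    cross_trait_corr: dict = None  # ((trait,wave),(trait,wave)) -> corr

    def factor_labels(self) -> list[tuple[str, str]]:
        return [(t, w) for t in self.traits for w in WAVES]

    def factor_corr_matrix(self) -> np.ndarray:
        labels = self.factor_labels()
        k = len(labels)
        m = np.eye(k)
        for a in range(k):
            for b in range(a + 1, k):
                (ta, wa), (tb, wb) = labels[a], labels[b]
                if ta == tb:
                    r = self.cross_wave_corr[ta]
                else:
                    key = (f"{ta}_{wa}", f"{tb}_{wb}")
                    rkey = (f"{tb}_{wb}", f"{ta}_{wa}")
                    r = self.cross_trait_corr.get(key,
                        self.cross_trait_corr.get(rkey, 0.0))
                m[a, b] = m[b, a] = r
        return m


@dataclass
class SimConfig:
    """Full study configuration; the defaults are the study conditions."""

    male: StratumParams | None
    female: StratumParams | None
    beta_cross: dict = field(default_factory=dict)    # trait -> std effect
    beta_change: dict = field(default_factory=dict)   # trait -> std effect
    residual_cross_wave_corr: float = 0.2
    missing_rate: float = 0.0
    single_snp_effect: tuple[int, float] | None = None
    seed: int = 0

    @property
    def n_male(self) -> int:
        return self.male.n if self.male else 0

    @property
    def n_female(self) -> int:
        return self.female.n if self.female else 0


@dataclass
class SyntheticCohort:
    geno: GenotypeTable
    items: ItemResponseTable
    truth: dict

    @property
    def config(self) -> SimConfig:
        return self.truth["config"]


def _stratum_defaults(sex: str, n: int, traits, invariance: str) -> StratumParams:
    item_ids = {"extraversion": EXTRAVERSION_ITEMS,
                "neuroticism": NEUROTICISM_ITEMS}
    loadings, thresholds = {}, {}
    for t in traits:
        for w in WAVES:
            src_wave = "t1" if invariance == "strict" else w
            lam = np.array(LOADINGS[(sex, t, src_wave)])
            p = np.array(ENDORSEMENT[(sex, t, src_wave)])
            loadings[(t, w)] = lam
            thresholds[(t, w)] = ndtri(1.0 - p)   # item=1 iff liability > tau
    cross_wave = {t: FACTOR_CORR[sex][(t, t)] for t in traits}
    cross_trait = {k: v for k, v in FACTOR_CORR[sex].items()
                   if isinstance(k[0], str) and "_" in k[0]}
    return StratumParams(
        sex=sex, n=n, snp_mafs=MAF[sex].copy(), snp_ld_r=LD_R[sex].copy(),
        snp_loadings=SNP_LOADINGS[sex].copy(), traits=tuple(traits),
        item_ids={t: item_ids[t] for t in traits},
        loadings=loadings, thresholds=thresholds,
        cross_wave_corr=cross_wave, cross_trait_corr=cross_trait)


def default_config(n_male: int = 1160, n_female: int = 1180,
                   traits=("extraversion", "neuroticism"),
                   beta_cross: dict | None = None,
                   beta_change: dict | None = None,
                   invariance: Literal["empirical", "strict"] = "empirical",
                   missing_rate: float = 0.0, seed: int = 0) -> SimConfig:
    """Study-structure defaults; ``invariance='strict'`` copies wave-1
    loadings/thresholds to wave 2 (used when the generating model should
    satisfy strict invariance exactly)."""
    male = _stratum_defaults(MALE, n_male, traits, invariance) if n_male else None
    female = (_stratum_defaults(FEMALE, n_female, traits, invariance)
              if n_female else None)
    return SimConfig(male=male, female=female,
                     beta_cross=dict(beta_cross or {}),
                     beta_change=dict(beta_change or {}),
                     missing_rate=missing_rate, seed=seed)


def power_template(effect_variance: float = 0.0, phenotype: str = "cross_sectional",
                   n: int = 1160, seed: int = 0,
                   beta_cross_fixed: float | None = None) -> SimConfig:
    """Single-trait male template for Monte Carlo power runs.

    The generating model satisfies strict invariance; the injected effect is
    beta = sqrt(effect_variance) on the standardized latent scale, applied
    to the wave-1 factor (cross_sectional) or the latent change (change).
    """
    if not 0 <= effect_variance < 1:
        raise ValueError("effect_variance must be in [0, 1)")
    beta = float(np.sqrt(effect_variance))
    cfg = default_config(n_male=n, n_female=0, traits=("extraversion",),
                         invariance="strict", seed=seed)
    if phenotype == "cross_sectional":
        cfg.beta_cross = {"extraversion": beta}
    elif phenotype == "change":
        cfg.beta_change = {"extraversion": beta}
        if beta_cross_fixed is not None:
            cfg.beta_cross = {"extraversion": beta_cross_fixed}
    else:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    return cfg


# ---------------------------------------------------------------------------
# SNP generation: maximum-entropy haplotype distribution
# ---------------------------------------------------------------------------

def fit_maxent_haplotypes(mafs, r_matrix) -> np.ndarray:
    """Fit the maximum-entropy distribution over 2^L haplotypes subject to
    per-locus minor-allele frequencies and pairwise allelic correlations.

    Returns frequencies indexed by the binary haplotype code (locus 0 is the
    least significant bit).  Raises FeasibilityError when a pairwise target
    violates its Frechet bound or the moment match cannot be attained.
    """
    mafs = np.asarray(mafs, dtype=float)
    r = np.asarray(r_matrix, dtype=float)
    L = len(mafs)
    if np.any(mafs <= 0) or np.any(mafs >= 1):
        raise FeasibilityError("allele frequencies must be in (0, 1)")
    sd = np.sqrt(mafs * (1 - mafs))
    pair_targets = {}
    for i in range(L):
        for j in range(i + 1, L):
            pij = mafs[i] * mafs[j] + r[i, j] * sd[i] * sd[j]
            lo = max(0.0, mafs[i] + mafs[j] - 1.0)
            hi = min(mafs[i], mafs[j])
            if not lo - 1e-12 <= pij <= hi + 1e-12:
                raise FeasibilityError(
                    f"pair ({i},{j}): target joint frequency {pij:.4f} outside "
                    f"Frechet bounds [{lo:.4f}, {hi:.4f}]")
            pair_targets[(i, j)] = pij

    haplos = np.array([[(h >> i) & 1 for i in range(L)]
                       for h in range(2 ** L)], dtype=float)
    feats = [haplos[:, i] for i in range(L)]
    feats += [haplos[:, i] * haplos[:, j] for (i, j) in pair_targets]
    F = np.column_stack(feats)
    targets = np.concatenate([mafs, list(pair_targets.values())])

    def dual(theta):
        eta = F @ theta
        m = eta.max()
        logz = m + np.log(np.exp(eta - m).sum())
        return logz - theta @ targets

    def grad(theta):
        eta = F @ theta
        p = np.exp(eta - eta.max())
        p /= p.sum()
        return F.T @ p - targets

    res = minimize(dual, np.zeros(F.shape[1]), jac=grad, method="BFGS",
                   options={"gtol": 1e-11, "maxiter": 500})
    if np.max(np.abs(grad(res.x))) > 1e-6:
        raise FeasibilityError(
            "maximum-entropy moment match failed: MAF/LD targets are jointly "
            "infeasible for a 3-locus haplotype distribution")
    eta = F @ res.x
    p = np.exp(eta - eta.max())
    return p / p.sum()


def generate_snps(params: StratumParams, rng: np.random.Generator
                  ) -> GenotypeTable:
    """Sample genotypes from the fitted haplotype distribution: one
    haplotype per male, two (random union) per female."""
    freqs = fit_maxent_haplotypes(params.snp_mafs, params.snp_ld_r)
    L = len(params.snp_mafs)
    codes = np.arange(2 ** L)
    alleles = ((codes[:, None] >> np.arange(L)[None, :]) & 1).astype(float)
    if params.sex == MALE:
        hap = rng.choice(codes, size=params.n, p=freqs)
        dos = alleles[hap]
    else:
        h1 = rng.choice(codes, size=params.n, p=freqs)
        h2 = rng.choice(codes, size=params.n, p=freqs)
        dos = alleles[h1] + alleles[h2]
    ids = [f"{params.sex[0]}{i:05d}" for i in range(params.n)]
    calls = pd.DataFrame(dos, index=ids, columns=list(params.snp_ids))
    sex = pd.Series(params.sex, index=ids)
    meta = {s: SnpMeta(snp_id=s) for s in params.snp_ids}
    return GenotypeTable(calls=calls, sex=sex, meta=meta)


# ---------------------------------------------------------------------------
# item generation: liability-threshold measurement model
# ---------------------------------------------------------------------------

def generate_items(loadings_by_wave: dict, thresholds_by_wave: dict,
                   eta_by_wave: dict, rng: np.random.Generator,
                   residual_cross_wave_corr: float = 0.0,
                   parameterization: Literal["standardized", "theta"] = "standardized",
                   ) -> dict[str, np.ndarray]:
    """Binary responses from liabilities lambda*eta + eps > tau.

    ``standardized``: residual sd = sqrt(1 - lambda^2) (unit liability
    variance, endorsement = Phi(-tau)); ``theta``: residual sd = 1
    (endorsement = Phi(-tau / sqrt(1 + lambda^2))).  Residuals of the same
    item are correlated across waves by ``residual_cross_wave_corr``.
    """
    w1, w2 = WAVES
    lam1 = np.asarray(loadings_by_wave[w1], dtype=float)
    lam2 = np.asarray(loadings_by_wave[w2], dtype=float)
    tau1 = np.asarray(thresholds_by_wave[w1], dtype=float)
    tau2 = np.asarray(thresholds_by_wave[w2], dtype=float)
    eta1 = np.asarray(eta_by_wave[w1], dtype=float)
    eta2 = np.asarray(eta_by_wave[w2], dtype=float)
    n, k = len(eta1), len(lam1)
    if parameterization == "standardized":
        if np.any(np.abs(lam1) >= 1) or np.any(np.abs(lam2) >= 1):
            raise ValueError("standardized loadings must lie in (-1, 1)")
        sd1 = np.sqrt(1 - lam1 ** 2)
        sd2 = np.sqrt(1 - lam2 ** 2)
    else:
        sd1 = np.ones(k)
        sd2 = np.ones(k)
    rr = residual_cross_wave_corr
    if not -1 < rr < 1:
        raise ValueError("residual cross-wave correlation must be in (-1, 1)")
    e1 = rng.standard_normal((n, k))
    e2 = rr * e1 + np.sqrt(1 - rr ** 2) * rng.standard_normal((n, k))
    y1 = (lam1 * eta1[:, None] + sd1 * e1 > tau1).astype(float)
    y2 = (lam2 * eta2[:, None] + sd2 * e2 > tau2).astype(float)
    return {w1: y1, w2: y2}


# ---------------------------------------------------------------------------
# full-study generation
# ---------------------------------------------------------------------------

def _latent_factors(params: StratumParams, g: np.ndarray, cfg: SimConfig,
                    rng: np.random.Generator,
                    snp_liab: np.ndarray) -> dict[tuple[str, str], np.ndarray]:
    """Phenotype factors (standardized) with the configured correlation
    structure and injected genetic effects.

    Effects: corr(G, eta_t1) = beta_cross; corr(G, change) = beta_change on
    the standardized change score, where change = eta_t2 - eta_t1 and both
    waves are standardized.
    """
    labels = params.factor_labels()
    sigma = params.factor_corr_matrix()
    c = np.zeros(len(labels))
    for idx, (trait, wave) in enumerate(labels):
        b1 = cfg.beta_cross.get(trait, 0.0)
        bd = cfg.beta_change.get(trait, 0.0)
        if abs(b1) >= 1 or abs(bd) >= 1:
            raise ValueError("beta^2 must be below 1 (variance accounting)")
        if wave == "t1":
            c[idx] = b1
        else:
            rho12 = params.cross_wave_corr[trait]
            v_delta = 2.0 * (1.0 - rho12)
            c[idx] = b1 + bd * np.sqrt(v_delta)
    if cfg.single_snp_effect is not None:
        snp_idx, b = cfg.single_snp_effect
        if abs(b) >= 1:
            raise ValueError("single-SNP beta^2 must be below 1")
        # effect runs through one SNP's liability instead of the factor G
        c = np.zeros(len(labels))
        predictor = snp_liab[:, snp_idx]
        for idx, (trait, wave) in enumerate(labels):
            if trait == params.traits[0]:
                c[idx] = b if wave == "t1" else b * params.cross_wave_corr[trait]
    else:
        predictor = g
    resid_cov = sigma - np.outer(c, c)
    eigmin = np.linalg.eigvalsh(resid_cov).min()
    if eigmin < -1e-10:
        raise ValueError(
            "injected effects exceed the variance budget of the configured "
            f"factor correlations (min residual eigenvalue {eigmin:.3e})")
    chol = np.linalg.cholesky(resid_cov + 1e-12 * np.eye(len(c)))
    z = rng.standard_normal((params.n, len(c)))
    eta = predictor[:, None] * c[None, :] + z @ chol.T
    return {lab: eta[:, i] for i, lab in enumerate(labels)}


def _genotypes_from_factor(params: StratumParams, g: np.ndarray,
                           rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """SNP dosages as categorized indicators of the genetic factor:
    liability = loading*G + residual, cut at the MAF-implied thresholds
    (one threshold for hemizygous males, two for diploid females)."""
    lam = np.asarray(params.snp_loadings, dtype=float)
    mafs = np.asarray(params.snp_mafs, dtype=float)
    if np.any(mafs <= 0) or np.any(mafs >= 1):
        raise ValueError("MAF targets must be in (0, 1)")
    n, k = len(g), len(lam)
    liab = lam * g[:, None] + np.sqrt(1 - lam ** 2) * rng.standard_normal((n, k))
    if params.sex == MALE:
        tau = ndtri(1.0 - mafs)
        dos = (liab > tau).astype(float)
    else:
        t1 = ndtri((1.0 - mafs) ** 2)
        t2 = ndtri(1.0 - mafs ** 2)
        dos = (liab > t1).astype(float) + (liab > t2).astype(float)
    return dos, liab


def _apply_missing(arr: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate <= 0:
        return arr
    mask = rng.random(arr.shape) < rate
    out = arr.astype(float).copy()
    out[mask] = np.nan
    return out


def generate_full_study(config: SimConfig) -> SyntheticCohort:
    """Generate a full cohort: genetic factor, SNP indicators, phenotype
    factors with injected effects, and binary items at both waves.

    Deterministic under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    geno_frames, sex_parts, item_frames, truth = [], [], [], {}
    traits_seen: dict[str, str] = {}
    for params in (config.male, config.female):
        if params is None or params.n == 0:
            continue
        g = rng.standard_normal(params.n)
        dos, snp_liab = _genotypes_from_factor(params, g, rng)
        eta = _latent_factors(params, g, config, rng, snp_liab)
        ids = [f"{params.sex[0]}{i:05d}" for i in range(params.n)]

        calls = _apply_missing(dos, config.missing_rate, rng)
        geno_frames.append(pd.DataFrame(calls, index=ids,
                                        columns=list(params.snp_ids)))
        sex_parts.append(pd.Series(params.sex, index=ids))

        item_cols: dict[str, dict[str, np.ndarray]] = {w: {} for w in WAVES}
        for trait in params.traits:
            resp = generate_items(
                {w: params.loadings[(trait, w)] for w in WAVES},
                {w: params.thresholds[(trait, w)] for w in WAVES},
                {w: eta[(trait, w)] for w in WAVES}, rng,
                residual_cross_wave_corr=config.residual_cross_wave_corr)
            for w in WAVES:
                vals = _apply_missing(resp[w], config.missing_rate, rng)
                for j, item in enumerate(params.item_ids[trait]):
                    item_cols[w][item] = vals[:, j]
                    traits_seen[item] = trait
        for w in WAVES:
            frame = pd.DataFrame(item_cols[w])
            frame.insert(0, "wave", w)
            frame.insert(0, "sample_id", ids)
            item_frames.append(frame)

        tdf = pd.DataFrame({"G": g}, index=ids)
        for (trait, wave), vals in eta.items():
            tdf[f"{trait}_{wave}"] = vals
        for j, snp in enumerate(params.snp_ids):
            tdf[f"liab_{snp}"] = snp_liab[:, j]
        truth[params.sex] = tdf

    geno = GenotypeTable(calls=pd.concat(geno_frames),
                         sex=pd.concat(sex_parts),
                         meta={s: SnpMeta(snp_id=s)
                               for s in geno_frames[0].columns})
    items = ItemResponseTable(pd.concat(item_frames, ignore_index=True),
                              traits_seen)
    truth["config"] = copy.deepcopy(config)
    return SyntheticCohort(geno=geno, items=items, truth=truth)
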