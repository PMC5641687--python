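"""Shared fixtures: small literal fixtures plus session-scoped Monte Carlo
batches reused by several calibration tests."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from latgen import synthetic as syn
from latgen.association import build_latent_change_spec, build_single_wave_spec
from latgen.data_model import GenotypeTable, ItemResponseTable
from latgen.polychoric import compute_poly_stats
from latgen.sem import fit_dwls

# published item endorsement bookkeeping: (trait_wave, sex, printed %,
# yes count, printed no %, no count) for every binary item row
ITEM_COUNT_ROWS = [
    ("extraversion_t1", "male", 0.306, 279, 0.694, 634),
    ("extraversion_t1", "male", 0.340, 294, 0.660, 571),
    ("extraversion_t1", "male", 0.305, 255, 0.695, 580),
    ("extraversion_t1", "male", 0.172, 151, 0.828, 727),
    ("extraversion_t1", "male", 0.318, 299, 0.682, 641),
    ("extraversion_t1", "male", 0.321, 287, 0.679, 608),
    ("neuroticism_t1", "male", 0.547, 538, 0.453, 446),
    ("neuroticism_t1", "male", 0.456, 452, 0.544, 539),
    ("neuroticism_t1", "male", 0.712, 694, 0.288, 281),
    ("neuroticism_t1", "male", 0.494, 476, 0.506, 487),
    ("neuroticism_t1", "male", 0.627, 608, 0.373, 361),
    ("neuroticism_t1", "male", 0.649, 628, 0.351, 340),
    ("extraversion_t2", "male", 0.200, 207, 0.800, 826),
    ("extraversion_t2", "male", 0.405, 403, 0.595, 591),
    ("extraversion_t2", "male", 0.265, 266, 0.735, 736),
    ("extraversion_t2", "male", 0.232, 233, 0.768, 770),
    ("extraversion_t2", "male", 0.445, 461, 0.555, 574),
    ("extraversion_t2", "male", 0.318, 313, 0.682, 672),
    ("neuroticism_t2", "male", 0.506, 528, 0.494, 515),
    ("neuroticism_t2", "male", 0.521, 546, 0.479, 501),
    ("neuroticism_t2", "male", 0.584, 609, 0.416, 433),
    ("neuroticism_t2", "male", 0.410, 424, 0.590, 610),
    ("neuroticism_t2", "male", 0.596, 613, 0.404, 415),
    ("neuroticism_t2", "male", 0.637, 664, 0.363, 378),
    ("extraversion_t1", "female", 0.437, 405, 0.563, 522),
    ("extraversion_t1", "female", 0.291, 266, 0.709, 647),
    ("extraversion_t1", "female", 0.451, 385, 0.549, 468),
    ("extraversion_t1", "female", 0.218, 193, 0.782, 692),
    ("extraversion_t1", "female", 0.332, 329, 0.668, 663),
    ("extraversion_t1", "female", 0.358, 335, 0.642, 602),
    ("neuroticism_t1", "female", 0.224, 234, 0.776, 809),
    ("neuroticism_t1", "female", 0.355, 365, 0.645, 664),
    ("neuroticism_t1", "female", 0.637, 649, 0.363, 370),
    ("neuroticism_t1", "female", 0.340, 344, 0.660, 668),
    ("neuroticism_t1", "female", 0.504, 502, 0.496, 494),
    ("neuroticism_t1", "female", 0.427, 430, 0.573, 576),
    ("extraversion_t2", "female", 0.322, 346, 0.678, 728),
    ("extraversion_t2", "female", 0.397, 421, 0.603, 640),
    ("extraversion_t2", "female", 0.443, 462, 0.557, 580),
    ("extraversion_t2", "female", 0.256, 261, 0.744, 759),
    ("extraversion_t2", "female", 0.411, 442, 0.589, 634),
    ("extraversion_t2", "female", 0.342, 351, 0.658, 676),
    ("neuroticism_t2", "female", 0.205, 226, 0.795, 876),
    ("neuroticism_t2", "female", 0.361, 397, 0.639, 704),
    ("neuroticism_t2", "female", 0.572, 625, 0.428, 468),
    ("neuroticism_t2", "female", 0.269, 293, 0.731, 795),
    ("neuroticism_t2", "female", 0.538, 586, 0.462, 504),
    ("neuroticism_t2", "female", 0.481, 526, 0.519, 568),
]

# female genotype counts (AA-coded 0 / heterozygous / minor-homozygous) and
# male allele counts for each of the three SNPs
FEMALE_GENOTYPE_COUNTS = {
    "rs3788862": (618, 462, 100),
    "rs5906957": (713, 406, 61),
    "rs979606": (610, 461, 109),
}
MALE_ALLELE_COUNTS = {
    "rs3788862": (816, 344),
    "rs5906957": (885, 275),
    "rs979606": (811, 349),
}


@pytest.fixture(scope="session")
def table_counts():
    return ITEM_COUNT_ROWS


def genotype_table_from_counts(female_counts, male_counts=None
                               ) -> GenotypeTable:
    """Expand per-SNP genotype counts into an explicit GenotypeTable."""
    frames = []
    sexes = []
    if female_counts:
        n_f = sum(next(iter(female_counts.values())))
        cols = {}
        for snp, (n0, n1, n2) in female_counts.items():
            cols[snp] = np.repeat([0.0, 1.0, 2.0], [n0, n1, n2])
        idx = [f"f{i}" for i in range(n_f)]
        frames.append(pd.DataFrame(cols, index=idx))
        sexes.append(pd.Series("female", index=idx))
    if male_counts:
        n_m = sum(next(iter(male_counts.values())))
        cols = {}
        for snp, (n0, n1) in male_counts.items():
            cols[snp] = np.repeat([0.0, 1.0], [n0, n1])
        idx = [f"m{i}" for i in range(n_m)]
        frames.append(pd.DataFrame(cols, index=idx))
        sexes.append(pd.Series("male", index=idx))
    return GenotypeTable(calls=pd.concat(frames), sex=pd.concat(sexes))


@pytest.fixture()
def small_tables():
    """4-sample toy genotype + item tables (2 males, 2 females, 3 SNPs)."""
    calls = pd.DataFrame(
        {"snp1": [0.0, 1.0, 2.0, 1.0], "snp2": [1.0, 0.0, 1.0, np.nan],
         "snp3": [0.0, 1.0, 0.0, 2.0]},
        index=["m1", "m2", "f1", "f2"])
    sex = pd.Series(["male", "male", "female", "female"],
                    index=calls.index)
    geno = GenotypeTable(calls=calls, sex=sex)
    rows = []
    for wave in ("t1", "t2"):
        for sid in calls.index:
            rows.append({"sample_id": sid, "wave": wave,
                         "i1": 1.0, "i2": 0.0, "i3": 1.0})
    items = ItemResponseTable(pd.DataFrame(rows),
                              {"i1": "extraversion", "i2": "extraversion",
                               "i3": "neuroticism"})
    return geno, items


def _study_seed(base: int, rep: int) -> int:
    return (base * 7919 + rep) % (2 ** 31 - 1)


@pytest.fixture(scope="session")
def change_recovery_batch():
    """300 latent-change fits at the observed effect sizes (beta_cross =
    -0.167, beta_change = 0.197), n=1160 males; returns per-replicate
    standardized estimates and SEs for both structural coefficients."""
    reps = 300
    out = {"b1": [], "se1": [], "bd": [], "sed": []}
    items = syn.EXTRAVERSION_ITEMS
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(reps):
            cfg = syn.power_template(effect_variance=0.197 ** 2,
                                     phenotype="change", n=1160,
                                     seed=_study_seed(11, rep),
                                     beta_cross_fixed=-0.167)
            coh = syn.generate_full_study(cfg)
            w1 = coh.items.wide("t1")[items]
            w2 = coh.items.wide("t2")[items]
            df = (w1.rename(columns={i: f"{i}_t1" for i in items})
                  .join(w2.rename(columns={i: f"{i}_t2" for i in items}))
                  .join(coh.geno.calls))
            fit = fit_dwls(build_latent_change_spec(
                items, list(coh.geno.snp_ids)), compute_poly_stats(df),
                compute_baseline=False)
            b1, se1 = fit.std_beta["std_b:eta1~G"]
            bd, sed = fit.std_beta["std_b:delta~G"]
            out["b1"].append(b1); out["se1"].append(se1)
            out["bd"].append(bd); out["sed"].append(sed)
    return {k: np.array(v) for k, v in out.items()}


@pytest.fixture(scope="session")
def null_association_batch():
    """300 cross-sectional fits under the null generator (no genetic
    effect), n=1160 males."""
    reps = 300
    items = syn.EXTRAVERSION_ITEMS
    bs, ses = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(reps):
            cfg = syn.power_template(effect_variance=0.0, n=1160,
                                     seed=_study_seed(13, rep))
            coh = syn.generate_full_study(cfg)
            df = coh.items.wide("t1")[items].join(coh.geno.calls)
            fit = fit_dwls(build_single_wave_spec(
                items, list(coh.geno.snp_ids)), compute_poly_stats(df),
                compute_baseline=False)
            b, se = fit.std_beta["std_b:eta1~G"]
            bs.append(b); ses.append(se)
    return {"b": np.array(bs), "se": np.array(ses)}
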