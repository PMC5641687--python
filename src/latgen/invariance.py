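"""Longitudinal measurement-invariance ladder for two-wave binary items.

Three nested models per sex stratum:

* configural — same factor structure at both waves, all loadings and
  thresholds free, residual variances fixed at 1 (theta scale), cross-wave
  correlated residuals for each repeated item;
* strong — loadings and thresholds constrained equal across waves (the two
  cannot be separated for binary ratings, so they are constrained jointly);
  wave-2 factor variances, factor means and item residual variances are
  then identified and freed;
* strict — wave-2 residual variances constrained back to the wave-1 value
  of 1.

Model comparison follows change-in-fit-index rules (ΔRMSEA < 0.015,
ΔCFI and ΔTLI < 0.01); scaled chi-square difference tests are reported
alongside but are not decisive, since with large samples they reject
trivially small deviations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import MALE, GenotypeTable, ItemResponseTable
from .polychoric import compute_poly_stats
from .sem import (FitResult, SemModelSpec, chi2_diff_test, fit_dwls,
                  fixed_at, free)

log = logging.getLogger(__name__)

__all__ = ["DeltaRules", "InvarianceLadder", "build_ladder_specs",
           "run_invariance", "LEVELS"]

LEVELS = ("configural", "strong", "strict")


@dataclass(frozen=True)
class DeltaRules:
    """Fit-index change limits for accepting the more restrictive model."""

    rmsea: float = 0.015
    cfi: float = 0.01
    tli: float = 0.01


@dataclass
class InvarianceLadder:
    fits: dict[str, FitResult] = field(default_factory=dict)
    diffs: dict[str, tuple[float, int, float]] = field(default_factory=dict)
    delta_indices: dict[str, dict[str, float]] = field(default_factory=dict)
    decision: str = "configural"
    truncated_at: str | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for level in LEVELS:
            if level not in self.fits:
                continue
            f = self.fits[level]
            row = {"model": level, "n": f.n, "chi2": f.chi2, "df": f.df,
                   "free_parameters": len(f._names),
                   "rmsea": f.rmsea, "cfi": f.cfi, "tli": f.tli}
            if level in self.diffs:
                stat, dfd, p = self.diffs[level]
                row.update({"diff_chi2": stat, "diff_df": dfd, "diff_p": p})
            rows.append(row)
        return pd.DataFrame(rows)


def build_ladder_specs(items_by_trait: dict[str, list[str]],
                       snps: list[str] | None = None,
                       snp_thresholds: int = 1) -> dict[str, SemModelSpec]:
    """Configural / strong / strict model triple for two-wave data.

    ``items_by_trait`` maps each trait to its (>= 3, ideally) item ids; the
    same items are modeled at both waves with per-item cross-wave residual
    correlations.  When ``snps`` is given, the latent genetic factor is
    included with free correlations to every phenotype factor, as in the
    published measurement models.
    """
    all_items = [i for items in items_by_trait.values() for i in items]
    for trait, items in items_by_trait.items():
        if len(items) < 3:
            warnings.warn(f"trait {trait!r} has {len(items)} items; a "
                          "single-factor model needs >= 3 for identification")
    observed = ([f"{i}_t1" for i in all_items]
                + [f"{i}_t2" for i in all_items] + list(snps or []))

    specs = {}
    for level in LEVELS:
        factors = []
        for trait in items_by_trait:
            factors += [f"{trait}_t1", f"{trait}_t2"]
        spec = SemModelSpec(observed=list(observed), latents=list(factors))
        for trait, items in items_by_trait.items():
            for it in items:
                if level == "configural":
                    spec.loadings[(f"{it}_t1", f"{trait}_t1")] = free()
                    spec.loadings[(f"{it}_t2", f"{trait}_t2")] = free()
                    spec.thresholds[f"{it}_t1"] = (free(),)
                    spec.thresholds[f"{it}_t2"] = (free(),)
                else:
                    spec.loadings[(f"{it}_t1", f"{trait}_t1")] = \
                        free(label=f"l_{it}")
                    spec.loadings[(f"{it}_t2", f"{trait}_t2")] = \
                        free(label=f"l_{it}")
                    spec.thresholds[f"{it}_t1"] = (free(label=f"t_{it}"),)
                    spec.thresholds[f"{it}_t2"] = (free(label=f"t_{it}"),)
                spec.theta_cov[(f"{it}_t1", f"{it}_t2")] = free()
                if level == "strong":
                    spec.theta[f"{it}_t2"] = free(1.0)
            spec.psi[(f"{trait}_t1", f"{trait}_t1")] = fixed_at(1.0)
            if level == "configural":
                spec.psi[(f"{trait}_t2", f"{trait}_t2")] = fixed_at(1.0)
            else:
                spec.psi[(f"{trait}_t2", f"{trait}_t2")] = free(1.0)
                spec.alpha[f"{trait}_t2"] = free()
        for a in range(len(factors)):
            for b in range(a + 1, len(factors)):
                spec.psi[(factors[a], factors[b])] = free(0.3)
        if snps:
            spec.latents.insert(0, "G")
            spec.psi[("G", "G")] = fixed_at(1.0)
            for snp in snps:
                spec.loadings[(snp, "G")] = free()
                spec.thresholds[snp] = tuple(free()
                                             for _ in range(snp_thresholds))
            for f in factors:
                spec.psi[("G", f)] = free()
        specs[level] = spec
    return specs


def run_invariance(items: ItemResponseTable,
                   geno: GenotypeTable | None = None,
                   sex: str = MALE,
                   rules: DeltaRules = DeltaRules(),
                   traits: tuple[str, ...] | None = None
                   ) -> InvarianceLadder:
    """Fit the full ladder on (analytic-filtered) data and decide the
    highest invariance level supported by the Δ-fit-index rules."""
    if traits is None:
        traits = tuple(dict.fromkeys(items.item_traits.values()))
    items_by_trait = {t: items.items_for(t) for t in traits}
    all_items = [i for ii in items_by_trait.values() for i in ii]

    w1 = items.wide("t1")[all_items]
    w2 = items.wide("t2")[all_items]
    frame = (w1.rename(columns={i: f"{i}_t1" for i in all_items})
             .join(w2.rename(columns={i: f"{i}_t2" for i in all_items})))
    snps = None
    snp_thresholds = 1
    if geno is not None:
        sub = geno.stratum(sex)
        frame = frame.join(sub.calls)
        snps = sub.snp_ids
        snp_thresholds = 1 if sex == MALE else 2
    stats = compute_poly_stats(frame)
    specs = build_ladder_specs(items_by_trait, snps=snps,
                               snp_thresholds=snp_thresholds)

    ladder = InvarianceLadder()
    previous = None
    accepted = "configural"
    warm: dict = {}
    for level in LEVELS:
        fit = fit_dwls(specs[level], stats, warm_start=warm)
        ladder.fits[level] = fit
        if not fit.converged:
            log.warning("invariance ladder truncated: %s did not converge",
                        level)
            ladder.truncated_at = level
            break
        if previous is not None:
            prev_fit = ladder.fits[previous]
            try:
                ladder.diffs[level] = chi2_diff_test(
                    fit, prev_fit, allow_reparameterized=True)
            except ValueError as exc:
                log.warning("difference test unavailable (%s)", exc)
            # decisions use conventionally truncated indices (TLI can
            # exceed 1 on near-perfectly fitting models and its raw change
            # is then pure noise); the untruncated TLI stays in the report
            deltas = {"rmsea": fit.rmsea - prev_fit.rmsea,
                      "cfi": prev_fit.cfi - fit.cfi,
                      "tli": min(prev_fit.tli, 1.0) - min(fit.tli, 1.0)}
            ladder.delta_indices[level] = deltas
            ok = (deltas["rmsea"] < rules.rmsea
                  and deltas["cfi"] < rules.cfi
                  and deltas["tli"] < rules.tli)
            if ok and accepted == previous:
                accepted = level
        # warm-start the next (more restrictive) step: pooled cross-wave
        # values for the newly constrained parameters, estimates elsewhere
        warm = dict(fit.estimates)
        if level == "configural":
            for trait, its in items_by_trait.items():
                for it in its:
                    l1 = fit.estimates.get(f"lam:{it}_t1~{trait}_t1")
                    l2 = fit.estimates.get(f"lam:{it}_t2~{trait}_t2")
                    t1 = fit.estimates.get(f"tau:{it}_t1:0")
                    t2 = fit.estimates.get(f"tau:{it}_t2:0")
                    if l1 is not None and l2 is not None:
                        warm[f"l_{it}"] = 0.5 * (l1 + l2)
                    if t1 is not None and t2 is not None:
                        warm[f"t_{it}"] = 0.5 * (t1 + t2)
        previous = level
    ladder.decision = accepted
    return ladder
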