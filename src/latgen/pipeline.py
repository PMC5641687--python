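"""End-to-end study replication on synthetic data.

Stages: simulate -> QC -> measurement invariance -> association (cross-
sectional + latent change, FDR) -> Monte Carlo power.  All randomness
flows from a single master seed recorded in the run manifest; rerunning
with the same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import associate_all, extreme_group_analysis
from .data_model import (FEMALE, MALE, apply_analytic_filter, qc_report,
                         write_genotype_csv, write_items_csv)
from .invariance import run_invariance
from .power import PowerScenario, apriori_table, run_power
from .synthetic import SyntheticCohort, default_config, generate_full_study

log = logging.getLogger(__name__)

__all__ = ["RunManifest", "load_config", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "cohort": {
        "n_male": 1160,
        "n_female": 0,
        "traits": ["extraversion"],
        "beta_cross": {"extraversion": -0.167},
        "beta_change": {"extraversion": 0.197},
        "missing_rate": 0.0,
        "invariance": "empirical",
    },
    "association": {"family_size": 12, "extreme_fraction": 0.30,
                    "enabled": True},
    "invariance": {"enabled": True, "include_genetic_factor": True},
    "power": {"enabled": True, "reps": 250,
              "posthoc": {"cross_sectional": 0.028, "change": 0.039},
              "apriori": [0.01, 0.02, 0.03]},
}

_SCHEMA = {
    "seed": int,
    "cohort": dict, "association": dict, "invariance": dict, "power": dict,
}


def _validate(cfg: dict) -> None:
    for key, val in cfg.items():
        if key not in _SCHEMA:
            raise ValueError(f"unknown config key {key!r}")
        if not isinstance(val, _SCHEMA[key]):
            raise ValueError(f"config key {key!r} must be {_SCHEMA[key]}")
    coh = cfg.get("cohort", {})
    if coh.get("n_male", 0) < 0 or coh.get("n_female", 0) < 0:
        raise ValueError("sample sizes must be non-negative")
    if not 0 <= coh.get("missing_rate", 0.0) < 1:
        raise ValueError("missing_rate must be in [0, 1)")


def load_config(path: str | Path | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    _validate(cfg)
    return cfg


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, seconds: float,
               error: str | None = None) -> None:
        self.stages[stage] = {"status": status,
                              "seconds": round(seconds, 2)}
        if error:
            self.stages[stage]["error"] = error

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _simulate_stage(cfg: dict, out: Path) -> SyntheticCohort:
    coh_cfg = cfg["cohort"]
    sim = default_config(
        n_male=coh_cfg.get("n_male", 1160),
        n_female=coh_cfg.get("n_female", 0),
        traits=tuple(coh_cfg.get("traits", ["extraversion"])),
        beta_cross=coh_cfg.get("beta_cross"),
        beta_change=coh_cfg.get("beta_change"),
        invariance=coh_cfg.get("invariance", "empirical"),
        missing_rate=coh_cfg.get("missing_rate", 0.0),
        seed=cfg["seed"])
    cohort = generate_full_study(sim)
    write_genotype_csv(cohort.geno, out / "genotypes.csv")
    write_items_csv(cohort.items, out / "items.csv")
    for sex, tdf in cohort.truth.items():
        if isinstance(tdf, pd.DataFrame):
            tdf.to_csv(out / f"truth_{sex}.csv")
    return cohort


def run_pipeline(config: str | Path | dict | None = None,
                 out_dir: str | Path = "latgen_run") -> RunManifest:
    """Run all stages in order; a stage failure is recorded in the manifest
    and downstream stages are skipped."""
    cfg = config if isinstance(config, dict) else load_config(config)
    _validate(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=cfg["seed"])
    cohort = None
    failed = False

    def stage(name, enabled, fn):
        nonlocal failed
        if failed or not enabled:
            manifest.record(name, "skipped", 0.0)
            return None
        t0 = time.time()
        try:
            result = fn()
            manifest.record(name, "ok", time.time() - t0)
            return result
        except Exception as exc:  # record and halt downstream stages
            log.exception("stage %s failed", name)
            manifest.record(name, "failed", time.time() - t0, error=str(exc))
            failed = True
            return None

    cohort = stage("simulate", True, lambda: _simulate_stage(cfg, out))
    if cohort is not None:
        manifest.outputs["genotypes"] = str(out / "genotypes.csv")
        manifest.outputs["items"] = str(out / "items.csv")

    def qc_stage():
        rep = qc_report(cohort.geno, cohort.items)
        rep.to_tsv(out / "qc_report.tsv")
        rep.to_json(out / "qc_report.json")
        manifest.outputs["qc"] = str(out / "qc_report.tsv")
        return rep

    stage("qc", cohort is not None, qc_stage)

    sexes = [s for s, nkey in ((MALE, "n_male"), (FEMALE, "n_female"))
             if cfg["cohort"].get(nkey, 0) > 0]

    def invariance_stage():
        rows = []
        geno_f, items_f, _ = apply_analytic_filter(cohort.geno, cohort.items)
        for sex in sexes:
            sub = geno_f.stratum(sex)
            items_sub = items_f.subset_samples(sub.sample_ids)
            ladder = run_invariance(
                items_sub,
                geno=sub if cfg["invariance"].get("include_genetic_factor",
                                                  True) else None,
                sex=sex)
            summ = ladder.summary()
            summ.insert(0, "sex", sex)
            summ["decision"] = ladder.decision
            rows.append(summ)
        table = pd.concat(rows, ignore_index=True)
        table.to_csv(out / "invariance.tsv", sep="\t", index=False)
        manifest.outputs["invariance"] = str(out / "invariance.tsv")
        return table

    stage("invariance", cfg["invariance"].get("enabled", True)
          and cohort is not None, invariance_stage)

    def association_stage():
        traits = tuple(cfg["cohort"].get("traits", ["extraversion"]))
        table = associate_all(cohort.geno, cohort.items, traits=traits,
                              sexes=tuple(sexes),
                              family_size=cfg["association"]
                              .get("family_size", 12))
        table.to_csv(out / "association.tsv", sep="\t", index=False)
        frac = cfg["association"].get("extreme_fraction", 0.30)
        ext = []
        for sex in sexes:
            for trait in traits:
                ext.append(extreme_group_analysis(
                    cohort.geno, cohort.items, trait, sex, fraction=frac))
        pd.concat(ext, ignore_index=True).to_csv(
            out / "extreme_groups.tsv", sep="\t", index=False)
        manifest.outputs["association"] = str(out / "association.tsv")
        manifest.outputs["extreme_groups"] = str(out / "extreme_groups.tsv")
        return table

    stage("associate", cfg["association"].get("enabled", True)
          and cohort is not None, association_stage)

    def power_stage():
        pw = cfg["power"]
        reps = pw.get("reps", 250)
        results = []
        posthoc = pw.get("posthoc", {})
        if "cross_sectional" in posthoc:
            results.append(run_power(PowerScenario(
                "latent", "cross_sectional", posthoc["cross_sectional"],
                reps=reps, seed=cfg["seed"])))
        if "change" in posthoc:
            results.append(run_power(PowerScenario(
                "latent", "change", posthoc["change"], reps=reps,
                seed=cfg["seed"] + 1)))
        results += apriori_table(tuple(pw.get("apriori", [])), reps=reps,
                                 seed=cfg["seed"] + 2)
        table = pd.DataFrame([r.as_dict() for r in results])
        table.to_csv(out / "power.tsv", sep="\t", index=False)
        manifest.outputs["power"] = str(out / "power.tsv")
        return table

    stage("power", cfg["power"].get("enabled", True), power_stage)

    manifest.write(out / "manifest.json")
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest
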