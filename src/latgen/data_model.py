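"""Data containers, file IO and quality-control statistics.

Genotypes are stored as minor-allele dosages at X-linked loci: males are
hemizygous (0/1), females diploid (0/1/2); missing calls are NaN, never a
dosage code.  Item responses are binary yes/no (1/0) indicators observed at
two measurement waves.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

log = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"
WAVES = ("t1", "t2")
MISSING_CODES = ("", "NA", "na", ".", "nan", "NaN")

__all__ = [
    "SnpMeta", "GenotypeTable", "ItemResponseTable", "QcReport", "LdResult",
    "read_tables", "read_genotype_csv", "read_items_csv", "read_genotype_vcf",
    "write_genotype_csv", "write_items_csv",
    "apply_analytic_filter", "compute_maf", "hwe_test", "ld_pair",
    "endorsement_table", "qc_report",
]


class CodingError(ValueError):
    """Genotype coding inconsistent with the declared sex (e.g. male dosage 2)."""


@dataclass(frozen=True)
class SnpMeta:
    snp_id: str
    position: int = 0
    allele_major: str = "A"
    allele_minor: str = "G"

    def __post_init__(self) -> None:
        if self.allele_major == self.allele_minor:
            raise ValueError("major and minor allele must differ")
        if self.position < 0:
            raise ValueError("position must be non-negative")


@dataclass
class GenotypeTable:
    """Sex-aware X-linked SNP dosages.

    ``calls``: DataFrame indexed by sample_id, one float column per SNP
    (NaN = missing).  ``sex``: Series of 'male'/'female' aligned to calls.
    """

    calls: pd.DataFrame
    sex: pd.Series
    meta: dict[str, SnpMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sex = self.sex.reindex(self.calls.index)
        if self.sex.isna().any():
            raise ValueError("every sample needs a sex assignment")
        bad_sex = set(self.sex.unique()) - {MALE, FEMALE}
        if bad_sex:
            raise ValueError(f"unrecognized sex codes: {sorted(bad_sex)}")
        vals = self.calls.to_numpy(dtype=float)
        obs = vals[np.isfinite(vals)]
        if obs.size and not np.isin(obs, [0.0, 1.0, 2.0]).all():
            raise CodingError("dosages must be 0, 1 or 2 (NaN for missing)")
        males = (self.sex == MALE).to_numpy()
        if males.any():
            male_vals = vals[males]
            bad = np.isfinite(male_vals) & (male_vals == 2.0)
            if bad.any():
                row, col = np.argwhere(bad)[0]
                sample = self.calls.index[np.flatnonzero(males)[row]]
                raise CodingError(
                    f"male sample {sample!r} has diploid dosage 2 at SNP "
                    f"{self.calls.columns[col]!r}")
        if len(self.calls):
            empty = [c for c in self.calls.columns
                     if self.calls[c].notna().sum() == 0]
            if empty:
                raise ValueError(
                    f"SNP columns with no non-missing calls: {empty}")
        for snp in self.calls.columns:
            self.meta.setdefault(snp, SnpMeta(snp_id=snp))

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def sample_ids(self) -> list:
        return list(self.calls.index)

    def stratum(self, sex: str | None) -> "GenotypeTable":
        if sex is None or sex == "all":
            return self
        keep = self.sex == sex
        return GenotypeTable(self.calls.loc[keep], self.sex.loc[keep],
                             dict(self.meta))

    def complete_mask(self) -> pd.Series:
        return self.calls.notna().all(axis=1)


@dataclass
class ItemResponseTable:
    """Binary item responses at two waves.

    ``data``: long DataFrame with columns sample_id, wave and one 0/1 column
    per item.  The same items must be present at both waves (repeated
    measures).  ``item_traits`` maps item id -> trait tag.
    """

    data: pd.DataFrame
    item_traits: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"sample_id", "wave"}
        if not required.issubset(self.data.columns):
            raise ValueError("item table needs 'sample_id' and 'wave' columns")
        bad_wave = set(self.data["wave"].unique()) - set(WAVES)
        if bad_wave:
            raise ValueError(f"unrecognized waves: {sorted(bad_wave)}")
        vals = self.data[self.item_ids].to_numpy(dtype=float)
        obs = vals[np.isfinite(vals)]
        if obs.size and not np.isin(obs, [0.0, 1.0]).all():
            raise ValueError("item responses must be 0/1 (NaN for missing)")
        for item in self.item_ids:
            self.item_traits.setdefault(item, "trait")

    @property
    def item_ids(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("sample_id", "wave")]

    def items_for(self, trait: str) -> list[str]:
        return [i for i in self.item_ids if self.item_traits.get(i) == trait]

    def wide(self, wave: str) -> pd.DataFrame:
        sub = self.data[self.data["wave"] == wave]
        return sub.set_index("sample_id")[self.item_ids]

    def subset_samples(self, sample_ids: Iterable) -> "ItemResponseTable":
        keep = self.data["sample_id"].isin(set(sample_ids))
        return ItemResponseTable(self.data.loc[keep].reset_index(drop=True),
                                 dict(self.item_traits))

    def subset_items(self, items: list[str]) -> "ItemResponseTable":
        cols = ["sample_id", "wave"] + items
        traits = {i: self.item_traits[i] for i in items}
        return ItemResponseTable(self.data[cols].copy(), traits)


class LdResult(NamedTuple):
    d_prime: float
    r: float
    haplotype_freqs: np.ndarray  # (p11, p10, p01, p00) over minor alleles


@dataclass
class QcReport:
    snp_stats: pd.DataFrame       # per SNP x stratum: maf, call_rate, hwe
    item_stats: pd.DataFrame      # per item x wave: endorsement, counts
    ld: pd.DataFrame              # per SNP pair x stratum: d_prime, r
    minor_allele: dict[str, str] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# SNP statistics\n")
            self.snp_stats.to_csv(fh, sep="\t", index=False)
            fh.write("\n# LD\n")
            self.ld.to_csv(fh, sep="\t", index=False)
            fh.write("\n# Item endorsement\n")
            self.item_stats.to_csv(fh, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "snp_stats": self.snp_stats.to_dict(orient="records"),
            "item_stats": self.item_stats.to_dict(orient="records"),
            "ld": self.ld.to_dict(orient="records"),
            "minor_allele": self.minor_allele,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _read_csv(path, missing_codes) -> pd.DataFrame:
    try:
        return pd.read_csv(path, na_values=list(missing_codes),
                           keep_default_na=True, skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - message formatting
        raise ValueError(f"malformed CSV {path}: {exc}") from exc


def read_genotype_csv(path: str | Path,
                      missing_codes: Iterable[str] = MISSING_CODES) -> GenotypeTable:
    """Genotype CSV: columns sample_id, sex, one dosage column per SNP."""
    df = _read_csv(path, missing_codes)
    for col in ("sample_id", "sex"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    snps = [c for c in df.columns if c not in ("sample_id", "sex")]
    if not snps:
        raise ValueError(f"{path}: no SNP columns found")
    calls = df.set_index("sample_id")[snps].astype(float)
    sex = df.set_index("sample_id")["sex"].str.lower()
    return GenotypeTable(calls=calls, sex=sex)


def read_items_csv(path: str | Path, trait_map: Mapping[str, str] | None = None,
                   missing_codes: Iterable[str] = MISSING_CODES) -> ItemResponseTable:
    """Item CSV: columns sample_id, wave, one 0/1 column per item."""
    df = _read_csv(path, missing_codes)
    table = ItemResponseTable(df, dict(trait_map) if trait_map else {})
    waves = set(table.data["wave"].unique())
    if waves != set(WAVES):
        raise ValueError(f"{path}: expected waves {WAVES}, found {sorted(waves)}")
    return table


def read_genotype_vcf(path: str | Path, sex: Mapping[str, str]) -> GenotypeTable:
    """Read biallelic SNPs from a VCF; dosages count the ALT allele.

    Positions are 1-based per the VCF standard and kept as metadata only.
    ``sex`` maps sample id -> 'male'/'female'.  Heterozygous calls for male
    samples are a coding error at X-linked loci.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: dict[str, np.ndarray] = {}
    meta: dict[str, SnpMeta] = {}
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        snp = var.ID or f"{var.CHROM}:{var.POS}"
        # cyvcf2 genotype entries end with the phased flag; haploid calls
        # have a single allele before it
        g = np.full((len(samples), 2), np.nan)
        for si, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            for ai, a in enumerate(alleles[:2]):
                g[si, ai] = a
        dosage = np.full(len(samples), np.nan)
        for si, sample in enumerate(samples):
            alleles = g[si]
            alleles = alleles[np.isfinite(alleles)]
            if alleles.size == 0:
                continue
            if sex.get(sample) == MALE:
                uniq = np.unique(alleles)
                if len(uniq) > 1:
                    raise CodingError(
                        f"male sample {sample!r} heterozygous at {snp}")
                dosage[si] = uniq[0]
            else:
                dosage[si] = alleles.sum() if alleles.size == 2 else np.nan
        rows[snp] = dosage
        meta[snp] = SnpMeta(snp_id=snp, position=int(var.POS),
                            allele_major=var.REF, allele_minor=var.ALT[0])
    calls = pd.DataFrame(rows, index=samples)
    return GenotypeTable(calls=calls,
                         sex=pd.Series({s: sex[s] for s in samples}),
                         meta=meta)


def read_tables(genotype_path: str | Path, item_path: str | Path,
                fmt: Literal["csv", "vcf"] = "csv",
                sex: Mapping[str, str] | None = None,
                trait_map: Mapping[str, str] | None = None):
    """Read genotype and item tables together (spec'd convenience entry)."""
    if fmt == "vcf":
        if sex is None:
            raise ValueError("VCF input requires an explicit sample->sex map")
        geno = read_genotype_vcf(genotype_path, sex)
    else:
        geno = read_genotype_csv(genotype_path)
    items = read_items_csv(item_path, trait_map=trait_map)
    return geno, items


def write_genotype_csv(geno: GenotypeTable, path: str | Path) -> None:
    out = geno.calls.copy()
    out.insert(0, "sex", geno.sex)
    out.index.name = "sample_id"
    out.to_csv(path)


def write_items_csv(items: ItemResponseTable, path: str | Path) -> None:
    items.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# analytic-sample rule
# ---------------------------------------------------------------------------

def apply_analytic_filter(geno: GenotypeTable, items: ItemResponseTable
                          ) -> tuple[GenotypeTable, ItemResponseTable, dict]:
    """Retain samples with complete genotypes and >= 1 non-missing item at
    each wave; returns filtered tables plus removal counts by reason."""
    geno_ids = set(geno.sample_ids)
    item_ids = set(items.data["sample_id"].unique())
    shared = geno_ids & item_ids
    if not shared:
        raise ValueError("no samples shared between genotype and item tables")

    complete_geno = set(geno.calls.index[geno.complete_mask()])
    ok_wave = {}
    for wave in WAVES:
        wide = items.wide(wave)
        ok_wave[wave] = set(wide.index[wide.notna().any(axis=1)])
    retained = shared & complete_geno & ok_wave["t1"] & ok_wave["t2"]
    if not retained:
        raise ValueError("analytic filter removed every sample")

    counts = {
        "input": len(shared),
        "incomplete_genotype": len(shared - complete_geno),
        "no_item_t1": len(shared - ok_wave["t1"]),
        "no_item_t2": len(shared - ok_wave["t2"]),
        "retained": len(retained),
    }
    log.info("analytic filter: %s", counts)
    keep_order = [s for s in geno.sample_ids if s in retained]
    geno_f = GenotypeTable(geno.calls.loc[keep_order],
                           geno.sex.loc[keep_order], dict(geno.meta))
    items_f = items.subset_samples(retained)
    return geno_f, items_f, counts


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------

def _allele_counts(geno: GenotypeTable, snp_id: str, sex_stratum: str
                   ) -> tuple[float, float]:
    """(minor-coded allele count, total alleles): males contribute 1 allele,
    females 2."""
    sub = geno.stratum(sex_stratum)
    calls = sub.calls[snp_id]
    males = sub.sex == MALE
    m = calls[males].dropna()
    f = calls[~males].dropna()
    count = float(m.sum() + f.sum())
    total = float(len(m) + 2 * len(f))
    if total == 0:
        raise ValueError(f"no non-missing calls for {snp_id} in {sex_stratum}")
    return count, total


def compute_maf(geno: GenotypeTable, snp_id: str,
                sex_stratum: str = "all") -> float:
    """Minor allele frequency, folded to [0, 0.5].

    The minor allele is defined empirically within the stratum; if the coded
    allele exceeds 0.5 the frequency is folded.
    """
    count, total = _allele_counts(geno, snp_id, sex_stratum)
    freq = count / total
    return min(freq, 1.0 - freq)


def coded_allele_frequency(geno: GenotypeTable, snp_id: str,
                           sex_stratum: str = "all") -> float:
    count, total = _allele_counts(geno, snp_id, sex_stratum)
    return count / total


def _hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE test (conditional on allele counts), mid-free two-sided
    version summing genotype configurations no more probable than observed."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    # heterozygote count parity is fixed by the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    logs = []
    from scipy.special import gammaln

    def logprob(h):
        a = (rare - h) // 2
        b = n - a - h
        return (gammaln(n + 1) - gammaln(a + 1) - gammaln(h + 1) - gammaln(b + 1)
                + h * np.log(2) + gammaln(rare + 1) + gammaln(2 * n - rare + 1)
                - gammaln(2 * n + 1))
    logs = np.array([logprob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs = probs / probs.sum()
    obs = n_ab
    p_obs = probs[hets == obs][0]
    return float(probs[probs <= p_obs + 1e-12].sum())


def hwe_test(geno: GenotypeTable, snp_id: str,
             method: Literal["chi2", "exact"] = "chi2") -> tuple[float, float]:
    """Hardy-Weinberg test on female diploid genotypes.

    Returns (chi2, p) for the default 1-df goodness-of-fit test, or
    (nan, p) for the exact test.  Hemizygous (male) genotypes carry no HWE
    information and calling on an all-male stratum is an error.
    """
    females = geno.stratum(FEMALE)
    calls = females.calls[snp_id].dropna() if snp_id in females.calls else pd.Series(dtype=float)
    if len(calls) == 0:
        raise ValueError(
            "HWE test requires diploid (female) genotypes; none present")
    n0 = int((calls == 0).sum())
    n1 = int((calls == 1).sum())
    n2 = int((calls == 2).sum())
    n = n0 + n1 + n2
    q = (2 * n2 + n1) / (2 * n)
    if q == 0 or q == 1:
        raise ValueError(f"SNP {snp_id} is monomorphic in females")
    if method == "exact":
        return float("nan"), _hwe_exact_p(n0, n1, n2)
    exp = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2]) * n
    obs = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(chi2_dist.sf(chi2, df=1))
    return chi2, p


def _em_haplotypes(g1: np.ndarray, g2: np.ndarray, tol: float = 1e-10,
                   max_iter: int = 500) -> np.ndarray:
    """2-locus haplotype frequencies (p11, p10, p01, p00) from female
    genotype dosages via EM over double-heterozygote phase."""
    n = len(g1)
    # fixed contributions: haplotype counts determined for all but (1,1)
    idx = g1 * 3 + g2  # 0..8
    base = np.zeros(4)
    # per genotype combo, known haplotype counts (h11,h10,h01,h00)
    known = {
        0: (0, 0, 0, 2), 1: (0, 0, 1, 1), 2: (0, 0, 2, 0),
        3: (0, 1, 0, 1), 5: (1, 0, 1, 0),
        6: (0, 2, 0, 0), 7: (1, 1, 0, 0), 8: (2, 0, 0, 0),
    }
    counts = np.bincount(idx.astype(int), minlength=9).astype(float)
    for combo, contrib in known.items():
        base += counts[combo] * np.array(contrib, dtype=float)
    ndh = counts[4]  # double heterozygotes: either (h11,h00) or (h10,h01)
    p = np.full(4, 0.25)
    for _ in range(max_iter):
        w_cis = p[0] * p[3]
        w_trans = p[1] * p[2]
        tot = w_cis + w_trans
        frac = 0.5 if tot == 0 else w_cis / tot
        new_counts = base + ndh * np.array([frac, 1 - frac, 1 - frac, frac])
        p_new = new_counts / (2 * n)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new
    return p


def _ld_from_haplotypes(p: np.ndarray) -> LdResult:
    p11, p10, p01, p00 = p
    pa = p11 + p10       # minor allele at locus 1
    pb = p11 + p01
    if min(pa, pb) <= 0 or max(pa, pb) >= 1:
        raise ValueError("monomorphic locus: LD undefined")
    d = p11 - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = 0.0 if dmax == 0 else abs(d) / dmax
    r = d / np.sqrt(pa * (1 - pa) * pb * (1 - pb))
    return LdResult(d_prime=float(d_prime), r=float(r),
                    haplotype_freqs=np.asarray(p, dtype=float))


def ld_pair(geno: GenotypeTable, snp_a: str, snp_b: str,
            sex_stratum: str = MALE) -> LdResult:
    """Pairwise linkage disequilibrium (D' and r).

    Haplotypes are observed directly in hemizygous males; in females the
    phase of double heterozygotes is resolved by EM.
    """
    sub = geno.stratum(sex_stratum)
    calls = sub.calls[[snp_a, snp_b]].dropna()
    if len(calls) == 0:
        raise ValueError("no overlapping non-missing calls")
    g1 = calls[snp_a].to_numpy()
    g2 = calls[snp_b].to_numpy()
    if sex_stratum == MALE:
        # each male carries exactly one haplotype
        p11 = float(((g1 == 1) & (g2 == 1)).mean())
        p10 = float(((g1 == 1) & (g2 == 0)).mean())
        p01 = float(((g1 == 0) & (g2 == 1)).mean())
        p00 = float(((g1 == 0) & (g2 == 0)).mean())
        p = np.array([p11, p10, p01, p00])
    else:
        p = _em_haplotypes(g1, g2)
    return _ld_from_haplotypes(p)


def endorsement_table(items: ItemResponseTable,
                      wave: str | None = None) -> pd.DataFrame:
    """Per-item yes-proportion with yes/no counts over non-missing rows."""
    rows = []
    waves = WAVES if wave is None else (wave,)
    for w in waves:
        wide = items.wide(w)
        for item in items.item_ids:
            col = wide[item].dropna()
            yes = int((col == 1).sum())
            no = int((col == 0).sum())
            if yes + no == 0:
                log.warning("item %s wave %s has no responses", item, w)
                continue
            rows.append({
                "item": item, "wave": w,
                "trait": items.item_traits.get(item, ""),
                "yes": yes, "no": no,
                "endorsement": yes / (yes + no),
            })
    return pd.DataFrame(rows)


def qc_report(geno: GenotypeTable, items: ItemResponseTable) -> QcReport:
    """Assemble MAF / call-rate / HWE / LD / endorsement statistics."""
    snp_rows = []
    minor = {}
    for snp in geno.snp_ids:
        for stratum in (MALE, FEMALE):
            sub = geno.stratum(stratum)
            if len(sub.calls) == 0:
                continue
            col = sub.calls[snp]
            call_rate = float(col.notna().mean())
            freq = coded_allele_frequency(geno, snp, stratum)
            maf = min(freq, 1 - freq)
            meta = geno.meta[snp]
            minor_allele = (meta.allele_minor if freq <= 0.5
                            else meta.allele_major)
            minor[f"{snp}:{stratum}"] = minor_allele
            row = {"snp": snp, "stratum": stratum, "maf": maf,
                   "coded_freq": freq, "call_rate": call_rate,
                   "minor_allele": minor_allele,
                   "hwe_chi2": np.nan, "hwe_p": np.nan}
            if stratum == FEMALE:
                try:
                    row["hwe_chi2"], row["hwe_p"] = hwe_test(geno, snp)
                except ValueError:
                    pass
            snp_rows.append(row)
    ld_rows = []
    snps = geno.snp_ids
    for stratum in (MALE, FEMALE):
        if len(geno.stratum(stratum).calls) == 0:
            continue
        for i in range(len(snps)):
            for j in range(i + 1, len(snps)):
                try:
                    res = ld_pair(geno, snps[i], snps[j], stratum)
                except ValueError:
                    continue
                ld_rows.append({"snp_a": snps[i], "snp_b": snps[j],
                                "stratum": stratum, "d_prime": res.d_prime,
                                "r": res.r})
    return QcReport(snp_stats=pd.DataFrame(snp_rows),
                    item_stats=endorsement_table(items),
                    ld=pd.DataFrame(ld_rows), minor_allele=minor)
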