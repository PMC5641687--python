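import numpy as np
import pandas as pd
import pytest

from latgen.data_model import (CodingError, GenotypeTable, ItemResponseTable,
                               apply_analytic_filter, compute_maf,
                               endorsement_table, hwe_test, ld_pair,
                               qc_report, read_genotype_csv,
                               read_genotype_vcf, read_items_csv,
                               write_genotype_csv, write_items_csv)
from conftest import (FEMALE_GENOTYPE_COUNTS, MALE_ALLELE_COUNTS,
                      genotype_table_from_counts)


class TestIO:
    def test_csv_round_trip(self, small_tables, tmp_path):
        geno, items = small_tables
        write_genotype_csv(geno, tmp_path / "g.csv")
        write_items_csv(items, tmp_path / "i.csv")
        g2 = read_genotype_csv(tmp_path / "g.csv")
        i2 = read_items_csv(tmp_path / "i.csv",
                            trait_map=items.item_traits)
        assert (g2.sex == "male").sum() == 2
        assert (g2.sex == "female").sum() == 2
        assert g2.snp_ids == ["snp1", "snp2", "snp3"]
        pd.testing.assert_frame_equal(g2.calls, geno.calls,
                                      check_names=False)
        assert i2.item_ids == items.item_ids
        assert np.isnan(g2.calls.loc["f2", "snp2"])

    def test_male_diploid_dosage_rejected(self):
        calls = pd.DataFrame({"s1": [2.0]}, index=["m1"])
        with pytest.raises(CodingError, match="diploid dosage 2"):
            GenotypeTable(calls=calls,
                          sex=pd.Series(["male"], index=["m1"]))

    def test_vcf_male_hemizygous_dosages(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=X>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tm1\tf1\n"
            "X\t43402308\trs1\tA\tG\t.\tPASS\t.\tGT\t1\t0/1\n"
            "X\t43432254\trs2\tA\tG\t.\tPASS\t.\tGT\t0\t1/1\n")
        geno = read_genotype_vcf(vcf, {"m1": "male", "f1": "female"})
        male = geno.calls.loc["m1"]
        assert set(male.dropna()) <= {0.0, 1.0}
        assert geno.calls.loc["f1", "rs1"] == 1.0
        assert geno.calls.loc["f1", "rs2"] == 2.0
        assert geno.meta["rs1"].position == 43402308

    def test_missing_codes_accepted(self, tmp_path):
        (tmp_path / "g.csv").write_text(
            "sample_id,sex,s1\nm1,male,NA\nm2,male,1\nf1,female,.\n"
            "f2,female,2\n")
        geno = read_genotype_csv(tmp_path / "g.csv")
        assert geno.calls["s1"].isna().sum() == 2


class TestAnalyticFilter:
    def test_rule_application(self, small_tables):
        geno, items = small_tables
        # f2 is missing one SNP call -> excluded
        g2, i2, counts = apply_analytic_filter(geno, items)
        assert "f2" not in g2.sample_ids
        assert counts["incomplete_genotype"] == 1
        assert counts["retained"] == 3

    def test_wave_missing_excludes(self, small_tables):
        geno, items = small_tables
        data = items.data.copy()
        mask = (data["sample_id"] == "m1") & (data["wave"] == "t2")
        data.loc[mask, ["i1", "i2", "i3"]] = np.nan
        items2 = ItemResponseTable(data, dict(items.item_traits))
        g2, _, counts = apply_analytic_filter(geno, items2)
        assert "m1" not in g2.sample_ids
        assert counts["no_item_t2"] == 1

    def test_matches_brute_force_row_scan(self):
        rng = np.random.default_rng(7)
        n = 1000
        ids = [f"s{i}" for i in range(n)]
        calls = pd.DataFrame(rng.integers(0, 2, (n, 3)).astype(float),
                             index=ids, columns=["a", "b", "c"])
        calls[rng.random((n, 3)) < 0.05] = np.nan
        sex = pd.Series("male", index=ids)
        geno = GenotypeTable(calls=calls, sex=sex)
        rows = []
        for wave in ("t1", "t2"):
            resp = rng.integers(0, 2, (n, 2)).astype(float)
            resp[rng.random((n, 2)) < 0.3] = np.nan
            for i, sid in enumerate(ids):
                rows.append({"sample_id": sid, "wave": wave,
                             "i1": resp[i, 0], "i2": resp[i, 1]})
        items = ItemResponseTable(pd.DataFrame(rows))
        g2, _, counts = apply_analytic_filter(geno, items)
        # independent row-by-row oracle
        w1 = items.wide("t1")
        w2 = items.wide("t2")
        expected = sum(
            1 for sid in ids
            if calls.loc[sid].notna().all()
            and w1.loc[sid].notna().any() and w2.loc[sid].notna().any())
        assert counts["retained"] == expected == len(g2.sample_ids)


class TestMaf:
    def test_female_allele_counting(self):
        geno = genotype_table_from_counts(
            {"rs3788862": FEMALE_GENOTYPE_COUNTS["rs3788862"]})
        maf = compute_maf(geno, "rs3788862", "female")
        assert maf == pytest.approx((2 * 100 + 462) / 2360, abs=1e-6)

    def test_male_single_allele(self):
        geno = genotype_table_from_counts(
            None, {"rs3788862": MALE_ALLELE_COUNTS["rs3788862"]})
        assert compute_maf(geno, "rs3788862", "male") == \
            pytest.approx(344 / 1160, abs=1e-6)

    def test_monomorphic_zero(self):
        geno = genotype_table_from_counts({"s": (50, 0, 0)})
        assert compute_maf(geno, "s", "female") == 0.0

    def test_folding_invariance(self):
        # swapping allele labels (dosage -> 2 - dosage) leaves MAF unchanged
        geno = genotype_table_from_counts({"s": (10, 30, 60)})
        flipped = genotype_table_from_counts({"s": (60, 30, 10)})
        a = compute_maf(geno, "s", "female")
        b = compute_maf(flipped, "s", "female")
        assert a == pytest.approx(b)
        assert a <= 0.5


class TestHwe:
    def test_exact_hw_proportions(self):
        geno = genotype_table_from_counts({"s": (360, 480, 160)})
        chi2, p = hwe_test(geno, "s")
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_published_female_counts(self):
        geno = genotype_table_from_counts(
            {"s": FEMALE_GENOTYPE_COUNTS["rs3788862"]})
        chi2, p = hwe_test(geno, "s")
        assert chi2 == pytest.approx(1.07, abs=0.02)
        assert p > 0.05

    def test_male_stratum_unsupported(self):
        geno = genotype_table_from_counts(None, {"s": (60, 40)})
        with pytest.raises(ValueError, match="diploid"):
            hwe_test(geno, "s")

    def test_exact_variant_reasonable(self):
        geno = genotype_table_from_counts({"s": (618, 462, 100)})
        _, p_exact = hwe_test(geno, "s", method="exact")
        assert 0.01 < p_exact <= 1.0

    def test_type_one_error_calibrated(self):
        # 5000 null simulations at alpha = 0.05
        rng = np.random.default_rng(42)
        q, n = 0.3, 500
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q ** 2]
        counts = rng.multinomial(n, probs, size=5000)
        rej = 0
        from scipy.stats import chi2 as chi2_dist
        for n0, n1, n2 in counts:
            qq = (2 * n2 + n1) / (2 * n)
            exp = np.array([(1 - qq) ** 2, 2 * qq * (1 - qq), qq ** 2]) * n
            stat = (((np.array([n0, n1, n2]) - exp) ** 2) / exp).sum()
            if chi2_dist.sf(stat, 1) < 0.05:
                rej += 1
        assert 0.04 <= rej / 5000 <= 0.06


class TestLd:
    def test_self_pair_perfect(self):
        rng = np.random.default_rng(0)
        calls = pd.DataFrame({"a": rng.integers(0, 2, 500).astype(float)})
        calls["b"] = calls["a"]
        calls.index = [f"m{i}" for i in range(500)]
        geno = GenotypeTable(calls=calls,
                             sex=pd.Series("male", index=calls.index))
        res = ld_pair(geno, "a", "b", "male")
        assert res.d_prime == pytest.approx(1.0, abs=1e-9)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_male_perfect_coupling(self):
        calls = pd.DataFrame({
            "a": np.repeat([1.0, 0.0], [50, 50]),
            "b": np.repeat([1.0, 0.0], [50, 50])},
            index=[f"m{i}" for i in range(100)])
        geno = GenotypeTable(calls=calls,
                             sex=pd.Series("male", index=calls.index))
        res = ld_pair(geno, "a", "b", "male")
        assert res.d_prime == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)

    def test_female_em_recovers_truth(self):
        # generate diploid genotypes from known haplotype frequencies
        rng = np.random.default_rng(3)
        freqs = np.array([0.55, 0.15, 0.05, 0.25])  # (11, 10, 01, 00)
        alleles = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        n = 5000
        h1 = rng.choice(4, size=n, p=freqs)
        h2 = rng.choice(4, size=n, p=freqs)
        dos = alleles[h1] + alleles[h2]
        calls = pd.DataFrame(dos.astype(float), columns=["a", "b"],
                             index=[f"f{i}" for i in range(n)])
        geno = GenotypeTable(calls=calls,
                             sex=pd.Series("female", index=calls.index))
        res = ld_pair(geno, "a", "b", "female")
        assert np.allclose(res.haplotype_freqs, freqs, atol=0.02)
        assert res.haplotype_freqs.sum() == pytest.approx(1.0, abs=1e-8)

    def test_em_equals_direct_count_without_double_hets(self):
        # no (1,1) genotype combination -> phase fully observed
        calls = pd.DataFrame({
            "a": [0.0, 0, 2, 2, 0, 2, 1, 1],
            "b": [0.0, 2, 0, 2, 0, 2, 0, 2]},
            index=[f"f{i}" for i in range(8)])
        geno = GenotypeTable(calls=calls,
                             sex=pd.Series("female", index=calls.index))
        res = ld_pair(geno, "a", "b", "female")
        # direct haplotype counting over 16 chromosomes
        expected = np.array([5, 3, 3, 5]) / 16
        assert np.allclose(res.haplotype_freqs, expected, atol=1e-6)

    def test_monomorphic_error(self):
        calls = pd.DataFrame({"a": [1.0] * 10, "b": [0.0, 1.0] * 5},
                             index=[f"m{i}" for i in range(10)])
        geno = GenotypeTable(calls=calls,
                             sex=pd.Series("male", index=calls.index))
        with pytest.raises(ValueError, match="monomorphic"):
            ld_pair(geno, "a", "b", "male")


class TestEndorsement:
    def test_proportions_and_counts(self, small_tables):
        _, items = small_tables
        table = endorsement_table(items, "t1")
        row = table[table["item"] == "i1"].iloc[0]
        assert row["yes"] == 4 and row["no"] == 0
        assert row["endorsement"] == 1.0

    def test_published_count_row(self):
        # yes=279 / no=634 -> 0.306 to three decimals
        assert round(279 / (279 + 634), 3) == 0.306
        assert round(664 / (664 + 378), 3) == 0.637

    def test_qc_report_shapes(self, small_tables):
        geno, items = small_tables
        rep = qc_report(geno, items)
        assert set(rep.snp_stats["stratum"]) == {"male", "female"}
        assert {"maf", "call_rate", "hwe_p"} <= set(rep.snp_stats.columns)
        assert len(rep.item_stats) == 6  # 3 items x 2 waves
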