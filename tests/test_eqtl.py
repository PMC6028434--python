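import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hiccnet.eqtl import (GeneAnnotation, GenotypeMatrix, cis_pairs, fit_eqtl,
                          group_rank_sum, permutation_p, read_dosage_tsv,
                          read_vcf_dosages, write_dosage_tsv)

from .conftest import make_expression


def simple_annot():
    return GeneAnnotation(pd.DataFrame(
        {"chrom": ["1"], "start": [1000], "end": [2000]}, index=["geneA"]))


def geno_at(positions, chroms=None, n_samples=4):
    snps = [f"s{k}" for k in range(len(positions))]
    chroms = chroms or ["1"] * len(positions)
    rng = np.random.default_rng(0)
    dos = pd.DataFrame(rng.integers(0, 3, size=(len(snps), n_samples)),
                       index=snps, dtype=float,
                       columns=[f"S{j:03d}" for j in range(n_samples)])
    return GenotypeMatrix(dosages=dos,
                          chrom=pd.Series(chroms, index=snps),
                          pos=pd.Series(positions, index=snps))


class TestCisPairs:
    def test_inclusive_window_boundary(self):
        # gene [1000, 2000], 250 kb window: 252000 in, 252001 out
        geno = geno_at([252_000, 252_001])
        pairs = cis_pairs(["geneA"], simple_annot(), geno)
        assert ("s0", "geneA") in pairs
        assert ("s1", "geneA") not in pairs

    def test_other_chromosome_excluded(self):
        geno = geno_at([1500], chroms=["2"])
        assert cis_pairs(["geneA"], simple_annot(), geno) == []

    def test_snp_in_gene_body_paired(self):
        geno = geno_at([1500])
        assert cis_pairs(["geneA"], simple_annot(), geno) == [("s0", "geneA")]

    def test_missing_annotation_warns_and_skips(self):
        geno = geno_at([1500])
        with pytest.warns(UserWarning, match="missing annotation"):
            pairs = cis_pairs(["geneA", "ghost"], simple_annot(), geno)
        assert pairs == [("s0", "geneA")]


def eqtl_sim(rng, n=100, beta=0.0, maf=0.3, n_null_snps=0):
    """One gene + its SNP (effect beta) + optional null SNPs."""
    g = rng.binomial(2, maf, size=n).astype(float)
    age = rng.normal(55, 8, size=n)
    sex = rng.integers(0, 2, size=n)
    y = beta * g + 0.02 * age + rng.normal(size=n)
    cov = pd.DataFrame({"disease": 0, "hba1c": 5.5, "age": age, "sex": sex})
    expr = make_expression({"gene": y}, cov)
    snps = {"snp0": g}
    for k in range(n_null_snps):
        snps[f"null{k}"] = rng.binomial(2, maf, size=n).astype(float)
    dos = pd.DataFrame(snps).T
    dos.columns = expr.samples
    geno = GenotypeMatrix(
        dosages=dos,
        chrom=pd.Series("1", index=dos.index),
        pos=pd.Series(1_000_000, index=dos.index))
    return expr, geno


class TestFitEqtl:
    def test_planted_effect_detected(self):
        rng = np.random.default_rng(1)
        expr, geno = eqtl_sim(rng, beta=1.0)
        rec = fit_eqtl(expr, geno, [("snp0", "gene")])
        assert rec[0].p < 1e-4
        assert rec[0].beta == pytest.approx(1.0, abs=0.4)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(25):
            expr, geno = eqtl_sim(rng, beta=0.0, n_null_snps=19)
            pairs = [(s, "gene") for s in geno.snps]
            pvals.extend(r.p for r in fit_eqtl(expr, geno, pairs))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_age_confounding_adjusted_away(self):
        # expression driven by age only: dosage stays null
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(100):
            g = rng.binomial(2, 0.3, size=80).astype(float)
            age = rng.normal(55, 8, size=80)
            y = 0.2 * age + rng.normal(size=80)
            cov = pd.DataFrame({"disease": 0, "hba1c": 5.5, "age": age,
                                "sex": rng.integers(0, 2, size=80)})
            expr = make_expression({"gene": y}, cov)
            dos = pd.DataFrame({"snp0": g}).T
            dos.columns = expr.samples
            geno = GenotypeMatrix(dosages=dos,
                                  chrom=pd.Series("1", index=["snp0"]),
                                  pos=pd.Series(1, index=["snp0"]))
            rec = fit_eqtl(expr, geno, [("snp0", "gene")])
            hits += rec[0].p < 0.05
        assert hits <= 12

    def test_monomorphic_snp_skipped(self):
        rng = np.random.default_rng(4)
        expr, geno = eqtl_sim(rng)
        geno.dosages.loc["snp0"] = 1.0
        with pytest.warns(UserWarning, match="monomorphic"):
            rec = fit_eqtl(expr, geno, [("snp0", "gene")])
        assert rec == []

    def test_bh_fdr_invariants(self):
        rng = np.random.default_rng(5)
        expr, geno = eqtl_sim(rng, beta=0.8, n_null_snps=30)
        rec = fit_eqtl(expr, geno, [(s, "gene") for s in geno.snps])
        by_p = sorted(rec, key=lambda r: r.p)
        qs = [r.fdr_q for r in by_p]
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(r.p - 1e-12 <= r.fdr_q <= 1.0 for r in rec)


class TestPermutationP:
    def _pair(self, rng, beta, n=100):
        expr, geno = eqtl_sim(rng, beta=beta, n=n)
        y = expr.values.loc["gene"].to_numpy()
        g = geno.dosages.loc["snp0"].to_numpy()
        return y, g, expr.covariates

    def test_legacy_floor_is_one_over_nperm(self):
        rng = np.random.default_rng(6)
        y, g, cov = self._pair(rng, beta=3.0)
        p = permutation_p(y, g, cov, n_perm=1000, seed=0)
        assert p == pytest.approx(1.0 / 1000)

    def test_add_one_convention(self):
        rng = np.random.default_rng(7)
        y, g, cov = self._pair(rng, beta=3.0)
        p = permutation_p(y, g, cov, n_perm=1000, seed=0,
                          legacy_perm_floor=False)
        assert p == pytest.approx(1.0 / 1001)

    def test_null_pair_large_p(self):
        rng = np.random.default_rng(8)
        y, g, cov = self._pair(rng, beta=0.0)
        assert permutation_p(y, g, cov, n_perm=500, seed=1) > 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        y, g, cov = self._pair(rng, beta=0.3)
        assert permutation_p(y, g, cov, n_perm=300, seed=5) == \
            permutation_p(y, g, cov, n_perm=300, seed=5)

    def test_rank_correlates_with_asymptotic_p(self):
        rng = np.random.default_rng(10)
        perm, asym = [], []
        for _ in range(40):
            beta = rng.uniform(0.0, 0.6)
            expr, geno = eqtl_sim(rng, beta=beta, n=60)
            rec = fit_eqtl(expr, geno, [("snp0", "gene")])
            y = expr.values.loc["gene"].to_numpy()
            g = geno.dosages.loc["snp0"].to_numpy()
            perm.append(permutation_p(y, g, expr.covariates, n_perm=500,
                                      seed=11))
            asym.append(rec[0].p)
        rho = stats.spearmanr(perm, asym).statistic
        assert rho > 0.95


class TestGroupRankSum:
    def test_exact_small_sample_tail(self):
        # 20 equally likely orderings of 3 vs 3; fully separated -> 1/20
        u, p = group_rank_sum([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(0.05)

    def test_identical_samples_large_p(self):
        u, p = group_rank_sum([1.0, 2.0, 3.0], [1.5, 2.5, 2.0])
        assert p >= 0.35

    def test_swap_flips_one_sided_tail(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=30)
        b = rng.normal(size=30) + 1.0
        _, p_ab = group_rank_sum(a, b, alternative="less")
        _, p_ba = group_rank_sum(b, a, alternative="greater")
        assert p_ab == pytest.approx(p_ba)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            group_rank_sum([], [1.0])


class TestGenotypeIO:
    def test_dosage_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(12)
        expr, geno = eqtl_sim(rng, n_null_snps=3)
        f = tmp_path / "geno.tsv"
        write_dosage_tsv(geno, f)
        back = read_dosage_tsv(f)
        assert back.snps == geno.snps
        assert np.allclose(back.dosages.to_numpy(), geno.dosages.to_numpy())
        assert (back.pos == geno.pos).all()

    def test_vcf_gt_to_dosage(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t1|1\n"
            "2\t200\t.\tC\tT\t.\t.\t.\tGT:DP\t0/0:12\t0/1:9\n")
        geno = read_vcf_dosages(vcf)
        assert geno.dosages.loc["rs1"].tolist() == [1.0, 2.0]
        assert geno.dosages.loc["2:200"].tolist() == [0.0, 1.0]
        assert geno.chrom.tolist() == ["1", "2"]

    def test_negative_position_rejected(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(
                dosages=pd.DataFrame([[0.0]], index=["s"], columns=["a"]),
                chrom=pd.Series(["1"], index=["s"]),
                pos=pd.Series([-5], index=["s"]))
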