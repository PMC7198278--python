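"""Mixed-model scan: calibration, power, FDR, compression, thinning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metgwas.genotypes import KinshipMatrix, maf_filter, vanraden_kinship
from metgwas.gwas import (
    GwasConfig,
    MLMScan,
    bh_fdr,
    candidate_window,
    compress_kinship,
    earliest_year_phenotype,
    select_pcs_bic,
    thin_top_snps,
)
from metgwas.simulate import default_sim_config, simulate_genotypes


def brute_force_bh(p, q):
    """Independent step-up oracle scanning every i."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    m0 = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            m0 = i
    flags = np.zeros(m, dtype=bool)
    flags[order[:m0]] = True
    return flags


class TestBhFdr:
    def test_all_ones_no_rejections(self):
        assert not bh_fdr(np.ones(10), 0.1).any()

    def test_hand_computed_step_up(self):
        flags = bh_fdr([0.001, 0.01, 0.03, 0.2], q=0.1)
        # thresholds 0.025, 0.05, 0.075, 0.1 -> first three rejected
        assert flags.tolist() == [True, True, True, False]

    def test_empty_input(self):
        assert bh_fdr([], 0.1).size == 0

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            q = float(rng.uniform(0.01, 0.5))
            np.testing.assert_array_equal(bh_fdr(p, q), brute_force_bh(p, q))

    def test_rejections_monotone_in_q(self, rng):
        p = rng.random(200)
        prev = 0
        for q in [0.01, 0.05, 0.1, 0.2, 0.4]:
            n = bh_fdr(p, q).sum()
            assert n >= prev
            prev = n


@pytest.fixture(scope="module")
def scan_setup():
    cfg = default_sim_config(n_entries=300, n_snps=2000, seed=21)
    geno = maf_filter(simulate_genotypes(cfg))
    kin = vanraden_kinship(geno)
    return geno, kin


class TestSelectPcsBic:
    def test_pure_noise_selects_zero_pcs_most_seeds(self, scan_setup):
        from metgwas.genotypes import genotype_pca

        geno, kin = scan_setup
        pcs = genotype_pca(geno, 5)
        zeros = 0
        for seed in range(20):
            y = np.random.default_rng(seed).standard_normal(geno.n_entries)
            if select_pcs_bic(y, pcs, kin, 5) == 0:
                zeros += 1
        assert zeros >= 16  # >= 80% of seeds

    def test_planted_structure_confounder_selects_pcs(self, scan_setup, rng):
        from metgwas.genotypes import genotype_pca

        geno, kin = scan_setup
        pcs = genotype_pca(geno, 5)
        y = 2.0 * pcs[:, 0] / pcs[:, 0].std() + 0.3 * rng.standard_normal(
            geno.n_entries
        )
        assert select_pcs_bic(y, pcs, kin, 5) >= 1

    def test_default_budget_allows_seven_pcs(self):
        assert GwasConfig().max_pcs >= 7

    def test_budget_cannot_exceed_available(self, scan_setup):
        geno, kin = scan_setup
        with pytest.raises(ValueError):
            select_pcs_bic(np.zeros(geno.n_entries), np.zeros((geno.n_entries, 2)), kin, 5)


class TestMlmScan:
    def test_permuted_phenotypes_give_uniform_pvalues(self, scan_setup):
        geno, kin = scan_setup
        rng = np.random.default_rng(17)
        base = rng.standard_normal(geno.n_entries)
        pooled = []
        for _ in range(20):
            y = rng.permutation(base)
            res = MLMScan(y, geno, kin).fit()
            pooled.append(res["p"].to_numpy())
        ks = stats.kstest(np.concatenate(pooled), "uniform").statistic
        assert ks < 0.05

    def test_planted_qtl_found_in_top_ten(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = default_sim_config(n_entries=300, n_snps=5000, seed=100 + seed)
            geno = maf_filter(simulate_genotypes(cfg))
            kin = vanraden_kinship(geno)
            rng = np.random.default_rng(seed)
            j = geno.n_snps // 2
            g = geno.dosages[:, j]
            gz = (g - g.mean()) / g.std()
            # QTL explaining 10% of phenotype variance
            y = gz * np.sqrt(0.1) + np.sqrt(0.9) * rng.standard_normal(300)
            res = MLMScan(y, geno, kin).fit()
            top = res.nsmallest(10, "p")
            peak_chrom = geno.snp_map.loc[j, "chrom"]
            peak_pos = geno.snp_map.loc[j, "pos"]
            block = (top["chrom"] == peak_chrom) & (
                (top["pos"] - peak_pos).abs() <= 10_000
            )
            hits += int(block.any())
        assert hits >= 0.9 * n_seeds

    def test_p3d_shortcut_close_to_exact_per_snp_refit(self):
        # independent SNPs so no single marker carries the kinship axis
        cfg = default_sim_config(n_entries=50, n_snps=80, seed=33)
        cfg.ld_block_size = 1
        geno = maf_filter(simulate_genotypes(cfg))
        kin = vanraden_kinship(geno)
        rng = np.random.default_rng(3)
        L = np.linalg.cholesky(kin.values + 1e-6 * np.eye(50))
        y = 0.6 * (L @ rng.standard_normal(50)) + rng.standard_normal(50)
        fast = MLMScan(y, geno, kin).fit()
        slow = MLMScan(y, geno, kin).fit(exact=True)
        ok = fast["se"].notna() & slow["se"].notna()
        dlog = np.abs(np.log10(fast.loc[ok, "p"]) - np.log10(slow.loc[ok, "p"]))
        # the fixed-variance shortcut tracks the exact refit for the bulk of
        # SNPs; the odd marker most correlated with the kinship axis can
        # deviate more, which is the known cost of the approximation
        assert np.quantile(dlog, 0.9) < 0.2
        assert np.median(dlog) < 0.05

    def test_pvalues_invariant_to_snp_order_and_shift(self, scan_setup, rng):
        geno, kin = scan_setup
        y = rng.standard_normal(geno.n_entries)
        a = MLMScan(y, geno, kin).fit()
        b = MLMScan(y + 7.5, geno, kin).fit()
        # identical up to the lambda-optimizer's floating-point tolerance
        np.testing.assert_allclose(a["p"], b["p"], rtol=1e-5)
        perm = rng.permutation(geno.n_snps)
        from metgwas.genotypes import GenotypeMatrix

        shuffled = GenotypeMatrix(
            geno.dosages[:, perm],
            pd.DataFrame(
                {
                    "chrom": "Pv01",
                    "pos": 1000 * np.arange(1, geno.n_snps + 1),
                    "ref": "A",
                    "alt": "T",
                }
            ),
            list(geno.entry_ids),
        )
        c = MLMScan(y, shuffled, kin).fit()
        np.testing.assert_allclose(
            a["p"].to_numpy()[perm], c["p"].to_numpy(), rtol=1e-8, atol=1e-12
        )

    def test_kinship_controls_structure_inflation(self, scan_setup):
        geno, kin = scan_setup
        rng = np.random.default_rng(9)
        # structured phenotype: polygenic background on the kinship
        L = np.linalg.cholesky(kin.values + 1e-6 * np.eye(geno.n_entries))
        y = L @ rng.standard_normal(geno.n_entries) + 0.5 * rng.standard_normal(
            geno.n_entries
        )
        with_k = MLMScan(y, geno, kin).fit()
        ident = KinshipMatrix(np.eye(geno.n_entries), geno.entry_ids)
        without_k = MLMScan(y, geno, ident).fit()

        def lambda_gc(res):
            z2 = stats.chi2.isf(res["p"], df=1)
            return np.median(z2) / stats.chi2.ppf(0.5, df=1)

        assert 0.8 <= lambda_gc(with_k) <= 1.2
        assert lambda_gc(without_k) > 1.5

    def test_constant_phenotype_rejected(self, scan_setup):
        geno, kin = scan_setup
        with pytest.raises(ValueError, match="constant"):
            MLMScan(np.ones(geno.n_entries), geno, kin)


class TestCompressKinship:
    def test_identity_compression_matches_uncompressed_likelihood(self, rng):
        n = 40
        A = rng.standard_normal((n, 60))
        K = A @ A.T / 60
        K /= np.diag(K).mean()
        kin = KinshipMatrix(K)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        y = L @ rng.standard_normal(n) + rng.standard_normal(n)
        comp = compress_kinship(kin, [n], y=y)
        from metgwas.reml import KinshipMixedLM

        full = KinshipMixedLM(y, np.ones((n, 1)), kin).fit()
        assert comp.loglik_by_count[n] == pytest.approx(full.llf, abs=1e-9)

    def test_two_block_structure_reproduces_block_means(self):
        base = np.array([[1.0, 0.9], [0.9, 1.0]])
        K = np.kron(base, np.ones((2, 2)))
        np.fill_diagonal(K, 1.2)
        kin = KinshipMatrix(K)
        comp = compress_kinship(kin, [2])
        Z = np.zeros((4, 2))
        lab = comp.groups.to_numpy()
        Z[np.arange(4), lab] = 1.0
        sizes = Z.sum(axis=0)
        expect = (Z.T @ K @ Z) / np.outer(sizes, sizes)
        np.testing.assert_allclose(comp.kinship.values, expect, atol=1e-8)
        # block membership respects the planted 2x2 blocks
        assert lab[0] == lab[1] and lab[2] == lab[3] and lab[0] != lab[2]

    def test_selected_compression_at_least_as_good_as_full(self, rng):
        n = 30
        A = rng.standard_normal((n, 50))
        K = A @ A.T / 50
        K /= np.diag(K).mean()
        kin = KinshipMatrix(K)
        y = rng.standard_normal(n)
        comp = compress_kinship(kin, [n, n // 2, n // 4], y=y)
        assert max(comp.loglik_by_count.values()) >= comp.loglik_by_count[n] - 1e-9


class TestWindowsAndThinning:
    def test_candidate_window_arithmetic_and_clamp(self):
        assert candidate_window("Pv01", 42_230_000) == (
            "Pv01",
            42_220_000,
            42_240_000,
        )
        assert candidate_window("Pv01", 4_000) == ("Pv01", 1, 14_000)
        chrom, lo, hi = candidate_window("Pv02", 1_000_000, 20_000)
        assert hi - lo == 20_000

    def test_thinning_keeps_one_snp_per_window(self):
        res = pd.DataFrame(
            {
                "chrom": ["Pv01", "Pv01", "Pv02", "Pv02"],
                "pos": [100_000, 105_000, 100_000, 125_000],
                "p": [1e-8, 1e-6, 1e-5, 1e-4],
            }
        )
        kept = thin_top_snps(res, n_top=10, window_bp=20_000)
        assert len(kept) == 3
        assert 105_000 not in kept["pos"].tolist()

    def test_cluster_thinned_to_single_representative(self, rng):
        cluster = pd.DataFrame(
            {
                "chrom": "Pv03",
                "pos": rng.integers(1_000_000, 1_010_000, 30),
                "p": rng.random(30) * 1e-4,
            }
        )
        isolated = pd.DataFrame(
            {
                "chrom": "Pv04",
                "pos": 1_000_000 + 100_000 * np.arange(12),
                "p": rng.random(12) * 1e-3,
            }
        )
        res = pd.concat([cluster, isolated], ignore_index=True)
        kept = thin_top_snps(res, n_top=10, window_bp=20_000)
        assert len(kept) <= 10
        assert (kept["chrom"] == "Pv03").sum() == 1


class TestEarliestYear:
    def test_min_year_per_entry(self):
        tab = pd.DataFrame(
            {
                "entry": ["a", "a", "a", "b"],
                "location": ["NDFA"] * 4,
                "year": [1988, 1989, 1995, 2001],
                "trait": "t",
                "value": 0.0,
            }
        )
        out = earliest_year_phenotype(tab)
        assert out["a"] == 1988 and out["b"] == 2001

    def test_covers_every_tested_entry(self, trial_data):
        design, pheno, _ = trial_data
        out = earliest_year_phenotype(pheno)
        assert len(out) == design["entry"].nunique()
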