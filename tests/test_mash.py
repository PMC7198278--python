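"""Multivariate shrinkage: bridge, EM, posteriors, lfsr, Bayes factors, sharing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from metgwas.mash import (
    MashModel,
    MixtureModel,
    PosteriorSummary,
    bayes_factor,
    build_snp_sets,
    canonical_covariances,
    compute_posteriors,
    default_scale_grid,
    fit_mixture_em,
    hedges_correction,
    hedges_g_se,
    learn_covariances,
    pairwise_sharing,
    standardize_effects,
)


class TestStandardizeEffects:
    def test_simple_example(self):
        b, s, (center, scale) = standardize_effects([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
        np.testing.assert_allclose(b, [-1.0, 0.0, 1.0])
        assert (center, scale) == (2.0, 1.0)
        np.testing.assert_allclose(s, [0.5, 0.5, 0.5])

    def test_idempotent_on_normalized_input(self):
        b0 = np.array([-1.0, 0.25, 1.0, -0.25])
        b, s, _ = standardize_effects(b0, np.ones(4))
        np.testing.assert_allclose(b, b0, atol=1e-12)

    def test_z_scores_preserved_for_centered_effects(self, rng):
        beta = rng.standard_normal(50)
        beta -= beta.mean()
        se = 0.1 + rng.random(50)
        b, s, _ = standardize_effects(beta, se)
        np.testing.assert_allclose(b / s, beta / se, atol=1e-10)
        assert abs(b.mean()) < 1e-12
        assert np.max(np.abs(b)) == pytest.approx(1.0)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_effects([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])


class TestHedgesG:
    def test_se_formula_by_hand(self):
        assert hedges_g_se(10, 10, 0.0) == pytest.approx(np.sqrt(0.2))

    def test_correction_factor_by_hand(self):
        assert hedges_correction(18) == pytest.approx(1 - 3 / 71)

    def test_se_increases_with_effect_magnitude(self):
        ses = [hedges_g_se(20, 30, g) for g in (0.0, 0.5, 1.0, 2.0)]
        assert all(a < b for a, b in zip(ses, ses[1:]))

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            hedges_g_se(1, 10, 0.0)


class TestSnpSets:
    def test_sets_reproducible_and_seed_sensitive(self, geno_maf):
        rng = np.random.default_rng(0)
        ids = list(geno_maf.snp_map["id"])
        scans = {
            "a": pd.DataFrame({"id": ids, "p": rng.random(len(ids))}),
            "b": pd.DataFrame({"id": ids, "p": rng.random(len(ids))}),
        }
        r1, s1 = build_snp_sets(scans, geno_maf, n_random=50, n_strong_per_trait=30, seed=1)
        r2, s2 = build_snp_sets(scans, geno_maf, n_random=50, n_strong_per_trait=30, seed=1)
        r3, _ = build_snp_sets(scans, geno_maf, n_random=50, n_strong_per_trait=30, seed=2)
        assert r1 == r2 and s1 == s2
        assert r1 != r3

    def test_strong_union_deduplicates(self, geno_maf):
        ids = list(geno_maf.snp_map["id"])
        p = np.linspace(0.001, 1, len(ids))
        scans = {"a": pd.DataFrame({"id": ids, "p": p}), "b": pd.DataFrame({"id": ids, "p": p})}
        _, strong = build_snp_sets(scans, geno_maf, n_random=10, n_strong_per_trait=25, seed=0)
        assert len(strong) == 25  # shared top SNPs collapse in the union

    def test_oversized_requests_capped(self, geno_maf):
        ids = list(geno_maf.snp_map["id"])
        scans = {"a": pd.DataFrame({"id": ids, "p": np.linspace(0.01, 1, len(ids))})}
        with pytest.warns(UserWarning, match="capped"):
            rand, strong = build_snp_sets(
                scans, geno_maf, n_random=10**6, n_strong_per_trait=10**6, seed=0
            )
        assert len(strong) == geno_maf.n_snps


class TestLearnCovariances:
    def test_single_phenotype_collapses_to_scalar(self):
        comps = learn_covariances(np.random.default_rng(0).standard_normal((20, 1)))
        assert len(comps) == 1
        np.testing.assert_allclose(comps[0][1], [[1.0]])

    def test_spiked_covariance_direction_recovered(self, rng):
        R, n = 6, 1000
        v = rng.standard_normal(R)
        v /= np.linalg.norm(v)
        B = np.outer(rng.standard_normal(n), v) + 0.05 * rng.standard_normal((n, R))
        comps = dict(learn_covariances(B))
        w, vecs = np.linalg.eigh(comps["empirical"])
        lead = vecs[:, -1]
        assert abs(lead @ v) > 0.9

    def test_all_components_psd_and_unit_scaled(self, rng):
        B = rng.standard_normal((50, 4))
        for name, U in learn_covariances(B):
            assert np.linalg.eigvalsh(U).min() >= -1e-8
            assert U.diagonal().max() <= 1.0 + 1e-9

    def test_insufficient_strong_set_skips_empirical(self, rng):
        with pytest.warns(UserWarning, match="skipped"):
            comps = learn_covariances(rng.standard_normal((3, 5)))
        assert "empirical" not in dict(comps)


def scalar_mixture(weights, variances):
    covs = np.array([[[v]] for v in [0.0] + list(variances)])
    labels = ["null"] + [f"c{v}" for v in variances]
    return MixtureModel(covs, labels, np.asarray(weights, dtype=float))


class TestMixtureEm:
    def test_null_data_concentrates_on_near_null(self, rng):
        n, R = 5000, 4
        shat = np.full((n, R), 0.1)
        bhat = rng.standard_normal((n, R)) * shat
        fit = MashModel(bhat, shat).fit()
        assert fit.mixture.near_null_weight() > 0.9

    def test_known_component_weight_recovered(self, rng):
        n, R = 5000, 4
        shat = np.full((n, R), 0.1)
        U = np.ones((R, R))
        L = np.linalg.cholesky(U + 1e-10 * np.eye(R))
        true = np.zeros((n, R))
        true[n // 2:] = (L @ rng.standard_normal((R, n // 2))).T * 0.5
        fit = MashModel(true + rng.standard_normal((n, R)) * shat, shat).fit()
        w = fit.mixture.component_weights()
        eq_total = w[[k for k in w.index if k.startswith("equal_effects")]].sum()
        assert 0.35 <= eq_total <= 0.65

    def test_plain_ml_loglik_monotone(self, rng):
        n, R = 800, 3
        shat = np.full((n, R), 0.2)
        bhat = rng.standard_normal((n, R)) * 0.3
        fit = MashModel(bhat, shat).fit(null_prior=1.0)
        trace = np.array(fit.mixture.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-7)

    def test_non_psd_component_rejected(self, rng):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="PSD"):
            MashModel(
                rng.standard_normal((10, 2)),
                np.ones((10, 2)),
                components=[("bad", bad)],
            )

    def test_functional_wrapper_returns_mixture(self, rng):
        bhat = rng.standard_normal((100, 2)) * 0.1
        mix = fit_mixture_em(
            bhat, np.full((100, 2), 0.1), canonical_covariances(2), [0.01, 1.0]
        )
        assert mix.weights.sum() == pytest.approx(1.0)


class TestPosteriors:
    def test_all_weight_on_null_gives_zero_means_unit_lfsr(self, rng):
        mix = scalar_mixture([1.0, 0.0], [1.0])
        post = compute_posteriors(rng.standard_normal((20, 1)), np.ones((20, 1)), mix)
        np.testing.assert_allclose(post.post_mean.to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(post.lfsr.to_numpy(), 1.0, atol=1e-12)

    def test_conjugate_normal_closed_form(self):
        # prior N(0,1), noise 1, observation 2: posterior N(1, 1/2)
        mix = scalar_mixture([0.0, 1.0], [1.0])
        post = compute_posteriors(np.array([[2.0]]), np.array([[1.0]]), mix)
        assert post.post_mean.iloc[0, 0] == pytest.approx(1.0)
        assert post.post_sd.iloc[0, 0] == pytest.approx(np.sqrt(0.5))
        assert post.lfsr.iloc[0, 0] == pytest.approx(
            stats.norm.cdf(-1 / np.sqrt(0.5)), abs=1e-6
        )

    def test_scalar_posterior_means_shrink_toward_zero(self, rng):
        mix = scalar_mixture([0.3, 0.4, 0.3], [0.5, 2.0])
        b = rng.standard_normal((200, 1)) * 2
        post = compute_posteriors(b, np.ones((200, 1)), mix)
        assert np.all(np.abs(post.post_mean.to_numpy()) <= np.abs(b) + 1e-12)

    def test_lfsr_matches_quadrature_oracle(self):
        # 1 phenotype, null + two normal slices: integrate the posterior
        # density numerically and compare lfsr to 1e-4
        w = np.array([0.5, 0.3, 0.2])
        variances = [0.5, 4.0]
        mix = scalar_mixture(w, variances)
        s = 1.0
        for bhat in (0.3, 1.5, -2.2):
            lik_null = stats.norm.pdf(bhat, 0, s)
            liks = [stats.norm.pdf(bhat, 0, np.sqrt(v + s**2)) for v in variances]
            marg = w[0] * lik_null + w[1] * liks[0] + w[2] * liks[1]
            resp = np.array([w[0] * lik_null, w[1] * liks[0], w[2] * liks[1]]) / marg

            def post_density(b):
                total = 0.0
                for rw, v in zip(resp[1:], variances):
                    pv = v * s**2 / (v + s**2)
                    pm = v / (v + s**2) * bhat
                    total += rw * stats.norm.pdf(b, pm, np.sqrt(pv))
                return total

            p_neg = quad(post_density, -np.inf, 0.0)[0] + resp[0]
            p_pos = quad(post_density, 0.0, np.inf)[0] + resp[0]
            oracle = min(p_neg, p_pos)
            post = compute_posteriors(np.array([[bhat]]), np.array([[s]]), mix)
            assert post.lfsr.iloc[0, 0] == pytest.approx(oracle, abs=1e-4)


class TestBayesFactor:
    def test_closed_form_single_slice(self):
        mix = scalar_mixture([0.5, 0.5], [9.0])
        bf = bayes_factor(np.array([[3.0]]), np.array([[1.0]]), mix)
        expect = np.sqrt(1 / 10) * np.exp(9 / 2 - 9 / 20)
        assert bf[0] == pytest.approx(expect, rel=1e-10)

    def test_null_favored_at_origin(self, rng):
        mix = scalar_mixture([0.5, 0.25, 0.25], [1.0, 4.0])
        bf = bayes_factor(np.zeros((5, 1)), np.ones((5, 1)), mix)
        assert np.all(bf < 1.0)

    def test_decisive_threshold_is_one_hundred(self):
        from metgwas.mash import DECISIVE_BF

        assert DECISIVE_BF == 100.0

    def test_large_effects_decisive_null_effects_not(self, rng):
        n, R = 400, 3
        shat = np.full((n, R), 0.1)
        bhat = rng.standard_normal((n, R)) * shat
        bhat[: n // 2] += rng.choice([-1.0, 1.0], (n // 2, R)) * 0.8
        fit = MashModel(bhat, shat).fit()
        post = fit.posterior()
        bf = post.bayes_factor.to_numpy()
        assert np.median(bf[: n // 2]) > 100.0
        assert np.median(bf[n // 2:]) < 1.0


class TestPairwiseSharing:
    @staticmethod
    def summary_from(post_mean, lfsr):
        pm = pd.DataFrame(post_mean, columns=["a", "b"])
        lf = pd.DataFrame(lfsr, columns=["a", "b"])
        return PosteriorSummary(pm, pm * 0 + 1.0, lf, pd.Series(np.ones(len(pm))))

    def test_rule_application_on_known_pairs(self):
        pm = np.array([[0.5, 0.45], [0.5, -0.45], [0.2, 0.7]])
        lf = np.full((3, 2), 0.01)
        share = pairwise_sharing(self.summary_from(pm, lf), magnitude_factor=2)
        # row 1 shares (ratio 1.11 same sign); row 2 opposite sign; row 3 ratio 3.5
        assert share.loc["a", "b"] == pytest.approx(1 / 3)
        assert share.loc["a", "a"] == 1.0
        assert share.equals(share.T)

    def test_no_significant_snps_is_error(self):
        pm = np.array([[0.5, 0.4]])
        lf = np.array([[0.5, 0.9]])
        with pytest.raises(ValueError):
            pairwise_sharing(self.summary_from(pm, lf))

    def test_planted_group_structure_separates_sharing(self):
        # two groups of 3 phenotypes; effects shared within, independent across
        rng = np.random.default_rng(11)
        n, R = 3000, 6
        shat = np.full((n, R), 0.05)
        true = np.zeros((n, R))
        strength = 0.5
        for j in range(n // 2):
            g = j % 2
            cols = slice(0, 3) if g == 0 else slice(3, 6)
            true[j, cols] = strength * np.sign(rng.standard_normal()) * (
                0.8 + 0.4 * rng.random(3)
            )
        bhat = true + rng.standard_normal((n, R)) * shat
        comps = learn_covariances(bhat[np.abs(true).sum(axis=1) > 0])
        fit = MashModel(bhat, shat, comps).fit()
        post = fit.posterior()
        share = pairwise_sharing(post).to_numpy()
        within, between = [], []
        for a in range(R):
            for b in range(a + 1, R):
                (within if (a < 3) == (b < 3) else between).append(share[a, b])
        assert np.nanmean(within) - np.nanmean(between) >= 0.3

    def test_lfsr_calibration_on_simulated_effects(self):
        # among lfsr <= 0.05 calls, realized wrong-or-null-sign rate <= 0.10
        rng = np.random.default_rng(5)
        n, R = 4000, 4
        shat = np.full((n, R), 0.1)
        true = np.zeros((n, R))
        nz = rng.random((n, R)) < 0.3
        true[nz] = rng.standard_normal(nz.sum()) * 0.4
        bhat = true + rng.standard_normal((n, R)) * shat
        fit = MashModel(bhat, shat).fit()
        post = fit.posterior()
        calls = post.lfsr.to_numpy() <= 0.05
        assert calls.sum() > 100
        wrong = (np.sign(post.post_mean.to_numpy()) != np.sign(true)) | (true == 0.0)
        assert wrong[calls].mean() <= 0.10


class TestScaleGrid:
    def test_grid_brackets_data(self, rng):
        bhat = rng.standard_normal((100, 2))
        shat = 0.1 + rng.random((100, 2))
        grid = default_scale_grid(bhat, shat)
        assert grid[0] <= np.min(shat) ** 2 / 4 * (1 + 1e-12)
        assert grid[-1] >= 4 * np.max(bhat**2) / 2
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, 2.0)
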