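"""Empirical-Bayes multivariate shrinkage of SNP effects across phenotypes.

Condition-by-condition association scans estimate each SNP's effect on each
phenotype separately.  When effects are shared across phenotypes — through
pleiotropy or linkage — pooling information across conditions raises power.
This module implements the multivariate adaptive shrinkage approach: SNP
effect vectors are modelled as draws from a mixture of zero-mean
multivariate normal priors,

    b_j ~ pi_0 delta_0 + sum_{k,l} pi_{k,l} N(0, omega_l * U_k),

with canonical and data-driven covariance components U_k on a geometric
scale grid omega_l.  The mixture weights are fitted by EM on a large random
SNP set (which mostly carries null effects), and posteriors are evaluated on
a "strong" set of top associations.  Reported per SNP and phenotype are the
posterior mean and SD, the local false-sign rate (lfsr: the posterior
probability that the reported sign is wrong or the effect is null), a
per-SNP Bayes factor against the all-null model, and the pairwise sharing
matrix (fraction of significant SNPs with same sign and similar magnitude in
each pair of phenotypes).

Observation noise is taken as independent across phenotypes given the
standard errors (S_j diagonal); measurement-error correlations between
phenotypes are assumed zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .genotypes import GenotypeMatrix, ld_prune

__all__ = [
    "EffectPanel",
    "MixtureModel",
    "PosteriorSummary",
    "MashModel",
    "MashResults",
    "standardize_effects",
    "hedges_correction",
    "hedges_g_se",
    "build_snp_sets",
    "build_effect_panel",
    "learn_covariances",
    "canonical_covariances",
    "default_scale_grid",
    "fit_mixture_em",
    "compute_posteriors",
    "bayes_factor",
    "pairwise_sharing",
]

DECISIVE_BF = 100.0  # Jeffreys' "decisive evidence" threshold, 10^2


# ---------------------------------------------------------------------------
# GWAS -> shrinkage bridge
# ---------------------------------------------------------------------------

def standardize_effects(beta, se):
    """Rescale one phenotype's effects to mean 0 with max |effect| = 1.

    The effects are centered by their mean and divided by the maximum
    absolute centered value; the standard errors are divided by the same
    factor (they are scales, so they are not centered).  Returns the scaled
    effects, scaled SEs and the (center, scale) pair for back-transforming.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if beta.size < 2:
        raise ValueError("need at least 2 effects to standardize")
    if np.ptp(beta) == 0.0:
        raise ValueError("effects are constant; standardization degenerate")
    center = float(beta.mean())
    centered = beta - center
    scale = float(np.max(np.abs(centered)))
    return centered / scale, se / scale, (center, scale)


def hedges_correction(df: int) -> float:
    """Small-sample bias correction J(df) = 1 - 3 / (4 df - 1)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g_se(n0: int, n1: int, g: float) -> float:
    """Standard error of Hedges' G for group sizes n0, n1.

    SE = sqrt((n0 + n1) / (n0 n1) + g^2 / (2 (n0 + n1))), the usual
    large-sample variance of the bias-corrected standardized mean
    difference.  Used as a fallback SE when the primary scan produced
    standard errors for too few SNPs (<= 95% coverage) for a phenotype.
    """
    if n0 < 2 or n1 < 2:
        raise ValueError("both group sizes must be >= 2")
    return float(np.sqrt((n0 + n1) / (n0 * n1) + g * g / (2.0 * (n0 + n1))))


@dataclass
class EffectPanel:
    """Aligned SNP x phenotype effect and SE matrices on a common scale."""

    bhat: pd.DataFrame
    shat: pd.DataFrame
    scales: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.bhat.shape != self.shat.shape:
            raise ValueError("bhat and shat must have identical shape")
        if (self.shat.to_numpy() <= 0).any():
            raise ValueError("standard errors must be strictly positive")

    @property
    def n_snps(self) -> int:
        return self.bhat.shape[0]

    @property
    def phenotypes(self) -> list[str]:
        return list(self.bhat.columns)


def build_effect_panel(
    results: dict[str, pd.DataFrame],
    snp_ids=None,
    geno: GenotypeMatrix | None = None,
    phenotypes: dict[str, np.ndarray] | None = None,
    se_coverage_min: float = 0.95,
) -> EffectPanel:
    """Assemble a standardized EffectPanel from per-phenotype scan tables.

    Each table needs columns id, beta, se.  Effects are standardized per
    phenotype to [-1, 1] with mean 0 (SEs rescaled by the same factor).  If
    a phenotype's scan provided usable SEs for <= ``se_coverage_min`` of
    SNPs, its SEs are replaced by the Hedges' G standard error computed from
    genotype group sizes (requires ``geno`` and the phenotype vector).
    """
    names = list(results)
    if snp_ids is None:
        snp_ids = list(results[names[0]]["id"])
    bcols, scols, scales = {}, {}, {}
    for name in names:
        tab = results[name].set_index("id")
        beta = tab["beta"].reindex(snp_ids).to_numpy(dtype=float)
        se = tab["se"].reindex(snp_ids).to_numpy(dtype=float)
        usable = np.isfinite(se) & (se > 0)
        if usable.mean() <= se_coverage_min:
            if geno is None or phenotypes is None or name not in phenotypes:
                raise ValueError(
                    f"{name}: SE coverage {usable.mean():.1%} needs the "
                    "Hedges' G fallback, but genotypes/phenotype not supplied"
                )
            se = _hedges_fallback_se(snp_ids, beta, geno, phenotypes[name])
        else:
            med = np.nanmedian(se[usable])
            se = np.where(usable, se, med)
        beta = np.where(np.isfinite(beta), beta, 0.0)
        b_s, s_s, sc = standardize_effects(beta, se)
        bcols[name], scols[name], scales[name] = b_s, s_s, sc
    bhat = pd.DataFrame(bcols, index=snp_ids)
    shat = pd.DataFrame(scols, index=snp_ids)
    return EffectPanel(bhat, shat, scales)


def _hedges_fallback_se(snp_ids, beta, geno: GenotypeMatrix, y: np.ndarray):
    """Per-SNP Hedges' G SE from alt-carrier vs reference group sizes."""
    y = np.asarray(y, dtype=float)
    sd = y.std(ddof=1)
    idx = pd.Index(geno.snp_map["id"]).get_indexer(snp_ids)
    out = np.empty(len(snp_ids))
    for k, j in enumerate(idx):
        if j < 0:
            out[k] = np.nan
            continue
        d = geno.dosages[:, j]
        n1 = int(np.sum(d >= 1))
        n0 = int(np.sum(d < 1))
        n0, n1 = max(n0, 2), max(n1, 2)
        df = n0 + n1 - 2
        g = hedges_correction(df) * beta[k] / (sd if sd > 0 else 1.0)
        out[k] = hedges_g_se(n0, n1, g)
    med = np.nanmedian(out)
    return np.where(np.isfinite(out), out, med)


def build_snp_sets(
    results: dict[str, pd.DataFrame],
    geno: GenotypeMatrix,
    n_random: int = 5000,
    n_strong_per_trait: int = 400,
    r2_max: float = 0.2,
    window_bp: int = 100_000,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Random (prior-fitting) and strong (posterior) SNP sets.

    The random set is drawn without replacement from the LD-pruned SNP
    universe (r^2 below ``r2_max`` within ``window_bp``); the strong set is
    the union over phenotypes of each phenotype's ``n_strong_per_trait``
    smallest-p SNPs.  Both are deduplicated and ordered by genome position;
    the draw is reproducible from ``seed``.
    """
    pruned = ld_prune(geno, r2_max=r2_max, window_bp=window_bp)
    universe = list(pruned.snp_map["id"])
    if n_random > len(universe):
        warnings.warn(
            f"n_random={n_random} exceeds pruned universe ({len(universe)}); capped"
        )
        n_random = len(universe)
    rng = np.random.default_rng(seed)
    random_ids = [universe[i] for i in rng.choice(len(universe), n_random, replace=False)]

    strong: set[str] = set()
    for name, tab in results.items():
        k = min(n_strong_per_trait, len(tab))
        strong.update(tab.nsmallest(k, "p")["id"])
    order = {s: i for i, s in enumerate(geno.snp_map["id"])}
    return (
        sorted(set(random_ids), key=order.get),
        sorted(strong, key=order.get),
    )


# ---------------------------------------------------------------------------
# covariance components and scale grid
# ---------------------------------------------------------------------------

def canonical_covariances(n_pheno: int) -> list[tuple[str, np.ndarray]]:
    """Identity, per-phenotype singletons, and the equal-effects matrix."""
    if n_pheno == 1:
        return [("scalar", np.ones((1, 1)))]
    comps = [("identity", np.eye(n_pheno))]
    for r in range(n_pheno):
        U = np.zeros((n_pheno, n_pheno))
        U[r, r] = 1.0
        comps.append((f"singleton_{r}", U))
    comps.append(("equal_effects", np.ones((n_pheno, n_pheno))))
    return comps


def _normalize_psd(U: np.ndarray) -> np.ndarray:
    """Project to PSD and scale to unit maximum diagonal."""
    U = (U + U.T) / 2.0
    w, v = np.linalg.eigh(U)
    U = (v * np.clip(w, 0.0, None)) @ v.T
    m = U.diagonal().max()
    return U / m if m > 0 else U


def learn_covariances(
    bhat: pd.DataFrame | np.ndarray,
    shat: pd.DataFrame | np.ndarray | None = None,
    rank: int = 5,
) -> list[tuple[str, np.ndarray]]:
    """Canonical plus data-driven covariance components from strong effects.

    Data-driven components are the empirical second-moment matrix of the
    strong effects and its rank-``rank`` truncated eigen-reconstruction
    (a PCA-denoised version), each normalized to unit maximum diagonal.
    """
    B = np.asarray(bhat, dtype=float)
    if B.ndim != 2:
        raise ValueError("bhat must be 2-D (SNPs x phenotypes)")
    n, R = B.shape
    comps = canonical_covariances(R)
    if R == 1:
        return comps
    if n < R:
        warnings.warn(
            f"only {n} strong SNPs for {R} phenotypes; empirical component skipped"
        )
        return comps
    emp = (B.T @ B) / n
    comps.append(("empirical", _normalize_psd(emp)))
    w, v = np.linalg.eigh(emp)
    k = min(rank, R)
    idx = np.argsort(w)[::-1][:k]
    trunc = (v[:, idx] * np.clip(w[idx], 0.0, None)) @ v[:, idx].T
    comps.append((f"empirical_rank{k}", _normalize_psd(trunc)))
    return comps


def default_scale_grid(bhat, shat) -> np.ndarray:
    """Geometric grid of prior variances bracketing plausible effect sizes.

    Spans [(min shat)^2 / 4, 4 (max |bhat|)^2] with sqrt(2) spacing on the
    standard-deviation scale (factor 2 in variance).
    """
    s = np.asarray(shat, dtype=float)
    b = np.asarray(bhat, dtype=float)
    lo = max(np.min(s) ** 2 / 4.0, 1e-12)
    hi = max(4.0 * np.max(b**2), lo * 2.0)
    n = int(np.ceil(np.log2(hi / lo))) + 1
    return lo * 2.0 ** np.arange(n)


# ---------------------------------------------------------------------------
# the mixture model
# ---------------------------------------------------------------------------

@dataclass
class MixtureModel:
    """Fitted covariance-mixture prior.

    ``covs[0]`` is the null point mass (zero matrix); the remaining slices
    are omega_l * U_k for every (component, scale) pair.  ``weights`` sums
    to 1 over all slices including the null.
    """

    covs: np.ndarray                     # (C, R, R), covs[0] = 0 (null)
    labels: list[str]
    weights: np.ndarray                  # (C,)
    loglik_trace: list[float] = field(default_factory=list)
    phenotypes: list[str] = field(default_factory=list)

    @property
    def null_weight(self) -> float:
        return float(self.weights[0])

    def near_null_weight(self, var_max: float | None = None) -> float:
        """Weight on the null plus slices of negligible prior variance.

        Components at the bottom of the scale grid are statistically close
        to the point mass; ``var_max`` (default: the smallest slice variance
        in the mixture) sets the cut on the maximum prior variance counted
        as near-null.
        """
        diag_max = np.array([c.diagonal().max() for c in self.covs])
        if var_max is None:
            pos = diag_max[diag_max > 0]
            var_max = pos.min() if pos.size else 0.0
        return float(self.weights[diag_max <= var_max].sum())

    def component_weights(self) -> pd.Series:
        return pd.Series(self.weights, index=self.labels)


def _component_loglik(bhat: np.ndarray, shat: np.ndarray, covs: np.ndarray):
    """log N(b_j; 0, S_j + C_c) for every SNP j and mixture slice c.

    Batched over SNPs per slice: build the (n, R, R) stack S_j + C, take
    slogdet and solve in one shot.  Returns (n, C).
    """
    n, R = bhat.shape
    C = covs.shape[0]
    out = np.empty((n, C))
    S2 = shat**2
    eye_idx = np.arange(R)
    const = R * np.log(2.0 * np.pi)
    for c in range(C):
        A = np.repeat(covs[c][None, :, :], n, axis=0)
        A[:, eye_idx, eye_idx] += S2
        sign, logdet = np.linalg.slogdet(A)
        sol = np.linalg.solve(A, bhat[:, :, None])[:, :, 0]
        quad = np.einsum("ij,ij->i", bhat, sol)
        out[:, c] = -0.5 * (const + logdet + quad)
    return out


class MashModel:
    """Empirical-Bayes mixture prior over SNP effect vectors.

    Parameters
    ----------
    bhat, shat : (n_snps, n_phenotypes) effects and standard errors, usually
        the random SNP set of a standardized :class:`EffectPanel`.
    components : list of (name, U) PSD covariance components; learned from
        strong effects via :func:`learn_covariances`, or canonical only.
    scales : grid of prior variances omega; :func:`default_scale_grid` when
        omitted.
    """

    def __init__(self, bhat, shat, components=None, scales=None):
        self.bhat_df = bhat if isinstance(bhat, pd.DataFrame) else pd.DataFrame(np.atleast_2d(bhat))
        self.shat_df = shat if isinstance(shat, pd.DataFrame) else pd.DataFrame(np.atleast_2d(shat))
        B, S = self.bhat_df.to_numpy(float), self.shat_df.to_numpy(float)
        if B.shape != S.shape:
            raise ValueError("bhat and shat shapes differ")
        if (S <= 0).any():
            raise ValueError("standard errors must be positive")
        self.bhat, self.shat = B, S
        R = B.shape[1]
        if components is None:
            components = canonical_covariances(R)
        for name, U in components:
            U = np.asarray(U, float)
            if U.shape != (R, R):
                raise ValueError(f"component {name} has wrong shape")
            if np.linalg.eigvalsh((U + U.T) / 2.0).min() < -1e-8:
                raise ValueError(f"component {name} is not PSD")
        self.components = [(nm, np.asarray(U, float)) for nm, U in components]
        if scales is None:
            scales = default_scale_grid(B, S)
        self.scales = np.asarray(scales, dtype=float)
        if (self.scales <= 0).any():
            raise ValueError("scales must be positive")

        covs = [np.zeros((R, R))]
        labels = ["null"]
        for nm, U in self.components:
            for om in self.scales:
                covs.append(om * U)
                labels.append(f"{nm}@{om:.3g}")
        self._covs = np.array(covs)
        self._labels = labels

    def fit(
        self,
        max_iter: int = 500,
        tol: float = 1e-6,
        null_prior: float = 10.0,
    ) -> "MashResults":
        """EM over the mixture weights; the penalized objective is monotone.

        ``null_prior`` is a Dirichlet pseudo-count on the null slice (the
        usual null-biased prior); it regularizes the split between the
        point mass and statistically indistinguishable tiny-scale slices.
        Set to 1 for plain maximum likelihood.
        """
        n, C = self.bhat.shape[0], self._covs.shape[0]
        L = _component_loglik(self.bhat, self.shat, self._covs)
        shift = L.max(axis=1)
        P = np.exp(L - shift[:, None])       # fixed likelihoods, row-scaled
        alpha = np.ones(C)
        alpha[0] = max(float(null_prior), 1.0)
        pi = np.full(C, 1.0 / C)
        trace: list[float] = []
        prev_obj = -np.inf
        for _ in range(max_iter):
            W = P * pi                        # (n, C)
            norm = W.sum(axis=1)
            ll = float(np.sum(np.log(norm) + shift))
            obj = ll + float((alpha - 1.0) @ np.log(np.maximum(pi, 1e-300)))
            trace.append(ll)
            if obj - prev_obj < tol and len(trace) > 1:
                break
            prev_obj = obj
            counts = (W / norm[:, None]).sum(axis=0) + (alpha - 1.0)
            pi = np.maximum(counts, 0.0)
            pi /= pi.sum()
        mixture = MixtureModel(
            self._covs,
            self._labels,
            pi,
            trace,
            [str(c) for c in self.bhat_df.columns],
        )
        return MashResults(self, mixture)


class MashResults:
    """Fitted mixture prior with posterior evaluation methods."""

    def __init__(self, model: MashModel, mixture: MixtureModel):
        self.model = model
        self.mixture = mixture

    @property
    def loglik(self) -> float:
        return self.mixture.loglik_trace[-1]

    def posterior(self, bhat=None, shat=None) -> "PosteriorSummary":
        """Posterior summaries for a panel (default: the fitting panel)."""
        if bhat is None:
            bhat, shat = self.model.bhat_df, self.model.shat_df
        return compute_posteriors(bhat, shat, self.mixture)

    def summary(self) -> str:
        w = self.mixture.component_weights().sort_values(ascending=False)
        lines = [
            "Multivariate adaptive shrinkage fit",
            "=" * 44,
            f"SNPs used: {self.model.bhat.shape[0]}   "
            f"phenotypes: {self.model.bhat.shape[1]}",
            f"mixture slices: {len(self.mixture.weights)}   "
            f"EM iterations: {len(self.mixture.loglik_trace)}",
            f"log-likelihood: {self.loglik:.4f}",
            f"null weight: {self.mixture.null_weight:.4f}",
            "top-weight slices:",
        ]
        for name, wt in w.head(6).items():
            lines.append(f"  {name:<28s} {wt:.4f}")
        return "\n".join(lines)


@dataclass
class PosteriorSummary:
    """Per-SNP, per-phenotype posterior summaries from the fitted mixture."""

    post_mean: pd.DataFrame
    post_sd: pd.DataFrame
    lfsr: pd.DataFrame
    bayes_factor: pd.Series

    def significant(self, lfsr_max: float = 0.05) -> pd.DataFrame:
        """Boolean SNP x phenotype table of lfsr <= threshold calls."""
        return self.lfsr <= lfsr_max

    def decisive(self) -> pd.Series:
        return self.bayes_factor > DECISIVE_BF


def fit_mixture_em(bhat, shat, components, scales, **kwargs) -> MixtureModel:
    """Functional wrapper: fit the weight mixture and return it."""
    return MashModel(bhat, shat, components, scales).fit(**kwargs).mixture


def compute_posteriors(bhat, shat, mixture: MixtureModel) -> PosteriorSummary:
    """Posterior means, SDs, lfsr and Bayes factors for an effect panel.

    Per SNP the posterior is a mixture over slices with responsibilities
    proportional to prior weight times marginal likelihood.  Conditional on
    a slice with prior covariance C, the posterior of the true effect b is
    normal with mean C (C + S)^{-1} bhat and covariance C - C (C + S)^{-1} C
    (computed via solves; singular C never inverted).  The lfsr of each
    entry is min{P(b <= 0 | data), P(b >= 0 | data)}, both sides including
    any point mass at zero.
    """
    if isinstance(bhat, pd.DataFrame):
        index, cols = bhat.index, list(bhat.columns)
        B = bhat.to_numpy(float)
        S = np.asarray(shat, dtype=float) if not isinstance(shat, pd.DataFrame) else shat.to_numpy(float)
    else:
        B = np.atleast_2d(np.asarray(bhat, float))
        S = np.atleast_2d(np.asarray(shat, float))
        index = pd.RangeIndex(B.shape[0])
        cols = mixture.phenotypes or [f"pheno{r}" for r in range(B.shape[1])]
    n, R = B.shape
    covs, w = mixture.covs, mixture.weights
    C = covs.shape[0]
    L = _component_loglik(B, S, covs)
    with np.errstate(divide="ignore"):
        A = L + np.log(np.maximum(w, 1e-300))
    norm = logsumexp(A, axis=1)
    resp = np.exp(A - norm[:, None])          # (n, C) responsibilities

    eye_idx = np.arange(R)
    mean = np.zeros((n, R))
    second = np.zeros((n, R))                 # E[b^2]
    p_le = np.zeros((n, R))                   # P(b <= 0 | data)
    p_ge = np.zeros((n, R))
    for c in range(C):
        r_c = resp[:, c]
        Uc = covs[c]
        if not Uc.any():                      # null point mass at zero
            p_le += r_c[:, None]
            p_ge += r_c[:, None]
            continue
        Amat = np.repeat(Uc[None, :, :], n, axis=0)
        Amat[:, eye_idx, eye_idx] += S**2
        P = np.linalg.solve(Amat, np.repeat(Uc[None, :, :], n, axis=0))
        mu = np.einsum("nij,ni->nj", P.transpose(0, 2, 1), B)
        Sig = Uc[None, :, :] - np.einsum("nij,jk->nik", P.transpose(0, 2, 1), Uc)
        var = np.clip(Sig[:, eye_idx, eye_idx], 0.0, None)
        sd = np.sqrt(var)
        mean += r_c[:, None] * mu
        second += r_c[:, None] * (var + mu**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, -mu / np.where(sd > 0, sd, 1.0), 0.0)
        cdf_le = np.where(sd > 0, stats.norm.cdf(z), (mu <= 0).astype(float))
        cdf_ge = np.where(sd > 0, stats.norm.sf(z), (mu >= 0).astype(float))
        p_le += r_c[:, None] * cdf_le
        p_ge += r_c[:, None] * cdf_ge
    var_mix = np.clip(second - mean**2, 0.0, None)
    lfsr = np.minimum(p_le, p_ge)
    lfsr = np.clip(lfsr, 0.0, 1.0)
    bf = bayes_factor(B, S, mixture)
    return PosteriorSummary(
        pd.DataFrame(mean, index=index, columns=cols),
        pd.DataFrame(np.sqrt(var_mix), index=index, columns=cols),
        pd.DataFrame(lfsr, index=index, columns=cols),
        pd.Series(bf, index=index, name="bayes_factor"),
    )


def bayes_factor(bhat, shat, mixture: MixtureModel) -> np.ndarray:
    """Per-SNP Bayes factor: non-null mixture likelihood over the null.

    BF_j = [sum_{c != null} pi_c' N(b_j; 0, S_j + C_c)] / N(b_j; 0, S_j)
    with pi' the fitted weights renormalized over the non-null slices.
    Values above 10^2 are conventionally "decisive" evidence for at least
    one real effect.
    """
    B = np.atleast_2d(np.asarray(bhat, float))
    S = np.atleast_2d(np.asarray(shat, float))
    w = mixture.weights
    if len(w) < 2:
        raise ValueError("mixture has no non-null slices")
    non_null = w[1:]
    if non_null.sum() > 0:
        pi = non_null / non_null.sum()
    else:  # degenerate all-null fit: uniform prior over alternative slices
        pi = np.full(non_null.shape, 1.0 / non_null.size)
    L = _component_loglik(B, S, mixture.covs)
    log_alt = logsumexp(L[:, 1:] + np.log(np.maximum(pi, 1e-300)), axis=1)
    return np.exp(log_alt - L[:, 0])


def pairwise_sharing(
    post: PosteriorSummary,
    lfsr_max: float = 0.05,
    magnitude_factor: float = 2.0,
) -> pd.DataFrame:
    """Fraction of significant SNPs with shared sign and similar magnitude.

    For each phenotype pair, over SNPs significant (lfsr <= ``lfsr_max``)
    in at least one of the two: the fraction whose posterior means have the
    same sign and a magnitude ratio within [1/factor, factor].  Diagonal 1;
    pairs with no significant SNPs are missing.
    """
    M = post.post_mean.to_numpy(float)
    sig = (post.lfsr.to_numpy(float) <= lfsr_max)
    if not sig.any():
        raise ValueError("no SNP is significant in any phenotype")
    R = M.shape[1]
    out = np.full((R, R), np.nan)
    np.fill_diagonal(out, 1.0)
    for a in range(R):
        for b in range(a + 1, R):
            use = sig[:, a] | sig[:, b]
            if not use.any():
                continue
            ma, mb = M[use, a], M[use, b]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.abs(ma) / np.abs(mb)
            same_sign = np.sign(ma) * np.sign(mb) > 0
            similar = (ratio >= 1.0 / magnitude_factor) & (ratio <= magnitude_factor)
            out[a, b] = out[b, a] = float(np.mean(same_sign & similar))
    cols = list(post.post_mean.columns)
    return pd.DataFrame(out, index=cols, columns=cols)
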