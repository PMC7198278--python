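"""Mixed-linear-model association scans on entry-level genetic values.

The scan follows the standard two-step shortcut: variance components are
estimated once under the null model (kinship plus optional principal
components of the genotype matrix as fixed covariates), then every SNP is
tested by generalized least squares in the eigenbasis of the kinship matrix
with those variances held fixed — the "population parameters previously
determined" (P3D) approximation.  An exact mode refits the variance
components per SNP for oracle comparisons.

Also here: BIC-based choice of how many principal components to carry,
optional kinship compression (entries clustered into groups whose block-mean
kinship replaces the full matrix), Benjamini-Hochberg FDR flags, candidate
windows around peaks, top-SNP thinning, and the earliest-trial-year proxy
phenotype used to scan for allele-frequency change over a trial's history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genotypes import GenotypeMatrix, KinshipMatrix
from .reml import KinshipMixedLM

__all__ = [
    "GwasConfig",
    "MLMScan",
    "mlm_scan",
    "select_pcs_bic",
    "compress_kinship",
    "CompressedKinship",
    "bh_fdr",
    "candidate_window",
    "thin_top_snps",
    "earliest_year_phenotype",
]


@dataclass
class GwasConfig:
    """Scan settings: PC budget, FDR level, window size, compression."""

    max_pcs: int = 10
    fdr_q: float = 0.1
    window_bp: int = 20_000
    compression: bool = False

    def __post_init__(self):
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


def bh_fdr(pvals, q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``.

    Rejects the m0 smallest p-values where m0 is the largest i with
    p_(i) <= i q / m.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    flags = np.zeros(m, dtype=bool)
    if below.any():
        m0 = int(np.max(np.nonzero(below)[0])) + 1
        flags[order[:m0]] = True
    return flags


def select_pcs_bic(
    y: np.ndarray,
    pcs: np.ndarray,
    kinship: KinshipMatrix,
    max_pcs: int = 10,
) -> int:
    """Number of leading PCs whose null mixed model wins on BIC.

    Fits the null model with 0..max_pcs leading principal components as
    fixed covariates and returns the count with the best (smallest)
    BIC = -2 llf + p log n; ties break toward fewer PCs.
    """
    y = np.asarray(y, dtype=float).ravel()
    pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
    if max_pcs > pcs.shape[1]:
        raise ValueError("max_pcs exceeds available PCs")
    best_k, best_bic = 0, np.inf
    for k in range(max_pcs + 1):
        X = np.column_stack([np.ones(y.size), pcs[:, :k]])
        res = KinshipMixedLM(y, X, kinship).fit()
        if res.bic < best_bic - 1e-9:
            best_k, best_bic = k, res.bic
    return best_k


class MLMScan:
    """Per-SNP mixed-model association scan for one phenotype.

    Parameters
    ----------
    y : per-entry phenotype (e.g. BLUPs), aligned with ``geno.entry_ids``;
        a pandas Series is aligned by its index.
    geno : GenotypeMatrix (MAF-filtered, missing dosages allowed)
    kinship : KinshipMatrix over at least the scanned entries
    n_pcs : leading genotype PCs carried as fixed covariates
    """

    def __init__(
        self,
        y,
        geno: GenotypeMatrix,
        kinship: KinshipMatrix,
        n_pcs: int = 0,
        config: GwasConfig | None = None,
    ):
        self.config = config or GwasConfig()
        if isinstance(y, pd.Series):
            keep = [i for i, e in enumerate(geno.entry_ids) if e in y.index]
            if len(keep) < len(geno.entry_ids):
                geno = geno.take_entries(np.array(keep))
            y = y.reindex(geno.entry_ids).to_numpy(dtype=float)
        else:
            y = np.asarray(y, dtype=float).ravel()
        mask = ~np.isnan(y)
        if not mask.all():
            geno = geno.take_entries(np.nonzero(mask)[0])
            y = y[mask]
        if y.size != geno.n_entries:
            raise ValueError("phenotype and genotype entries do not align")
        if np.ptp(y) == 0.0:
            raise ValueError("phenotype is constant; scan is degenerate")
        self.y = y
        self.geno = geno.impute_missing()
        self.kinship = kinship.subset(self.geno.entry_ids)
        if n_pcs > 0:
            from .genotypes import genotype_pca

            self.pcs = genotype_pca(self.geno, n_pcs)
        else:
            self.pcs = np.zeros((self.geno.n_entries, 0))
        self.n_pcs = n_pcs

    def _null_design(self) -> np.ndarray:
        return np.column_stack([np.ones(self.y.size), self.pcs])

    def fit(self, exact: bool = False) -> pd.DataFrame:
        """Run the scan; returns one row per SNP.

        Columns: id, chrom, pos, ref, alt, maf, beta, se, p, fdr_significant.
        ``beta`` is the effect of one alternate-allele dose.  With
        ``exact=True`` the variance components are re-estimated for every
        SNP model (slow; used to quantify the shortcut's approximation).
        """
        X0 = self._null_design()
        null = KinshipMixedLM(self.y, X0, self.kinship).fit()
        self.null_fit_ = null
        if exact:
            beta, se, pval = self._scan_exact(X0)
        else:
            beta, se, pval = self._scan_p3d(X0, null)
        res = self.geno.snp_map.copy()
        if "id" not in res.columns:
            res["id"] = [
                f"{c}_{p}" for c, p in zip(res["chrom"], res["pos"])
            ]
        res["maf"] = self.geno.maf
        res["beta"] = beta
        res["se"] = se
        res["p"] = pval
        res["fdr_significant"] = bh_fdr(res["p"].to_numpy(), self.config.fdr_q)
        return res

    def _scan_p3d(self, X0, null):
        d, U = self.kinship.eig()
        w = null.va * np.clip(d, 0.0, None) + null.ve
        w = np.maximum(w, 1e-12 * w.max())
        sw = 1.0 / np.sqrt(w)
        ty = (U.T @ self.y) * sw
        tX0 = (U.T @ X0) * sw[:, None]
        tG = (U.T @ self.geno.dosages) * sw[:, None]
        # Frisch-Waugh: project out the null covariates, then per-SNP OLS
        Q, _ = np.linalg.qr(tX0)
        y_r = ty - Q @ (Q.T @ ty)
        G_r = tG - Q @ (Q.T @ tG)
        gg = np.einsum("ij,ij->j", G_r, G_r)
        gy = y_r @ G_r
        n, p0 = self.y.size, X0.shape[1]
        df = n - p0 - 1
        yy = float(y_r @ y_r)
        ok = gg > 1e-10 * max(1.0, float(np.max(gg)))
        beta = np.zeros(gg.size)
        se = np.full(gg.size, np.nan)
        pval = np.ones(gg.size)
        beta[ok] = gy[ok] / gg[ok]
        rss = np.maximum(yy - beta[ok] ** 2 * gg[ok], 0.0)
        sigma2 = rss / df
        se[ok] = np.sqrt(sigma2 / gg[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta[ok] / se[ok]
        pval[ok] = 2.0 * stats.t.sf(np.abs(tstat), df)
        pval = np.clip(pval, np.finfo(float).tiny, 1.0)
        return beta, se, pval

    def _scan_exact(self, X0):
        n, p0 = self.y.size, X0.shape[1]
        m = self.geno.n_snps
        beta = np.zeros(m)
        se = np.full(m, np.nan)
        pval = np.ones(m)
        for j in range(m):
            g = self.geno.dosages[:, j]
            if np.ptp(g) == 0.0:
                continue
            X = np.column_stack([X0, g])
            res = KinshipMixedLM(self.y, X, self.kinship).fit()
            beta[j] = res.params[-1]
            se[j] = res.bse[-1]
            t = beta[j] / se[j]
            pval[j] = 2.0 * stats.t.sf(abs(t), n - p0 - 1)
        return beta, se, np.clip(pval, np.finfo(float).tiny, 1.0)


def mlm_scan(
    y,
    geno: GenotypeMatrix,
    kinship: KinshipMatrix,
    n_pcs: int = 0,
    config: GwasConfig | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Functional wrapper around :class:`MLMScan`."""
    return MLMScan(y, geno, kinship, n_pcs=n_pcs, config=config).fit(exact=exact)


@dataclass
class CompressedKinship:
    """Group-level kinship with the entry-to-group assignment."""

    kinship: KinshipMatrix
    groups: pd.Series                      # entry id -> group index
    n_groups: int
    loglik_by_count: dict[int, float] = field(default_factory=dict)

    @property
    def incidence(self) -> np.ndarray:
        Z = np.zeros((len(self.groups), self.kinship.n))
        for r, g in enumerate(self.groups.to_numpy()):
            Z[r, g] = 1.0
        return Z


def compress_kinship(
    kinship: KinshipMatrix,
    candidate_group_counts: list[int],
    y=None,
    exog: np.ndarray | None = None,
) -> CompressedKinship:
    """Cluster entries and replace kinship by within/between block means.

    Entries are clustered by average linkage on the distance max(K) - K;
    for each candidate group count the compressed null model's restricted
    likelihood is evaluated (given ``y``; intercept-only fixed effects
    unless ``exog`` is passed) and the best count is returned.  Without a
    phenotype the finest candidate compression is returned unscored.  A
    small ridge is added if a compressed matrix is not PSD.
    """
    K = kinship.values
    n = K.shape[0]
    counts = sorted({int(c) for c in candidate_group_counts})
    if any(c < 1 or c > n for c in counts):
        raise ValueError("candidate group counts must lie in [1, n]")
    D = np.max(K) - K
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    link = linkage(squareform(D, checks=False), method="average")

    def build(c: int):
        if c == n:
            lab = np.arange(n)
        else:
            lab = fcluster(link, t=c, criterion="maxclust") - 1
        c_eff = int(lab.max()) + 1
        Z = np.zeros((n, c_eff))
        Z[np.arange(n), lab] = 1.0
        sizes = Z.sum(axis=0)
        Kg = (Z.T @ K @ Z) / np.outer(sizes, sizes)
        w = np.linalg.eigvalsh((Kg + Kg.T) / 2.0)
        if w.min() < -1e-8:
            Kg = Kg + (1e-8 - w.min()) * np.eye(c_eff)
        return KinshipMatrix((Kg + Kg.T) / 2.0), lab, Z

    if y is None:
        c = counts[-1]
        Kg, lab, _ = build(c)
        return CompressedKinship(
            Kg, pd.Series(lab, index=kinship.entry_ids), int(lab.max()) + 1
        )

    y = np.asarray(y, dtype=float).ravel()
    X = exog if exog is not None else np.ones((n, 1))
    best = None
    scores: dict[int, float] = {}
    for c in counts:
        Kg, lab, Z = build(c)
        mm = KinshipMixedLM(y, X, Kg, incidence=None if c == n else Z)
        res = mm.fit()
        scores[c] = res.llf
        if best is None or res.llf > scores[best[0]]:
            best = (c, Kg, lab)
    c, Kg, lab = best
    return CompressedKinship(
        Kg, pd.Series(lab, index=kinship.entry_ids), int(lab.max()) + 1, scores
    )


def candidate_window(chrom: str, pos: int, window_bp: int = 20_000):
    """Interval of ``window_bp`` centered on a peak SNP, clamped at 1."""
    if pos < 1:
        raise ValueError("position must be >= 1")
    half = window_bp // 2
    return (chrom, max(1, pos - half), pos + half)


def thin_top_snps(
    results: pd.DataFrame, n_top: int = 10, window_bp: int = 20_000
) -> pd.DataFrame:
    """Keep the ``n_top`` smallest-p SNPs, one per ``window_bp`` region.

    SNPs are scanned in ascending p; a SNP is kept only when no kept SNP
    lies within ``window_bp`` on the same chromosome.
    """
    ordered = results.sort_values("p", kind="stable")
    kept: list[int] = []
    kept_pos: dict[str, list[int]] = {}
    for idx, row in ordered.iterrows():
        c, pos = row["chrom"], row["pos"]
        if any(abs(pos - q) <= window_bp for q in kept_pos.get(c, [])):
            continue
        kept.append(idx)
        kept_pos.setdefault(c, []).append(pos)
        if len(kept) >= n_top:
            break
    return results.loc[kept]


def earliest_year_phenotype(table: pd.DataFrame) -> pd.Series:
    """Earliest trial year per entry, a proxy for the entry's age.

    Usable directly as a scan phenotype to detect allele-frequency change
    over the trial's history.
    """
    s = table.groupby("entry")["year"].min()
    s.name = "earliest_year"
    return s.astype(float)
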