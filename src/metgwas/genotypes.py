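"""Genotype and kinship containers with the standard panel operations.

The central objects are :class:`GenotypeMatrix` — an entries x SNPs matrix of
alternate-allele dosages together with a SNP map — and
:class:`KinshipMatrix`, the genomic relationship matrix estimated from it.
Dosages are oriented as counts of the ALT allele (0, 1 or 2 for biallelic
inbred material); all downstream effect signs refer to the alternate allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "maf_filter",
    "vanraden_kinship",
    "genotype_pca",
    "ld_prune",
    "read_vcf",
    "read_dosage_tsv",
    "write_vcf",
    "write_dosage_tsv",
]


@dataclass
class GenotypeMatrix:
    """Entries x SNPs alternate-allele dosage matrix with its SNP map.

    Parameters
    ----------
    dosages : ndarray of shape (n_entries, n_snps)
        Alternate-allele dosages in [0, 2].  ``nan`` marks missing calls.
    snp_map : DataFrame with columns chrom, pos, ref, alt (pos is 1-based bp)
    entry_ids : sequence of entry identifiers
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    entry_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D entries x SNPs matrix")
        if self.dosages.shape[1] == 0:
            raise ValueError("genotype matrix has zero SNPs")
        if len(self.snp_map) != self.dosages.shape[1]:
            raise ValueError(
                f"snp_map has {len(self.snp_map)} rows but dosages has "
                f"{self.dosages.shape[1]} columns"
            )
        if not self.entry_ids:
            self.entry_ids = [f"entry{i:04d}" for i in range(self.dosages.shape[0])]
        if len(self.entry_ids) != self.dosages.shape[0]:
            raise ValueError("entry_ids length does not match dosage rows")
        self.snp_map = self.snp_map.reset_index(drop=True)
        # positions must be strictly increasing within each chromosome
        for chrom, sub in self.snp_map.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_entries(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def alt_freq(self) -> np.ndarray:
        """Per-SNP alternate-allele frequency, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        p = self.alt_freq
        return np.minimum(p, 1.0 - p)

    def impute_missing(self) -> "GenotypeMatrix":
        """Replace missing dosages by the per-SNP mean dosage."""
        if not np.any(np.isnan(self.dosages)):
            return self
        filled = self.dosages.copy()
        col_mean = np.nanmean(filled, axis=0)
        idx = np.where(np.isnan(filled))
        filled[idx] = col_mean[idx[1]]
        return GenotypeMatrix(filled, self.snp_map.copy(), list(self.entry_ids))

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.snp_map.iloc[index].reset_index(drop=True),
            list(self.entry_ids),
        )

    def take_entries(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index, :],
            self.snp_map.copy(),
            [self.entry_ids[i] for i in index],
        )


class KinshipMatrix:
    """Symmetric genomic relationship matrix with a cached eigendecomposition."""

    def __init__(self, values: np.ndarray, entry_ids: Sequence | None = None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("kinship must be a square matrix")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric (tolerance 1e-10)")
        self.values = (values + values.T) / 2.0
        if entry_ids is None:
            entry_ids = [f"entry{i:04d}" for i in range(values.shape[0])]
        if len(entry_ids) != values.shape[0]:
            raise ValueError("entry_ids length does not match kinship order")
        self.entry_ids = list(entry_ids)
        self._eig: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending) and eigenvectors, computed once and cached."""
        if self._eig is None:
            w, v = np.linalg.eigh(self.values)
            if w.min() < -1e-8 * max(1.0, abs(w.max())):
                raise ValueError("kinship is not PSD beyond numerical tolerance")
            self._eig = (w, v)
        return self._eig

    def sqrt(self) -> np.ndarray:
        """Symmetric PSD square root."""
        w, v = self.eig()
        return (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T

    def subset(self, ids: Sequence) -> "KinshipMatrix":
        pos = {e: i for i, e in enumerate(self.entry_ids)}
        missing = [e for e in ids if e not in pos]
        if missing:
            raise KeyError(f"entries absent from kinship: {missing[:5]}")
        idx = np.array([pos[e] for e in ids])
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entry_ids, columns=self.entry_ids)


def maf_filter(geno: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Retain SNPs whose minor-allele frequency exceeds ``threshold``.

    The conventional panel filter: a SNP is kept when
    ``min(p, 1 - p) > threshold`` with ``p`` its alternate-allele frequency.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    keep = np.where(geno.maf > threshold)[0]
    if keep.size == 0:
        raise ValueError("no SNPs pass the MAF filter")
    return geno.take_snps(keep)


def vanraden_kinship(geno: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix.

    K = Z Z' / (2 * sum_j p_j (1 - p_j)) where Z is the dosage matrix with
    each column centered by twice its alternate-allele frequency.  Missing
    dosages are mean-imputed per SNP first.
    """
    if geno.n_entries < 2:
        raise ValueError("kinship needs at least two entries")
    geno = geno.impute_missing()
    p = geno.alt_freq
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    Z = geno.dosages - 2.0 * p
    K = (Z @ Z.T) / denom
    return KinshipMatrix(K, geno.entry_ids)


def genotype_pca(geno: GenotypeMatrix, n_pcs: int) -> np.ndarray:
    """Principal-component scores of the column-centered dosage matrix.

    Scores are ordered by decreasing variance explained.  Sign convention:
    within each component, the loading of largest magnitude is positive, so
    results are deterministic across LAPACK builds.
    """
    if n_pcs <= 0:
        return np.zeros((geno.n_entries, 0))
    if n_pcs >= min(geno.n_entries, geno.n_snps):
        raise ValueError("n_pcs must be < min(entries, SNPs)")
    geno = geno.impute_missing()
    Z = geno.dosages - geno.dosages.mean(axis=0)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    for k in range(n_pcs):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    return U[:, :n_pcs] * s[:n_pcs]


def ld_prune(
    geno: GenotypeMatrix, r2_max: float = 0.2, window_bp: int = 100_000
) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning within a physical window.

    Scanning each chromosome in map order, a SNP is dropped when its squared
    Pearson correlation with any already-retained SNP within ``window_bp``
    exceeds ``r2_max``.  The scan is per chromosome, so the result does not
    depend on chromosome processing order.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must lie in (0, 1]")
    geno = geno.impute_missing()
    X = geno.dosages
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    keep: list[int] = []
    for chrom, sub in geno.snp_map.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        kept_local: list[int] = []  # positions into idx
        for i in range(len(idx)):
            j_global = idx[i]
            if norms[j_global] == 0.0:
                continue  # monomorphic: carries no information, drop
            ok = True
            for k in reversed(kept_local):
                if pos[i] - pos[k] > window_bp:
                    break
                g = idx[k]
                r = (Xc[:, j_global] @ Xc[:, g]) / (norms[j_global] * norms[g])
                if r * r > r2_max:
                    ok = False
                    break
            if ok:
                kept_local.append(i)
                keep.append(j_global)
    keep_arr = np.sort(np.array(keep, dtype=int))
    return geno.take_snps(keep_arr)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix using GT-based ALT dosages."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    entry_ids = list(vcf.samples)
    rows = []
    dosage_cols = []
    for var in vcf:
        # gt_types with gts012: 0=hom ref, 1=het, 2=hom alt, 3=missing
        gt = var.gt_types.astype(float)
        gt[gt == 3] = np.nan
        dosage_cols.append(gt)
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
    vcf.close()
    if not rows:
        raise ValueError(f"no variants found in {path}")
    snp_map = pd.DataFrame(rows)
    dosages = np.column_stack(dosage_cols)
    if np.any(np.all(np.isnan(dosages), axis=0)):
        raise ValueError("VCF contains an all-missing SNP column")
    return GenotypeMatrix(dosages, snp_map, entry_ids)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write unphased GT-only VCF (text, uncompressed)."""
    contigs = list(dict.fromkeys(geno.snp_map["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=metgwas\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(e) for e in geno.entry_ids)
            + "\n"
        )
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in geno.snp_map.iterrows():
            d = geno.dosages[:, j]
            calls = []
            for x in d:
                if np.isnan(x):
                    calls.append("./.")
                else:
                    calls.append(gt_code[int(round(x))])
            snp_id = row["id"] if "id" in row.index else f"{row['chrom']}_{row['pos']}"
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp_id}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Read the paired dosage-matrix / SNP-map TSV written by write_dosage_tsv."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    map_path = str(path).replace(".tsv", "") + ".map.tsv"
    snp_map = pd.read_csv(map_path, sep="\t")
    return GenotypeMatrix(df.to_numpy(dtype=float), snp_map, list(df.index))


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    cols = [f"{c}_{p}" for c, p in zip(geno.snp_map["chrom"], geno.snp_map["pos"])]
    pd.DataFrame(geno.dosages, index=geno.entry_ids, columns=cols).to_csv(
        path, sep="\t", index_label="entry"
    )
    map_path = str(path).replace(".tsv", "") + ".map.tsv"
    geno.snp_map.to_csv(map_path, sep="\t", index=False)
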