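"""Cross-study association-overlap analysis.

Given a catalog of GWAS associations (study, trait, chromosome, position in
Mb, optional candidate gene), this module clusters associations into
overlapping genomic regions by single-linkage within a distance threshold —
optionally also requiring a shared candidate gene — counts multi-study
overlaps, and compares overlap rates between two sets of studies with a
Pearson chi-square test.

A transcription of a published common-bean association catalog (80
literature associations from 11 balanced-panel GWAS plus the sparse-trial
associations they were compared against) ships with the package as the
default input.  Positions printed as ranges are represented by their
midpoint; two associations link when their distance is strictly below the
threshold (ties at the printed 10-kb resolution do not link) and, when the
same-gene criterion is active, when both name the same candidate gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "OverlapGroup",
    "load_catalog",
    "group_associations",
    "overlap_counts",
    "overlap_rate_test",
    "percent_yield_change",
]

_VALID_CHROMS = {f"Pv{i:02d}" for i in range(1, 12)}


@dataclass
class OverlapGroup:
    """A cluster of >= 2 catalog associations on one chromosome."""

    members: pd.DataFrame
    chrom: str
    span_kb: float
    n_studies: int

    @property
    def n_members(self) -> int:
        return len(self.members)


def _normalize_chrom(c) -> str:
    s = str(c)
    if s in _VALID_CHROMS:
        return s
    try:
        return f"Pv{int(float(s)):02d}"
    except ValueError:
        raise ValueError(f"unrecognized chromosome {c!r}") from None


def load_catalog(path=None) -> pd.DataFrame:
    """Load an association catalog TSV (bundled catalog when path is None).

    Expected columns: study, trait, chrom, and either pos_mb or
    pos_mb_start/pos_mb_end, plus optional candidate_gene, fdr_flag and
    published.  Adds a pos_kb column (range midpoints) and normalizes
    chromosome names to Pv01..Pv11.
    """
    if path is None:
        ref = resources.files("metgwas.data") / "association_catalog.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype={"candidate_gene": "string"})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"candidate_gene": "string"})
    df["chrom"] = df["chrom"].map(_normalize_chrom)
    if "pos_mb" in df.columns:
        mid = df["pos_mb"].astype(float)
    else:
        mid = (df["pos_mb_start"].astype(float) + df["pos_mb_end"].astype(float)) / 2.0
    if (mid <= 0).any():
        raise ValueError("positions must be positive")
    df["pos_kb"] = mid * 1000.0
    if "candidate_gene" not in df.columns:
        df["candidate_gene"] = pd.NA
    return df


def group_associations(
    entries: pd.DataFrame,
    threshold_kb: float,
    require_same_gene: bool = False,
) -> list[OverlapGroup]:
    """Single-linkage clusters of associations within a distance threshold.

    Two associations on the same chromosome link when |delta pos| is
    strictly below ``threshold_kb`` and — if ``require_same_gene`` — both
    carry the same, non-missing candidate gene.  Clusters are connected
    components of the link graph; only groups with >= 2 members are
    returned, ordered by chromosome and position.  The result does not
    depend on input row order.
    """
    df = entries.reset_index(drop=True)
    if "pos_kb" not in df.columns:
        if "pos_mb" in df.columns:
            df["pos_kb"] = df["pos_mb"].astype(float) * 1000.0
        else:
            raise ValueError("entries need a pos_kb or pos_mb column")
    if "candidate_gene" not in df.columns:
        df["candidate_gene"] = pd.NA
    groups: list[OverlapGroup] = []
    for chrom in sorted(df["chrom"].unique()):
        sub = df[df["chrom"] == chrom]
        idx = sub.index.to_numpy()
        pos = sub["pos_kb"].to_numpy(dtype=float)
        genes = sub["candidate_gene"].to_numpy(dtype=object)
        n = len(idx)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if abs(pos[i] - pos[j]) >= threshold_kb:
                    continue
                if require_same_gene:
                    gi, gj = genes[i], genes[j]
                    if pd.isna(gi) or pd.isna(gj) or str(gi) != str(gj):
                        continue
                parent[find(i)] = find(j)
        comp: dict[int, list[int]] = {}
        for i in range(n):
            comp.setdefault(find(i), []).append(i)
        for members in comp.values():
            if len(members) < 2:
                continue
            rows = df.loc[idx[members]].sort_values("pos_kb")
            groups.append(
                OverlapGroup(
                    members=rows,
                    chrom=chrom,
                    span_kb=float(rows["pos_kb"].max() - rows["pos_kb"].min()),
                    n_studies=int(rows["study"].nunique()),
                )
            )
    groups.sort(key=lambda g: (g.chrom, g.members["pos_kb"].min()))
    return groups


def overlap_counts(groups: list[OverlapGroup]) -> tuple[int, int]:
    """(number of associations inside groups, number of groups)."""
    return sum(g.n_members for g in groups), len(groups)


def overlap_rate_test(
    a_in: int, a_total: int, b_in: int, b_total: int
) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) comparing overlap rates.

    The 2x2 table is {in overlap, not in overlap} x {set A, set B}.
    Returns (chi2, p).
    """
    if a_in > a_total or b_in > b_total:
        raise ValueError("counts cannot exceed totals")
    table = np.array(
        [[a_in, a_total - a_in], [b_in, b_total - b_in]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a margin is zero")
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def percent_yield_change(effect: float, median: float) -> float:
    """Effect size as a percentage of the population median, 1 d.p.

    Puts an allele-substitution effect (trait units) in context relative to
    a subpopulation's median phenotype.
    """
    if median <= 0:
        raise ValueError("median must be positive")
    return round(100.0 * effect / median, 1)
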