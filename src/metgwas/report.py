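"""Plot-ready summary tables: QQ coordinates, Manhattan data, UpSet counts.

Plots themselves are left to the caller; everything here returns plain
DataFrames that can be written as TSV and drawn with any tool.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["qq_coordinates", "manhattan_table", "upset_counts"]


def qq_coordinates(pvals) -> pd.DataFrame:
    """Expected vs observed -log10 p for a quantile-quantile plot.

    Observed p-values are sorted ascending; the i-th expected quantile is
    -log10((i - 0.5) / m).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return pd.DataFrame({"expected": [], "observed": []})
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    obs = -np.log10(np.sort(p))[::-1]
    m = p.size
    exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)[::-1]
    return pd.DataFrame({"expected": exp[::-1], "observed": obs[::-1]})


def manhattan_table(results: pd.DataFrame) -> pd.DataFrame:
    """Cumulative genome coordinate and -log10 p for a Manhattan plot."""
    out = results[["chrom", "pos", "p"]].copy().reset_index(drop=True)
    offset = 0
    coords = np.empty(len(out))
    for chrom, sub in out.groupby("chrom", sort=True):
        coords[sub.index] = sub["pos"].to_numpy() + offset
        offset += sub["pos"].max() + 1_000_000
    out["genome_pos"] = coords
    out["neglog10p"] = -np.log10(out["p"])
    return out


def upset_counts(sets: dict[str, list]) -> pd.DataFrame:
    """Exact-intersection counts over named sets (UpSet-style).

    Every element of the union is assigned to exactly one membership
    pattern (the tuple of sets it belongs to); counts over patterns sum to
    the union size.  Returns a DataFrame with one 0/1 column per set name
    plus a ``count`` column, sorted by decreasing count.
    """
    if not sets:
        raise ValueError("need at least one named set")
    names = list(sets)
    members = {n: set(s) for n, s in sets.items()}
    universe = set().union(*members.values())
    patterns: dict[tuple[int, ...], int] = {}
    for x in universe:
        pat = tuple(int(x in members[n]) for n in names)
        patterns[pat] = patterns.get(pat, 0) + 1
    rows = [dict(zip(names, pat), count=c) for pat, c in patterns.items()]
    df = pd.DataFrame(rows).sort_values("count", ascending=False).reset_index(drop=True)
    return df
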