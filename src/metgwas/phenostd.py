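"""Harmonization of heterogeneous trait scales and outlier-cell removal.

Long-running trial networks score the same trait on different scales at
different locations and in different years (percent scales, 1-5, 0-9, 1-9
visual scores).  This module maps such records onto one common scale by an
endpoint-preserving affine transform, removes location x year cells whose
mean is an IQR outlier for the trait, and provides the BLUP correlation
matrix used to describe genetic correlations between traits.

Outlier fences follow the Tukey rule applied to the distribution of
location x year cell MEANS for a trait: the whole cell is dropped when its
mean falls below Q1 - 1.5 IQR or above Q3 + 1.5 IQR, so no cell is ever
partially removed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScaleSpec",
    "harmonize_scale",
    "harmonize_table",
    "remove_outlier_cells",
    "aggregate_duplicates",
    "correlate_blups",
    "load_scale_registry",
    "LOCATION_CODE_RE",
]

# four-letter location codes, state/province prefix, optional trailing "2"
# for a second (treated) trial at the same site and year
LOCATION_CODE_RE = re.compile(r"^[A-Z]{2}[A-Za-z]{2}2?$")


@dataclass(frozen=True)
class ScaleSpec:
    """A named measurement scale with its endpoints."""

    name: str
    kind: str  # percent | ordinal | continuous
    lo: float
    hi: float

    def __post_init__(self):
        if self.kind not in ("percent", "ordinal", "continuous"):
            raise ValueError(f"unknown scale kind {self.kind!r}")
        if not self.lo < self.hi:
            raise ValueError(f"scale {self.name}: lo must be < hi")


def harmonize_scale(
    value: float, from_spec: ScaleSpec, to_spec: ScaleSpec, record: str = ""
) -> float:
    """Affine map taking ``from_spec``'s endpoints onto ``to_spec``'s.

    lo maps to lo and hi to hi; interior values map linearly.  Ordinal
    outputs are deliberately not rounded: downstream mixed models treat the
    harmonized scores as continuous.
    """
    tol = 1e-9
    if value < from_spec.lo - tol or value > from_spec.hi + tol:
        where = f" in record {record}" if record else ""
        raise ValueError(
            f"value {value} outside scale {from_spec.name} "
            f"[{from_spec.lo}, {from_spec.hi}]{where}"
        )
    frac = (value - from_spec.lo) / (from_spec.hi - from_spec.lo)
    return to_spec.lo + (to_spec.hi - to_spec.lo) * frac


def harmonize_table(
    table: pd.DataFrame,
    registry: dict[tuple[str, str], tuple[ScaleSpec, ScaleSpec]],
    trait_col: str = "trait",
    source_col: str = "source_scale",
) -> pd.DataFrame:
    """Harmonize every record whose (trait, source scale) is in the registry.

    Records with no registry entry pass through unchanged.  Adds a boolean
    ``harmonized`` provenance column.
    """
    out = table.copy()
    out["harmonized"] = False
    if source_col not in out.columns:
        return out
    for (trait, source), (f_spec, t_spec) in registry.items():
        mask = (out[trait_col] == trait) & (out[source_col] == source)
        if not mask.any():
            continue
        vals = out.loc[mask, "value"].to_numpy(dtype=float)
        out.loc[mask, "value"] = [
            harmonize_scale(v, f_spec, t_spec, record=f"{trait}/{source}")
            for v in vals
        ]
        out.loc[mask, "harmonized"] = True
    return out


def aggregate_duplicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate (entry, location, year, trait) records.

    Plot means are the unit of record in trial reports; repeated rows for
    the same cell are collapsed to their mean before any filtering.
    """
    keys = ["entry", "location", "year", "trait"]
    if not table.duplicated(subset=keys).any():
        return table.reset_index(drop=True)
    extra = [c for c in table.columns if c not in keys + ["value"]]
    agg = {"value": "mean", **{c: "first" for c in extra}}
    return table.groupby(keys, as_index=False, sort=False).agg(agg)


def remove_outlier_cells(
    table: pd.DataFrame, trait: str, k: float = 1.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop every record of location x year cells with outlying means.

    For the given trait, each location x year cell's mean is computed; Tukey
    fences at ``k`` times the IQR are placed on the distribution of those
    cell means, and ALL records of any cell outside the fences are removed
    (never a partial cell).  Returns the filtered table (all traits) and a
    log of dropped cells with their means and the fences.

    With fewer than 4 cells the fences are not estimable; a warning is
    issued and nothing is filtered.
    """
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in table")
    means = sub.groupby(["location", "year"])["value"].mean()
    if len(means) < 4:
        warnings.warn(
            f"trait {trait!r}: only {len(means)} location x year cells; "
            "outlier fences not estimable, no filtering applied"
        )
        return table.reset_index(drop=True), means.reset_index().iloc[0:0]
    q1, q3 = means.quantile(0.25), means.quantile(0.75)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    bad = means[(means < lo) | (means > hi)]
    log = bad.reset_index().rename(columns={"value": "cell_mean"})
    log["trait"] = trait
    log["fence_lo"] = lo
    log["fence_hi"] = hi
    if bad.empty:
        return table.reset_index(drop=True), log
    bad_keys = set(bad.index)
    drop_mask = (
        (table["trait"] == trait)
        & table.set_index(["location", "year"]).index.isin(bad_keys)
    )
    return table[~drop_mask].reset_index(drop=True), log


def correlate_blups(blups: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between per-entry genetic values.

    Uses entries with both traits observed for each pair; traits that are
    constant (zero variance) get missing correlations off the diagonal.
    Requires at least 3 complete pairs somewhere in the table.
    """
    if blups.shape[0] < 3:
        raise ValueError("need at least 3 entries to correlate BLUPs")
    corr = blups.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def load_scale_registry(path) -> dict[tuple[str, str], tuple[ScaleSpec, ScaleSpec]]:
    """Read a YAML scale registry.

    Format::

        lodging:
          target: {kind: ordinal, lo: 1, hi: 5}
          sources:
            percent: {kind: percent, lo: 0, hi: 100}
            score09: {kind: ordinal, lo: 0, hi: 9}

    Returns a mapping (trait, source name) -> (source spec, target spec).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    registry = {}
    for trait, spec in raw.items():
        tgt = spec["target"]
        t_spec = ScaleSpec(f"{trait}:target", tgt["kind"], float(tgt["lo"]), float(tgt["hi"]))
        for source, s in spec.get("sources", {}).items():
            s_spec = ScaleSpec(f"{trait}:{source}", s["kind"], float(s["lo"]), float(s["hi"]))
            registry[(trait, source)] = (s_spec, t_spec)
    return registry
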