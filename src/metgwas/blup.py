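"""Entry-level genetic BLUPs from sparse trial records.

Fits the record-level mixed model

    y = mu + location + location:year + g + e,
    g ~ N(0, Va * K),   e ~ N(0, Ve * I),

where records map to entries through an incidence matrix, location and the
location-by-year interaction are fixed effects, and K is the genomic
relationship matrix.  The REML variance components come from the spectral
engine in :mod:`metgwas.reml`; the returned genetic values are empirical
BLUPs at those variances, reported as deviations (centered), for entries
phenotyped at least once.

Unbalanced designs routinely produce aliased fixed-effect columns (a
location x year cell observed once, locations nested in a single year);
these are detected by pivoted QR and dropped, and the dropped names are
reported on the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import KinshipMatrix
from .reml import KinshipMixedLM, KinshipMixedLMResults, drop_aliased_columns

__all__ = ["EntryBlup", "EntryBlupResults", "fit_blup", "narrow_sense_h2"]


def narrow_sense_h2(va: float, ve: float) -> float:
    """Narrow-sense heritability h2 = Va / (Va + Ve)."""
    if va < 0 or ve < 0:
        raise ValueError("variance components must be non-negative")
    if va + ve == 0:
        raise ValueError("h2 undefined when Va + Ve = 0")
    return va / (va + ve)


class EntryBlup:
    """Mixed model for one trait's records from a sparse trial design.

    Parameters
    ----------
    table : DataFrame with columns entry, location, year, trait, value
    trait : which trait's records to model
    kinship : KinshipMatrix; must contain every phenotyped entry
    """

    def __init__(self, table: pd.DataFrame, trait: str, kinship: KinshipMatrix):
        sub = table[table["trait"] == trait].reset_index(drop=True)
        if sub.empty:
            raise ValueError(f"no records for trait {trait!r}")
        if sub["location"].nunique() < 2:
            raise ValueError("need records from at least 2 locations")
        entries = sorted(sub["entry"].unique())
        known = set(kinship.entry_ids)
        missing = [e for e in entries if e not in known]
        if missing:
            raise KeyError(
                f"entries phenotyped but absent from kinship: {missing[:5]}"
            )
        self.trait = trait
        self.entries = entries
        self.kinship = kinship.subset(entries)
        self.records = sub

        y = sub["value"].to_numpy(dtype=float)
        X, names, dropped = self._fixed_design(sub)
        n_rec = len(sub)
        Z = np.zeros((n_rec, len(entries)))
        eidx = {e: i for i, e in enumerate(entries)}
        for r, e in enumerate(sub["entry"]):
            Z[r, eidx[e]] = 1.0
        self.endog = y
        self.exog = X
        self.exog_names = names
        self.dropped_columns = dropped
        self.incidence = Z
        self._mm = KinshipMixedLM(y, X, self.kinship, incidence=Z)

    @staticmethod
    def _fixed_design(sub: pd.DataFrame):
        loc = sub["location"].astype(str)
        ly = loc + ":" + sub["year"].astype(str)
        loc_d = pd.get_dummies(loc, prefix="loc", drop_first=True, dtype=float)
        ly_d = pd.get_dummies(ly, prefix="locyear", drop_first=True, dtype=float)
        X = np.column_stack(
            [np.ones(len(sub)), loc_d.to_numpy(), ly_d.to_numpy()]
        )
        names = ["intercept"] + list(loc_d.columns) + list(ly_d.columns)
        return drop_aliased_columns(X, names)

    def fit(self) -> "EntryBlupResults":
        fit = self._mm.fit()
        g = fit.blup()
        g = g - g.mean()  # genetic values reported as deviations
        blups = pd.Series(g, index=self.entries, name=self.trait)
        return EntryBlupResults(self, fit, blups)


class EntryBlupResults:
    """BLUPs plus the REML fit they were derived from."""

    def __init__(self, model: EntryBlup, fit: KinshipMixedLMResults, blups: pd.Series):
        self.model = model
        self.fit = fit
        self.blups = blups
        self.n_records_used = len(model.records)

    @property
    def va(self) -> float:
        return self.fit.va

    @property
    def ve(self) -> float:
        return self.fit.ve

    @property
    def h2(self) -> float:
        return narrow_sense_h2(self.fit.va, self.fit.ve)

    def to_frame(self) -> pd.DataFrame:
        n_obs = self.model.records.groupby("entry").size()
        return pd.DataFrame(
            {
                "entry": self.blups.index,
                "blup": self.blups.to_numpy(),
                "n_obs": n_obs.reindex(self.blups.index).to_numpy(),
            }
        )

    def summary(self) -> str:
        lines = [
            f"Entry BLUPs for {self.model.trait!r}",
            "=" * 44,
            f"records: {self.n_records_used}   entries: {len(self.blups)}",
            f"Va: {self.va:.6g}   Ve: {self.ve:.6g}   h2: {self.h2:.4f}",
            f"BLUP range: {self.blups.max() - self.blups.min():.6g}",
            f"aliased fixed-effect columns dropped: {len(self.model.dropped_columns)}",
        ]
        return "\n".join(lines)


def fit_blup(table: pd.DataFrame, trait: str, kinship: KinshipMatrix) -> EntryBlupResults:
    """Convenience wrapper: build and fit :class:`EntryBlup` in one call."""
    return EntryBlup(table, trait, kinship).fit()
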