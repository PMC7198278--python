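"""Synthetic sparse multi-environment-trial (MET) data with known truth.

The generator emulates the statistical structure of a long-running cooperative
variety trial: a few hundred inbred entries from a small number of diverged
subpopulations, dense biallelic SNPs in LD blocks, a sparse entry x location x
year testing design driven by entry turnover, and additive phenotypes with
location and location-by-year environmental effects plus planted pleiotropic
QTL whose effects are sign-coherent within trait groups.

Population structure uses the Balding-Nichols construction: each SNP has an
ancestral frequency drawn Uniform(0.1, 0.9) and subpopulation frequencies
drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) at divergence F.  Genotypes are
sampled under inbreeding coefficient f (heterozygote frequency deflated by
1 - f).  LD blocks are modelled by copying the previous SNP column and
re-drawing each entry's genotype with a small per-site perturbation
probability, which gives r^2 near 1 within blocks and near 0 between them.

Every function derives its random stream from ``config.seed`` plus a fixed
stage offset, so identical configurations give byte-identical outputs and the
stages can be re-run independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "TraitSpec",
    "SimConfig",
    "SimTruth",
    "default_sim_config",
    "simulate_genotypes",
    "simulate_design",
    "simulate_phenotypes",
]

_CHROMS = [f"Pv{i:02d}" for i in range(1, 12)]
_STATE_CODES = [
    "ND", "MI", "NE", "CO", "WA", "ID", "OR", "CA", "NY", "WI", "MN", "MT",
    "WY", "KS", "ON", "MB", "AB", "SK", "TX", "FL", "GA", "NC", "MD", "PA",
    "UT", "NM", "AZ", "WV", "VA", "OK", "SD", "IA",
]


@dataclass
class TraitSpec:
    """One simulated trait: target heritability, reporting scale and group.

    ``group_id`` ties traits into pleiotropy clusters: planted QTL have
    sign-coherent effect vectors within a group and no effect outside it.
    ``scale_type`` is ``continuous``, ``percent`` or ``ordinal:<lo>:<hi>``.
    """

    name: str
    h2_target: float
    scale_type: str = "continuous"
    group_id: int = 0

    def __post_init__(self):
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError(f"h2_target must be in [0, 1], got {self.h2_target}")


@dataclass
class SimConfig:
    """Design constants for the synthetic MET.

    Defaults mirror a long-running bean variety trial: ~327 inbred entries in
    three subpopulations, high selfing, 16-61 entries and 10-28 locations per
    year, and a median of 2 distinct trial years per tested entry.
    """

    n_entries: int = 327
    n_subpops: int = 3
    fst: float = 0.3
    inbreeding: float = 0.95
    n_snps: int = 5000
    ld_block_size: int = 10
    n_locations: int = 28
    n_years: int = 20
    start_year: int = 1981
    entries_per_year_range: tuple[int, int] = (16, 61)
    locations_per_year_range: tuple[int, int] = (10, 28)
    years_per_entry_median: int = 2
    trait_specs: list[TraitSpec] = field(default_factory=list)
    planted_qtl: list[tuple[int, np.ndarray]] = field(default_factory=list)
    var_location: list[float] = field(default_factory=list)
    var_locyear: list[float] = field(default_factory=list)
    var_error: list[float] = field(default_factory=list)
    flip_prob: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("n_entries", "n_subpops", "n_snps", "ld_block_size",
                     "n_locations", "n_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if not 0.0 <= self.inbreeding <= 1.0:
            raise ValueError(f"inbreeding must be in [0, 1], got {self.inbreeding}")
        lo, hi = self.entries_per_year_range
        if not (1 <= lo <= hi <= self.n_entries):
            raise ValueError("entries_per_year_range must lie within [1, n_entries]")
        lo, hi = self.locations_per_year_range
        if not (1 <= lo <= hi <= self.n_locations):
            raise ValueError(
                "locations_per_year_range must lie within [1, n_locations]"
            )
        if self.years_per_entry_median < 1:
            raise ValueError("years_per_entry_median must be >= 1")
        n_t = len(self.trait_specs)
        for name in ("var_location", "var_locyear", "var_error"):
            v = getattr(self, name)
            if v and len(v) != n_t:
                raise ValueError(f"{name} must have one value per trait")

    @property
    def n_traits(self) -> int:
        return len(self.trait_specs)

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated phenotypes."""

    true_breeding_values: pd.DataFrame      # entries x traits, latent units
    qtl_effects: pd.DataFrame               # planted snp x trait effects
    realized_h2: dict[str, float]
    subpop_labels: np.ndarray
    location_effects: pd.DataFrame | None = None
    locyear_effects: pd.DataFrame | None = None


def default_sim_config(
    n_entries: int = 327,
    n_snps: int = 5000,
    n_traits: int = 8,
    seed: int = 0,
    qtl_variance_share: float = 0.35,
    n_qtl_per_group: int = 3,
    h2_grid: tuple[float, ...] | None = None,
) -> SimConfig:
    """Study-condition defaults with two pleiotropy groups of traits.

    Trait heritabilities span the wide range seen in real trial data (~0.07
    to ~0.73).  Planted QTL sit at LD-block starts on distinct chromosomes;
    within a group every QTL affects all group traits with the same sign,
    and per-trait magnitudes are scaled so the planted QTL jointly explain
    about ``qtl_variance_share`` of each group trait's additive variance
    (the polygenic term supplies the rest, keeping realized h2 on target).
    """
    if h2_grid is None:
        h2_grid = (0.733, 0.5, 0.4, 0.3, 0.25, 0.2, 0.1, 0.067)
    specs = []
    for t in range(n_traits):
        h2 = h2_grid[t % len(h2_grid)]
        group = 0 if t < (n_traits + 1) // 2 else 1
        specs.append(TraitSpec(f"trait{t + 1:02d}", h2, "continuous", group))
    var_error = [1.0] * n_traits
    e_hi = min(61, n_entries)
    e_lo = min(16, e_hi)
    cfg = SimConfig(
        n_entries=n_entries,
        n_snps=n_snps,
        trait_specs=specs,
        var_location=[0.5] * n_traits,
        var_locyear=[0.3] * n_traits,
        var_error=var_error,
        entries_per_year_range=(e_lo, e_hi),
        seed=seed,
    )
    # plant group-structured pleiotropic QTL at block starts, spread out
    rng = np.random.default_rng([int(seed), 99])
    n_blocks = max(1, n_snps // cfg.ld_block_size)
    groups = sorted({s.group_id for s in specs})
    # nominal dosage variance 2 p q (1 + f) at p ~ 0.3, f ~ 0.95
    v_dos = 2.0 * 0.3 * 0.7 * (1.0 + cfg.inbreeding)
    target_vg = np.array(
        [s.h2_target / (1.0 - s.h2_target) * ve for s, ve in zip(specs, var_error)]
    )
    base_mag = np.sqrt(qtl_variance_share * target_vg / (n_qtl_per_group * v_dos))
    qtl = []
    block_stride = max(1, n_blocks // (n_qtl_per_group * len(groups) + 1))
    b = 1
    for g in groups:
        in_group = np.array([s.group_id == g for s in specs])
        for _ in range(n_qtl_per_group):
            snp_idx = min(b * block_stride * cfg.ld_block_size, n_snps - 1)
            mag = base_mag * (0.75 + 0.5 * rng.random(len(specs)))
            eff = np.where(in_group, mag, 0.0)
            qtl.append((int(snp_idx), eff))
            b += 1
    cfg.planted_qtl = qtl
    return cfg


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _subpop_assignment(config: SimConfig) -> np.ndarray:
    sizes = np.full(config.n_subpops, config.n_entries // config.n_subpops)
    sizes[: config.n_entries % config.n_subpops] += 1
    return np.repeat(np.arange(config.n_subpops), sizes)


def _draw_dosages(
    rng: np.random.Generator, freqs: np.ndarray, f: float
) -> np.ndarray:
    """Sample dosages under HWE deflated by inbreeding f; freqs per entry."""
    p = freqs
    q = 1.0 - p
    p_het = 2.0 * p * q * (1.0 - f)
    p_alt2 = p * p + f * p * q
    u = rng.random(p.shape)
    return np.where(u < p_alt2, 2.0, np.where(u < p_alt2 + p_het, 1.0, 0.0))


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Structured inbred genotypes with block LD.

    Returns a :class:`GenotypeMatrix` with an extra ``subpop_labels``
    attribute (per-entry subpopulation index).
    """
    rng = config._rng(1)
    labels = _subpop_assignment(config)
    n, m, f = config.n_entries, config.n_snps, config.inbreeding
    F = config.fst

    dosages = np.empty((n, m))
    sub_freqs = np.empty((config.n_subpops, m))
    for j in range(m):
        if j % config.ld_block_size == 0:
            p_anc = rng.uniform(0.1, 0.9)
            if F > 0.0:
                a = p_anc * (1.0 - F) / F
                b = (1.0 - p_anc) * (1.0 - F) / F
                sp = rng.beta(a, b, size=config.n_subpops)
            else:
                sp = np.full(config.n_subpops, p_anc)
            sub_freqs[:, j] = sp
            entry_freq = sp[labels]
            dosages[:, j] = _draw_dosages(rng, entry_freq, f)
        else:
            sub_freqs[:, j] = sub_freqs[:, j - 1]
            entry_freq = sub_freqs[labels, j]
            col = dosages[:, j - 1].copy()
            flip = rng.random(n) < config.flip_prob
            if flip.any():
                col[flip] = _draw_dosages(rng, entry_freq[flip], f)
            dosages[:, j] = col

    # map SNPs onto 11 chromosomes, 1 kb apart, blocks kept contiguous
    per_chrom = int(math.ceil(m / len(_CHROMS)))
    chroms, positions = [], []
    for j in range(m):
        c = min(j // per_chrom, len(_CHROMS) - 1)
        chroms.append(_CHROMS[c])
        positions.append((j - c * per_chrom) * 1000 + 1)
    snp_map = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": ["A"] * m,
            "alt": ["T"] * m,
        }
    )
    snp_map["id"] = [f"{c}_{p}" for c, p in zip(snp_map["chrom"], snp_map["pos"])]
    geno = GenotypeMatrix(dosages, snp_map, [f"E{i + 1:04d}" for i in range(n)])
    geno.subpop_labels = labels
    return geno


# ---------------------------------------------------------------------------
# trial design
# ---------------------------------------------------------------------------

def simulate_design(config: SimConfig) -> pd.DataFrame:
    """Sparse (entry, location, year) trial cells driven by entry turnover.

    Each year draws an entry count and a location count uniformly within the
    configured ranges; every grown entry appears at every location used that
    year.  Entries enter service with a geometric participation duration
    (success probability calibrated so the median number of distinct years
    per tested entry hits ``years_per_entry_median``) and are retired when it
    expires; the yearly roster keeps surviving entries and fills up with new
    ones, mimicking the turnover of breeding material under selection.
    """
    rng = config._rng(2)
    e_lo, e_hi = config.entries_per_year_range
    l_lo, l_hi = config.locations_per_year_range

    loc_codes = []
    for i in range(config.n_locations):
        st = _STATE_CODES[i % len(_STATE_CODES)]
        suffix = chr(ord("A") + (i // len(_STATE_CODES))) + chr(ord("A") + i % 26)
        loc_codes.append(st + suffix)

    # geometric duration: median m  <=>  q = 1 - 0.5 ** (1/m)
    q = 1.0 - 0.5 ** (1.0 / config.years_per_entry_median)

    pool = list(rng.permutation(config.n_entries))
    entry_ids = [f"E{i + 1:04d}" for i in range(config.n_entries)]
    expiry: dict[int, int] = {}       # active entry -> last active year index
    retired: list[int] = []
    rows = []
    for yi in range(config.n_years):
        year = config.start_year + yi
        n_e = int(rng.integers(e_lo, e_hi + 1))
        n_l = int(rng.integers(l_lo, l_hi + 1))
        locs = [loc_codes[k] for k in rng.choice(config.n_locations, n_l, replace=False)]

        expired = [e for e, last in expiry.items() if last < yi]
        for e in expired:
            retired.append(e)
            del expiry[e]
        active = list(expiry.keys())
        if len(active) >= n_e:
            grown = [active[k] for k in rng.choice(len(active), n_e, replace=False)]
        else:
            grown = list(active)
            while len(grown) < n_e:
                if pool:
                    e = pool.pop()
                elif retired:
                    e = retired.pop(int(rng.integers(len(retired))))
                else:  # tiny configs: every entry already active
                    break
                dur = int(rng.geometric(q))
                expiry[e] = yi + min(dur, config.n_years) - 1
                grown.append(e)
        for e in grown:
            for loc in locs:
                rows.append((entry_ids[e], loc, year))
    if not rows:
        raise ValueError("design simulation produced no cells")
    return pd.DataFrame(rows, columns=["entry", "location", "year"])


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _scale_records(latent: np.ndarray, scale_type: str) -> np.ndarray:
    """Map latent normal records onto the trait's reporting scale."""
    if scale_type == "continuous":
        return latent
    sd = latent.std()
    if sd == 0.0:
        sd = 1.0
    z = (latent - latent.mean()) / sd
    if scale_type == "percent":
        return np.clip(50.0 + 20.0 * z, 0.0, 100.0)
    if scale_type.startswith("ordinal:"):
        _, lo, hi = scale_type.split(":")
        lo, hi = int(lo), int(hi)
        # threshold the latent normal into equally spaced ordinal classes
        edges = np.linspace(-2.0, 2.0, hi - lo)
        return (lo + np.searchsorted(edges, z)).astype(float)
    raise ValueError(f"unknown scale_type {scale_type!r}")


def simulate_phenotypes(
    geno: GenotypeMatrix, design: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Additive phenotypes over the trial design, with full truth records.

    Per record: y = mu + g(entry) + L(location) + LY(location, year) + e,
    where g combines planted-QTL effects and a kinship-structured polygenic
    term scaled so that Var(g) / (Var(g) + var_error) hits the trait's
    ``h2_target``.
    """
    if design.empty:
        raise ValueError("design is empty")
    if not config.trait_specs:
        raise ValueError("trait_specs is empty")
    rng = config._rng(3)
    n_traits = config.n_traits
    var_loc = config.var_location or [0.0] * n_traits
    var_ly = config.var_locyear or [0.0] * n_traits
    var_err = config.var_error or [0.0] * n_traits

    n = geno.n_entries
    Zc = geno.dosages - geno.dosages.mean(axis=0)
    entry_index = {e: i for i, e in enumerate(geno.entry_ids)}
    rec_entry = design["entry"].map(entry_index).to_numpy()
    if np.any(pd.isna(rec_entry)):
        raise KeyError("design references entries absent from the genotype matrix")
    rec_entry = rec_entry.astype(int)
    locs = design["location"].to_numpy()
    years = design["year"].to_numpy()
    uniq_loc = pd.unique(locs)
    ly_series = pd.Series([f"{l}|{y}" for l, y in zip(locs, years)])
    ly_keys = pd.unique(ly_series)
    rec_ly = pd.Index(ly_keys).get_indexer(ly_series)
    rec_loc = pd.Index(uniq_loc).get_indexer(locs)

    qtl_idx = [int(j) for j, _ in config.planted_qtl]
    B = np.zeros((len(qtl_idx), n_traits))
    for r, (_, eff) in enumerate(config.planted_qtl):
        eff = np.asarray(eff, dtype=float)
        if eff.shape != (n_traits,):
            raise ValueError("planted QTL effect vector length must equal n_traits")
        B[r] = eff

    tbv = np.zeros((n, n_traits))
    realized_h2: dict[str, float] = {}
    frames = []
    loc_eff_tbl = np.zeros((len(uniq_loc), n_traits))
    ly_eff_tbl = np.zeros((len(ly_keys), n_traits))
    for t, spec in enumerate(config.trait_specs):
        if spec.h2_target >= 1.0 and var_err[t] > 0.0:
            raise ValueError(
                f"{spec.name}: h2_target = 1 is inconsistent with var_error > 0"
            )
        g_qtl = np.zeros(n)
        if qtl_idx:
            g_qtl = Zc[:, qtl_idx] @ B[:, t]
        var_qtl = float(g_qtl.var())
        if spec.h2_target >= 1.0:
            target_vg = max(var_qtl, 1.0)
        else:
            target_vg = spec.h2_target / (1.0 - spec.h2_target) * var_err[t]
        var_poly = max(0.0, target_vg - var_qtl)
        poly = np.zeros(n)
        if var_poly > 0.0:
            raw = Zc @ rng.standard_normal(geno.n_snps)
            s = raw.std()
            if s > 0:
                poly = raw / s * math.sqrt(var_poly)
        g = g_qtl + poly
        tbv[:, t] = g

        L = rng.normal(0.0, math.sqrt(var_loc[t]), len(uniq_loc)) if var_loc[t] > 0 else np.zeros(len(uniq_loc))
        LY = rng.normal(0.0, math.sqrt(var_ly[t]), len(ly_keys)) if var_ly[t] > 0 else np.zeros(len(ly_keys))
        e = rng.normal(0.0, math.sqrt(var_err[t]), len(design)) if var_err[t] > 0 else np.zeros(len(design))
        loc_eff_tbl[:, t] = L
        ly_eff_tbl[:, t] = LY

        latent = g[rec_entry] + L[rec_loc] + LY[rec_ly] + e
        values = _scale_records(latent, spec.scale_type)
        frames.append(
            pd.DataFrame(
                {
                    "entry": design["entry"].to_numpy(),
                    "location": locs,
                    "year": years,
                    "trait": spec.name,
                    "value": values,
                }
            )
        )
        tested = np.unique(rec_entry)
        vg_tested = float(g[tested].var())
        denom = vg_tested + var_err[t]
        realized_h2[spec.name] = vg_tested / denom if denom > 0 else float("nan")

    table = pd.concat(frames, ignore_index=True)
    truth = SimTruth(
        true_breeding_values=pd.DataFrame(
            tbv, index=geno.entry_ids, columns=[s.name for s in config.trait_specs]
        ),
        qtl_effects=pd.DataFrame(
            B,
            index=[geno.snp_map["id"].iloc[j] for j in qtl_idx],
            columns=[s.name for s in config.trait_specs],
        ),
        realized_h2=realized_h2,
        subpop_labels=getattr(geno, "subpop_labels", np.zeros(n, dtype=int)),
        location_effects=pd.DataFrame(
            loc_eff_tbl, index=list(uniq_loc), columns=[s.name for s in config.trait_specs]
        ),
        locyear_effects=pd.DataFrame(
            ly_eff_tbl, index=list(ly_keys), columns=[s.name for s in config.trait_specs]
        ),
    )
    return table, truth
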