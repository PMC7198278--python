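"""End-to-end pipeline driver with a YAML config and a run manifest.

Stages: (optional) simulate -> standardize -> kinship -> BLUP per trait ->
GWAS per trait plus the earliest-trial-year proxy -> multivariate shrinkage
-> pairwise sharing.  Every output file starts with a header comment
carrying the run seed and a hash of the full parameter set, and the
manifest records per-stage record counts, so two runs with the same config
are byte-identical and easy to diff.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blup import fit_blup
from .genotypes import (
    maf_filter,
    read_dosage_tsv,
    read_vcf,
    vanraden_kinship,
    write_dosage_tsv,
    write_vcf,
)
from .gwas import GwasConfig, MLMScan, earliest_year_phenotype, select_pcs_bic
from .mash import (
    MashModel,
    build_effect_panel,
    build_snp_sets,
    learn_covariances,
    pairwise_sharing,
)
from .phenostd import aggregate_duplicates, harmonize_table, load_scale_registry, remove_outlier_cells
from .report import qq_coordinates
from .simulate import (
    default_sim_config,
    simulate_design,
    simulate_genotypes,
    simulate_phenotypes,
)

log = logging.getLogger("metgwas")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs for one pipeline run."""

    out_dir: str
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)      # overrides for default_sim_config
    genotypes: str | None = None                 # VCF or dosage TSV (when not simulating)
    phenotypes: str | None = None                # long-format TSV
    scales: str | None = None                    # YAML scale registry
    maf_threshold: float = 0.05
    max_pcs: int = 10
    fdr_q: float = 0.1
    window_bp: int = 20_000
    n_random: int = 5000
    n_strong_per_trait: int = 400
    r2_max: float = 0.2
    prune_window_bp: int = 100_000
    lfsr_max: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            for fld in ("genotypes", "phenotypes"):
                v = getattr(self, fld)
                if v is None:
                    raise ValueError(f"config field {fld!r} is required when simulate is off")
                if not Path(v).exists():
                    raise FileNotFoundError(f"config field {fld!r}: no such file {v}")
        GwasConfig(max_pcs=self.max_pcs, fdr_q=self.fdr_q, window_bp=self.window_bp)

    def param_hash(self) -> str:
        """Hash of the scientific parameters (paths and logging excluded)."""
        params = asdict(self)
        for bookkeeping in ("out_dir", "log_level"):
            params.pop(bookkeeping, None)
        blob = json.dumps(params, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _header(cfg: PipelineConfig) -> str:
    return f"# metgwas {__version__} seed={cfg.seed} params={cfg.param_hash()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", **kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest.

    Any stage failure raises with the stage name; outputs of completed
    stages are left in place.
    """
    config.validate()
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "stages": {},
    }
    stage = "setup"
    try:
        # -- simulate / load ------------------------------------------------
        stage = "simulate" if config.simulate else "load"
        t0 = time.perf_counter()
        if config.simulate:
            sim_cfg = default_sim_config(seed=config.seed, **config.sim)
            geno = simulate_genotypes(sim_cfg)
            design = simulate_design(sim_cfg)
            pheno, truth = simulate_phenotypes(geno, design, sim_cfg)
            write_vcf(geno, out / "genotypes.vcf")
            write_dosage_tsv(geno, str(out / "dosages.tsv"))
            _write_tsv(pheno, out / "phenotypes.tsv", config)
            _write_tsv(
                truth.true_breeding_values.reset_index(names="entry"),
                out / "truth_breeding_values.tsv",
                config,
            )
            _write_tsv(
                truth.qtl_effects.reset_index(names="snp"),
                out / "truth_qtl_effects.tsv",
                config,
            )
        else:
            gpath = str(config.genotypes)
            geno = read_vcf(gpath) if gpath.endswith(".vcf") else read_dosage_tsv(gpath)
            pheno = pd.read_csv(config.phenotypes, sep="\t", comment="#")
        manifest["stages"][stage] = {
            "entries": geno.n_entries,
            "snps": geno.n_snps,
            "records": int(len(pheno)),
            "secs": round(time.perf_counter() - t0, 2),
        }
        log.info("%s: %s", stage, manifest["stages"][stage])

        # -- standardize ----------------------------------------------------
        stage = "standardize"
        t0 = time.perf_counter()
        if config.scales:
            registry = load_scale_registry(config.scales)
            pheno = harmonize_table(pheno, registry)
        pheno = aggregate_duplicates(pheno)
        traits = sorted(pheno["trait"].unique())
        dropped_cells = 0
        for trait in traits:
            pheno, logtab = remove_outlier_cells(pheno, trait)
            dropped_cells += len(logtab)
        _write_tsv(pheno, out / "phenotypes_standardized.tsv", config)
        manifest["stages"][stage] = {
            "records": int(len(pheno)),
            "traits": len(traits),
            "outlier_cells_dropped": dropped_cells,
            "secs": round(time.perf_counter() - t0, 2),
        }
        log.info("%s: %s", stage, manifest["stages"][stage])

        # -- kinship --------------------------------------------------------
        stage = "kinship"
        t0 = time.perf_counter()
        geno_f = maf_filter(geno, config.maf_threshold)
        kin = vanraden_kinship(geno_f)
        with open(out / "kinship.tsv", "w") as fh:
            fh.write(_header(config))
            kin.to_frame().to_csv(fh, sep="\t", index_label="entry", lineterminator="\n")
        manifest["stages"][stage] = {
            "snps_after_maf": geno_f.n_snps,
            "secs": round(time.perf_counter() - t0, 2),
        }
        log.info("%s: %s", stage, manifest["stages"][stage])

        # -- BLUPs ----------------------------------------------------------
        stage = "blup"
        t0 = time.perf_counter()
        blups: dict[str, pd.Series] = {}
        h2: dict[str, float] = {}
        for trait in traits:
            res = fit_blup(pheno, trait, kin)
            blups[trait] = res.blups
            h2[trait] = res.h2
            _write_tsv(res.to_frame(), out / f"blup_{trait}.tsv", config)
        _write_tsv(
            pd.DataFrame({"trait": list(h2), "h2": list(h2.values())}),
            out / "heritability.tsv",
            config,
        )
        manifest["stages"][stage] = {
            "traits": len(blups),
            "h2": {k: round(v, 4) for k, v in h2.items()},
            "secs": round(time.perf_counter() - t0, 2),
        }
        log.info("%s: %s", stage, manifest["stages"][stage])

        # -- GWAS -----------------------------------------------------------
        stage = "gwas"
        t0 = time.perf_counter()
        scans: dict[str, pd.DataFrame] = {}
        pcs_used: dict[str, int] = {}
        phenos_for_scan = dict(blups)
        phenos_for_scan["earliest_year"] = earliest_year_phenotype(pheno)
        from .genotypes import genotype_pca

        pc_budget = min(config.max_pcs, geno_f.n_entries - 1, geno_f.n_snps - 1)
        all_pcs = genotype_pca(geno_f, pc_budget)
        entry_pos = {e: i for i, e in enumerate(geno_f.entry_ids)}
        for name, y in phenos_for_scan.items():
            y = y.dropna()
            common = [e for e in geno_f.entry_ids if e in set(y.index)]
            yv = y.reindex(common).to_numpy(dtype=float)
            rows = np.array([entry_pos[e] for e in common])
            k_sub = kin.subset(common)
            n_pcs = select_pcs_bic(yv, all_pcs[rows], k_sub, max_pcs=pc_budget)
            pcs_used[name] = n_pcs
            scan = MLMScan(
                y,
                geno_f,
                kin,
                n_pcs=n_pcs,
                config=GwasConfig(
                    max_pcs=config.max_pcs,
                    fdr_q=config.fdr_q,
                    window_bp=config.window_bp,
                ),
            ).fit()
            scans[name] = scan
            _write_tsv(scan, out / f"gwas_{name}.tsv", config)
            _write_tsv(qq_coordinates(scan["p"]), out / f"qq_{name}.tsv", config)
        manifest["stages"][stage] = {
            "scans": len(scans),
            "pcs_used": pcs_used,
            "fdr_hits": {k: int(v["fdr_significant"].sum()) for k, v in scans.items()},
            "secs": round(time.perf_counter() - t0, 2),
        }
        log.info("%s: %s", stage, manifest["stages"][stage])

        # -- multivariate shrinkage -----------------------------------------
        stage = "mash"
        t0 = time.perf_counter()
        random_ids, strong_ids = build_snp_sets(
            scans,
            geno_f,
            n_random=config.n_random,
            n_strong_per_trait=config.n_strong_per_trait,
            r2_max=config.r2_max,
            window_bp=config.prune_window_bp,
            seed=config.seed,
        )
        panel_random = build_effect_panel(scans, random_ids)
        panel_strong = build_effect_panel(scans, strong_ids)
        components = learn_covariances(panel_strong.bhat)
        fit = MashModel(panel_random.bhat, panel_random.shat, components).fit()
        post = fit.posterior(panel_strong.bhat, panel_strong.shat)
        long = (
            post.post_mean.stack()
            .rename("post_mean")
            .to_frame()
            .join(post.post_sd.stack().rename("post_sd"))
            .join(post.lfsr.stack().rename("lfsr"))
            .reset_index(names=["snp", "phenotype"])
        )
        _write_tsv(long, out / "mash_posteriors.tsv", config)
        _write_tsv(
            post.bayes_factor.rename_axis("snp").reset_index(),
            out / "mash_bayes_factors.tsv",
            config,
        )
        sharing = pairwise_sharing(post, lfsr_max=config.lfsr_max)
        with open(out / "mash_sharing.tsv", "w") as fh:
            fh.write(_header(config))
            sharing.to_csv(fh, sep="\t", index_label="phenotype", lineterminator="\n")
        sig = post.significant(config.lfsr_max)
        manifest["stages"][stage] = {
            "random_set": len(random_ids),
            "strong_set": len(strong_ids),
            "null_weight": round(fit.mixture.null_weight, 4),
            "phenotypes_with_lfsr_hits": int((sig.sum(axis=0) > 0).sum()),
            "decisive_bf_snps": int(post.decisive().sum()),
            "secs": round(time.perf_counter() - t0, 2),
        }
        log.info("%s: %s", stage, manifest["stages"][stage])
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    # timers are logged to stderr; they stay out of the manifest hashable part
    slim = {
        k: {kk: vv for kk, vv in v.items() if kk != "secs"}
        for k, v in manifest["stages"].items()
    }
    manifest["stages"] = slim
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
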