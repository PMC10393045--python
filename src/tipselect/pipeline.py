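"""End-to-end pipeline: simulate (optional) -> TIP filtering -> cis-eQTL
scans -> PBS selection scan -> sweep scans -> summary reports.

The pipeline is configured by a :class:`PipelineConfig` (loadable from a
YAML file with per-stage sections; unknown keys are rejected) and writes
every intermediate table as TSV plus a JSON summary. All outputs carry a
provenance header (package version, config hash, seed), and a fixed seed
makes the whole run byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import (
    CIS_WINDOW_BP,
    FDR_THRESHOLD,
    N_PERMUTATIONS,
    PBS_PERCENTILES,
    PRESENCE_CUTOFF,
    ZYGOSITY_MIN,
)
from .eqtl import (
    compare_variance_explained,
    consolidate_replicates,
    run_eqtl_scan,
)
from .pbs import eqtl_enrichment_test, pbs_scan, rank_sum_compare
from .simulate import Cohort, SimulationConfig, generate_cohort
from .sweep import scan_locus
from .tip_matrix import (
    allele_frequency,
    binarize_zygosity,
    filter_low_zygosity,
    filter_maf_missing,
    impute_missing,
)
from . import io as tio

log = logging.getLogger("tipselect")

_STAGE_KEYS = {
    "simulate": set(SimulationConfig.__dataclass_fields__),
    "filter": {"min_zygosity", "presence_cutoff"},
    "eqtl": {"window", "fdr"},
    "pbs": {"percentiles"},
    "sweep": {"n_perm", "max_loci"},
}


@dataclass
class PipelineConfig:
    """Run configuration; every stage parameter defaults to the published
    analysis value."""

    outdir: str = "tipselect_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    eqtl: dict = field(default_factory=dict)
    pbs: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stage, allowed in _STAGE_KEYS.items():
            given = set(getattr(self, stage))
            unknown = given - allowed
            if unknown:
                raise ValueError(
                    f"unknown keys in [{stage}] config: {sorted(unknown)}"
                )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location and
        log level excluded, so renaming a run directory does not change its
        provenance)."""
        payload = asdict(self)
        payload.pop("outdir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(cfg: PipelineConfig) -> str:
    return (
        f"# tipselect {__version__} | config {cfg.config_hash()} | "
        f"seed {cfg.seed}\n"
    )


def _write_tsv(frame: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA",
                     float_format="%.6g", lineterminator="\n")


def run_pipeline(cfg: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Execute the full pipeline and return the summary dictionary.

    With no pre-built ``cohort``, a synthetic one is generated from the
    [simulate] section (seeded by the top-level seed unless the section
    sets its own).
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- stage: simulate -------------------------------------------------
    if cohort is None:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", cfg.seed)
        cohort = generate_cohort(SimulationConfig(**sim_kwargs))
        log.info("simulated cohort: %d TIPs, %d SNPs, %d genes, %d libraries",
                 cohort.genotypes.n_loci, cohort.snps.n_loci,
                 len(cohort.genes), len(cohort.metadata))
    tio.write_marker_tsv(cohort.zygosity, outdir / "tip_zygosity.tsv")
    tio.write_vcf(cohort.snps, outdir / "snps.vcf")
    tio.write_gff_genes(cohort.genes, outdir / "genes.gff3")
    tio.write_counts_tsv(cohort.counts, outdir / "counts.tsv")
    tio.write_metadata_tsv(cohort.metadata, outdir / "metadata.tsv")
    tio.write_truth_tables(cohort.truth, outdir)

    # --- stage: filter-tips ----------------------------------------------
    min_zyg = cfg.filter.get("min_zygosity", ZYGOSITY_MIN)
    cutoff = cfg.filter.get("presence_cutoff", PRESENCE_CUTOFF)
    zyg = filter_low_zygosity(cohort.zygosity, min_zyg)
    geno_all = binarize_zygosity(zyg, cutoff)
    log.info("zygosity filter: %d -> %d loci", cohort.zygosity.n_loci,
             geno_all.n_loci)

    acc_meta = cohort.metadata.drop_duplicates("accession")
    pop_of = dict(zip(acc_meta["accession"], acc_meta["population"]))
    pops = cohort.populations

    # --- stage: map-eqtl (per population x marker type) ------------------
    window = cfg.eqtl.get("window", CIS_WINDOW_BP)
    fdr = cfg.eqtl.get("fdr", FDR_THRESHOLD)
    results, hits, r2_compare = {}, {}, {}
    derived = pops[:2]
    for pop in derived:
        pop_accs = [a for a in geno_all.samples if pop_of[a] == pop]
        cols = [geno_all.samples.index(a) for a in pop_accs]
        pop_hits = {}
        for marker_type, markers in (("TIP", geno_all), ("SNP", cohort.snps)):
            sub = type(markers)(
                markers.loci.copy(), pop_accs, markers.calls[:, cols]
            )
            sub = filter_maf_missing(sub, preset="eqtl")
            scan = run_eqtl_scan(
                cohort.counts, sub, cohort.metadata, cohort.genes,
                population=pop, marker_type=marker_type, window=window,
            )
            results[(pop, marker_type)] = scan
            pop_hits[marker_type] = consolidate_replicates(scan, fdr)
            log.info("%s %s-eQTL scan: %d tests, %d hits", pop, marker_type,
                     len(scan), len(pop_hits[marker_type]))
            _write_tsv(scan, outdir / f"eqtl_{pop}_{marker_type}.tsv", cfg)
            _write_tsv(pop_hits[marker_type],
                       outdir / f"hits_{pop}_{marker_type}.tsv", cfg)
        hits[pop] = pop_hits
        r2_compare[pop] = compare_variance_explained(
            pop_hits["TIP"], pop_hits["SNP"]
        )
        _write_tsv(r2_compare[pop], outdir / f"r2_compare_{pop}.tsv", cfg)

    # --- stage: pbs -------------------------------------------------------
    percentiles = tuple(cfg.pbs.get("percentiles", PBS_PERCENTILES))
    pbs_geno = filter_maf_missing(geno_all, preset="pbs")
    pbs_geno = impute_missing(pbs_geno, mode="expected")
    freqs = allele_frequency(pbs_geno, pop_of)
    # only loci whose insertion is observed in all three populations enter
    # the branch-statistic scan
    present_all = np.ones(len(freqs), dtype=bool)
    for p in pops:
        present_all &= freqs[p].to_numpy() > 0
    freqs = freqs.loc[present_all].reset_index(drop=True)
    sizes = {p: sum(v == p for v in pop_of.values()) for p in pops}
    pbs_table = pbs_scan(freqs, pops, sizes, percentiles)
    eqtl_tips = set()
    for pop in derived:
        eqtl_tips |= set(
            hits[pop]["TIP"].get("marker", pd.Series(dtype=object))
        )
    flags = pbs_table["id"].isin(eqtl_tips).to_numpy()
    enrich = eqtl_enrichment_test(pbs_table, flags, percentiles[0])
    if flags.any() and (~flags).any():
        ranksum = rank_sum_compare(
            pbs_table.loc[flags, "abs_pbs"], pbs_table.loc[~flags, "abs_pbs"]
        )
    else:
        ranksum = {"u": float("nan"), "p_value": float("nan")}
    pbs_out = pbs_table.assign(is_eqtl=flags)
    _write_tsv(pbs_out, outdir / "pbs.tsv", cfg)
    log.info("PBS scan: %d loci, %d eQTL-flagged", len(pbs_table),
             int(flags.sum()))

    # --- stage: sweep-scan ------------------------------------------------
    n_perm = cfg.sweep.get("n_perm", N_PERMUTATIONS)
    max_loci = cfg.sweep.get("max_loci", len(cohort.sweep_blocks))
    rng = np.random.default_rng(cfg.seed)
    sweep_frames = []
    for tip_id, block in list(cohort.sweep_blocks.items())[:max_loci]:
        res = scan_locus(block, n_perm=n_perm,
                         seed=int(rng.integers(2**31 - 1)))
        res.insert(0, "tip", tip_id)
        sweep_frames.append(res)
        log.info("sweep scan at %s: %d windows", tip_id, len(res))
    sweep_table = (pd.concat(sweep_frames, ignore_index=True)
                   if sweep_frames else pd.DataFrame())
    _write_tsv(sweep_table, outdir / "sweep_scan.tsv", cfg)

    # --- summary ----------------------------------------------------------
    summary = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_tips_raw": int(cohort.zygosity.n_loci),
        "n_tips_filtered": int(geno_all.n_loci),
        "n_pbs_loci": int(len(pbs_table)),
        "pbs_enrichment_odds_ratio": enrich["odds_ratio"],
        "pbs_enrichment_p": enrich["p_value"],
        "mean_abs_pbs_eqtl": (float(pbs_table.loc[flags, "abs_pbs"].mean())
                              if flags.any() else float("nan")),
        "mean_abs_pbs_non_eqtl": (float(pbs_table.loc[~flags, "abs_pbs"].mean())
                                  if (~flags).any() else float("nan")),
        "wilcoxon_p": ranksum["p_value"],
    }
    for pop in derived:
        summary[f"n_tip_eqtl_hits_{pop}"] = int(len(hits[pop]["TIP"]))
        summary[f"n_snp_eqtl_hits_{pop}"] = int(len(hits[pop]["SNP"]))
        cats = r2_compare[pop]["category"].value_counts().to_dict() \
            if len(r2_compare[pop]) else {}
        summary[f"r2_categories_{pop}"] = {k: int(v) for k, v in cats.items()}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
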