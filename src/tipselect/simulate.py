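"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a three-population crop study design — two derived
populations (defaults: 126 and 82 inbred accessions, mirroring an
indica-like and a japonica-like panel) plus an 82-accession wild-relative
proxy for their ancestor. Transposon-insertion presence frequencies follow
the Balding-Nichols model: an ancestral frequency p0 ~ Beta(0.5, 0.5) and
per-derived-population frequencies Beta(p0(1-F)/F, (1-p0)(1-F)/F), which
gives a tunable and analytically checkable FST of about F between each
derived population and the ancestral pool. A configurable subset of TIPs is
"selected": its frequency in exactly one derived population is pushed to a
target drawn from [0.8, 0.99] (or [0.01, 0.2]), producing lineage-specific
branches for the PBS scan to find.

Expression counts are negative binomial with a log link over 2 conditions x
3 replicates per accession; planted cis effects multiply the mean by
exp(beta) per insertion allele. Local haplotype structure around focal TIPs
is simulated directly: neutral regions have independent SNPs at uniform
frequencies, swept regions draw carrier haplotypes from a small number of
template haplotypes with a per-site mutation probability, mimicking the
reduced diversity and elevated haplotype homozygosity of a recent sweep.

Everything is driven by one integer seed; a fixed seed reproduces the
cohort bit for bit. Ground truth (planted eQTLs, selected TIPs, sweep loci)
is returned alongside the data so every downstream stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sweep import HaplotypeBlock
from .tip_matrix import GenotypeMatrix, ZygosityMatrix

CHROM = "chr1"
GENE_SPACING = 20_000
GENE_LENGTH = 3_000
SWEEP_REGION_SPACING = 1_000_000


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the emulated study design: 126 + 82 derived accessions
    and 82 wild-relative accessions, 2 conditions x 3 replicates of
    3'-mRNA-seq-like counts, 2% missing TIP calls.
    """

    n_pop1: int = 126
    n_pop2: int = 82
    n_pop3: int = 82
    n_tips: int = 400
    n_snps: int = 1_500
    n_genes: int = 150
    fst_drift: float = 0.1
    n_selected_tips: int = 20
    n_eqtl_tips: int = 30
    beta_range: tuple[float, float] = (0.5, 1.5)
    nb_dispersion: float = 0.2
    sweep_carrier_haplotypes: int = 2
    missing_frac: float = 0.02
    n_sweep_loci: int = 3
    sweep_region_snps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pop1", "n_pop2", "n_pop3", "n_tips", "n_snps",
                     "n_genes", "sweep_carrier_haplotypes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.fst_drift < 1.0:
            raise ValueError("fst_drift must lie in (0, 1)")
        if self.n_selected_tips > self.n_tips:
            raise ValueError("n_selected_tips cannot exceed n_tips")
        if self.n_eqtl_tips > self.n_tips:
            raise ValueError("n_eqtl_tips cannot exceed n_tips")
        if self.n_eqtl_tips > self.n_genes:
            raise ValueError("need at least one gene per planted eQTL")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must lie in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort."""

    planted_eqtls: pd.DataFrame  # tip_id, gene_id, beta, condition_specific
    selected_tips: pd.DataFrame  # tip_id, focal_population, target_freq
    sweep_loci: pd.DataFrame  # tip_id, sweep_type


@dataclass
class Cohort:
    """A complete simulated dataset plus its ground truth."""

    config: SimulationConfig
    zygosity: ZygosityMatrix
    genotypes: GenotypeMatrix  # true TIP presence, before missingness
    snps: GenotypeMatrix
    genes: pd.DataFrame
    counts: pd.DataFrame  # genes x libraries
    metadata: pd.DataFrame  # one row per library
    frequencies: np.ndarray  # n_tips x 3 planted frequencies
    sweep_blocks: dict[str, HaplotypeBlock]
    truth: TruthTable

    @property
    def populations(self) -> tuple[str, str, str]:
        return ("pop1", "pop2", "pop3")


# ---------------------------------------------------------------------------
# frequencies and genotypes

def _balding_nichols(p0: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    scale = (1.0 - f) / f
    return rng.beta(p0 * scale, (1.0 - p0) * scale)


def draw_tip_frequencies(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    selected_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Planted presence frequencies of every TIP in the three populations.

    Column order is (pop1, pop2, pop3) where pop3 is the ancestral-proxy
    wild population kept at the ancestral frequency p0. Selected TIPs get
    their frequency in exactly one derived population replaced by a target
    drawn from [0.8, 0.99] if p0 < 0.5 else [0.01, 0.2], so the shift is
    always large. ``selected_indices`` pins which loci are selected
    (default: a uniform draw of ``cfg.n_selected_tips``). Returns
    (frequencies, selected-TIP table).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    p0 = np.clip(rng.beta(0.5, 0.5, size=cfg.n_tips), 0.02, 0.98)
    f = cfg.fst_drift
    freqs = np.column_stack([
        _balding_nichols(p0, f, rng),
        _balding_nichols(p0, f, rng),
        p0,
    ])
    if selected_indices is None:
        sel_idx = rng.choice(cfg.n_tips, size=cfg.n_selected_tips, replace=False)
    else:
        sel_idx = np.asarray(selected_indices, dtype=int)
        if sel_idx.size != cfg.n_selected_tips:
            raise ValueError("selected_indices length must equal n_selected_tips")
    focal = rng.integers(0, 2, size=cfg.n_selected_tips)  # 0 -> pop1, 1 -> pop2
    high = p0[sel_idx] < 0.5
    target = np.where(
        high,
        rng.uniform(0.8, 0.99, size=cfg.n_selected_tips),
        rng.uniform(0.01, 0.2, size=cfg.n_selected_tips),
    )
    freqs[sel_idx, focal] = target
    selected = pd.DataFrame({
        "tip_index": sel_idx,
        "focal_population": np.where(focal == 0, "pop1", "pop2"),
        "target_freq": target,
    })
    return freqs, selected


def draw_genotypes(
    frequencies: np.ndarray, n_samples: int, seed_or_rng
) -> np.ndarray:
    """Loci x samples Bernoulli presence/absence draws at the given
    per-locus frequencies (haploid-equivalent inbred samples)."""
    freqs = np.asarray(frequencies, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return (rng.random((freqs.size, n_samples)) < freqs[:, None]).astype(np.int8)


# ---------------------------------------------------------------------------
# local haplotype structure

def simulate_haplotype_region(
    n_samples: int,
    n_snps: int,
    carriers: np.ndarray,
    sweep: bool,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    focal_pos: int = 50_000,
    chrom: str = CHROM,
    mutation_prob: float = 0.01,
    samples: list[str] | None = None,
) -> HaplotypeBlock:
    """SNP haplotypes of all samples over the 100,001 bp region centred on
    a focal TIP.

    Non-sweep: every SNP is independent with a frequency ~ Uniform(0.05,
    0.95). Sweep: carriers copy one of ``cfg.sweep_carrier_haplotypes``
    template haplotypes with per-site mutation probability
    ``mutation_prob``; non-carriers stay neutral.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    carriers = np.asarray(carriers)
    if carriers.dtype == bool:
        carrier_idx = np.nonzero(carriers)[0]
    else:
        carrier_idx = carriers.astype(int)
    if sweep and carrier_idx.size == 0:
        raise ValueError("sweep region needs a non-empty carrier set")
    flank = 50_000
    start = max(0, focal_pos - flank)
    end = focal_pos + flank + 1
    positions = np.sort(rng.choice(np.arange(start, end), size=n_snps, replace=False))
    site_freq = rng.uniform(0.05, 0.95, size=n_snps)
    alleles = (rng.random((n_samples, n_snps)) < site_freq[None, :]).astype(np.int8)
    if sweep:
        templates = (
            rng.random((cfg.sweep_carrier_haplotypes, n_snps)) < site_freq[None, :]
        ).astype(np.int8)
        choice = rng.integers(0, cfg.sweep_carrier_haplotypes, size=carrier_idx.size)
        hap = templates[choice]
        flips = rng.random(hap.shape) < mutation_prob
        alleles[carrier_idx] = np.where(flips, 1 - hap, hap)
    carrier_mask = np.zeros(n_samples, dtype=bool)
    carrier_mask[carrier_idx] = True
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return HaplotypeBlock(
        chrom=chrom,
        start=start,
        end=end,
        positions=positions,
        alleles=alleles,
        samples=samples,
        carrier=carrier_mask,
    )


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    genotypes: np.ndarray,
    tip_ids: list[str],
    gene_ids: list[str],
    truth: pd.DataFrame,
    metadata: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Negative-binomial counts for every gene and library.

    Per gene and accession the log mean is b0 + b_subpop + beta * g for the
    planted cis TIP (plus an extra beta in the "drought" condition when the
    effect is condition-specific); counts are NB with dispersion
    ``cfg.nb_dispersion`` (variance mu + dispersion * mu^2), independent
    across the 2 conditions x 3 replicates. dispersion -> 0 reduces to
    Poisson.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    tip_index = {t: i for i, t in enumerate(tip_ids)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)
    accessions = metadata["accession"].unique().tolist()
    acc_index = {a: i for i, a in enumerate(accessions)}

    b0 = rng.normal(5.5, 0.8, size=n_genes)
    subpops = metadata["subpopulation"].unique().tolist()
    b_sub = {sp: rng.normal(0.0, 0.2, size=n_genes) for sp in subpops}

    # per-gene planted effect of its cis TIP, if any
    beta_vec = np.zeros((n_genes, len(accessions)))
    beta_cond = np.zeros((n_genes, len(accessions)))
    for _, row in truth.iterrows():
        gi = gene_index[row["gene_id"]]
        g = genotypes[tip_index[row["tip_id"]], [acc_index[a] for a in accessions]]
        if row["condition_specific"]:
            beta_cond[gi] += row["beta"] * g
        else:
            beta_vec[gi] += row["beta"] * g

    counts = np.empty((n_genes, len(metadata)), dtype=np.int64)
    for col, (_, lib) in enumerate(metadata.iterrows()):
        ai = acc_index[lib["accession"]]
        log_mu = b0 + b_sub[lib["subpopulation"]] + beta_vec[:, ai]
        if lib["condition"] == "drought":
            log_mu = log_mu + beta_cond[:, ai]
        mu = np.exp(log_mu)
        if cfg.nb_dispersion <= 1e-12:
            counts[:, col] = rng.poisson(mu)
        else:
            n_nb = 1.0 / cfg.nb_dispersion
            p_nb = n_nb / (n_nb + mu)
            counts[:, col] = rng.negative_binomial(n_nb, p_nb)
    return pd.DataFrame(counts, index=gene_ids, columns=metadata["sample"].tolist())


# ---------------------------------------------------------------------------
# cohort assembly

def _sample_names(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    names, pops = [], []
    for pop, n in (("pop1", cfg.n_pop1), ("pop2", cfg.n_pop2), ("pop3", cfg.n_pop3)):
        names += [f"{pop}_a{i:03d}" for i in range(n)]
        pops += [pop] * n
    return names, pops


def _make_metadata(
    accessions: list[str], populations: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Library-level metadata: 2 conditions x 3 replicates per accession.

    Each derived population is split into two subpopulation covariate
    groups (emulating variety-group structure); the wild proxy is one group.
    """
    sub_of = {}
    for acc, pop in zip(accessions, populations):
        if pop == "pop3":
            sub_of[acc] = "pop3_wild"
        else:
            sub_of[acc] = f"{pop}_g{rng.integers(1, 3)}"
    rows = []
    for acc, pop in zip(accessions, populations):
        for cond in ("wet", "drought"):
            for rep in (1, 2, 3):
                rows.append({
                    "sample": f"{acc}_{cond}_r{rep}",
                    "accession": acc,
                    "population": pop,
                    "subpopulation": sub_of[acc],
                    "condition": cond,
                    "replicate": rep,
                })
    return pd.DataFrame(rows)


def _te_annotation(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """TE order/superfamily labels with genome-like proportions (MITE-heavy
    DNA transposons, minor LTR fraction)."""
    orders = rng.choice(
        ["TIR", "MITE", "LTR", "LINE", "Helitron"],
        size=n,
        p=[0.25, 0.45, 0.12, 0.08, 0.10],
    )
    family_of = {
        "MITE": ["Stowaway", "Tourist"],
        "TIR": ["MULE", "hAT", "CACTA"],
        "LTR": ["Gypsy", "Copia"],
        "LINE": ["L1"],
        "Helitron": ["Helitron"],
    }
    families = [rng.choice(family_of[o]) for o in orders]
    return pd.DataFrame({"te_family": families, "te_order": orders})


def generate_cohort(cfg: SimulationConfig) -> Cohort:
    """Build a full synthetic cohort: TIP zygosity matrix, SNP matrix, gene
    models, expression counts, sweep regions and the truth table."""
    rng = np.random.default_rng(cfg.seed)

    accessions, populations = _sample_names(cfg)
    pop_arr = np.array(populations)
    n_total = len(accessions)
    metadata = _make_metadata(accessions, populations, rng)

    # --- gene models on a regular grid
    gene_ids = [f"gene_{i:04d}" for i in range(cfg.n_genes)]
    starts = GENE_SPACING * np.arange(cfg.n_genes) + 5_000
    genes = pd.DataFrame({
        "id": gene_ids,
        "chrom": CHROM,
        "start": starts,
        "end": starts + GENE_LENGTH,
        "strand": rng.choice(["+", "-"], size=cfg.n_genes),
    })

    # --- TIP frequencies, positions, genotypes. Selected TIPs overlap the
    # planted eQTL set (half of them, where possible): the emulated study
    # design is that expression-associated insertions are the ones under
    # differential selection, which is what the PBS enrichment test probes.
    eqtl_tip_idx = rng.choice(cfg.n_tips, size=cfg.n_eqtl_tips, replace=False)
    n_overlap = min(cfg.n_selected_tips // 2, cfg.n_eqtl_tips)
    sel_from_eqtl = rng.choice(eqtl_tip_idx, size=n_overlap, replace=False)
    others = np.setdiff1d(np.arange(cfg.n_tips), eqtl_tip_idx)
    n_rest = cfg.n_selected_tips - n_overlap
    sel_rest = rng.choice(others, size=min(n_rest, others.size), replace=False)
    sel_idx = np.concatenate([sel_from_eqtl, sel_rest])[: cfg.n_selected_tips]
    freqs, selected = draw_tip_frequencies(cfg, rng, selected_indices=sel_idx)
    tip_ids = [f"tip_{i:05d}" for i in range(cfg.n_tips)]
    genome_span = int(starts[-1]) + GENE_SPACING
    tip_pos = rng.choice(np.arange(genome_span), size=cfg.n_tips, replace=False)
    # planted eQTL TIPs sit within the cis window of their own gene
    eqtl_genes = rng.choice(cfg.n_genes, size=cfg.n_eqtl_tips, replace=False)
    for t_idx, g_idx in zip(eqtl_tip_idx, eqtl_genes):
        gene = genes.iloc[g_idx]
        offset = int(rng.integers(-4_000, GENE_LENGTH + 4_000))
        tip_pos[t_idx] = max(0, gene["start"] + offset)

    geno = np.empty((cfg.n_tips, n_total), dtype=np.int8)
    for k, pop in enumerate(("pop1", "pop2", "pop3")):
        cols = pop_arr == pop
        geno[:, cols] = draw_genotypes(freqs[:, k], int(cols.sum()), rng)

    tip_loci = pd.DataFrame({
        "id": tip_ids, "chrom": CHROM, "pos": tip_pos,
    }).join(_te_annotation(cfg.n_tips, rng))

    # --- zygosity view: present -> high read support, absent -> 0, plus
    # missing cells
    # Missingness is clustered on a subset of loci (40% of loci carry all
    # of it) so that the published "no missing data" eQTL filter still
    # leaves most loci standing, as it does on real caller output.
    zyg = np.where(geno == 1, rng.uniform(0.6, 1.0, size=geno.shape), 0.0)
    if cfg.missing_frac > 0:
        affected = rng.random(cfg.n_tips) < 0.4
        cell_rate = min(1.0, cfg.missing_frac / 0.4)
        miss = (rng.random(geno.shape) < cell_rate) & affected[:, None]
        zyg = np.where(miss, np.nan, zyg)
    zygosity = ZygosityMatrix(tip_loci, accessions, zyg)
    genotypes = GenotypeMatrix(tip_loci.copy(), accessions, geno.astype(float))

    # --- genome-wide SNPs (half near genes so SNP-eQTL cis pairs exist)
    snp_ids = [f"snp_{i:06d}" for i in range(cfg.n_snps)]
    n_near = cfg.n_snps // 2
    near_gene = rng.choice(cfg.n_genes, size=n_near)
    near_pos = (
        genes["start"].to_numpy()[near_gene]
        + rng.integers(-4_500, GENE_LENGTH + 4_500, size=n_near)
    )
    far_pos = rng.choice(np.arange(genome_span), size=cfg.n_snps - n_near, replace=False)
    snp_pos = np.abs(np.concatenate([near_pos, far_pos]))
    p0_snp = np.clip(rng.beta(0.5, 0.5, size=cfg.n_snps), 0.05, 0.95)
    snp_freqs = np.column_stack([
        _balding_nichols(p0_snp, cfg.fst_drift, rng),
        _balding_nichols(p0_snp, cfg.fst_drift, rng),
        p0_snp,
    ])
    snp_geno = np.empty((cfg.n_snps, n_total), dtype=np.int8)
    for k, pop in enumerate(("pop1", "pop2", "pop3")):
        cols = pop_arr == pop
        snp_geno[:, cols] = draw_genotypes(snp_freqs[:, k], int(cols.sum()), rng)
    snp_loci = pd.DataFrame({
        "id": snp_ids, "chrom": CHROM, "pos": snp_pos,
        "te_family": "SNP", "te_order": "SNP",
    })
    order = np.argsort(snp_loci["pos"].to_numpy(), kind="mergesort")
    snps = GenotypeMatrix(
        snp_loci.iloc[order].reset_index(drop=True),
        accessions,
        snp_geno[order].astype(float),
    )

    # --- planted eQTL effects and expression
    lo, hi = cfg.beta_range
    betas = rng.uniform(lo, hi, size=cfg.n_eqtl_tips) * rng.choice(
        [-1.0, 1.0], size=cfg.n_eqtl_tips
    )
    cond_specific = rng.random(cfg.n_eqtl_tips) < 0.2
    planted = pd.DataFrame({
        "tip_id": [tip_ids[i] for i in eqtl_tip_idx],
        "gene_id": [gene_ids[i] for i in eqtl_genes],
        "beta": betas,
        "condition_specific": cond_specific,
    })
    counts = simulate_expression(
        geno, tip_ids, gene_ids, planted, metadata, cfg, rng
    )

    # --- sweep regions around focal TIPs, in population 1 (the largest)
    pop1_mask = pop_arr == "pop1"
    sweep_rows, sweep_blocks = [], {}
    n_sweep = min(cfg.n_sweep_loci, cfg.n_tips)
    # focal TIPs need enough carriers and non-carriers within pop1
    pop1_freq = geno[:, pop1_mask].mean(axis=1)
    eligible = np.nonzero((pop1_freq >= 0.2) & (pop1_freq <= 0.8))[0]
    focal_idx = rng.choice(eligible, size=min(n_sweep, eligible.size), replace=False)
    pop1_names = [a for a, p in zip(accessions, populations) if p == "pop1"]
    for j, t_idx in enumerate(focal_idx):
        sweep_type = "hard" if cfg.sweep_carrier_haplotypes == 1 else "soft"
        carriers = geno[t_idx, pop1_mask].astype(bool)
        center = SWEEP_REGION_SPACING * (j + 1)
        block = simulate_haplotype_region(
            n_samples=int(pop1_mask.sum()),
            n_snps=cfg.sweep_region_snps,
            carriers=carriers,
            sweep=True,
            cfg=cfg,
            rng=rng,
            focal_pos=center,
            chrom=f"chr_sweep{j + 1}",
            samples=pop1_names,
        )
        sweep_blocks[tip_ids[t_idx]] = block
        sweep_rows.append({"tip_id": tip_ids[t_idx], "sweep_type": sweep_type})

    truth = TruthTable(
        planted_eqtls=planted,
        selected_tips=pd.DataFrame({
            "tip_id": [tip_ids[i] for i in selected["tip_index"]],
            "focal_population": selected["focal_population"].tolist(),
            "target_freq": selected["target_freq"].tolist(),
        }),
        sweep_loci=pd.DataFrame(sweep_rows, columns=["tip_id", "sweep_type"]),
    )
    return Cohort(
        config=cfg,
        zygosity=zygosity,
        genotypes=genotypes,
        snps=snps,
        genes=genes,
        counts=counts,
        metadata=metadata,
        frequencies=freqs,
        sweep_blocks=sweep_blocks,
        truth=truth,
    )
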