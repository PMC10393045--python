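"""Published analysis thresholds, centralized.

Every filtering and scanning stage of the pipeline refers to these named
constants rather than hard-coding numbers, so the provenance of each
threshold is visible in one place and presets stay consistent between the
library, the CLI and the configuration file.
"""

#: Minimum per-sample zygosity (read-support fraction) that at least one
#: sample must reach for a TIP locus to be retained; loci below this in
#: every sample are treated as likely false positives of the caller.
ZYGOSITY_MIN = 0.25

#: Zygosity at or above which an insertion is called present when the
#: zygosity matrix is collapsed to binary presence/absence.
PRESENCE_CUTOFF = 0.05

#: Strict lower bound on minor allele frequency for markers entering the
#: cis-eQTL scans (kept iff MAF > this value).
EQTL_MIN_MAF = 0.03

#: Missingness ceiling for eQTL markers (no missing data tolerated).
EQTL_MAX_MISSING = 0.0

#: Strict lower bound on MAF for loci entering the PBS scan.
PBS_MIN_MAF = 0.05

#: Maximum tolerated fraction of missing calls per locus in the PBS scan;
#: the survivors are imputed before frequencies are computed.
PBS_MAX_MISSING = 0.05

#: Half-width in bp of the cis window around the gene body within which a
#: marker-gene pair is tested for association.
CIS_WINDOW_BP = 5_000

#: Benjamini-Hochberg false discovery rate threshold for calling a
#: marker-gene association significant within one scan.
FDR_THRESHOLD = 0.05

#: Relaxed, unadjusted p-value cutoff used only to ask whether a hit found
#: in one condition/population replicates in another.
RELAXED_P = 0.05

#: Minimum fraction of samples in which a gene must show nonzero counts
#: (strictly more than this fraction) to be considered expressed.
MIN_EXPRESSED_FRAC = 0.10

#: Nucleotide-diversity window: number of SNPs per window and SNP step.
PI_WINDOW_SNPS = 25
PI_STEP_SNPS = 5

#: H12 haplotype-homozygosity window: number of SNPs per window and step.
#: Wider than the pi window because sweeps leave long homozygosity tracts.
H12_WINDOW_SNPS = 50
H12_STEP_SNPS = 25

#: Flank in bp on each side of a focal TIP over which the sweep scan runs.
SWEEP_FLANK_BP = 50_000

#: Number of random resampling draws for the sweep permutation null.
N_PERMUTATIONS = 1_000

#: Percentiles of |PBS| used to flag candidate selected loci.
PBS_PERCENTILES = (95.0, 99.0)

#: Default positional tolerance (bp) when matching predicted TIPs against
#: an annotated truth set in the benchmark.
BENCHMARK_TOLERANCE_BP = 100
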