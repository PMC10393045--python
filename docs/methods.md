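# Methods

This note documents the statistical models implemented in `tipselect`,
the defaults and their rationale, what the synthetic cohorts do and do not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic cohort

The generator (`tipselect.simulate`) emulates a three-population crop
study: two derived populations of inbred accessions (defaults 126 and 82,
mirroring an indica-like and a japonica-like panel) and an 82-accession
wild-relative pool standing in for their common ancestor. Samples are
haploid-equivalent — inbred lines carry or lack an insertion, so no
heterozygotes are simulated and a "haplotype" is simply a sample's allele
string.

**Allele frequencies.** Each TIP has an ancestral frequency
p₀ ~ Beta(0.5, 0.5) truncated to [0.02, 0.98]; each derived population's
frequency is Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with F = `fst_drift`
(Balding–Nichols). The wild pool keeps p₀. This choice is deliberate: it
is tunable by a single parameter and analytically checkable. Under it the
genome-wide Hudson F_ST between the two derived populations is ≈ F, while
between a derived population and the undrifted wild pool it is ≈ F/2
(only one side contributes drift variance); both expectations are asserted
by Monte-Carlo tests. The default F = 0.1 gives differentiation strong
enough to exercise the PBS machinery without swamping planted signals.

**Selection.** `n_selected_tips` loci have their frequency in exactly one
derived population replaced by a target drawn from [0.8, 0.99] (when
p₀ < 0.5) or [0.01, 0.2] (otherwise), producing one long branch on the
three-taxon tree. Half of the selected loci are drawn from the planted
eQTL set: the emulated design is that expression-associated insertions
are the ones under differential selection, which is precisely what the
downstream enrichment and rank-sum analyses probe. Without this overlap
those analyses would have nothing to find and could only be tested for
type-I behaviour.

**Expression.** Counts are negative binomial with log link:
μ = exp(b₀ + b_subpop + β·g), variance μ + αμ² with dispersion α =
`nb_dispersion` (default 0.2, a typical 3′-mRNA-seq value; α → 0 recovers
Poisson and is tested as such). b₀ ~ N(5.5, 0.8) puts median depth near
250 counts so the +1 in the log2 normalization is negligible. Each
accession yields 2 conditions × 3 replicate libraries; condition-specific
effects (20% of planted eQTLs) add β only under the "drought" condition.
Planted effects β are drawn from `beta_range` (default 0.5–1.5 natural-log
units, i.e. 1.6–4.5-fold per insertion allele) with random sign, and the
planted TIP is placed inside the cis window of its gene.

**Missingness.** The zygosity view marks present calls with read-support
values in [0.6, 1.0] and absent calls 0. Missing cells (default 2%
overall) are clustered on 40% of loci rather than spread uniformly:
caller dropout is locus-structured in practice, and uniform missingness
would let the published "no missing data" eQTL filter annihilate the
matrix (with 290 samples, almost no locus would be complete).

**Sweeps.** Around `n_sweep_loci` focal TIPs, regional SNP haplotypes are
simulated directly rather than coalescently: neutral samples draw each
SNP independently at a frequency ~ U(0.05, 0.95); carrier samples at a
swept locus copy one of `sweep_carrier_haplotypes` template haplotypes
(1 = hard sweep, default 2 = soft) with per-site mutation probability
0.01. This reproduces the two features the scan statistics measure —
depressed carrier diversity and elevated haplotype homozygosity — at a
controllable strength.

**What the generator does not emulate.** No linkage disequilibrium
between markers outside sweep regions (so SNP-eQTLs arise only from
planted TIP effects, not tagging), no recombination gradients or
demographic history, no read-level error structure, no expression
heteroscedasticity beyond NB, and the wild pool is panmictic (the real
wild group pools two species). Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated model,
not that the pipeline is robust to every pathology of real data.

## TIP matrix conventions

Boundary semantics are centralized: zygosity-style cutoffs keep values
**≥** the threshold (a locus with one sample at exactly 0.25 survives;
zygosity exactly 0.05 is "present"), while MAF filters are **strict**
(MAF must exceed 3% or 5%), following the published "higher than"
phrasing. Missing is NaN and is never conflated with absence.

The imputation of residual missingness (≤ 5% per locus after the PBS
preset) offers two modes because the reference algorithm is not publicly
specified: `expected` (deterministic majority rule — missing becomes
present iff locus frequency ≥ 0.5; the default, for reproducibility) and
`bernoulli` (a seeded draw at the locus frequency, which preserves
frequency in expectation and is checked by a binomial-bound test). For
loci that pass the 5% missingness ceiling the two modes can differ on at
most a handful of calls per locus.

## eQTL mapping

Normalization is a documented stand-in for a variance-stabilizing
transform: DESeq-style median-of-ratios size factors (geometric-mean
reference over genes with all-positive counts; library-size fallback with
a warning), then log2(x/s + 1). The association model is invariant to any
monotone variance-stabilizing choice under the null, so FDR calibration
does not depend on this choice; effect sizes are reported in
log2-normalized units.

The OLS fit residualizes both expression and genotype on the covariates
(intercept + subpopulation treatment dummies, largest group as reference)
and regresses residual on residual — algebraically identical to the full
fit for the marker coefficient, and vectorized across all cis pairs of a
scan. Reported r² is the squared partial correlation t²/(t²+df). BH
adjustment is applied per (replicate × condition × population ×
marker-type) scan over all tested pairs — the convention of standard
matrix-eQTL software — because adjusting over pairs, not genes, is what
the per-pair q-values mean.

The cis window is gene body ± 5,000 bp with strict outer bounds: the
signed distance is 0 inside the body, p − start upstream, p − end + 1
beyond the last base (negative upstream of the 5′ end, strand-aware), and
a pair is tested iff |distance| < 5,000. A marker exactly 5 kb away is
excluded ("less than 5 kb").

Consolidation: a (gene, marker, condition, population) is a hit iff
q < 0.05 in ≥ 1 replicate; the reported effect comes from the smallest-q
replicate, sign conflicts among significant replicates are flagged, and
the leading marker per gene is chosen by min q, then smaller |distance|,
then lexicographic marker id — an invented but deterministic tie-break.
"Shared" associations use the relaxed criterion (unadjusted p < 0.05 with
concordant sign in any replicate of the other scan); "condition-specific"
means significant in one condition and not shared in the other.

## Selection statistics

**F_ST.** The per-locus estimator is the Hudson-style form
(H_T − H_W)/H_T with H_W the unweighted mean within-population expected
heterozygosity 2p(1−p)·n/(n−1) and H_T the heterozygosity of the
size-weighted pooled frequency with the pooled n/(n−1) correction,
clamped to [0, 1−10⁻⁹]; a pooled-monomorphic locus is defined as F_ST = 0.
Note this pooled-H_T form is systematically below the classic
ratio-of-heterozygosities 1 − H_W/H_B at strong differentiation (0.64 vs
0.78 at p = 0.9/0.1, n = 100); it is verified against a brute-force
count-table oracle to 10⁻¹⁰. A Weir–Cockerham variance-components
estimator is available behind `estimator="wc"` for sensitivity analyses.

**PBS.** T = −ln(1 − F_ST) (inputs must be pre-clamped below 1; negative
estimates are clamped to 0 since branch lengths cannot be negative). Both
derived branches are emitted, pbs_i + pbs_j = t_ij holds as an algebraic
identity, and the wild branch follows by symmetry. Because published
analyses report a single "absolute PBS" without naming the branch,
ranking and percentile flags use max(|pbs_i|, |pbs_j|), with per-branch
values in the output so either convention is recoverable. Enrichment of
eQTLs among extreme loci uses the sample odds ratio ad/bc (Haldane 0.5
correction when a cell is zero — this differs from the conditional-MLE OR
that some software reports) with the two-sided Fisher exact p; the group
comparison is a two-sided Mann–Whitney U with tie and continuity
corrections (all-tied input is defined as p = 1).

## Sweep scan

Windows are defined over SNP indices exactly as published — π in 25-SNP
windows stepping by 5, H12 in 50-SNP windows stepping by 25 — so the
genomic span of a window varies with SNP density; spans are reported so
per-bp rescaling is possible. π is the mean per-site unbiased diversity
2p̂(1−p̂)·n/(n−1), which equals the average pairwise Hamming distance per
site (asserted against exhaustive pair counting). H12 pools the two most
frequent haplotypes: (p₁+p₂)² + Σ_{i≥3} p_i².

The permutation null redraws groups of the observed size uniformly from
**all** samples of the region, irrespective of TIP state, and recomputes
the statistic in the same windows. P-values are one-sided toward the
sweep signature (low π, high H12) with the add-one correction
(1 + #extreme)/(N + 1), so p ≥ 1/(N+1) always; a two-sided variant is
available. Group size must be strictly smaller than the sample count
(otherwise the null is degenerate) and both carrier groups need ≥ 2
samples.

## Benchmark

Matching a predicted call set to an annotated truth set abstracts
assembly-orthology comparison as coordinate proximity (±100 bp default)
plus TE-family identity. Matching is greedy nearest-first and one-to-one,
which conserves counts (TP+FN = truth size, TP+FP = prediction size) and
is order-invariant; optimal bipartite matching would differ only in
contrived tie configurations at this tolerance.

## Problem sizes and determinism

The default cohort (400 TIPs, 1,500 SNPs, 150 genes, 290 accessions,
1,740 libraries) runs the full pipeline in a few seconds; validation
experiments use 120-accession cohorts with 50–60 genes (power), 200 genes
(null FDR), 2,000 loci (PBS recovery) and 60-sample × 120-SNP regions
(sweeps) — sizes chosen so the whole suite and the acceptance script run
comfortably on a single CPU while leaving the statistical margins wide.
Every stochastic component is driven by `numpy.random.default_rng` seeded
from one integer; the pipeline's outputs are byte-identical across runs
at a fixed seed, and output provenance headers record version, a hash of
the analysis-relevant configuration, and the seed (timestamps are
deliberately omitted).

## Known limitations

- No LD between markers means TIP-vs-SNP variance-explained comparisons
  on synthetic cohorts mostly produce "TIP_only" genes; the
  `compare_variance_explained` categories are exercised directly by unit
  tests instead.
- The effect estimate reported for a hit comes from its best replicate,
  which is mildly optimistic (winner's curse); the acceptance experiment
  averages over significant conditions and still observes a small upward
  bias (~10%) — expected, and within its stated band.
- The `expected` imputation mode biases rare-allele frequencies toward
  the major allele (by at most the missingness ceiling, 5%); use
  `bernoulli` when unbiased frequencies matter more than determinism.
- trans-eQTLs, kinship/mixed models, haplotype-based PBS, iHS/XP-EHH and
  phasing are out of scope by design.
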