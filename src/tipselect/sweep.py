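"""Locus-level sweep scan around a focal TIP: windowed nucleotide diversity
(pi) and H12 haplotype homozygosity for insertion carriers vs non-carriers,
each against a permutation null.

Samples are haploid-equivalent (inbred accessions), so a "haplotype" is
simply a sample's allele string over a window. Windows are defined over SNP
*indices*, not base pairs: 25 SNPs stepping by 5 for pi, 50 stepping by 25
for H12, so the genomic span of a window varies with local SNP density and
is reported alongside each value.

The permutation null redraws groups of the same size uniformly from *all*
samples in the region, irrespective of TIP state, and recomputes the
statistic in the same windows; p-values are one-sided toward the sweep
signature (low pi, high H12) with the add-one correction
p = (1 + #{perm at least as extreme}) / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    H12_STEP_SNPS,
    H12_WINDOW_SNPS,
    N_PERMUTATIONS,
    PI_STEP_SNPS,
    PI_WINDOW_SNPS,
    SWEEP_FLANK_BP,
)


class ScanError(ValueError):
    """A sweep scan could not run; the message names the deficiency."""


@dataclass
class HaplotypeBlock:
    """Binary alleles of all samples over the SNPs of one genomic region."""

    chrom: str
    start: int
    end: int
    positions: np.ndarray  # ascending, within [start, end)
    alleles: np.ndarray  # samples x SNPs, values 0/1
    samples: list[str]
    carrier: np.ndarray  # bool per sample, True if the focal TIP is present

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles)
        self.carrier = np.asarray(self.carrier, dtype=bool)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be samples x SNPs")
        if self.alleles.shape != (len(self.samples), self.positions.size):
            raise ValueError("alleles shape does not match samples x positions")
        if self.positions.size and (
            np.any(np.diff(self.positions) <= 0)
            or self.positions[0] < self.start
            or self.positions[-1] >= self.end
        ):
            raise ValueError("positions must be strictly increasing inside region")
        if np.isnan(self.alleles.astype(float)).any():
            raise ValueError("alleles must be imputed before scanning")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.positions.size


def _window_starts(n_snps: int, window: int, step: int) -> np.ndarray:
    """Start indices of full windows; a trailing partial window is dropped."""
    if n_snps < window:
        return np.empty(0, dtype=int)
    return np.arange(0, n_snps - window + 1, step)


def _pi_values(alleles: np.ndarray, window: int, step: int) -> np.ndarray:
    """Mean per-site pairwise diversity per window for one sample subset.

    Per site, diversity is the unbiased expected heterozygosity
    2*p*(1-p)*n/(n-1); the window value is the mean over its SNPs, which
    equals the average pairwise Hamming distance per site.
    """
    n = alleles.shape[0]
    p = alleles.mean(axis=0)
    site_pi = 2.0 * p * (1.0 - p) * n / (n - 1)
    starts = _window_starts(alleles.shape[1], window, step)
    csum = np.concatenate([[0.0], np.cumsum(site_pi)])
    return (csum[starts + window] - csum[starts]) / window


def _h12_values(alleles: np.ndarray, window: int, step: int) -> np.ndarray:
    """H12 per window: (p1+p2)^2 + sum_{i>=3} p_i^2 over sorted haplotype
    frequencies."""
    starts = _window_starts(alleles.shape[1], window, step)
    out = np.empty(starts.size)
    packed = np.ascontiguousarray(alleles.astype(np.uint8))
    for k, s in enumerate(starts):
        win = packed[:, s : s + window]
        _, counts = np.unique(win, axis=0, return_counts=True)
        freqs = np.sort(counts / win.shape[0])[::-1]
        if freqs.size == 1:
            out[k] = 1.0
        else:
            out[k] = (freqs[0] + freqs[1]) ** 2 + np.sum(freqs[2:] ** 2)
    return out


def _window_frame(
    block: HaplotypeBlock, starts: np.ndarray, window: int, stat: str
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window": np.arange(starts.size),
            "snp_start": starts,
            "snp_end": starts + window,
            "span_start": block.positions[starts] if starts.size else [],
            "span_end": block.positions[starts + window - 1] if starts.size else [],
            "stat": stat,
        }
    )


def _subset_indices(block: HaplotypeBlock, samples_subset) -> np.ndarray:
    if np.asarray(samples_subset).dtype == bool:
        idx = np.nonzero(np.asarray(samples_subset))[0]
    else:
        lookup = {s: i for i, s in enumerate(block.samples)}
        idx = np.array([lookup[s] for s in samples_subset], dtype=int)
    if idx.size < 2:
        raise ScanError("need at least 2 samples to compute diversity")
    return idx


def window_pi(
    block: HaplotypeBlock,
    samples_subset,
    window_snps: int = PI_WINDOW_SNPS,
    step_snps: int = PI_STEP_SNPS,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity for a subset of samples."""
    idx = _subset_indices(block, samples_subset)
    starts = _window_starts(block.n_snps, window_snps, step_snps)
    if starts.size == 0:
        warnings.warn("fewer SNPs than one window; empty pi scan", stacklevel=2)
    frame = _window_frame(block, starts, window_snps, "pi")
    frame["value"] = _pi_values(block.alleles[idx], window_snps, step_snps)
    return frame


def window_h12(
    block: HaplotypeBlock,
    samples_subset,
    window_snps: int = H12_WINDOW_SNPS,
    step_snps: int = H12_STEP_SNPS,
) -> pd.DataFrame:
    """Sliding-window H12 haplotype homozygosity for a subset of samples."""
    idx = _subset_indices(block, samples_subset)
    starts = _window_starts(block.n_snps, window_snps, step_snps)
    if starts.size == 0:
        warnings.warn("fewer SNPs than one window; empty H12 scan", stacklevel=2)
    frame = _window_frame(block, starts, window_snps, "h12")
    frame["value"] = _h12_values(block.alleles[idx], window_snps, step_snps)
    return frame


def permutation_null(
    block: HaplotypeBlock,
    group_size: int,
    stat: str,
    observed: np.ndarray,
    window_snps: int | None = None,
    step_snps: int | None = None,
    n_perm: int = N_PERMUTATIONS,
    seed: int | None = None,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Permutation null for a windowed statistic.

    Each of ``n_perm`` draws samples ``group_size`` accessions uniformly
    without replacement from all samples in the block and recomputes the
    statistic in the same windows. Returns per-window ``perm_mean`` and
    ``perm_p``, one-sided toward the sweep signature (pi low, H12 high)
    unless ``two_sided``.
    """
    if stat not in ("pi", "h12"):
        raise ValueError(f"stat must be 'pi' or 'h12', got {stat!r}")
    if group_size >= block.n_samples:
        raise ScanError("permutation null needs group_size < total samples")
    if group_size < 2:
        raise ScanError("group_size must be >= 2")
    if window_snps is None:
        window_snps = PI_WINDOW_SNPS if stat == "pi" else H12_WINDOW_SNPS
    if step_snps is None:
        step_snps = PI_STEP_SNPS if stat == "pi" else H12_STEP_SNPS
    observed = np.asarray(observed, dtype=float)
    rng = np.random.default_rng(seed)
    compute = _pi_values if stat == "pi" else _h12_values
    perm = np.empty((n_perm, observed.size))
    for i in range(n_perm):
        idx = rng.choice(block.n_samples, size=group_size, replace=False)
        perm[i] = compute(block.alleles[idx], window_snps, step_snps)
    if stat == "pi":
        extreme = perm <= observed[None, :]
    else:
        extreme = perm >= observed[None, :]
    p = (1 + extreme.sum(axis=0)) / (n_perm + 1)
    if two_sided:
        other = (1 + (~extreme).sum(axis=0)) / (n_perm + 1)
        p = np.minimum(1.0, 2.0 * np.minimum(p, other))
    return pd.DataFrame({"perm_mean": perm.mean(axis=0), "perm_p": p})


def scan_locus(
    block: HaplotypeBlock,
    pi_window: int = PI_WINDOW_SNPS,
    pi_step: int = PI_STEP_SNPS,
    h12_window: int = H12_WINDOW_SNPS,
    h12_step: int = H12_STEP_SNPS,
    n_perm: int = N_PERMUTATIONS,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full sweep scan at one focal TIP.

    Computes windowed pi and H12 separately for carriers and non-carriers
    and attaches, per window and group, the permutation mean and p-value of
    a null that resamples groups of the same size from all samples.
    Requires >= 2 carriers and >= 2 non-carriers and at least one full
    window of SNPs.
    """
    n_car = int(block.carrier.sum())
    n_non = block.n_samples - n_car
    if n_car < 2:
        raise ScanError(f"only {n_car} carrier(s); need >= 2")
    if n_non < 2:
        raise ScanError(f"only {n_non} non-carrier(s); need >= 2")
    if block.n_snps < max(pi_window, h12_window):
        raise ScanError(
            f"{block.n_snps} SNPs in region; need >= {max(pi_window, h12_window)}"
        )
    rng = np.random.default_rng(seed)
    pieces = []
    for stat, window, step in (("pi", pi_window, pi_step), ("h12", h12_window, h12_step)):
        scan = window_pi if stat == "pi" else window_h12
        for group, mask in (("carriers", block.carrier), ("noncarriers", ~block.carrier)):
            obs = scan(block, mask, window, step)
            null = permutation_null(
                block,
                int(mask.sum()),
                stat,
                obs["value"].to_numpy(),
                window,
                step,
                n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )
            obs = obs.assign(group=group, chrom=block.chrom, **null)
            pieces.append(obs)
    return pd.concat(pieces, ignore_index=True)


def extract_block(
    snp_positions: np.ndarray,
    snp_alleles: np.ndarray,
    samples: list[str],
    chrom: str,
    focal_pos: int,
    carrier: np.ndarray,
    flank: int = SWEEP_FLANK_BP,
) -> HaplotypeBlock:
    """Cut the +/-``flank`` bp region around a focal position out of a SNP
    matrix (SNPs x samples) and return it as a HaplotypeBlock."""
    start = max(0, focal_pos - flank)
    end = focal_pos + flank + 1
    positions = np.asarray(snp_positions, dtype=np.int64)
    inside = (positions >= start) & (positions < end)
    return HaplotypeBlock(
        chrom=chrom,
        start=start,
        end=end,
        positions=positions[inside],
        alleles=np.asarray(snp_alleles)[inside].T,
        samples=list(samples),
        carrier=np.asarray(carrier, dtype=bool),
    )
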