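"""Population Branch Statistic scan over TIP presence frequencies.

Given presence frequencies of each locus in three populations (two derived
crop populations and a wild-relative proxy for their common ancestor), the
scan computes the three pairwise Hudson FST values, transforms them to
branch lengths t = -ln(1 - FST), and places each locus on a three-taxon
tree. The branch length private to population *i*,

    PBS_i = (t_ij + t_iw - t_jw) / 2,

measures allele-frequency change along that lineage since the split; large
values flag lineage-specific differentiation consistent with selection.

The Hudson estimator is used by default because it is well behaved under
unequal sample sizes; Weir-Cockerham is available behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .constants import PBS_PERCENTILES

_FST_CEIL = 1.0 - 1e-9


def per_locus_fst(
    p1: np.ndarray,
    n1: int,
    p2: np.ndarray,
    n2: int,
    estimator: str = "hudson",
) -> np.ndarray:
    """Pairwise FST between two populations from presence frequencies.

    Hudson (default): FST = (Ht - Hw) / Ht where Hw is the unweighted mean
    within-population expected heterozygosity 2p(1-p) with the unbiased
    n/(n-1) small-sample correction, and Ht is the heterozygosity of the
    pooled (size-weighted) frequency with the pooled-sample correction.
    Weir-Cockerham ("wc") follows the two-population variance-components
    estimator for haploid-equivalent allele counts.

    Estimates are clamped to [0, 1 - 1e-9]; a monomorphic pooled locus
    (Ht = 0) is defined to have FST = 0.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per population")
    if estimator == "hudson":
        hw = 0.5 * (
            2.0 * p1 * (1.0 - p1) * n1 / (n1 - 1)
            + 2.0 * p2 * (1.0 - p2) * n2 / (n2 - 1)
        )
        ntot = n1 + n2
        pbar = (n1 * p1 + n2 * p2) / ntot
        ht = 2.0 * pbar * (1.0 - pbar) * ntot / (ntot - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = np.where(ht > 0, (ht - hw) / np.where(ht > 0, ht, 1.0), 0.0)
    elif estimator == "wc":
        # Weir & Cockerham theta for haploid-equivalent samples.
        nbar = (n1 + n2) / 2.0
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / 1.0
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        msp = s2 * nbar / 1.0
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 + n2 - 2)
        num = msp - msg
        den = msp + (nc - 1) * msg
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    else:
        raise ValueError(f"unknown FST estimator {estimator!r}")
    return np.clip(fst, 0.0, _FST_CEIL)


def branch_length(fst: np.ndarray) -> np.ndarray:
    """Branch-length transform t = -ln(1 - FST); requires FST in [0, 1)."""
    fst = np.asarray(fst, dtype=float)
    if np.any(fst >= 1.0) or np.any(fst < 0.0):
        raise ValueError("FST must be pre-clamped to [0, 1)")
    return -np.log1p(-fst)


def pbs_scan(
    freqs: pd.DataFrame,
    pops: tuple[str, str, str],
    sample_sizes: dict[str, int],
    percentiles: tuple[float, float] = PBS_PERCENTILES,
    estimator: str = "hudson",
) -> pd.DataFrame:
    """Per-locus PBS for the two derived branches of a three-population tree.

    ``pops`` names (derived_i, derived_j, wild_proxy) columns of ``freqs``.
    Loci with a missing frequency in any population are dropped. Returns a
    table with pairwise FSTs, branch transforms, pbs_i, pbs_j, the implied
    wild branch, abs_pbs = max(|pbs_i|, |pbs_j|) and a percentile flag
    ("none"/"top5"/"top1" for the default 95/99 percentiles of abs_pbs over
    all scanned loci).
    """
    pi_name, pj_name, pw_name = pops
    sub = freqs.dropna(subset=list(pops)).reset_index(drop=True)
    p_i = sub[pi_name].to_numpy(float)
    p_j = sub[pj_name].to_numpy(float)
    p_w = sub[pw_name].to_numpy(float)
    n_i, n_j, n_w = (sample_sizes[p] for p in pops)

    fst_ij = per_locus_fst(p_i, n_i, p_j, n_j, estimator)
    fst_iw = per_locus_fst(p_i, n_i, p_w, n_w, estimator)
    fst_jw = per_locus_fst(p_j, n_j, p_w, n_w, estimator)
    t_ij = branch_length(fst_ij)
    t_iw = branch_length(fst_iw)
    t_jw = branch_length(fst_jw)
    pbs_i = (t_ij + t_iw - t_jw) / 2.0
    pbs_j = (t_ij + t_jw - t_iw) / 2.0
    pbs_w = (t_iw + t_jw - t_ij) / 2.0
    abs_pbs = np.maximum(np.abs(pbs_i), np.abs(pbs_j))

    out = pd.DataFrame(
        {
            "id": sub["id"],
            "fst_ij": fst_ij,
            "fst_iw": fst_iw,
            "fst_jw": fst_jw,
            "t_ij": t_ij,
            "t_iw": t_iw,
            "t_jw": t_jw,
            "pbs_i": pbs_i,
            "pbs_j": pbs_j,
            "pbs_w": pbs_w,
            "abs_pbs": abs_pbs,
        }
    )
    lo, hi = percentiles
    flag = np.full(len(out), "none", dtype=object)
    if len(out):
        q_lo = np.percentile(abs_pbs, lo)
        q_hi = np.percentile(abs_pbs, hi)
        flag[abs_pbs >= q_lo] = "top5"
        flag[abs_pbs >= q_hi] = "top1"
    out["pct_flag"] = flag
    return out


def eqtl_enrichment_test(
    pbs_table: pd.DataFrame,
    eqtl_flags: np.ndarray,
    percentile: float = 95.0,
) -> dict:
    """Are extreme-PBS loci enriched for eQTL markers? (2x2 Fisher test.)

    Cross-tabulates {abs_pbs above the given percentile} x {eQTL flag};
    returns the sample odds ratio ad/bc (Haldane 0.5 correction applied if
    any cell is zero), the two-sided Fisher exact p-value and the table.
    Degenerate margins give p = 1 and an undefined OR flag.
    """
    flags = np.asarray(eqtl_flags, dtype=bool)
    if flags.shape[0] != len(pbs_table):
        raise ValueError("eqtl_flags length does not match PBS table")
    abs_pbs = pbs_table["abs_pbs"].to_numpy(float)
    extreme = abs_pbs >= np.percentile(abs_pbs, percentile)
    a = int(np.sum(extreme & flags))
    b = int(np.sum(extreme & ~flags))
    c = int(np.sum(~extreme & flags))
    d = int(np.sum(~extreme & ~flags))
    table = np.array([[a, b], [c, d]])
    degenerate = any(m == 0 for m in (a + b, c + d, a + c, b + d))
    if degenerate:
        return {
            "odds_ratio": np.nan,
            "p_value": 1.0,
            "table": table,
            "or_defined": False,
        }
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "odds_ratio": float(odds),
        "p_value": float(p),
        "table": table,
        "or_defined": True,
    }


def rank_sum_compare(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """Two-sided Mann-Whitney U comparison of two groups of PBS values.

    Normal approximation with tie and continuity corrections. If every
    value is tied across both groups the test is undefined and p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return {"u": a.size * b.size / 2.0, "p_value": 1.0}
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return {"u": float(res.statistic), "p_value": float(res.pvalue)}
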