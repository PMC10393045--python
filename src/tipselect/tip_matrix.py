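"""TIP zygosity/genotype matrices: filtering, binarization, imputation,
per-population frequencies and population-specificity classification.

The raw input is a per-locus, per-sample *zygosity* matrix: the fraction of
read evidence supporting an insertion, in [0, 1], or missing. Downstream
analyses use a binary presence/absence matrix derived from it. Missingness
is encoded as NaN throughout and is distinct from 0 (absence evidence is
evidence; no evidence is not).

Boundary semantics are centralized here: zygosity and binarization cutoffs
keep values >= the cutoff, while MAF filters are strict (kept iff
MAF > min_maf). See :func:`passes_ge` and :func:`passes_maf`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import (
    EQTL_MAX_MISSING,
    EQTL_MIN_MAF,
    PBS_MAX_MISSING,
    PBS_MIN_MAF,
    PRESENCE_CUTOFF,
    ZYGOSITY_MIN,
)

LOCUS_COLUMNS = ["id", "chrom", "pos", "te_family", "te_order"]

#: (min_maf, max_missing_frac) presets for the two published filtering paths.
MAF_PRESETS: dict[str, tuple[float, float]] = {
    "eqtl": (EQTL_MIN_MAF, EQTL_MAX_MISSING),
    "pbs": (PBS_MIN_MAF, PBS_MAX_MISSING),
}


def passes_ge(values: np.ndarray, cutoff: float) -> np.ndarray:
    """Inclusive keep-rule for zygosity-style thresholds (value >= cutoff)."""
    return values >= cutoff


def passes_maf(maf: np.ndarray, min_maf: float) -> np.ndarray:
    """Strict keep-rule for MAF thresholds (MAF must exceed min_maf)."""
    return maf > min_maf


def _check_loci(loci: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in LOCUS_COLUMNS if c not in loci.columns]
    if missing_cols:
        raise ValueError(f"locus table lacks columns {missing_cols}")
    if loci["id"].duplicated().any():
        dupes = loci.loc[loci["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate locus ids: {dupes[:5]}")
    if (loci["pos"] < 0).any():
        raise ValueError("locus positions must be >= 0")
    return loci.reset_index(drop=True)


@dataclass
class ZygosityMatrix:
    """Loci x samples zygosity values in [0, 1], NaN for missing."""

    loci: pd.DataFrame
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.loci = _check_loci(self.loci)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.loci), len(self.samples)):
            raise ValueError(
                f"value matrix {self.values.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("zygosity values must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, mask: np.ndarray) -> "ZygosityMatrix":
        return ZygosityMatrix(
            self.loci.loc[mask].reset_index(drop=True),
            list(self.samples),
            self.values[mask],
        )


@dataclass
class GenotypeMatrix:
    """Binary presence/absence calls (0/1, NaN = missing) with locus metadata.

    Used for both TIP and SNP markers; SNP loci carry placeholder TE columns.
    """

    loci: pd.DataFrame
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.loci = _check_loci(self.loci)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.loci), len(self.samples)):
            raise ValueError("call matrix shape does not match loci x samples")
        finite = self.calls[np.isfinite(self.calls)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("calls must be 0, 1 or NaN")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.loci.loc[mask].reset_index(drop=True),
            list(self.samples),
            self.calls[mask],
        )

    def presence_frequency(self) -> np.ndarray:
        """Per-locus presence frequency over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.calls, axis=1)


def filter_low_zygosity(
    m: ZygosityMatrix, min_zygosity: float = ZYGOSITY_MIN
) -> ZygosityMatrix:
    """Drop loci whose zygosity never reaches ``min_zygosity`` in any sample.

    Loci supported only by weak read evidence everywhere are likely caller
    artifacts. A locus is kept iff its maximum non-missing zygosity is
    >= ``min_zygosity`` (inclusive boundary).
    """
    if m.n_loci == 0:
        return m
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        peak = np.nanmax(m.values, axis=1)
    keep = np.where(np.isnan(peak), False, passes_ge(peak, min_zygosity))
    if not keep.any():
        warnings.warn("all loci removed by zygosity filter", stacklevel=2)
    return m.subset_loci(keep)


def binarize_zygosity(
    m: ZygosityMatrix, cutoff: float = PRESENCE_CUTOFF
) -> GenotypeMatrix:
    """Collapse zygosity to presence/absence: value >= cutoff means present.

    Missing values stay missing.
    """
    calls = np.where(np.isnan(m.values), np.nan,
                     passes_ge(m.values, cutoff).astype(float))
    return GenotypeMatrix(m.loci.copy(), list(m.samples), calls)


def filter_maf_missing(
    g: GenotypeMatrix,
    min_maf: float | None = None,
    max_missing_frac: float | None = None,
    preset: str | None = None,
) -> GenotypeMatrix:
    """Keep loci with missingness <= ``max_missing_frac`` and MAF > ``min_maf``.

    MAF is min(f, 1-f) of the presence frequency over non-missing calls.
    ``preset`` may be "eqtl" (MAF > 3%, no missing data) or "pbs"
    (MAF > 5%, <= 5% missing); explicit arguments override the preset.
    """
    if preset is not None:
        p_maf, p_miss = MAF_PRESETS[preset]
        min_maf = p_maf if min_maf is None else min_maf
        max_missing_frac = p_miss if max_missing_frac is None else max_missing_frac
    if min_maf is None or max_missing_frac is None:
        raise ValueError("provide min_maf and max_missing_frac, or a preset")
    if min_maf >= 0.5:
        raise ValueError("min_maf must be < 0.5")
    if g.n_loci == 0:
        return g
    miss_frac = np.isnan(g.calls).mean(axis=1)
    freq = g.presence_frequency()
    maf = np.minimum(freq, 1.0 - freq)
    keep = (miss_frac <= max_missing_frac) & np.where(
        np.isnan(maf), False, passes_maf(maf, min_maf)
    )
    return g.subset_loci(keep)


def impute_missing(
    g: GenotypeMatrix, mode: str = "expected", seed: int | None = None
) -> GenotypeMatrix:
    """Fill missing calls from the locus presence frequency.

    mode "expected": deterministic majority rule — missing becomes present
    iff the locus frequency is >= 0.5. mode "bernoulli": each missing call
    is an independent Bernoulli(frequency) draw under ``seed``. Non-missing
    calls are never altered.
    """
    if mode not in ("expected", "bernoulli"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    calls = g.calls.copy()
    missing = np.isnan(calls)
    if not missing.any():
        return GenotypeMatrix(g.loci.copy(), list(g.samples), calls)
    all_missing = missing.all(axis=1)
    if all_missing.any():
        bad = g.loci.loc[all_missing, "id"].tolist()
        raise ValueError(f"loci with all calls missing cannot be imputed: {bad[:5]}")
    freq = g.presence_frequency()
    rows, cols = np.nonzero(missing)
    if mode == "expected":
        fill = (freq[rows] >= 0.5).astype(float)
    else:
        rng = np.random.default_rng(seed)
        fill = (rng.random(rows.size) < freq[rows]).astype(float)
    calls[rows, cols] = fill
    return GenotypeMatrix(g.loci.copy(), list(g.samples), calls)


def allele_frequency(
    g: GenotypeMatrix, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-locus presence frequency within each population group.

    ``groups`` maps every sample id to a population label. Returns a frame
    indexed like ``g.loci`` with one frequency column per population plus an
    ``n_<pop>`` column of non-missing call counts. A group with zero
    non-missing calls at a locus gets NaN.
    """
    unmapped = [s for s in g.samples if s not in groups]
    if unmapped:
        raise ValueError(f"samples missing from group map: {unmapped[:5]}")
    labels = np.array([groups[s] for s in g.samples])
    out = g.loci[["id", "chrom", "pos"]].copy()
    for pop in pd.unique(labels):
        cols = labels == pop
        sub = g.calls[:, cols]
        n_obs = np.sum(~np.isnan(sub), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[pop] = np.nanmean(sub, axis=1)
        out[f"n_{pop}"] = n_obs
    return out


def classify_population_specificity(
    freqs: pd.DataFrame,
    pop_a: str,
    pop_b: str,
    maf_threshold: float = EQTL_MIN_MAF,
) -> pd.Series:
    """Label each locus by how its presence is shared between two populations.

    - ``popA_specific`` / ``popB_specific``: above-threshold frequency in one
      population and complete absence (frequency 0) in the other — the
      strict, "truly specific" definition.
    - ``popA_private`` / ``popB_private``: the looser definition, where the
      other population is at or below ``maf_threshold`` but not necessarily 0.
    - ``shared``: above threshold in both.
    - ``rare_both``: at or below threshold in both.
    """
    fa = freqs[pop_a].to_numpy(dtype=float)
    fb = freqs[pop_b].to_numpy(dtype=float)
    labels = np.full(len(freqs), "rare_both", dtype=object)
    labels[(fa > maf_threshold) & (fb > maf_threshold)] = "shared"
    labels[(fa > maf_threshold) & (fb <= maf_threshold)] = f"{pop_a}_private"
    labels[(fb > maf_threshold) & (fa <= maf_threshold)] = f"{pop_b}_private"
    labels[(fa > maf_threshold) & (fb == 0.0)] = f"{pop_a}_specific"
    labels[(fb > maf_threshold) & (fa == 0.0)] = f"{pop_b}_specific"
    return pd.Series(labels, index=freqs.index, name="specificity")


def cross_population_frequency_table(
    freqs: pd.DataFrame,
    pop_a: str,
    pop_b: str,
    eqtl_flags: np.ndarray,
    bin_width: float = 0.05,
    equal_tol: float = 0.1,
) -> dict:
    """Joint frequency distribution of loci in two populations, split by
    eQTL status.

    Returns, per class (``eqtl`` / ``non_eqtl``), the (freq_A, freq_B) pairs,
    a 2D histogram with ``bin_width`` bins over [0, 1], and the fraction of
    loci whose frequencies agree to within ``equal_tol``.
    """
    flags = np.asarray(eqtl_flags, dtype=bool)
    if flags.shape[0] != len(freqs):
        raise ValueError("eqtl_flags length does not match frequency table")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    edges[-1] = 1.0 + 1e-12  # close the top bin
    out: dict[str, dict] = {"bin_edges": np.minimum(edges, 1.0)}
    fa = freqs[pop_a].to_numpy(dtype=float)
    fb = freqs[pop_b].to_numpy(dtype=float)
    for name, mask in (("eqtl", flags), ("non_eqtl", ~flags)):
        a, b = fa[mask], fb[mask]
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        hist, _, _ = np.histogram2d(a, b, bins=[edges, edges])
        equal_frac = float(np.mean(np.abs(a - b) <= equal_tol)) if a.size else np.nan
        out[name] = {
            "pairs": np.column_stack([a, b]),
            "hist": hist,
            "equal_frequency_fraction": equal_frac,
        }
    return out
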