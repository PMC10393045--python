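"""cis-eQTL mapping of TIP and SNP markers against gene expression.

Each (replicate x condition x population x marker-type) expression matrix
is scanned independently: genes are filtered for expression, counts are
normalized by median-of-ratios size factors followed by log2(x + 1), every
marker within 5 kb of a gene body is tested with an ordinary least squares
model that includes subpopulation dummies as covariates, and p-values are
Benjamini-Hochberg adjusted over all tested cis pairs of the scan. Hits are
then consolidated across replicates: a pair is significant if adjusted
p < 0.05 in at least one replicate.

The normalization is a documented stand-in for a variance-stabilizing
transform: size factors are DESeq-style medians of ratios to a geometric
reference, and the association model is invariant under any monotone
variance-stabilizing choice at the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    CIS_WINDOW_BP,
    FDR_THRESHOLD,
    MIN_EXPRESSED_FRAC,
    RELAXED_P,
)
from .tip_matrix import GenotypeMatrix


# ---------------------------------------------------------------------------
# expression preprocessing

def filter_expressed_genes(
    counts: pd.DataFrame, min_sample_frac: float = MIN_EXPRESSED_FRAC
) -> pd.DataFrame:
    """Keep genes with a nonzero count in strictly more than
    ``min_sample_frac`` of samples."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    frac = (counts > 0).mean(axis=1)
    return counts.loc[frac > min_sample_frac]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean reference.

    Only genes with all-positive counts define the reference. If there are
    none, falls back to library-size factors with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if allpos.any():
        logref = np.log(mat[allpos]).mean(axis=1)
        sf = np.exp(np.median(np.log(mat[allpos]) - logref[:, None], axis=0))
    else:
        warnings.warn(
            "no gene with all-positive counts; using library-size factors",
            stacklevel=2,
        )
        lib = mat.sum(axis=0)
        sf = lib / lib.mean()
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Size-factor normalization followed by log2(x + 1)."""
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    sf = size_factors(counts)
    return np.log2(counts / sf + 1.0)


# ---------------------------------------------------------------------------
# cis pair enumeration

def enumerate_cis_pairs(
    genes: pd.DataFrame,
    markers: pd.DataFrame,
    window: int = CIS_WINDOW_BP,
) -> pd.DataFrame:
    """All (gene, marker) pairs with the marker within ``window`` bp of the
    gene body.

    ``genes`` needs columns id, chrom, start, end (0-based half-open) and
    optionally strand; ``markers`` needs id, chrom, pos. Distance is 0
    inside the gene body; otherwise it is the bp gap to the nearest gene
    base (p - start upstream of the left edge, p - end + 1 past the last
    base), signed negative upstream of the 5' end (strand-aware;
    '.'-strand genes are treated as '+'). A pair is included iff
    |gap| < window — a marker exactly ``window`` bp away is excluded.
    """
    out = []
    strand = genes["strand"] if "strand" in genes else pd.Series("+", index=genes.index)
    mby_chrom = {c: g.sort_values("pos") for c, g in markers.groupby("chrom")}
    for (_, gene), strd in zip(genes.iterrows(), strand):
        sub = mby_chrom.get(gene["chrom"])
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, gene["start"] - window, side="right")
        hi = np.searchsorted(pos, gene["end"] + window - 1, side="left")
        for mid, p in zip(sub["id"].to_numpy()[lo:hi], pos[lo:hi]):
            if p < gene["start"]:
                dist = p - gene["start"]  # negative gap to the left edge
            elif p >= gene["end"]:
                dist = p - gene["end"] + 1  # bp past the last gene base
            else:
                dist = 0
            if strd == "-":
                dist = -dist  # 5' end of a minus-strand gene is the right edge
            out.append((gene["id"], mid, int(dist)))
    return pd.DataFrame(out, columns=["gene", "marker", "distance"])


# ---------------------------------------------------------------------------
# association model

def _covariate_matrix(subpop: pd.Series) -> np.ndarray:
    """Intercept plus treatment dummies with the largest group as reference;
    redundant (empty or collinear) dummies are dropped with a warning."""
    counts = subpop.value_counts()
    ref = counts.index[0]
    levels = [lv for lv in counts.index if lv != ref]
    cols = [np.ones(len(subpop))]
    cols += [(subpop == lv).to_numpy(float) for lv in levels]
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        warnings.warn("collinear covariates; dropping redundant dummies",
                      stacklevel=2)
        q, r = np.linalg.qr(x)
        keep = np.abs(np.diag(r)) > 1e-10
        x = x[:, keep]
    return x


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of (columns of) y after OLS projection on x."""
    q, _ = np.linalg.qr(x)
    return y - q @ (q.T @ y)


def fit_linear_association(
    y: np.ndarray, g: np.ndarray, covariates: np.ndarray | None = None
) -> dict:
    """OLS of expression y on marker g with optional covariate columns.

    The model is y ~ 1 + covariates + g; returns the marker coefficient
    beta, its standard error, t statistic, two-sided p-value and the
    squared partial correlation of g with y given the covariates (marginal
    variance explained after covariates).

    Implemented by residualizing both y and g on the covariates (with
    intercept) and regressing residual on residual, which is algebraically
    identical to the full OLS fit for the marker coefficient.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = y.size
    if covariates is None:
        x = np.ones((n, 1))
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if not np.any(np.ptp(x, axis=0) == 0):  # no constant column yet
            x = np.column_stack([np.ones(n), x])
    k = np.linalg.matrix_rank(x)
    if np.ptp(g) == 0:
        raise ValueError("marker genotype is constant; cannot fit association")
    if n < k + 3:
        raise ValueError("too few samples for the design")
    ry = _residualize(y, x)
    rg = _residualize(g, x)
    gg = float(rg @ rg)
    beta = float(rg @ ry) / gg
    df = n - k - 1
    rss = float(ry @ ry) - beta * float(rg @ ry)
    se = np.sqrt(max(rss, 0.0) / df / gg)
    if se == 0:
        t = np.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
        r2 = 1.0 if beta != 0 else 0.0
    else:
        t = beta / se
        p = 2.0 * stats.t.sf(abs(t), df)
        r2 = t * t / (t * t + df)
    return {"beta": beta, "se": float(se), "t": float(t), "p": float(p),
            "r2": float(r2), "df": int(df)}


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (with the usual
    running-minimum monotonicity enforcement)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# scans

def _scan_one_matrix(
    norm: pd.DataFrame,
    geno: np.ndarray,
    marker_index: dict[str, int],
    pairs: pd.DataFrame,
    covariates: np.ndarray,
) -> pd.DataFrame:
    """Vectorized OLS over all cis pairs of one replicate matrix.

    Residualizes the expression matrix and the genotype matrix on the
    covariates once, then computes all marker coefficients with dot
    products; numerically identical to per-pair fit_linear_association.
    """
    n = norm.shape[1]
    k = np.linalg.matrix_rank(covariates)
    df = n - k - 1
    ry = _residualize(norm.to_numpy(dtype=float).T, covariates)  # n x genes
    rg = _residualize(geno.T.astype(float), covariates)  # n x markers
    gene_index = {gid: i for i, gid in enumerate(norm.index)}
    gi = pairs["gene"].map(gene_index).to_numpy()
    mi = pairs["marker"].map(marker_index).to_numpy()
    gg = np.einsum("ij,ij->j", rg, rg)
    yy = np.einsum("ij,ij->j", ry, ry)
    gy = np.einsum("ij,ij->i", rg[:, mi].T, ry[:, gi].T)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg[mi]
        rss = yy[gi] - beta * gy
        se = np.sqrt(np.maximum(rss, 0.0) / df / gg[mi])
        t = np.where(se > 0, beta / se, np.where(beta != 0, np.inf, 0.0))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        r2 = t * t / (t * t + df)
    out = pairs.copy()
    out["beta"] = beta
    out["se"] = se
    out["t"] = t
    out["p"] = p
    out["r2"] = np.where(np.isinf(t), 1.0, r2)
    out["q"] = bh_adjust(p)
    return out


def run_eqtl_scan(
    counts: pd.DataFrame,
    markers: GenotypeMatrix,
    metadata: pd.DataFrame,
    genes: pd.DataFrame,
    population: str,
    marker_type: str = "TIP",
    window: int = CIS_WINDOW_BP,
    min_sample_frac: float = MIN_EXPRESSED_FRAC,
) -> pd.DataFrame:
    """cis-eQTL scan for one population over every condition x replicate.

    ``counts`` is genes x libraries (library ids in metadata); ``metadata``
    needs columns sample (library id), accession, population, subpopulation,
    condition, replicate. Markers are indexed by accession. Each replicate
    matrix is independently expression-filtered, normalized, fitted and
    BH-adjusted over all its cis pairs. Returns the concatenated
    association table.
    """
    meta = metadata.loc[metadata["population"] == population]
    if meta.empty:
        raise ValueError(f"no samples for population {population!r}")
    missing = set(meta["sample"]) - set(counts.columns)
    if missing:
        raise ValueError(f"libraries absent from counts: {sorted(missing)[:5]}")
    acc_index = {a: i for i, a in enumerate(markers.samples)}
    unknown = set(meta["accession"]) - set(acc_index)
    if unknown:
        raise ValueError(f"accessions absent from markers: {sorted(unknown)[:5]}")
    if np.isnan(markers.calls).any():
        raise ValueError("markers must be imputed (no missing calls)")

    pairs_all = enumerate_cis_pairs(genes, markers.loci, window)
    results = []
    for (condition, replicate), grp in meta.groupby(["condition", "replicate"]):
        sub = counts[grp["sample"].tolist()]
        expressed = filter_expressed_genes(sub, min_sample_frac)
        if expressed.empty:
            continue
        norm = normalize_counts(expressed)
        cols = [acc_index[a] for a in grp["accession"]]
        geno = markers.calls[:, cols]
        # drop markers constant within this population subset
        variable = np.ptp(geno, axis=1) > 0
        marker_ids = set(np.asarray(markers.loci["id"])[variable])
        pairs = pairs_all[
            pairs_all["gene"].isin(set(expressed.index))
            & pairs_all["marker"].isin(marker_ids)
        ].reset_index(drop=True)
        if pairs.empty:
            continue
        covars = _covariate_matrix(grp["subpopulation"].reset_index(drop=True))
        marker_index = {mid: i for i, mid in enumerate(markers.loci["id"])}
        res = _scan_one_matrix(norm, geno, marker_index, pairs, covars)
        res["condition"] = condition
        res["replicate"] = replicate
        res["population"] = population
        res["marker_type"] = marker_type
        results.append(res)
    if not results:
        return pd.DataFrame(
            columns=["gene", "marker", "distance", "beta", "se", "t", "p",
                     "r2", "q", "condition", "replicate", "population",
                     "marker_type"]
        )
    return pd.concat(results, ignore_index=True)


def consolidate_replicates(
    results: pd.DataFrame, fdr: float = FDR_THRESHOLD
) -> pd.DataFrame:
    """Collapse per-replicate associations to per-(gene, marker, condition,
    population) hits.

    A pair is a hit iff q < ``fdr`` in at least one replicate. The reported
    beta/r2/sign come from the best (smallest-q) replicate; sign conflicts
    among significant replicates are flagged. ``leading`` marks, per
    (gene, condition, population), the marker with the smallest min-q, ties
    broken by smaller |distance| then leftmost marker id.
    """
    if results.empty:
        return pd.DataFrame(
            columns=["gene", "marker", "condition", "population", "marker_type",
                     "min_q", "p_best", "beta", "r2", "sign", "distance",
                     "sign_conflict", "leading"]
        )
    rows = []
    keys = ["gene", "marker", "condition", "population"]
    for key, grp in results.groupby(keys, sort=True):
        min_q = grp["q"].min()
        if min_q >= fdr:
            continue
        best = grp.loc[grp["q"].idxmin()]
        sig = grp[grp["q"] < fdr]
        signs = set(np.sign(sig["beta"]))
        rows.append(dict(zip(keys, key)) | {
            "marker_type": best["marker_type"],
            "min_q": float(min_q),
            "p_best": float(best["p"]),
            "beta": float(best["beta"]),
            "r2": float(best["r2"]),
            "sign": int(np.sign(best["beta"])),
            "distance": int(best["distance"]),
            "sign_conflict": len(signs) > 1,
        })
    hits = pd.DataFrame(rows)
    if hits.empty:
        hits["leading"] = []
        return hits
    hits["abs_dist"] = hits["distance"].abs()
    hits = hits.sort_values(
        ["gene", "condition", "population", "min_q", "abs_dist", "marker"]
    ).reset_index(drop=True)
    hits["leading"] = ~hits.duplicated(["gene", "condition", "population"])
    return hits.drop(columns="abs_dist")


def compare_variance_explained(
    tip_hits: pd.DataFrame, snp_hits: pd.DataFrame
) -> pd.DataFrame:
    """Per gene with a TIP hit, compare variance explained by the leading
    TIP against the leading significant SNP.

    Categories: TIP_only (no significant SNP for the gene), TIP_gt_SNP
    (leading TIP r2 strictly greater), SNP_ge_TIP otherwise.
    """
    tip_lead = tip_hits[tip_hits["leading"]]
    snp_best = (
        snp_hits.groupby("gene")["r2"].max() if not snp_hits.empty else pd.Series(dtype=float)
    )
    rows = []
    for _, h in tip_lead.iterrows():
        snp_r2 = snp_best.get(h["gene"], np.nan)
        if np.isnan(snp_r2):
            cat = "TIP_only"
        elif h["r2"] > snp_r2:
            cat = "TIP_gt_SNP"
        else:
            cat = "SNP_ge_TIP"
        rows.append({"gene": h["gene"], "condition": h["condition"],
                     "population": h["population"], "tip_r2": h["r2"],
                     "snp_r2": snp_r2, "category": cat})
    return pd.DataFrame(rows)


def shared_associations(
    hits_a: pd.DataFrame,
    full_results_b: pd.DataFrame,
    relaxed_p: float = RELAXED_P,
) -> pd.DataFrame:
    """Which hits of scan A replicate in scan B at a relaxed cutoff?

    A hit (gene, marker) of A is shared iff the same pair reaches
    unadjusted p < ``relaxed_p`` with the same effect sign in any replicate
    of B. Returns the hits of A with a ``shared`` flag; the ``shared``
    fraction and sign-concordance count are attributes ``.attrs``.
    """
    out = hits_a.copy()
    shared_flags = []
    for _, h in hits_a.iterrows():
        b = full_results_b[
            (full_results_b["gene"] == h["gene"])
            & (full_results_b["marker"] == h["marker"])
        ]
        ok = b[(b["p"] < relaxed_p) & (np.sign(b["beta"]) == h["sign"])]
        shared_flags.append(len(ok) > 0)
    out["shared"] = shared_flags
    out.attrs["shared_fraction"] = float(np.mean(shared_flags)) if shared_flags else np.nan
    out.attrs["n_shared"] = int(np.sum(shared_flags))
    return out


def effect_size_frequency_profile(
    hits: pd.DataFrame,
    frequencies: pd.Series,
    bin_width: float = 0.05,
) -> pd.DataFrame:
    """Mean effect size per population-frequency bin, split by effect sign.

    Bins are [0, 0.05), ..., [0.95, 1.0]; empty bins are reported with
    count 0.
    """
    missing = set(hits["marker"]) - set(frequencies.index)
    if missing:
        raise ValueError(f"no frequency for markers: {sorted(missing)[:5]}")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    freq = hits["marker"].map(frequencies).to_numpy(dtype=float)
    idx = np.clip(np.digitize(freq, edges) - 1, 0, len(edges) - 2)
    beta = hits["beta"].to_numpy(dtype=float)
    rows = []
    for sign, mask in (("positive", beta > 0), ("negative", beta < 0)):
        for b in range(len(edges) - 1):
            sel = mask & (idx == b)
            rows.append({
                "sign": sign,
                "bin_low": edges[b],
                "bin_high": min(edges[b + 1], 1.0),
                "n": int(sel.sum()),
                "mean_beta": float(beta[sel].mean()) if sel.any() else np.nan,
            })
    return pd.DataFrame(rows)
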