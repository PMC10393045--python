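"""Score predicted TIP calls against an annotated truth set.

A prediction is a true positive when a truth insertion of the same TE
family lies within a positional tolerance (default 100 bp, abstracting
assembly-orthology matching as coordinate proximity plus family identity).
Matching is greedy nearest-first and one-to-one, so counts are conserved:
TP + FN equals the number of truth insertions and TP + FP the number of
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import BENCHMARK_TOLERANCE_BP


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    sensitivity: float  # TP / (TP + FN), NaN if undefined
    precision: float  # TP / (TP + FP), NaN if undefined
    per_family: pd.DataFrame


def match_predictions(
    predicted: pd.DataFrame,
    truth: pd.DataFrame,
    tolerance_bp: int = BENCHMARK_TOLERANCE_BP,
) -> pd.DataFrame:
    """Label each prediction TP/FP and each unmatched truth record FN.

    Both frames need columns chrom, pos, te_family. Within each
    (chrom, family) stratum, candidate pairs within ``tolerance_bp`` are
    assigned greedily by increasing distance; every truth record matches at
    most one prediction. Returns a long table with columns
    label ∈ {TP, FP, FN}, chrom, pos, te_family.
    """
    pred = predicted.reset_index(drop=True)
    tru = truth.reset_index(drop=True)
    matched_pred: set[int] = set()
    matched_truth: set[int] = set()
    for (chrom, fam), p_grp in pred.groupby(["chrom", "te_family"], sort=False):
        t_grp = tru[(tru["chrom"] == chrom) & (tru["te_family"] == fam)]
        if t_grp.empty:
            continue
        cand = [
            (abs(int(pp) - int(tp)), pi, ti)
            for pi, pp in zip(p_grp.index, p_grp["pos"])
            for ti, tp in zip(t_grp.index, t_grp["pos"])
            if abs(int(pp) - int(tp)) <= tolerance_bp
        ]
        for _, pi, ti in sorted(cand):
            if pi in matched_pred or ti in matched_truth:
                continue
            matched_pred.add(pi)
            matched_truth.add(ti)
    rows = []
    for pi, row in pred.iterrows():
        rows.append({
            "label": "TP" if pi in matched_pred else "FP",
            "chrom": row["chrom"], "pos": row["pos"],
            "te_family": row["te_family"],
        })
    for ti, row in tru.iterrows():
        if ti not in matched_truth:
            rows.append({
                "label": "FN",
                "chrom": row["chrom"], "pos": row["pos"],
                "te_family": row["te_family"],
            })
    return pd.DataFrame(rows, columns=["label", "chrom", "pos", "te_family"])


def score(matches: pd.DataFrame) -> BenchmarkResult:
    """Sensitivity = TP/(TP+FN) and precision = TP/(TP+FP), globally and per
    TE family; undefined ratios are NaN."""

    def _summarize(sub: pd.DataFrame) -> tuple[int, int, int, float, float]:
        tp = int((sub["label"] == "TP").sum())
        fp = int((sub["label"] == "FP").sum())
        fn = int((sub["label"] == "FN").sum())
        sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
        prec = tp / (tp + fp) if tp + fp > 0 else float("nan")
        return tp, fp, fn, sens, prec

    tp, fp, fn, sens, prec = _summarize(matches)
    fam_rows = []
    for fam, sub in matches.groupby("te_family", sort=True):
        f_tp, f_fp, f_fn, f_sens, f_prec = _summarize(sub)
        fam_rows.append({
            "te_family": fam, "tp": f_tp, "fp": f_fp, "fn": f_fn,
            "sensitivity": f_sens, "precision": f_prec,
        })
    return BenchmarkResult(
        tp=tp, fp=fp, fn=fn, sensitivity=sens, precision=prec,
        per_family=pd.DataFrame(fam_rows),
    )
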