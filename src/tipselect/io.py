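"""Readers and writers for the pipeline's on-disk formats.

Internal coordinates are 0-based half-open everywhere (BED-native); the
1-based conventions of VCF and GFF3 are converted exactly once, at the file
boundary, by :func:`to_internal_pos` / :func:`to_vcf_pos`. All tabular
writers emit a header line and readers reject files whose header disagrees
with the expected schema. Missing values are written as "NA".
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .tip_matrix import LOCUS_COLUMNS, GenotypeMatrix, ZygosityMatrix

_FLOAT_FMT = "%.6g"


def to_internal_pos(pos_1based: int) -> int:
    """1-based (VCF/GFF) -> 0-based internal position."""
    return pos_1based - 1


def to_vcf_pos(pos_0based: int) -> int:
    """0-based internal -> 1-based VCF/GFF position."""
    return pos_0based + 1


def _check_header(found: list[str], expected: list[str], path) -> None:
    if list(found[: len(expected)]) != expected:
        raise ValueError(
            f"{path}: header {found[:len(expected)]} does not match expected "
            f"{expected}"
        )


# ---------------------------------------------------------------------------
# marker matrices (TSV)

def write_marker_tsv(m: ZygosityMatrix | GenotypeMatrix, path) -> None:
    """First five columns id, chrom, pos, te_family, te_order; then one
    column per sample. Missing cells are NA."""
    values = m.values if isinstance(m, ZygosityMatrix) else m.calls
    frame = pd.concat(
        [m.loci[LOCUS_COLUMNS].reset_index(drop=True),
         pd.DataFrame(values, columns=m.samples)],
        axis=1,
    )
    frame.to_csv(path, sep="\t", index=False, na_rep="NA",
                 float_format=_FLOAT_FMT)


def _read_marker_frame(path) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    _check_header(list(frame.columns), LOCUS_COLUMNS, path)
    samples = list(frame.columns[len(LOCUS_COLUMNS):])
    values = frame[samples].to_numpy(dtype=float)
    return frame[LOCUS_COLUMNS], samples, values


def read_zygosity_tsv(path) -> ZygosityMatrix:
    loci, samples, values = _read_marker_frame(path)
    return ZygosityMatrix(loci, samples, values)


def read_genotype_tsv(path) -> GenotypeMatrix:
    loci, samples, values = _read_marker_frame(path)
    return GenotypeMatrix(loci, samples, values)


def write_loci_bed(loci: pd.DataFrame, path) -> None:
    """Single-base BED intervals (0-based half-open) for marker loci."""
    bed = pd.DataFrame({
        "chrom": loci["chrom"],
        "start": loci["pos"],
        "end": loci["pos"] + 1,
        "name": loci["id"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# VCF

def write_vcf(g: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 with haploid GT calls (0 = reference, 1 = alt)."""
    loci = g.loci
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for i in range(g.n_loci):
            calls = g.calls[i]
            gt = ["." if np.isnan(c) else str(int(c)) for c in calls]
            fh.write(
                f"{loci['chrom'].iat[i]}\t{to_vcf_pos(int(loci['pos'].iat[i]))}\t"
                f"{loci['id'].iat[i]}\tA\tT\t.\t.\t.\tGT\t" + "\t".join(gt) + "\n"
            )


def read_vcf_snps(path, het_policy: str = "error") -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a binary presence matrix.

    Haploid calls and homozygous diploid calls collapse to 0/1.
    Heterozygous calls are rejected with a count report unless
    ``het_policy`` is "drop-site" (skip the record) or "drop-call" (set the
    call missing). Multiallelic records are skipped with a warning.
    Positions are converted to the internal 0-based convention.
    """
    if het_policy not in ("error", "drop-site", "drop-call"):
        raise ValueError(f"unknown het policy {het_policy!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, positions, rows = [], [], [], []
    n_het_sites = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(
                f"skipping multiallelic record at {rec.CHROM}:{rec.POS}",
                stacklevel=2,
            )
            continue
        calls = np.full(len(samples), np.nan)
        het = np.zeros(len(samples), dtype=bool)
        for j, gt in enumerate(rec.genotypes):
            alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            if not alleles:
                continue
            uniq = set(alleles)
            if len(uniq) > 1:
                het[j] = True
            else:
                calls[j] = float(uniq.pop() > 0)
        if het.any():
            n_het_sites += 1
            if het_policy == "error":
                raise ValueError(
                    f"heterozygous call(s) at {rec.CHROM}:{rec.POS} in "
                    f"{int(het.sum())} sample(s); pass het_policy="
                    "'drop-site' or 'drop-call' to proceed"
                )
            if het_policy == "drop-site":
                continue
            # drop-call: het genotypes stay NaN
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}_{rec.POS}")
        chroms.append(rec.CHROM)
        positions.append(to_internal_pos(rec.POS))
        rows.append(calls)
    if n_het_sites and het_policy != "error":
        warnings.warn(
            f"{n_het_sites} site(s) contained heterozygous calls "
            f"(policy {het_policy})",
            stacklevel=2,
        )
    loci = pd.DataFrame({
        "id": ids, "chrom": chroms, "pos": positions,
        "te_family": "SNP", "te_order": "SNP",
    })
    calls = np.array(rows) if rows else np.empty((0, len(samples)))
    return GenotypeMatrix(loci, samples, calls)


# ---------------------------------------------------------------------------
# GFF3

def write_gff_genes(genes: pd.DataFrame, path) -> None:
    """Write gene models as GFF3 'gene' features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['chrom']}\ttipselect\tgene\t{to_vcf_pos(int(g['start']))}\t"
                f"{int(g['end'])}\t.\t{g.get('strand', '.')}\t.\tID={g['id']}\n"
            )


def read_gff_genes(path) -> pd.DataFrame:
    """Gene models from GFF3 feature type 'gene' with an ID attribute.

    Coordinates convert from 1-based inclusive to 0-based half-open.
    Records without an ID are skipped with a warning; duplicate IDs are an
    error.
    """
    empty = pd.DataFrame(columns=["id", "chrom", "start", "end", "strand"])
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return empty
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [None])[0]
        if gid is None:
            warnings.warn(
                f"gene record without ID at {feat.seqid}:{feat.start} skipped",
                stacklevel=2,
            )
            continue
        rows.append({
            "id": gid,
            "chrom": feat.seqid,
            "start": to_internal_pos(feat.start),
            "end": feat.end,  # GFF inclusive end == half-open end
            "strand": feat.strand if feat.strand in "+-" else ".",
        })
    genes = pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand"])
    if genes["id"].duplicated().any():
        dupes = genes.loc[genes["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate gene IDs in {path}: {dupes[:5]}")
    return genes


# ---------------------------------------------------------------------------
# counts / metadata / truth

COUNTS_INDEX = "gene"
METADATA_COLUMNS = ["sample", "accession", "population", "subpopulation",
                    "condition", "replicate"]


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.rename_axis(COUNTS_INDEX).to_csv(path, sep="\t")


def read_counts_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    _check_header(list(frame.columns[:1]), [COUNTS_INDEX], path)
    return frame.set_index(COUNTS_INDEX)


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    _check_header(list(frame.columns), METADATA_COLUMNS, path)
    return frame


def write_truth_tables(truth, outdir) -> None:
    outdir = Path(outdir)
    truth.planted_eqtls.to_csv(outdir / "truth_eqtls.tsv", sep="\t", index=False)
    truth.selected_tips.to_csv(outdir / "truth_selected.tsv", sep="\t", index=False)
    truth.sweep_loci.to_csv(outdir / "truth_sweeps.tsv", sep="\t", index=False)
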