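"""Flat-file I/O for the pipeline's tabular formats.

Everything is plain TSV: expression matrices (first column gene_id,
remaining columns cells, values TPM), per-cell QC tables, pileup base
counts, copy-number segments, genotype matrices (0/1/NA) and SNV calls
(also exportable as a minimal VCF).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_expression", "write_expression",
    "read_qc", "read_pileup", "write_pileup",
    "read_segments", "read_genotype_matrix", "write_genotype_matrix",
    "write_calls_vcf",
]


def read_expression(path) -> pd.DataFrame:
    """Gene x cell TPM matrix from TSV (first column gene_id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_qc(path) -> pd.DataFrame:
    """Per-cell QC metrics indexed by cell_id."""
    return pd.read_csv(path, sep="\t", index_col="cell_id")


def read_pileup(path) -> pd.DataFrame:
    """Pileup TSV: chrom, pos (1-based), ref, count per base, depth."""
    df = pd.read_csv(path, sep="\t")
    rename = {f"count_{b}": b for b in "ACGT" if f"count_{b}" in df.columns}
    return df.rename(columns=rename)


def write_pileup(pileup: pd.DataFrame, path) -> None:
    out = pileup.rename(columns={b: f"count_{b}" for b in "ACGT"})
    out.to_csv(path, sep="\t", index=False)


def read_segments(path, zero_based_half_open: bool = False) -> pd.DataFrame:
    """Copy-number segments: chrom, start, end, log2_ratio.

    Coordinates are 1-based inclusive by default; pass
    ``zero_based_half_open=True`` for BED-dialect input (converted on
    read).
    """
    seg = pd.read_csv(path, sep="\t")
    if zero_based_half_open:
        seg = seg.assign(start=seg["start"] + 1)
    return seg


def read_genotype_matrix(path) -> pd.DataFrame:
    """Cells x sites matrix with values 0/1/NA."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_genotype_matrix(data: pd.DataFrame, path) -> None:
    data.to_csv(path, sep="\t", index_label="cell_id", na_rep="NA")


def write_calls_vcf(calls: pd.DataFrame, path) -> None:
    """Minimal VCF export of single-cell SNV calls.

    INFO carries VAF, VC (variant count) and CHI2 (Yates statistic).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,'
                 'Description="Variant allele frequency">\n')
        fh.write('##INFO=<ID=VC,Number=1,Type=Integer,'
                 'Description="Variant read count">\n')
        fh.write('##INFO=<ID=CHI2,Number=1,Type=Float,'
                 'Description="Yates-corrected chi-square statistic">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in calls.itertuples(index=False):
            info = (f"VAF={row.vaf:.4f};VC={row.variant_count};"
                    f"CHI2={row.chi2_yates:.3f}")
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t{info}\n")
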