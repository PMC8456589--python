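"""Cell/gene quality filtering of TPM matrices and replicate variability.

Single-cell RNA libraries are dropped when they look like doublets or
failed captures: an excessive number of genes expressed at TPM >= 10, too
few uniquely mapped reads, or a too-low unique-mapping rate.  Genes are
kept only when expressed at or above a TPM threshold in at least one
retained cell.  Replicate variability of expression levels is estimated by
a read-resampling bootstrap: the cell's per-gene read counts are
multinomially resampled at the observed library size and the relative
error of log2(TPM+1) is averaged over expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QcThresholds",
    "filter_cells",
    "filter_genes",
    "bootstrap_expression_error",
]


@dataclass
class QcThresholds:
    """Cell/gene QC thresholds.

    max_genes_tpm10
        Cells with at least this many genes at TPM >= 10 are removed
        (suspected doublet / amplification artefact; default 5200).
    min_unique_reads
        Minimum uniquely mapped reads per cell (default 2.2e6).
    min_mapping_rate
        Minimum unique-mapping rate (default 0.20).
    gene_keep_tpm
        A gene is kept when its TPM reaches this value in at least one
        retained cell (default 10).
    """

    max_genes_tpm10: int = 5200
    min_unique_reads: float = 2.2e6
    min_mapping_rate: float = 0.20
    gene_keep_tpm: float = 10.0

    def __post_init__(self) -> None:
        if min(self.max_genes_tpm10, self.min_unique_reads,
               self.min_mapping_rate, self.gene_keep_tpm) <= 0:
            raise ValueError("all thresholds must be positive")


def filter_cells(matrix: pd.DataFrame, qc: pd.DataFrame,
                 thr: QcThresholds | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove low-quality cells from a gene x cell TPM matrix.

    Parameters
    ----------
    matrix
        Genes x cells TPM.
    qc
        Per-cell metrics indexed by cell id with columns
        ``unique_mapped_reads, unique_mapping_rate`` and optionally
        ``n_genes_tpm_ge_10`` (computed from the matrix when absent).
    thr
        :class:`QcThresholds`.

    Returns
    -------
    (filtered matrix, removal report with one row per removed cell and the
    triggering rule(s))
    """
    thr = thr or QcThresholds()
    missing = [c for c in matrix.columns if c not in qc.index]
    if missing:
        raise ValueError(f"cells missing a QC record: {missing}")
    qc = qc.loc[list(matrix.columns)]
    if "n_genes_tpm_ge_10" in qc.columns:
        n_genes10 = qc["n_genes_tpm_ge_10"]
    else:
        n_genes10 = (matrix >= 10).sum(axis=0)

    removed = []
    for cell in matrix.columns:
        rules = []
        if n_genes10[cell] >= thr.max_genes_tpm10:
            rules.append(f"n_genes_tpm_ge_10 >= {thr.max_genes_tpm10}")
        if qc.at[cell, "unique_mapped_reads"] < thr.min_unique_reads:
            rules.append(f"unique_mapped_reads < {thr.min_unique_reads:g}")
        if qc.at[cell, "unique_mapping_rate"] < thr.min_mapping_rate:
            rules.append(f"unique_mapping_rate < {thr.min_mapping_rate:g}")
        if rules:
            removed.append((cell, "; ".join(rules)))
    report = pd.DataFrame(removed, columns=["cell", "rule"])
    kept = [c for c in matrix.columns if c not in set(report["cell"])]
    return matrix[kept], report


def filter_genes(matrix: pd.DataFrame,
                 thr: QcThresholds | None = None) -> pd.DataFrame:
    """Keep genes with TPM >= ``gene_keep_tpm`` in at least one cell."""
    thr = thr or QcThresholds()
    if matrix.empty:
        raise ValueError("expression matrix is empty")
    keep = (matrix >= thr.gene_keep_tpm).any(axis=1)
    return matrix.loc[keep]


def bootstrap_expression_error(counts, n_replicates: int = 3,
                               seed: int | None = None) -> float:
    """Mean relative error of log2(TPM+1) under read resampling.

    The cell's total read count is resampled multinomially over genes
    ``n_replicates`` times; for each replicate the relative error
    ``|boot - obs| / obs`` of log2(TPM+1) is averaged over genes with a
    non-zero observed value, then averaged over replicates.  Counts are
    taken as already length-normalised, so TPM is proportional to
    count / total.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("counts must be a non-empty 1-D array")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    rng = np.random.default_rng(seed)
    obs_tpm = x / total * 1e6
    obs = np.log2(obs_tpm + 1.0)
    expressed = obs > 0
    errs = np.empty(n_replicates)
    p = x / total
    for r in range(n_replicates):
        boot = rng.multinomial(int(round(total)), p).astype(float)
        boot_log = np.log2(boot / boot.sum() * 1e6 + 1.0)
        rel = np.abs(boot_log[expressed] - obs[expressed]) / obs[expressed]
        errs[r] = rel.mean()
    return float(errs.mean())
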