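"""Transcriptional heterogeneity: variable-gene detection, clustering,
PCA embedding and the RNA diversity index.

Highly variable genes (HVGs) are detected by the *corrected* coefficient
of variation (cCV).  The raw CV of log2(TPM+1) is strongly
mean-dependent, so within three mean-expression ranges a LOWESS curve of
CV against mean expression is fitted together with a local residual-SD
curve; the upper variability band is ``fit + z * local_sd`` and
``cCV = CV / band``.  A gene is highly variable when its cCV exceeds a
threshold (default 1.3) at high mean expression (default
log2(TPM+1) >= 4).

The RNA diversity index of a cell group is the per-cell Euclidean
distance from the group centroid in the full-dimensional PCA space,
summarised by the median and compared between groups with the two-sided
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "HvgParams",
    "log_expression",
    "corrected_cv",
    "select_hvg",
    "GeneVariabilityModel",
    "GeneVariabilityResults",
    "cluster_cells",
    "cluster_genes",
    "pca_embed",
    "rna_diversity",
    "RnaDiversityModel",
    "RnaDiversityResults",
]


@dataclass
class HvgParams:
    """Parameters of corrected-CV variable-gene detection.

    range_breaks
        Mean-expression breakpoints (log2 units) splitting genes into
        three independently smoothed ranges: below the first break,
        between the breaks, and at or above the second (default [4, 8.5];
        left-closed on the upper side, so a gene exactly at a break falls
        in the higher range).
    band_z
        Multiplier of the local residual SD forming the upper variability
        band (default 1.96).
    ccv_threshold
        Strict lower bound on cCV for HVG status (default 1.3).
    mean_threshold
        Minimum mean log2(TPM+1) for HVG status (default 4).
    lowess_span
        LOWESS smoothing fraction (default 2/3, three robustness
        iterations).
    """

    range_breaks: tuple[float, float] = (4.0, 8.5)
    band_z: float = 1.96
    ccv_threshold: float = 1.3
    mean_threshold: float = 4.0
    lowess_span: float = 2.0 / 3.0
    lowess_iterations: int = 3

    def __post_init__(self) -> None:
        if not self.range_breaks[0] < self.range_breaks[1]:
            raise ValueError("range_breaks must be increasing")
        if not 0 < self.lowess_span <= 1:
            raise ValueError("lowess_span must be in (0, 1]")


def log_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM + 1) transform of a gene x cell TPM matrix."""
    return np.log2(matrix + 1.0)


def _range_of(means: np.ndarray, breaks: tuple[float, float]) -> np.ndarray:
    lo, hi = breaks
    return np.where(means < lo, 0, np.where(means < hi, 1, 2))


def corrected_cv(matrix: pd.DataFrame,
                 params: HvgParams | None = None) -> pd.DataFrame:
    """Per-gene corrected CV statistics.

    Parameters
    ----------
    matrix
        Genes x cells TPM (not yet log-transformed).
    params
        :class:`HvgParams`.

    Returns
    -------
    DataFrame indexed by gene with columns ``mean_log_expr, cv,
    smoothed_cv, band_upper, ccv, is_hvg``.  Genes with zero mean get NA
    statistics and are never HVGs.
    """
    params = params or HvgParams()
    if matrix.shape[0] < 10:
        raise ValueError("need at least 10 genes")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    log = log_expression(matrix)
    means = log.mean(axis=1).to_numpy()
    sds = log.std(axis=1, ddof=1).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(means > 0, sds / means, np.nan)

    smoothed = np.full_like(cv, np.nan)
    band = np.full_like(cv, np.nan)
    which = _range_of(means, params.range_breaks)
    valid = means > 0
    for r in range(3):
        in_r = (which == r) & valid
        n_r = int(in_r.sum())
        if n_r == 0:
            continue
        if n_r < 5:
            raise ValueError(
                f"mean-expression range {r} holds only {n_r} genes; "
                "cannot smooth")
        x, y = means[in_r], cv[in_r]
        fit = lowess(y, x, frac=params.lowess_span,
                     it=params.lowess_iterations, return_sorted=False)
        resid2 = (y - fit) ** 2
        var_fit = lowess(resid2, x, frac=params.lowess_span,
                         it=params.lowess_iterations, return_sorted=False)
        local_sd = np.sqrt(np.clip(var_fit, 0.0, None))
        smoothed[in_r] = fit
        band[in_r] = fit + params.band_z * local_sd

    with np.errstate(invalid="ignore", divide="ignore"):
        ccv = np.where(band > 0, cv / band, np.nan)
    is_hvg = (np.nan_to_num(ccv) > params.ccv_threshold) & \
        (means >= params.mean_threshold)
    return pd.DataFrame({
        "mean_log_expr": means, "cv": cv, "smoothed_cv": smoothed,
        "band_upper": band, "ccv": ccv, "is_hvg": is_hvg,
    }, index=matrix.index)


def select_hvg(stats_frame: pd.DataFrame,
               params: HvgParams | None = None) -> list:
    """Genes with cCV strictly above threshold at high mean expression,
    sorted by cCV descending."""
    params = params or HvgParams()
    sel = stats_frame[
        (stats_frame["ccv"] > params.ccv_threshold)
        & (stats_frame["mean_log_expr"] >= params.mean_threshold)]
    return list(sel.sort_values("ccv", ascending=False).index)


class GeneVariabilityModel:
    """Mean-variability trend model for variable-gene detection.

    Fits the LOWESS CV-vs-mean trend with its upper band per
    mean-expression range; the results object carries per-gene statistics
    and the HVG list.

    >>> res = GeneVariabilityModel(tpm).fit()          # doctest: +SKIP
    >>> res.hvg                                        # doctest: +SKIP
    """

    def __init__(self, matrix: pd.DataFrame,
                 params: HvgParams | None = None) -> None:
        self.matrix = matrix
        self.params = params or HvgParams()

    def fit(self) -> "GeneVariabilityResults":
        stats_frame = corrected_cv(self.matrix, self.params)
        return GeneVariabilityResults(self, stats_frame)


class GeneVariabilityResults:
    def __init__(self, model, stats_frame: pd.DataFrame) -> None:
        self.model = model
        self.stats = stats_frame

    @property
    def hvg(self) -> list:
        return select_hvg(self.stats, self.model.params)

    def summary(self) -> str:
        p = self.model.params
        head = (f"corrected-CV variable genes: {len(self.hvg)} of "
                f"{len(self.stats)} genes (cCV > {p.ccv_threshold}, "
                f"mean log2(TPM+1) >= {p.mean_threshold})")
        top = self.stats.loc[self.hvg].sort_values("ccv", ascending=False)
        return head + "\n\n" + top.to_string(
            float_format=lambda v: f"{v:.3f}")


def cluster_cells(matrix: pd.DataFrame, k: int | None = None
                  ) -> tuple[np.ndarray, pd.Series | None]:
    """Ward-linkage hierarchical clustering of cells on Euclidean
    distances of log2(TPM+1), typically restricted to HVGs.

    Returns the scipy linkage matrix and, when ``k`` is given, flat labels
    at that cut.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    log = log_expression(matrix)
    z = hierarchy.linkage(log.T.to_numpy(), method="ward",
                          metric="euclidean")
    labels = None
    if k is not None:
        flat = hierarchy.fcluster(z, t=k, criterion="maxclust")
        labels = pd.Series(flat, index=matrix.columns, name="cluster")
    return z, labels


def cluster_genes(matrix: pd.DataFrame, k: int = 3
                  ) -> tuple[np.ndarray, pd.Series, list]:
    """Cluster genes on 1 - Pearson correlation of expression across
    cells (Ward linkage) and cut into ``k`` groups.

    Returns (linkage matrix, labels, genes in dendrogram leaf order) --
    the leaf order is what heatmap columns should follow.
    """
    if matrix.shape[0] < k:
        raise ValueError(f"need at least k={k} genes")
    log = log_expression(matrix)
    x = log.to_numpy()
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = matrix.index[sd == 0][0]
        raise ValueError(f"gene {bad!r} has zero variance")
    corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    from scipy.spatial.distance import squareform
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    z = hierarchy.linkage(condensed, method="ward")
    flat = hierarchy.fcluster(z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=matrix.index, name="gene_group")
    order = [matrix.index[i] for i in hierarchy.leaves_list(z)]
    return z, labels, order


def pca_embed(matrix: pd.DataFrame
              ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of cells on log2(TPM+1): centred, NOT variance-scaled.

    Returns all principal-component scores (cells x components) and the
    eigenvalues of the covariance matrix.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    log = log_expression(matrix)
    x = log.T.to_numpy(dtype=float)           # cells x genes
    if np.unique(x, axis=0).shape[0] < 2:
        raise ValueError("fewer than 2 distinct cell profiles")
    centred = x - x.mean(axis=0)
    u, s, _vt = np.linalg.svd(centred, full_matrices=False)
    scores = u * s
    evals = s**2 / (x.shape[0] - 1)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=matrix.columns, columns=cols), evals


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value; exact for small untied
    samples, normal approximation with tie correction otherwise."""
    use_exact = (len(a) <= 25 and len(b) <= 25
                 and len(np.unique(np.concatenate([a, b])))
                 == len(a) + len(b))
    method = "exact" if use_exact else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def rna_diversity(embedding: pd.DataFrame, groups: pd.Series
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """RNA diversity index per group with pairwise Wilcoxon comparisons.

    Per cell, the Euclidean distance from its group centroid over *all*
    PCA dimensions; the group index is the median distance.

    Returns (per-group table with ``n, diversity``, pairwise p-value
    matrix, per-cell distances).
    """
    groups = groups.loc[embedding.index]
    labels = list(dict.fromkeys(groups))
    coords = embedding.to_numpy(dtype=float)
    dist = pd.Series(index=embedding.index, dtype=float,
                     name="distance_from_centroid")
    per_group: dict = {}
    for lab in labels:
        idx = np.flatnonzero((groups == lab).to_numpy())
        if len(idx) < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 cells")
        sub = coords[idx]
        d = np.linalg.norm(sub - sub.mean(axis=0), axis=1)
        dist.iloc[idx] = d
        per_group[lab] = d
    table = pd.DataFrame({
        "n": [len(per_group[lab]) for lab in labels],
        "diversity": [float(np.median(per_group[lab])) for lab in labels],
    }, index=labels)
    pvals = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                p = _wilcoxon(per_group[a], per_group[b])
                pvals.loc[a, b] = pvals.loc[b, a] = p
    return table, pvals, dist


class RnaDiversityModel:
    """Transcriptional diversity analysis in PCA space.

    Construct from a gene x cell TPM matrix (typically QC-filtered) and a
    cell -> group mapping; :meth:`fit` embeds cells by unscaled PCA of
    log2(TPM+1) and computes the per-group centroid-distance index with
    Wilcoxon group comparisons.
    """

    def __init__(self, matrix: pd.DataFrame, groups: pd.Series) -> None:
        self.matrix = matrix
        self.groups = groups

    def fit(self) -> "RnaDiversityResults":
        embedding, evals = pca_embed(self.matrix)
        table, pvals, dist = rna_diversity(embedding, self.groups)
        return RnaDiversityResults(self, embedding, evals, table, pvals,
                                   dist)


class RnaDiversityResults:
    def __init__(self, model, embedding, eigenvalues, diversity,
                 pairwise_pvalues, distances) -> None:
        self.model = model
        self.embedding = embedding
        self.eigenvalues = eigenvalues
        self.diversity = diversity
        self.pairwise_pvalues = pairwise_pvalues
        self.distances = distances

    def summary(self) -> str:
        lines = ["RNA diversity index (median distance from group "
                 "centroid, full PCA space)", "",
                 self.diversity.to_string(
                     float_format=lambda v: f"{v:.4f}"), "",
                 "pairwise Wilcoxon rank-sum p-values:",
                 self.pairwise_pvalues.to_string(
                     float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)
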