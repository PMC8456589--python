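"""Genetic intra-tumor heterogeneity from single-cell genotype matrices.

The DNA side of the pipeline condenses per-cell SNV calls at bulk-defined
polymorphic sites into a cell x site matrix with entries

* ``1``  -- the SNV was called in the cell,
* ``0``  -- not called and the site had read depth >= ``depth_floor``
  (treated as a true negative),
* ``NA`` -- not called with depth below the floor (undetermined).

Pairwise genetic distance is the p-distance (proportion of differing sites
over sites observed in both cells), embedded by classical (Torgerson)
multidimensional scaling.  The diversity index of a cell group is the mean
Euclidean distance from the group centroid in the first few MDS dimensions.
Because allelic dropout (ADO) biases individual genotypes, inference on the
index uses a bootstrap that resamples cells within groups and re-runs the
whole distance -> MDS -> index pipeline per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DnaIthParams",
    "GenotypeMatrix",
    "site_id",
    "ado_rate",
    "build_genotype_matrix",
    "filter_matrix",
    "p_distance",
    "classical_mds",
    "dna_diversity",
    "bootstrap_diversity",
    "DnaDiversityModel",
    "DnaDiversityResults",
]


@dataclass
class DnaIthParams:
    """Tuning parameters of the DNA heterogeneity pipeline.

    depth_floor
        Reads needed to accept a non-call as a true negative (default 30).
    vaf_lo, vaf_hi
        Bulk-VAF window defining a *polymorphic* site, i.e. one segregating
        among cells rather than clonal (default 0.10-0.35).
    het_lo, het_hi
        Bulk-VAF window defining a *heterozygous* site for ADO estimation
        (default 0.45-0.55).
    hom_vaf
        A called site with VAF at or above this value is treated as
        homozygous-variant when scoring ADO (default 0.9).
    ado_max
        Cells with ADO above this are flagged as outliers (default 0.80).
    mds_dims
        MDS dimensions used by the diversity index (default 6); capped at
        the number of positive eigenvalues.
    n_boot
        Bootstrap replicates (default 10000).
    na_frac_bounds
        (low, high) acceptable NA fraction per cell/site; rows or columns
        outside the bounds are removed by :func:`filter_matrix`.
    """

    depth_floor: int = 30
    vaf_lo: float = 0.10
    vaf_hi: float = 0.35
    het_lo: float = 0.45
    het_hi: float = 0.55
    hom_vaf: float = 0.90
    ado_max: float = 0.80
    mds_dims: int = 6
    n_boot: int = 10_000
    na_frac_bounds: tuple[float, float] = (0.0, 0.8)

    def __post_init__(self) -> None:
        for lo, hi, name in [(self.vaf_lo, self.vaf_hi, "vaf"),
                             (self.het_lo, self.het_hi, "het"),
                             (*self.na_frac_bounds, "na_frac")]:
            if not lo < hi:
                raise ValueError(f"{name} bounds must satisfy lo < hi")


def site_id(chrom, pos, alt) -> str:
    return f"{chrom}:{pos}:{alt}"


@dataclass
class GenotypeMatrix:
    """Cell x site matrix of {0, 1, NA} with per-site bulk metadata.

    ``data`` is indexed by cell id with one column per site id
    (``chrom:pos:alt``); ``sites`` carries chrom/pos/ref/alt plus the bulk
    VAF history columns (``vaf_*``).
    """

    data: pd.DataFrame
    sites: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def cells(self) -> list[str]:
        return list(self.data.index)

    def na_fraction(self, axis: int) -> pd.Series:
        return self.data.isna().mean(axis=axis)


def ado_rate(calls_by_cell: Mapping[str, pd.DataFrame],
             depths: pd.DataFrame,
             bulk_vaf: pd.Series,
             params: DnaIthParams | None = None) -> pd.DataFrame:
    """Per-cell allelic-dropout rate at bulk-heterozygous sites.

    ADO is the rate at which a site that is heterozygous in bulk (VAF in
    ``[het_lo, het_hi]``) appears homozygous in a single cell: either no
    variant called at adequate depth (homozygous reference) or called with
    VAF >= ``hom_vaf`` (homozygous variant, the other allele dropped).

    Parameters
    ----------
    calls_by_cell
        Mapping cell id -> call table (``chrom, pos, alt, vaf`` columns).
    depths
        Cell x site-id read depths.
    bulk_vaf
        Bulk VAF per site id at the matching time point.
    """
    params = params or DnaIthParams()
    het_sites = bulk_vaf.index[
        (bulk_vaf >= params.het_lo) & (bulk_vaf <= params.het_hi)]
    het_sites = [s for s in het_sites if s in depths.columns]
    rows = []
    for cell, calls in calls_by_cell.items():
        if cell not in depths.index:
            raise ValueError(f"no depth data for cell {cell!r}")
        called_vaf = {
            site_id(c, p, a): v
            for c, p, a, v in zip(calls["chrom"], calls["pos"],
                                  calls["alt"], calls["vaf"])
        }
        n_assessable = 0
        n_hom = 0
        for s in het_sites:
            if depths.at[cell, s] < params.depth_floor:
                continue
            n_assessable += 1
            v = called_vaf.get(s)
            if v is None or v >= params.hom_vaf:
                n_hom += 1
        rate = n_hom / n_assessable if n_assessable else np.nan
        rows.append((cell, rate, n_assessable,
                     bool(n_assessable and rate > params.ado_max)))
    out = pd.DataFrame(rows, columns=["cell", "ado", "n_assessable",
                                      "outlier"]).set_index("cell")
    if out["ado"].isna().all():
        import warnings
        warnings.warn("no assessable bulk-heterozygous sites for any cell")
    return out


def _vaf_columns(bulk_sites: pd.DataFrame) -> list[str]:
    cols = [c for c in bulk_sites.columns if c.startswith("vaf")]
    if not cols:
        raise ValueError("bulk_sites needs at least one vaf* column")
    return cols


def build_genotype_matrix(calls_by_cell: Mapping[str, pd.DataFrame],
                          depths: pd.DataFrame,
                          bulk_sites: pd.DataFrame,
                          params: DnaIthParams | None = None
                          ) -> GenotypeMatrix:
    """Assemble the 0/1/NA genotype matrix at polymorphic bulk sites.

    The site universe is restricted to bulk sites whose VAF lies inside the
    polymorphic window at one or more time points (``vaf*`` columns of
    ``bulk_sites``) *and* that were called in at least one cell (matching
    the alt allele).
    """
    params = params or DnaIthParams()
    vaf_cols = _vaf_columns(bulk_sites)
    vafs = bulk_sites[vaf_cols].to_numpy(dtype=float)
    poly = ((vafs >= params.vaf_lo) & (vafs <= params.vaf_hi)).any(axis=1)
    sites = bulk_sites.loc[poly].copy()
    sites["site_id"] = [site_id(c, p, a) for c, p, a in
                        zip(sites["chrom"], sites["pos"], sites["alt"])]
    sites = sites.set_index("site_id")

    called: dict[str, set[str]] = {}
    for cell, calls in calls_by_cell.items():
        if cell not in depths.index:
            raise ValueError(f"no depth data for cell {cell!r}")
        called[cell] = {site_id(c, p, a) for c, p, a in
                        zip(calls["chrom"], calls["pos"], calls["alt"])}

    ever_called = set().union(*called.values()) if called else set()
    keep = [s for s in sites.index if s in ever_called]
    sites = sites.loc[keep]

    cells = list(calls_by_cell)
    data = np.full((len(cells), len(keep)), np.nan)
    for i, cell in enumerate(cells):
        cset = called[cell]
        for j, s in enumerate(keep):
            if s in cset:
                data[i, j] = 1.0
            elif depths.at[cell, s] >= params.depth_floor:
                data[i, j] = 0.0
    return GenotypeMatrix(pd.DataFrame(data, index=cells, columns=keep),
                          sites)


def filter_matrix(matrix: GenotypeMatrix,
                  params: DnaIthParams | None = None
                  ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Iteratively drop cells/sites whose NA fraction is out of bounds.

    Returns the filtered matrix and a report of removals
    (``kind, id, na_fraction``).
    """
    params = params or DnaIthParams()
    lo, hi = params.na_frac_bounds
    data = matrix.data.copy()
    removed = []
    changed = True
    while changed:
        changed = False
        cell_na = data.isna().mean(axis=1)
        bad_cells = cell_na.index[(cell_na < lo) | (cell_na > hi)]
        if len(bad_cells):
            for c in bad_cells:
                removed.append(("cell", c, cell_na[c]))
            data = data.drop(index=bad_cells)
            changed = True
        if data.empty:
            raise ValueError("NA filtering removed all cells")
        site_na = data.isna().mean(axis=0)
        bad_sites = site_na.index[(site_na < lo) | (site_na > hi)]
        if len(bad_sites):
            for s in bad_sites:
                removed.append(("site", s, site_na[s]))
            data = data.drop(columns=bad_sites)
            changed = True
        if data.shape[1] == 0:
            raise ValueError("NA filtering removed all sites")
    report = pd.DataFrame(removed, columns=["kind", "id", "na_fraction"])
    sites = matrix.sites.loc[[s for s in matrix.sites.index
                              if s in data.columns]]
    return GenotypeMatrix(data, sites), report


def _p_distance_array(values: np.ndarray) -> np.ndarray:
    """p-distance on a float array with NaN for missing; raises on
    incomparable pairs."""
    mask = ~np.isnan(values)
    x = np.where(mask, values, 0.0)
    p = x * mask            # 1 where called & observed
    q = (1.0 - x) * mask    # 1 where explicit 0 & observed
    diff = p @ q.T + q @ p.T
    comp = mask.astype(float) @ mask.T
    n = values.shape[0]
    off = ~np.eye(n, dtype=bool)
    if (comp[off] == 0).any():
        i, j = np.argwhere((comp == 0) & off)[0]
        raise ValueError(f"cells {i} and {j} share no comparable sites")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = diff / comp
    np.fill_diagonal(d, 0.0)
    return d


def p_distance(matrix: GenotypeMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise p-distance between cells of a 0/1/NA genotype matrix.

    ``d(i, j)`` is the number of sites where the two cells differ divided
    by the number of sites observed (non-NA) in both -- pairwise deletion
    of missing genotypes, as used for molecular sequence data.
    """
    data = matrix.data if isinstance(matrix, GenotypeMatrix) else matrix
    d = _p_distance_array(data.to_numpy(dtype=float))
    return pd.DataFrame(d, index=data.index, columns=data.index)


def _classical_mds_array(d: np.ndarray, dims: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    n = d.shape[0]
    d2 = d * d
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    dims = min(dims, n)
    coords = evecs[:, :dims] * np.sqrt(np.clip(evals[:dims], 0.0, None))
    return coords, evals


def classical_mds(distances: pd.DataFrame | np.ndarray, dims: int = 6
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres the squared distance matrix, eigendecomposes it and
    scales eigenvectors by the square root of the (non-negative-clipped)
    eigenvalues.  Returns the first ``dims`` coordinate columns and the
    full eigenvalue spectrum in non-increasing order.
    """
    if isinstance(distances, pd.DataFrame):
        index = distances.index
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        index = pd.RangeIndex(d.shape[0])
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    coords, evals = _classical_mds_array(d, dims)
    cols = [f"dim{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=index, columns=cols), evals


def _diversity_from_coords(coords: np.ndarray, evals: np.ndarray,
                           group_idx: list[np.ndarray],
                           mds_dims: int) -> np.ndarray:
    n_pos = int((evals > 1e-12).sum())
    dims = min(mds_dims, max(n_pos, 1), coords.shape[1])
    if dims == 0:
        raise ValueError("no positive MDS dimensions")
    out = np.empty(len(group_idx))
    for g, idx in enumerate(group_idx):
        sub = coords[idx, :dims]
        centroid = sub.mean(axis=0)
        out[g] = np.linalg.norm(sub - centroid, axis=1).mean()
    return out


def dna_diversity(embedding: pd.DataFrame, eigenvalues: np.ndarray,
                  groups: pd.Series,
                  params: DnaIthParams | None = None) -> pd.Series:
    """Diversity index per cell group: mean Euclidean distance from the
    group centroid over the first ``min(mds_dims, #positive-eigenvalue)``
    MDS dimensions."""
    params = params or DnaIthParams()
    groups = groups.loc[embedding.index]
    labels = list(dict.fromkeys(groups))
    for lab in labels:
        if (groups == lab).sum() < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 cells")
    idx = [np.flatnonzero((groups == lab).to_numpy()) for lab in labels]
    vals = _diversity_from_coords(embedding.to_numpy(dtype=float),
                                  np.asarray(eigenvalues), idx,
                                  params.mds_dims)
    return pd.Series(vals, index=labels, name="diversity")


def bootstrap_diversity(matrix: GenotypeMatrix | pd.DataFrame,
                        groups: pd.Series,
                        params: DnaIthParams | None = None,
                        seed: int | None = None,
                        n_boot: int | None = None) -> dict:
    """Bootstrap inference for the group diversity indices.

    Each replicate resamples cells with replacement *within* each group,
    then re-runs p-distance -> classical MDS -> diversity index on the
    resampled matrix.  Replicates containing a cell pair with no comparable
    sites are redrawn (and counted).  Distance-from-centroid is invariant
    to the arbitrary rotation of each replicate's MDS solution, so no
    Procrustes alignment is needed.

    Returns a dict with ``observed`` (Series), ``ci`` (DataFrame with
    ci_low/ci_high/sd per group), ``pairwise`` (DataFrame of two-sided
    bootstrap p-values), ``replicates`` (n_boot x n_groups array) and
    ``n_redrawn``.
    """
    params = params or DnaIthParams()
    n_boot = n_boot if n_boot is not None else params.n_boot
    data = matrix.data if isinstance(matrix, GenotypeMatrix) else matrix
    groups = groups.loc[data.index]
    labels = list(dict.fromkeys(groups))
    values = data.to_numpy(dtype=float)
    group_idx = [np.flatnonzero((groups == lab).to_numpy())
                 for lab in labels]
    for lab, idx in zip(labels, group_idx):
        if len(idx) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 cells")

    d_obs = _p_distance_array(values)
    coords, evals = _classical_mds_array(d_obs, params.mds_dims)
    obs = _diversity_from_coords(coords, evals, group_idx, params.mds_dims)

    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, len(labels)))
    n_redrawn = 0
    concat = np.concatenate
    for b in range(n_boot):
        while True:
            take = concat([rng.choice(idx, size=len(idx), replace=True)
                           for idx in group_idx])
            sub = values[take]
            try:
                d = _p_distance_array(sub)
            except ValueError:
                n_redrawn += 1
                continue
            break
        c, ev = _classical_mds_array(d, params.mds_dims)
        offsets = np.cumsum([0] + [len(idx) for idx in group_idx])
        rep_idx = [np.arange(offsets[g], offsets[g + 1])
                   for g in range(len(labels))]
        reps[b] = _diversity_from_coords(c, ev, rep_idx, params.mds_dims)

    ci = pd.DataFrame({
        "index": obs,
        "ci_low": np.percentile(reps, 2.5, axis=0),
        "ci_high": np.percentile(reps, 97.5, axis=0),
        "sd": reps.std(axis=0, ddof=1),
    }, index=labels)
    pair = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j, b_ in enumerate(labels):
            if i >= j:
                continue
            diff = reps[:, i] - reps[:, j]
            p = 2.0 * min((diff <= 0).mean(), (diff >= 0).mean())
            pair.loc[a, b_] = pair.loc[b_, a] = min(p, 1.0)
    return {"observed": pd.Series(obs, index=labels, name="diversity"),
            "ci": ci, "pairwise": pair, "replicates": reps,
            "n_redrawn": n_redrawn}


class DnaDiversityModel:
    """Genetic diversity analysis of a genotype matrix with cell groups.

    Statsmodels-style wrapper: construct from the 0/1/NA matrix and a cell
    -> group mapping, then :meth:`fit` runs p-distance, classical MDS, the
    per-group diversity index and (optionally) the within-group cell
    bootstrap.

    Examples
    --------
    >>> model = DnaDiversityModel(gm, groups)          # doctest: +SKIP
    >>> res = model.fit(n_boot=1000, seed=1)           # doctest: +SKIP
    >>> print(res.summary())                           # doctest: +SKIP
    """

    def __init__(self, matrix: GenotypeMatrix | pd.DataFrame,
                 groups: pd.Series,
                 params: DnaIthParams | None = None) -> None:
        self.matrix = matrix
        self.groups = groups
        self.params = params or DnaIthParams()

    def fit(self, n_boot: int | None = None,
            seed: int | None = None) -> "DnaDiversityResults":
        data = (self.matrix.data if isinstance(self.matrix, GenotypeMatrix)
                else self.matrix)
        dist = p_distance(data)
        embedding, evals = classical_mds(dist, self.params.mds_dims)
        index = dna_diversity(embedding, evals, self.groups, self.params)
        boot = None
        if n_boot is None or n_boot > 0:
            boot = bootstrap_diversity(data, self.groups, self.params,
                                       seed=seed, n_boot=n_boot)
        return DnaDiversityResults(self, dist, embedding, evals, index,
                                   boot)


class DnaDiversityResults:
    """Results of :class:`DnaDiversityModel.fit`."""

    def __init__(self, model, distances, embedding, eigenvalues, diversity,
                 bootstrap) -> None:
        self.model = model
        self.distances = distances
        self.embedding = embedding
        self.eigenvalues = eigenvalues
        self.diversity = diversity
        self.bootstrap = bootstrap

    @property
    def ci(self) -> pd.DataFrame | None:
        return None if self.bootstrap is None else self.bootstrap["ci"]

    @property
    def pairwise_pvalues(self) -> pd.DataFrame | None:
        return None if self.bootstrap is None else self.bootstrap["pairwise"]

    def summary(self) -> str:
        lines = ["DNA diversity index (mean distance from group centroid, "
                 f"MDS dims <= {self.model.params.mds_dims})", ""]
        if self.bootstrap is not None:
            tab = self.bootstrap["ci"]
            lines.append(tab.to_string(float_format=lambda v: f"{v:.4f}"))
            lines.append("")
            lines.append("pairwise bootstrap p-values:")
            lines.append(self.pairwise_pvalues.to_string(
                float_format=lambda v: f"{v:.4f}"))
        else:
            lines.append(self.diversity.to_string(
                float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)
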