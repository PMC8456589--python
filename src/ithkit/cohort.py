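"""Cross-cohort subpopulation matching by normalised correlation distance.

Bulk cohort samples (e.g. human tumours) are assigned to single-cell
expression groups (e.g. mouse transcriptional subpopulations) through the
MADN-normalised 1-r distance::

    d(h, G) = (1 - r(h, m_G)) / MADN_i( 1 - r(m_i_G, m_G) )

where ``r`` is the Pearson correlation over a shared set of highly
variable genes, ``m_i_G`` are the group's single cells (log expression),
``m_G`` is their per-gene median centroid, and MADN is the median absolute
deviation scaled by 1.4826 for consistency with the normal SD.  The
denominator expresses a sample's dissimilarity in units of the group's own
cell-to-centroid spread, making distances comparable across groups of
different tightness.  A sample is assigned to its nearest group only when
the minimum distance is small enough and clearly separated from the
second-best group.

The module also carries the downstream association machinery: joint MDS
of samples and cells on the unnormalised 1-r distance, Fisher's exact
test of group membership against a binary phenotype, and a
Kruskal-Wallis feature filter feeding a (library-delegated) random-forest
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dna_ith import classical_mds

__all__ = [
    "AssignmentParams",
    "madn",
    "CohortMatchModel",
    "CohortMatchResults",
    "group_distance",
    "assign_samples",
    "joint_mds",
    "phenotype_association",
    "kw_filter",
    "train_classify",
]


@dataclass
class AssignmentParams:
    """Assignment thresholds for the normalised 1-r distance.

    dmin_max
        A sample is assignable only when its minimum distance across
        groups is strictly below this (default 4.05).
    gap_min
        ... and the gap between the second-smallest and smallest distance
        strictly exceeds this (default 0.31).
    """

    dmin_max: float = 4.05
    gap_min: float = 0.31

    def __post_init__(self) -> None:
        if self.dmin_max <= 0 or self.gap_min <= 0:
            raise ValueError("thresholds must be positive")


def madn(values) -> float:
    """Median absolute deviation x 1.4826 (normal-consistent scale)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(np.corrcoef(a, b)[0, 1])


class CohortMatchModel:
    """Normalised 1-r matcher built from single-cell group expression.

    Parameters
    ----------
    group_cells
        Log-scale expression, genes (HVGs) x cells.
    cell_groups
        Series mapping cell id -> group label.
    params
        :class:`AssignmentParams`.

    :meth:`fit` computes per-group median centroids and MADN scales;
    the results object assigns cohort samples and reports distances.
    """

    def __init__(self, group_cells: pd.DataFrame, cell_groups: pd.Series,
                 params: AssignmentParams | None = None) -> None:
        self.group_cells = group_cells
        self.cell_groups = cell_groups.loc[group_cells.columns]
        self.params = params or AssignmentParams()

    def fit(self) -> "CohortMatchResults":
        labels = list(dict.fromkeys(self.cell_groups))
        if len(labels) < 2:
            raise ValueError("need at least 2 groups")
        centroids = {}
        scales = {}
        for lab in labels:
            cells = self.cell_groups.index[self.cell_groups == lab]
            sub = self.group_cells[cells]
            centroid = sub.median(axis=1).to_numpy()
            dists = [1.0 - _pearson(sub[c].to_numpy(), centroid)
                     for c in cells]
            scale = madn(dists)
            if scale <= 0:
                raise ValueError(
                    f"group {lab!r} has zero within-group MADN scale")
            centroids[lab] = centroid
            scales[lab] = scale
        centroid_frame = pd.DataFrame(centroids,
                                      index=self.group_cells.index)
        scale_series = pd.Series(scales, name="within_group_scale")
        return CohortMatchResults(self, centroid_frame, scale_series)


class CohortMatchResults:
    """Fitted matcher: per-group centroids and MADN scales."""

    def __init__(self, model: CohortMatchModel,
                 centroids: pd.DataFrame, scales: pd.Series) -> None:
        self.model = model
        self.centroids = centroids
        self.scales = scales

    @property
    def groups(self) -> list:
        return list(self.centroids.columns)

    def distance(self, sample: pd.Series | np.ndarray,
                 group) -> float:
        """Normalised 1-r distance from one sample to one group."""
        x = np.asarray(sample, dtype=float)
        if x.shape[0] != self.centroids.shape[0]:
            raise ValueError("sample does not share the HVG gene index")
        r = _pearson(x, self.centroids[group].to_numpy())
        return (1.0 - r) / float(self.scales[group])

    def distances(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Distance of every cohort sample (columns) to every group."""
        if list(cohort.index) != list(self.centroids.index):
            cohort = cohort.reindex(self.centroids.index)
            if cohort.isna().any().any():
                raise ValueError("cohort does not share the HVG gene index")
        out = {g: [self.distance(cohort[s], g) for s in cohort.columns]
               for g in self.groups}
        return pd.DataFrame(out, index=cohort.columns)

    def assign(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Assign each cohort sample to its nearest group, or leave it
        unassigned when too far (d1 >= dmin_max), too ambiguous
        (d2 - d1 <= gap_min) or tied.

        Returns a DataFrame ``group (NA when unassigned), d1, d2``.
        """
        p = self.model.params
        d = self.distances(cohort)
        rows = []
        for s in d.index:
            vals = d.loc[s].to_numpy()
            order = np.argsort(vals)
            d1, d2 = vals[order[0]], vals[order[1]]
            group = self.groups[order[0]]
            ok = d1 < p.dmin_max and (d2 - d1) > p.gap_min and d1 != d2
            rows.append((group if ok else pd.NA, d1, d2))
        return pd.DataFrame(rows, index=d.index,
                            columns=["group", "d1", "d2"])

    def summary(self) -> str:
        tab = self.centroids.describe().T[["mean", "std"]]
        lines = ["cohort matcher: normalised 1-r distance",
                 f"groups: {self.groups}",
                 "within-group MADN scales:",
                 self.scales.to_string(float_format=lambda v: f"{v:.4f}"),
                 "centroid summary:",
                 tab.to_string(float_format=lambda v: f"{v:.3f}")]
        return "\n".join(lines)


def group_distance(sample, group_cells: pd.DataFrame,
                   cell_groups: pd.Series, group,
                   params: AssignmentParams | None = None) -> float:
    """Functional form of the normalised 1-r distance to one group."""
    res = CohortMatchModel(group_cells, cell_groups, params).fit()
    return res.distance(sample, group)


def assign_samples(cohort: pd.DataFrame, group_cells: pd.DataFrame,
                   cell_groups: pd.Series,
                   params: AssignmentParams | None = None) -> pd.DataFrame:
    """Fit the matcher and assign cohort samples in one call."""
    return CohortMatchModel(group_cells, cell_groups, params).fit() \
        .assign(cohort)


def joint_mds(entities: pd.DataFrame, dims: int = 2
              ) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical MDS of samples + cells on the unnormalised 1-r distance.

    ``entities`` is genes x entities (selected cohort samples together
    with all single cells) on the log scale.
    """
    if entities.shape[1] < 3:
        raise ValueError("need at least 3 entities")
    x = entities.to_numpy(dtype=float).T
    if (x.std(axis=1) == 0).any():
        bad = entities.columns[x.std(axis=1) == 0][0]
        raise ValueError(f"entity {bad!r} has zero variance")
    corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    frame = pd.DataFrame(dist, index=entities.columns,
                         columns=entities.columns)
    return classical_mds(frame, dims)


def phenotype_association(assignments: pd.Series, labels: pd.Series,
                          positive_groups) -> dict:
    """Fisher's exact association between group membership and a binary
    phenotype.

    Groups are collapsed into ``positive_groups`` vs the rest (unassigned
    samples are excluded); the 2x2 table of collapsed group x label is
    tested with the exact two-sided hypergeometric test.

    Returns ``{"odds_ratio", "p_value", "table"}``.
    """
    assigned = assignments.dropna()
    labels = labels.loc[assigned.index]
    in_pos = assigned.isin(set(positive_groups))
    lab = labels.astype(bool)
    a = int((in_pos & lab).sum())
    b = int((in_pos & ~lab).sum())
    c = int((~in_pos & lab).sum())
    d = int((~in_pos & ~lab).sum())
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("2x2 table has an empty margin")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"odds_ratio": float(odds), "p_value": float(p), "table": table}


def kw_filter(features: pd.DataFrame, labels: pd.Series,
              alpha: float) -> tuple[list, pd.Series]:
    """Kruskal-Wallis feature filter.

    Keeps variables (columns of the samples x variables frame) whose
    Kruskal-Wallis test across label classes has p < ``alpha``
    (chi-square approximation with tie correction).  Constant variables
    get p = 1 and are dropped.

    Returns (selected variable list, per-variable p-values).
    """
    labels = labels.loc[features.index]
    classes = list(dict.fromkeys(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 label classes")
    for cl in classes:
        if (labels == cl).sum() < 2:
            raise ValueError(f"class {cl!r} has fewer than 2 samples")
    groups_idx = [np.flatnonzero((labels == cl).to_numpy())
                  for cl in classes]
    pvals = {}
    for var in features.columns:
        x = features[var].to_numpy(dtype=float)
        if np.all(x == x[0]):
            pvals[var] = 1.0
            continue
        samples = [x[idx] for idx in groups_idx]
        try:
            pvals[var] = float(stats.kruskal(*samples).pvalue)
        except ValueError:  # all values identical within the test
            pvals[var] = 1.0
    pseries = pd.Series(pvals, name="kw_pvalue")
    selected = [v for v in features.columns if pseries[v] < alpha]
    return selected, pseries


def train_classify(features: pd.DataFrame, labels: pd.Series,
                   query: pd.DataFrame | None = None,
                   n_trees: int = 10_000, vars_per_split: int = 5,
                   seed: int | None = None):
    """Random-forest classification of filtered features.

    Bagged decision trees with ``vars_per_split`` candidate variables per
    split and majority vote (delegated to scikit-learn).  Returns the
    fitted classifier and, when ``query`` rows are given, a DataFrame of
    class vote fractions per query row.
    """
    from sklearn.ensemble import RandomForestClassifier

    labels = labels.loc[features.index]
    if labels.nunique() < 2:
        raise ValueError("training labels contain a single class")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(vars_per_split, features.shape[1]),
        oob_score=True, random_state=seed)
    clf.fit(features.to_numpy(), labels.to_numpy())
    votes = None
    if query is not None:
        if list(query.columns) != list(features.columns):
            raise ValueError("query does not share the variable index")
        proba = clf.predict_proba(query.to_numpy())
        votes = pd.DataFrame(proba, index=query.index,
                             columns=clf.classes_)
    return clf, votes
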