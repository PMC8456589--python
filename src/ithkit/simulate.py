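"""Synthetic single-cell DNA and RNA data with known ground truth.

The DNA generator emulates a clonal cell population observed through
error-prone, depth-variable single-cell pileups: a small set of clones
shares *fixed* heterozygous SNVs (carried by every clone) and segregates
*polymorphic* SNVs (carried by a proper subset of clones).  Each simulated
cell is drawn from a clone, per-site read depth follows a negative
binomial, heterozygous sites emit reads ~50/50 ref/alt unless allelic
dropout (ADO) removes one allele, and sequencing errors substitute reads
uniformly among the three other bases.  The bulk pileup is the
deterministic infinite-population limit (expected base fractions at a
large depth), so bulk VAFs equal the clone-fraction arithmetic.

The RNA generator emulates 2-3 transcriptional subpopulations with
marker-gene structure, a configurable set of overdispersed
(highly variable) genes and expression dropout, on the log2(TPM+1) scale
used throughout the analysis.

All generators take an explicit seed and never touch global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dna_snv import BASES

__all__ = [
    "CloneSpec",
    "DnaNoiseModel",
    "RnaPopulationSpec",
    "DnaSimulation",
    "RnaSimulation",
    "make_clone_spec",
    "make_rna_spec",
    "simulate_dna",
    "simulate_expression",
    "simulate_cohort",
]


@dataclass
class CloneSpec:
    """Clonal structure of the simulated population.

    clone_fractions
        Population fraction of each clone; must sum to 1.
    n_fixed_sites
        Heterozygous SNV sites carried by every clone.
    n_polymorphic_sites
        SNV sites carried by at least one but not all clones.
    site_positions
        1-based genomic positions, one per site (fixed sites first);
        generated on a single chromosome when omitted.
    """

    clone_fractions: tuple[float, ...]
    n_fixed_sites: int
    n_polymorphic_sites: int
    site_positions: np.ndarray | None = None
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        frac = np.asarray(self.clone_fractions, dtype=float)
        if (frac <= 0).any() or (frac > 1).any():
            raise ValueError("clone fractions must lie in (0, 1]")
        if abs(frac.sum() - 1.0) > 1e-9:
            raise ValueError("clone fractions must sum to 1")
        n = self.n_fixed_sites + self.n_polymorphic_sites
        if self.site_positions is None:
            self.site_positions = np.arange(1, n + 1) * 1000
        elif len(self.site_positions) != n:
            raise ValueError("need one position per site")

    @property
    def n_clones(self) -> int:
        return len(self.clone_fractions)

    @property
    def n_sites(self) -> int:
        return self.n_fixed_sites + self.n_polymorphic_sites


@dataclass
class DnaNoiseModel:
    """Observation noise of single-cell DNA sequencing.

    mean_depth
        Mean per-site read depth.
    depth_dispersion
        Negative-binomial overdispersion alpha (variance =
        mean + alpha * mean^2); 0 gives Poisson depths.  Non-zero values
        reproduce the uneven whole-genome-amplification coverage that high
        Gini coefficients summarise.
    error_rate
        Per-read probability of substitution to a uniformly chosen other
        base.
    ado_rate
        Probability that a heterozygous site presents only one (uniformly
        chosen) allele in a cell; fires independently per (cell, site).
    """

    mean_depth: float = 50.0
    depth_dispersion: float = 0.5
    error_rate: float = 1e-3
    ado_rate: float = 0.45

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for r in (self.error_rate, self.ado_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")


@dataclass
class DnaSimulation:
    """Outputs of :func:`simulate_dna`."""

    cell_pileups: dict
    bulk_pileup: pd.DataFrame
    background_pileup: pd.DataFrame  # variant-free normal sample
    truth_genotypes: pd.DataFrame   # cells x site_id, {0, 1}
    truth_clones: pd.Series         # cell -> clone index
    sites: pd.DataFrame             # site_id-indexed metadata + true VAF
    depths: pd.DataFrame            # cells x site_id total depth
    bulk_sites: pd.DataFrame        # chrom, pos, ref, alt, vaf


def make_clone_spec(n_fixed_sites: int = 100,
                    n_polymorphic_sites: int = 50,
                    clone_fractions: tuple[float, ...] = (0.5, 0.3, 0.2),
                    ) -> CloneSpec:
    """Default clonal structure: three clones, fixed SNVs dominating
    polymorphic ones roughly 2:1 at desk scale (the study population was
    ~90% fixed)."""
    return CloneSpec(clone_fractions=clone_fractions,
                     n_fixed_sites=n_fixed_sites,
                     n_polymorphic_sites=n_polymorphic_sites)


def _sample_depths(rng, noise: DnaNoiseModel, shape) -> np.ndarray:
    m = noise.mean_depth
    if noise.depth_dispersion == 0:
        return rng.poisson(m, size=shape)
    r = 1.0 / noise.depth_dispersion
    return rng.negative_binomial(r, r / (r + m), size=shape)


def _error_transform(p0: np.ndarray, e: float) -> np.ndarray:
    """Per-base read probabilities after uniform substitution errors."""
    return p0 * (1.0 - e) + (1.0 - p0) * (e / 3.0)


def _multinomial_counts(rng, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorised multinomial via conditional binomials.

    ``n`` has shape S, ``p`` shape S + (k,); returns counts S + (k,).
    """
    k = p.shape[-1]
    remaining = n.astype(np.int64).copy()
    rest = np.ones(n.shape)
    out = np.zeros(n.shape + (k,), dtype=np.int64)
    for b in range(k - 1):
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(rest > 0, p[..., b] / rest, 0.0)
        cond = np.clip(cond, 0.0, 1.0)
        draw = rng.binomial(remaining, cond)
        out[..., b] = draw
        remaining -= draw
        rest = rest - p[..., b]
    out[..., k - 1] = remaining
    return out


def simulate_dna(clone_spec: CloneSpec, noise: DnaNoiseModel,
                 n_cells: int, seed: int,
                 bulk_depth: int = 10_000) -> DnaSimulation:
    """Simulate single-cell and bulk pileups from a clonal population.

    Returns a :class:`DnaSimulation` carrying per-cell pileup tables, the
    deterministic bulk pileup, truth genotypes/clone labels, per-cell
    depths and the bulk site list with true VAFs.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    n_sites = clone_spec.n_sites
    n_clones = clone_spec.n_clones

    # per-site ref/alt alleles
    base_idx = rng.integers(0, 4, size=n_sites)
    alt_shift = rng.integers(1, 4, size=n_sites)
    refs = np.array(BASES)[base_idx]
    alts = np.array(BASES)[(base_idx + alt_shift) % 4]

    # carriers: fixed sites in every clone; polymorphic in a proper,
    # non-empty subset
    carriers = np.ones((n_sites, n_clones), dtype=bool)
    for j in range(clone_spec.n_fixed_sites, n_sites):
        size = rng.integers(1, n_clones)
        chosen = rng.choice(n_clones, size=size, replace=False)
        carriers[j] = False
        carriers[j, chosen] = True

    frac = np.asarray(clone_spec.clone_fractions)
    clone_of = rng.choice(n_clones, size=n_cells, p=frac)
    cells = [f"cell{i:03d}" for i in range(n_cells)]
    genotypes = carriers[:, clone_of].T.astype(float)  # cells x sites

    depth = _sample_depths(rng, noise, (n_cells, n_sites))

    # base-probability tensor per (cell, site)
    ref_onehot = np.eye(4)[base_idx]                   # sites x 4
    alt_onehot = np.eye(4)[(base_idx + alt_shift) % 4]
    het = genotypes.astype(bool)
    ado = het & (rng.random((n_cells, n_sites)) < noise.ado_rate)
    keep_alt = rng.random((n_cells, n_sites)) < 0.5    # allele kept on ADO
    p0 = np.broadcast_to(ref_onehot, (n_cells, n_sites, 4)).copy()
    mix = 0.5 * (ref_onehot + alt_onehot)
    p0[het & ~ado] = np.broadcast_to(
        mix, (n_cells, n_sites, 4))[het & ~ado]
    p0[ado & keep_alt] = np.broadcast_to(
        alt_onehot, (n_cells, n_sites, 4))[ado & keep_alt]
    p = _error_transform(p0, noise.error_rate)
    counts = _multinomial_counts(rng, depth, p)

    site_ids = [f"{clone_spec.chrom}:{pos}:{alt}"
                for pos, alt in zip(clone_spec.site_positions, alts)]
    cell_pileups = {}
    for i, cell in enumerate(cells):
        cell_pileups[cell] = pd.DataFrame({
            "chrom": clone_spec.chrom,
            "pos": clone_spec.site_positions,
            "ref": refs,
            "A": counts[i, :, 0], "C": counts[i, :, 1],
            "G": counts[i, :, 2], "T": counts[i, :, 3],
            "depth": counts[i].sum(axis=1),
        })

    # bulk: deterministic infinite-population limit
    carrier_frac = carriers @ frac
    p0_bulk = (np.eye(4)[base_idx] * (1 - 0.5 * carrier_frac[:, None])
               + np.eye(4)[(base_idx + alt_shift) % 4]
               * (0.5 * carrier_frac[:, None]))
    p_bulk = _error_transform(p0_bulk, noise.error_rate)
    bulk_counts = np.round(p_bulk * bulk_depth).astype(int)
    bulk_pileup = pd.DataFrame({
        "chrom": clone_spec.chrom, "pos": clone_spec.site_positions,
        "ref": refs,
        "A": bulk_counts[:, 0], "C": bulk_counts[:, 1],
        "G": bulk_counts[:, 2], "T": bulk_counts[:, 3],
        "depth": bulk_counts.sum(axis=1),
    })
    alt_col = bulk_counts[np.arange(n_sites), (base_idx + alt_shift) % 4]
    bulk_vaf = alt_col / bulk_counts.sum(axis=1)

    # matched normal background: reference only, same error process
    p_bg = _error_transform(np.eye(4)[base_idx], noise.error_rate)
    bg_counts = np.round(p_bg * bulk_depth).astype(int)
    background_pileup = pd.DataFrame({
        "chrom": clone_spec.chrom, "pos": clone_spec.site_positions,
        "ref": refs,
        "A": bg_counts[:, 0], "C": bg_counts[:, 1],
        "G": bg_counts[:, 2], "T": bg_counts[:, 3],
        "depth": bg_counts.sum(axis=1),
    })

    sites = pd.DataFrame({
        "chrom": clone_spec.chrom, "pos": clone_spec.site_positions,
        "ref": refs, "alt": alts,
        "fixed": np.arange(n_sites) < clone_spec.n_fixed_sites,
        "carrier_fraction": carrier_frac,
        "true_vaf": 0.5 * carrier_frac,
        "vaf": bulk_vaf,
    }, index=pd.Index(site_ids, name="site_id"))

    return DnaSimulation(
        cell_pileups=cell_pileups,
        bulk_pileup=bulk_pileup,
        background_pileup=background_pileup,
        truth_genotypes=pd.DataFrame(genotypes, index=cells,
                                     columns=site_ids),
        truth_clones=pd.Series(clone_of, index=cells, name="clone"),
        sites=sites,
        depths=pd.DataFrame(counts.sum(axis=2), index=cells,
                            columns=site_ids),
        bulk_sites=sites.reset_index()[
            ["chrom", "pos", "ref", "alt", "vaf"]],
    )


@dataclass
class RnaPopulationSpec:
    """Transcriptional-subpopulation structure of the RNA generator.

    group_mean_profiles
        Genes x groups matrix of log2(TPM+1)-scale means.
    hvg_indices
        Genes given an inflated noise SD (the truth highly variable set).
    variance_inflation
        Multiplier (>= 1) on the noise SD of those genes.
    noise_sd
        Baseline Gaussian noise SD on the log2 scale.
    dropout_rate
        Probability that a *weakly expressed* gene reads as 0 in a cell.
        Dropout in full-length single-cell chemistry is expression
        dependent, so the realised probability decays logistically with
        the gene's log2 expression (midpoint ``dropout_midpoint``, scale
        ``dropout_scale``); strongly expressed genes essentially never
        drop out.
    tpm_total
        Column sum of the output TPM matrix.
    """

    cells_per_group: tuple[int, ...]
    group_mean_profiles: np.ndarray
    hvg_indices: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int))
    variance_inflation: float = 3.0
    noise_sd: float = 0.5
    dropout_rate: float = 0.3
    dropout_midpoint: float = 3.0
    dropout_scale: float = 0.5
    tpm_total: float = 1e6

    def __post_init__(self) -> None:
        self.group_mean_profiles = np.atleast_2d(
            np.asarray(self.group_mean_profiles, dtype=float))
        if self.group_mean_profiles.shape[1] != len(self.cells_per_group):
            raise ValueError("one mean-profile column per group required")
        self.hvg_indices = np.asarray(self.hvg_indices, dtype=int)
        if len(self.hvg_indices) and (
                self.hvg_indices.min() < 0
                or self.hvg_indices.max() >= self.n_genes):
            raise ValueError("hvg_indices outside the gene range")
        if self.variance_inflation < 1:
            raise ValueError("variance_inflation must be >= 1")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")

    @property
    def n_groups(self) -> int:
        return len(self.cells_per_group)

    @property
    def n_genes(self) -> int:
        return self.group_mean_profiles.shape[0]


@dataclass
class RnaSimulation:
    """Outputs of :func:`simulate_expression`."""

    matrix: pd.DataFrame        # genes x cells, TPM
    truth_groups: pd.Series     # cell -> group index
    truth_hvg: list             # gene ids of truth highly variable genes


def make_rna_spec(seed: int, n_groups: int = 3,
                  cells_per_group: tuple[int, ...] | None = None,
                  n_genes: int = 500, n_hvg: int = 20,
                  group_shift: float = 2.0, n_marker: int = 30,
                  variance_inflation: float = 3.0,
                  noise_sd: float = 0.5,
                  dropout_rate: float = 0.3) -> RnaPopulationSpec:
    """Randomised population spec with realistic structure.

    Baseline gene means are uniform on [1, 11] log2 units; each group
    beyond the first shifts ``n_marker`` distinct marker genes by
    ``group_shift``; ``n_hvg`` genes with means in [5, 9] receive the
    inflated noise SD.  ``tpm_total`` is set to the expected raw column
    sum so that the TPM renormalisation leaves designed means in place.
    """
    rng = np.random.default_rng(seed)
    if cells_per_group is None:
        cells_per_group = tuple([50] * n_groups)
    base = rng.uniform(1.0, 11.0, size=n_genes)
    profiles = np.tile(base[:, None], (1, n_groups))
    free = rng.permutation(n_genes)
    used = 0
    for g in range(1, n_groups):
        markers = free[used:used + n_marker]
        used += n_marker
        sign = rng.choice([-1.0, 1.0], size=n_marker)
        profiles[markers, g] = np.clip(
            profiles[markers, g] + sign * group_shift, 0.0, None)
    candidates = np.setdiff1d(
        np.flatnonzero((base >= 5.0) & (base <= 9.0)), free[:used])
    if len(candidates) < n_hvg:
        raise ValueError("too few candidate genes for the HVG set")
    hvg = rng.choice(candidates, size=n_hvg, replace=False)
    if variance_inflation == 1.0:
        hvg = np.array([], dtype=int)
    tpm_total = float(np.sum(2.0**base - 1.0))
    return RnaPopulationSpec(
        cells_per_group=cells_per_group,
        group_mean_profiles=profiles,
        hvg_indices=hvg,
        variance_inflation=variance_inflation,
        noise_sd=noise_sd,
        dropout_rate=dropout_rate,
        tpm_total=tpm_total,
    )


def simulate_expression(spec: RnaPopulationSpec, seed: int
                        ) -> RnaSimulation:
    """Simulate a gene x cell TPM matrix with known groups and HVGs.

    Per cell and gene, log2 expression is the group mean plus Gaussian
    noise (SD multiplied by ``variance_inflation`` for the truth HVG
    set), back-transformed to TPM, zeroed with probability
    ``dropout_rate`` and column-normalised to ``tpm_total``.
    """
    rng = np.random.default_rng(seed)
    n_genes = spec.n_genes
    cells = []
    groups = []
    for g, n in enumerate(spec.cells_per_group):
        for i in range(n):
            cells.append(f"g{g}_cell{i:03d}")
            groups.append(g)
    n_cells = len(cells)
    group_arr = np.asarray(groups)
    means = spec.group_mean_profiles[:, group_arr]     # genes x cells
    sd = np.full(n_genes, spec.noise_sd)
    sd[spec.hvg_indices] = spec.noise_sd * spec.variance_inflation
    log = means + rng.standard_normal((n_genes, n_cells)) * sd[:, None]
    log = np.clip(log, 0.0, None)
    tpm = 2.0**log - 1.0
    if spec.dropout_rate > 0:
        p_drop = spec.dropout_rate / (
            1.0 + np.exp((log - spec.dropout_midpoint)
                         / spec.dropout_scale))
        drop = rng.random((n_genes, n_cells)) < p_drop
        tpm[drop] = 0.0
    colsum = tpm.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("a simulated cell has zero total expression")
    tpm = tpm / colsum * spec.tpm_total
    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    matrix = pd.DataFrame(tpm, index=gene_ids, columns=cells)
    truth_hvg = [gene_ids[i] for i in np.sort(spec.hvg_indices)]
    return RnaSimulation(
        matrix=matrix,
        truth_groups=pd.Series(group_arr, index=cells, name="group"),
        truth_hvg=truth_hvg,
    )


def simulate_cohort(group_centroids: pd.DataFrame,
                    n_samples_per_group,
                    noise_sd: float,
                    phenotype_odds,
                    seed: int
                    ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Simulate a bulk cohort around single-cell group centroids.

    Each sample is its group's centroid (log-scale expression over the
    shared HVG gene index) plus i.i.d. Gaussian noise; a binary phenotype
    label is drawn per sample with its group's probability.

    Returns (cohort genes x samples, truth group labels, binary labels).
    """
    rng = np.random.default_rng(seed)
    groups = list(group_centroids.columns)
    n_per = list(n_samples_per_group)
    odds = list(phenotype_odds)
    if not len(groups) == len(n_per) == len(odds):
        raise ValueError("per-group argument lengths must match")
    cols, labels, pheno, data = [], [], [], []
    for g, (grp, n, q) in enumerate(zip(groups, n_per, odds)):
        centroid = group_centroids[grp].to_numpy(dtype=float)
        noise = rng.standard_normal((len(centroid), n)) * noise_sd
        data.append(centroid[:, None] + noise)
        for i in range(n):
            cols.append(f"{grp}_s{i:03d}")
            labels.append(grp)
        pheno.extend(rng.random(n) < q)
    cohort = pd.DataFrame(np.concatenate(data, axis=1),
                          index=group_centroids.index, columns=cols)
    return (cohort,
            pd.Series(labels, index=cols, name="group"),
            pd.Series(pheno, index=cols, name="phenotype"))
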