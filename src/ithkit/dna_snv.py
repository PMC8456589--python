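"""Single-cell SNV calling at bulk-defined sites.

Single-cell whole-genome-amplified exome data are too error-prone for de
novo variant discovery, so calls are restricted to sites already called in
bulk sequencing of the same population.  At each site the candidate variant
is the non-reference base that maximises the Yates-corrected chi-square
statistic contrasting the cell's base counts with a matched background
(normal) sample; the candidate is retained when it clears minimum
variant-read-count and variant-allele-frequency thresholds and matches the
bulk-called allele.

A simplified bulk-site filter (Fisher's exact test of foreground vs
background allele counts plus a one-sided binomial test that the allele
frequency exceeds a floor) stands in for a full production bulk caller; an
externally produced bulk site list can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

BASES = ("A", "C", "G", "T")

__all__ = [
    "BASES",
    "ScSnvParams",
    "yates_chi2",
    "call_single_cell_snvs",
    "simple_bulk_site_filter",
    "estimate_fp_rate",
]


@dataclass
class ScSnvParams:
    """Thresholds for single-cell SNV calling.

    min_variant_count
        Minimum variant-supporting reads in the cell (default 2).
    min_vaf
        Minimum variant allele frequency in the cell (default 0.02).
    restrict_to_bulk
        When True (default) the final call set is intersected with the
        bulk-called site list on (chrom, pos, alt).
    """

    min_variant_count: int = 2
    min_vaf: float = 0.02
    restrict_to_bulk: bool = True

    def __post_init__(self) -> None:
        if self.min_variant_count < 1:
            raise ValueError("min_variant_count must be >= 1")
        if not 0 < self.min_vaf < 1:
            raise ValueError("min_vaf must be in (0, 1)")


def yates_chi2(cell_variant: float, cell_ref: float,
               bg_variant: float, bg_ref: float) -> float:
    """Yates continuity-corrected chi-square statistic for a 2x2 table.

    The table contrasts variant vs reference reads in the cell against the
    background sample::

        chi2 = N * max(|ad - bc| - N/2, 0)^2 / (r1 * r2 * c1 * c2)

    Returns 0 when any marginal total is zero.
    """
    a, b, c, d = cell_variant, cell_ref, bg_variant, bg_ref
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if r1 == 0 or r2 == 0:
        raise ValueError("both row sums must be positive")
    if c1 == 0 or c2 == 0:
        return 0.0
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    return n * num * num / (r1 * r2 * c1 * c2)


def _check_pileup(pileup: pd.DataFrame, name: str) -> pd.DataFrame:
    required = {"chrom", "pos", "ref", "A", "C", "G", "T"}
    missing = required - set(pileup.columns)
    if missing:
        raise ValueError(f"{name} pileup missing columns: {sorted(missing)}")
    out = pileup.copy()
    if "depth" not in out.columns:
        out["depth"] = out[list(BASES)].sum(axis=1)
    return out


def call_single_cell_snvs(cell: pd.DataFrame, background: pd.DataFrame,
                          bulk_sites: pd.DataFrame | None = None,
                          params: ScSnvParams | None = None) -> pd.DataFrame:
    """Call SNVs in one cell's pileup against a background pileup.

    Parameters
    ----------
    cell, background
        Pileup tables with columns ``chrom, pos, ref, A, C, G, T[, depth]``
        of high-quality base counts.  Every cell site must be present in the
        background.
    bulk_sites
        Bulk-called sites with columns ``chrom, pos, ref, alt``; required
        when ``params.restrict_to_bulk``.
    params
        :class:`ScSnvParams`.

    Returns
    -------
    DataFrame with columns ``chrom, pos, ref, alt, variant_count, depth,
    vaf, chi2_yates`` -- one row per called site.
    """
    params = params or ScSnvParams()
    cell = _check_pileup(cell, "cell")
    background = _check_pileup(background, "background")
    if params.restrict_to_bulk and bulk_sites is None:
        raise ValueError("bulk_sites required when restrict_to_bulk is set")

    bg = background.set_index(["chrom", "pos"])
    if bg.index.has_duplicates:
        raise ValueError("duplicate (chrom, pos) in background pileup")
    records = []
    for row in cell.itertuples(index=False):
        key = (row.chrom, row.pos)
        if key not in bg.index:
            raise ValueError(f"site {key} absent from background pileup")
        bgrow = bg.loc[key]
        ref = row.ref
        cell_counts = {b: getattr(row, b) for b in BASES}
        cell_ref = cell_counts[ref]
        depth = sum(cell_counts.values())
        if depth == 0:
            continue
        best = None
        # alphabetical base order breaks chi2 ties deterministically
        for alt in BASES:
            if alt == ref:
                continue
            bg_alt, bg_ref = float(bgrow[alt]), float(bgrow[ref])
            if cell_counts[alt] + cell_ref == 0 or bg_alt + bg_ref == 0:
                stat = 0.0
            else:
                stat = yates_chi2(cell_counts[alt], cell_ref, bg_alt, bg_ref)
            if best is None or stat > best[1]:
                best = (alt, stat)
        alt, stat = best
        vc = cell_counts[alt]
        vaf = vc / depth
        if vc >= params.min_variant_count and vaf >= params.min_vaf:
            records.append((row.chrom, row.pos, ref, alt, int(vc),
                            int(depth), vaf, stat))

    calls = pd.DataFrame(records, columns=[
        "chrom", "pos", "ref", "alt", "variant_count", "depth", "vaf",
        "chi2_yates"])
    if params.restrict_to_bulk and len(calls):
        keys = set(zip(bulk_sites["chrom"], bulk_sites["pos"],
                       bulk_sites["alt"]))
        keep = [
            (c, p, a) in keys
            for c, p, a in zip(calls["chrom"], calls["pos"], calls["alt"])
        ]
        calls = calls.loc[keep].reset_index(drop=True)
    return calls


def simple_bulk_site_filter(fore: pd.DataFrame, background: pd.DataFrame,
                            alpha_fisher: float,
                            af_floor: float = 0.01) -> pd.DataFrame:
    """Two-test bulk SNV site filter.

    Retains sites where (a) a two-sided Fisher's exact test of foreground
    variant/reference counts against the background is significant at
    ``alpha_fisher`` and (b) a one-sided binomial test rejects
    ``AF <= af_floor`` at p < 0.05.  The candidate variant at each site is
    the non-reference base maximising the Yates chi-square against the
    background, mirroring the single-cell caller.

    Returns a DataFrame ``chrom, pos, ref, alt, vaf, p_fisher, p_binom``.
    """
    fore = _check_pileup(fore, "fore")
    background = _check_pileup(background, "background")
    bg = background.set_index(["chrom", "pos"])
    records = []
    for row in fore.itertuples(index=False):
        key = (row.chrom, row.pos)
        if key not in bg.index:
            raise ValueError(f"site {key} absent from background pileup")
        bgrow = bg.loc[key]
        depth = sum(getattr(row, b) for b in BASES)
        if depth == 0:
            continue
        ref = row.ref
        best = None
        for alt in BASES:
            if alt == ref:
                continue
            bg_alt, bg_ref = float(bgrow[alt]), float(bgrow[ref])
            fg_alt, fg_ref = getattr(row, alt), getattr(row, ref)
            if fg_alt + fg_ref == 0 or bg_alt + bg_ref == 0:
                stat = 0.0
            else:
                stat = yates_chi2(fg_alt, fg_ref, bg_alt, bg_ref)
            if best is None or stat > best[1]:
                best = (alt, stat)
        alt = best[0]
        vc = getattr(row, alt)
        table = [[vc, getattr(row, ref)],
                 [int(bgrow[alt]), int(bgrow[ref])]]
        p_fisher = float(stats.fisher_exact(table, alternative="two-sided")[1])
        p_binom = float(stats.binomtest(int(vc), int(depth), af_floor,
                                        alternative="greater").pvalue)
        if p_fisher < alpha_fisher and p_binom < 0.05:
            records.append((row.chrom, row.pos, ref, alt, vc / depth,
                            p_fisher, p_binom))
    return pd.DataFrame(records, columns=[
        "chrom", "pos", "ref", "alt", "vaf", "p_fisher", "p_binom"])


def estimate_fp_rate(cross_individual_call_rate,
                     half_split_call_rate,
                     sc_callable_fraction) -> dict:
    """False-positive-rate interval estimation for bulk and single cells.

    Parameters
    ----------
    cross_individual_call_rate, half_split_call_rate
        Per-position call rates, one per sample pair; the bulk FP interval
        is [min, max] of their pairwise sums.
    sc_callable_fraction
        (low, high) fraction of chromosomal positions callable in single
        cells; the single-cell interval scales the bulk interval by these
        bounds (single-cell calls are restricted to bulk-called sites, so
        the single-cell rate cannot exceed the bulk rate).

    Returns
    -------
    dict with ``bulk`` and ``single_cell`` (low, high) tuples, per
    chromosomal position.
    """
    cross = np.atleast_1d(np.asarray(cross_individual_call_rate, dtype=float))
    half = np.atleast_1d(np.asarray(half_split_call_rate, dtype=float))
    if cross.shape != half.shape:
        raise ValueError("rate arrays must have identical shapes")
    if (cross < 0).any() or (half < 0).any():
        raise ValueError("rates must be non-negative")
    frac = np.atleast_1d(np.asarray(sc_callable_fraction, dtype=float))
    if (frac < 0).any() or (frac > 1).any():
        raise ValueError("callable fraction must lie in [0, 1]")
    totals = cross + half
    bulk = (float(totals.min()), float(totals.max()))
    sc = (bulk[0] * float(frac.min()), bulk[1] * float(frac.max()))
    return {"bulk": bulk, "single_cell": sc}
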