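"""Copy-number and coverage-uniformity summaries.

The average copy number (ACN) condenses a set of copy-number-altered (CNA)
segments, each with a log2 tumour/normal depth ratio, into a single
genome-wide ploidy-like value::

    ACN = 2 * { 2^( sum(log2Ri * Li) / sum(Li) ) * (sum(Li) / GL)
                + (1 - sum(Li) / GL) }

where ``log2Ri`` and ``Li`` are the log-ratio and length of segment *i* and
``GL`` is the genome length.  Regions outside any called segment are assumed
diploid.  Coverage uniformity of (single-cell) sequencing is summarised by
the Lorenz curve of per-site read depths and its Gini coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AcnParams",
    "GENOME_LENGTH_MOUSE",
    "GENOME_LENGTH_HUMAN",
    "average_copy_number",
    "lorenz_gini",
]

#: Genome-length constants used for the ACN denominator.  They are the
#: conventional round figures for the two species, deliberately generous
#: relative to assembly sizes; both are configurable through AcnParams.
GENOME_LENGTH_MOUSE = 50e9
GENOME_LENGTH_HUMAN = 40e9


@dataclass
class AcnParams:
    """Parameters for :func:`average_copy_number`.

    genome_length
        ``GL`` in bases.  Defaults to the mouse constant (50 Gb); use
        :data:`GENOME_LENGTH_HUMAN` (40 Gb) for human segment sets.
    """

    genome_length: float = GENOME_LENGTH_MOUSE

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")


def _as_segment_frame(segments) -> pd.DataFrame:
    seg = pd.DataFrame(segments)
    required = {"chrom", "start", "end", "log2_ratio"}
    missing = required - set(seg.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    if (seg["end"] < seg["start"]).any():
        bad = seg.loc[seg["end"] < seg["start"]]
        raise ValueError(f"segment with end < start:\n{bad}")
    return seg


def _check_no_overlap(seg: pd.DataFrame) -> None:
    for _, sub in seg.groupby("chrom"):
        sub = sub.sort_values("start")
        prev_end = None
        for start, end in zip(sub["start"], sub["end"]):
            if prev_end is not None and start <= prev_end:
                raise ValueError(
                    f"overlapping segments on {sub['chrom'].iloc[0]} "
                    f"around position {start}"
                )
            prev_end = end


def average_copy_number(segments, params: AcnParams | None = None) -> float:
    """Average copy number from CNA segments (1-based inclusive coordinates).

    Parameters
    ----------
    segments
        DataFrame-like with columns ``chrom, start, end, log2_ratio``.
        Segments must not overlap; their total length must not exceed the
        genome length.  An empty segment set returns 2.0 (fully diploid).
    params
        :class:`AcnParams`; defaults to the mouse genome length.

    Returns
    -------
    float
        The length-weighted average copy number.
    """
    params = params or AcnParams()
    seg = _as_segment_frame(segments)
    if len(seg) == 0:
        return 2.0
    _check_no_overlap(seg)
    lengths = (seg["end"] - seg["start"] + 1).to_numpy(dtype=float)
    total = lengths.sum()
    if total > params.genome_length:
        raise ValueError(
            f"total segment length {total:.3g} exceeds genome length "
            f"{params.genome_length:.3g}"
        )
    mean_log2 = float(np.sum(seg["log2_ratio"].to_numpy() * lengths) / total)
    frac = total / params.genome_length
    return 2.0 * (2.0**mean_log2 * frac + (1.0 - frac))


def lorenz_gini(depths) -> tuple[pd.DataFrame, float]:
    """Lorenz curve and Gini coefficient of per-site read depths.

    The curve is the cumulative share of reads against the cumulative share
    of sites, after sorting sites by depth; the Gini coefficient is
    ``1 - 2 * area`` under the curve (trapezoid rule over the n+1 points).
    A Gini of 0 means perfectly uniform coverage; values near 1 indicate
    that a few sites absorb almost all reads.

    Returns
    -------
    (DataFrame with columns ``frac_sites, frac_reads``, float Gini)
    """
    x = np.asarray(depths, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("depths must be a non-empty 1-D array")
    if (x < 0).any():
        raise ValueError("depths must be non-negative")
    if not (x > 0).any():
        raise ValueError("all depths are zero; Lorenz curve undefined")
    x = np.sort(x)
    n = x.size
    cum = np.concatenate([[0.0], np.cumsum(x)]) / x.sum()
    frac_sites = np.arange(n + 1) / n
    curve = pd.DataFrame({"frac_sites": frac_sites, "frac_reads": cum})
    area = float(np.trapezoid(cum, frac_sites))
    gini = max(1.0 - 2.0 * area, 0.0)  # trapezoid round-off can dip below 0
    return curve, gini
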