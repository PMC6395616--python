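"""Weighted methylation levels, metagene profiles and group comparisons.

All levels are *weighted*: summed methylated read counts divided by summed
total counts over the covered cytosines of one context (CG/CHG/CHH) in a
region — never a mean of per-cytosine ratios.  Metagene profiles pool counts
across genes the same way (sum of counts per bin, then one division), over a
fixed-width 3-kb flank grid and a length-scaled gene body, oriented 5'→3' so
minus-strand genes are flipped onto the transcription axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from paleofrac.io_formats import FormatError, MethylationTable
from paleofrac.stats import TestResult, mann_whitney_u

CONTEXTS = ("CG", "CHG", "CHH")
REGIONS = ("upstream", "body", "downstream")


@dataclass
class RegionMethylation:
    gene_id: str
    region: str
    context: str
    level: float
    covered_cytosines: int


@dataclass
class MetageneProfile:
    """Binned pooled methylation over upstream flank, body and downstream."""

    context: str
    levels: np.ndarray  # length n_upstream + body_bins + n_downstream
    n_genes: int
    flank: int
    flank_bin: int
    body_bins: int

    @property
    def n_flank_bins(self) -> int:
        return self.flank // self.flank_bin

    @property
    def upstream(self) -> np.ndarray:
        return self.levels[: self.n_flank_bins]

    @property
    def body(self) -> np.ndarray:
        return self.levels[self.n_flank_bins : self.n_flank_bins + self.body_bins]

    @property
    def downstream(self) -> np.ndarray:
        return self.levels[self.n_flank_bins + self.body_bins :]


# ---------------------------------------------------------------------------
# Replicate pooling
# ---------------------------------------------------------------------------


def pool_replicates(tables: Sequence[MethylationTable]) -> MethylationTable:
    """Sum counts per (chromosome, position, strand) across replicates.

    Sites present in only one replicate are carried through; a site reported
    with different contexts in different replicates is an error.
    """
    df = pd.concat([t.df for t in tables], ignore_index=True)
    grouped = df.groupby(["chromosome", "position", "strand"], sort=True)
    ctx = grouped["context"].nunique()
    if (ctx > 1).any():
        bad = ctx[ctx > 1].index[0]
        raise FormatError(f"conflicting context at site {bad}")
    pooled = grouped.agg(
        context=("context", "first"),
        count_methylated=("count_methylated", "sum"),
        count_total=("count_total", "sum"),
    ).reset_index()
    return MethylationTable(pooled)


# ---------------------------------------------------------------------------
# Indexed count sums
# ---------------------------------------------------------------------------


class MethylationIndex:
    """Cumulative-count index over a methylation table for fast region sums.

    Positions stay 1-based as in the CX dialect; queries take internal
    0-based half-open intervals and convert here.  Cytosines with
    ``count_total < min_total`` are excluded at construction.
    """

    def __init__(self, table: MethylationTable, min_total: int = 1):
        self.min_total = min_total
        self._index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        df = table.df[table.df["count_total"] >= min_total]
        for (chrom, context), sub in df.groupby(["chromosome", "context"], sort=True):
            sub = sub.sort_values("position")
            pos = sub["position"].to_numpy()
            cum_m = np.concatenate([[0], np.cumsum(sub["count_methylated"].to_numpy())])
            cum_t = np.concatenate([[0], np.cumsum(sub["count_total"].to_numpy())])
            self._index[(chrom, context)] = (pos, cum_m, cum_t)

    def region_counts(
        self, chromosome: str, context: str, start: int, end: int
    ) -> tuple[int, int, int]:
        """(methylated, total, n_cytosines) in 0-based half-open [start, end)."""
        entry = self._index.get((chromosome, context))
        if entry is None:
            return 0, 0, 0
        pos, cum_m, cum_t = entry
        i = np.searchsorted(pos, start + 1, side="left")
        j = np.searchsorted(pos, end, side="right")
        return int(cum_m[j] - cum_m[i]), int(cum_t[j] - cum_t[i]), int(j - i)

    def edge_counts(
        self, chromosome: str, context: str, edges: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-bin (methylated, total) sums for consecutive 0-based edges."""
        entry = self._index.get((chromosome, context))
        if entry is None:
            n = len(edges) - 1
            return np.zeros(n), np.zeros(n)
        pos, cum_m, cum_t = entry
        idx = np.searchsorted(pos, edges + 1, side="left")
        return np.diff(cum_m[idx]), np.diff(cum_t[idx])


def _as_index(meth, min_total: int) -> MethylationIndex:
    if isinstance(meth, MethylationIndex):
        return meth
    return MethylationIndex(meth, min_total=min_total)


def weighted_methylation(
    meth: MethylationTable | MethylationIndex,
    gene_id: str,
    chromosome: str,
    start: int,
    end: int,
    context: str,
    region: str = "body",
    min_total: int = 1,
) -> RegionMethylation | None:
    """Weighted methylation level of one interval, or None when uncovered."""
    index = _as_index(meth, min_total)
    m, t, n = index.region_counts(chromosome, context, start, end)
    if t == 0:
        return None
    return RegionMethylation(gene_id, region, context, m / t, n)


def _region_interval(row, region: str, flank: int) -> tuple[int, int]:
    if region == "body":
        return row.start, row.end
    if (region == "upstream") == (row.strand == "+"):
        return row.start - flank, row.start
    return row.end, row.end + flank


def region_levels(
    genes: pd.DataFrame,
    meth: MethylationTable | MethylationIndex,
    context: str,
    region: str,
    flank: int = 3000,
    min_total: int = 1,
) -> pd.Series:
    """Per-gene weighted level of one region/context; uncovered genes NaN.

    ``genes`` needs columns gene_id, chromosome, start, end, strand.  Regions
    are transcription-oriented: "upstream" is 5' of the TSS on the gene's
    strand.
    """
    index = _as_index(meth, min_total)
    out = {}
    for row in genes.itertuples(index=False):
        lo, hi = _region_interval(row, region, flank)
        m, t, _ = index.region_counts(row.chromosome, context, max(lo, 0), hi)
        out[row.gene_id] = m / t if t > 0 else np.nan
    return pd.Series(out, name=f"{context}_{region}")


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------


def metagene_profile(
    genes: pd.DataFrame,
    meth: MethylationTable | MethylationIndex,
    context: str,
    flank: int = 3000,
    flank_bin: int = 100,
    body_bins: int = 40,
    min_total: int = 1,
) -> MetageneProfile:
    """Pooled-count metagene profile over flank/body/flank bins.

    Per gene, the upstream and downstream flanks are cut into fixed
    ``flank_bin``-bp bins and the body into ``body_bins`` equal-width slices;
    counts are summed over genes per bin (a minus-strand gene's bin order is
    flipped so bins run TSS→TTS), and each bin's level is the pooled
    methylated/total ratio.
    """
    index = _as_index(meth, min_total)
    n_flank = flank // flank_bin
    n_bins = 2 * n_flank + body_bins
    meth_sum = np.zeros(n_bins)
    total_sum = np.zeros(n_bins)
    n_genes = 0
    for row in genes.itertuples(index=False):
        left = row.start - flank + flank_bin * np.arange(n_flank + 1, dtype=float)
        body = np.linspace(row.start, row.end, body_bins + 1)
        right = row.end + flank_bin * np.arange(n_flank + 1, dtype=float)
        edges = np.concatenate([left, body[1:], right[1:]])
        m, t = index.edge_counts(row.chromosome, context, edges)
        if row.strand == "-":
            m, t = m[::-1], t[::-1]
        meth_sum += m
        total_sum += t
        n_genes += 1
    with np.errstate(invalid="ignore"):
        levels = np.where(total_sum > 0, meth_sum / np.maximum(total_sum, 1), np.nan)
    return MetageneProfile(
        context=context,
        levels=levels,
        n_genes=n_genes,
        flank=flank,
        flank_bin=flank_bin,
        body_bins=body_bins,
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def compare_region_methylation(
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    region: str,
    context: str,
    meth: MethylationTable | MethylationIndex,
    flank: int = 3000,
    min_total: int = 1,
) -> TestResult:
    """Mann-Whitney U on per-gene region levels of two gene groups.

    Genes without coverage in the region are dropped; each group must retain
    at least 3 genes.
    """
    index = _as_index(meth, min_total)
    a = region_levels(genes_a, index, context, region, flank, min_total).dropna()
    b = region_levels(genes_b, index, context, region, flank, min_total).dropna()
    if len(a) < 3 or len(b) < 3:
        raise ValueError(
            f"too few covered genes for {context} {region}: {len(a)} vs {len(b)}"
        )
    return mann_whitney_u(a.to_numpy(), b.to_numpy())
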