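"""Reconstruction of the two post-WGD subgenomes against an outgroup.

Convention used throughout: genome A (the ``query``/``gene_a`` side of hits
and blocks) is the duplicated genome; genome B is the unduplicated outgroup.

Each outgroup chromosome is tiled into segments by the footprints of the
recent (ancient-WGD-free) syntenic blocks; a segment covered by two duplicated
-genome blocks is a homologous region pair.  Within each pair, outgroup genes
retained in only one region are singletons of that region, genes retained in
both yield a homeolog pair, and the region with MORE singletons is labelled
subgenome 1 (ties: more retained genes in total, then the lexicographically
smaller duplicated-genome chromosome name).

Labels are assigned per region pair, so "subgenome 1" is not claimed to be a
single ancestral haplotype genome-wide: it is, per region, the more
fractionation-scarred copy as measured by surviving singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from paleofrac.io_formats import GeneTable
from paleofrac.synteny import SyntenicBlock

logger = logging.getLogger(__name__)

LABELS = ("subgenome1", "subgenome2", "unassigned")


@dataclass
class RegionPair:
    """Two duplicated-genome regions tied to one outgroup segment."""

    outgroup_chrom: str
    interval: tuple[int, int]  # outgroup gene-rank interval, half-open
    region_1: SyntenicBlock | None
    region_2: SyntenicBlock | None
    # filled by count_singletons
    singleton_counts: tuple[int, int] = (0, 0)
    n_homeologs: int = 0
    n_lost: int = 0
    singletons: list[tuple[str, int, str]] = field(default_factory=list)  # (dup_gene, region, out_gene)
    homeolog_pairs: list[tuple[str, str, str]] = field(default_factory=list)  # (dup1, dup2, out_gene)
    labels: tuple[str, str] | None = None  # label of region_1, region_2

    @property
    def n_outgroup_genes(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class SubgenomeAssignment:
    """Per-gene subgenome labels plus the per-outgroup-gene retention table.

    ``genes``: indexed by duplicated-genome gene id with columns label
    (subgenome1/subgenome2/unassigned), gene_class (singleton/homeolog),
    partner (homeolog partner or None), outgroup_anchor, outgroup_chrom,
    high_confidence.  ``retention``: one row per outgroup gene with boolean
    retained_sg1 / retained_sg2 columns, the backbone of the fractionation
    statistics.
    """

    genes: pd.DataFrame
    retention: pd.DataFrame
    region_pairs: list[RegionPair]

    def counts(self) -> dict[str, int]:
        g = self.genes
        singles = g[g["gene_class"] == "singleton"]
        return {
            "singletons_sg1": int((singles["label"] == "subgenome1").sum()),
            "singletons_sg2": int((singles["label"] == "subgenome2").sum()),
            "homeolog_pairs": int((g["gene_class"] == "homeolog").sum()) // 2,
            "unassigned": int((g["label"] == "unassigned").sum()),
            "high_confidence": int(g["high_confidence"].sum()),
        }


# ---------------------------------------------------------------------------
# Region pairing
# ---------------------------------------------------------------------------


def pair_homologous_regions(recent_blocks: Sequence[SyntenicBlock]) -> list[RegionPair]:
    """Tile outgroup chromosomes by block footprints into region pairs.

    Breakpoints are the footprint boundaries of every block on the chromosome;
    consecutive elementary intervals with an identical covering-block set are
    merged.  Segments covered by two blocks become full pairs; segments
    covered once get ``region_2 = None``; more than two covering blocks keeps
    the top two by chain score and logs the conflict.
    """
    by_chrom: dict[str, list[SyntenicBlock]] = {}
    for b in recent_blocks:
        by_chrom.setdefault(b.chrom_b, []).append(b)

    pairs: list[RegionPair] = []
    for chrom in sorted(by_chrom):
        blocks = by_chrom[chrom]
        foot = [(b.span_b()[0], b.span_b()[1] + 1, b) for b in blocks]
        points = sorted({p for lo, hi, _ in foot for p in (lo, hi)})
        segments: list[tuple[int, int, tuple]] = []
        for lo, hi in zip(points, points[1:]):
            cover = tuple(
                sorted(
                    (b for flo, fhi, b in foot if flo <= lo and fhi >= hi),
                    key=lambda b: (-b.score, b.chrom_a, b.span_a()[0]),
                )
            )
            if not cover:
                continue
            if segments and segments[-1][1] == lo and segments[-1][2] == cover:
                segments[-1] = (segments[-1][0], hi, cover)
            else:
                segments.append((lo, hi, cover))
        for lo, hi, cover in segments:
            if len(cover) > 2:
                logger.info(
                    "outgroup %s[%d:%d): %d covering regions, keeping top 2 by score",
                    chrom,
                    lo,
                    hi,
                    len(cover),
                )
                cover = cover[:2]
            r1 = cover[0]
            r2 = cover[1] if len(cover) > 1 else None
            pairs.append(RegionPair(chrom, (lo, hi), r1, r2))
    return pairs


def build_block_anchor_index(
    blocks: Sequence[SyntenicBlock],
) -> dict[int, dict[int, tuple[str, str]]]:
    """Map id(block) -> {outgroup gene rank -> (outgroup gene, dup gene)}."""
    index: dict[int, dict[int, tuple[str, str]]] = {}
    for b in blocks:
        index[id(b)] = {p.order_b: (p.gene_b, p.gene_a) for p in b.pairs}
    return index


# ---------------------------------------------------------------------------
# Singleton counting
# ---------------------------------------------------------------------------


def count_singletons(
    pair: RegionPair,
    anchor_index: Mapping[int, Mapping[int, tuple[str, str]]],
    outgroup: GeneTable,
    dup_tandem: set[str] = frozenset(),
    outgroup_tandem: set[str] = frozenset(),
) -> tuple[int, int]:
    """Classify every outgroup gene in the pair's segment and count singletons.

    An outgroup gene retained only in region 1 increments n1, only in region 2
    increments n2, in both it forms a homeolog candidate, in neither it is
    lost-in-both.  Tandem-array genes (either genome) are excluded before
    counting.  The classification is stored on the pair and (n1, n2) returned.
    """
    a1 = anchor_index.get(id(pair.region_1), {}) if pair.region_1 is not None else {}
    a2 = anchor_index.get(id(pair.region_2), {}) if pair.region_2 is not None else {}
    chrom_genes = outgroup.genes_on(pair.outgroup_chrom)
    lo, hi = pair.interval
    n1 = n2 = n_hom = n_lost = 0
    singles: list[tuple[str, int, str]] = []
    homs: list[tuple[str, str, str]] = []
    for row in chrom_genes.iloc[lo:hi].itertuples(index=False):
        if row.gene_id in outgroup_tandem:
            continue
        hit1 = a1.get(row.order_index)
        hit2 = a2.get(row.order_index)
        if hit1 is not None and hit1[1] in dup_tandem:
            hit1 = None
        if hit2 is not None and hit2[1] in dup_tandem:
            hit2 = None
        if hit1 and hit2:
            n_hom += 1
            homs.append((hit1[1], hit2[1], row.gene_id))
        elif hit1:
            n1 += 1
            singles.append((hit1[1], 1, row.gene_id))
        elif hit2:
            n2 += 1
            singles.append((hit2[1], 2, row.gene_id))
        else:
            n_lost += 1
    pair.singleton_counts = (n1, n2)
    pair.n_homeologs = n_hom
    pair.n_lost = n_lost
    pair.singletons = singles
    pair.homeolog_pairs = homs
    return n1, n2


def region_order_key(n_singletons: int, n_retained: int, chrom_name: str):
    """Sort key making the subgenome-1 region first.

    More singletons wins; ties go to more retained genes in total, then to the
    lexicographically smaller duplicated-genome chromosome name.
    """
    return (-n_singletons, -n_retained, chrom_name)


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------


def assign_subgenomes(
    pairs: Sequence[RegionPair], outgroup: GeneTable
) -> SubgenomeAssignment:
    """Label region pairs and genes by the singleton-count rule.

    Pairs with both regions are labelled directly.  A pair whose segment is
    covered by a single block inherits that block's label from the pair where
    the block was paired (largest shared segment wins); blocks never paired
    anywhere stay unassigned.
    """
    # first pass: label two-region pairs
    block_votes: dict[int, list[tuple[int, str]]] = {}
    for pair in pairs:
        if pair.region_2 is None:
            continue
        n1, n2 = pair.singleton_counts
        ret1 = n1 + pair.n_homeologs
        ret2 = n2 + pair.n_homeologs
        key1 = region_order_key(n1, ret1, pair.region_1.chrom_a)
        key2 = region_order_key(n2, ret2, pair.region_2.chrom_a)
        if key1 <= key2:
            pair.labels = ("subgenome1", "subgenome2")
        else:
            pair.labels = ("subgenome2", "subgenome1")
        for region, lab in zip((pair.region_1, pair.region_2), pair.labels):
            block_votes.setdefault(id(region), []).append((pair.n_outgroup_genes, lab))

    block_label = {
        bid: max(votes)[1] for bid, votes in block_votes.items()
    }
    for pair in pairs:
        if pair.region_2 is None:
            lab = block_label.get(id(pair.region_1), "unassigned")
            pair.labels = (lab, "unassigned")

    # second pass: gene records and outgroup retention flags
    gene_rows: dict[str, dict] = {}
    out_df = outgroup.df.copy()
    retained_sg1 = np.zeros(len(out_df), dtype=bool)
    retained_sg2 = np.zeros(len(out_df), dtype=bool)
    out_row = {
        (c, o): i
        for i, (c, o) in enumerate(zip(out_df["chromosome"], out_df["order_index"]))
    }

    def mark(chrom: str, out_gene: str, label: str) -> None:
        i = out_row.get((chrom, _order_of(outgroup, out_gene)))
        if i is None:
            return
        if label == "subgenome1":
            retained_sg1[i] = True
        elif label == "subgenome2":
            retained_sg2[i] = True

    for pair in pairs:
        lab1, lab2 = pair.labels if pair.labels else ("unassigned", "unassigned")
        for dup_gene, region, out_gene in pair.singletons:
            lab = lab1 if region == 1 else lab2
            _add_gene(gene_rows, dup_gene, lab, "singleton", None, out_gene, pair.outgroup_chrom)
            mark(pair.outgroup_chrom, out_gene, lab)
        for dup1, dup2, out_gene in pair.homeolog_pairs:
            mark(pair.outgroup_chrom, out_gene, lab1)
            mark(pair.outgroup_chrom, out_gene, lab2)
            if dup1 in gene_rows or dup2 in gene_rows:
                # a gene already classified via another segment (possible only
                # through spurious multi-anchor chains); keep partner links mutual
                continue
            _add_gene(gene_rows, dup1, lab1, "homeolog", dup2, out_gene, pair.outgroup_chrom)
            _add_gene(gene_rows, dup2, lab2, "homeolog", dup1, out_gene, pair.outgroup_chrom)

    genes = pd.DataFrame.from_dict(gene_rows, orient="index")
    if genes.empty:
        genes = pd.DataFrame(
            columns=["label", "gene_class", "partner", "outgroup_anchor", "outgroup_chrom", "high_confidence"]
        )
    genes.index.name = "gene_id"
    retention = out_df[["gene_id", "chromosome", "order_index"]].copy()
    retention["retained_sg1"] = retained_sg1
    retention["retained_sg2"] = retained_sg2
    return SubgenomeAssignment(genes=genes, retention=retention, region_pairs=list(pairs))


def _order_of(outgroup: GeneTable, gene_id: str) -> int:
    return outgroup.position(gene_id)[1]


def _add_gene(rows, gene_id, label, gene_class, partner, out_gene, out_chrom) -> None:
    if gene_id in rows:
        return  # a duplicated gene is counted once (first covering pair wins)
    rows[gene_id] = {
        "label": label,
        "gene_class": gene_class,
        "partner": partner,
        "outgroup_anchor": out_gene,
        "outgroup_chrom": out_chrom,
        "high_confidence": False,
    }


# ---------------------------------------------------------------------------
# High-confidence flags
# ---------------------------------------------------------------------------


def flag_high_confidence(
    assignment: SubgenomeAssignment, second_outgroup_blocks: Sequence[SyntenicBlock]
) -> SubgenomeAssignment:
    """Flag genes that are also anchored in a second-outgroup block.

    A duplicated-genome gene is high-confidence when it has a syntenic
    counterpart in both outgroups: it is already anchored in the first
    outgroup (it is in the assignment) and appears as an anchor in at least
    one filtered block against the second outgroup.
    """
    anchored = {p.gene_a for b in second_outgroup_blocks for p in b.pairs}
    assignment.genes["high_confidence"] = [
        g in anchored for g in assignment.genes.index
    ]
    return assignment


def singleton_table(assignment: SubgenomeAssignment) -> pd.DataFrame:
    g = assignment.genes
    out = g[g["gene_class"] == "singleton"].reset_index()
    return out[["gene_id", "label", "outgroup_anchor", "high_confidence"]]


def homeolog_table(assignment: SubgenomeAssignment) -> pd.DataFrame:
    g = assignment.genes
    rows = []
    seen = set()
    for gene_id, row in g[g["gene_class"] == "homeolog"].iterrows():
        key = tuple(sorted((gene_id, row["partner"])))
        if key in seen:
            continue
        seen.add(key)
        g1, g2 = (
            (gene_id, row["partner"])
            if row["label"] == "subgenome1"
            else (row["partner"], gene_id)
        )
        hc = bool(g.loc[g1, "high_confidence"] and g.loc[g2, "high_confidence"])
        rows.append(
            {
                "gene_sg1": g1,
                "gene_sg2": g2,
                "outgroup_anchor": row["outgroup_anchor"],
                "high_confidence": hc,
            }
        )
    return pd.DataFrame(rows, columns=["gene_sg1", "gene_sg2", "outgroup_anchor", "high_confidence"])
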