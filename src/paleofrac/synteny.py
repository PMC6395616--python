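"""Collinear block detection, tandem classification and synteny statistics.

The chainer is a documented dynamic-programming implementation of the classic
anchor-chaining parameter semantics (match_score, match_size, gap_penalty,
overlap_window, max_gaps): extending a chain earns ``match_score`` and pays
``gap_penalty`` per unit of gene-rank gap on either genome, extension is
forbidden when either gap exceeds ``max_gaps``, and chains with fewer than
``match_size`` anchor pairs are discarded.  Both orientations (collinear and
inverted) are searched.  Pipelines that already have MCScanX ``.collinearity``
output can bypass the chainer via :func:`paleofrac.io_formats.read_collinearity`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from paleofrac.io_formats import GeneTable, HitRecord

logger = logging.getLogger(__name__)

#: numerical floor for the multiplicative block E-value surrogate
BLOCK_EVALUE_FLOOR = 1e-300


class AnchorPair(NamedTuple):
    """One collinear gene pair (a dot in a synteny dot plot)."""

    gene_a: str
    gene_b: str
    evalue: float
    chrom_a: str | None
    order_a: int | None
    chrom_b: str | None
    order_b: int | None


@dataclass(eq=False)  # identity semantics: blocks are mutable and indexed by id
class SyntenicBlock:
    """A chained run of anchor pairs between two genomic regions."""

    pairs: list[AnchorPair]
    chrom_a: str
    chrom_b: str
    score: float
    block_evalue: float
    orientation: str  # 'same' or 'inverted'
    median_ks: float | None = None
    block_id: int | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    def span_a(self) -> tuple[int, int]:
        """(min, max) gene-rank footprint on genome A, inclusive."""
        orders = [p.order_a for p in self.pairs]
        return min(orders), max(orders)

    def span_b(self) -> tuple[int, int]:
        orders = [p.order_b for p in self.pairs]
        return min(orders), max(orders)

    def genes_a(self) -> list[str]:
        return [p.gene_a for p in self.pairs]

    def genes_b(self) -> list[str]:
        return [p.gene_b for p in self.pairs]


@dataclass
class ChainParams:
    """Anchor-chaining parameters (defaults are the standard published set)."""

    match_score: float = 50.0
    match_size: int = 5
    gap_penalty: float = -1.0
    overlap_window: int = 5
    max_gaps: int = 25
    evalue_cutoff: float = 1e-5

    def __post_init__(self) -> None:
        if self.match_size < 2:
            raise ValueError("match_size must be >= 2")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")


# ---------------------------------------------------------------------------
# Tandem duplicates
# ---------------------------------------------------------------------------


def classify_tandem(
    hits: Sequence[HitRecord], genes: GeneTable, max_intervening: int = 1
) -> set[str]:
    """Return all genes belonging to a tandem duplicate array.

    Two hit genes on the same chromosome separated by at most
    ``max_intervening`` intervening genes seed an array; arrays are closed
    transitively (g1-g2 and g2-g3 adjacent puts all three in one array).
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    linked: set[str] = set()
    for h in hits:
        if h.query not in genes or h.subject not in genes:
            raise KeyError(f"hit gene not in gene table: {h.query}/{h.subject}")
        if h.query == h.subject:
            continue
        ca, oa = genes.position(h.query)
        cb, ob = genes.position(h.subject)
        if ca != cb or abs(oa - ob) > max_intervening + 1:
            continue
        for g in (h.query, h.subject):
            parent.setdefault(g, g)
        union(h.query, h.subject)
        linked.update((h.query, h.subject))
    return linked


# ---------------------------------------------------------------------------
# Anchor chaining
# ---------------------------------------------------------------------------


def _hits_to_anchors(
    hits: Sequence[HitRecord], genes_a: GeneTable, genes_b: GeneTable
) -> list[AnchorPair]:
    anchors = []
    for h in hits:
        if h.query not in genes_a or h.subject not in genes_b:
            continue
        ca, oa = genes_a.position(h.query)
        cb, ob = genes_b.position(h.subject)
        anchors.append(AnchorPair(h.query, h.subject, h.evalue, ca, oa, cb, ob))
    return anchors


def chain_anchors(
    hits: Sequence[HitRecord],
    genes_a: GeneTable,
    genes_b: GeneTable,
    params: ChainParams | None = None,
) -> list[SyntenicBlock]:
    """Chain filtered hits into syntenic blocks by dynamic programming.

    Hits are interpreted with ``query`` on genome A and ``subject`` on genome
    B; hits whose genes are missing from either table are ignored (they are
    typically on unplaced scaffolds).  Chains are extracted greedily per
    chromosome pair: the best-scoring chain (ties resolved toward the longer
    chain, then the lower starting rank) is removed and the programme repeats
    until no chain of ``match_size`` pairs remains.
    """
    params = params or ChainParams()
    hits = [h for h in hits if h.evalue < params.evalue_cutoff]
    anchors = _hits_to_anchors(hits, genes_a, genes_b)
    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[SyntenicBlock] = []
    for (ca, cb), group in sorted(groups.items()):
        blocks.extend(_chain_group(group, params))
    blocks = _merge_overlaps(blocks, params)
    blocks.sort(key=lambda b: (-b.score, b.chrom_a, b.chrom_b))
    for i, b in enumerate(blocks):
        b.block_id = i
    return blocks


def _chain_group(group: list[AnchorPair], params: ChainParams) -> list[SyntenicBlock]:
    remaining = list(group)
    out: list[SyntenicBlock] = []
    while len(remaining) >= params.match_size:
        best = None
        for orientation in ("same", "inverted"):
            chain = _best_chain(remaining, params, orientation)
            if chain is None:
                continue
            score, members = chain
            key = (score, len(members), -members[0].order_a)
            if len(members) >= params.match_size and (best is None or key > best[0]):
                best = (key, members, orientation)
        if best is None:
            break
        _, members, orientation = best
        out.append(_make_block(members, orientation, params))
        used = set(id(m) for m in members)
        remaining = [a for a in remaining if id(a) not in used]
    return out


def _best_chain(anchors: list[AnchorPair], params: ChainParams, orientation: str):
    """DP over anchors; returns (score, member list) of the best chain."""
    if not anchors:
        return None
    sign = 1 if orientation == "same" else -1
    # sort by order_a then (signed) order_b for deterministic scanning
    idx = sorted(
        range(len(anchors)), key=lambda i: (anchors[i].order_a, sign * anchors[i].order_b)
    )
    oa = [anchors[i].order_a for i in idx]
    ob = [sign * anchors[i].order_b for i in idx]
    n = len(idx)
    score = [params.match_score] * n
    length = [1] * n
    start = list(oa)
    prev = [-1] * n
    lo_ptr = 0
    for j in range(n):
        while oa[lo_ptr] < oa[j] - params.max_gaps - 1:
            lo_ptr += 1
        best_key = (score[j], length[j], -start[j])  # starting fresh at j
        for i in range(lo_ptr, j):
            if oa[i] >= oa[j] or ob[i] >= ob[j]:
                continue
            gap_b = ob[j] - ob[i] - 1
            if gap_b > params.max_gaps:
                continue
            gap_a = oa[j] - oa[i] - 1
            cand = score[i] + params.match_score + params.gap_penalty * (gap_a + gap_b)
            key = (cand, length[i] + 1, -start[i])
            if key > best_key:
                best_key = key
                score[j] = cand
                length[j] = length[i] + 1
                start[j] = start[i]
                prev[j] = i
    end = max(range(n), key=lambda j: (score[j], length[j], -start[j]))
    if length[end] < 2:
        return None
    members = []
    j = end
    while j != -1:
        members.append(anchors[idx[j]])
        j = prev[j]
    members.reverse()
    return score[end], members


def _make_block(members: list[AnchorPair], orientation: str, params: ChainParams) -> SyntenicBlock:
    return SyntenicBlock(
        pairs=members,
        chrom_a=members[0].chrom_a,
        chrom_b=members[0].chrom_b,
        score=_chain_score(members, params),
        block_evalue=_block_evalue(members),
        orientation=orientation,
    )


def _chain_score(members: list[AnchorPair], params: ChainParams) -> float:
    score = params.match_score * len(members)
    for p, q in zip(members, members[1:]):
        gap_a = abs(q.order_a - p.order_a) - 1
        gap_b = abs(q.order_b - p.order_b) - 1
        score += params.gap_penalty * (gap_a + gap_b)
    return score


def _block_evalue(members: list[AnchorPair]) -> float:
    """min(per-pair E-value) ** n_pairs with a 1e-300 floor.

    A monotone surrogate for a chain significance score, adequate for
    thresholding; files produced by MCScanX carry that tool's own value.
    """
    min_e = min(p.evalue for p in members)
    if min_e <= 0:
        return BLOCK_EVALUE_FLOOR
    log10 = len(members) * math.log10(min_e)
    return 10.0 ** max(log10, -300.0)


def _monotone_valid(members: list[AnchorPair], params: ChainParams, orientation: str) -> bool:
    sign = 1 if orientation == "same" else -1
    for p, q in zip(members, members[1:]):
        if q.order_a <= p.order_a or sign * q.order_b <= sign * p.order_b:
            return False
        if q.order_a - p.order_a - 1 > params.max_gaps:
            return False
        if sign * (q.order_b - p.order_b) - 1 > params.max_gaps:
            return False
    return True


def _merge_overlaps(blocks: list[SyntenicBlock], params: ChainParams) -> list[SyntenicBlock]:
    """Resolve chains sharing > overlap_window genes on one chromosome pair.

    Compatible overlapping chains (joint anchor set still a valid chain) are
    merged; otherwise the lower-scoring chain loses its anchors inside the
    overlap and is dropped if it falls below match_size.
    """
    changed = True
    while changed:
        changed = False
        by_pair: dict[tuple[str, str, str], list[SyntenicBlock]] = {}
        for b in blocks:
            by_pair.setdefault((b.chrom_a, b.chrom_b, b.orientation), []).append(b)
        for key, group in by_pair.items():
            group.sort(key=lambda b: -b.score)
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    hi_b, lo_b = group[i], group[j]
                    ov = _span_overlap(hi_b.span_a(), lo_b.span_a())
                    if ov <= params.overlap_window:
                        continue
                    merged = sorted(
                        hi_b.pairs + lo_b.pairs, key=lambda p: (p.order_a, p.order_b)
                    )
                    if _monotone_valid(merged, params, hi_b.orientation):
                        hi_b.pairs = merged
                        hi_b.score = _chain_score(merged, params)
                        hi_b.block_evalue = _block_evalue(merged)
                        blocks.remove(lo_b)
                    else:
                        lo, hi = hi_b.span_a()
                        kept = [p for p in lo_b.pairs if not lo <= p.order_a <= hi]
                        if len(kept) >= params.match_size:
                            lo_b.pairs = kept
                            lo_b.score = _chain_score(kept, params)
                            lo_b.block_evalue = _block_evalue(kept)
                        else:
                            blocks.remove(lo_b)
                    changed = True
                    break
                if changed:
                    break
            if changed:
                break
    return blocks


def _span_overlap(s1: tuple[int, int], s2: tuple[int, int]) -> int:
    return min(s1[1], s2[1]) - max(s1[0], s2[0]) + 1


# ---------------------------------------------------------------------------
# False-positive block filtering
# ---------------------------------------------------------------------------


def filter_blocks(
    blocks: Sequence[SyntenicBlock],
    block_evalue_cutoff: float = 1e-10,
    min_pairs: int = 10,
    pair_evalue_cutoff: float = 1e-10,
    weak_fraction: float = 0.5,
) -> tuple[list[SyntenicBlock], pd.DataFrame]:
    """Remove false-positive blocks by the two published criteria.

    1. block E-value > ``block_evalue_cutoff``;
    2. fewer than ``min_pairs`` gene pairs AND more than ``weak_fraction`` of
       the pairs with per-pair E-value > ``pair_evalue_cutoff``.

    Returns the surviving blocks and a removal log (block id, reason).
    """
    kept: list[SyntenicBlock] = []
    log_rows = []
    for b in blocks:
        if b.block_evalue > block_evalue_cutoff:
            log_rows.append({"block_id": b.block_id, "n_pairs": len(b), "reason": "block_evalue"})
            continue
        weak = sum(1 for p in b.pairs if p.evalue > pair_evalue_cutoff)
        if len(b) < min_pairs and weak / len(b) > weak_fraction:
            log_rows.append({"block_id": b.block_id, "n_pairs": len(b), "reason": "weak_pairs"})
            continue
        kept.append(b)
    log = pd.DataFrame(log_rows, columns=["block_id", "n_pairs", "reason"])
    if len(log):
        logger.info(
            "filter_blocks removed %d/%d blocks (%s)",
            len(log),
            len(blocks),
            log["reason"].value_counts().to_dict(),
        )
    return kept, log


# ---------------------------------------------------------------------------
# Syntenic depth and coverage
# ---------------------------------------------------------------------------


def syntenic_depth(
    blocks: Sequence[SyntenicBlock],
    reference: str = "b",
    gene_table: GeneTable | None = None,
) -> pd.DataFrame:
    """Tally reference genes by the number of distinct blocks covering them.

    ``reference`` selects which genome of the block pairs is the reference
    ('a' = query side, 'b' = subject side).  A gene is covered by a block when
    its gene rank lies inside the block footprint on its chromosome.  Depths
    are reported as ratio labels 0:1 .. 4+:1 with gene counts and percentages
    over two denominators: genes covered by at least one block, and (when a
    gene table is given) all annotated genes.
    """
    depth: dict[tuple[str, int], int] = {}
    for b in blocks:
        if reference == "a":
            chrom, (lo, hi) = b.chrom_a, b.span_a()
        else:
            chrom, (lo, hi) = b.chrom_b, b.span_b()
        for o in range(lo, hi + 1):
            depth[(chrom, o)] = depth.get((chrom, o), 0) + 1

    counts = {k: 0 for k in ["0", "1", "2", "3", "4+"]}
    if gene_table is not None:
        for row in gene_table.df.itertuples(index=False):
            d = depth.get((row.chromosome, row.order_index), 0)
            counts[_depth_label(d)] += 1
    else:
        for d in depth.values():
            counts[_depth_label(d)] += 1

    n_in_blocks = sum(v for k, v in counts.items() if k != "0")
    n_all = sum(counts.values()) if gene_table is not None else None
    rows = []
    for label, count in counts.items():
        rows.append(
            {
                "ratio": f"{label}:1",
                "gene_count": count,
                "pct_of_block_genes": (
                    coverage_percentage(count, n_in_blocks) if n_in_blocks and label != "0" else 0.0
                ),
                "pct_of_all_genes": (
                    coverage_percentage(count, n_all) if n_all else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def _depth_label(d: int) -> str:
    return str(d) if d < 4 else "4+"


def coverage_percentage(n_in_blocks: int, n_total: int) -> float:
    """100 * n_in_blocks / n_total, rounded half-up to 2 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_in_blocks <= n_total:
        raise ValueError("n_in_blocks out of range")
    pct = Decimal(100 * n_in_blocks) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def block_summary(blocks: Sequence[SyntenicBlock]) -> pd.DataFrame:
    rows = []
    for b in blocks:
        rows.append(
            {
                "block_id": b.block_id,
                "chrom_a": b.chrom_a,
                "chrom_b": b.chrom_b,
                "n_pairs": len(b),
                "score": b.score,
                "block_evalue": b.block_evalue,
                "orientation": b.orientation,
                "median_ks": b.median_ks,
            }
        )
    return pd.DataFrame(rows)


def dotplot_table(blocks: Sequence[SyntenicBlock]) -> pd.DataFrame:
    """Per-anchor (order_a, order_b, block_id) table for external plotting."""
    rows = []
    for b in blocks:
        for p in b.pairs:
            rows.append(
                {
                    "chrom_a": p.chrom_a,
                    "order_a": p.order_a,
                    "chrom_b": p.chrom_b,
                    "order_b": p.order_b,
                    "block_id": b.block_id,
                }
            )
    return pd.DataFrame(rows)
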