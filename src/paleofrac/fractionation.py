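"""Gene retention/loss statistics along outgroup chromosomes.

Two complementary views of fractionation: 100-gene sliding windows of the
retained-orthologue fraction per subgenome, and a per-chromosome loss-rate
table (fraction of outgroup genes without a surviving anchor in subgenome 1,
subgenome 2, or either).  Reported rates are rounded half-up to two decimals;
the loss-rate difference is computed from the unrounded rates and then
rounded, so a printed difference can disagree with the difference of the
printed rates by one unit in the last place.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from paleofrac.io_formats import GeneTable
from paleofrac.subgenome import SubgenomeAssignment

logger = logging.getLogger(__name__)


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _retention_arrays(
    outgroup: GeneTable,
    assignment: SubgenomeAssignment,
    chromosome: str,
    exclude_tandem: set[str] = frozenset(),
) -> tuple[np.ndarray, np.ndarray]:
    ret = assignment.retention
    sub = ret[ret["chromosome"] == chromosome].sort_values("order_index")
    if exclude_tandem:
        sub = sub[~sub["gene_id"].isin(exclude_tandem)]
    return sub["retained_sg1"].to_numpy(), sub["retained_sg2"].to_numpy()


def window_retention(
    outgroup: GeneTable,
    assignment: SubgenomeAssignment,
    window: int = 100,
    step: int = 1,
    exclude_tandem: set[str] = frozenset(),
) -> pd.DataFrame:
    """Sliding-window retained fraction per subgenome along each chromosome.

    Windows span ``window`` consecutive (tandem-excluded) outgroup genes and
    slide by ``step`` genes; a chromosome shorter than one window yields a
    single truncated window with a warning.  Columns: chromosome,
    window_start (gene rank of the first gene in the window),
    retained_sg1/retained_sg2/retained_both fractions.
    """
    rows = []
    for chrom in outgroup.chromosomes:
        r1, r2 = _retention_arrays(outgroup, assignment, chrom, exclude_tandem)
        n = r1.size
        if n == 0:
            continue
        w = window
        if n < window:
            logger.warning(
                "chromosome %s has %d genes < window %d; single truncated window",
                chrom,
                n,
                window,
            )
            w = n
        both = r1 & r2
        c1 = np.concatenate([[0], np.cumsum(r1)])
        c2 = np.concatenate([[0], np.cumsum(r2)])
        cb = np.concatenate([[0], np.cumsum(both)])
        for start in range(0, n - w + 1, step):
            end = start + w
            rows.append(
                {
                    "chromosome": chrom,
                    "window_start": start,
                    "retained_sg1": (c1[end] - c1[start]) / w,
                    "retained_sg2": (c2[end] - c2[start]) / w,
                    "retained_both": (cb[end] - cb[start]) / w,
                }
            )
    return pd.DataFrame(
        rows, columns=["chromosome", "window_start", "retained_sg1", "retained_sg2", "retained_both"]
    )


def chromosome_loss_rates(
    outgroup: GeneTable,
    assignment: SubgenomeAssignment,
    exclude_tandem: set[str] = frozenset(),
) -> pd.DataFrame:
    """Per-chromosome loss-rate table.

    For each outgroup chromosome: the number of genes, the fraction lost from
    subgenome 1, from subgenome 2, from both, and |loss_sg1 - loss_sg2|.
    Rates are reported rounded to 2 decimals (columns ``loss_sg1`` etc.) with
    the unrounded values kept in ``*_raw`` columns; the difference is computed
    from the unrounded rates.  Empty chromosomes are skipped.
    """
    rows = []
    for chrom in outgroup.chromosomes:
        r1, r2 = _retention_arrays(outgroup, assignment, chrom, exclude_tandem)
        n = r1.size
        if n == 0:
            continue
        loss1 = 1.0 - r1.mean()
        loss2 = 1.0 - r2.mean()
        loss_both = 1.0 - (r1 | r2).mean()
        rows.append(
            {
                "chromosome": chrom,
                "n_genes": n,
                "loss_sg1": _round2(loss1),
                "loss_sg2": _round2(loss2),
                "loss_both": _round2(loss_both),
                "difference": loss_rate_difference(loss1, loss2),
                "loss_sg1_raw": loss1,
                "loss_sg2_raw": loss2,
                "loss_both_raw": loss_both,
            }
        )
    return pd.DataFrame(rows)


def loss_rate_difference(r1: float, r2: float) -> float:
    """|r1 - r2| rounded half-up to 2 decimals; rates must lie in [0, 1]."""
    if not (0 <= r1 <= 1 and 0 <= r2 <= 1):
        raise ValueError("loss rates must lie in [0, 1]")
    return _round2(abs(r1 - r2))
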