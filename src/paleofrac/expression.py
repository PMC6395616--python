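"""Expression-bias analysis: threshold, breadth, homeolog dominance, qPCR.

The expression threshold separating "expressed" from background is derived
from the data itself: the median TPM of intergenic regions per tissue,
averaged over tissues.  Expression breadth is the percentage of surveyed
tissues in which a gene exceeds that threshold (strictly).  Homeolog
dominance follows the more-than-twofold rule: a pair member whose TPM is more
than ``fold`` times its partner's is dominant in that tissue; pairs with both
members at or below the threshold are silent; everything else is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from paleofrac.io_formats import ExpressionMatrix, GeneTable

DOMINANCE_CLASSES = ("dominant_sg1", "dominant_sg2", "conserved", "both_silent")
_EPS = 1e-9


@dataclass
class ExpressionThreshold:
    value: float
    per_tissue_medians: list[float]


def intergenic_threshold(intergenic_tpm: ExpressionMatrix) -> ExpressionThreshold:
    """Mean over tissues of the median intergenic TPM per tissue."""
    df = intergenic_tpm.df
    if df.empty or not len(df.columns):
        raise ValueError("empty intergenic expression matrix")
    medians = df.median(axis=0)
    return ExpressionThreshold(
        value=float(medians.mean()), per_tissue_medians=[float(m) for m in medians]
    )


def expression_breadth(gene_tpm: Sequence[float], threshold: float) -> float:
    """Percentage of tissues with TPM strictly above the threshold."""
    tpm = np.asarray(gene_tpm, dtype=float)
    if tpm.size == 0:
        raise ValueError("need at least one tissue")
    return round(100.0 * float((tpm > threshold).sum()) / tpm.size, 2)


def classify_dominance(
    tpm_sg1: float, tpm_sg2: float, threshold: float, fold: float = 2.0
) -> str:
    """Dominance class of one homeolog pair in one tissue."""
    if tpm_sg1 < 0 or tpm_sg2 < 0:
        raise ValueError("TPM must be non-negative")
    if tpm_sg1 <= threshold and tpm_sg2 <= threshold:
        return "both_silent"
    hi, lo = max(tpm_sg1, tpm_sg2), min(tpm_sg1, tpm_sg2)
    if hi / max(lo, _EPS) > fold:
        return "dominant_sg1" if tpm_sg1 > tpm_sg2 else "dominant_sg2"
    return "conserved"


def dominance_calls(
    pairs: pd.DataFrame,
    expression: ExpressionMatrix,
    threshold: float,
    fold: float = 2.0,
) -> pd.DataFrame:
    """Classify every homeolog pair in every tissue.

    ``pairs`` needs columns gene_sg1, gene_sg2; pairs with either member
    absent from the expression matrix are skipped.  Returns one row per
    (pair, tissue) with the dominance class.
    """
    idx = expression.df.index
    ok = pairs["gene_sg1"].isin(idx) & pairs["gene_sg2"].isin(idx)
    kept = pairs.loc[ok, ["gene_sg1", "gene_sg2"]]
    t1 = expression.df.loc[kept["gene_sg1"]].to_numpy()  # (pairs, tissues)
    t2 = expression.df.loc[kept["gene_sg2"]].to_numpy()
    silent = (t1 <= threshold) & (t2 <= threshold)
    hi = np.maximum(t1, t2)
    lo = np.maximum(np.minimum(t1, t2), _EPS)
    dominant = ~silent & (hi / lo > fold)
    cls = np.where(
        silent,
        "both_silent",
        np.where(dominant, np.where(t1 > t2, "dominant_sg1", "dominant_sg2"), "conserved"),
    )
    tissues = expression.tissues
    rows = {
        "gene_sg1": np.repeat(kept["gene_sg1"].to_numpy(), len(tissues)),
        "gene_sg2": np.repeat(kept["gene_sg2"].to_numpy(), len(tissues)),
        "tissue": np.tile(tissues, len(kept)),
        "class": cls.ravel(),
    }
    return pd.DataFrame(rows, columns=["gene_sg1", "gene_sg2", "tissue", "class"])


def dominance_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue percentage of each dominance class (rows sum to 100)."""
    if calls.empty:
        return pd.DataFrame(columns=DOMINANCE_CLASSES)
    counts = (
        calls.groupby("tissue")["class"].value_counts().unstack(fill_value=0)
    )
    for cls in DOMINANCE_CLASSES:
        if cls not in counts.columns:
            counts[cls] = 0
    counts = counts[list(DOMINANCE_CLASSES)]
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def relative_expression_ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative qPCR expression by the 2^-ddCt method."""
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))


def mean_tpm(expression: ExpressionMatrix, genes: Iterable[str]) -> pd.Series:
    """Per-gene TPM averaged over tissues, for the genes present."""
    present = [g for g in genes if g in expression.df.index]
    return expression.df.loc[present].mean(axis=1)


def breadth_series(
    expression: ExpressionMatrix, genes: Iterable[str], threshold: float
) -> pd.Series:
    present = [g for g in genes if g in expression.df.index]
    sub = expression.df.loc[present]
    return (sub.gt(threshold).sum(axis=1) / len(sub.columns) * 100.0).round(2)


def intergenic_regions(
    genes: GeneTable, chrom_sizes: dict[str, int], buffer: int = 500
) -> pd.DataFrame:
    """Complement of gene spans (each padded by ``buffer`` bp) per chromosome.

    Helper for building an intergenic quantification target set; the
    threshold itself is always recomputed from whatever intergenic TPM matrix
    is supplied.
    """
    rows = []
    for chrom, size in chrom_sizes.items():
        sub = genes.df[genes.df["chromosome"] == chrom]
        cursor = 0
        for r in sub.sort_values("start").itertuples(index=False):
            lo = max(0, r.start - buffer)
            if lo > cursor:
                rows.append({"chromosome": chrom, "start": cursor, "end": lo})
            cursor = max(cursor, r.end + buffer)
        if cursor < size:
            rows.append({"chromosome": chrom, "start": cursor, "end": size})
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])
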