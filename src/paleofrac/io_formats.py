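"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are normalised at the reader boundary to 0-based
half-open intervals; GFF3 (1-based closed) and BED (0-based half-open) inputs
therefore yield identical in-memory objects for the same genes.  Bismark
cytosine (CX) reports keep their native 1-based positions in the table and are
converted at query time by the methylation module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "order_index"]
_CONTEXT_ALIASES = {"CG": "CG", "CPG": "CG", "CHG": "CHG", "CHH": "CHH"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------


@dataclass
class GeneTable:
    """Ordered gene models of one genome.

    ``df`` holds one row per gene with columns ``gene_id, chromosome, start,
    end, strand, order_index``; ``order_index`` is the dense 0..n-1 rank of the
    gene along its chromosome sorted by start coordinate.  This rank space is
    the backbone of all collinearity logic.
    """

    genome_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _normalise_gene_frame(self.df)
        self._order: dict[str, tuple[str, int]] = {
            g: (c, o)
            for g, c, o in zip(
                self.df["gene_id"], self.df["chromosome"], self.df["order_index"]
            )
        }

    @classmethod
    def from_records(
        cls, genome_id: str, records: Iterable[tuple[str, str, int, int, str]]
    ) -> "GeneTable":
        """Build from ``(gene_id, chromosome, start, end, strand)`` tuples."""
        df = pd.DataFrame(
            list(records), columns=["gene_id", "chromosome", "start", "end", "strand"]
        )
        return cls(genome_id, df)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._order

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.df["chromosome"].unique())

    def position(self, gene_id: str) -> tuple[str, int]:
        """Return ``(chromosome, order_index)`` of a gene."""
        return self._order[gene_id]

    def genes_on(self, chromosome: str) -> pd.DataFrame:
        sub = self.df[self.df["chromosome"] == chromosome]
        return sub.sort_values("order_index").reset_index(drop=True)

    def to_bed(self, path: str) -> None:
        out = self.df[["chromosome", "start", "end", "gene_id", "strand"]].copy()
        out.insert(4, "score", 0)
        out.to_csv(path, sep="\t", header=False, index=False)

    def to_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in self.df.itertuples(index=False):
                attrs = f"ID={row.gene_id}"
                fh.write(
                    f"{row.chromosome}\tpaleofrac\tgene\t{row.start + 1}\t{row.end}\t.\t"
                    f"{row.strand}\t.\t{attrs}\n"
                )


def _normalise_gene_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = {"gene_id", "chromosome", "start", "end", "strand"} - set(df.columns)
    if missing:
        raise FormatError(f"gene table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].head(3).tolist()
        raise FormatError(f"duplicate gene_id(s): {dups}")
    bad = df["start"] >= df["end"]
    if bad.any():
        raise FormatError(f"{int(bad.sum())} gene(s) with start >= end")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError("strand must be '+' or '-'")
    sorted_df = df.sort_values(["chromosome", "start", "end"], kind="mergesort")
    if not sorted_df.index.equals(df.index):
        logger.info("gene table not sorted by position; sorting")
    df = sorted_df.reset_index(drop=True)
    df["order_index"] = df.groupby("chromosome", sort=False).cumcount()
    return df[GENE_COLUMNS]


def read_gene_positions(path: str, format: str, genome_id: str | None = None) -> GeneTable:
    """Read gene positions from a GFF3 or BED file into a :class:`GeneTable`.

    GFF3 coordinates (1-based closed) are converted to the internal 0-based
    half-open convention; BED is already in that convention.
    """
    genome_id = genome_id or str(path)
    rows: list[tuple[str, str, int, int, str]] = []
    if format == "bed":
        for lineno, line in enumerate(_data_lines(path), 1):
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: BED line with <4 columns")
            strand = f[5] if len(f) >= 6 else "+"
            rows.append((f[3], f[0], int(f[1]), int(f[2]), strand))
    elif format == "gff3":
        for lineno, line in enumerate(_data_lines(path), 1):
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 line with {len(f)} columns")
            if f[2] != "gene":
                continue
            gene_id = _gff3_id(f[8])
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: GFF3 attributes lack ID=")
            rows.append((gene_id, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    else:
        raise ValueError(f"unknown gene position format: {format!r}")
    df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])
    return GeneTable(genome_id, df)


def _gff3_id(attrs: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith("ID="):
            return part[3:]
    return None


def _data_lines(path: str) -> Iterable[str]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line


# ---------------------------------------------------------------------------
# BLAST tabular hits
# ---------------------------------------------------------------------------


class HitRecord(NamedTuple):
    """One pairwise protein hit (query, subject, E-value, bit score)."""

    query: str
    subject: str
    evalue: float
    bitscore: float


def read_blast_m8(path: str, max_evalue: float = 1e-5) -> list[HitRecord]:
    """Read 12-column BLAST tabular (m8 / outfmt 6) output.

    Hits with ``evalue >= max_evalue`` and self-hits are dropped.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(f)}")
            try:
                evalue = float(f[10])
                bitscore = float(f[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed numeric field") from exc
            if f[0] == f[1]:
                continue
            if evalue >= max_evalue:
                continue
            hits.append(HitRecord(f[0], f[1], evalue, bitscore))
    return hits


def write_blast_m8(hits: Sequence[HitRecord], path: str) -> None:
    """Write hits as 12-column BLAST tabular; alignment columns are dummies."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t90.0\t100\t10\t0\t1\t100\t1\t100\t"
                f"{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Collinearity files (MCScanX dialect)
# ---------------------------------------------------------------------------


def read_collinearity(path: str):
    """Read syntenic blocks from a MCScanX-style ``.collinearity`` file.

    Block headers carry score, E-value, pair count and orientation; pair lines
    carry the two gene ids and the per-pair E-value.  Headers without any pair
    line are skipped with a warning.  Anchor order indices are left unset; they
    can be filled from gene tables downstream.
    """
    from paleofrac.synteny import AnchorPair, SyntenicBlock

    blocks = []
    header = None
    pairs: list[AnchorPair] = []

    def flush():
        nonlocal header, pairs
        if header is not None:
            if not pairs:
                logger.warning("collinearity block %s has no gene pairs; skipped", header[0])
            else:
                bid, score, evalue, chrom_a, chrom_b, orientation = header
                blocks.append(
                    SyntenicBlock(
                        pairs=list(pairs),
                        chrom_a=chrom_a,
                        chrom_b=chrom_b,
                        score=score,
                        block_evalue=evalue,
                        orientation=orientation,
                        block_id=bid,
                    )
                )
        header, pairs = None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("## Alignment"):
                flush()
                header = _parse_block_header(line)
            elif line.startswith("#") or not line.strip():
                continue
            else:
                f = [tok for tok in line.replace(":", "\t").split("\t") if tok.strip()]
                if len(f) < 3 or header is None:
                    raise FormatError(f"unexpected collinearity line: {line!r}")
                gene_a, gene_b = f[-3].strip(), f[-2].strip()
                evalue = float(f[-1])
                pairs.append(
                    AnchorPair(gene_a, gene_b, evalue, None, None, None, None)
                )
    flush()
    return blocks


def _parse_block_header(line: str):
    # '## Alignment 3: score=250.0 e_value=1e-30 N=5 chrA&chrB plus'
    body = line[len("## Alignment") :].strip()
    bid_str, rest = body.split(":", 1)
    tokens = rest.split()
    score = evalue = None
    chrom_a = chrom_b = None
    orientation = "same"
    for tok in tokens:
        if tok.startswith("score="):
            score = float(tok[6:])
        elif tok.startswith("e_value="):
            evalue = float(tok[8:])
        elif "&" in tok:
            chrom_a, chrom_b = tok.split("&", 1)
        elif tok in ("plus", "minus"):
            orientation = "same" if tok == "plus" else "inverted"
    return int(bid_str), score, evalue, chrom_a, chrom_b, orientation


def write_collinearity(blocks, path: str) -> None:
    """Write blocks in the MCScanX ``.collinearity`` dialect."""
    with open(path, "w") as fh:
        fh.write("############### paleofrac collinearity ###############\n")
        for i, b in enumerate(blocks):
            orient = "plus" if b.orientation == "same" else "minus"
            fh.write(
                f"## Alignment {i}: score={b.score:.1f} e_value={b.block_evalue:.3g} "
                f"N={len(b.pairs)} {b.chrom_a}&{b.chrom_b} {orient}\n"
            )
            for j, p in enumerate(b.pairs):
                fh.write(f"{i:3d}-{j:3d}:\t{p.gene_a}\t{p.gene_b}\t{p.evalue:.3g}\n")


# ---------------------------------------------------------------------------
# Bismark cytosine (CX) reports
# ---------------------------------------------------------------------------


@dataclass
class MethylationTable:
    """Per-cytosine bisulfite counts, one row per covered-or-known cytosine.

    Columns: ``chromosome, position`` (1-based, as in the CX dialect),
    ``strand, context`` (CG/CHG/CHH), ``count_methylated, count_total``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"chromosome", "position", "strand", "context", "count_methylated", "count_total"}
        missing = need - set(self.df.columns)
        if missing:
            raise FormatError(f"methylation table missing columns: {sorted(missing)}")
        if (self.df["count_methylated"] < 0).any() or (self.df["count_total"] < 0).any():
            raise FormatError("negative methylation counts")
        if (self.df["count_methylated"] > self.df["count_total"]).any():
            raise FormatError("count_methylated exceeds count_total")
        if not self.df["context"].isin(["CG", "CHG", "CHH"]).all():
            raise FormatError("context must be CG, CHG or CHH")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def covered(self) -> pd.DataFrame:
        """Rows with at least one read."""
        return self.df[self.df["count_total"] > 0]


def read_cx_report(path: str) -> MethylationTable:
    """Read a Bismark cytosine (CX) report.

    Columns: chromosome, position (1-based), strand, count_methylated,
    count_unmethylated, context[, trinucleotide].  Rows with zero total reads
    are retained (uncovered cytosines); unknown context tokens are an error.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3, 4, 5],
        names=["chromosome", "position", "strand", "count_methylated", "count_unmethylated", "context"],
        dtype={"chromosome": str, "strand": str, "context": str},
    )
    if (df["count_methylated"] < 0).any() or (df["count_unmethylated"] < 0).any():
        raise FormatError(f"{path}: negative counts")
    ctx = df["context"].str.upper().map(_CONTEXT_ALIASES)
    if ctx.isna().any():
        bad = df.loc[ctx.isna(), "context"].unique()[:3]
        raise FormatError(f"{path}: unknown methylation context token(s): {list(bad)}")
    df["context"] = ctx
    df["count_total"] = df["count_methylated"] + df["count_unmethylated"]
    df = df.drop(columns="count_unmethylated")
    return MethylationTable(df)


def write_cx_report(table: MethylationTable, path: str) -> None:
    out = table.df.copy()
    out["count_unmethylated"] = out["count_total"] - out["count_methylated"]
    out[
        ["chromosome", "position", "strand", "count_methylated", "count_unmethylated", "context"]
    ].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> dict[str, str]:
    """Sequences keyed by record id (coding sequences for Ka/Ks)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x tissues TPM matrix (replicates already averaged per tissue)."""

    df: pd.DataFrame  # index: gene_id, columns: tissue names
    replicate_map: Mapping[str, Sequence[str]] | None = None

    def __post_init__(self) -> None:
        if (self.df.values < 0).any():
            raise FormatError("negative TPM values")

    @property
    def tissues(self) -> list[str]:
        return list(self.df.columns)

    def gene(self, gene_id: str) -> pd.Series | None:
        """Per-tissue TPM of one gene, or None when the gene is absent."""
        if gene_id not in self.df.index:
            return None
        return self.df.loc[gene_id]


def read_tpm_matrix(
    path: str, replicate_map: Mapping[str, Sequence[str]] | None = None
) -> ExpressionMatrix:
    """Read a TSV TPM matrix (first column gene ids, header of sample names).

    When ``replicate_map`` maps tissue name -> replicate column names, the
    replicate columns are averaged to one per-tissue column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative TPM values")
    if replicate_map:
        cols = {}
        for tissue, reps in replicate_map.items():
            missing = [r for r in reps if r not in df.columns]
            if missing:
                raise FormatError(f"{path}: replicate columns not found: {missing}")
            cols[tissue] = df[list(reps)].mean(axis=1)
        df = pd.DataFrame(cols)
    return ExpressionMatrix(df, replicate_map=replicate_map)


def write_tpm_matrix(matrix: ExpressionMatrix, path: str) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="gene_id")
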