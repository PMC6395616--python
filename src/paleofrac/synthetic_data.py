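"""Synthetic inputs with ground truth for every pipeline stage.

The generator emulates the study design the pipeline expects: an unduplicated
outgroup genome (~8 chromosomes), a second more distant outgroup sharing the
ancestral gene order, and a duplicated genome carrying two post-WGD copies of
every ancestral gene with independent per-gene retention, segmental
translocations/inversions, a handful of older duplicated segments descending
from a shared ancient WGD, tandem arrays, protein-hit tables with spurious
hits, codon sequences diverged at a controlled dN/dS and Ks, log-normal
per-tissue expression with planted group effects, and binomially sampled
bisulfite counts with context- and region-specific methylation levels.

Every emitted object is paired with ground-truth labels (copy of origin,
planted block membership, singleton/homeolog class, subgenome label under the
singleton-majority rule, planted expression and methylation effects) so each
analysis stage can be scored against truth.

Coding-sequence evolution uses a symmetric codon Markov process over the 61
sense codons: single-nucleotide exchanges at rate 1 when synonymous and rate
dN/dS when nonsynonymous.  Branch lengths are calibrated numerically against
the expected NG86 Ks of the process so a block's target Ks is realised (up to
finite-length noise) by the emitted sequences.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from paleofrac.io_formats import (
    ExpressionMatrix,
    GeneTable,
    HitRecord,
    MethylationTable,
    write_blast_m8,
    write_cx_report,
    write_tpm_matrix,
)
from paleofrac.molevol import AMINO, CODONS, SYN_DIFF, SYN_SITES
from paleofrac.subgenome import region_order_key

# 61 sense codons and maps between 61-space and 64-space
SENSE = np.array([i for i in range(64) if AMINO[i] != "*"])
_TO61 = np.full(64, -1)
_TO61[SENSE] = np.arange(61)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ExpressionConfig:
    """Log-normal TPM model across tissues with planted group effects.

    Homeolog partners share a per-family baseline and per-tissue effect, so
    their expression ratio is governed by ``member_sd`` plus any planted
    dominance effect.  Shifts are on the natural-log scale.
    """

    tissue_count: int = 7
    log_mean: float = 2.0
    gene_sd: float = 1.2
    tissue_sd: float = 0.3
    member_sd: float = 0.15
    singleton_shift: float = 0.6
    dominance_fraction: float = 0.2
    dominance_fold: float = 4.0
    subgenome_shift: float = 0.0
    intergenic_mean: float = 0.7
    n_intergenic: int = 5000


@dataclass
class MethylationConfig:
    """Bisulfite model: per-context per-region levels, binomial counts."""

    depth: int = 20
    n_replicates: int = 2
    site_spacing: int = 50
    context_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)  # CG, CHG, CHH
    levels: dict = field(
        default_factory=lambda: {
            "CG": (0.35, 0.55, 0.35),  # upstream, body, downstream
            "CHG": (0.25, 0.10, 0.25),
            "CHH": (0.05, 0.05, 0.05),
        }
    )
    gene_sd_logit: float = 0.5
    singleton_shift: float = 0.0  # logit shift for singleton genes
    subgenome_shift: float = 0.0  # logit shift for second-copy genes
    max_genes: int = 3000


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic genome trio."""

    seed: int = 1
    n_outgroup_genes: int = 8000
    n_chromosomes: int = 8
    retention_probs: tuple[float, float] = (0.6, 0.6)
    rearrangement_events: int = 4
    segment_size: tuple[int, int] = (50, 500)
    inversion_prob: float = 0.5
    ancient_segments: int = 6
    ancient_segment_size: tuple[int, int] = (100, 300)
    ancient_retention: float = 0.3
    ks_weights: tuple[float, float] = (0.55, 0.45)
    ks_means: tuple[float, float] = (0.40, 1.37)
    ks_sds: tuple[float, float] = (0.08, 0.20)
    second_outgroup_ks: float = 0.90
    second_outgroup_retention: float = 0.85
    dnds: float = 0.2
    cds_codons: int = 300
    spurious_hit_fraction: float = 0.02
    tandem_arrays: int = 60
    gene_length: int = 2000
    gene_spacing: int = 8000
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    methylation: MethylationConfig = field(default_factory=MethylationConfig)

    def __post_init__(self) -> None:
        p1, p2 = self.retention_probs
        if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
            raise ValueError("retention probabilities must lie in [0, 1]")
        if p1 == 0 and p2 == 0:
            raise ValueError("retention_probs (0, 0) would produce an empty genome")
        if abs(sum(self.ks_weights) - 1) > 1e-9:
            raise ValueError("ks_weights must sum to 1")


def unbiased_preset(seed: int = 1) -> SimulationConfig:
    """Equal retention in both copies; no planted subgenome-level effects."""
    return SimulationConfig(seed=seed)


def biased_preset(seed: int = 1) -> SimulationConfig:
    """Retention bias p1 - p2 = 0.15 (copy A under-fractionated)."""
    return SimulationConfig(seed=seed, retention_probs=(0.675, 0.525))


@dataclass
class GroundTruth:
    """Per-gene and per-segment truth labels consistent with emitted files."""

    genes: pd.DataFrame  # indexed by duplicated-genome gene id
    segments: pd.DataFrame
    outgroup_map: pd.DataFrame  # per outgroup gene: chromosome, slot, out2 id or None

    def homeolog_pairs(self) -> pd.DataFrame:
        g = self.genes
        sub = g[(g["true_class"] == "homeolog") & (g["copy"] == "A")]
        return pd.DataFrame(
            {"gene_a": sub.index, "gene_b": sub["partner"].to_numpy()}
        )


@dataclass
class SimulatedGenomes:
    outgroup: GeneTable
    second_outgroup: GeneTable
    duplicated: GeneTable
    truth: GroundTruth
    hits_dup_out1: list[HitRecord]
    hits_dup_out2: list[HitRecord]
    hits_dup_intra: list[HitRecord]
    config: SimulationConfig


@dataclass
class SimulatedDataset(SimulatedGenomes):
    """Genome trio plus sequence, expression and methylation layers."""

    cds: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    expression: ExpressionMatrix | None = None
    intergenic: ExpressionMatrix | None = None
    methylation_replicates: list[MethylationTable] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Codon process calibration
# ---------------------------------------------------------------------------


class CodonProcess:
    """Symmetric sense-codon substitution process with selectable dN/dS.

    Exchange rate between codons one nucleotide apart is 1 for synonymous and
    ``dnds`` for nonsynonymous changes (stop codons unreachable).  The
    spectral decomposition gives transition kernels for any branch length,
    and the expected NG86 Ks as a function of total path time is inverted to
    map target Ks values onto branch lengths.
    """

    def __init__(self, dnds: float):
        if dnds <= 0:
            raise ValueError("dnds must be positive")
        self.dnds = dnds
        q = np.zeros((61, 61))
        for a in range(61):
            ca = CODONS[SENSE[a]]
            for pos in range(3):
                for b_nt in "ACGT":
                    if b_nt == ca[pos]:
                        continue
                    cb = ca[:pos] + b_nt + ca[pos + 1 :]
                    j64 = CODONS.index(cb)
                    b = _TO61[j64]
                    if b < 0:
                        continue
                    q[a, b] = 1.0 if AMINO[SENSE[a]] == AMINO[j64] else dnds
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalise to one expected event per unit time
        q /= -np.mean(np.diag(q))
        self._eigval, self._eigvec = np.linalg.eigh(q)
        self._syn61 = SYN_SITES[SENSE]
        self._synd61 = SYN_DIFF[np.ix_(SENSE, SENSE)]
        grid = np.concatenate([[0.0], np.geomspace(1e-3, 30.0, 600)])
        ks = np.array([self._expected_ks(t) for t in grid])
        keep = np.isfinite(ks)
        self._grid_t = grid[keep]
        self._grid_ks = ks[keep]

    def kernel(self, t: float) -> np.ndarray:
        p = (self._eigvec * np.exp(self._eigval * t)) @ self._eigvec.T
        p = np.clip(p, 0, None)
        return p / p.sum(axis=1, keepdims=True)

    def _expected_ks(self, t: float) -> float:
        j = self.kernel(t) / 61.0
        sd = float((j * self._synd61).sum())
        s = float(self._syn61.mean())
        ps = sd / s
        if ps >= 0.75:
            return math.inf
        return -0.75 * math.log(1 - 4 * ps / 3)

    def time_for_ks(self, ks: float) -> float:
        """Branch-path time whose expected NG86 Ks equals ``ks``."""
        ks = min(ks, self._grid_ks[-1] * 0.999)
        return float(np.interp(ks, self._grid_ks, self._grid_t))

    def evolve(self, codons61: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
        """Evolve a 61-space codon array for time t (vectorised by state)."""
        if t <= 0:
            return codons61.copy()
        p = self.kernel(t)
        out = np.empty_like(codons61)
        flat = codons61.ravel()
        oflat = out.ravel()
        for v in range(61):
            mask = flat == v
            k = int(mask.sum())
            if k:
                oflat[mask] = rng.choice(61, size=k, p=p[v])
        return out


def to64(codons61: np.ndarray) -> np.ndarray:
    return SENSE[codons61]


def codons_to_seq(codons64: np.ndarray) -> str:
    return "".join(np.asarray(CODONS, dtype=object)[codons64])


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


def simulate_genomes(config: SimulationConfig) -> SimulatedGenomes:
    """Generate the genome trio, hit tables and ground-truth labels."""
    rng = np.random.default_rng(config.seed)
    n_chrom = config.n_chromosomes
    sizes = [config.n_outgroup_genes // n_chrom] * n_chrom
    sizes[0] += config.n_outgroup_genes - sum(sizes)
    out_chroms = [f"oc{c + 1:02d}" for c in range(n_chrom)]

    # --- outgroup gene table -------------------------------------------------
    out_rows = []
    for c, chrom in enumerate(out_chroms):
        for i in range(sizes[c]):
            out_rows.append(
                (
                    f"out1_{c + 1:02d}g{i:04d}",
                    chrom,
                    i * 3000,
                    i * 3000 + 2000,
                    "+" if rng.random() < 0.5 else "-",
                )
            )
    outgroup = GeneTable.from_records("outgroup1", out_rows)
    out_gene_id = {
        (c, i): f"out1_{c + 1:02d}g{i:04d}" for c in range(n_chrom) for i in range(sizes[c])
    }

    # --- ancestral duplicated layout: segments on proto-chromosomes ----------
    # each segment: [out_chrom_idx, lo, hi, orient, copy]
    protos: list[list[list]] = []
    for copy in ("A", "B"):
        for c in range(n_chrom):
            protos.append([[c, 0, sizes[c], 1, copy]])
    for _ in range(config.ancient_segments):
        c = int(rng.integers(n_chrom))
        size = int(rng.integers(*config.ancient_segment_size))
        lo = int(rng.integers(0, max(1, sizes[c] - size)))
        seg = [c, lo, min(lo + size, sizes[c]), 1 if rng.random() < 0.5 else -1, "C"]
        protos[int(rng.integers(len(protos)))].append(seg)

    for _ in range(config.rearrangement_events):
        donor_idx = int(rng.integers(len(protos)))
        donor = protos[donor_idx]
        seg_lens = [s[2] - s[1] for s in donor]
        big = [k for k, L in enumerate(seg_lens) if L >= 3 * config.segment_size[0]]
        if not big:
            continue
        k = int(rng.choice(big))
        c, lo, hi, orient, copy = donor[k]
        max_cut = min(config.segment_size[1], hi - lo - 2 * config.segment_size[0])
        if max_cut < config.segment_size[0]:
            continue
        cut = int(rng.integers(config.segment_size[0], max_cut + 1))
        cut_lo = int(rng.integers(lo + config.segment_size[0], hi - config.segment_size[0] - cut + 1))
        piece = [c, cut_lo, cut_lo + cut, orient, copy]
        if rng.random() < config.inversion_prob:
            piece[3] = -piece[3]
        donor[k : k + 1] = [
            [c, lo, cut_lo, orient, copy],
            [c, cut_lo + cut, hi, orient, copy],
        ]
        choices = [i for i in range(len(protos)) if i != donor_idx]
        acceptor = protos[int(rng.choice(choices))]
        acceptor.insert(int(rng.integers(len(acceptor) + 1)), piece)

    # --- retention and segment bookkeeping -----------------------------------
    p1, p2 = config.retention_probs
    p_by_copy = {"A": p1, "B": p2, "C": config.ancient_retention}
    seg_records = []
    seg_masks = []
    seg_id = 0
    for proto in protos:
        for seg in proto:
            c, lo, hi, orient, copy = seg
            mask = rng.random(hi - lo) < p_by_copy[copy]
            ks_target = _draw_ks(rng, config, copy)
            seg.append(seg_id)
            seg_masks.append(mask)
            seg_records.append(
                {
                    "segment_id": seg_id,
                    "copy": copy,
                    "out_chrom_idx": c,
                    "lo": lo,
                    "hi": hi,
                    "orient": orient,
                    "ks_target": ks_target,
                    "n_retained": int(mask.sum()),
                }
            )
            seg_id += 1

    # --- materialise duplicated genome ---------------------------------------
    order = rng.permutation(len(protos))
    dup_chrom_names = {int(p): f"dc{r + 1:02d}" for r, p in enumerate(order)}
    gene_rows = []
    truth_rows = []
    serial = 0
    seg_dup_chrom: dict[int, str] = {}
    for p_idx, proto in enumerate(protos):
        chrom = dup_chrom_names[p_idx]
        pos = 0
        for seg in proto:
            c, lo, hi, orient, copy, sid = seg
            seg_dup_chrom[sid] = chrom
            mask = seg_masks[sid]
            slots = np.arange(lo, hi)[mask]
            if orient < 0:
                slots = slots[::-1]
            for o in slots:
                gid = f"dupg{serial:05d}"
                serial += 1
                gene_rows.append(
                    (
                        gid,
                        chrom,
                        pos * config.gene_spacing,
                        pos * config.gene_spacing + config.gene_length,
                        "+" if rng.random() < 0.5 else "-",
                    )
                )
                pos += 1
                truth_rows.append(
                    {
                        "gene_id": gid,
                        "dup_chrom": chrom,
                        "copy": copy,
                        "out_chrom_idx": c,
                        "out_slot": int(o),
                        "out_gene": out_gene_id[(c, int(o))],
                        "segment_id": sid,
                        "is_tandem": False,
                    }
                )

    truth_genes = pd.DataFrame(truth_rows).set_index("gene_id")

    # --- tandem arrays --------------------------------------------------------
    hits_intra: list[HitRecord] = []
    tandem_extras = []
    n_real = len(gene_rows)
    if config.tandem_arrays and n_real:
        hosts = rng.choice(n_real, size=min(config.tandem_arrays, n_real), replace=False)
        for h in sorted(hosts, reverse=True):
            host_row = gene_rows[h]
            n_extra = int(rng.integers(1, 3))
            members = [host_row[0]]
            for e in range(n_extra):
                gid = f"dupg{serial:05d}"
                serial += 1
                members.append(gid)
                tandem_extras.append((gid, host_row[0], h, e))
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    ev = 10.0 ** (-rng.uniform(30, 80))
                    hits_intra.append(HitRecord(members[i], members[j], ev, 500.0))
                    hits_intra.append(HitRecord(members[j], members[i], ev, 500.0))

    # rebuild gene rows with extras inserted after their host (shifting positions)
    extras_by_host: dict[int, list[str]] = {}
    for gid, host_gid, h, e in tandem_extras:
        extras_by_host.setdefault(h, []).append(gid)
    final_rows = []
    by_chrom_pos: dict[str, int] = {}
    for h, row in enumerate(gene_rows):
        gid, chrom, start, end, strand = row
        pos = by_chrom_pos.get(chrom, 0)
        final_rows.append((gid, chrom, pos * config.gene_spacing, pos * config.gene_spacing + config.gene_length, strand))
        pos += 1
        for egid in extras_by_host.get(h, []):
            final_rows.append(
                (egid, chrom, pos * config.gene_spacing, pos * config.gene_spacing + config.gene_length, "+" if rng.random() < 0.5 else "-")
            )
            pos += 1
        by_chrom_pos[chrom] = pos
    duplicated = GeneTable.from_records("duplicated", final_rows)

    host_lookup = {gid: gene_rows[h][0] for gid, _, h, _ in tandem_extras}
    extra_truth = pd.DataFrame(
        {
            "gene_id": [gid for gid, *_ in tandem_extras],
            "dup_chrom": [duplicated.position(gid)[0] for gid, *_ in tandem_extras],
            "copy": [truth_genes.loc[host_lookup[gid], "copy"] for gid, *_ in tandem_extras],
            "out_chrom_idx": -1,
            "out_slot": -1,
            "out_gene": None,
            "segment_id": -1,
            "is_tandem": True,
        }
    ).set_index("gene_id")
    tandem_hosts = set(host_lookup.values())
    truth_genes.loc[list(tandem_hosts), "is_tandem"] = True
    truth_genes = pd.concat([truth_genes, extra_truth])

    segments = pd.DataFrame(seg_records)
    segments["dup_chrom"] = segments["segment_id"].map(seg_dup_chrom)

    # --- second outgroup ------------------------------------------------------
    out2_rows = []
    out2_of: dict[str, str] = {}
    for c, chrom in enumerate(out_chroms):
        keep = rng.random(sizes[c]) < config.second_outgroup_retention
        pos = 0
        for i in range(sizes[c]):
            if not keep[i]:
                continue
            gid = f"out2_{c + 1:02d}g{i:04d}"
            out2_rows.append((gid, f"sc{c + 1:02d}", pos * 3000, pos * 3000 + 2000, "+" if rng.random() < 0.5 else "-"))
            out2_of[out_gene_id[(c, i)]] = gid
            pos += 1
    second_outgroup = GeneTable.from_records("outgroup2", out2_rows)

    # --- truth classes, partners and subgenome labels -------------------------
    truth_genes = _finish_truth(truth_genes, segments, sizes)

    # --- hit tables -----------------------------------------------------------
    hits1: list[HitRecord] = []
    hits2: list[HitRecord] = []
    for gid, row in truth_genes.iterrows():
        if row["is_tandem"] and row["out_gene"] is None:
            continue
        if row["out_gene"] is None or row["is_tandem"]:
            continue
        ev = 10.0 ** (-rng.uniform(10, 100))
        hits1.append(HitRecord(gid, row["out_gene"], ev, float(rng.uniform(200, 2000))))
        if row["copy"] in ("A", "B"):
            o2 = out2_of.get(row["out_gene"])
            if o2 is not None:
                ev2 = 10.0 ** (-rng.uniform(10, 80))
                hits2.append(HitRecord(gid, o2, ev2, float(rng.uniform(200, 2000))))
    # tandem hosts still hit their outgroup anchor (the pipeline excludes them
    # through the tandem classifier, not through hit absence)
    for gid, row in truth_genes.iterrows():
        if row["is_tandem"] and row["out_gene"] is not None:
            ev = 10.0 ** (-rng.uniform(10, 100))
            hits1.append(HitRecord(gid, row["out_gene"], ev, float(rng.uniform(200, 2000))))

    n_sp = int(round(config.spurious_hit_fraction * len(hits1)))
    all_dup = list(truth_genes.index)
    all_out = list(outgroup.df["gene_id"])
    for _ in range(n_sp):
        q = all_dup[int(rng.integers(len(all_dup)))]
        s = all_out[int(rng.integers(len(all_out)))]
        hits1.append(HitRecord(q, s, 10.0 ** (-rng.uniform(6, 9)), float(rng.uniform(50, 200))))

    outmap = outgroup.df[["gene_id", "chromosome", "order_index"]].copy()
    outmap["out2_gene"] = outmap["gene_id"].map(out2_of)
    truth = GroundTruth(genes=truth_genes, segments=segments, outgroup_map=outmap)
    return SimulatedGenomes(
        outgroup=outgroup,
        second_outgroup=second_outgroup,
        duplicated=duplicated,
        truth=truth,
        hits_dup_out1=hits1,
        hits_dup_out2=hits2,
        hits_dup_intra=hits_intra,
        config=config,
    )


def _draw_ks(rng: np.random.Generator, config: SimulationConfig, copy: str) -> float:
    if copy == "C":
        mu, sd, lo = config.ks_means[1], config.ks_sds[1], 0.6
    else:
        mu, sd, lo = config.ks_means[0], config.ks_sds[0], 0.08
    for _ in range(100):
        v = rng.normal(mu, sd)
        if v >= lo:
            return float(v)
    return mu


def _finish_truth(truth_genes: pd.DataFrame, segments: pd.DataFrame, sizes: list[int]) -> pd.DataFrame:
    """Add true class, partner and subgenome label per duplicated gene.

    The true label applies the pipeline's own singleton-majority rule to the
    *planted* segments (footprints spanning first to last retained,
    non-tandem gene), i.e. the label an ideal synteny detector would assign.
    Tandem-array genes are treated as excluded, mirroring the analysis.
    """
    n_chrom = len(sizes)
    real = truth_genes[~truth_genes["is_tandem"] | truth_genes["out_gene"].notna()]
    countable = truth_genes[(~truth_genes["is_tandem"]) & truth_genes["out_gene"].notna()]

    # retention grids per chromosome per copy, and segment id grids
    ret = {copy: [np.zeros(s, dtype=bool) for s in sizes] for copy in ("A", "B")}
    piece = {copy: [np.full(s, -1) for s in sizes] for copy in ("A", "B")}
    for gid, row in countable.iterrows():
        if row["copy"] in ("A", "B"):
            ret[row["copy"]][row["out_chrom_idx"]][row["out_slot"]] = True
    for seg in segments.itertuples(index=False):
        if seg.copy in ("A", "B"):
            piece[seg.copy][seg.out_chrom_idx][seg.lo : seg.hi] = seg.segment_id

    # footprints of recent segments: first..last retained countable slot
    foot: dict[int, tuple[int, int]] = {}
    seg_chrom_name = dict(zip(segments["segment_id"], segments["dup_chrom"]))
    for seg in segments.itertuples(index=False):
        if seg.copy not in ("A", "B"):
            continue
        mask = ret[seg.copy][seg.out_chrom_idx][seg.lo : seg.hi] & (
            piece[seg.copy][seg.out_chrom_idx][seg.lo : seg.hi] == seg.segment_id
        )
        idx = np.flatnonzero(mask)
        if idx.size >= 5:
            foot[seg.segment_id] = (seg.lo + int(idx[0]), seg.lo + int(idx[-1]) + 1)

    # elementary segmentation per outgroup chromosome and label rule
    seg_label_votes: dict[int, list[tuple[int, str]]] = {}
    elem_by_chrom: dict[int, list[tuple[int, int, dict[int, int]]]] = {}
    for c in range(n_chrom):
        pieces_here = [
            (sid, lo, hi)
            for sid, (lo, hi) in foot.items()
            if segments.loc[segments["segment_id"] == sid, "out_chrom_idx"].iloc[0] == c
        ]
        points = sorted({p for _, lo, hi in pieces_here for p in (lo, hi)})
        elems = []
        for lo, hi in zip(points, points[1:]):
            cover = [sid for sid, flo, fhi in pieces_here if flo <= lo and fhi >= hi]
            if not cover:
                continue
            if elems and elems[-1][1] == lo and set(elems[-1][2]) == set(cover):
                elems[-1] = (elems[-1][0], hi, elems[-1][2])
            else:
                elems.append((lo, hi, {sid: None for sid in cover}))
        for k, (lo, hi, cover) in enumerate(elems):
            if len(cover) < 2:
                continue
            sids = sorted(cover)
            counts = {}
            for sid in sids:
                copy = segments.loc[segments["segment_id"] == sid, "copy"].iloc[0]
                r_self = ret[copy][c][lo:hi] & (piece[copy][c][lo:hi] == sid)
                other = "B" if copy == "A" else "A"
                r_other = ret[other][c][lo:hi]
                counts[sid] = (
                    int((r_self & ~r_other).sum()),
                    int(r_self.sum()),
                )
            keyed = sorted(
                sids,
                key=lambda sid: region_order_key(
                    counts[sid][0], counts[sid][1], seg_chrom_name[sid]
                ),
            )
            labels = {keyed[0]: "subgenome1", keyed[1]: "subgenome2"}
            for sid in sids[:2]:
                lab = labels.get(sid, "unassigned")
                cover[sid] = lab
                seg_label_votes.setdefault(sid, []).append((hi - lo, lab))
        elem_by_chrom[c] = elems

    seg_global = {sid: max(v)[1] for sid, v in seg_label_votes.items()}

    # per-gene labels, classes and partners
    partner_lookup: dict[tuple[str, int, int], str] = {}
    for gid, row in countable.iterrows():
        if row["copy"] in ("A", "B"):
            partner_lookup[(row["copy"], row["out_chrom_idx"], row["out_slot"])] = gid

    classes, partners, labels_out = {}, {}, {}
    for gid, row in truth_genes.iterrows():
        if row["is_tandem"]:
            classes[gid] = "tandem"
            partners[gid] = None
            labels_out[gid] = None
            continue
        copy = row["copy"]
        if copy == "C":
            classes[gid] = "ancient"
            partners[gid] = None
            labels_out[gid] = None
            continue
        c, o = row["out_chrom_idx"], row["out_slot"]
        other = "B" if copy == "A" else "A"
        mate = partner_lookup.get((other, c, o))
        if mate is not None:
            classes[gid] = "homeolog"
            partners[gid] = mate
        else:
            classes[gid] = "singleton"
            partners[gid] = None
        sid = row["segment_id"]
        lab = None
        for lo, hi, cover in elem_by_chrom.get(c, []):
            if lo <= o < hi and sid in cover:
                lab = cover[sid]
                break
        if lab is None:
            lab = seg_global.get(sid)
        labels_out[gid] = lab
    truth_genes = truth_genes.copy()
    truth_genes["true_class"] = pd.Series(classes)
    truth_genes["partner"] = pd.Series(partners)
    truth_genes["true_label"] = pd.Series(labels_out)
    return truth_genes


# ---------------------------------------------------------------------------
# Coding sequences
# ---------------------------------------------------------------------------


def simulate_cds_pairs(
    n_pairs: int, length_codons: int, dnds: float, ks_target: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent sequence pairs at a target Ks (64-space codon arrays)."""
    rng = np.random.default_rng(seed)
    proc = CodonProcess(dnds)
    t = proc.time_for_ks(ks_target)
    anc = rng.integers(0, 61, size=(n_pairs, length_codons))
    a = proc.evolve(anc, t / 2, rng)
    b = proc.evolve(anc, t / 2, rng)
    return [(to64(x), to64(y)) for x, y in zip(a, b)]


def simulate_cds(sim: SimulatedGenomes, rng: np.random.Generator | None = None) -> dict[str, dict[str, np.ndarray]]:
    """Codon sequences for every gene of the trio, consistent with block Ks.

    Per ancestral gene family the tree is: root (speciation with the second
    outgroup) -> pear/peach-like split -> duplicated-copy split.  Branch
    lengths are set so the duplicated-vs-outgroup pairwise Ks matches the
    gene's planted segment Ks, the second-outgroup distance matches
    ``second_outgroup_ks``, and homeologs are younger than the speciation.
    Returns 64-space codon arrays keyed by genome then gene id.
    """
    config = sim.config
    rng = rng or np.random.default_rng(config.seed + 1_000_003)
    proc = CodonProcess(config.dnds)
    L = config.cds_codons
    out_df = sim.outgroup.df
    fam_index = {g: i for i, g in enumerate(out_df["gene_id"])}
    n_fam = len(fam_index)

    t_spec = proc.time_for_ks(config.ks_means[0])
    w = t_spec / 2  # first-outgroup branch from the speciation root
    u = max(proc.time_for_ks(config.second_outgroup_ks) - w, 0.05 * t_spec)

    root = rng.integers(0, 61, size=(n_fam, L))
    out1_seq = proc.evolve(root, w, rng)
    out2_seq = proc.evolve(root, u, rng)

    truth = sim.truth.genes
    seg_ks = dict(zip(sim.truth.segments["segment_id"], sim.truth.segments["ks_target"]))
    real = truth[truth["out_gene"].notna()]

    dup_seqs: dict[str, np.ndarray] = {}
    # group genes by segment so one kernel serves the whole segment
    for sid, group in real.groupby("segment_id"):
        ks = seg_ks.get(sid)
        if ks is None:
            continue
        t_total = max(proc.time_for_ks(ks) - w, 0.02 * t_spec)
        fams = np.array([fam_index[g] for g in group["out_gene"]])
        tips = proc.evolve(root[fams], t_total, rng)
        for gid, row_seq in zip(group.index, tips):
            dup_seqs[gid] = row_seq

    cds = {
        "outgroup1": {
            g: to64(out1_seq[i]) for g, i in fam_index.items()
        },
        "outgroup2": {},
        "duplicated": {g: to64(s) for g, s in dup_seqs.items()},
    }
    out2_map = dict(zip(sim.truth.outgroup_map["gene_id"], sim.truth.outgroup_map["out2_gene"]))
    for g, i in fam_index.items():
        o2 = out2_map.get(g)
        if isinstance(o2, str):
            cds["outgroup2"][o2] = to64(out2_seq[i])
    # tandem extras have no outgroup anchor; they get fresh random sequences
    # (they are excluded from Ka/Ks analyses, which only touch anchor pairs)
    missing = [g for g in truth.index if g not in dup_seqs and truth.loc[g, "out_gene"] is None]
    if missing:
        cds["duplicated"].update(
            {g: to64(s) for g, s in zip(missing, rng.integers(0, 61, size=(len(missing), L)))}
        )
    return cds


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Gene and intergenic TPM matrices plus the planted-effect table.

    Homeolog partners share a family baseline and per-tissue effect; a
    configured fraction of homeolog pairs receives a log(dominance_fold)
    boost on one random member in every tissue.  Singletons get
    ``singleton_shift``; copy-B genes get ``subgenome_shift``.  Intergenic
    regions are exponential with mean ``intergenic_mean``.
    """
    ec = config.expression
    rng = rng or np.random.default_rng(config.seed + 2_000_003)
    genes = truth.genes
    tissues = [f"tissue{t + 1}" for t in range(ec.tissue_count)]
    fam_key = genes["out_gene"].fillna(genes.index.to_series())
    fams = fam_key.unique()
    fam_idx = {f: i for i, f in enumerate(fams)}
    base = rng.normal(ec.log_mean, ec.gene_sd, size=len(fams))
    tissue_eff = rng.normal(0, ec.tissue_sd, size=(len(fams), ec.tissue_count))

    fam_of = fam_key.map(fam_idx).to_numpy()
    log_tpm = base[fam_of][:, None] + tissue_eff[fam_of]
    log_tpm = log_tpm + rng.normal(0, ec.member_sd, size=log_tpm.shape)
    is_singleton = (genes["true_class"] == "singleton").to_numpy()
    log_tpm[is_singleton] += ec.singleton_shift
    if ec.subgenome_shift:
        log_tpm[(genes["copy"] == "B").to_numpy()] += ec.subgenome_shift

    pairs = truth.homeolog_pairs()
    n_dom = int(round(ec.dominance_fraction * len(pairs)))
    effects = []
    if n_dom:
        chosen = rng.choice(len(pairs), size=n_dom, replace=False)
        gene_pos = {g: i for i, g in enumerate(genes.index)}
        for k in chosen:
            ga, gb = pairs.iloc[k]["gene_a"], pairs.iloc[k]["gene_b"]
            winner = ga if rng.random() < 0.5 else gb
            log_tpm[gene_pos[winner]] += math.log(ec.dominance_fold)
            effects.append({"gene_a": ga, "gene_b": gb, "dominant_member": winner})
    effect_df = pd.DataFrame(effects, columns=["gene_a", "gene_b", "dominant_member"])

    expr = ExpressionMatrix(pd.DataFrame(np.exp(log_tpm), index=genes.index, columns=tissues))
    inter = ExpressionMatrix(
        pd.DataFrame(
            rng.exponential(ec.intergenic_mean, size=(ec.n_intergenic, ec.tissue_count)),
            index=[f"intergenic{i:05d}" for i in range(ec.n_intergenic)],
            columns=tissues,
        )
    )
    return expr, inter, effect_df


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(
    duplicated: GeneTable,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    extra_logit: pd.DataFrame | None = None,
    gene_subset: list[str] | None = None,
) -> tuple[list[MethylationTable], pd.DataFrame]:
    """Replicate CX tables with per-gene, per-region, per-context true levels.

    Cytosines are laid every ~``site_spacing`` bp across the 3-kb flanks and
    body of each simulated gene; per replicate, coverage is Poisson(depth)
    and methylated counts are Binomial(coverage, level).  ``extra_logit`` may
    add per-gene logit shifts in columns named like ``CHG_body``.  Returns
    the replicate tables and the per-gene true-level table.
    """
    mc = config.methylation
    rng = rng or np.random.default_rng(config.seed + 3_000_003)
    genes = duplicated.df.set_index("gene_id")
    if gene_subset is None:
        gene_subset = _default_methylation_genes(truth, mc.max_genes)
    genes = genes.loc[[g for g in gene_subset if g in genes.index]]
    tg = truth.genes

    contexts = ["CG", "CHG", "CHH"]
    level_rows = []
    chrom_arrays: dict[str, dict[str, list]] = {}
    flank = 3000
    for gid, row in genes.iterrows():
        is_single = tg.loc[gid, "true_class"] == "singleton" if gid in tg.index else False
        is_b = tg.loc[gid, "copy"] == "B" if gid in tg.index else False
        levels = {}
        for ctx in contexts:
            base = mc.levels[ctx]
            for region, b in zip(("upstream", "body", "downstream"), base):
                x = _logit(min(max(b, 1e-4), 1 - 1e-4)) + rng.normal(0, mc.gene_sd_logit)
                if is_single:
                    x += mc.singleton_shift
                if is_b:
                    x += mc.subgenome_shift
                if extra_logit is not None and gid in extra_logit.index:
                    col = f"{ctx}_{region}"
                    if col in extra_logit.columns:
                        x += float(extra_logit.loc[gid, col])
                levels[(ctx, region)] = float(_sigmoid(np.array([x]))[0])
        level_rows.append({"gene_id": gid, **{f"{c}_{r}": v for (c, r), v in levels.items()}})

        start, end, strand, chrom = row["start"], row["end"], row["strand"], row["chromosome"]
        lo = max(start - flank, 0)
        hi = end + flank
        n_sites = max(int((hi - lo) // mc.site_spacing), 1)
        pos0 = lo + rng.integers(0, mc.site_spacing) + mc.site_spacing * np.arange(n_sites)
        pos0 = pos0[pos0 < hi]
        ctx_draw = rng.choice(len(contexts), size=pos0.size, p=mc.context_probs)
        strands = np.where(rng.random(pos0.size) < 0.5, "+", "-")
        # region of each cytosine, transcription-oriented
        if strand == "+":
            region_idx = np.where(pos0 < start, 0, np.where(pos0 < end, 1, 2))
        else:
            region_idx = np.where(pos0 < start, 2, np.where(pos0 < end, 1, 0))
        region_names = np.array(["upstream", "body", "downstream"])
        lv = np.array(
            [
                levels[(contexts[c], region_names[r])]
                for c, r in zip(ctx_draw, region_idx)
            ]
        )
        arrs = chrom_arrays.setdefault(
            chrom, {"pos": [], "strand": [], "context": [], "level": []}
        )
        arrs["pos"].append(pos0 + 1)  # CX reports are 1-based
        arrs["strand"].append(strands)
        arrs["context"].append(np.array(contexts, dtype=object)[ctx_draw])
        arrs["level"].append(lv)

    replicates = []
    for _ in range(mc.n_replicates):
        frames = []
        for chrom in sorted(chrom_arrays):
            arrs = chrom_arrays[chrom]
            pos = np.concatenate(arrs["pos"])
            lv = np.concatenate(arrs["level"])
            total = rng.poisson(mc.depth, size=pos.size)
            meth = rng.binomial(total, lv)
            frames.append(
                pd.DataFrame(
                    {
                        "chromosome": chrom,
                        "position": pos,
                        "strand": np.concatenate(arrs["strand"]),
                        "context": np.concatenate(arrs["context"]),
                        "count_methylated": meth,
                        "count_total": total,
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        replicates.append(MethylationTable(df))
    return replicates, pd.DataFrame(level_rows).set_index("gene_id")


def _default_methylation_genes(truth: GroundTruth, max_genes: int) -> list[str]:
    """Homeolog pairs first (kept whole), then singletons, up to the cap."""
    pairs = truth.homeolog_pairs()
    out: list[str] = []
    for r in pairs.itertuples(index=False):
        if len(out) + 2 > int(max_genes * 0.7):
            break
        out.extend((r.gene_a, r.gene_b))
    singles = truth.genes[truth.genes["true_class"] == "singleton"].index.tolist()
    out.extend(singles[: max_genes - len(out)])
    return out


# ---------------------------------------------------------------------------
# Full dataset and file emission
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Genomes plus CDS, expression and methylation layers."""
    sim = simulate_genomes(config)
    cds = simulate_cds(sim)
    expr, inter, effects = simulate_expression(sim.truth, config)
    meth, levels = simulate_methylation(sim.duplicated, sim.truth, config)
    ds = SimulatedDataset(
        outgroup=sim.outgroup,
        second_outgroup=sim.second_outgroup,
        duplicated=sim.duplicated,
        truth=sim.truth,
        hits_dup_out1=sim.hits_dup_out1,
        hits_dup_out2=sim.hits_dup_out2,
        hits_dup_intra=sim.hits_dup_intra,
        config=config,
        cds=cds,
        expression=expr,
        intergenic=inter,
        methylation_replicates=meth,
    )
    ds.truth.genes["planted_dominant"] = ds.truth.genes.index.isin(
        set(effects["dominant_member"]) if len(effects) else set()
    )
    ds.planted_dominance = effects  # type: ignore[attr-defined]
    ds.true_methylation_levels = levels  # type: ignore[attr-defined]
    return ds


def write_fasta(seqs: dict[str, np.ndarray], path: str) -> None:
    with open(path, "w") as fh:
        for gid in sorted(seqs):
            fh.write(f">{gid}\n{codons_to_seq(seqs[gid])}\n")


def write_dataset(ds: SimulatedDataset, outdir: str) -> dict[str, str]:
    """Write every layer as plain-text pipeline inputs; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    paths = {
        "outgroup_bed": p("outgroup1.bed"),
        "second_outgroup_bed": p("outgroup2.bed"),
        "duplicated_bed": p("duplicated.bed"),
        "hits_dup_out1": p("dup_vs_out1.m8"),
        "hits_dup_out2": p("dup_vs_out2.m8"),
        "hits_dup_intra": p("dup_intra.m8"),
        "cds_duplicated": p("duplicated.cds.fa"),
        "cds_outgroup1": p("outgroup1.cds.fa"),
        "cds_outgroup2": p("outgroup2.cds.fa"),
        "tpm": p("tpm.tsv"),
        "intergenic_tpm": p("intergenic_tpm.tsv"),
        "truth": p("truth.tsv"),
    }
    ds.outgroup.to_bed(paths["outgroup_bed"])
    ds.second_outgroup.to_bed(paths["second_outgroup_bed"])
    ds.duplicated.to_bed(paths["duplicated_bed"])
    write_blast_m8(ds.hits_dup_out1, paths["hits_dup_out1"])
    write_blast_m8(ds.hits_dup_out2, paths["hits_dup_out2"])
    write_blast_m8(ds.hits_dup_intra, paths["hits_dup_intra"])
    if ds.cds:
        write_fasta(ds.cds["duplicated"], paths["cds_duplicated"])
        write_fasta(ds.cds["outgroup1"], paths["cds_outgroup1"])
        write_fasta(ds.cds["outgroup2"], paths["cds_outgroup2"])
    if ds.expression is not None:
        write_tpm_matrix(ds.expression, paths["tpm"])
        write_tpm_matrix(ds.intergenic, paths["intergenic_tpm"])
    for i, rep in enumerate(ds.methylation_replicates, 1):
        paths[f"methylation_rep{i}"] = p(f"methylation_rep{i}.cx")
        write_cx_report(rep, paths[f"methylation_rep{i}"])
    ds.truth.genes.to_csv(paths["truth"], sep="\t")
    with open(p("config.json"), "w") as fh:
        json.dump(asdict(ds.config), fh, indent=1, default=list)
    return paths
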