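"""End-to-end orchestration: synteny -> Ks dating -> subgenomes -> biases.

``run_all`` executes the stages in order from a single configuration, writes
per-stage TSV products plus a JSON report, and records every filter's removal
counts.  Optional inputs (second outgroup, expression, methylation) that are
absent cause their stage to be skipped and flagged in the report rather than
aborting; a genuine failure inside a stage aborts with the stage name.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from paleofrac import expression as expr_mod
from paleofrac import fractionation as frac_mod
from paleofrac import methylation as meth_mod
from paleofrac.io_formats import (
    ExpressionMatrix,
    GeneTable,
    HitRecord,
    MethylationTable,
    read_blast_m8,
    read_cx_report,
    read_fasta,
    read_gene_positions,
    read_tpm_matrix,
    write_collinearity,
)
from paleofrac.molevol import (
    KsMixtureModel,
    batch_ng86,
    block_ks,
    classify_blocks_by_ks,
    encode_cds,
    fit_ks_mixture,
)
from paleofrac.stats import comparison_row, mann_whitney_u
from paleofrac.subgenome import (
    SubgenomeAssignment,
    assign_subgenomes,
    build_block_anchor_index,
    count_singletons,
    flag_high_confidence,
    homeolog_table,
    pair_homologous_regions,
    singleton_table,
)
from paleofrac.synteny import (
    ChainParams,
    SyntenicBlock,
    block_summary,
    chain_anchors,
    classify_tandem,
    filter_blocks,
    syntenic_depth,
)

logger = logging.getLogger(__name__)

ANALYSIS_CONTEXTS = ("CG", "CHG")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths to inputs plus the knobs of every stage.

    Optional inputs may be None; their stages are then skipped and flagged.
    """

    duplicated_genes: str = ""
    outgroup_genes: str = ""
    second_outgroup_genes: str | None = None
    gene_format: str = "bed"
    hits_dup_out1: str = ""
    hits_dup_out2: str | None = None
    hits_dup_intra: str | None = None
    cds_duplicated: str | None = None
    cds_outgroup1: str | None = None
    cds_outgroup2: str | None = None
    tpm: str | None = None
    intergenic_tpm: str | None = None
    methylation: list[str] = field(default_factory=list)
    outdir: str | None = None

    chain: ChainParams = field(default_factory=ChainParams)
    mixture_k: int = 2
    ks_cap: float = 3.0
    seed: int = 0
    window: int = 100
    step: int = 1
    fold: float = 2.0
    flank: int = 3000
    flank_bin: int = 100
    body_bins: int = 40
    min_total: int = 1
    tandem_max_intervening: int = 1


@dataclass
class InputBundle:
    """In-memory pipeline inputs (what the path config loads)."""

    duplicated: GeneTable
    outgroup: GeneTable
    second_outgroup: GeneTable | None = None
    hits_dup_out1: list[HitRecord] = field(default_factory=list)
    hits_dup_out2: list[HitRecord] | None = None
    hits_dup_intra: list[HitRecord] | None = None
    cds_duplicated: dict | None = None
    cds_outgroup1: dict | None = None
    cds_outgroup2: dict | None = None
    expression: ExpressionMatrix | None = None
    intergenic: ExpressionMatrix | None = None
    methylation: list[MethylationTable] = field(default_factory=list)


@dataclass
class PipelineResult:
    report: dict
    assignment: SubgenomeAssignment | None
    recent_blocks: list[SyntenicBlock]
    ancient_blocks: list[SyntenicBlock]
    mixture: KsMixtureModel | None
    loss_table: pd.DataFrame
    retention_profile: pd.DataFrame
    comparisons: pd.DataFrame
    dominance_summary: pd.DataFrame
    tables: dict = field(default_factory=dict)


def load_inputs(config: PipelineConfig) -> InputBundle:
    def cds(path):
        if not path:
            return None
        return {g: encode_cds(s) for g, s in read_fasta(path).items()}

    bundle = InputBundle(
        duplicated=read_gene_positions(config.duplicated_genes, config.gene_format, "duplicated"),
        outgroup=read_gene_positions(config.outgroup_genes, config.gene_format, "outgroup1"),
        hits_dup_out1=read_blast_m8(config.hits_dup_out1, config.chain.evalue_cutoff),
    )
    if config.second_outgroup_genes:
        bundle.second_outgroup = read_gene_positions(
            config.second_outgroup_genes, config.gene_format, "outgroup2"
        )
    if config.hits_dup_out2:
        bundle.hits_dup_out2 = read_blast_m8(config.hits_dup_out2, config.chain.evalue_cutoff)
    if config.hits_dup_intra:
        bundle.hits_dup_intra = read_blast_m8(config.hits_dup_intra, config.chain.evalue_cutoff)
    bundle.cds_duplicated = cds(config.cds_duplicated)
    bundle.cds_outgroup1 = cds(config.cds_outgroup1)
    bundle.cds_outgroup2 = cds(config.cds_outgroup2)
    if config.tpm:
        bundle.expression = read_tpm_matrix(config.tpm)
    if config.intergenic_tpm:
        bundle.intergenic = read_tpm_matrix(config.intergenic_tpm)
    bundle.methylation = [read_cx_report(p) for p in config.methylation]
    return bundle


def config_from_paths(paths: dict[str, str], **overrides) -> PipelineConfig:
    """PipelineConfig from the path map of :func:`synthetic_data.write_dataset`."""
    meth = sorted(v for k, v in paths.items() if k.startswith("methylation_rep"))
    return PipelineConfig(
        duplicated_genes=paths["duplicated_bed"],
        outgroup_genes=paths["outgroup_bed"],
        second_outgroup_genes=paths.get("second_outgroup_bed"),
        gene_format="bed",
        hits_dup_out1=paths["hits_dup_out1"],
        hits_dup_out2=paths.get("hits_dup_out2"),
        hits_dup_intra=paths.get("hits_dup_intra"),
        cds_duplicated=paths.get("cds_duplicated"),
        cds_outgroup1=paths.get("cds_outgroup1"),
        cds_outgroup2=paths.get("cds_outgroup2"),
        tpm=paths.get("tpm"),
        intergenic_tpm=paths.get("intergenic_tpm"),
        methylation=meth,
        **overrides,
    )


def bundle_from_dataset(ds) -> InputBundle:
    """In-memory bundle from a :class:`~paleofrac.synthetic_data.SimulatedDataset`."""
    return InputBundle(
        duplicated=ds.duplicated,
        outgroup=ds.outgroup,
        second_outgroup=ds.second_outgroup,
        hits_dup_out1=ds.hits_dup_out1,
        hits_dup_out2=ds.hits_dup_out2,
        hits_dup_intra=ds.hits_dup_intra,
        cds_duplicated=ds.cds.get("duplicated") if ds.cds else None,
        cds_outgroup1=ds.cds.get("outgroup1") if ds.cds else None,
        cds_outgroup2=ds.cds.get("outgroup2") if ds.cds else None,
        expression=ds.expression,
        intergenic=ds.intergenic,
        methylation=list(ds.methylation_replicates),
    )


def label_accuracy(assignment: SubgenomeAssignment, truth_genes: pd.DataFrame) -> float:
    """Gene-level subgenome label accuracy against truth, up to global swap."""
    pred = assignment.genes["label"]
    pred = pred[pred.isin(["subgenome1", "subgenome2"])]
    true = truth_genes["true_label"].reindex(pred.index)
    mask = true.isin(["subgenome1", "subgenome2"])
    if not mask.any():
        return math.nan
    agree = float((pred[mask] == true[mask]).mean())
    return max(agree, 1.0 - agree)


# ---------------------------------------------------------------------------
# Ka/Ks over block anchor pairs
# ---------------------------------------------------------------------------


def pair_kaks_table(
    blocks: Sequence[SyntenicBlock], cds_a: dict, cds_b: dict
) -> pd.DataFrame:
    """NG86 Ka/Ks for every anchor pair with equal-length CDS on both sides.

    Pairs whose sequences are missing or of unequal length are skipped (the
    pipeline does not align; CDS inputs must be comparable as given).
    """
    rows = []
    arrs_a, arrs_b = [], []
    for b in blocks:
        for p in b.pairs:
            sa = cds_a.get(p.gene_a)
            sb = cds_b.get(p.gene_b)
            if sa is None or sb is None or len(sa) != len(sb):
                continue
            rows.append((b.block_id, p.gene_a, p.gene_b, len(sa)))
            arrs_a.append(sa)
            arrs_b.append(sb)
    if not rows:
        return pd.DataFrame(columns=["block_id", "gene_a", "gene_b", "ka", "ks", "ratio"])
    df = pd.DataFrame(rows, columns=["block_id", "gene_a", "gene_b", "length"])
    out_parts = []
    for length, idx in df.groupby("length").groups.items():
        idx = list(idx)
        a = np.stack([arrs_a[i] for i in idx])
        b = np.stack([arrs_b[i] for i in idx])
        res = batch_ng86(a, b)
        part = df.loc[idx, ["block_id", "gene_a", "gene_b"]].copy()
        part["ka"] = res["ka"]
        part["ks"] = res["ks"]
        part["ratio"] = res["ratio"]
        out_parts.append(part)
    return pd.concat(out_parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run every stage from file inputs; see module docstring."""
    try:
        bundle = load_inputs(config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load_inputs", exc) from exc
    return run_bundle(bundle, config)


def run_bundle(bundle: InputBundle, config: PipelineConfig) -> PipelineResult:
    report: dict = {"parameters": _echo_params(config), "skipped_stages": []}
    comparisons: list[dict] = []

    # --- synteny --------------------------------------------------------------
    try:
        dup_tandem = (
            classify_tandem(bundle.hits_dup_intra, bundle.duplicated, config.tandem_max_intervening)
            if bundle.hits_dup_intra
            else set()
        )
        blocks_raw = chain_anchors(
            bundle.hits_dup_out1, bundle.duplicated, bundle.outgroup, config.chain
        )
        blocks, removal_log = filter_blocks(blocks_raw)
        report["synteny"] = {
            "n_hits": len(bundle.hits_dup_out1),
            "n_tandem_genes": len(dup_tandem),
            "blocks_before_filter": len(blocks_raw),
            "blocks_after_filter": len(blocks),
            "removed_by_reason": removal_log["reason"].value_counts().to_dict()
            if len(removal_log)
            else {},
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("synteny", exc) from exc

    # --- Ks dating ------------------------------------------------------------
    mixture = None
    ancient: list[SyntenicBlock] = []
    recent = blocks
    kaks1 = pd.DataFrame()
    try:
        if bundle.cds_duplicated and bundle.cds_outgroup1:
            kaks1 = pair_kaks_table(blocks, bundle.cds_duplicated, bundle.cds_outgroup1)
            ks_map = {
                (r.gene_a, r.gene_b): r.ks for r in kaks1.itertuples(index=False)
            }
            for b in blocks:
                block_ks(b, ks_map)
            med = [b.median_ks for b in blocks if b.median_ks is not None]
            # fit on the per-pair Ks distribution (large n keeps EM stable);
            # blocks are then dated by the posterior of their median Ks
            pair_ks = kaks1["ks"].to_numpy()
            mixture = fit_ks_mixture(
                pair_ks[np.isfinite(pair_ks)],
                k=config.mixture_k,
                seed=config.seed,
                ks_cap=config.ks_cap,
            )
            recent, ancient = classify_blocks_by_ks(blocks, mixture)
            report["ks_dating"] = {
                "n_pairs_with_ks": int(np.isfinite(pair_ks).sum()),
                "n_blocks_with_ks": len(med),
                "weights": list(np.round(mixture.weights, 4)),
                "means": list(np.round(mixture.means, 4)),
                "sds": list(np.round(mixture.sds, 4)),
                "recent_blocks": len(recent),
                "ancient_blocks_removed": len(ancient),
            }
        else:
            report["skipped_stages"].append("ks_dating")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("ks_dating", exc) from exc

    # --- subgenome assignment ---------------------------------------------------
    try:
        pairs = pair_homologous_regions(recent)
        anchor_index = build_block_anchor_index(recent)
        for pair in pairs:
            count_singletons(pair, anchor_index, bundle.outgroup, dup_tandem)
        assignment = assign_subgenomes(pairs, bundle.outgroup)
        second_blocks: list[SyntenicBlock] = []
        if bundle.second_outgroup is not None and bundle.hits_dup_out2:
            second_raw = chain_anchors(
                bundle.hits_dup_out2, bundle.duplicated, bundle.second_outgroup, config.chain
            )
            second_blocks, _ = filter_blocks(second_raw)
            flag_high_confidence(assignment, second_blocks)
        else:
            report["skipped_stages"].append("high_confidence")
        report["subgenome"] = {
            "region_pairs": len(pairs),
            "paired_regions": sum(1 for p in pairs if p.region_2 is not None),
            **assignment.counts(),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("subgenome", exc) from exc

    # --- fractionation ----------------------------------------------------------
    try:
        loss_table = frac_mod.chromosome_loss_rates(bundle.outgroup, assignment)
        profile = frac_mod.window_retention(
            bundle.outgroup, assignment, config.window, config.step
        )
        depth_out = syntenic_depth(recent, "b", bundle.outgroup)
        depth_dup = syntenic_depth(recent, "a", bundle.duplicated)
        report["fractionation"] = {
            "loss_table": loss_table.drop(
                columns=[c for c in loss_table.columns if c.endswith("_raw")]
            ).to_dict("records"),
            "max_loss_rate_difference": float(loss_table["difference"].max())
            if len(loss_table)
            else math.nan,
            "less_fractionated_by_chromosome": {
                r.chromosome: ("subgenome1" if r.loss_sg1_raw <= r.loss_sg2_raw else "subgenome2")
                for r in loss_table.itertuples(index=False)
            },
        }
        report["syntenic_depth"] = {
            "outgroup_reference": depth_out.to_dict("records"),
            "duplicated_reference": depth_dup.to_dict("records"),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fractionation", exc) from exc

    homeologs = homeolog_table(assignment)
    singletons = singleton_table(assignment)
    hc_pairs = homeologs[homeologs["high_confidence"]] if len(homeologs) else homeologs

    # --- expression -------------------------------------------------------------
    dom_summary = pd.DataFrame()
    threshold = None
    try:
        if bundle.expression is not None and bundle.intergenic is not None:
            threshold = expr_mod.intergenic_threshold(bundle.intergenic)
            use_pairs = hc_pairs if len(hc_pairs) else homeologs
            calls = expr_mod.dominance_calls(
                use_pairs, bundle.expression, threshold.value, config.fold
            )
            dom_summary = expr_mod.dominance_summary(calls)
            mean1 = expr_mod.mean_tpm(bundle.expression, use_pairs["gene_sg1"])
            mean2 = expr_mod.mean_tpm(bundle.expression, use_pairs["gene_sg2"])
            comparisons.append(
                comparison_row(
                    "expression:homeolog_sg1_vs_sg2",
                    mann_whitney_u(mean1.to_numpy(), mean2.to_numpy()),
                )
            )
            for label in ("subgenome1", "subgenome2"):
                single_genes = singletons.loc[singletons["label"] == label, "gene_id"]
                hom_genes = (
                    use_pairs["gene_sg1"] if label == "subgenome1" else use_pairs["gene_sg2"]
                )
                s_tpm = expr_mod.mean_tpm(bundle.expression, single_genes)
                h_tpm = expr_mod.mean_tpm(bundle.expression, hom_genes)
                if len(s_tpm) >= 3 and len(h_tpm) >= 3:
                    comparisons.append(
                        comparison_row(
                            f"expression:singleton_vs_homeolog_{label}",
                            mann_whitney_u(s_tpm.to_numpy(), h_tpm.to_numpy()),
                        )
                    )
                    s_b = expr_mod.breadth_series(bundle.expression, single_genes, threshold.value)
                    h_b = expr_mod.breadth_series(bundle.expression, hom_genes, threshold.value)
                    comparisons.append(
                        comparison_row(
                            f"breadth:singleton_vs_homeolog_{label}",
                            mann_whitney_u(s_b.to_numpy(), h_b.to_numpy()),
                        )
                    )
            report["expression"] = {
                "threshold": threshold.value,
                "per_tissue_medians": threshold.per_tissue_medians,
                "n_pairs_used": int(len(use_pairs)),
                "dominance_summary": dom_summary.round(2).to_dict(),
                "mean_pct_dominant_sg1": float(dom_summary["dominant_sg1"].mean())
                if len(dom_summary)
                else math.nan,
                "mean_pct_dominant_sg2": float(dom_summary["dominant_sg2"].mean())
                if len(dom_summary)
                else math.nan,
            }
        else:
            report["skipped_stages"].append("expression")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("expression", exc) from exc

    # --- evolutionary rates vs second outgroup ----------------------------------
    try:
        if bundle.cds_duplicated and bundle.cds_outgroup2 and "second_blocks" in locals() and second_blocks:
            kaks2 = pair_kaks_table(second_blocks, bundle.cds_duplicated, bundle.cds_outgroup2)
            per_gene = (
                kaks2.dropna(subset=["ks"])
                .drop_duplicates(subset="gene_a")
                .set_index("gene_a")[["ka", "ks", "ratio"]]
            )
            _rate_comparisons(per_gene, hc_pairs, singletons, comparisons)
            report["evolutionary_rate"] = {"n_genes_with_kaks": int(len(per_gene))}
        else:
            report["skipped_stages"].append("evolutionary_rate")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("evolutionary_rate", exc) from exc

    # --- methylation -------------------------------------------------------------
    try:
        if bundle.methylation:
            pooled = (
                meth_mod.pool_replicates(bundle.methylation)
                if len(bundle.methylation) > 1
                else bundle.methylation[0]
            )
            index = meth_mod.MethylationIndex(pooled, min_total=config.min_total)
            gdf = bundle.duplicated.df
            use_pairs = hc_pairs if len(hc_pairs) else homeologs
            g_sg1 = gdf[gdf["gene_id"].isin(use_pairs["gene_sg1"])]
            g_sg2 = gdf[gdf["gene_id"].isin(use_pairs["gene_sg2"])]
            meth_report = {}
            for ctx in ANALYSIS_CONTEXTS:
                for region in meth_mod.REGIONS:
                    try:
                        res = meth_mod.compare_region_methylation(
                            g_sg1, g_sg2, region, ctx, index, config.flank, config.min_total
                        )
                    except ValueError:
                        continue
                    comparisons.append(
                        comparison_row(f"methylation:{ctx}_{region}_sg1_vs_sg2", res)
                    )
                for label in ("subgenome1", "subgenome2"):
                    single_genes = gdf[
                        gdf["gene_id"].isin(
                            singletons.loc[singletons["label"] == label, "gene_id"]
                        )
                    ]
                    hom_genes = g_sg1 if label == "subgenome1" else g_sg2
                    for region in meth_mod.REGIONS:
                        try:
                            res = meth_mod.compare_region_methylation(
                                single_genes, hom_genes, region, ctx, index,
                                config.flank, config.min_total,
                            )
                        except ValueError:
                            continue
                        comparisons.append(
                            comparison_row(
                                f"methylation:{ctx}_{region}_singleton_vs_homeolog_{label}", res
                            )
                        )
                prof1 = meth_mod.metagene_profile(
                    g_sg1, index, ctx, config.flank, config.flank_bin, config.body_bins
                )
                prof2 = meth_mod.metagene_profile(
                    g_sg2, index, ctx, config.flank, config.flank_bin, config.body_bins
                )
                meth_report[ctx] = {
                    "profile_sg1_mean": float(np.nanmean(prof1.levels)),
                    "profile_sg2_mean": float(np.nanmean(prof2.levels)),
                    "n_genes_sg1": prof1.n_genes,
                    "n_genes_sg2": prof2.n_genes,
                }
            report["methylation"] = meth_report
        else:
            report["skipped_stages"].append("methylation")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("methylation", exc) from exc

    comp_df = pd.DataFrame(comparisons)
    report["comparisons"] = comparisons
    report["consistency"] = _consistency(report, assignment)

    tables = {
        "singletons": singletons,
        "homeologs": homeologs,
        "block_summary": block_summary(recent),
        "pair_kaks_out1": kaks1,
    }
    result = PipelineResult(
        report=report,
        assignment=assignment,
        recent_blocks=recent,
        ancient_blocks=ancient,
        mixture=mixture,
        loss_table=loss_table,
        retention_profile=profile,
        comparisons=comp_df,
        dominance_summary=dom_summary,
        tables=tables,
    )
    if config.outdir:
        _write_products(result, config)
    return result


def _rate_comparisons(per_gene, hc_pairs, singletons, comparisons):
    for metric in ("ka", "ks", "ratio"):
        a = per_gene.reindex(hc_pairs["gene_sg1"])[metric].dropna()
        b = per_gene.reindex(hc_pairs["gene_sg2"])[metric].dropna()
        if len(a) >= 3 and len(b) >= 3:
            comparisons.append(
                comparison_row(
                    f"rate:{metric}_sg1_vs_sg2", mann_whitney_u(a.to_numpy(), b.to_numpy())
                )
            )
        for label, hom_col in (("subgenome1", "gene_sg1"), ("subgenome2", "gene_sg2")):
            s = per_gene.reindex(
                singletons.loc[singletons["label"] == label, "gene_id"]
            )[metric].dropna()
            h = per_gene.reindex(hc_pairs[hom_col])[metric].dropna()
            if len(s) >= 3 and len(h) >= 3:
                comparisons.append(
                    comparison_row(
                        f"rate:{metric}_singleton_vs_homeolog_{label}",
                        mann_whitney_u(s.to_numpy(), h.to_numpy()),
                    )
                )


def _consistency(report: dict, assignment: SubgenomeAssignment) -> dict:
    c = assignment.counts()
    anchored = len(assignment.genes)
    ok = 2 * c["homeolog_pairs"] + c["singletons_sg1"] + c["singletons_sg2"] <= anchored
    return {
        "anchored_genes": anchored,
        "identity_2hom_plus_singletons_le_anchored": bool(ok),
    }


def _echo_params(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


def _write_products(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    result.loss_table.to_csv(os.path.join(outdir, "loss_rates.tsv"), sep="\t", index=False)
    result.retention_profile.to_csv(
        os.path.join(outdir, "retention_profile.tsv"), sep="\t", index=False
    )
    result.tables["singletons"].to_csv(
        os.path.join(outdir, "singletons.tsv"), sep="\t", index=False
    )
    result.tables["homeologs"].to_csv(
        os.path.join(outdir, "homeologs.tsv"), sep="\t", index=False
    )
    result.tables["block_summary"].to_csv(
        os.path.join(outdir, "blocks.tsv"), sep="\t", index=False
    )
    if len(result.tables["pair_kaks_out1"]):
        result.tables["pair_kaks_out1"].to_csv(
            os.path.join(outdir, "pair_kaks.tsv"), sep="\t", index=False
        )
    if len(result.comparisons):
        result.comparisons.to_csv(
            os.path.join(outdir, "comparisons.tsv"), sep="\t", index=False
        )
    if len(result.dominance_summary):
        result.dominance_summary.to_csv(os.path.join(outdir, "dominance.tsv"), sep="\t")
    write_collinearity(result.recent_blocks, os.path.join(outdir, "recent.collinearity"))
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(result.report, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    return str(obj)
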