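"""End-to-end pipeline: filter -> aggregate -> normalize -> DE -> cluster /
enrich / network / angioscore.

Each stage logs one structured line with its input/output protein counts,
mirroring the funnel a regional proteomics study reports (identified ->
CV-reproducible -> presence-aggregated -> common -> significant).  All
outputs are deterministic TSV/Newick/JSON so a fixed seed reproduces every
byte.  Human and mouse proteins are processed as parallel datasets: every
stage runs per species.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from invadome import angioscore as angio
from invadome import cluster as clust
from invadome import diffexpr, enrichment, network, repro
from invadome.config import PipelineConfig
from invadome.quant import QuantTable, read_quant_table, write_table

logger = logging.getLogger("invadome")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log_stage(stage: str, species: str, n_in: int, n_out: int) -> dict:
    rec = {"stage": stage, "species": species, "n_in": n_in, "n_out": n_out}
    logger.info("stage=%s species=%s n_in=%d n_out=%d", stage, species, n_in, n_out)
    return rec


def run_pipeline(
    config: PipelineConfig,
    quant: QuantTable | str | Path,
    out_dir: str | Path,
    species: str = "both",
    gmt_path: str | Path | None = None,
    edges_path: str | Path | None = None,
    corpus_dir: str | Path | None = None,
) -> dict:
    """Execute every stage for the requested species and write all outputs.

    Parameters
    ----------
    config:
        Validated :class:`PipelineConfig`.
    quant:
        Quantification table or path to its TSV.
    out_dir:
        Output directory (created if absent).
    species:
        ``human``, ``mouse`` or ``both``.
    gmt_path, edges_path, corpus_dir:
        Optional gene-set collection, interaction edge list and
        publication corpus; the corresponding stages are skipped when
        absent.

    Returns a summary dict (also written as ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(quant, QuantTable):
        quant = read_quant_table(quant)
    species_list = ["human", "mouse"] if species == "both" else [species]
    summary: dict = {"species": {}, "stages": []}

    collection = enrichment.read_gmt(gmt_path) if gmt_path else None
    edges_graph = network.read_edges(edges_path) if edges_path else None
    corpus = angio.read_corpus(corpus_dir) if corpus_dir else None

    for sp in species_list:
        table = quant.subset_species(sp)
        if table.n_proteins == 0:
            continue
        sp_summary: dict = {"n_input": table.n_proteins}
        stages = summary["stages"]

        # -- reproducibility filter -----------------------------------
        try:
            filtered, cv_report = repro.cv_filter(table, config.cv_threshold)
        except Exception as e:  # noqa: BLE001
            raise StageError("cv_filter", e) from e
        stages.append(_log_stage("cv_filter", sp, table.n_proteins, filtered.n_proteins))
        write_table(cv_report.to_frame(), out / f"cv_report_{sp}.tsv")
        write_table(cv_report.histogram(), out / f"cv_histogram_{sp}.tsv")
        write_table(filtered, out / f"filtered_{sp}.tsv")
        sp_summary["n_cv_retained"] = filtered.n_proteins

        # -- presence aggregation -------------------------------------
        try:
            aggregated, common = repro.aggregate(
                filtered, config.presence_min, config.presence_total
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("aggregate", e) from e
        stages.append(
            _log_stage("aggregate", sp, filtered.n_proteins, aggregated.n_proteins)
        )
        agg_frame = aggregated.to_frame()
        agg_frame.insert(3, "common", common.to_numpy())
        write_table(agg_frame, out / f"aggregated_{sp}.tsv")
        sp_summary["n_aggregated"] = aggregated.n_proteins
        sp_summary["n_common"] = int(common.sum())

        # -- normalization --------------------------------------------
        try:
            normalized, scales = diffexpr.median_ratio_normalize(aggregated)
        except Exception as e:  # noqa: BLE001
            raise StageError("normalize", e) from e
        write_table(normalized, out / f"normalized_{sp}.tsv")

        # -- differential expression (observed values only) -----------
        try:
            de = diffexpr.differential_expression(normalized)
            de = diffexpr.flag_hits(de, config)
        except Exception as e:  # noqa: BLE001
            raise StageError("diffexp", e) from e
        n_sig = int(de["significant"].sum())
        stages.append(_log_stage("diffexp", sp, normalized.n_proteins, n_sig))
        write_table(de, out / f"de_{sp}.tsv")
        write_table(diffexpr.hit_summary(de), out / f"hit_summary_{sp}.tsv")
        volcano = de[["protein_id", "gene_symbol", "log2fc", "padj"]].copy()
        with np.errstate(divide="ignore"):
            volcano["neg_log10_padj"] = -np.log10(volcano.pop("padj"))
        write_table(volcano, out / f"volcano_{sp}.tsv")
        sp_summary["n_significant"] = n_sig
        sp_summary["n_invasive_up"] = int(
            (de["significant"] & (de["direction"] == "invasive-up")).sum()
        )
        sp_summary["n_core_up"] = int(
            (de["significant"] & (de["direction"] == "core-up")).sum()
        )

        # -- imputation + clustering ----------------------------------
        try:
            imputed, _flags = diffexpr.impute_missing(normalized)
        except Exception as e:  # noqa: BLE001
            raise StageError("impute", e) from e

        try:
            common_ids = common.index[common]
            if len(common_ids) >= 2:
                # sample dendrogram on log2 ratios to the reference profile
                vals = imputed.values.loc[common_ids]
                reference = vals.median(axis=1)
                log_ratio = np.log2(vals.div(reference, axis=0))
                dend = clust.bootstrap_support(
                    log_ratio.T,
                    n_boot=config.bootstrap_n,
                    seed=config.rng_seed,
                    labels=list(log_ratio.columns),
                )
                (out / f"sample_dendrogram_{sp}.nwk").write_text(
                    dend.to_newick() + "\n"
                )
            cm = clust.clustermap_export(de, imputed)
            if "warning" not in cm:
                mat = cm["matrix"].copy()
                mat.insert(0, "protein_id", mat.index)
                write_table(mat.reset_index(drop=True), out / f"clustermap_{sp}.tsv")
                (out / f"clustermap_rows_{sp}.nwk").write_text(
                    cm["row_dendrogram"].to_newick(support=None) + "\n"
                )
                (out / f"clustermap_cols_{sp}.nwk").write_text(
                    cm["col_dendrogram"].to_newick(support=None) + "\n"
                )
            sp_summary["n_clustermap_hits"] = int(de["clustermap_hit"].sum())
        except Exception as e:  # noqa: BLE001
            raise StageError("cluster", e) from e

        # -- over-representation analysis -----------------------------
        if collection is not None:
            try:
                query = de.loc[de["enrichment_hit"], "gene_symbol"].tolist()
                universe = de["gene_symbol"].tolist()
                if query:
                    ora = enrichment.ora_test(
                        query, collection, universe, config.ora_padj
                    )
                    write_table(ora, out / f"enrichment_{sp}.tsv")
                    sp_summary["n_enriched_sets"] = int(ora["enriched"].sum())
            except Exception as e:  # noqa: BLE001
                raise StageError("enrich", e) from e

        # -- interaction network of invasive-area proteins ------------
        if edges_graph is not None:
            try:
                invasive_genes = set(
                    de.loc[
                        de["significant"] & (de["direction"] == "invasive-up"),
                        "gene_symbol",
                    ]
                )
                sub = edges_graph.subgraph(
                    n for n in edges_graph.nodes if n in invasive_genes
                ).copy()
                sub = network.filter_graph(sub, config.edge_confidence_min)
                labels, edge_table = network.mcl_cluster(
                    sub,
                    inflation=config.mcl_inflation,
                    max_iter=config.mcl_max_iter,
                    prune=config.mcl_prune,
                )
                assignment = labels.rename_axis("gene").reset_index()
                write_table(assignment, out / f"network_clusters_{sp}.tsv")
                write_table(edge_table, out / f"network_edges_{sp}.tsv")
                sp_summary["n_network_nodes"] = int(len(labels))
                sp_summary["n_network_clusters"] = int(labels.nunique())
            except Exception as e:  # noqa: BLE001
                raise StageError("network", e) from e

        # -- AngioScore -----------------------------------------------
        if corpus is not None:
            try:
                scores = angio.score_corpus(corpus)
                write_table(scores, out / f"angioscore_{sp}.tsv")
                sig = de[de["significant"]]
                core_ranked = (
                    sig[sig["direction"] == "core-up"]
                    .assign(abs_lfc=lambda d: d["log2fc"].abs())
                    .sort_values(["abs_lfc", "gene_symbol"], ascending=[False, True])[
                        "gene_symbol"
                    ]
                    .tolist()
                )
                inv_ranked = (
                    sig[sig["direction"] == "invasive-up"]
                    .assign(abs_lfc=lambda d: d["log2fc"].abs())
                    .sort_values(["abs_lfc", "gene_symbol"], ascending=[False, True])[
                        "gene_symbol"
                    ]
                    .tolist()
                )
                top_n = min(config.angioscore_top_n, len(core_ranked), len(inv_ranked))
                if top_n >= 2:
                    comp = angio.compare_groups(
                        scores, core_ranked, inv_ranked, top_n=top_n
                    )
                    sp_summary["angioscore_ratio"] = comp["ratio_core_over_invasive"]
                    sp_summary["angioscore_p"] = comp["p_value"]
                    report = pd.DataFrame(
                        [
                            (
                                comp["mean_core"],
                                comp["mean_invasive"],
                                comp["ratio_core_over_invasive"],
                                comp["t_statistic"],
                                comp["p_value"],
                                top_n,
                            )
                        ],
                        columns=[
                            "mean_core",
                            "mean_invasive",
                            "ratio_core_over_invasive",
                            "t",
                            "p",
                            "top_n",
                        ],
                    )
                    write_table(report, out / f"angioscore_summary_{sp}.tsv")
            except Exception as e:  # noqa: BLE001
                raise StageError("angioscore", e) from e

        summary["species"][sp] = sp_summary

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
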