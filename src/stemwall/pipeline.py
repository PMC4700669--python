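"""End-to-end orchestration: simulate -> de -> cluster -> enrich -> network -> qpcr.

Each stage logs a timestamped banner with its parameters to stderr, writes
its tab-delimited outputs into the run directory, and contributes to a
machine-readable JSON summary. All randomness fans out from the single
master seed, so a run is idempotent given (config, seed).
"""

from __future__ import annotations

import logging
import sys
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import clustering, coexpression, config, diffexpr, enrichment, io, qpcr, synthetic
from .config import PipelineConfig
from .containers import StudyDesign

logger = logging.getLogger("stemwall")
if not logger.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s | %(name)s | %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)


def _banner(stage: str, **params) -> None:
    rendered = " ".join(f"{k}={v}" for k, v in params.items())
    logger.info("=== %s === %s", stage, rendered)


def run_pipeline(cfg: PipelineConfig, outdir: Path | str) -> dict:
    """Run every stage on freshly simulated inputs; returns the summary.

    Outputs land under ``outdir``; a failing stage raises with its name
    after earlier outputs have already been written (partial results are
    retained)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = StudyDesign()
    seeds = config.fan_out_seeds(cfg.seed, 6)
    summary: dict = {"profile": cfg.profile, "seed": cfg.seed}
    t0 = time.time()

    stage = "simulate"
    try:
        _banner(stage, n_probesets=cfg.n_probesets, noise_sd_log2=cfg.noise_sd_log2, seed=seeds[0])
        stem, truth = synthetic.generate_stem_matrix(
            cfg.n_probesets, design, noise_sd_log2=cfg.noise_sd_log2, seed=seeds[0]
        )
        net_matrix, truth = synthetic.generate_network_matrix(
            stem, truth, design, seed=seeds[1]
        )
        io.write_matrix(stem, outdir / "stem_matrix.tsv", outdir / "stem_design.tsv")
        io.write_matrix(net_matrix, outdir / "network_matrix.tsv", outdir / "network_design.tsv")
        io.write_truth(truth, outdir / "truth_labels.tsv")

        stage = "de"
        _banner(stage, alpha=cfg.alpha, fc_min=cfg.fc_min, n_chip=cfg.n_chip,
                background_quantile=cfg.background_quantile)
        stem.n_chip = cfg.n_chip
        de = diffexpr.associative_de_test(
            stem, background_quantile=cfg.background_quantile,
            alpha=cfg.alpha, fc_min=cfg.fc_min,
        )
        de_genes = diffexpr.select_de_genes(de)
        io.write_de_table(de.table, outdir / "de_results.tsv")
        summary["de_gene_count"] = int(len(de_genes))
        summary["bonferroni_threshold"] = diffexpr.bonferroni_threshold(cfg.alpha, cfg.n_chip)

        stage = "cluster"
        _banner(stage, k=cfg.k, linkage=cfg.linkage, wall_clusters=cfg.wall_clusters)
        profiles = clustering.relative_profile(stem, de_genes)
        assignment = clustering.hierarchical_cluster(profiles, k=cfg.k, linkage=cfg.linkage)
        io.write_assignment(
            assignment.labels, assignment.centroids, assignment.archetype_corr,
            outdir / "cluster_assignment.tsv", outdir / "cluster_centroids.tsv",
        )
        sizes = assignment.sizes()
        summary["cluster_sizes"] = {int(k): int(v) for k, v in sizes.items()}
        is_tf = truth.table["is_tf"]
        wall_tf_counts = {
            int(lab): int(is_tf.reindex(assignment.members(lab), fill_value=False).sum())
            for lab in cfg.wall_clusters
        }
        summary["wall_cluster_tf_counts"] = wall_tf_counts
        wall_tfs = clustering.select_wall_clusters(
            assignment, cfg.wall_clusters, tf_annotation=is_tf
        )
        summary["wall_tf_count"] = int(len(wall_tfs))

        stage = "enrich"
        _banner(stage, selection=len(wall_tfs))
        tf_universe = truth.tf_probes()
        family_map = truth.table["tf_family"].dropna().to_dict()
        enr = enrichment.family_enrichment(wall_tfs, family_map, tf_universe)
        enr.to_csv(outdir / "family_enrichment.tsv", sep="\t", index=False)
        summary["enrichment_families"] = int(len(enr))
        summary["enrichment_top"] = (
            enr.iloc[0][["family", "occurrence"]].to_dict() if len(enr) else None
        )

        stage = "network"
        _banner(stage, min_fold=cfg.min_fold, prefixes=cfg.prefixes,
                bin_width=cfg.bin_width, seed=seeds[2])
        filtered = coexpression.filter_probesets(net_matrix, cfg.prefixes, cfg.min_fold)
        filtered = coexpression.drop_zero_variance(filtered)
        permuted = coexpression.permute_rows(filtered, seed=seeds[2])
        hist, max_abs = coexpression.null_pcc_summary(permuted, cfg.bin_width)
        threshold = coexpression.estimate_threshold(
            bin_width=cfg.bin_width, null_max_abs=max_abs
        )
        net = coexpression.build_network(filtered, threshold, null_hist=hist)
        io.write_network(
            net, outdir / "network_edges.tsv",
            graphml_path=outdir / "network.graphml",
            histogram_path=outdir / "null_histogram.tsv",
        )
        summary["network_nodes"] = int(net.graph.number_of_nodes())
        summary["network_edges"] = int(net.n_edges)
        summary["network_threshold"] = float(threshold)
        summary["null_max_abs_pcc"] = float(max_abs)

        present = set(filtered.values.index)
        tf_nodes = [t for t in tf_universe if t in present]
        hub_lists = {}
        for pathway in ("lignin", "cellulose", "hemicellulose"):
            genes = [g for g in truth.pathway_probes(pathway) if g in present]
            if not genes:
                hub_lists[pathway] = []
                continue
            sub, degree = coexpression.extract_pathway_subnetwork(net, tf_nodes, genes)
            pd.Series(degree, name="pathway_degree").to_csv(
                outdir / f"{pathway}_tf_degree.tsv", sep="\t", index_label="tf"
            )
            hub_lists[pathway] = coexpression.rank_hub_tfs(degree, min_degree=4)
        summary["hub_tfs"] = hub_lists

        stage = "qpcr"
        _banner(stage, n_tfs=cfg.n_qpcr_tfs, fold_min=cfg.fold_min,
                ct_ceiling=cfg.ct_ceiling, seed=seeds[3])
        table, planted = synthetic.generate_qpcr_table(
            cfg.n_qpcr_tfs, design, seed=seeds[3]
        )
        io.write_qpcr_table(table, outdir / "qpcr_table.tsv")
        expressed = qpcr.expressed_genes(table, cfg.ct_ceiling)
        folds = qpcr.relative_expression(table, cfg.reference_internode)
        folds.loc[[g for g in expressed if g != table.reference_gene]].to_csv(
            outdir / "qpcr_folds.tsv", sep="\t", index_label="gene"
        )
        calls = qpcr.call_regulated(
            folds.loc[[g for g in expressed if g != table.reference_gene]], cfg.fold_min
        )
        calls.rename("direction").to_csv(outdir / "qpcr_hits.tsv", sep="\t", index_label="gene")

        # Synthetic chip concordance: map a deterministic share of qPCR genes
        # onto the chip, a share of those onto the array-significant set.
        rng = np.random.default_rng(seeds[4])
        hits = list(calls.index)
        presence = {g: bool(rng.random() < 0.6) for g in sorted(set(table.genes) - {table.reference_gene})}
        chip_de = {g for g in hits if presence.get(g, False) and rng.random() < 0.55}
        part = qpcr.concord_with_chip(hits, presence, chip_de)
        sizes_part = qpcr.concordance_sizes(part)
        pd.Series(sizes_part).to_csv(outdir / "qpcr_concordance.tsv", sep="\t", header=False)
        summary["qpcr_expressed"] = int(len(expressed) - (table.reference_gene in expressed))
        summary["qpcr_hit_count"] = int(len(hits))
        summary["qpcr_concordance"] = sizes_part
    except Exception as err:
        logger.error("stage %r failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    summary["runtime_s"] = round(time.time() - t0, 2)
    io.write_summary(summary, outdir / "summary.json")
    _banner("done", runtime_s=summary["runtime_s"])
    return summary
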