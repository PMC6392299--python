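"""End-to-end orchestration: expression matrix -> modules -> trait
correlations -> potentiating selection -> pathway enrichment.

Deterministic for identical inputs and configuration; every stage logs the
gene/module counts after it runs so the accounting is visible on any
input.  All output tables are UTF-8 TSV; the run summary is JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import network
from .archetypes import ARMS
from .config import AnalysisConfig
from .enrichment import enrich_modules
from .io import (
    GeneSetCollection,
    validate_expression,
    validate_metadata,
    write_table_tsv,
)
from .traits import build_traits, correlate, select_potentiating

logger = logging.getLogger(__name__)


def run_pipeline(
    config: AnalysisConfig,
    expression: pd.DataFrame,
    metadata: pd.Series,
    gene_sets: "Optional[GeneSetCollection]" = None,
    out_dir: "str | Path | None" = None,
) -> dict:
    """Run filter -> network -> modules -> traits -> selection -> enrichment.

    Returns the run summary (module count, potentiating modules, top trait
    and top pathway per module).  When ``out_dir`` is given, writes
    module_assignments.tsv, eigengenes.tsv, trait_correlations.tsv,
    potentiating_modules.tsv, enrichment.tsv, scale_free_fit.tsv,
    dendrogram.tsv and summary.json there.
    """
    config.validate()
    validate_expression(expression)
    validate_metadata(metadata)
    missing_arms = [a for a in ARMS if a not in set(metadata)]
    if missing_arms:
        raise ValueError(f"metadata is missing arm(s): {missing_arms}")
    extra = [s for s in expression.columns if s not in metadata.index]
    if extra:
        raise ValueError(f"samples without metadata: {extra[:5]}")
    metadata = metadata.reindex(expression.columns)

    filtered = network.filter_genes(expression, config.tpm_threshold)
    working = network.log2_transform(filtered) if config.log_transform else filtered
    variances = working.var(axis=1)
    if (variances == 0).any():
        n_drop = int((variances == 0).sum())
        logger.info("dropping %d zero-variance gene(s) before correlation", n_drop)
        working = working.loc[variances > 0]
    logger.info("network input: %d genes x %d samples", *working.shape)

    detector = network.CoexpressionModuleDetector(
        power_grid=config.soft_power_grid,
        scale_free_r2_target=config.scale_free_r2_target,
        apply_power_floor=config.apply_power_floor,
        min_module_size=config.min_module_size,
        merge_dissimilarity=config.merge_dissimilarity,
        cut_quantile=config.cut_quantile,
        split_dissimilarity=config.split_dissimilarity,
        kme_threshold=config.kme_threshold,
        refine_iterations=config.refine_iterations,
    )
    detector.fit(working.T)
    labels = detector.module_assignments_
    eigengenes = detector.eigengenes_
    modules = list(eigengenes.index)
    logger.info("detected %d module(s); soft power %d", len(modules), detector.soft_power_)

    summary: dict = {
        "n_genes_input": int(expression.shape[0]),
        "n_genes_analyzed": int(working.shape[0]),
        "n_samples": int(expression.shape[1]),
        "soft_power": int(detector.soft_power_),
        "n_modules": len(modules),
        "module_sizes": {m: int((labels == m).sum()) for m in modules},
    }

    trait_corr = pd.DataFrame()
    selection_table = pd.DataFrame()
    if modules:
        traits = build_traits(metadata)
        trait_corr = correlate(eigengenes, traits)
        selection = select_potentiating(
            trait_corr, config.trait_r_threshold, config.trait_p_threshold
        )
        selection_table = selection.table
        top = trait_corr.loc[trait_corr["is_top"]]
        summary["top_trait_per_module"] = {
            row["module"]: {"trait": row["trait"], "r": row["r"], "p": row["p"]}
            for _, row in top.iterrows()
        }
        summary["potentiating_modules"] = selection_table["module"].tolist()
        logger.info("potentiating modules: %s", summary["potentiating_modules"])
    else:
        summary["top_trait_per_module"] = {}
        summary["potentiating_modules"] = []

    enrichment_table = pd.DataFrame()
    if gene_sets is not None and modules:
        enrichment_table = enrich_modules(
            labels, gene_sets, universe=working.index, fdr_threshold=config.fdr_threshold
        )
        tops = enrichment_table.loc[enrichment_table["is_top"]]
        summary["top_pathway_per_module"] = {
            row["module"]: {
                "gene_set": row["gene_set"],
                "overlap": int(row["overlap"]),
                "p_adjusted": row["p_adjusted"],
                "significant": bool(row["significant"]),
            }
            for _, row in tops.iterrows()
        }
    else:
        summary["top_pathway_per_module"] = {}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        assignments = pd.DataFrame(
            {
                "gene_id": labels.index,
                "module": labels.to_numpy(),
                "kWithin": detector.k_within_.to_numpy(),
            }
        )
        write_table_tsv(assignments, out / "module_assignments.tsv")
        eigengenes.rename_axis(index="module").to_csv(
            out / "eigengenes.tsv", sep="\t", float_format="%.10g"
        )
        if detector.scale_free_table_ is not None:
            write_table_tsv(detector.scale_free_table_, out / "scale_free_fit.tsv")
        write_table_tsv(network.dendrogram_table(detector.dendrogram_),
                        out / "dendrogram.tsv")
        if not trait_corr.empty:
            write_table_tsv(trait_corr, out / "trait_correlations.tsv")
        with open(out / "potentiating_modules.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# r_threshold={config.trait_r_threshold}"
                     f"\tp_threshold={config.trait_p_threshold}\n")
            selection_table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        if not enrichment_table.empty:
            write_table_tsv(enrichment_table, out / "enrichment.tsv")
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return summary
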