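"""End-to-end orchestration: config -> catalog -> networks -> predictions ->
genetics -> structured report.

The report is a nested plain dict with stable key order; timestamps live in
one provenance field so the rest of the report is byte-diffable across runs.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .catalog import (
    Catalog,
    Category,
    Delivery,
    annotation_summary,
    delivery_correlation,
    gene_targets,
    load_catalog,
    summarize_catalog,
    unique_gene_targets,
)
from .genetics import (
    ALL_VARIANT_CLASSES,
    VariantClass,
    compare_frequency_sets,
    drug_count_correlation,
    hypergeometric_enrichment,
    list_overlap,
    load_gene_list,
    load_mutations,
    mutation_frequency,
    partition_gene_sets,
    threshold_fraction,
)
from .networks import (
    EDGE_DRUG_CANCER,
    EDGE_DRUG_TARGET,
    build_cancer_drug_target_network,
    build_drug_cancer_network,
    compare_degree_distributions,
    degree_breakdown,
    degree_summary,
    export_network,
)
from .repurposing import (
    evaluate_support,
    drugs_sharing_targets,
    load_trial_counts,
    predict_common_target,
    write_predictions,
)

__all__ = ["RunConfig", "run_pipeline", "render_report", "load_config"]

logger = logging.getLogger(__name__)

#: Number of protein-coding genes used as the enrichment background.
PROTEIN_CODING_GENES = 20729


@dataclass
class RunConfig:
    """Validated inputs and knobs of a pipeline run."""

    catalog: str
    cancers: str
    annotations: str | None = None
    trials: str | None = None
    mutations: str | None = None
    cancer_genes: str | None = None
    ocg: str | None = None
    tsg: str | None = None
    outdir: str = "oncodrug_out"
    threshold_pct: float = 2.0
    include_silent: bool = True
    n_protein_coding: int = PROTEIN_CODING_GENES
    seed: int = 0

    def validate(self) -> None:
        for name in ("catalog", "cancers", "annotations", "trials",
                     "mutations", "cancer_genes", "ocg", "tsg"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config input {name!r}: no such file {value}")
        if not 0.0 <= self.threshold_pct <= 100.0:
            raise ValueError("threshold_pct must be in [0, 100]")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def _catalog_block(catalog: Catalog) -> dict[str, Any]:
    summary = summarize_catalog(catalog)
    block: dict[str, Any] = {
        "n_total": summary.n_total,
        "n_cytotoxic": summary.n_cytotoxic,
        "n_targeted": summary.n_targeted,
        "counts_by_delivery": {m.value: n for m, n in summary.counts_by_delivery.items()},
        "counts_by_period": {f"{lo}-{hi}": n for (lo, hi), n in summary.counts_by_period.items()},
        "n_unique_gene_targets": len(unique_gene_targets(catalog)),
    }
    try:
        r, p = delivery_correlation(catalog, Category.TARGETED, Delivery.SINGLE)
        block["targeted_single_correlation"] = {"r": round(r, 4), "p": float(p)}
    except ValueError as exc:  # degenerate series on tiny catalogs
        block["targeted_single_correlation"] = {"error": str(exc)}
    if catalog.annotations:
        block["annotation_summary"] = {
            axis: {label: {"count": n, "pct": pct} for label, (n, pct) in counts.items()}
            for axis, counts in annotation_summary(catalog.annotations).items()
        }
    return block


def _network_block(catalog: Catalog, outdir: Path) -> dict[str, Any]:
    bip = build_drug_cancer_network(catalog)
    tri = build_cancer_drug_target_network(catalog)
    export_network(bip, "edge-tsv", outdir / "drug_cancer_network.tsv")
    export_network(tri, "edge-tsv", outdir / "cancer_drug_target_network.tsv")

    drug_deg = degree_summary(bip, "drug")
    cancer_deg = degree_summary(bip, "cancer")
    cyt = {d.name for d in catalog.cytotoxic_drugs}
    tar = {d.name for d in catalog.targeted_drugs}
    block: dict[str, Any] = {
        "drug_cancer": {
            "n_nodes": bip.n_nodes,
            "n_drugs": len(bip.drug_nodes),
            "n_cancers": len(bip.cancer_nodes),
            "n_edges": len(bip.edges),
            "drug_degree": _deg(drug_deg),
            "cancer_degree": _deg(cancer_deg),
            "drugs_by_degree": degree_breakdown(bip, "drug", ["=1", "=2", ">=3"]),
            "cancers_by_degree": degree_breakdown(bip, "cancer", ["=1", "2-9", ">=10"]),
        }
    }
    if cyt and tar:
        cyt_deg = degree_summary(bip, "drug", node_subset=cyt)
        tar_deg = degree_summary(bip, "drug", node_subset=tar)
        ks = compare_degree_distributions(
            list(cyt_deg.degrees.values()), list(tar_deg.degrees.values())
        )
        block["drug_cancer"]["cytotoxic_vs_targeted"] = {
            "mean_cytotoxic": round(cyt_deg.mean, 2),
            "mean_targeted": round(tar_deg.mean, 2),
            "ks_statistic": round(ks.statistic, 4),
            "ks_p": float(ks.p_value),
        }
    if tri.drug_nodes:
        block["cancer_drug_target"] = {
            "n_nodes": tri.n_nodes,
            "n_drugs": len(tri.drug_nodes),
            "n_targets": len(tri.target_nodes),
            "n_cancers": len(tri.cancer_nodes),
            "n_edges": tri.n_edges,
            "n_drug_cancer_edges": len(tri.drug_cancer_edges),
            "n_drug_target_edges": len(tri.drug_target_edges),
            "drug_target_degree": _deg(degree_summary(tri, "drug", edge_type=EDGE_DRUG_TARGET)),
            "drug_cancer_degree": _deg(degree_summary(tri, "drug", edge_type=EDGE_DRUG_CANCER)),
            "target_degree": _deg(degree_summary(tri, "target")),
            "cancer_degree": _deg(degree_summary(tri, "cancer")),
        }
    return block


def _deg(summary) -> dict[str, float]:
    return {
        "mean": round(summary.mean, 2),
        "min": summary.min,
        "max": summary.max,
        "skewness": round(summary.skewness, 3),
    }


def _prediction_block(catalog: Catalog, config: RunConfig, outdir: Path) -> dict[str, Any]:
    predictions = predict_common_target(catalog)
    trial_table = (
        load_trial_counts(config.trials, catalog) if config.trials else {}
    )
    report = evaluate_support(predictions, trial_table)
    write_predictions(report.predictions, outdir / "predictions.tsv")
    top = report.top_association
    return {
        "n_drugs_sharing_targets": len(drugs_sharing_targets(catalog)),
        "n_predictions": report.n_predictions,
        "n_drugs": report.n_drugs,
        "n_cancers": report.n_cancers,
        "n_supported": report.n_supported,
        "n_unsupported": report.n_unsupported,
        "top_association": (
            {"drug": top.drug, "cancer": top.cancer, "n_trials": top.trial_count}
            if top and trial_table
            else None
        ),
        "unmatched_trial_pairs": [list(t) for t in report.unmatched_trial_pairs],
    }


def _genetics_block(catalog: Catalog, config: RunConfig) -> dict[str, Any]:
    table = load_mutations(config.mutations)
    cancer_genes = load_gene_list(config.cancer_genes)
    targets = unique_gene_targets(catalog)
    partition = partition_gene_sets(targets, cancer_genes, table.genes)
    k = len(partition.target_cancer)
    enrichment_p = hypergeometric_enrichment(
        k, len(targets), len(cancer_genes), config.n_protein_coding
    )

    classes = (
        ALL_VARIANT_CLASSES
        if config.include_silent
        else ALL_VARIANT_CLASSES - {VariantClass.SILENT}
    )
    profiles = {
        name: mutation_frequency(table, genes, include_classes=classes)
        for name, genes in partition.as_dict().items()
        if genes
    }
    block: dict[str, Any] = {
        "partition_sizes": {name: len(genes) for name, genes in partition.as_dict().items()},
        "enrichment": {
            "k_overlap": k,
            "n_targets": len(targets),
            "K_cancer_genes": len(cancer_genes),
            "N_population": config.n_protein_coding,
            "p_upper_tail": float(enrichment_p),
        },
        "set_means_pct": {name: round(p.set_mean, 4) for name, p in profiles.items()},
    }
    if len(profiles) >= 2:
        block["ks_comparisons"] = compare_frequency_sets(profiles).round(6).to_dict("records")
        fractions, chi2 = threshold_fraction(profiles, config.threshold_pct)
        block["threshold"] = {
            "threshold_pct": config.threshold_pct,
            "fractions": {k_: round(v, 4) for k_, v in fractions.items()},
            "chi2_tests": chi2.round(6).to_dict("records"),
        }
    drugs_per_gene: dict[str, int] = {}
    for d in catalog.targeted_drugs:
        for g in gene_targets(d):
            drugs_per_gene[g] = drugs_per_gene.get(g, 0) + 1
    if len(partition.target_cancer) >= 3:
        freq = profiles.get("target_cancer")
        if freq is not None:
            try:
                r, p = drug_count_correlation(
                    partition.target_cancer, freq.per_gene, drugs_per_gene
                )
                block["drug_count_correlation"] = {"r": round(r, 4), "p": float(p)}
            except ValueError as exc:
                block["drug_count_correlation"] = {"error": str(exc)}
    for name, path in (("ocg", config.ocg), ("tsg", config.tsg)):
        if path:
            _, n = list_overlap(partition.target_cancer, load_gene_list(path))
            block[f"{name}_overlap"] = n
    return block


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute catalog -> networks -> repurposing -> genetics.

    The genetics stage is skipped with a logged notice when mutation inputs
    are absent.  Per-stage TSVs are written under ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = load_catalog(config.catalog, config.cancers, config.annotations)

    report: dict[str, Any] = {
        "catalog": _catalog_block(catalog),
        "networks": _network_block(catalog, outdir),
        "predictions": _prediction_block(catalog, config, outdir),
    }
    if config.mutations and config.cancer_genes:
        report["genetics"] = _genetics_block(catalog, config)
    else:
        logger.info("genetics stage skipped: mutation or cancer-gene input absent")
        report["genetics"] = {"skipped": "mutation or cancer-gene input absent"}
    report["provenance"] = {
        "config_hash": config.content_hash(),
        "oncodrug_version": __version__,
        "inputs": {
            "catalog": config.catalog,
            "cancers": config.cancers,
            "annotations": config.annotations,
            "trials": config.trials,
            "mutations": config.mutations,
            "cancer_genes": config.cancer_genes,
        },
        "seed": config.seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return report


def render_report(report: dict[str, Any], format: str = "json") -> str:
    """Serialize a report: ``json`` (stable key order) or ``markdown``."""
    if format == "json":
        return json.dumps(report, indent=2, sort_keys=True)
    if format == "markdown":
        lines = ["# oncodrug results", ""]
        titles = {
            "catalog": "Drug catalog",
            "networks": "Drug-cancer network",
            "predictions": "Common-target predictions",
            "genetics": "Target genetics",
            "provenance": "Provenance",
        }
        for key in ("catalog", "networks", "predictions", "genetics", "provenance"):
            if key not in report:
                continue
            lines.append(f"## {titles[key]}")
            lines.append("")
            lines.append("```json")
            lines.append(json.dumps(report[key], indent=2, sort_keys=True))
            lines.append("```")
            lines.append("")
        return "\n".join(lines)
    raise ValueError(f"unknown report format {format!r}")
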