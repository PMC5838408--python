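"""End-to-end orchestration: ingest -> enrichment -> properties ->
network -> population stages, with a single machine-readable run report.

A run is driven by one config mapping (YAML/JSON file or dict). Inputs
are either file paths (``inputs:`` block) or a simulation spec
(``simulate:`` block); with a simulation spec the planted ground truth
is scored in a ``recovery`` section of the report. Stage outputs are
written as they are produced, so a failure names the failing stage and
leaves the earlier outputs on disk. Reports are serialized with sorted
keys and no timestamps: the same config and seed give byte-identical
reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment, ingest, network, properties, simulate

logger = logging.getLogger(__name__)

CLASS_ORDER = ("rare", "common", "disease")

DEFAULTS = {
    "alpha": 0.05,
    "pli_threshold": 0.9,
    "percent_precision": 1,
    "excluded_consequences": sorted(ingest.DEFAULT_EXCLUDED_CONSEQUENCES),
}


class StageError(RuntimeError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    return yaml.safe_load(text)


def _check_inputs(config: dict) -> None:
    inputs = config.get("inputs") or {}
    for key, value in inputs.items():
        if value and not Path(value).exists():
            raise FileNotFoundError(f"input file for {key!r} not found: {value}")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute all stages and return (and write) the run report."""
    _check_inputs(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULTS, **{k: v for k, v in config.items() if k in DEFAULTS}}
    alpha = float(params["alpha"])

    report: dict = {"parameters": dict(params)}
    truth = None
    variants = genes = edges = populations = None

    if "simulate" in config:
        sim_cfg = simulate.SimulationConfig.from_dict(config["simulate"])
        report["parameters"]["seed"] = sim_cfg.seed
        logger.info("pipeline: simulate stage (seed=%d)", sim_cfg.seed)
        dataset = simulate.simulate_dataset(sim_cfg)
        simulate.write_dataset(dataset, out / "simulated")
        variants, genes, edges, populations, truth = dataset
    elif "inputs" in config:
        paths = config["inputs"]
        variants = ingest.read_variants(paths["variants"])
        if paths.get("genes"):
            genes = pd.read_csv(paths["genes"], sep="\t")
        if paths.get("edges"):
            edges = pd.read_csv(paths["edges"], sep="\t")
        if paths.get("populations"):
            populations = pd.read_csv(paths["populations"], sep="\t")
    else:
        raise ValueError("config must contain a 'simulate' or an 'inputs' block")

    # --- ingest ----------------------------------------------------------
    try:
        records, ingest_report = ingest.process_variants(
            variants, excluded_terms=set(params["excluded_consequences"])
        )
        counts, genes_per_class = ingest.aggregate_counts(records)
        counts.to_csv(out / "gene_counts.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError("ingest", exc) from exc
    report["inputs"] = {**ingest_report, "genes_per_class": genes_per_class}

    # --- enrichment -------------------------------------------------------
    try:
        results = {cls: enrichment.enrich_genes(counts, cls, alpha) for cls in CLASS_ORDER}
        evsets = enrichment.build_evsets(results, alpha)
        enrichment.write_enrichment(results, evsets, out)
    except Exception as exc:
        raise StageError("enrichment", exc) from exc
    report["evsets"] = {
        "sizes": evsets.sizes,
        "alpha": alpha,
        "overlap": {k: v for k, v in evsets.overlap.items()},
    }

    set_map = {
        cls: set(evsets.for_class(cls)) for cls in CLASS_ORDER if evsets.for_class(cls)
    }

    # --- gene properties --------------------------------------------------
    if genes is not None and set_map:
        try:
            ess = {
                cls: properties.essentiality_summary(members, genes)
                for cls, members in set_map.items()
            }
            report["essentiality"] = {
                cls: {"n_essential": c, "percent": p} for cls, (c, p) in ess.items()
            }
            report["scores"] = {}
            if len(set_map) >= 2:
                for score in ("pli", "dn_ds"):
                    cmp = properties.compare_score_across_sets(set_map, genes, score)
                    report["scores"][score] = cmp.to_dict()
            constrained = {
                cls: properties.count_constrained(
                    members, genes, float(params["pli_threshold"])
                )
                for cls, members in set_map.items()
            }
            report["constrained"] = {
                cls: {"n_constrained": c, "n_missing_pli": m}
                for cls, (c, m) in constrained.items()
            }
            report["disease_overlap"] = properties.disease_overlap_summary(
                evsets, genes, precision=int(params["percent_precision"])
            )
        except Exception as exc:
            raise StageError("properties", exc) from exc
    else:
        report["essentiality"] = {"skipped": True}
        report["disease_overlap"] = {"skipped": True}

    # --- network ----------------------------------------------------------
    if edges is not None and set_map:
        try:
            graph = network.load_edges(edges)
            deg = network.degree_stats(set_map, graph)
            sub = network.enriched_adjacency_subnetwork(evsets, graph)
            network.write_network_report(deg, sub, out)
            report["network"] = {
                "n_nodes": graph.number_of_nodes(),
                "n_edges": graph.number_of_edges(),
                "degree": deg.to_dict(),
                "subnetwork": sub.to_dict(),
            }
        except Exception as exc:
            raise StageError("network", exc) from exc
    else:
        report["network"] = {"skipped": True}

    # --- populations ------------------------------------------------------
    if populations is not None and len(populations):
        try:
            gene_map = records.drop_duplicates("variant_id").set_index("variant_id")["gene"]
            _, pop_summary = properties.population_specificity(populations, gene_map)
            pop_summary.pop("fraction_not_population_specific_per_gene", None)
            switches = properties.detect_class_switches(populations)
            report["populations"] = {
                **pop_summary,
                "n_class_switch": len(switches),
            }
        except Exception as exc:
            raise StageError("populations", exc) from exc
    else:
        report["populations"] = {"skipped": True}

    # --- planted-truth recovery ------------------------------------------
    if truth is not None:
        recovery = {}
        for cls in CLASS_ORDER:
            planted = truth.planted_for(cls)
            declared = set(evsets.for_class(cls))
            tp = len(declared & planted)
            recovery[cls] = {
                "n_planted": len(planted),
                "n_declared": len(declared),
                "n_recovered": tp,
                "recall": tp / len(planted) if planted else None,
                "false_discoveries": len(declared - planted),
            }
        report["recovery"] = recovery

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("pipeline: run report written to %s", out / "report.json")
    return report
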