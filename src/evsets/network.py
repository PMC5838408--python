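"""Protein-protein interaction network analysis.

Builds a simple undirected graph over gene symbols from a BioGRID-style
edge list (self-loops and redundant records removed), computes per-set
degree statistics with pairwise rank tests, induces the adjacency
subnetwork of the enriched gene sets, and extracts disease-annotated
first-degree neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import EVSets, bh_adjust
from .properties import mann_whitney

logger = logging.getLogger(__name__)


def load_edges(edge_rows: Iterable[tuple[str, str]] | pd.DataFrame) -> nx.Graph:
    """Build a simple undirected graph from raw interaction rows.

    ``(A, B)`` and ``(B, A)`` collapse to one edge, self-loops and
    duplicate rows are dropped, malformed rows (missing or empty
    symbols) are skipped with a warning. Raises if no valid edge
    survives cleaning.
    """
    if isinstance(edge_rows, pd.DataFrame):
        if edge_rows.shape[1] < 2:
            raise ValueError("edge table needs two gene-symbol columns")
        edge_rows = edge_rows.iloc[:, :2].itertuples(index=False, name=None)

    graph = nx.Graph()
    n_rows = n_malformed = n_loops = n_dup = 0
    for row in edge_rows:
        n_rows += 1
        try:
            a, b = row
        except (TypeError, ValueError):
            n_malformed += 1
            continue
        if not isinstance(a, str) or not isinstance(b, str) or not a.strip() or not b.strip():
            n_malformed += 1
            continue
        a, b = a.strip(), b.strip()
        if a == b:
            n_loops += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b)
    if n_malformed:
        logger.warning("network: skipped %d malformed edge rows", n_malformed)
    if graph.number_of_edges() == 0:
        raise ValueError("no valid interaction edges after cleaning")
    logger.info(
        "network: %d nodes, %d edges (%d duplicate rows, %d self-loops removed)",
        graph.number_of_nodes(),
        graph.number_of_edges(),
        n_dup,
        n_loops,
    )
    return graph


def read_edges(path: str | Path) -> nx.Graph:
    """Read a two-column tab-separated edge list (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    first = df.iloc[0]
    if {"gene_a", "gene_b"} <= set(first.astype(str)):
        df = df.iloc[1:]
    return load_edges(df)


@dataclass
class DegreeReport:
    per_set: dict[str, dict] = field(default_factory=dict)
    pairwise: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"per_set": self.per_set, "pairwise": self.pairwise}


def degree_stats(gene_sets: Mapping[str, set[str]], graph: nx.Graph) -> DegreeReport:
    """Degree summaries per gene set, with pairwise Mann-Whitney tests.

    The degree of a gene is its number of distinct interactors in the
    full network; genes absent from the network have degree 0 and are
    retained in the medians and ranges. Pairwise two-tailed Mann-Whitney
    p-values on the degree vectors are Benjamini-Hochberg adjusted
    across the pairs.
    """
    report = DegreeReport()
    degrees: dict[str, np.ndarray] = {}
    for label, members in gene_sets.items():
        if not members:
            raise ValueError(f"gene set {label!r} is empty")
        deg = np.array([graph.degree(g) if g in graph else 0 for g in sorted(members)])
        degrees[label] = deg
        report.per_set[label] = {
            "n": int(len(deg)),
            "fraction_with_interactor": float((deg >= 1).mean()),
            "median_degree": float(np.median(deg)),
            "min_degree": int(deg.min()),
            "max_degree": int(deg.max()),
        }
    labels = sorted(gene_sets)
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    p_list = [mann_whitney(degrees[a], degrees[b]) for a, b in pairs]
    if p_list:
        adjusted = bh_adjust(p_list)
        for (a, b), p, q in zip(pairs, p_list, adjusted):
            report.pairwise[f"{a}|{b}"] = {
                "test": "mann-whitney two-tailed",
                "p": float(p),
                "p_adj": float(q),
            }
    return report


@dataclass
class EnrichedSubnetwork:
    """Induced subgraph on the union of enriched genes, isolates dropped."""

    graph: nx.Graph
    per_set_counts: dict[str, int]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "per_set_counts": self.per_set_counts,
        }


def enriched_adjacency_subnetwork(evsets: EVSets, graph: nx.Graph) -> EnrichedSubnetwork:
    """Adjacency subnetwork of the enriched genes.

    Induces the subgraph on the union of the three EVsets (edges kept
    only when both endpoints are enriched) and drops isolated nodes, so
    every remaining gene is adjacent to another enriched gene. Per-set
    node counts partition the nodes with priority disease > rare >
    common for the (empirically absent) case of a gene in several sets.
    """
    union = evsets.union()
    sub = graph.subgraph(n for n in union if n in graph).copy()
    sub.remove_nodes_from([n for n, d in list(sub.degree()) if d == 0])
    counts = {"disease": 0, "rare": 0, "common": 0}
    for node in sub.nodes:
        for cls in ("disease", "rare", "common"):
            if node in evsets.for_class(cls):
                counts[cls] += 1
                break
    result = EnrichedSubnetwork(graph=sub, per_set_counts=counts)
    logger.info(
        "network: enriched adjacency subnetwork has %d nodes and %d edges "
        "(disease=%d, rare=%d, common=%d)",
        result.n_nodes,
        result.n_edges,
        counts["disease"],
        counts["rare"],
        counts["common"],
    )
    return result


def disease_neighbors(
    gene: str, graph: nx.Graph, annotations: pd.DataFrame
) -> set[str]:
    """First-degree neighbors of ``gene`` carrying a disease annotation."""
    if gene not in graph:
        logger.warning("network: gene %s absent from the interaction network", gene)
        return set()
    flagged = annotations.set_index("gene")["disease_annotated"].fillna(False).astype(bool)
    return {n for n in graph.neighbors(gene) if bool(flagged.get(n, False))}


def write_network_report(
    report: DegreeReport, subnetwork: EnrichedSubnetwork, out_dir: str | Path
) -> dict[str, Path]:
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": out / "network_report.json",
        "subnetwork": out / "subnetwork.edgelist",
    }
    payload = {"degree": report.to_dict(), "subnetwork": subnetwork.to_dict()}
    paths["report"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    rows = sorted(tuple(sorted(e)) for e in subnetwork.graph.edges())
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(
        paths["subnetwork"], sep="\t", index=False
    )
    return paths
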