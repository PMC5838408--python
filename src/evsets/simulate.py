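"""Synthetic variant-catalogue generator with planted enrichment structure.

Emulates, at configurable scale, the inputs of a gene-level variant
enrichment study: a table of coding variants labelled rare (MAF < 0.01),
common (MAF >= 0.01) or disease-causing (clinically asserted pathogenic,
irrespective of frequency), a gene annotation table (essentiality flags,
pLi, dN/dS, disease-annotation flags), an undirected protein-protein
interaction edge list, and a per-population allele-frequency table.

A configurable number of "planted" genes have the odds of one variant
class multiplied by an enrichment shift, so downstream enrichment calls
can be scored against known ground truth. The default configuration
reproduces the global scale of the emulated study: 589,983 variants in
the proportions 481,277 rare / 81,822 common / 26,884 disease-causing
over 17,975 protein-coding genes, and a scale-free interaction network
whose mean degree matches 279,904 interactions over ~21k genes.

All randomness flows from a single seed through named sub-streams, so a
seed fully determines every output table byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_ORDER = ("rare", "common", "disease")
_CLASS_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}

#: set labels used to key per-set annotation parameters
SET_LABELS = ("disease", "rare", "common", "background")

# study-scale global class proportions: 481,277 / 81,822 / 26,884 of 589,983
_STUDY_PROPORTIONS = (481_277 / 589_983, 81_822 / 589_983, 26_884 / 589_983)

_CONSEQUENCES = np.array(
    [
        "missense_variant",
        "synonymous_variant",
        "frameshift_variant",
        "stop_gained",
        "splice_acceptor_variant",
        "inframe_deletion",
    ]
)
_CONSEQUENCE_PROBS = np.array([0.55, 0.30, 0.05, 0.04, 0.03, 0.03])

#: gnomAD-style population labels, cycled when n_populations > 7
POPULATION_LABELS = ("AFR", "AMR", "ASJ", "EAS", "FIN", "NFE", "SAS")


class ConfigError(ValueError):
    """A simulation parameter violates its constraint; names the field."""


def _default_essential_probs() -> dict[str, float]:
    # study-style essentiality rates: ~64% disease-set, ~53% rare-set,
    # ~11% common-set; background near the genome-wide rate
    return {"disease": 0.64, "rare": 0.53, "common": 0.11, "background": 0.35}


def _default_pli_params() -> dict[str, tuple[float, float]]:
    # Beta(a, b) per set: constrained sets skew toward pLi 1, the
    # common-variant set toward 0, background U-shaped as in real exomes
    return {
        "disease": (1.2, 0.5),
        "rare": (1.2, 0.5),
        "common": (0.35, 1.4),
        "background": (0.5, 0.9),
    }


def _default_dnds_params() -> dict[str, tuple[float, float]]:
    # log-normal (mu, sigma) on the natural scale; medians ~0.15 for the
    # constrained sets, ~0.45 for the common set
    return {
        "disease": (math.log(0.15), 0.5),
        "rare": (math.log(0.15), 0.5),
        "common": (math.log(0.45), 0.5),
        "background": (math.log(0.30), 0.6),
    }


def _default_disease_annot_probs() -> dict[str, float]:
    return {"disease": 0.90, "rare": 0.50, "common": 0.25, "background": 0.20}


def _default_gwas_probs() -> dict[str, float]:
    return {"disease": 0.30, "rare": 0.15, "common": 0.10, "background": 0.08}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``class_proportions`` is the (rare, common, disease) probability triple
    used for unplanted genes; planted genes have the planted class's odds
    multiplied by ``enrichment_shift`` and renormalized. ``enrichment_shift``
    of exactly 1 yields a null simulation (no planting effect).
    """

    n_genes: int = 17_975
    n_variants_total: int = 589_983
    class_proportions: tuple[float, float, float] = _STUDY_PROPORTIONS
    planted_rare_genes: int = 32
    planted_common_genes: int = 282
    planted_disease_genes: int = 800
    enrichment_shift: float = 8.0
    planted_intensity_boost: float = 1.0
    gene_intensity_dispersion: float = 1.0
    network_model: str = "scale_free"
    network_mean_degree: float = 26.3
    network_gene_fraction: float = 0.8
    essential_prob_by_set: dict[str, float] = field(default_factory=_default_essential_probs)
    pli_params: dict[str, tuple[float, float]] = field(default_factory=_default_pli_params)
    dnds_params: dict[str, tuple[float, float]] = field(default_factory=_default_dnds_params)
    disease_annot_prob_by_set: dict[str, float] = field(default_factory=_default_disease_annot_probs)
    gwas_prob_by_set: dict[str, float] = field(default_factory=_default_gwas_probs)
    missing_score_fraction: float = 0.05
    n_populations: int = 7
    population_max_variants: int = 5_000
    pop_specific_fraction: float = 0.30
    switch_fraction: float = 0.05
    allele_number: int = 10_000
    duplicate_edge_rows: int = 100
    self_loop_rows: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be a positive integer")
        if self.n_variants_total <= 0:
            raise ConfigError("n_variants_total must be a positive integer")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (3,) or np.any(props < 0) or np.any(props > 1):
            raise ConfigError("class_proportions must be three probabilities in [0, 1]")
        if abs(float(props.sum()) - 1.0) > 1e-9:
            raise ConfigError("class_proportions must sum to 1 within 1e-9")
        for name in ("planted_rare_genes", "planted_common_genes", "planted_disease_genes"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        n_planted = (
            self.planted_rare_genes + self.planted_common_genes + self.planted_disease_genes
        )
        if n_planted >= self.n_genes:
            raise ConfigError("planted gene counts must sum to less than n_genes")
        # shift == 1 is the explicit null; < 1 would deplete, not enrich
        if self.enrichment_shift < 1:
            raise ConfigError("enrichment_shift must be >= 1")
        if self.gene_intensity_dispersion <= 0:
            raise ConfigError("gene_intensity_dispersion must be positive")
        if self.planted_intensity_boost <= 0:
            raise ConfigError("planted_intensity_boost must be positive")
        if self.network_model not in ("scale_free", "erdos_renyi"):
            raise ConfigError("network_model must be 'scale_free' or 'erdos_renyi'")
        if self.network_mean_degree <= 0:
            raise ConfigError("network_mean_degree must be positive")
        if not 0 < self.network_gene_fraction <= 1:
            raise ConfigError("network_gene_fraction must be in (0, 1]")
        if self.n_populations < 2:
            raise ConfigError("n_populations must be at least 2")
        if not 0 <= self.pop_specific_fraction <= 1:
            raise ConfigError("pop_specific_fraction must be in [0, 1]")
        if not 0 <= self.switch_fraction <= 1:
            raise ConfigError("switch_fraction must be in [0, 1]")
        if self.pop_specific_fraction + self.switch_fraction > 1:
            raise ConfigError("pop_specific_fraction + switch_fraction must be <= 1")
        if self.allele_number <= 0:
            raise ConfigError("allele_number must be positive")
        for name in (
            "essential_prob_by_set",
            "disease_annot_prob_by_set",
            "gwas_prob_by_set",
        ):
            table = getattr(self, name)
            for label in SET_LABELS:
                p = table.get(label)
                if p is None or not 0 <= p <= 1:
                    raise ConfigError(f"{name}[{label!r}] must be a probability")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown simulation fields: {sorted(unknown)}")
        cfg = cls(**data)
        if "class_proportions" in data:
            cfg.class_proportions = tuple(data["class_proportions"])
        return cfg


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure, for recovery scoring."""

    planted_rare: set[str]
    planted_common: set[str]
    planted_disease: set[str]
    baseline_probs: tuple[float, float, float]
    per_gene_class_probs: dict[str, tuple[float, float, float]]
    population_specific: set[str]
    class_switch: set[str]
    n_network_nodes: int
    n_edges_clean: int

    def planted_for(self, variant_class: str) -> set[str]:
        return {
            "rare": self.planted_rare,
            "common": self.planted_common,
            "disease": self.planted_disease,
        }[variant_class]

    def to_dict(self) -> dict:
        return {
            "planted_rare": sorted(self.planted_rare),
            "planted_common": sorted(self.planted_common),
            "planted_disease": sorted(self.planted_disease),
            "baseline_probs": list(self.baseline_probs),
            "per_gene_class_probs": {
                g: list(p) for g, p in sorted(self.per_gene_class_probs.items())
            },
            "population_specific": sorted(self.population_specific),
            "class_switch": sorted(self.class_switch),
            "n_network_nodes": self.n_network_nodes,
            "n_edges_clean": self.n_edges_clean,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticTruth":
        return cls(
            planted_rare=set(data["planted_rare"]),
            planted_common=set(data["planted_common"]),
            planted_disease=set(data["planted_disease"]),
            baseline_probs=tuple(data["baseline_probs"]),
            per_gene_class_probs={
                g: tuple(p) for g, p in data["per_gene_class_probs"].items()
            },
            population_specific=set(data["population_specific"]),
            class_switch=set(data["class_switch"]),
            n_network_nodes=data["n_network_nodes"],
            n_edges_clean=data["n_edges_clean"],
        )


class SimulatedDataset(NamedTuple):
    variants: pd.DataFrame
    genes: pd.DataFrame
    edges: pd.DataFrame
    populations: pd.DataFrame
    truth: SyntheticTruth


def shifted_probs(
    baseline: tuple[float, float, float], variant_class: str, shift: float
) -> tuple[float, float, float]:
    """Multiply one class's odds by ``shift`` and renormalize the triple."""
    w = np.asarray(baseline, dtype=float).copy()
    w[_CLASS_INDEX[variant_class]] *= shift
    w /= w.sum()
    return tuple(float(x) for x in w)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate all four input tables plus the planted ground truth.

    Variant counts per gene follow a multinomial over log-normal relative
    gene intensities (a proxy for coding length); each variant's class is
    drawn from its gene's class-probability triple; MAFs are drawn
    uniformly inside the class boundary. The same seed always produces
    identical tables.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    r_assign, r_var, r_genes, r_net, r_pop, r_shuffle = (
        np.random.default_rng(s) for s in streams
    )

    width = max(5, len(str(config.n_genes)))
    gene_symbols = np.array([f"G{i:0{width}d}" for i in range(config.n_genes)])

    # planted sets: a disjoint partition of a random gene permutation
    perm = r_assign.permutation(config.n_genes)
    nd, nr, nc = (
        config.planted_disease_genes,
        config.planted_rare_genes,
        config.planted_common_genes,
    )
    idx_disease = perm[:nd]
    idx_rare = perm[nd : nd + nr]
    idx_common = perm[nd + nr : nd + nr + nc]
    set_label = np.full(config.n_genes, "background", dtype=object)
    set_label[idx_disease] = "disease"
    set_label[idx_rare] = "rare"
    set_label[idx_common] = "common"

    baseline = tuple(float(p) for p in config.class_proportions)
    triples = {
        "background": baseline,
        "disease": shifted_probs(baseline, "disease", config.enrichment_shift),
        "rare": shifted_probs(baseline, "rare", config.enrichment_shift),
        "common": shifted_probs(baseline, "common", config.enrichment_shift),
    }

    variants = _simulate_variants(
        config, r_var, r_shuffle, gene_symbols, set_label, triples
    )
    genes = _simulate_gene_annotations(config, r_genes, gene_symbols, set_label)
    edges, n_net_nodes, n_edges_clean = _simulate_network(
        config, r_net, gene_symbols, set_label
    )
    populations, specific_ids, switch_ids = _simulate_populations(
        config, r_pop, variants
    )

    per_gene_probs = {
        str(gene_symbols[i]): triples[str(set_label[i])]
        for i in np.concatenate([idx_disease, idx_rare, idx_common])
    }
    truth = SyntheticTruth(
        planted_rare=set(gene_symbols[idx_rare]),
        planted_common=set(gene_symbols[idx_common]),
        planted_disease=set(gene_symbols[idx_disease]),
        baseline_probs=baseline,
        per_gene_class_probs=per_gene_probs,
        population_specific=specific_ids,
        class_switch=switch_ids,
        n_network_nodes=n_net_nodes,
        n_edges_clean=n_edges_clean,
    )
    variants = variants.drop(columns=["_class"])
    return SimulatedDataset(variants, genes, edges, populations, truth)


def _simulate_variants(config, rng, r_shuffle, gene_symbols, set_label, triples):
    n = config.n_variants_total
    intensity = rng.lognormal(0.0, config.gene_intensity_dispersion, config.n_genes)
    if config.planted_intensity_boost != 1.0:
        intensity[set_label != "background"] *= config.planted_intensity_boost
    gene_counts = rng.multinomial(n, intensity / intensity.sum())

    gene_idx = np.repeat(np.arange(config.n_genes), gene_counts)
    var_set_label = set_label[gene_idx]
    class_idx = np.empty(n, dtype=np.int8)
    for label in SET_LABELS:
        mask = var_set_label == label
        if mask.any():
            class_idx[mask] = rng.choice(3, size=int(mask.sum()), p=triples[label])

    maf = np.full(n, np.nan)
    is_rare = class_idx == _CLASS_INDEX["rare"]
    is_common = class_idx == _CLASS_INDEX["common"]
    is_disease = class_idx == _CLASS_INDEX["disease"]
    # numpy uniform is half-open [low, high): rare stays strictly below 0.01
    maf[is_rare] = rng.uniform(1e-6, 0.01, int(is_rare.sum()))
    maf[is_common] = rng.uniform(0.01, 0.5, int(is_common.sum()))
    disease_has_maf = is_disease & (rng.random(n) < 0.5)
    maf[disease_has_maf] = rng.uniform(1e-6, 0.5, int(disease_has_maf.sum()))

    # source priority structure: most frequencies live in the ExAC-style
    # column; some only in the dbSNP-style column
    in_exac = rng.random(n) < 0.85
    also_dbsnp = rng.random(n) < 0.5
    maf_exac = np.where(in_exac, maf, np.nan)
    maf_dbsnp = np.where(~in_exac | also_dbsnp, maf, np.nan)

    clinvar = is_disease & (rng.random(n) < 0.8)
    uniprot = is_disease & (rng.random(n) < 0.5)
    neither = is_disease & ~clinvar & ~uniprot
    clinvar |= neither  # every disease variant carries >= 1 assertion

    consequence = rng.choice(_CONSEQUENCES, size=n, p=_CONSEQUENCE_PROBS)

    order = r_shuffle.permutation(n)
    id_width = max(7, len(str(n)))
    df = pd.DataFrame(
        {
            "variant_id": [f"v{i:0{id_width}d}" for i in range(n)],
            "gene": gene_symbols[gene_idx][order],
            "consequence": consequence[order],
            "maf_exac": maf_exac[order],
            "maf_dbsnp": maf_dbsnp[order],
            "clinvar_pathogenic": clinvar[order],
            "uniprot_pathogenic": uniprot[order],
            "_class": np.array(CLASS_ORDER, dtype=object)[class_idx][order],
        }
    )
    return df


def _simulate_gene_annotations(config, rng, gene_symbols, set_label):
    n = config.n_genes
    p_ess = np.array([config.essential_prob_by_set[s] for s in set_label])
    essential = rng.random(n) < p_ess
    mgi = essential & (rng.random(n) < 0.7)
    ogee = essential & (rng.random(n) < 0.6)
    # essential genes must carry at least one supporting flag
    ogee |= essential & ~mgi & ~ogee

    pli = np.empty(n)
    dnds = np.empty(n)
    for label in SET_LABELS:
        mask = set_label == label
        if not mask.any():
            continue
        a, b = config.pli_params[label]
        pli[mask] = rng.beta(a, b, int(mask.sum()))
        mu, sigma = config.dnds_params[label]
        dnds[mask] = rng.lognormal(mu, sigma, int(mask.sum()))
    pli[rng.random(n) < config.missing_score_fraction] = np.nan
    dnds[rng.random(n) < config.missing_score_fraction] = np.nan

    p_da = np.array([config.disease_annot_prob_by_set[s] for s in set_label])
    p_gwas = np.array([config.gwas_prob_by_set[s] for s in set_label])
    return pd.DataFrame(
        {
            "gene": gene_symbols,
            "essential_mgi": mgi,
            "essential_ogee": ogee,
            "pli": pli,
            "dn_ds": dnds,
            "disease_annotated": rng.random(n) < p_da,
            "gwas_associated": rng.random(n) < p_gwas,
        }
    )


def _simulate_network(config, rng, gene_symbols, set_label):
    """Scale-free (or ER) graph over a subset of genes.

    Planted disease- and rare-set genes are always network members and are
    mapped onto high-degree nodes (top quartile), emulating the hub-like
    position of disease genes in curated interactomes; the remaining slots
    are a uniform sample of the other genes.
    """
    hub_mask = (set_label == "disease") | (set_label == "rare")
    hub_genes = gene_symbols[hub_mask]
    n_net = max(int(round(config.network_gene_fraction * config.n_genes)), len(hub_genes))
    n_net = min(n_net, config.n_genes)
    other_pool = gene_symbols[~hub_mask]
    n_other = n_net - len(hub_genes)
    member_other = rng.choice(other_pool, size=n_other, replace=False)

    nx_seed = int(rng.integers(2**31))
    if config.network_model == "scale_free":
        m = max(1, int(round(config.network_mean_degree / 2)))
        m = min(m, max(1, n_net - 1))
        graph = nx.barabasi_albert_graph(n_net, m, seed=nx_seed)
    else:
        p = min(1.0, config.network_mean_degree / max(1, n_net - 1))
        graph = nx.gnp_random_graph(n_net, p, seed=nx_seed)

    degrees = np.array([d for _, d in graph.degree()])
    by_degree = np.argsort(-degrees, kind="stable")
    top_k = max(len(hub_genes), int(0.25 * n_net))
    hub_slots = rng.choice(by_degree[:top_k], size=len(hub_genes), replace=False)
    rest_slots = np.setdiff1d(np.arange(n_net), hub_slots)
    rest_slots = rng.permutation(rest_slots)

    node_to_gene = np.empty(n_net, dtype=object)
    node_to_gene[hub_slots] = hub_genes
    node_to_gene[rest_slots] = member_other

    rows = [
        tuple(sorted((node_to_gene[u], node_to_gene[v]))) for u, v in graph.edges()
    ]
    n_edges_clean = len(rows)
    if rows:
        dup_idx = rng.integers(0, len(rows), config.duplicate_edge_rows)
        for i in dup_idx:
            a, b = rows[i]
            rows.append((b, a))  # reversed duplicate, as raw interaction files have
        loop_genes = rng.choice(node_to_gene, size=config.self_loop_rows)
        rows.extend((g, g) for g in loop_genes)
    rows = [rows[i] for i in rng.permutation(len(rows))]
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b"])
    return edges, n_net, n_edges_clean


def _simulate_populations(config, rng, variants):
    """Allele counts per population for a sample of non-disease variants.

    Planted patterns: a fraction of rare variants are observed in exactly
    one population (population-specific); a disjoint fraction are rare in
    at least one population but common (frequency >= 0.01) in another
    (class switches); everything else is observed in >= 2 populations on
    one side of the 0.01 boundary. Common variants are never
    population-specific and never switch.
    """
    n_pops = config.n_populations
    pop_labels = [
        POPULATION_LABELS[i % len(POPULATION_LABELS)]
        + ("" if i < len(POPULATION_LABELS) else str(i // len(POPULATION_LABELS)))
        for i in range(n_pops)
    ]
    an = config.allele_number
    eligible = variants.index[variants["_class"] != "disease"].to_numpy()
    n_take = min(config.population_max_variants, len(eligible))
    if n_take == 0:
        empty = pd.DataFrame(
            columns=["variant_id", "population", "allele_count", "allele_number"]
        )
        return empty, set(), set()
    chosen = rng.choice(eligible, size=n_take, replace=False)
    chosen_ids = variants.loc[chosen, "variant_id"].to_numpy()
    chosen_class = variants.loc[chosen, "_class"].to_numpy()

    def rare_ac(k):
        # frequency in [5e-4, 0.0095] -> count in [5, 95] at AN=10,000
        return np.maximum(1, np.round(rng.uniform(5e-4, 0.0095, k) * an)).astype(int)

    def common_ac(k):
        return np.round(rng.uniform(0.015, 0.4, k) * an).astype(int)

    specific_ids: set[str] = set()
    switch_ids: set[str] = set()
    counts = np.zeros((n_take, n_pops), dtype=int)
    u = rng.random(n_take)
    for i in range(n_take):
        if chosen_class[i] == "rare":
            if u[i] < config.pop_specific_fraction:
                pop = rng.integers(n_pops)
                counts[i, pop] = rare_ac(1)[0]
                specific_ids.add(chosen_ids[i])
                continue
            if u[i] < config.pop_specific_fraction + config.switch_fraction:
                pops = rng.choice(n_pops, size=2, replace=False)
                counts[i, pops[0]] = rare_ac(1)[0]
                counts[i, pops[1]] = common_ac(1)[0]
                switch_ids.add(chosen_ids[i])
                continue
            k_obs = int(rng.integers(2, n_pops + 1))
            pops = rng.choice(n_pops, size=k_obs, replace=False)
            counts[i, pops] = rare_ac(k_obs)
        else:
            k_obs = int(rng.integers(2, n_pops + 1))
            pops = rng.choice(n_pops, size=k_obs, replace=False)
            counts[i, pops] = common_ac(k_obs)

    table = pd.DataFrame(
        {
            "variant_id": np.repeat(chosen_ids, n_pops),
            "population": np.tile(pop_labels, n_take),
            "allele_count": counts.ravel(),
            "allele_number": an,
        }
    )
    return table, specific_ids, switch_ids


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the five outputs as TSV/JSON under ``out_dir``; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": out / "variants.tsv",
        "genes": out / "genes.tsv",
        "edges": out / "edges.tsv",
        "populations": out / "populations.tsv",
        "truth": out / "truth.json",
    }
    dataset.variants.to_csv(paths["variants"], sep="\t", index=False)
    dataset.genes.to_csv(paths["genes"], sep="\t", index=False)
    dataset.edges.to_csv(paths["edges"], sep="\t", index=False)
    dataset.populations.to_csv(paths["populations"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(dataset.truth.to_dict(), indent=2, sort_keys=True))
    logger.info(
        "simulate: wrote %d variants, %d genes, %d edge rows, %d population rows to %s",
        len(dataset.variants),
        len(dataset.genes),
        len(dataset.edges),
        len(dataset.populations),
        out,
    )
    return paths
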