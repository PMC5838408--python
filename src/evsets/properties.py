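"""Gene-set characterization: essentiality, constraint scores, disease
annotation overlap and population-level allele-frequency behaviour.

A gene is *essential* when its mouse ortholog knockout is lethal (MGI
flag) or it is listed in the OGEE essentiality database. Constraint is
summarized by pLi (probability of loss-of-function intolerance, in
[0, 1]) and dN/dS; score distributions across gene sets are compared
with the Kruskal-Wallis rank-sum test (omnibus) and two-tailed
Mann-Whitney tests (pairwise, Benjamini-Hochberg adjusted). Proportions
are compared with Fisher's exact test, which remains valid at the small
set sizes involved (n = 32).

A variant is *population-specific* when its allele count is non-zero in
exactly one population; a *class switch* is a variant whose frequency is
below 0.01 in at least one population where it is observed and at or
above 0.01 in at least one other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EVSets, bh_adjust
from .ingest import RARE_MAF_THRESHOLD

logger = logging.getLogger(__name__)

PLI_CONSTRAINED_THRESHOLD = 0.9

#: group size above which Mann-Whitney switches from exact enumeration to
#: the tie-corrected normal approximation
_MW_EXACT_MAX_N = 50


# ---------------------------------------------------------------------------
# essentiality


def classify_essential(essential_mgi, essential_ogee) -> bool:
    """Essential iff the MGI flag or the OGEE flag is true; missing = false."""
    mgi = bool(essential_mgi) if not pd.isna(essential_mgi) else False
    ogee = bool(essential_ogee) if not pd.isna(essential_ogee) else False
    return mgi or ogee


def essential_mask(annotations: pd.DataFrame) -> pd.Series:
    """Vectorized essentiality call, indexed by gene symbol."""
    mgi = annotations["essential_mgi"].fillna(False).astype(bool)
    ogee = annotations["essential_ogee"].fillna(False).astype(bool)
    return pd.Series((mgi | ogee).to_numpy(), index=annotations["gene"].to_numpy())


def essentiality_summary(
    gene_set: set[str], annotations: pd.DataFrame, precision: int = 0
) -> tuple[int, float]:
    """Count and percentage of essential genes in a set.

    Genes absent from the annotation table count as not essential. The
    percentage is rounded to ``precision`` decimals (nearest integer by
    default, matching the usual figure-legend style).
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    mask = essential_mask(annotations)
    count = int(sum(bool(mask.get(g, False)) for g in gene_set))
    pct = round(100.0 * count / len(gene_set), precision)
    if precision == 0:
        pct = int(pct)
    return count, pct


def count_constrained(
    gene_set: set[str],
    annotations: pd.DataFrame,
    threshold: float = PLI_CONSTRAINED_THRESHOLD,
) -> tuple[int, int]:
    """Number of genes with pLi >= threshold; also the number unscored.

    Returns ``(count, n_missing)`` where ``n_missing`` counts set members
    without a pLi value (absent from the table or NaN).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    pli = annotations.set_index("gene")["pli"]
    values = pli.reindex(sorted(gene_set))
    n_missing = int(values.isna().sum())
    count = int((values >= threshold).sum())
    if n_missing:
        logger.info("properties: %d genes without pLi excluded from constraint count", n_missing)
    return count, n_missing


# ---------------------------------------------------------------------------
# rank tests on scores


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-tailed Mann-Whitney p-value.

    Exact enumeration when both groups have <= 50 observations and the
    pooled sample is tie-free; otherwise the normal approximation with
    mid-ranks and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and max(len(x), len(y)) <= _MW_EXACT_MAX_N) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


@dataclass
class SetComparisonReport:
    """Summaries and test results for one score compared across gene sets."""

    score: str
    per_set: dict[str, dict] = field(default_factory=dict)
    omnibus_test: str = "kruskal-wallis"
    omnibus_p: float | None = None
    pairwise: dict[str, dict] = field(default_factory=dict)
    unavailable: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "per_set": self.per_set,
            "omnibus_test": self.omnibus_test,
            "omnibus_p": self.omnibus_p,
            "pairwise": self.pairwise,
            "unavailable": sorted(self.unavailable),
        }


def compare_score_across_sets(
    sets: Mapping[str, set[str]],
    annotations: pd.DataFrame,
    score_name: str,
) -> SetComparisonReport:
    """Kruskal-Wallis omnibus plus pairwise two-tailed Mann-Whitney tests.

    Missing scores are dropped per set (complete case) with the dropped
    count reported; a set with fewer than two scored genes makes any
    comparison involving it unavailable rather than fabricated.
    """
    if score_name not in ("pli", "dn_ds"):
        raise ValueError(f"unknown score {score_name!r}")
    scores = annotations.set_index("gene")[score_name]
    groups: dict[str, np.ndarray] = {}
    report = SetComparisonReport(score=score_name)
    for label, members in sets.items():
        values = scores.reindex(sorted(members))
        scored = values.dropna().to_numpy(dtype=float)
        groups[label] = scored
        report.per_set[label] = {
            "n": int(len(members)),
            "n_scored": int(len(scored)),
            "n_missing": int(len(members) - len(scored)),
            "median": float(np.median(scored)) if len(scored) else None,
            "min": float(scored.min()) if len(scored) else None,
            "max": float(scored.max()) if len(scored) else None,
        }

    usable = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(usable) >= 2:
        report.omnibus_p = float(stats.kruskal(*usable.values()).pvalue)
    else:
        report.unavailable.append("omnibus")

    labels = sorted(sets)
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    p_list, tested = [], []
    for a, b in pairs:
        key = f"{a}|{b}"
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            report.unavailable.append(key)
            continue
        p_list.append(mann_whitney(groups[a], groups[b]))
        tested.append(key)
    if p_list:
        adjusted = bh_adjust(p_list)
        for key, p, q in zip(tested, p_list, adjusted):
            report.pairwise[key] = {
                "test": "mann-whitney two-tailed",
                "p": float(p),
                "p_adj": float(q),
            }
    return report


# ---------------------------------------------------------------------------
# proportions and disease-annotation overlap


def proportion_test(a_yes: int, a_total: int, b_yes: int, b_total: int) -> float:
    """Two-sided Fisher exact p-value for a difference in proportions."""
    if not (0 <= a_yes <= a_total and 0 <= b_yes <= b_total):
        raise ValueError("need 0 <= yes <= total in both groups")
    if a_total < 1 or b_total < 1:
        raise ValueError("group totals must be at least 1")
    table = [[a_yes, a_total - a_yes], [b_yes, b_total - b_yes]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def disease_overlap_summary(
    evsets: EVSets, annotations: pd.DataFrame, precision: int = 1
) -> dict:
    """Per-set counts of disease-annotated genes and the rare-vs-common test.

    A gene counts as disease-linked when it carries a curated disease
    annotation or a genome-wide-significant GWAS association. Set members
    absent from the annotation table are treated as unannotated (logged).
    """
    ann = annotations.set_index("gene")
    linked = (
        ann["disease_annotated"].fillna(False).astype(bool)
        | ann["gwas_associated"].fillna(False).astype(bool)
    )
    out: dict = {"per_set": {}}
    counts = {}
    for cls in ("disease", "rare", "common"):
        members = sorted(evsets.for_class(cls))
        missing = [g for g in members if g not in linked.index]
        if missing:
            logger.info(
                "properties: %d %s-set genes missing from annotations treated as unannotated",
                len(missing),
                cls,
            )
        n_yes = int(sum(bool(linked.get(g, False)) for g in members))
        counts[cls] = (n_yes, len(members))
        out["per_set"][cls] = {
            "n": len(members),
            "n_disease_linked": n_yes,
            "percent": round(100.0 * n_yes / len(members), precision) if members else 0.0,
        }
    if counts["rare"][1] >= 1 and counts["common"][1] >= 1:
        out["rare_vs_common_p"] = proportion_test(
            counts["rare"][0], counts["rare"][1], counts["common"][0], counts["common"][1]
        )
        out["rare_vs_common_test"] = "fisher exact two-sided"
    return out


# ---------------------------------------------------------------------------
# population-level behaviour


def _per_variant_pop_stats(table: pd.DataFrame) -> pd.DataFrame:
    required = {"variant_id", "population", "allele_count", "allele_number"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"population table missing columns: {sorted(missing)}")
    if (table["allele_count"] > table["allele_number"]).any():
        raise ValueError("allele_count exceeds allele_number")
    df = table.copy()
    df["freq"] = df["allele_count"] / df["allele_number"]
    return df


def population_specificity(
    table: pd.DataFrame, gene_map: pd.Series | None = None
) -> tuple[pd.DataFrame, dict]:
    """Flag population-specific variants; summarize the complement fraction.

    "Observed in a population" means allele_count > 0, regardless of the
    allele number. Returns a per-variant frame (``variant_id,
    n_populations_observed, population_specific, unobserved``) and a
    summary with the overall fraction of observed variants that are not
    population-specific, broken down per gene when ``gene_map``
    (variant_id -> gene) is supplied.
    """
    df = _per_variant_pop_stats(table)
    n_pops = df["population"].nunique()
    if n_pops < 2:
        raise ValueError("population table must contain at least 2 populations")
    observed = (
        df.assign(obs=df["allele_count"] > 0).groupby("variant_id", sort=True)["obs"].sum()
    )
    per_variant = pd.DataFrame(
        {
            "variant_id": observed.index,
            "n_populations_observed": observed.to_numpy(dtype=int),
            "population_specific": (observed == 1).to_numpy(),
            "unobserved": (observed == 0).to_numpy(),
        }
    ).reset_index(drop=True)
    n_unobserved = int(per_variant["unobserved"].sum())
    if n_unobserved:
        logger.warning("properties: %d variants have zero allele count everywhere", n_unobserved)

    seen = per_variant.loc[~per_variant["unobserved"]]
    frac_not_specific = (
        float((~seen["population_specific"]).mean()) if len(seen) else float("nan")
    )
    summary = {
        "n_variants": int(len(per_variant)),
        "n_unobserved": n_unobserved,
        "n_population_specific": int(per_variant["population_specific"].sum()),
        "fraction_not_population_specific": frac_not_specific,
    }
    if gene_map is not None:
        mapped = seen.assign(gene=seen["variant_id"].map(gene_map))
        unmapped = int(mapped["gene"].isna().sum())
        if unmapped:
            logger.warning("properties: %d variants absent from the gene map skipped", unmapped)
        mapped = mapped.dropna(subset=["gene"])
        per_gene = (
            mapped.groupby("gene", sort=True)["population_specific"]
            .agg(lambda s: float((~s).mean()))
            .to_dict()
        )
        summary["fraction_not_population_specific_per_gene"] = per_gene
    return per_variant, summary


def detect_class_switches(
    table: pd.DataFrame, threshold: float = RARE_MAF_THRESHOLD
) -> list[str]:
    """Variants that change from rare to common across populations.

    A switch requires a population where the variant is observed
    (allele_count > 0) at frequency below ``threshold`` and another
    population at frequency >= ``threshold``.
    """
    df = _per_variant_pop_stats(table)
    if df["population"].nunique() < 2:
        raise ValueError("population table must contain at least 2 populations")
    df["rare_side"] = (df["allele_count"] > 0) & (df["freq"] < threshold)
    df["common_side"] = df["freq"] >= threshold
    flags = df.groupby("variant_id", sort=True)[["rare_side", "common_side"]].any()
    return sorted(flags.index[flags["rare_side"] & flags["common_side"]])
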