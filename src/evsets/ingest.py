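"""Variant-table ingestion: consequence filtering, MAF resolution, class
assignment and per-gene aggregation.

The classification rules follow the usual population-genetics conventions:
a variant asserted pathogenic in a clinical database is *disease-causing*
regardless of its frequency; otherwise its resolved global minor allele
frequency places it in *rare* (MAF < 0.01) or *common* (MAF >= 0.01).
The global MAF comes from the ExAC-style column when present, falling
back to the dbSNP-style column. Variants annotated to non-exonic
consequence classes (downstream gene, 3' UTR, 5' UTR) are excluded
before classification.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_ORDER = ("rare", "common", "disease")

#: consequence terms removed by default (after normalization)
DEFAULT_EXCLUDED_CONSEQUENCES = frozenset(
    {"downstream_gene", "3_prime_utr", "5_prime_utr"}
)

RARE_MAF_THRESHOLD = 0.01

_PRIME_RE = re.compile(r"([35])\s*[''′`]")


def normalize_consequence(term: str) -> str:
    """Normalize a consequence term to a lowercase underscore vocabulary.

    ``"3' UTR"``, ``"3′UTR"`` and ``"3_prime_UTR"`` all map to
    ``"3_prime_utr"``; spaces and apostrophes become underscores.
    """
    t = str(term).strip().lower()
    t = _PRIME_RE.sub(r"\1_prime ", t)
    t = re.sub(r"[ ''′`]+", "_", t)
    t = re.sub(r"_+", "_", t).strip("_")
    return t


def filter_consequences(
    variants: pd.DataFrame,
    excluded_terms: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CONSEQUENCES,
) -> pd.DataFrame:
    """Drop rows whose normalized consequence is in ``excluded_terms``.

    Input order is preserved; the number of removed rows is logged.
    Unknown terms pass through (and are warned about only at debug level,
    since the consequence vocabulary is open-ended).
    """
    if not excluded_terms:
        raise ValueError("excluded_terms must be non-empty")
    excluded = {normalize_consequence(t) for t in excluded_terms}
    normalized = variants["consequence"].map(normalize_consequence)
    keep = ~normalized.isin(excluded)
    n_removed = int((~keep).sum())
    logger.info("ingest: excluded %d variants by consequence class", n_removed)
    return variants.loc[keep]


def resolve_maf(
    maf_exac: float | None, maf_dbsnp: float | None
) -> tuple[float | None, str]:
    """Resolve one global MAF with ExAC-first priority.

    Returns ``(maf, source)`` where source is ``"exac"``, ``"dbsnp"`` or
    ``"none"``. Values in (0.5, 1] are folded to the minor allele
    (1 - value); values outside [0, 1] raise.
    """
    for value, source in ((maf_exac, "exac"), (maf_dbsnp, "dbsnp")):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        v = float(value)
        if v < 0 or v > 1:
            raise ValueError(f"allele frequency {v} outside [0, 1] ({source})")
        if v > 0.5:
            logger.warning("ingest: folding %s frequency %.4g to minor allele", source, v)
            v = 1.0 - v
        return v, source
    return None, "none"


def classify_variant(maf: float | None, pathogenic: bool) -> str:
    """Assign rare / common / disease / unclassifiable.

    A pathogenicity assertion wins over any frequency; MAF exactly 0 is
    rare (it satisfies MAF < 0.01); a missing MAF without an assertion is
    unclassifiable.
    """
    if pathogenic:
        return "disease"
    if maf is None or (isinstance(maf, float) and math.isnan(maf)):
        return "unclassifiable"
    return "rare" if maf < RARE_MAF_THRESHOLD else "common"


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated variant-table dialect."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "gene", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    for col in ("maf_exac", "maf_dbsnp"):
        if col not in df.columns:
            df[col] = np.nan
    for col in ("clinvar_pathogenic", "uniprot_pathogenic"):
        if col not in df.columns:
            df[col] = False
        df[col] = df[col].fillna(False).astype(bool)
    return df


def process_variants(
    variants: pd.DataFrame,
    excluded_terms: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CONSEQUENCES,
    deduplicate: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Full ingestion: filter, resolve MAF, classify, deduplicate.

    Returns the classified record table (columns ``variant_id, gene,
    consequence, maf, maf_source, pathogenic, variant_class``; one row
    per (variant, gene) pair, unclassifiable rows dropped) and a report
    dict of counts at each step.
    """
    report: dict = {"n_input": int(len(variants))}
    df = filter_consequences(variants, excluded_terms)
    report["n_excluded_consequence"] = report["n_input"] - len(df)
    df = df.copy()

    exac = pd.to_numeric(df["maf_exac"], errors="coerce").to_numpy(dtype=float)
    dbsnp = pd.to_numeric(df["maf_dbsnp"], errors="coerce").to_numpy(dtype=float)
    for name, arr in (("maf_exac", exac), ("maf_dbsnp", dbsnp)):
        bad = (~np.isnan(arr)) & ((arr < 0) | (arr > 1))
        if bad.any():
            ids = df.loc[bad, "variant_id"].head(5).tolist()
            raise ValueError(
                f"{name} outside [0, 1] for {int(bad.sum())} variants, e.g. {ids}"
            )
    n_folded = int(((exac > 0.5) | ((np.isnan(exac)) & (dbsnp > 0.5))).sum())
    exac = np.where(exac > 0.5, 1.0 - exac, exac)
    dbsnp = np.where(dbsnp > 0.5, 1.0 - dbsnp, dbsnp)
    report["n_folded_maf"] = n_folded
    if n_folded:
        logger.warning("ingest: folded %d frequencies > 0.5 to the minor allele", n_folded)

    has_exac = ~np.isnan(exac)
    maf = np.where(has_exac, exac, dbsnp)
    source = np.where(has_exac, "exac", np.where(~np.isnan(dbsnp), "dbsnp", "none"))

    pathogenic = (
        df["clinvar_pathogenic"].astype(bool) | df["uniprot_pathogenic"].astype(bool)
    ).to_numpy()
    variant_class = np.where(
        pathogenic,
        "disease",
        np.where(
            np.isnan(maf),
            "unclassifiable",
            np.where(maf < RARE_MAF_THRESHOLD, "rare", "common"),
        ),
    )

    records = pd.DataFrame(
        {
            "variant_id": df["variant_id"].to_numpy(),
            "gene": df["gene"].to_numpy(),
            "consequence": df["consequence"].map(normalize_consequence).to_numpy(),
            "maf": maf,
            "maf_source": source,
            "pathogenic": pathogenic,
            "variant_class": variant_class,
        }
    )

    if deduplicate:
        before = len(records)
        records = records.drop_duplicates(subset=["variant_id", "gene"], keep="first")
        report["n_duplicates_removed"] = before - len(records)
    else:
        report["n_duplicates_removed"] = 0

    n_unclassifiable = int((records["variant_class"] == "unclassifiable").sum())
    report["n_unclassifiable"] = n_unclassifiable
    if n_unclassifiable:
        logger.warning(
            "ingest: dropped %d variants with no MAF and no pathogenicity assertion",
            n_unclassifiable,
        )
    records = records.loc[records["variant_class"] != "unclassifiable"].reset_index(
        drop=True
    )
    tallies = records["variant_class"].value_counts()
    report["n_classified"] = int(len(records))
    for cls in CLASS_ORDER:
        report[f"n_{cls}"] = int(tallies.get(cls, 0))
    return records, report


def aggregate_counts(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene class tallies and the number of genes touched per class.

    Returns a frame with one row per gene holding >= 1 classified variant
    (columns ``gene, n_total, n_rare, n_common, n_disease``) and a dict
    mapping each class to the count of genes containing it.
    """
    if len(records) == 0:
        empty = pd.DataFrame(
            columns=["gene", "n_total", "n_rare", "n_common", "n_disease"]
        )
        return empty, {c: 0 for c in CLASS_ORDER}
    pivot = (
        records.groupby(["gene", "variant_class"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    for cls in CLASS_ORDER:
        if cls not in pivot.columns:
            pivot[cls] = 0
    counts = pd.DataFrame(
        {
            "gene": pivot.index,
            "n_total": pivot[list(CLASS_ORDER)].sum(axis=1).to_numpy(),
            "n_rare": pivot["rare"].to_numpy(),
            "n_common": pivot["common"].to_numpy(),
            "n_disease": pivot["disease"].to_numpy(),
        }
    ).reset_index(drop=True)
    genes_per_class = {
        cls: int((counts[f"n_{cls}"] > 0).sum()) for cls in CLASS_ORDER
    }
    logger.info(
        "ingest: %d genes with variants (rare in %d, common in %d, disease in %d)",
        len(counts),
        genes_per_class["rare"],
        genes_per_class["common"],
        genes_per_class["disease"],
    )
    return counts, genes_per_class
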