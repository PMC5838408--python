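"""Per-gene hypergeometric enrichment with FDR control.

For each gene and variant class, tests whether the gene's variants
contain more of that class than expected when drawing the gene's ``n``
variants without replacement from a universe of ``N`` variants of which
``K`` belong to the class. The upper-tail p-value P(X >= k) is computed
on the survival-function form for numerical stability, adjusted per
class with the Benjamini-Hochberg step-up procedure, and genes with
adjusted p <= alpha form the class's enriched-variant gene set (EVset).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CLASS_ORDER = ("rare", "common", "disease")
DEFAULT_ALPHA = 0.05


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Parameters follow the enrichment convention: ``k`` observed
    class-c variants in the gene, ``n`` variants in the gene, ``K``
    class-c variants in the universe, ``N`` variants in the universe.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"invalid hypergeometric parameters k={k}, n={n}, K={K}, N={N}: "
            "need 0 <= k <= min(n, K), n <= N, K <= N"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X > k-1) = P(X >= k); never underflows to exactly 0 for
    # feasible k since the point mass at min(n, K) is positive
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_genes(
    counts: pd.DataFrame, variant_class: str, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Hypergeometric enrichment of one class across all genes.

    ``counts`` is the per-gene tally frame from
    :func:`evsets.ingest.aggregate_counts`. Every gene with at least one
    classified variant is tested (so the BH family size is the same for
    each class). Returns a frame with columns ``gene, variant_class, k,
    n, K, N, p_raw, p_adj, enriched`` sorted by ``p_raw``.
    """
    if variant_class not in CLASS_ORDER:
        raise ValueError(f"unknown variant class {variant_class!r}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if len(counts) == 0:
        raise ValueError("counts is empty")

    n = counts["n_total"].to_numpy(dtype=np.int64)
    k = counts[f"n_{variant_class}"].to_numpy(dtype=np.int64)
    N = int(n.sum())
    K = int(k.sum())
    if K == 0:
        logger.warning("enrich: no %s variants in the universe; empty result", variant_class)
        return pd.DataFrame(
            columns=["gene", "variant_class", "k", "n", "K", "N", "p_raw", "p_adj", "enriched"]
        )

    p_raw = np.where(k == 0, 1.0, hypergeom.sf(k - 1, N, K, n))
    p_raw = np.minimum(p_raw, 1.0)
    p_adj = bh_adjust(p_raw)
    result = pd.DataFrame(
        {
            "gene": counts["gene"].to_numpy(),
            "variant_class": variant_class,
            "k": k,
            "n": n,
            "K": K,
            "N": N,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "enriched": p_adj <= alpha,
        }
    )
    result = result.sort_values(["p_raw", "gene"], kind="stable").reset_index(drop=True)
    logger.info(
        "enrich: %s class, K=%d of N=%d variants, %d of %d genes enriched at alpha=%g",
        variant_class,
        K,
        N,
        int(result["enriched"].sum()),
        len(result),
        alpha,
    )
    return result


@dataclass
class EVSets:
    """The three enriched-variant gene sets at a common FDR level.

    Overlaps between sets are reported, never silently resolved: the
    observed disjointness of the three sets in real data is an empirical
    finding, not an enforced rule.
    """

    disease: frozenset[str]
    rare: frozenset[str]
    common: frozenset[str]
    alpha: float
    overlap: dict[str, list[str]]

    def for_class(self, variant_class: str) -> frozenset[str]:
        return getattr(self, variant_class)

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(self.for_class(c)) for c in CLASS_ORDER}

    def union(self) -> frozenset[str]:
        return self.disease | self.rare | self.common

    def to_dict(self) -> dict:
        return {
            "disease_evset": sorted(self.disease),
            "rare_evset": sorted(self.rare),
            "common_evset": sorted(self.common),
            "alpha": self.alpha,
            "overlap": {k: list(v) for k, v in sorted(self.overlap.items())},
        }


def build_evsets(results: Mapping[str, pd.DataFrame], alpha: float = DEFAULT_ALPHA) -> EVSets:
    """Assemble EVsets from per-class enrichment results.

    ``results`` maps class name to the frame from :func:`enrich_genes`
    (classes absent from the universe may map to empty frames). Pairwise
    intersections are recorded in ``overlap``.
    """
    sets: dict[str, frozenset[str]] = {}
    for cls in CLASS_ORDER:
        frame = results.get(cls)
        if frame is None or len(frame) == 0:
            sets[cls] = frozenset()
        else:
            sets[cls] = frozenset(frame.loc[frame["enriched"], "gene"])
    overlap = {}
    pairs = [("rare", "common"), ("rare", "disease"), ("common", "disease")]
    for a, b in pairs:
        shared = sorted(sets[a] & sets[b])
        overlap[f"{a}|{b}"] = shared
        if shared:
            logger.warning("evsets: %d genes enriched in both %s and %s", len(shared), a, b)
    ev = EVSets(
        disease=sets["disease"],
        rare=sets["rare"],
        common=sets["common"],
        alpha=alpha,
        overlap=overlap,
    )
    logger.info(
        "evsets: sizes disease=%d rare=%d common=%d at alpha=%g",
        len(ev.disease),
        len(ev.rare),
        len(ev.common),
        alpha,
    )
    return ev


def write_enrichment(
    results: Mapping[str, pd.DataFrame], evsets: EVSets, out_dir: str | Path
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = [results[c] for c in CLASS_ORDER if c in results and len(results[c])]
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    paths = {"enrichment": out / "enrichment.tsv", "evsets": out / "evsets.json"}
    table.to_csv(paths["enrichment"], sep="\t", index=False)
    paths["evsets"].write_text(json.dumps(evsets.to_dict(), indent=2, sort_keys=True))
    return paths
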