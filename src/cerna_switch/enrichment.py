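"""Over-representation analysis of gene lists against gene-set collections.

Plain one-sided Fisher / hypergeometric ORA with Benjamini-Hochberg FDR:
no ontology-graph decorrelation, no depletion testing. The background
universe defaults to all genes tested for differential expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = ["EnrichmentResult", "enrich"]

DEFAULT_MAX_FDR = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap_count: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    fdr: float
    overlap_genes: tuple[str, ...]


def enrich(
    query_genes: Iterable[str],
    gene_sets: GeneSetCollection,
    universe: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of the query in each set.

    Query genes outside the universe are dropped with a warning; sets with
    no member in the universe are skipped. Results are BH-corrected across
    all tested sets and sorted by p-value.
    """
    if universe is None:
        universe = gene_sets.universe
    if not universe:
        raise ValueError("a non-empty background universe is required")
    uni = set(universe)
    query = set(query_genes)
    outside = query - uni
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped"
        )
        query &= uni
    if not query:
        raise ValueError("query is empty after intersecting with the universe")

    N, n = len(uni), len(query)
    rows = []
    for name, members in gene_sets.sets.items():
        in_universe = set(members) & uni
        if not in_universe:
            continue
        K = len(in_universe)
        overlap = sorted(query & in_universe)
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, overlap, min(p, 1.0)))
    if not rows:
        return []
    fdrs = multipletests([r[4] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(name, k, K, n, N, p, max(float(q), p), tuple(overlap))
        for (name, k, K, overlap, p), q in zip(rows, fdrs)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.set_name))


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "overlap_count": r.overlap_count,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "universe_size": r.universe_size,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "overlap_genes": ",".join(r.overlap_genes),
            }
            for r in results
        ]
    )
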