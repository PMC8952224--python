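"""Hub scoring on the protein-protein interaction graph and key-axis
selection.

Maximal clique centrality (MCC) of a node v is the sum of (|C| - 1)! over
the maximal cliques C containing v, computed by exact Bron-Kerbosch
enumeration (networkx ``find_cliques``). Following the convention of the
originating hub scorer, a node whose neighborhood contains no edge scores
its degree (for such nodes every maximal clique through them is an edge, so
the sum already equals the degree), and an isolated node scores 0.

Key axes are ceRNA triples whose mRNA is a hub protein and whose
lncRNA-mRNA expression correlation, Pearson on log2(FPKM + 1) across all
samples of both conditions pooled, exceeds a threshold (default 0.5).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cerna_network import CeRNANetwork
from .io_formats import ExpressionMatrix, PPITable

__all__ = [
    "HubScore",
    "KeyAxis",
    "filter_ppi",
    "mcc_scores",
    "top_hubs",
    "intersect_with_cerna",
    "rank_axes",
]

DEFAULT_MIN_SCORE = 0.4
DEFAULT_TOP_K = 10
DEFAULT_R_THRESHOLD = 0.5
MAX_EXACT_NODES = 5000


@dataclass(frozen=True)
class HubScore:
    node_id: str
    mcc: int
    rank: int  # dense rank, 1 = highest MCC


@dataclass(frozen=True)
class KeyAxis:
    lncRNA_id: str
    miRNA_id: str
    mRNA_id: str
    mcc_of_mRNA: int
    pearson_r: float


def filter_ppi(ppi: PPITable, min_score: float = DEFAULT_MIN_SCORE) -> nx.Graph:
    """Undirected simple graph of edges with combined score >= min_score."""
    g = nx.Graph()
    kept = ppi.edges[ppi.edges["combined_score"] >= min_score]
    g.add_edges_from(zip(kept["protein_a"], kept["protein_b"]))
    return g


def mcc_scores(graph: nx.Graph, max_nodes: int = MAX_EXACT_NODES) -> list[HubScore]:
    """Exact MCC for every node, dense-ranked descending."""
    if graph.number_of_nodes() > max_nodes:
        raise ValueError(
            f"graph has {graph.number_of_nodes()} nodes; exact maximal-clique "
            f"enumeration is bounded at {max_nodes} (raise max_nodes to force)"
        )
    scores: dict[str, int] = {n: 0 for n in graph.nodes}
    for clique in nx.find_cliques(graph):
        if len(clique) == 1:  # isolated node: score stays 0
            continue
        w = math.factorial(len(clique) - 1)
        for n in clique:
            scores[n] += w
    # convention: edge-free neighborhoods score the degree (already equal
    # here because every maximal clique through such nodes is a 2-clique);
    # isolated nodes score 0.
    distinct = sorted(set(scores.values()), reverse=True)
    rank_of = {v: i + 1 for i, v in enumerate(distinct)}
    return sorted(
        (HubScore(n, s, rank_of[s]) for n, s in scores.items()),
        key=lambda h: (-h.mcc, h.node_id),
    )


def top_hubs(scores: list[HubScore], k: int = DEFAULT_TOP_K) -> set[str]:
    """Nodes with the k highest MCC values; ties at the cut included."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if not scores:
        return set()
    ordered = sorted(scores, key=lambda h: -h.mcc)
    if k >= len(ordered):
        return {h.node_id for h in ordered}
    cutoff = ordered[k - 1].mcc
    return {h.node_id for h in ordered if h.mcc >= cutoff}


def intersect_with_cerna(
    network: CeRNANetwork, hub_genes: set[str]
) -> CeRNANetwork:
    """Restrict the ceRNA network to triples whose mRNA is a hub gene."""
    sub = network.subset_by_mrna(hub_genes)
    if not sub.triples:
        warnings.warn("ceRNA network and hub genes have an empty intersection")
    return sub


def rank_axes(
    network: CeRNANetwork,
    fpkm: ExpressionMatrix,
    mcc: dict[str, int],
    r_threshold: float = DEFAULT_R_THRESHOLD,
    log_transform: bool = True,
) -> list[KeyAxis]:
    """Correlation-filtered axes sorted by (mRNA MCC, r) descending.

    Pearson r is computed between the lncRNA and the mRNA across all
    samples (conditions pooled) on log2(FPKM + 1) by default. Axes with an
    undefined correlation (zero variance) are dropped with a warning; axes
    are retained when r exceeds ``r_threshold``.
    """
    if len(fpkm.samples) < 3:
        raise ValueError("rank_axes needs at least three samples")
    values = fpkm.values
    if log_transform:
        values = np.log2(values + 1.0)
    axes: list[KeyAxis] = []
    for t in network.triples:
        for gene in (t.lncRNA_id, t.mRNA_id):
            if gene not in values.index:
                raise ValueError(f"axis member {gene!r} missing from FPKM")
        x = values.loc[t.lncRNA_id].to_numpy()
        y = values.loc[t.mRNA_id].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(
                f"zero-variance expression for axis {t.lncRNA_id}/{t.mRNA_id}; dropped"
            )
            continue
        r = float(stats.pearsonr(x, y)[0])
        if r > r_threshold:
            axes.append(
                KeyAxis(t.lncRNA_id, t.miRNA_id, t.mRNA_id, mcc.get(t.mRNA_id, 0), r)
            )
    return sorted(axes, key=lambda a: (-a.mcc_of_mRNA, -a.pearson_r, a.lncRNA_id))
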