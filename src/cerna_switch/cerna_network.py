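"""Competing-endogenous-RNA network construction.

A ceRNA triple (lncRNA, miRNA, mRNA) is admitted when all three transcripts
pass their ceRNA-tier differential-expression flags, both interaction edges
(miRNA-lncRNA and miRNA-mRNA) are supported by the interaction tables under
the source rule, and the directions satisfy the sponge-opposition pattern:
the miRNA moves opposite to the lncRNA and the mRNA, which move together
(lncRNA up / miRNA down / mRNA up, or the mirrored pattern).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import InteractionTable

__all__ = ["CeRNATriple", "CeRNANetwork", "build_cerna", "network_summary"]


@dataclass(frozen=True)
class CeRNATriple:
    lncRNA_id: str
    miRNA_id: str
    mRNA_id: str
    lnc_direction: str
    mir_direction: str
    m_direction: str
    lnc_mir_sources: frozenset[str]
    mir_m_sources: frozenset[str]
    pearson_r: float | None = None


@dataclass
class CeRNANetwork:
    """Triples plus the derived node/edge view used for reporting.

    Edges are deduplicated: the reported interaction count is the number of
    distinct (miRNA, partner) pairs, matching how an edge list drawn in a
    graph viewer would be counted.
    """

    triples: list[CeRNATriple]

    @property
    def node_class(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for t in self.triples:
            out[t.lncRNA_id] = "lncRNA"
            out[t.miRNA_id] = "miRNA"
            out[t.mRNA_id] = "mRNA"
        return out

    @property
    def node_direction(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for t in self.triples:
            out[t.lncRNA_id] = t.lnc_direction
            out[t.miRNA_id] = t.mir_direction
            out[t.mRNA_id] = t.m_direction
        return out

    def nodes(self, rna_class: str | None = None) -> set[str]:
        nc = self.node_class
        if rna_class is None:
            return set(nc)
        return {n for n, c in nc.items() if c == rna_class}

    def edge_list(self) -> list[tuple[str, str, str]]:
        """Distinct edges as (source, interaction, target), sorted."""
        edges = set()
        for t in self.triples:
            edges.add((t.lncRNA_id, "lncRNA-miRNA", t.miRNA_id))
            edges.add((t.miRNA_id, "miRNA-mRNA", t.mRNA_id))
        return sorted(edges)

    @property
    def interaction_count(self) -> int:
        return len(self.edge_list())

    def subset_by_mrna(self, mrna_ids: Iterable[str]) -> "CeRNANetwork":
        keep = set(mrna_ids)
        return CeRNANetwork([t for t in self.triples if t.mRNA_id in keep])


def build_cerna(
    classified: pd.DataFrame,
    mi_mrna: InteractionTable,
    mi_lnc: InteractionTable,
    source_rule: str = "any",
    lnc_whitelist: set[str] | None = None,
) -> CeRNANetwork:
    """Assemble the ceRNA network from tier-flagged DE results.

    ``classified`` is the output of :func:`cerna_switch.diffexpr.classify`.
    ``source_rule="any"`` admits an interaction edge present in at least one
    source database table; ``"all"`` requires every declared source.
    ``lnc_whitelist`` optionally restricts lncRNA membership (e.g. to
    discovery survivors plus known lncRNAs).
    """
    if source_rule not in ("any", "all"):
        raise ValueError(f"unknown source_rule {source_rule!r}")
    if classified.empty:
        raise ValueError("empty differential-expression input")

    lnc = classified[classified["cerna_lnc"]]
    if lnc_whitelist is not None:
        lnc = lnc[lnc.index.isin(lnc_whitelist)]
    small = classified[classified["cerna_small"]]
    mir = small[small["gene_class"] == "miRNA"]
    mrna = small[small["gene_class"] == "mRNA"]

    def admitted(table: InteractionTable) -> dict[tuple[str, str], frozenset[str]]:
        grouped: dict[tuple[str, str], set[str]] = {}
        for m, t, s in table.edges[["miRNA", "target", "source"]].itertuples(
            index=False
        ):
            grouped.setdefault((m, t), set()).add(s)
        if source_rule == "any":
            return {k: frozenset(v) for k, v in grouped.items()}
        n_required = len(set(table.edges["source"]))
        return {
            k: frozenset(v) for k, v in grouped.items() if len(v) >= n_required
        }

    lnc_edges = admitted(mi_lnc)
    m_edges = admitted(mi_mrna)
    de_ids = set(classified.index)
    orphan = {
        t for (_, t) in list(lnc_edges) + list(m_edges) if t not in de_ids
    }
    if orphan:
        warnings.warn(
            f"{len(orphan)} interaction targets absent from DE results"
        )

    directions = classified["direction"]
    triples: list[CeRNATriple] = []
    by_mir_lnc: dict[str, list[str]] = {}
    for (m, t) in lnc_edges:
        if t in lnc.index:
            by_mir_lnc.setdefault(m, []).append(t)
    by_mir_mrna: dict[str, list[str]] = {}
    for (m, t) in m_edges:
        if t in mrna.index:
            by_mir_mrna.setdefault(m, []).append(t)
    for mu in sorted(mir.index):
        d_mu = directions[mu]
        if d_mu not in ("up", "down"):
            continue
        opposite = "down" if d_mu == "up" else "up"
        for L in sorted(by_mir_lnc.get(mu, [])):
            if directions[L] != opposite:
                continue
            for M in sorted(by_mir_mrna.get(mu, [])):
                if directions[M] != opposite:
                    continue
                triples.append(
                    CeRNATriple(
                        L,
                        mu,
                        M,
                        directions[L],
                        d_mu,
                        directions[M],
                        lnc_edges[(mu, L)],
                        m_edges[(mu, M)],
                    )
                )
    return CeRNANetwork(triples)


def network_summary(network: CeRNANetwork) -> dict:
    """Node and interaction counts, split by miRNA direction component."""
    def count(triples: Sequence[CeRNATriple]) -> dict:
        sub = CeRNANetwork(list(triples))
        return {
            "n_miRNA": len(sub.nodes("miRNA")),
            "n_lncRNA": len(sub.nodes("lncRNA")),
            "n_mRNA": len(sub.nodes("mRNA")),
            "n_interactions": sub.interaction_count,
            "n_triples": len(sub.triples),
        }

    down = [t for t in network.triples if t.mir_direction == "down"]
    up = [t for t in network.triples if t.mir_direction == "up"]
    return {
        "total": count(network.triples),
        "miRNA_down": count(down),
        "miRNA_up": count(up),
    }
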