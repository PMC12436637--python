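"""Protein-interaction network construction and connectivity ranking.

Interaction records (PSI-MITAB) become an undirected simple graph over
uppercase gene symbols: reciprocal duplicates collapse to one edge with
merged source-database lists, self-interactions are dropped, and an
optional taxon filter keeps human-human pairs only. Connectivity of a hit
set is summarised by degree ranking within the induced subnetwork ("most
densely connected" = highest degree; ties broken by symbol).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from cargoscreen.io import MitabRecord

logger = logging.getLogger("cargoscreen")


def build_network(
    records: Iterable[MitabRecord], taxon_filter: int | None = 9606
) -> nx.Graph:
    """Undirected simple graph from interaction records.

    Edges are canonicalized (sorted symbol pair) and deduplicated with
    merged source lists; self-pairs are dropped; when ``taxon_filter`` is
    set, records whose stated taxa do not both match are dropped (records
    without taxon annotation are kept)."""
    g = nx.Graph()
    dropped_taxon = dropped_self = 0
    for r in records:
        if taxon_filter is not None:
            taxa = [t for t in (r.taxon_a, r.taxon_b) if t is not None]
            if any(t != taxon_filter for t in taxa):
                dropped_taxon += 1
                continue
        a, b = sorted((r.symbol_a.upper(), r.symbol_b.upper()))
        if a == b:
            dropped_self += 1
            continue
        if g.has_edge(a, b):
            g[a][b]["sources"] = sorted(
                set(g[a][b]["sources"]) | {r.source_db})
        else:
            g.add_edge(a, b, sources=[r.source_db])
    if dropped_taxon or dropped_self:
        logger.info("network build: dropped %d non-matching-taxon and %d "
                    "self-interaction record(s)", dropped_taxon, dropped_self)
    return g


def edges(network: nx.Graph) -> list[MitabRecord]:
    """Network back to records (one per edge, first source kept per edge
    list); build_network(edges(network)) is a fixpoint."""
    out = []
    for a, b, data in network.edges(data=True):
        for src in data.get("sources", ["unknown"]):
            out.append(MitabRecord(a, b, None, None, src))
    return out


def induced_subnetwork(network: nx.Graph, gene_set: Iterable[str]) -> nx.Graph:
    """Subgraph on gene_set: members present in the network are retained
    even when isolated (degree 0); edges need both ends in the set."""
    members = {g.upper() for g in gene_set}
    present = members & set(network.nodes)
    sub = nx.Graph(network.subgraph(present))
    return sub


def connectivity_report(network: nx.Graph, top_n: int = 10) -> pd.DataFrame:
    """Degree-ranked table of the most connected nodes.

    For each of the top nodes, lists its neighbors that are themselves in
    the top ranks (supporting statements like "interacts directly with two
    of the five most connected proteins")."""
    ranked = sorted(network.degree, key=lambda kv: (-kv[1], kv[0]))
    top = ranked[:top_n]
    top_names = [name for name, _ in top]
    rows = []
    for rank, (name, deg) in enumerate(top, start=1):
        nbrs = set(network.neighbors(name))
        rows.append({
            "rank": rank,
            "gene": name,
            "degree": deg,
            "neighbors_in_top": ",".join(
                n for n in top_names if n in nbrs),
            "neighbors": ",".join(sorted(nbrs)),
        })
    return pd.DataFrame(rows)


def connected_components(network: nx.Graph) -> list[set[str]]:
    """Components, largest first (ties by smallest member symbol)."""
    comps = [set(c) for c in nx.connected_components(network)]
    return sorted(comps, key=lambda c: (-len(c), min(c) if c else ""))
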