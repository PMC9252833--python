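"""Chain-level interaction graph: the data behind the circular ribbon diagram.

Nodes are chains (with polymer type and length); an undirected edge between
two chains is weighted by the number of intermolecular residue-residue
contacts at the chosen cutoff.  Zero-weight pairs are omitted.
"""

from __future__ import annotations

import json
from typing import Sequence

import networkx as nx

from .contacts import contact_list, contact_map, distance_matrix
from .structure import Chain

__all__ = ["chain_contact_graph", "graph_neighbors", "graph_to_json", "graph_to_tsv"]


def chain_contact_graph(chains: Sequence[Chain], cutoff: float) -> nx.Graph:
    """Build the chain interaction graph for one model.

    Each unordered chain pair is evaluated once; the edge weight is the
    number of residue pairs whose minimal heavy-atom distance is below the
    cutoff.  A single-chain model yields a graph with one node and no edges.
    """
    g = nx.Graph(cutoff=cutoff)
    for ch in chains:
        g.add_node(ch.id, polymer_type=ch.polymer_type.value, length=len(ch))
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            dm = distance_matrix(chains[i], chains[j])
            cm = contact_map(dm, cutoff)
            w = int(cm.mask.sum())
            if w > 0:
                g.add_edge(chains[i].id, chains[j].id, weight=w)
    return g


def graph_neighbors(g: nx.Graph, chain_id: str) -> list[tuple[str, int]]:
    """Neighbours of a chain sorted by descending weight, ties by chain id."""
    if chain_id not in g:
        raise KeyError(f"chain {chain_id!r} not in graph; nodes: {sorted(g.nodes)}")
    nbrs = [(n, g[chain_id][n]["weight"]) for n in g.neighbors(chain_id)]
    return sorted(nbrs, key=lambda t: (-t[1], t[0]))


def graph_to_json(g: nx.Graph) -> str:
    payload = {
        "cutoff": g.graph.get("cutoff"),
        "nodes": [
            {"id": n, "type": d.get("polymer_type"), "length": d.get("length")}
            for n, d in sorted(g.nodes(data=True))
        ],
        "edges": [
            {"a": a, "b": b, "weight": d["weight"]}
            for a, b, d in _sorted_edges(g)
        ],
    }
    return json.dumps(payload, indent=2)


def _sorted_edges(g: nx.Graph):
    edges = [(*sorted((a, b)), d) for a, b, d in g.edges(data=True)]
    return sorted(edges, key=lambda e: (e[0], e[1]))


def graph_to_tsv(g: nx.Graph) -> str:
    rows = ["chain_a\tchain_b\tn_contacts"]
    for a, b, d in _sorted_edges(g):
        rows.append(f"{a}\t{b}\t{d['weight']}")
    return "\n".join(rows) + "\n"
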