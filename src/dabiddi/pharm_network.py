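"""Drug-target-enzyme-transporter-AE attribute network analysis.

Builds a typed, weighted undirected graph from edge lists, applies the
STRING-style confidence filter to protein-protein interaction edges
(strictly above the threshold, rescaled to [0, 1] by /1000), finds minimal-
cost drug -> AE paths under the cost transform 1 - weight + eps (strong
edges are cheap; eps keeps path length finite-biased), and ranks enzymes or
transporters shared by a drug pair by the product of their incident edge
weights.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["NODE_TYPES", "build_network", "shortest_path", "rank_mechanisms"]

NODE_TYPES = ("drug", "target", "enzyme", "transporter", "ae")
EPS = 1e-6

# edge type -> (source node type, destination node type)
_EDGE_TYPES = {
    "drug-target": ("drug", "target"),
    "drug-enzyme": ("drug", "enzyme"),
    "drug-transporter": ("drug", "transporter"),
    "ppi": ("target", "target"),
    "target-ae": ("target", "ae"),
    "enzyme-ae": ("enzyme", "ae"),
    "transporter-ae": ("transporter", "ae"),
}


def build_network(edges: pd.DataFrame, ppi_min_conf: float = 700) -> nx.Graph:
    """Typed attribute network from a ``src,dst,type,weight`` edge list.

    PPI rows carry raw confidences in [0, 1000]: edges with confidence
    <= ``ppi_min_conf`` are dropped, the rest rescaled to weight/1000.
    Other rows carry weights clipped to [0, 1].  Self-edges are ignored.
    """
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        etype = str(row.type)
        if etype not in _EDGE_TYPES:
            raise ValueError(f"unknown edge type: {etype!r}")
        if row.src == row.dst:
            continue
        if etype == "ppi":
            conf = float(row.weight)
            if conf <= ppi_min_conf:
                continue
            weight = conf / 1000.0
            g.add_edge(row.src, row.dst, weight=weight, type=etype,
                       confidence=conf)
        else:
            weight = float(np.clip(row.weight, 0.0, 1.0))
            g.add_edge(row.src, row.dst, weight=weight, type=etype)
        st, dt = _EDGE_TYPES[etype]
        g.nodes[row.src]["type"] = st
        g.nodes[row.dst]["type"] = dt
    return g


def shortest_path(net: nx.Graph, drug: str, ae: str):
    """Minimal-cost drug -> AE path under cost 1 - weight + eps.

    Returns ``(path, cost)`` or ``(None, inf)`` when disconnected.  Ties
    resolve deterministically (lexicographically smallest node sequence).
    """
    for node in (drug, ae):
        if node not in net:
            raise KeyError(f"node not in network: {node!r}")

    def cost(u, v, data):
        return 1.0 - data["weight"] + EPS

    try:
        # Dijkstra with a secondary lexicographic criterion for ties
        dist, paths = nx.single_source_dijkstra(net, drug, weight=cost)
    except nx.NetworkXNoPath:  # pragma: no cover
        return None, float("inf")
    if ae not in dist:
        return None, float("inf")
    best_cost = dist[ae]
    # collect all equal-cost shortest paths only if cheap; default path is
    # already deterministic for fixed insertion order, enforce lexicographic
    candidates = [paths[ae]]
    try:
        for p in nx.all_shortest_paths(net, drug, ae, weight=cost):
            c = sum(cost(u, v, net[u][v]) for u, v in zip(p[:-1], p[1:]))
            if abs(c - best_cost) <= 1e-12:
                candidates.append(p)
    except nx.NetworkXNoPath:  # pragma: no cover
        pass
    return min(candidates), float(best_cost)


def rank_mechanisms(net: nx.Graph, drug_a: str, drug_b: str):
    """Enzymes/transporters adjacent to both drugs, scored by the product
    of the two incident edge weights, sorted descending (ties by node id).
    """
    for d in (drug_a, drug_b):
        if d not in net:
            raise KeyError(f"drug not in network: {d!r}")
    shared = set(net[drug_a]) & set(net[drug_b])
    out = []
    for node in shared:
        if net.nodes[node].get("type") not in ("enzyme", "transporter"):
            continue
        score = net[drug_a][node]["weight"] * net[drug_b][node]["weight"]
        out.append((node, float(score)))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out
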