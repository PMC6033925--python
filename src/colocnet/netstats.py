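"""Network descriptors used to track structure across inference iterations.

Density, per-node degree and (unnormalized) betweenness centrality, tables of
key genes, percentage changes of node descriptors between two networks, and
the fraction of one network's edges conserved in another.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd


def density(network: nx.Graph) -> float:
    """Edge density as a percentage, 100·E / (p(p−1)/2), to two decimals."""
    p = network.number_of_nodes()
    if p < 2:
        raise ValueError(f"density needs at least 2 nodes, got {p}")
    e = network.number_of_edges()
    return round(100.0 * e / (p * (p - 1) / 2.0), 2)


def node_stats(network: nx.Graph) -> pd.DataFrame:
    """Degree and raw betweenness for every node.

    Betweenness is the unnormalized count of shortest paths between node
    pairs passing through the node (endpoints excluded, ties split
    fractionally); on disconnected graphs only existing paths count.
    """
    betweenness = nx.betweenness_centrality(network, normalized=False)
    rows = [
        (node, network.degree(node), betweenness[node])
        for node in sorted(network.nodes)
    ]
    return pd.DataFrame(rows, columns=["gene", "degree", "betweenness"]).set_index(
        "gene"
    )


def _check_same_nodes(a: nx.Graph, b: nx.Graph) -> None:
    only_a = sorted(set(a.nodes) - set(b.nodes))
    only_b = sorted(set(b.nodes) - set(a.nodes))
    if only_a or only_b:
        raise ValueError(
            f"node sets differ: only in first={only_a}, only in second={only_b}"
        )


def key_gene_deltas(a: nx.Graph, b: nx.Graph) -> pd.DataFrame:
    """Per-gene percentage change of degree and betweenness from a to b.

    Changes are 100·(new−old)/old; genes with a zero baseline get NaN and a
    False flag in the corresponding ``*_defined`` column rather than an
    infinite percentage.
    """
    _check_same_nodes(a, b)
    sa, sb = node_stats(a), node_stats(b)
    out = pd.DataFrame(index=sa.index)
    for col in ("degree", "betweenness"):
        old = sa[col].astype(float)
        new = sb[col].astype(float)
        defined = old > 0
        pct = pd.Series(np.nan, index=out.index)
        pct[defined] = 100.0 * (new[defined] - old[defined]) / old[defined]
        out[f"{col}_change_pct"] = pct
        out[f"{col}_change_defined"] = defined
    return out


def edge_overlap(a: nx.Graph, b: nx.Graph) -> float:
    """Percentage of a's edges also present in b (node sets must match)."""
    _check_same_nodes(a, b)
    ea = {frozenset(e) for e in a.edges}
    if not ea:
        raise ValueError("first network has no edges; overlap undefined")
    eb = {frozenset(e) for e in b.edges}
    return 100.0 * len(ea & eb) / len(ea)


def top_genes(network: nx.Graph, q: int = 25, by: str = "betweenness") -> pd.DataFrame:
    """Top-q genes by a descriptor ('degree' or 'betweenness')."""
    stats = node_stats(network)
    if by not in stats.columns:
        raise ValueError(f"unknown descriptor {by!r}; use 'degree' or 'betweenness'")
    return (
        stats.reset_index()
        .sort_values([by, "gene"], ascending=[False, True])
        .set_index("gene")
        .head(q)
    )
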