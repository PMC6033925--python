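"""Community structure: Louvain clustering, permutation significance, NMI.

Each inferred network is partitioned by Louvain modularity optimization.
Significance of the partition is assessed against degree-preserving random
graphs (double-edge-swap rewiring), and partitions of successive networks are
compared by contingency tables and normalized mutual information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score

_NMI_AVERAGING = {"arithmetic": "arithmetic", "max": "max", "sqrt": "geometric"}


@dataclass(frozen=True)
class Clustering:
    """A gene → cluster assignment (ids contiguous from 1) and its modularity."""

    assignment: Mapping[str, int]
    modularity: float

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.assignment)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[int, set]:
        out: dict[int, set] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return out


@dataclass(frozen=True)
class SignificanceResult:
    """Observed modularity against a degree-preserving null ensemble."""

    observed_modularity: float
    null_modularities: tuple[float, ...]
    p_value: float


@dataclass(frozen=True)
class ClusteringComparison:
    """Contingency table, best-match share percentages and NMI of two partitions."""

    nmi: float
    contingency: pd.DataFrame
    share_pct: Mapping[int, float]


def modularity(network: nx.Graph, assignment: Mapping[str, int]) -> float:
    """Newman–Girvan modularity Q = Σ_c (e_c/m − (d_c/2m)²).

    m is the total edge count, e_c the intra-cluster edge count and d_c the
    summed degree of cluster c.  Every node must be assigned.
    """
    uncovered = sorted(set(network.nodes) - set(assignment))
    if uncovered:
        raise ValueError(f"nodes without a cluster assignment: {uncovered}")
    m = network.number_of_edges()
    if m == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    e_c: dict[int, int] = {}
    d_c: dict[int, int] = {}
    for node in network.nodes:
        d_c[assignment[node]] = d_c.get(assignment[node], 0) + network.degree(node)
    for u, v in network.edges:
        if assignment[u] == assignment[v]:
            e_c[assignment[u]] = e_c.get(assignment[u], 0) + 1
    return float(
        sum(
            e_c.get(c, 0) / m - (d_c[c] / (2.0 * m)) ** 2
            for c in set(assignment.values())
        )
    )


def _canonical_ids(communities: Sequence[set]) -> dict[str, int]:
    # deterministic ids: clusters ordered by their lexicographically smallest node
    ordered = sorted(communities, key=lambda c: min(map(str, c)))
    return {node: cid for cid, comm in enumerate(ordered, start=1) for node in comm}


def louvain_cluster(
    network: nx.Graph, seed: int = 0, *, restarts: int = 1, weighted: bool = False
) -> Clustering:
    """Louvain partition of the network, deterministic for a fixed seed.

    ``restarts`` > 1 reruns Louvain with derived seeds and keeps the
    partition with the highest modularity.  Isolated nodes become singleton
    clusters.  By default the graph topology alone is used (edge weights are
    partial correlations, possibly negative, and are not modularity weights).
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    weight = "weight" if weighted else None
    if network.number_of_edges() == 0:
        assignment = _canonical_ids([{n} for n in network.nodes])
        return Clustering(assignment=assignment, modularity=0.0)
    best: Clustering | None = None
    for r in range(max(1, restarts)):
        comms = nx.community.louvain_communities(network, weight=weight, seed=seed + r)
        assignment = _canonical_ids(comms)
        q = modularity(network, assignment)
        if best is None or q > best.modularity:
            best = Clustering(assignment=assignment, modularity=q)
    return best


def degree_preserving_rewire(
    network: nx.Graph, rng: np.random.Generator, n_attempts: int | None = None
) -> tuple[nx.Graph, int]:
    """Randomize edges by double-edge swaps, preserving every node's degree.

    Each attempt picks two edges (u,v), (x,y) and proposes (u,y), (x,v);
    the swap is applied unless it would create a self-loop or multi-edge.
    ``n_attempts`` defaults to 10·E.  Returns the rewired copy and the number
    of successful swaps.
    """
    g = network.copy()
    edges = [tuple(e) for e in g.edges]
    n_edges = len(edges)
    if n_attempts is None:
        n_attempts = 10 * n_edges
    if n_edges < 2:
        return g, 0
    swaps = 0
    for _ in range(n_attempts):
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if rng.random() < 0.5:
            x, y = y, x
        # propose (u, y) and (x, v)
        if len({u, v, x, y}) < 4:
            continue
        if g.has_edge(u, y) or g.has_edge(x, v):
            continue
        g.remove_edge(u, v)
        g.remove_edge(x, y)
        g.add_edge(u, y)
        g.add_edge(x, v)
        edges[i] = (u, y)
        edges[j] = (x, v)
        swaps += 1
    return g, swaps


def clustering_significance(
    network: nx.Graph, b: int = 500, seed: int = 0, *, observed: Clustering | None = None
) -> SignificanceResult:
    """Permutation test of the Louvain modularity against rewired graphs.

    Generates ``b`` degree-preserving random graphs (double-edge swaps, 10·E
    attempts each), clusters each with Louvain, and returns the add-one
    permutation p-value (1 + #{Q_null ≥ Q_obs}) / (1 + b).  Every null
    graph's degree sequence equals the original's by construction.
    """
    if b <= 0:
        raise ValueError(f"number of null networks must be positive, got {b}")
    if network.number_of_edges() == 0:
        raise ValueError("significance test needs a network with at least one edge")
    if observed is None:
        observed = louvain_cluster(network, seed=seed)
    master = np.random.default_rng(seed)
    nulls = []
    total_swaps = 0
    for _ in range(b):
        rng = np.random.default_rng(master.integers(0, 2**31))
        null_graph, swaps = degree_preserving_rewire(network, rng)
        total_swaps += swaps
        null_seed = int(master.integers(0, 2**31))
        nulls.append(louvain_cluster(null_graph, seed=null_seed).modularity)
    if total_swaps == 0:
        warnings.warn(
            "no degree-preserving swap was possible; null graphs equal the "
            "observed network and the test has no power (p = 1)",
            stacklevel=2,
        )
    exceed = sum(q >= observed.modularity for q in nulls)
    p_value = (1.0 + exceed) / (1.0 + b)
    return SignificanceResult(
        observed_modularity=observed.modularity,
        null_modularities=tuple(nulls),
        p_value=p_value,
    )


def _aligned_labels(a: Clustering, b: Clustering) -> tuple[list[int], list[int]]:
    if a.nodes != b.nodes:
        only_a = sorted(a.nodes - b.nodes)
        only_b = sorted(b.nodes - a.nodes)
        raise ValueError(
            f"clusterings cover different nodes: only in first={only_a}, "
            f"only in second={only_b}"
        )
    nodes = sorted(a.nodes)
    return [a.assignment[n] for n in nodes], [b.assignment[n] for n in nodes]


def nmi(a: Clustering, b: Clustering, *, normalization: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    Mutual information of the joint label distribution normalized by the
    arithmetic mean of the two label entropies (options: 'max', 'sqrt').
    Symmetric, 1 for identical partitions, 0 for independent ones.
    """
    if normalization not in _NMI_AVERAGING:
        raise ValueError(
            f"unknown normalization {normalization!r}; "
            f"choose from {sorted(_NMI_AVERAGING)}"
        )
    la, lb = _aligned_labels(a, b)
    return float(
        normalized_mutual_info_score(
            la, lb, average_method=_NMI_AVERAGING[normalization]
        )
    )


def compare_clusterings(a: Clustering, b: Clustering) -> ClusteringComparison:
    """Contingency table, per-cluster best-match shares, and NMI.

    Each cluster of ``a`` is matched to the cluster of ``b`` containing most
    of its nodes; the share is the percentage of the cluster's nodes found
    there.
    """
    la, lb = _aligned_labels(a, b)
    ids_a = sorted(set(la))
    ids_b = sorted(set(lb))
    table = pd.DataFrame(0, index=ids_a, columns=ids_b)
    for ca, cb in zip(la, lb):
        table.loc[ca, cb] += 1
    share = {
        ca: float(100.0 * table.loc[ca].max() / table.loc[ca].sum()) for ca in ids_a
    }
    return ClusteringComparison(nmi=nmi(a, b), contingency=table, share_pct=share)
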