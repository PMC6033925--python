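import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from colocnet.clustering import (
    Clustering,
    clustering_significance,
    compare_clusterings,
    degree_preserving_rewire,
    louvain_cluster,
    modularity,
    nmi,
)

from conftest import two_block_graph


def two_triangles() -> nx.Graph:
    return nx.Graph(
        [("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y"), ("Y", "Z"), ("X", "Z")]
    )


def all_partitions(items):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in all_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield [[first]] + partition


def best_partition_by_enumeration(g: nx.Graph) -> float:
    best = -math.inf
    for partition in all_partitions(g.nodes):
        assignment = {n: i for i, block in enumerate(partition) for n in block}
        best = max(best, modularity(g, assignment))
    return best


class TestModularity:
    def test_single_cluster_has_zero_modularity(self):
        g = nx.gnm_random_graph(10, 20, seed=1)
        assert modularity(g, {n: 1 for n in g.nodes}) == pytest.approx(0.0)

    def test_two_triangles_split_scores_one_half(self):
        g = two_triangles()
        assignment = {"A": 1, "B": 1, "C": 1, "X": 2, "Y": 2, "Z": 2}
        assert modularity(g, assignment) == pytest.approx(0.5)

    def test_all_singletons_on_a_triangle_scores_minus_one_third(self):
        g = nx.complete_graph(3)
        assert modularity(g, {0: 0, 1: 1, 2: 2}) == pytest.approx(-1 / 3)

    def test_agrees_with_networkx_on_random_graphs(self):
        # independent route: networkx's own modularity implementation
        rng = np.random.default_rng(2)
        for seed in range(3):
            g = nx.gnm_random_graph(12, 24, seed=seed)
            labels = {n: int(rng.integers(0, 3)) for n in g.nodes}
            communities = [
                {n for n, c in labels.items() if c == k} for k in set(labels.values())
            ]
            assert modularity(g, labels) == pytest.approx(
                nx.community.modularity(g, communities)
            )

    def test_uncovered_node_is_an_error(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            modularity(g, {0: 1, 1: 1})

    @given(st.integers(0, 4))
    def test_modularity_is_bounded(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnm_random_graph(8, 12, seed=seed)
        labels = {n: int(rng.integers(0, 4)) for n in g.nodes}
        q = modularity(g, labels)
        assert -0.5 <= q <= 1.0


class TestLouvain:
    def test_recovers_two_disjoint_triangles(self):
        g = two_triangles()
        clustering = louvain_cluster(g, seed=0)
        assert set(frozenset(c) for c in clustering.clusters().values()) == {
            frozenset({"A", "B", "C"}),
            frozenset({"X", "Y", "Z"}),
        }
        # exhaustive-search oracle: no partition scores higher
        assert clustering.modularity == pytest.approx(
            best_partition_by_enumeration(g)
        )

    def test_complete_graph_stays_one_cluster(self):
        g = nx.complete_graph(5)
        clustering = louvain_cluster(g, seed=0)
        assert clustering.n_clusters == 1
        assert clustering.modularity == pytest.approx(
            best_partition_by_enumeration(g)
        )

    def test_isolated_node_becomes_singleton(self):
        g = nx.Graph([("A", "B")])
        g.add_node("C")
        clustering = louvain_cluster(g, seed=0)
        clusters = {frozenset(c) for c in clustering.clusters().values()}
        assert clusters == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_deterministic_given_seed(self):
        g = two_block_graph(seed=3)
        a = louvain_cluster(g, seed=5)
        b = louvain_cluster(g, seed=5)
        assert a.assignment == b.assignment

    def test_cluster_ids_are_contiguous_from_one(self):
        g = two_block_graph(seed=4)
        clustering = louvain_cluster(g, seed=1)
        ids = sorted(set(clustering.assignment.values()))
        assert ids == list(range(1, len(ids) + 1))

    def test_beats_singleton_partition(self):
        g = nx.gnm_random_graph(15, 30, seed=6)
        clustering = louvain_cluster(g, seed=2)
        singletons = {n: i for i, n in enumerate(g.nodes)}
        assert clustering.modularity >= modularity(g, singletons)

    def test_empty_graph_is_an_error(self):
        with pytest.raises(ValueError):
            louvain_cluster(nx.Graph(), seed=0)


class TestRewiring:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_degree_sequence_is_preserved_exactly(self, seed):
        g = two_block_graph(seed=seed)
        rng = np.random.default_rng(seed)
        rewired, swaps = degree_preserving_rewire(g, rng)
        assert sorted(d for _, d in rewired.degree) == sorted(
            d for _, d in g.degree
        )
        assert swaps > 0
        assert rewired.number_of_edges() == g.number_of_edges()

    def test_no_self_loops_or_multi_edges(self):
        g = nx.gnm_random_graph(20, 50, seed=9)
        rng = np.random.default_rng(0)
        rewired, _ = degree_preserving_rewire(g, rng)
        assert all(u != v for u, v in rewired.edges)
        assert rewired.number_of_edges() == len(set(map(frozenset, rewired.edges)))

    def test_star_admits_no_swap(self):
        g = nx.star_graph(5)
        rng = np.random.default_rng(0)
        rewired, swaps = degree_preserving_rewire(g, rng)
        assert swaps == 0
        assert set(map(frozenset, rewired.edges)) == set(map(frozenset, g.edges))


class TestSignificance:
    def test_add_one_p_value_formula(self):
        g = two_block_graph(seed=7)
        result = clustering_significance(g, b=49, seed=1)
        exceed = sum(
            q >= result.observed_modularity for q in result.null_modularities
        )
        assert result.p_value == pytest.approx((1 + exceed) / (1 + 49))
        assert len(result.null_modularities) == 49

    def test_strong_community_structure_reaches_the_minimal_p(self):
        g = two_block_graph(seed=7)
        result = clustering_significance(g, b=49, seed=1)
        assert result.p_value == pytest.approx(1 / 50)

    def test_observed_below_all_nulls_gives_p_one(self):
        g = two_block_graph(seed=7)
        weak = Clustering(assignment={n: 1 for n in g.nodes}, modularity=0.0)
        result = clustering_significance(g, b=19, seed=2, observed=weak)
        assert result.p_value == 1.0

    def test_star_graph_warns_and_returns_p_one(self):
        g = nx.star_graph(6)
        with pytest.warns(UserWarning, match="no power"):
            result = clustering_significance(g, b=19, seed=0)
        assert result.p_value == 1.0

    def test_invalid_b_is_rejected(self):
        with pytest.raises(ValueError):
            clustering_significance(two_block_graph(), b=0, seed=0)


def random_clustering(nodes, k, seed) -> Clustering:
    rng = np.random.default_rng(seed)
    assignment = {n: int(rng.integers(1, k + 1)) for n in nodes}
    return Clustering(assignment=assignment, modularity=0.0)


class TestNMI:
    def test_identical_nontrivial_clusterings_score_one(self):
        c = random_clustering(range(20), 3, seed=1)
        assert nmi(c, c) == pytest.approx(1.0)

    def test_one_cluster_vs_singletons_scores_zero(self):
        nodes = list(range(6))
        a = Clustering(assignment={n: 1 for n in nodes}, modularity=0.0)
        b = Clustering(assignment={n: n + 1 for n in nodes}, modularity=0.0)
        assert nmi(a, b) == 0.0

    def test_matches_entropy_formula_oracle_on_known_contingency(self):
        # contingency [[2, 1], [0, 3]] over 6 items, evaluated by hand:
        # I = sum p_ij log(p_ij / (p_i q_j)); NMI = 2 I / (H_a + H_b)
        nodes = list(range(6))
        a = Clustering(
            assignment={0: 1, 1: 1, 2: 1, 3: 2, 4: 2, 5: 2}, modularity=0.0
        )
        b = Clustering(
            assignment={0: 1, 1: 1, 2: 2, 3: 2, 4: 2, 5: 2}, modularity=0.0
        )
        p = np.array([[2, 1], [0, 3]]) / 6.0
        pa, pb = p.sum(axis=1), p.sum(axis=0)
        mi = sum(
            p[i, j] * math.log(p[i, j] / (pa[i] * pb[j]))
            for i in range(2)
            for j in range(2)
            if p[i, j] > 0
        )
        h_a = -sum(x * math.log(x) for x in pa)
        h_b = -sum(x * math.log(x) for x in pb)
        expected = 2 * mi / (h_a + h_b)
        assert nmi(a, b) == pytest.approx(expected)
        assert expected == pytest.approx(0.4787, abs=1e-4)

    @given(st.integers(0, 5), st.integers(0, 5))
    def test_symmetric_and_bounded(self, seed_a, seed_b):
        a = random_clustering(range(12), 3, seed_a)
        b = random_clustering(range(12), 4, seed_b)
        v = nmi(a, b)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert v == pytest.approx(nmi(b, a))

    def test_invariant_to_relabelling(self):
        a = random_clustering(range(15), 3, seed=3)
        relabelled = Clustering(
            assignment={n: c + 10 for n, c in a.assignment.items()},
            modularity=a.modularity,
        )
        b = random_clustering(range(15), 3, seed=4)
        assert nmi(a, b) == pytest.approx(nmi(relabelled, b))

    def test_node_mismatch_is_an_error(self):
        a = random_clustering(range(5), 2, seed=0)
        b = random_clustering(range(1, 6), 2, seed=0)
        with pytest.raises(ValueError):
            nmi(a, b)


class TestCompareClusterings:
    def test_identical_clusterings_share_everything(self):
        c = random_clustering(range(20), 3, seed=5)
        comparison = compare_clusterings(c, c)
        assert comparison.nmi == pytest.approx(1.0)
        assert all(v == 100.0 for v in comparison.share_pct.values())

    def test_share_of_25_in_39_is_64_point_1(self):
        # one 39-gene cluster whose best match in the other clustering holds
        # 25 of its genes
        nodes = [f"g{i}" for i in range(39)]
        a = Clustering(assignment={n: 1 for n in nodes}, modularity=0.0)
        b = Clustering(
            assignment={n: (1 if i < 25 else 2) for i, n in enumerate(nodes)},
            modularity=0.0,
        )
        comparison = compare_clusterings(a, b)
        assert comparison.share_pct[1] == pytest.approx(64.1, abs=0.05)

    def test_contingency_margins_match_cluster_sizes(self):
        a = random_clustering(range(30), 3, seed=6)
        b = random_clustering(range(30), 4, seed=7)
        comparison = compare_clusterings(a, b)
        sizes_a = {c: len(nodes) for c, nodes in a.clusters().items()}
        sizes_b = {c: len(nodes) for c, nodes in b.clusters().items()}
        assert comparison.contingency.sum(axis=1).to_dict() == sizes_a
        assert comparison.contingency.sum(axis=0).to_dict() == sizes_b

    def test_relabelled_partition_keeps_full_shares(self):
        c = random_clustering(range(10), 2, seed=8)
        relabelled = Clustering(
            assignment={n: 3 - cid for n, cid in c.assignment.items()},
            modularity=c.modularity,
        )
        comparison = compare_clusterings(c, relabelled)
        assert all(v == 100.0 for v in comparison.share_pct.values())
        assert comparison.nmi == pytest.approx(1.0)
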