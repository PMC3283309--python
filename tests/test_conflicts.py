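"""Haploid/diploid conflict detection against placement and coloring oracles."""

import numpy as np
import pytest

from condel.conflicts import (
    ConflictHypergraph,
    ConflictSet,
    Node,
    build_hypergraph,
    diploid_conflict_triplets,
    enumerate_minimal_conflicts,
    free_space,
    is_consistent_haploid,
    two_color,
)
from condel.core import Interval
from .generators import random_haploid_config
from .oracles import (
    minimal_conflicting_sets_exhaustive,
    placement_consistent,
    two_copy_assignable,
)


def cluster_node(ident, br, demand, blocked):
    return Node(id=ident, kind="cluster", br=Interval(*br), demand=demand,
                blocked=Interval(*blocked))


def concordant_node(ident, span):
    return Node(id=ident, kind="concordant", blocked=Interval(*span))


# A pair where one cluster's remaining space (80) is below its demand (220).
SQUEEZED = [
    cluster_node("A", br=(20, 400), demand=220, blocked=(0, 410)),
    cluster_node("B", br=(420, 500), demand=50, blocked=(100, 520)),
]

# A chain whose middle cluster is starved only by both neighbors together.
CHAIN3 = [
    cluster_node("L", br=(20, 140), demand=100, blocked=(0, 350)),
    cluster_node("M", br=(200, 800), demand=400, blocked=(150, 850)),
    cluster_node("R", br=(860, 980), demand=100, blocked=(650, 1000)),
]


def test_free_space_examples():
    c = cluster_node("c", br=(20, 400), demand=220, blocked=(0, 410))
    others = [concordant_node("s", (100, 520))]
    assert free_space(c, others) == [Interval(20, 100)]
    assert free_space(c, []) == [Interval(20, 400)]
    mid = cluster_node("m", br=(200, 800), demand=400, blocked=(150, 850))
    blockers = [concordant_node("a", (0, 350)), concordant_node("b", (650, 1000))]
    assert free_space(mid, blockers) == [Interval(350, 650)]


def test_consistency_examples():
    assert not is_consistent_haploid(SQUEEZED)
    assert is_consistent_haploid([])  # vacuous
    a = cluster_node("a", br=(20, 400), demand=220, blocked=(0, 420))
    b = cluster_node("b", br=(320, 700), demand=220, blocked=(300, 720))
    # each side keeps >= 280 free bases
    assert is_consistent_haploid([a, b])


def test_minimal_conflict_pair():
    out = enumerate_minimal_conflicts(SQUEEZED)
    assert [set(cs.node_ids) for cs in out] == [{"A", "B"}]


def test_minimal_conflict_triple_with_consistent_pairs():
    for i in range(3):
        for j in range(i + 1, 3):
            assert is_consistent_haploid([CHAIN3[i], CHAIN3[j]])
    out = enumerate_minimal_conflicts(CHAIN3)
    assert [set(cs.node_ids) for cs in out] == [{"L", "M", "R"}]
    # the pairwise heuristic deliberately misses this non-pairwise structure
    assert diploid_conflict_triplets(CHAIN3) == []


def test_disjoint_clusters_no_conflicts():
    nodes = [
        cluster_node(f"c{i}", br=(i * 1000 + 20, i * 1000 + 300), demand=100,
                     blocked=(i * 1000, i * 1000 + 320))
        for i in range(3)
    ]
    assert enumerate_minimal_conflicts(nodes) == []


def test_conflict_monotone_under_superset():
    extra = cluster_node("Z", br=(5020, 5300), demand=100, blocked=(5000, 5320))
    assert not is_consistent_haploid(SQUEEZED + [extra])


def test_pairwise_conflicting_triplet_detected():
    nodes = [
        cluster_node("a", br=(100, 400), demand=250, blocked=(80, 420)),
        cluster_node("b", br=(120, 420), demand=250, blocked=(100, 440)),
        cluster_node("c", br=(140, 440), demand=250, blocked=(120, 460)),
    ]
    for i in range(3):
        for j in range(i + 1, 3):
            assert not is_consistent_haploid([nodes[i], nodes[j]])
    assert diploid_conflict_triplets(nodes) == [frozenset({"a", "b", "c"})]
    assert diploid_conflict_triplets(nodes[:1]) == []


def test_two_color_basics():
    a, b, c = (cluster_node(x, br=(0, 100), demand=10, blocked=(0, 100)) for x in "abc")
    edge = lambda *ids: ConflictSet(node_ids=frozenset(ids), kinds=("cluster",) * len(ids))
    one_pair = ConflictHypergraph(nodes=[a, b], hyperedges=[edge("a", "b")])
    coloring = two_color(one_pair)
    assert coloring is not None and coloring["a"] != coloring["b"]
    triangle = ConflictHypergraph(
        nodes=[a, b, c],
        hyperedges=[edge("a", "b"), edge("b", "c"), edge("a", "c")],
    )
    assert two_color(triangle) is None  # odd cycle of pair conflicts
    one_triple = ConflictHypergraph(nodes=[a, b, c], hyperedges=[edge("a", "b", "c")])
    coloring = two_color(one_triple)
    assert coloring is not None and len(set(coloring.values())) == 2


def test_two_color_refuses_large_instances():
    nodes = [cluster_node(f"c{i}", br=(0, 100), demand=10, blocked=(0, 100))
             for i in range(25)]
    H = ConflictHypergraph(nodes=nodes, hyperedges=[])
    with pytest.raises(ValueError):
        two_color(H, max_nodes=20)


def test_consistency_matches_placement_oracle(rng):
    for _ in range(80):
        nodes = random_haploid_config(
            rng, int(rng.integers(1, 5)), int(rng.integers(0, 3))
        )
        assert is_consistent_haploid(nodes) == placement_consistent(nodes)


def test_minimal_conflicts_match_exhaustive_clusters_only(rng):
    for _ in range(60):
        nodes = random_haploid_config(rng, int(rng.integers(2, 6)))
        got = {cs.node_ids for cs in enumerate_minimal_conflicts(nodes)}
        want = set(minimal_conflicting_sets_exhaustive(nodes, is_consistent_haploid))
        assert got == want


def test_two_color_matches_copy_assignment(rng):
    for _ in range(40):
        nodes = random_haploid_config(rng, int(rng.integers(2, 7)))
        H = build_hypergraph(nodes)
        sat = two_color(H) is not None
        assert sat == two_copy_assignable(nodes)
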