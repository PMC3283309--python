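"""Haploid and diploid consistency of deletion clusters.

On a single chromosome copy, every deletion cluster must be able to place a
deleted segment of at least its minimal deletion length inside its breakpoint
region, avoiding all positions covered by reads of other clusters or by
concordant mappings (a concordant mapping acts as a cluster with minimal
deletion length zero).  A set of clusters/mappings violating this for some
cluster is *conflicting*; a *minimal* conflicting set is one whose every
proper subset is consistent.  For clusters alone, minimal conflicting sets
have exactly two or three elements, so all haploid conflicts are found by
testing overlapping pairs and triples.

For a diploid genome, clusters may be split over two chromosome copies.
Consistency is then equivalent to 2-colorability of the hypergraph whose
nodes are the clusters (and concordant mappings) and whose hyperedges are the
minimal conflicting sets: a proper coloring is exactly an assignment to two
copies leaving no copy with a complete conflicting set.  Hypergraph
2-coloring is NP-hard even with edges of size two and three, so an exact
backtracking solver is provided for small instances and a polynomial-time
lower-bound heuristic (pairwise-conflicting triples are never 2-colorable)
for larger ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .core import DeletionCluster, Interval, PairedMapping

__all__ = [
    "Node",
    "ConflictSet",
    "ConflictHypergraph",
    "free_space",
    "is_consistent_haploid",
    "enumerate_minimal_conflicts",
    "diploid_conflict_triplets",
    "build_hypergraph",
    "two_color",
]

DEFAULT_MAX_NODES = 20


@dataclass(frozen=True)
class Node:
    """A consistency-graph node: a deletion cluster or a concordant mapping.

    ``blocked`` is the region the node's reads occupy (span hull for a
    cluster, full span for a concordant mapping); no deletion of another node
    may overlap it.  ``demand`` is the minimal deletion length the node must
    place inside its own breakpoint region ``br`` (zero for concordant
    mappings, which only block).
    """

    id: str
    kind: str  # 'cluster' | 'concordant'
    blocked: Interval
    demand: int = 0
    br: Optional[Interval] = None

    def __post_init__(self) -> None:
        if self.kind not in ("cluster", "concordant"):
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.demand < 0:
            raise ValueError("demand must be >= 0")
        if self.kind == "concordant" and self.demand != 0:
            raise ValueError("concordant nodes have demand 0")
        if self.kind == "cluster" and self.br is None:
            raise ValueError("cluster nodes need a breakpoint region")

    @classmethod
    def from_cluster(cls, c: DeletionCluster) -> "Node":
        return cls(id=c.id, kind="cluster", blocked=c.span_hull, demand=c.del_min, br=c.br)

    @classmethod
    def from_concordant(cls, m: PairedMapping) -> "Node":
        return cls(id=m.id, kind="concordant", blocked=m.span, demand=0, br=None)


@dataclass(frozen=True)
class ConflictSet:
    """A minimal conflicting set of nodes (hyperedge of the conflict graph)."""

    node_ids: frozenset[str]
    kinds: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.node_ids)


@dataclass
class ConflictHypergraph:
    nodes: list[Node]
    hyperedges: list[ConflictSet]


def _subtract(base: Interval, blocks: Iterable[Interval]) -> list[Interval]:
    """Maximal sub-intervals of ``base`` not covered by any block."""
    pieces = [base]
    for b in sorted(blocks, key=lambda iv: (iv.start, iv.end)):
        nxt: list[Interval] = []
        for p in pieces:
            if b.end <= p.start or b.start >= p.end:
                nxt.append(p)
                continue
            if b.start > p.start:
                nxt.append(Interval(p.start, b.start))
            if b.end < p.end:
                nxt.append(Interval(b.end, p.end))
        pieces = nxt
        if not pieces:
            break
    return pieces


def free_space(c: Node, others: Iterable[Node]) -> list[Interval]:
    """Sub-intervals of ``c``'s breakpoint region left free by the others' reads."""
    if c.kind != "cluster" or c.br is None:
        raise ValueError("free space is defined for cluster nodes")
    return _subtract(c.br, (o.blocked for o in others if o is not c))


def is_consistent_haploid(
    clusters: Iterable[Node], concordant: Iterable[Node] = ()
) -> bool:
    """Whether all clusters can place their deletions on one chromosome copy.

    True iff every cluster's free space (its breakpoint region minus the
    regions blocked by all other nodes) contains an interval at least as long
    as its minimal deletion length.  Vacuously true without clusters.
    """
    nodes = list(clusters) + list(concordant)
    cluster_nodes = [n for n in nodes if n.kind == "cluster"]
    for c in cluster_nodes:
        gaps = free_space(c, nodes)
        if not any(g.length >= c.demand for g in gaps):
            return False
    return True


def _interacting(nodes: Sequence[Node]) -> list[tuple[int, int]]:
    """Pairs of node indices whose blocked regions overlap."""
    tree = IntervalTree()
    for i, n in enumerate(nodes):
        if n.blocked.length > 0:
            tree.addi(n.blocked.start, n.blocked.end, i)
    pairs = set()
    for i, n in enumerate(nodes):
        for hit in tree.overlap(n.blocked.start, n.blocked.end):
            j = hit.data
            if j != i:
                pairs.add((min(i, j), max(i, j)))
    return sorted(pairs)


def enumerate_minimal_conflicts(
    clusters: Iterable[Node], concordant: Iterable[Node] = ()
) -> list[ConflictSet]:
    """All minimal conflicting sets of size two and three.

    Every pair with at least one cluster and every overlap-connected triple
    with at most one concordant node is tested with the consistency oracle.
    For cluster-only nodes this finds *all* minimal conflicting sets (they
    cannot exceed size three); triples with two or more concordant nodes are
    skipped — two zero-demand nodes cannot both be essential to a conflict
    unless one of the pairs already conflicts.
    """
    nodes = list(clusters) + list(concordant)
    out: list[ConflictSet] = []
    pairs = _interacting(nodes)
    conflicting_pairs: set[tuple[int, int]] = set()
    adj: dict[int, set[int]] = {}
    for i, j in pairs:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
        if nodes[i].kind == "concordant" and nodes[j].kind == "concordant":
            continue
        if not is_consistent_haploid([nodes[i], nodes[j]]):
            conflicting_pairs.add((i, j))
            out.append(
                ConflictSet(
                    node_ids=frozenset({nodes[i].id, nodes[j].id}),
                    kinds=(nodes[i].kind, nodes[j].kind),
                )
            )
    # Triples: overlap-connected, at most one concordant node, all pairs consistent.
    candidate_triples = set()
    for i in adj:
        for j, k in combinations(sorted(adj[i]), 2):
            candidate_triples.add(tuple(sorted((i, j, k))))
    for i, j, k in sorted(candidate_triples):
        trio = (nodes[i], nodes[j], nodes[k])
        if sum(1 for n in trio if n.kind == "concordant") >= 2:
            continue
        if any(
            (a, b) in conflicting_pairs
            for a, b in combinations((i, j, k), 2)
        ):
            continue  # a conflicting pair inside makes the triple non-minimal
        if not is_consistent_haploid(trio):
            out.append(
                ConflictSet(
                    node_ids=frozenset(n.id for n in trio),
                    kinds=tuple(n.kind for n in trio),
                )
            )
    return out


def diploid_conflict_triplets(
    clusters: Iterable[Node], concordant: Iterable[Node] = ()
) -> list[frozenset[str]]:
    """Triples of nodes that are pairwise haploid-conflicting.

    Three nodes (at most one concordant) whose three pairs each conflict
    cannot be split over two chromosome copies, so every reported triple is a
    certified diploid conflict.  This is a polynomial-time lower bound, not a
    complete diploid test: conflicts relying on non-pairwise structure are
    deliberately not detected here.
    """
    nodes = list(clusters) + list(concordant)
    conflicting: set[tuple[int, int]] = set()
    adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
    for i, j in _interacting(nodes):
        if nodes[i].kind == "concordant" and nodes[j].kind == "concordant":
            continue
        if not is_consistent_haploid([nodes[i], nodes[j]]):
            conflicting.add((i, j))
            adj[i].add(j)
            adj[j].add(i)
    out = []
    seen = set()
    for i, j in sorted(conflicting):
        for k in sorted(adj[i] & adj[j]):
            trio = tuple(sorted((i, j, k)))
            if trio in seen:
                continue
            seen.add(trio)
            if sum(1 for t in trio if nodes[t].kind == "concordant") >= 2:
                continue
            out.append(frozenset(nodes[t].id for t in trio))
    return sorted(out, key=sorted)


def build_hypergraph(
    clusters: Iterable[Node], concordant: Iterable[Node] = ()
) -> ConflictHypergraph:
    """Conflict hypergraph: nodes plus minimal conflicting sets as hyperedges."""
    cl = list(clusters)
    co = list(concordant)
    return ConflictHypergraph(nodes=cl + co, hyperedges=enumerate_minimal_conflicts(cl, co))


def two_color(
    H: ConflictHypergraph, max_nodes: int = DEFAULT_MAX_NODES
) -> Optional[dict[str, int]]:
    """Exact hypergraph 2-coloring by backtracking, or ``None`` if UNSAT.

    A proper coloring assigns 0/1 to every node such that no hyperedge is
    monochromatic; it corresponds to a conflict-free assignment of the nodes
    to two chromosome copies.  Refuses instances above ``max_nodes`` (the
    problem is NP-hard); use :func:`diploid_conflict_triplets` there instead.
    """
    if len(H.nodes) > max_nodes:
        raise ValueError(
            f"{len(H.nodes)} nodes exceed the exact-search bound of {max_nodes}; "
            "use the pairwise-conflicting-triplet heuristic for large instances"
        )
    ids = [n.id for n in H.nodes]
    constrained = sorted({i for e in H.hyperedges for i in e.node_ids})
    edges = [sorted(e.node_ids) for e in H.hyperedges]
    color: dict[str, int] = {}

    def edge_ok(e: list[str]) -> bool:
        vals = [color[i] for i in e if i in color]
        if len(vals) < len(e):
            return True  # not fully colored yet
        return len(set(vals)) > 1

    def bt(pos: int) -> bool:
        if pos == len(constrained):
            return True
        node = constrained[pos]
        for v in (0, 1):
            color[node] = v
            if all(edge_ok(e) for e in edges if node in e):
                if bt(pos + 1):
                    return True
            del color[node]
        return False

    if not bt(0):
        return None
    return {i: color.get(i, 0) for i in ids}
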