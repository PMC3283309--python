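"""Independent brute-force oracles used to validate the package's algorithms.

Each oracle favors exhaustive enumeration and first-principles checks over
the clever search paths implemented in the package, so agreement between the
two routes is meaningful.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence

from condel.conflicts import Node, is_consistent_haploid
from condel.core import (
    DeletionCluster,
    Interval,
    LibraryStats,
    PairedMapping,
    deletion_bounds,
    is_valid_cluster,
)


def placement_consistent(nodes: Sequence[Node]) -> bool:
    """Consistency by enumerating every deletion placement position.

    A configuration is consistent iff each cluster can place a deleted
    segment of its minimal length at some integer offset of its breakpoint
    region without touching any other node's reads.
    """
    for c in nodes:
        if c.kind != "cluster":
            continue
        assert c.br is not None
        blocked = [o.blocked for o in nodes if o is not c]
        placed = False
        for x in range(c.br.start, c.br.end - c.demand + 1):
            iv = Interval(x, x + c.demand)
            if all(
                not (iv.start < b.end and b.start < iv.end) for b in blocked
            ) or c.demand == 0:
                placed = True
                break
        if not placed:
            return False
    return True


def minimal_conflicting_sets_exhaustive(
    nodes: Sequence[Node],
    consistent=placement_consistent,
    max_size: Optional[int] = None,
) -> list[frozenset[str]]:
    """All minimal conflicting subsets, over every subset size."""
    n = len(nodes)
    top = n if max_size is None else min(n, max_size)
    conflicting: list[tuple[int, ...]] = []
    for size in range(1, top + 1):
        for idxs in combinations(range(n), size):
            if not consistent([nodes[i] for i in idxs]):
                conflicting.append(idxs)
    minimal = []
    for s in conflicting:
        ss = set(s)
        if not any(set(t) < ss for t in conflicting):
            minimal.append(frozenset(nodes[i].id for i in s))
    return minimal


def maximal_valid_clusters_exhaustive(
    ms: Sequence[PairedMapping], lib: LibraryStats
) -> set[frozenset[str]]:
    """Inclusion-maximal valid clusters by checking every nonempty subset."""
    n = len(ms)
    valid: list[set[int]] = []
    for size in range(1, n + 1):
        for idxs in combinations(range(n), size):
            if is_valid_cluster([ms[i] for i in idxs], lib):
                valid.append(set(idxs))
    out = set()
    for s in valid:
        if not any(s < t for t in valid):
            out.add(frozenset(ms[i].id for i in s))
    return out


def two_copy_assignable(
    nodes: Sequence[Node], consistent=is_consistent_haploid
) -> bool:
    """Whether some split of the nodes over two copies is consistent per copy."""
    n = len(nodes)
    for mask in range(2**n):
        side_a = [nodes[i] for i in range(n) if mask >> i & 1]
        side_b = [nodes[i] for i in range(n) if not mask >> i & 1]
        if consistent(side_a) and consistent(side_b):
            return True
    return False


def max_support_exhaustive(
    c: DeletionCluster, M: Sequence[PairedMapping], lib: LibraryStats
) -> list[str]:
    """Largest subset merging validly with ``c``; lexicographic tie-break."""
    best: Optional[tuple[int, tuple[str, ...]]] = None
    for size in range(len(M), -1, -1):
        for sub in combinations(sorted(M, key=lambda m: m.id), size):
            if c.extended(list(sub), lib) is not None:
                key = (-size, tuple(m.id for m in sub))
                if best is None or key < best:
                    best = key
        if best is not None:
            break
    assert best is not None
    return list(best[1])


def min_discards_exhaustive(
    c_prime: DeletionCluster,
    R: Sequence[PairedMapping],
    lib: LibraryStats,
    blockers: Sequence[Node] = (),
) -> int:
    """Minimum discard count over all partitions of ``R`` into clusters on two
    tumor copies consistent with the refined normal cluster.

    Plain recursive enumeration with feasibility pruning only (invalid or
    inconsistent partial states cannot recover, since adding members only
    shrinks free space); no bounding, no incumbent-based cuts.
    """
    cp = Node.from_cluster(c_prime)
    stats = []
    for m in R:
        b = m.br
        assert b is not None
        stats.append((b, *deletion_bounds(m, lib), m.span))

    best = [len(R)]

    def node_of(block: tuple[Interval, int, int, Interval], k: int) -> Node:
        br, dmin, _, hull = block
        return Node(id=f"b{k}", kind="cluster", blocked=hull, demand=dmin, br=br)

    def consistent(blocks: list[tuple], copies: list[int]) -> bool:
        one = [cp] + [node_of(b, k) for k, b in enumerate(blocks) if copies[k] == 1]
        two = [node_of(b, k) for k, b in enumerate(blocks) if copies[k] == 2]
        return is_consistent_haploid(one, blockers) and is_consistent_haploid(two, blockers)

    def rec(i: int, blocks: list[tuple], copies: list[int], ndisc: int) -> None:
        if i == len(R):
            best[0] = min(best[0], ndisc)
            return
        b, lo, hi, span = stats[i]
        for k in range(len(blocks)):
            bbr, bdmin, bdmax, bhull = blocks[k]
            nbr = bbr.intersect(b)
            if nbr is None:
                continue
            ndmin, ndmax = max(bdmin, lo), min(bdmax, hi)
            if ndmin > ndmax or ndmin > nbr.length:
                continue
            nb = (nbr, ndmin, ndmax, bhull.hull(span))
            trial = blocks[:k] + [nb] + blocks[k + 1 :]
            if consistent(trial, copies):
                rec(i + 1, trial, copies, ndisc)
        for copy in (1, 2):
            nb = (b, lo, hi, span)
            if consistent(blocks + [nb], copies + [copy]):
                rec(i + 1, blocks + [nb], copies + [copy], ndisc)
        rec(i + 1, blocks, copies, ndisc + 1)

    rec(0, [], [], 0)
    return best[0]
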