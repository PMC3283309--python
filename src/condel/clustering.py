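"""Enumeration of maximal valid deletion clusters.

Cluster validity is hereditary (every subset of a valid cluster is valid), so
the inclusion-maximal valid clusters can be enumerated by a Bron–Kerbosch
style branch-and-extend over the pairwise-compatibility graph, with the *full*
multi-way validity check applied at every extension.  The pairwise graph alone
is not enough: the deletion-length constraint couples all members through the
shared breakpoint-region intersection, so a pairwise-compatible triple can be
jointly invalid.

Mappings are first split into connected components of span overlap — clusters
cannot cross such components because disjoint spans have disjoint breakpoint
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    DeletionCluster,
    Interval,
    LibraryStats,
    PairedMapping,
    cluster_from_mappings,
    deletion_bounds,
    is_valid_cluster,
)

__all__ = [
    "pairwise_compatible",
    "enumerate_maximal_valid_clusters",
    "ClusterLimitExceeded",
    "ClusteringResult",
]

DEFAULT_MAX_CLUSTERS = 10**6


class ClusterLimitExceeded(RuntimeError):
    """Raised internally when a chromosome exceeds the cluster budget."""


@dataclass
class ClusteringResult:
    """Maximal valid clusters plus per-chromosome failure diagnostics."""

    clusters: list[DeletionCluster]
    skipped: dict[str, str] = field(default_factory=dict)


def pairwise_compatible(m1: PairedMapping, m2: PairedMapping, lib: LibraryStats) -> bool:
    """Whether two deletion-indicating mappings form a valid two-element cluster."""
    if m1.chrom != m2.chrom:
        return False
    if m1 is m2 or m1.id == m2.id:
        return True
    return is_valid_cluster([m1, m2], lib)


@dataclass
class _Pool:
    """Per-mapping arrays for O(1) incremental validity checks."""

    br_start: list[int]
    br_end: list[int]
    dmin: list[int]
    dmax: list[int]

    @classmethod
    def build(cls, ms: Sequence[PairedMapping], lib: LibraryStats) -> "_Pool":
        bs, be, lo_, hi_ = [], [], [], []
        for m in ms:
            b = m.br
            assert b is not None
            lo, hi = deletion_bounds(m, lib)
            bs.append(b.start)
            be.append(b.end)
            lo_.append(lo)
            hi_.append(hi)
        return cls(bs, be, lo_, hi_)


_EMPTY_STATS = (0, 0, 0, 0)  # br_start, br_end(sentinel), dmin, dmax — unused for empty R


def _extend_stats(pool: _Pool, stats: Optional[tuple], j: int) -> Optional[tuple]:
    """Aggregate stats of R ∪ {j}, or ``None`` if invalid."""
    if stats is None:
        bs, be = pool.br_start[j], pool.br_end[j]
        dmin, dmax = pool.dmin[j], pool.dmax[j]
    else:
        bs = max(stats[0], pool.br_start[j])
        be = min(stats[1], pool.br_end[j])
        dmin = max(stats[2], pool.dmin[j])
        dmax = min(stats[3], pool.dmax[j])
    if bs >= be or dmin > dmax or dmin > be - bs:
        return None
    return (bs, be, dmin, dmax)


def _branch(
    pool: _Pool,
    R: list[int],
    stats: Optional[tuple],
    P: list[int],
    X: list[int],
    out: list[frozenset[int]],
    seen: set[frozenset[int]],
    limit: int,
) -> None:
    # Invariant: every index in P or X validly extends R.
    if not P and not X:
        key = frozenset(R)
        if key not in seen:
            seen.add(key)
            out.append(key)
            if len(out) > limit:
                raise ClusterLimitExceeded()
        return
    P = list(P)
    while P:
        j = P.pop(0)
        stats_j = _extend_stats(pool, stats, j)
        assert stats_j is not None
        newP = [p for p in P if _extend_stats(pool, stats_j, p) is not None]
        newX = [x for x in X if _extend_stats(pool, stats_j, x) is not None]
        _branch(pool, R + [j], stats_j, newP, newX, out, seen, limit)
        X = X + [j]


def _span_overlap_components(ms: Sequence[PairedMapping]) -> list[list[int]]:
    """Indices grouped into connected components of span overlap."""
    order = sorted(range(len(ms)), key=lambda i: (ms[i].span.start, ms[i].span.end))
    comps: list[list[int]] = []
    cur: list[int] = []
    cur_end = None
    for i in order:
        s = ms[i].span
        if cur_end is None or s.start >= cur_end:
            if cur:
                comps.append(cur)
            cur, cur_end = [i], s.end
        else:
            cur.append(i)
            cur_end = max(cur_end, s.end)
    if cur:
        comps.append(cur)
    return comps


def enumerate_maximal_valid_clusters(
    ms: Sequence[PairedMapping],
    lib: LibraryStats,
    max_clusters: int = DEFAULT_MAX_CLUSTERS,
    id_prefix: str = "c",
) -> ClusteringResult:
    """Enumerate exactly the inclusion-maximal valid clusters of ``ms``.

    Mappings are grouped by chromosome; a chromosome whose cluster count would
    exceed ``max_clusters`` is skipped with a diagnostic (combinatorial
    explosion), while the others are still processed.  Clusters are reported
    sorted by ``(chrom, br.start, br.end, support)`` and numbered with
    ``id_prefix``.
    """
    by_chrom: dict[str, list[PairedMapping]] = {}
    for m in ms:
        if m.br is None:
            raise ValueError(f"{m.id}: not a deletion-indicating mapping (no breakpoint region)")
        by_chrom.setdefault(m.chrom, []).append(m)

    all_clusters: list[DeletionCluster] = []
    skipped: dict[str, str] = {}
    raw: list[tuple[str, frozenset[int], list[PairedMapping]]] = []
    for chrom in sorted(by_chrom):
        cms = by_chrom[chrom]
        pool = _Pool.build(cms, lib)
        out: list[frozenset[int]] = []
        seen: set[frozenset[int]] = set()
        try:
            for comp in _span_overlap_components(cms):
                _branch(pool, [], None, sorted(comp), [], out, seen, max_clusters)
        except ClusterLimitExceeded:
            skipped[chrom] = (
                f"more than {max_clusters} maximal clusters; chromosome skipped"
            )
            continue
        for members in out:
            raw.append((chrom, members, cms))

    keyed = []
    for chrom, members, cms in raw:
        sub = [cms[i] for i in sorted(members)]
        c = cluster_from_mappings("tmp", sub, lib)
        keyed.append((chrom, c.br.start, c.br.end, c.support, c))
    keyed.sort(key=lambda t: t[:4])
    for k, (_, _, _, _, c) in enumerate(keyed, start=1):
        all_clusters.append(
            DeletionCluster(
                id=f"{id_prefix}{k}", chrom=c.chrom, member_ids=c.member_ids,
                br=c.br, del_min=c.del_min, del_max=c.del_max,
                span_hull=c.span_hull, n_normal=c.n_normal, n_tumor=c.n_tumor,
            )
        )
    return ClusteringResult(clusters=all_clusters, skipped=skipped)
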