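"""Assignment of contaminated-tumor mappings to four chromosome copies.

A tumor specimen usually contains normal cells, so its read pairs originate
from four chromosome copies: two from the patient's normal genome and two
from the tumor genome.  Around each deletion cluster found in the matched
normal sample, the tumor mappings that directly or transitively overlap it
(an *overlapping component*) are explained as follows, treating all deletions
as heterozygous:

1. every concordant mapping is placed on the normal chromosome copy that does
   not carry the patient deletion, where it cannot interfere;
2. a maximum subset of the discordant mappings that *supports* the patient
   deletion (calls for one single deletion together with the normal cluster)
   is merged into it, refining its breakpoint region and size bracket;
3. the remaining discordant mappings are partitioned into valid clusters on
   the two tumor chromosome copies — the refined patient deletion occupies
   one of them — such that each copy is haploid-consistent and the number of
   discarded mappings is minimal.  Step 3 is solved by branch-and-bound with
   a configurable time budget; results found at the deadline are labeled
   ``time_limited``.

The surviving clusters on the tumor copies are candidate tumor-specific
deletions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .conflicts import Node, is_consistent_haploid
from .core import (
    DeletionCluster,
    Interval,
    LibraryStats,
    PairedMapping,
    classify_mapping,
    deletion_bounds,
)

__all__ = [
    "OverlappingComponent",
    "AssignmentResult",
    "build_components",
    "max_supporting_subset",
    "assign_component",
    "refinement_ratios",
]

DEFAULT_TIME_LIMIT = 600.0  # seconds per component


@dataclass(frozen=True)
class OverlappingComponent:
    """All tumor mappings tied to one normal deletion cluster.

    ``deletion_mappings`` are the tumor discordant (deletion-indicating)
    mappings whose span overlaps the normal cluster's breakpoint region
    directly, or transitively via span overlap with another member.
    ``concordant_mappings`` are the tumor concordant mappings overlapping the
    component's footprint (hull of the normal breakpoint region and all
    member spans).
    """

    id: str
    normal_cluster_id: str
    chrom: str
    deletion_mappings: tuple[PairedMapping, ...]
    concordant_mappings: tuple[PairedMapping, ...]
    footprint: Interval


@dataclass(frozen=True)
class AssignmentResult:
    """Solution of the four-copy assignment for one overlapping component."""

    component_id: str
    refined_normal: DeletionCluster
    support_ids: tuple[str, ...]
    tumor_clusters: tuple[DeletionCluster, ...]
    copy_of: dict[str, int]
    normal_concordant_ids: tuple[str, ...]
    tumor_concordant_ids: tuple[str, ...]
    discarded_ids: tuple[str, ...]
    status: str  # 'optimal' | 'time_limited'

    @property
    def n_discarded(self) -> int:
        return len(self.discarded_ids)


def build_components(
    normal_clusters: Sequence[DeletionCluster],
    tumor_mappings: Sequence[PairedMapping],
    lib: LibraryStats,
    overlap_on: str = "span",
) -> tuple[list[OverlappingComponent], list[tuple[str, str]]]:
    """Group tumor mappings into overlapping components around normal deletions.

    ``overlap_on`` selects whether a tumor mapping's full span or only its
    breakpoint region is tested against the normal cluster's breakpoint
    region for the direct-overlap seed.  Components that are not independent
    — sharing a tumor deletion mapping, or built on normal clusters with
    overlapping breakpoint regions — are dropped and reported as
    ``(normal_cluster_id, reason)`` pairs.
    """
    if overlap_on not in ("span", "br"):
        raise ValueError("overlap_on must be 'span' or 'br'")
    dels: list[PairedMapping] = []
    concs: list[PairedMapping] = []
    for m in tumor_mappings:
        kind = classify_mapping(m, lib)
        if kind == "deletion":
            dels.append(m)
        elif kind == "concordant":
            concs.append(m)

    by_chrom_del: dict[str, list[int]] = {}
    for i, m in enumerate(dels):
        by_chrom_del.setdefault(m.chrom, []).append(i)
    trees: dict[str, IntervalTree] = {}
    for chrom, idxs in by_chrom_del.items():
        t = IntervalTree()
        for i in idxs:
            s = dels[i].span
            t.addi(s.start, s.end, i)
        trees[chrom] = t

    members: list[set[int]] = []
    for c in normal_clusters:
        tree = trees.get(c.chrom)
        got: set[int] = set()
        if tree is not None:
            seed_iv = {
                "span": lambda m: m.span,
                "br": lambda m: m.br,
            }[overlap_on]
            seeds = [
                hit.data
                for hit in tree.overlap(c.br.start, c.br.end)
                if seed_iv(dels[hit.data]) is not None
                and seed_iv(dels[hit.data]).overlaps(c.br)
            ]
            queue = list(seeds)
            got = set(seeds)
            while queue:  # transitive closure over span overlap
                i = queue.pop()
                s = dels[i].span
                for hit in tree.overlap(s.start, s.end):
                    j = hit.data
                    if j not in got:
                        got.add(j)
                        queue.append(j)
        members.append(got)

    dropped: list[tuple[str, str]] = []
    bad: set[int] = set()
    for a, b in combinations(range(len(normal_clusters)), 2):
        ca, cb = normal_clusters[a], normal_clusters[b]
        if ca.chrom == cb.chrom and ca.br.overlaps(cb.br):
            bad.update((a, b))
            dropped.append((ca.id, f"normal clusters {ca.id}/{cb.id} overlap"))
            dropped.append((cb.id, f"normal clusters {ca.id}/{cb.id} overlap"))
            continue
        if members[a] & members[b]:
            bad.update((a, b))
            reason = f"components of {ca.id}/{cb.id} share tumor mappings"
            dropped.append((ca.id, reason))
            dropped.append((cb.id, reason))

    conc_trees: dict[str, IntervalTree] = {}
    for i, m in enumerate(concs):
        conc_trees.setdefault(m.chrom, IntervalTree()).addi(m.span.start, m.span.end, i)

    components: list[OverlappingComponent] = []
    for k, c in enumerate(normal_clusters):
        if k in bad:
            continue
        ms = sorted(members[k], key=lambda i: (dels[i].span.start, dels[i].id))
        foot = c.br
        for i in ms:
            foot = foot.hull(dels[i].span)
        ctree = conc_trees.get(c.chrom)
        conc = (
            sorted(
                (concs[h.data] for h in ctree.overlap(foot.start, foot.end)),
                key=lambda m: (m.span.start, m.id),
            )
            if ctree is not None
            else []
        )
        components.append(
            OverlappingComponent(
                id=f"comp_{c.id}",
                normal_cluster_id=c.id,
                chrom=c.chrom,
                deletion_mappings=tuple(dels[i] for i in ms),
                concordant_mappings=tuple(conc),
                footprint=foot,
            )
        )
    return components, dropped


def max_supporting_subset(
    c: DeletionCluster, M: Sequence[PairedMapping], lib: LibraryStats
) -> list[PairedMapping]:
    """Maximum subset of ``M`` that merges with ``c`` into one valid cluster.

    A set supports the deletion iff one deleted segment placement explains
    everything: an interval ``[x, x + d)`` inside every member's breakpoint
    region with ``d`` inside every member's deletion-size bracket.  An optimal
    placement can always be normalized so that ``x`` is some breakpoint-region
    start and ``d`` some minimal deletion length, so scanning those O(n²)
    candidate placements and collecting all compatible mappings is exact.
    Ties are broken by the lexicographically smallest id set.
    """
    infos = []
    for m in M:
        b = m.br
        if b is None:
            raise ValueError(f"{m.id}: not a deletion-indicating mapping")
        infos.append((m, b, deletion_bounds(m, lib)))
    xs = sorted({b.start for _, b, _ in infos} | {c.br.start})
    ds = sorted({lo for _, _, (lo, _) in infos} | {c.del_min})
    best_key: Optional[tuple[int, tuple[str, ...]]] = None
    best: list[PairedMapping] = []
    for d in ds:
        if d < c.del_min or d > c.del_max:
            continue
        for x in xs:
            if x < c.br.start or x + d > c.br.end:
                continue
            S = [
                m
                for (m, b, (lo, hi)) in infos
                if b.start <= x and x + d <= b.end and lo <= d <= hi
            ]
            key = (-len(S), tuple(sorted(m.id for m in S)))
            if best_key is None or key < best_key:
                best_key, best = key, S
    return sorted(best, key=lambda m: m.id)


@dataclass
class _Acc:
    """Open tumor cluster during the branch-and-bound search."""

    idxs: list[int]
    br: Interval
    dmin: int
    dmax: int
    hull: Interval
    copy: int

    def node(self, ident: str) -> Node:
        return Node(id=ident, kind="cluster", blocked=self.hull, demand=self.dmin, br=self.br)


def _try_join(acc: _Acc, b: Interval, lo: int, hi: int, span: Interval) -> Optional[_Acc]:
    br = acc.br.intersect(b)
    if br is None:
        return None
    dmin, dmax = max(acc.dmin, lo), min(acc.dmax, hi)
    if dmin > dmax or dmin > br.length:
        return None
    return _Acc(
        idxs=acc.idxs,  # caller appends
        br=br,
        dmin=dmin,
        dmax=dmax,
        hull=acc.hull.hull(span),
        copy=acc.copy,
    )


def _pair_unplaceable(
    a_stats: tuple[Interval, int, int, Interval],
    b_stats: tuple[Interval, int, int, Interval],
    cprime_node: Node,
    blockers: Sequence[Node],
) -> bool:
    """True if no two-copy placement keeps both mappings (given only c')."""
    (ba, loa, hia, sa) = a_stats
    (bb, lob, hib, sb) = b_stats

    def single(b: Interval, lo: int, s: Interval, ident: str) -> Node:
        return Node(id=ident, kind="cluster", blocked=s, demand=lo, br=b)

    na, nb = single(ba, loa, sa, "_a"), single(bb, lob, sb, "_b")
    # joint cluster
    br = ba.intersect(bb)
    if br is not None:
        dmin, dmax = max(loa, lob), min(hia, hib)
        if dmin <= dmax and dmin <= br.length:
            nj = Node(id="_ab", kind="cluster", blocked=sa.hull(sb), demand=dmin, br=br)
            if is_consistent_haploid([cprime_node, nj], blockers) or is_consistent_haploid(
                [nj], blockers
            ):
                return False
    # separate clusters over the two copies
    for copy_a in (1, 2):
        for copy_b in (1, 2):
            c1 = [cprime_node] + [n for n, cp in ((na, copy_a), (nb, copy_b)) if cp == 1]
            c2 = [n for n, cp in ((na, copy_a), (nb, copy_b)) if cp == 2]
            if is_consistent_haploid(c1, blockers) and is_consistent_haploid(c2, blockers):
                return False
    return True


def assign_component(
    comp: OverlappingComponent,
    c: DeletionCluster,
    lib: LibraryStats,
    time_limit: float = DEFAULT_TIME_LIMIT,
    concordant_constrain: bool = False,
) -> AssignmentResult:
    """Solve the four-copy assignment for one overlapping component.

    Returns the refined normal cluster, the tumor-specific clusters with
    their copy assignment, the concordant sets and a minimum discard set.
    ``concordant_constrain`` additionally places the component's concordant
    mappings as blocking reads on both tumor copies (stricter than the
    default, which explains them all on the deletion-free normal copy).

    Raises ``ValueError`` for an invalid normal cluster or a non-positive
    ``time_limit``.
    """
    if time_limit <= 0:
        raise ValueError("time_limit must be positive")
    if c.del_min > c.del_max or c.del_min > c.br.length:
        raise ValueError(f"{c.id}: normal cluster is not valid")
    if comp.chrom != c.chrom:
        raise ValueError("component and cluster are from different chromosomes")

    S = max_supporting_subset(c, comp.deletion_mappings, lib)
    support_ids = tuple(m.id for m in S)
    c_prime = c.extended(S, lib, new_id=f"{c.id}p")
    assert c_prime is not None, "supporting subset must merge validly"
    cprime_node = Node.from_cluster(c_prime)

    blockers: list[Node] = []
    if concordant_constrain:
        blockers = [Node.from_concordant(m) for m in comp.concordant_mappings]

    in_support = set(support_ids)
    R = sorted(
        (m for m in comp.deletion_mappings if m.id not in in_support),
        key=lambda m: (m.br.start, m.br.end, m.id),  # type: ignore[union-attr]
    )
    stats = []
    for m in R:
        b = m.br
        assert b is not None
        lo, hi = deletion_bounds(m, lib)
        stats.append((b, lo, hi, m.span))

    n = len(R)
    deadline = time.monotonic() + time_limit

    # Root lower bound: greedy matching over pairs that cannot both be kept.
    edges = [
        (i, j)
        for i, j in combinations(range(n), 2)
        if _pair_unplaceable(stats[i], stats[j], cprime_node, blockers)
    ]

    def matching_lb(start: int) -> int:
        used: set[int] = set()
        cnt = 0
        for i, j in edges:
            if i >= start and j >= start and i not in used and j not in used:
                used.update((i, j))
                cnt += 1
        return cnt

    root_lb = matching_lb(0)

    def consistent(accs: list[_Acc]) -> bool:
        c1 = [cprime_node] + [a.node(f"_t{k}") for k, a in enumerate(accs) if a.copy == 1]
        c2 = [a.node(f"_t{k}") for k, a in enumerate(accs) if a.copy == 2]
        return is_consistent_haploid(c1, blockers) and is_consistent_haploid(c2, blockers)

    best_cost = n + 1
    best_state: Optional[tuple[list[_Acc], list[int]]] = None
    timed_out = False

    def dfs(i: int, accs: list[_Acc], discards: list[int]) -> bool:
        """Returns True to abort the whole search (timeout or proven optimum)."""
        nonlocal best_cost, best_state, timed_out
        if time.monotonic() > deadline:
            timed_out = True
            return True
        if len(discards) + matching_lb(i) >= best_cost:
            return False
        if i == n:
            best_cost = len(discards)
            best_state = ([_Acc(list(a.idxs), a.br, a.dmin, a.dmax, a.hull, a.copy) for a in accs],
                          list(discards))
            return best_cost <= root_lb  # cannot do better
        b, lo, hi, span = stats[i]
        # join an open cluster
        for k, acc in enumerate(accs):
            joined = _try_join(acc, b, lo, hi, span)
            if joined is None:
                continue
            joined.idxs = acc.idxs + [i]
            trial = accs[:k] + [joined] + accs[k + 1 :]
            if consistent(trial):
                if dfs(i + 1, trial, discards):
                    return True
        # open a new cluster on either tumor copy; the copy not carrying the
        # refined normal deletion is tried first (more room there)
        for copy in (2, 1):
            acc = _Acc(idxs=[i], br=b, dmin=lo, dmax=hi, hull=span, copy=copy)
            trial = accs + [acc]
            if consistent(trial):
                if dfs(i + 1, trial, discards):
                    return True
        # discard
        if dfs(i + 1, accs, discards + [i]):
            return True
        return False

    dfs(0, [], [])
    if best_state is None:
        # Deadline hit before the greedy-first leaf: fall back to discarding all.
        best_state = ([], list(range(n)))
        timed_out = True
    accs, discards = best_state

    accs_sorted = sorted(accs, key=lambda a: (a.br.start, a.br.end, min(a.idxs)))
    tumor_clusters: list[DeletionCluster] = []
    copy_of: dict[str, int] = {}
    for k, a in enumerate(accs_sorted, start=1):
        cid = f"{comp.id}.t{k}"
        tumor_clusters.append(
            DeletionCluster(
                id=cid,
                chrom=comp.chrom,
                member_ids=tuple(R[i].id for i in sorted(a.idxs)),
                br=a.br,
                del_min=a.dmin,
                del_max=a.dmax,
                span_hull=a.hull,
                n_normal=0,
                n_tumor=len(a.idxs),
            )
        )
        copy_of[cid] = a.copy

    return AssignmentResult(
        component_id=comp.id,
        refined_normal=c_prime,
        support_ids=support_ids,
        tumor_clusters=tuple(tumor_clusters),
        copy_of=copy_of,
        normal_concordant_ids=tuple(m.id for m in comp.concordant_mappings),
        tumor_concordant_ids=(),
        discarded_ids=tuple(R[i].id for i in sorted(discards)),
        status="time_limited" if timed_out else "optimal",
    )


def refinement_ratios(c: DeletionCluster, c_prime: DeletionCluster) -> tuple[float, float]:
    """How much refinement shrank the deletion-size range and breakpoint region.

    Returns ``(width(c') / width(c), |br(c')| / |br(c)|)`` where width is the
    deletion-size range ``del_max - del_min``.  Both ratios are at most 1 for
    any refinement by member addition; a zero-width initial range maps to 1.
    """
    w0, w1 = c.del_range_width, c_prime.del_range_width
    del_ratio = 1.0 if w0 == 0 else w1 / w0
    br_ratio = 1.0 if c.br.length == 0 else c_prime.br.length / c.br.length
    return del_ratio, br_ratio
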