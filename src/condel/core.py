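"""Domain model for paired-end deletion detection.

A *paired-end mapping* places the two reads of a sequenced fragment on a
reference chromosome.  If the mapped distance (the *span*, measured from the
left end of the left read to the right end of the right read, reads included)
exceeds the maximum expected insert size, the mapping indicates a deletion in
the donor genome.  The deleted segment must lie between the inner read ends
(the *breakpoint region*), and its size is bracketed by the span length minus
the insert-size cutoffs.

A *valid cluster* is a set of deletion-indicating mappings that can all be
explained by one common deletion: their breakpoint regions share a nonempty
intersection that is long enough to host a deletion length compatible with
every member's size bracket.  Validity is hereditary (every subset of a valid
cluster is valid), which the clustering module exploits.

All coordinates are 0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "Interval",
    "LibraryStats",
    "PairedMapping",
    "DeletionCluster",
    "classify_mapping",
    "deletion_bounds",
    "is_valid_cluster",
    "cluster_from_mappings",
]


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval ``[start, end)`` with ``start <= end``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def is_empty(self) -> bool:
        return self.end <= self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def intersect(self, other: "Interval") -> Optional["Interval"]:
        """Intersection, or ``None`` if the two intervals are disjoint."""
        s, e = max(self.start, other.start), min(self.end, other.end)
        if s >= e:
            return None
        return Interval(s, e)

    def hull(self, other: "Interval") -> "Interval":
        return Interval(min(self.start, other.start), max(self.end, other.end))


@dataclass(frozen=True)
class LibraryStats:
    """Insert-size cutoffs and filters of one sequencing library.

    ``min_len``/``max_len`` bracket the insert size (fragment length including
    both reads) of concordant mappings; they are typically estimated as low and
    high quantiles of the observed insert-size distribution (see
    :func:`condel.io.estimate_insert_bounds`).
    """

    min_len: int
    max_len: int
    quality_min: int = 20
    q_low: float = 0.001
    q_high: float = 0.999

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError(
                f"need 0 < min_len <= max_len, got ({self.min_len}, {self.max_len})"
            )
        if not (0.0 <= self.q_low < self.q_high <= 1.0):
            raise ValueError(f"need 0 <= q_low < q_high <= 1, got ({self.q_low}, {self.q_high})")


@dataclass(frozen=True)
class PairedMapping:
    """One read pair mapped to a reference chromosome.

    ``left``/``right`` are the read alignment intervals, ordered so that
    ``left.start <= right.start``.  Orientation flags are ``'+'``/``'-'``;
    a *proper* pair has the left read on the forward and the right read on the
    reverse strand.
    """

    id: str
    chrom: str
    left: Interval
    right: Interval
    left_orient: str
    right_orient: str
    quality: int
    source: str = "normal"

    def __post_init__(self) -> None:
        if self.left.start > self.right.start:
            raise ValueError(f"{self.id}: left read must not start after right read")
        for o in (self.left_orient, self.right_orient):
            if o not in ("+", "-"):
                raise ValueError(f"{self.id}: orientation must be '+' or '-', got {o!r}")

    @property
    def span(self) -> Interval:
        """Outer extent: left end of the left read to right end of the right read."""
        return Interval(self.left.start, max(self.left.end, self.right.end))

    @property
    def insert(self) -> int:
        return self.span.length

    @property
    def proper_orientation(self) -> bool:
        return self.left_orient == "+" and self.right_orient == "-"

    @property
    def br(self) -> Optional[Interval]:
        """Breakpoint region: the gap between the inner read ends.

        ``None`` when the reads overlap (no gap in which a deleted segment
        could lie).
        """
        if self.left.end > self.right.start:
            return None
        return Interval(self.left.end, self.right.start)


def classify_mapping(m: PairedMapping, lib: LibraryStats) -> str:
    """Classify a mapping as ``'concordant'``, ``'deletion'`` or ``'other'``.

    Orientation is tested first: improperly oriented pairs are ``'other'``
    regardless of distance.  A properly oriented pair is concordant when its
    insert lies within ``[min_len, max_len]`` and deletion-indicating when the
    insert exceeds ``max_len`` (and the reads leave a nonempty breakpoint
    region).  Pairs with insert below ``min_len`` — possible insertions — are
    ``'other'``: only deletions are modeled here.
    """
    if not m.proper_orientation:
        return "other"
    ins = m.insert
    if ins < lib.min_len:
        return "other"
    if ins <= lib.max_len:
        return "concordant"
    if m.br is None:
        return "other"
    return "deletion"


def deletion_bounds(m: PairedMapping, lib: LibraryStats) -> tuple[int, int]:
    """Deletion-size bracket ``(del_min, del_max)`` implied by a mapping.

    A fragment of insert size between ``min_len`` and ``max_len`` whose mapped
    span is ``|span|`` must straddle a deletion of at least
    ``|span| - max_len`` and at most ``|span| - min_len`` bases.

    Raises ``ValueError`` if the mapping is not deletion-indicating.
    """
    if classify_mapping(m, lib) != "deletion":
        raise ValueError(f"{m.id}: not a deletion-indicating mapping (insert {m.insert})")
    return m.insert - lib.max_len, m.insert - lib.min_len


@dataclass(frozen=True)
class DeletionCluster:
    """A valid set of deletion-indicating mappings, summarized.

    ``br`` is the intersection of the members' breakpoint regions, ``del_min``
    the largest and ``del_max`` the smallest member deletion-size bound, and
    ``span_hull`` the union hull of the member spans (the region the cluster's
    reads block for other deletions).  Validity of the member set means
    ``del_min <= del_max`` and ``del_min <= br.length``.
    """

    id: str
    chrom: str
    member_ids: tuple[str, ...]
    br: Interval
    del_min: int
    del_max: int
    span_hull: Interval
    n_normal: int = 0
    n_tumor: int = 0

    @property
    def support(self) -> int:
        return len(self.member_ids)

    @property
    def del_range_width(self) -> int:
        return self.del_max - self.del_min

    def extended(
        self, mappings: Sequence[PairedMapping], lib: LibraryStats, new_id: str | None = None
    ) -> Optional["DeletionCluster"]:
        """The cluster grown by ``mappings``, or ``None`` if the union is invalid.

        Works on the cluster's aggregate statistics, so the original member
        mappings need not be available.
        """
        br: Optional[Interval] = self.br
        dmin, dmax = self.del_min, self.del_max
        hull = self.span_hull
        n_norm, n_tum = self.n_normal, self.n_tumor
        for m in mappings:
            b = m.br
            if b is None or br is None:
                return None
            br = br.intersect(b)
            lo, hi = deletion_bounds(m, lib)
            dmin, dmax = max(dmin, lo), min(dmax, hi)
            hull = hull.hull(m.span)
            if m.source == "tumor":
                n_tum += 1
            else:
                n_norm += 1
        if br is None or dmin > dmax or dmin > br.length:
            return None
        return DeletionCluster(
            id=new_id if new_id is not None else self.id,
            chrom=self.chrom,
            member_ids=self.member_ids + tuple(m.id for m in mappings),
            br=br,
            del_min=dmin,
            del_max=dmax,
            span_hull=hull,
            n_normal=n_norm,
            n_tumor=n_tum,
        )


def _cluster_stats(
    ms: Sequence[PairedMapping], lib: LibraryStats
) -> Optional[tuple[Interval, int, int, Interval]]:
    """``(br, del_min, del_max, span_hull)`` of a mapping set, ``None`` if invalid."""
    if not ms:
        raise ValueError("empty mapping set")
    chrom = ms[0].chrom
    br: Optional[Interval] = None
    dmin = dmax = 0
    hull: Optional[Interval] = None
    for i, m in enumerate(ms):
        if m.chrom != chrom:
            raise ValueError("cluster members must share one chromosome")
        b = m.br
        if b is None:
            return None
        lo, hi = deletion_bounds(m, lib)
        if i == 0:
            br, dmin, dmax, hull = b, lo, hi, m.span
        else:
            assert br is not None and hull is not None
            br = br.intersect(b)
            if br is None:
                return None
            dmin, dmax = max(dmin, lo), min(dmax, hi)
            hull = hull.hull(m.span)
    assert br is not None and hull is not None
    if dmin > dmax or dmin > br.length:
        return None
    return br, dmin, dmax, hull


def is_valid_cluster(ms: Sequence[PairedMapping], lib: LibraryStats) -> bool:
    """Whether the mappings admit one common deletion length.

    True iff the breakpoint regions intersect nonemptily, the deletion-size
    brackets intersect (``max del_min <= min del_max``), and the shared
    breakpoint region is long enough (``max del_min <= |br|``).

    Raises ``ValueError`` on an empty set.
    """
    return _cluster_stats(list(ms), lib) is not None


def cluster_from_mappings(
    cluster_id: str, ms: Sequence[PairedMapping], lib: LibraryStats
) -> DeletionCluster:
    """Build a :class:`DeletionCluster`; raises ``ValueError`` if invalid."""
    ms = list(ms)
    stats = _cluster_stats(ms, lib)
    if stats is None:
        raise ValueError(f"{cluster_id}: mapping set is not a valid cluster")
    br, dmin, dmax, hull = stats
    return DeletionCluster(
        id=cluster_id,
        chrom=ms[0].chrom,
        member_ids=tuple(m.id for m in ms),
        br=br,
        del_min=dmin,
        del_max=dmax,
        span_hull=hull,
        n_normal=sum(1 for m in ms if m.source != "tumor"),
        n_tumor=sum(1 for m in ms if m.source == "tumor"),
    )
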