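"""Random-instance generators for oracle-equivalence tests.

All generators take an explicit ``numpy`` Generator so tests are seeded and
reproducible.  Geometry is kept small (windows of a few hundred bases) so the
brute-force oracles stay fast.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from condel.conflicts import Node
from condel.core import DeletionCluster, Interval, LibraryStats, PairedMapping
from condel.core import cluster_from_mappings

TEST_LIB = LibraryStats(min_len=100, max_len=200)


def deletion_mapping(
    ident: str,
    span_start: int,
    span_len: int,
    read_len: int = 20,
    chrom: str = "chr1",
    source: str = "normal",
    quality: int = 60,
) -> PairedMapping:
    """A deletion-indicating mapping with the given outer span."""
    assert span_len > 2 * read_len
    return PairedMapping(
        id=ident,
        chrom=chrom,
        left=Interval(span_start, span_start + read_len),
        right=Interval(span_start + span_len - read_len, span_start + span_len),
        left_orient="+",
        right_orient="-",
        quality=quality,
        source=source,
    )


def random_deletion_mappings(
    rng: np.random.Generator,
    n: int,
    lib: LibraryStats = TEST_LIB,
    window: int = 500,
    source: str = "normal",
) -> list[PairedMapping]:
    """Deletion-type mappings crowded into one window so clusters interact."""
    out = []
    for i in range(n):
        span_len = int(lib.max_len + rng.integers(1, 350))
        start = int(rng.integers(0, window))
        out.append(deletion_mapping(f"m{i}", start, span_len, source=source))
    return out


def random_cluster_node(
    rng: np.random.Generator, ident: str, window: int = 400
) -> Node:
    """A node shaped like a valid deletion cluster.

    Its breakpoint region lies inside the blocked read hull and the demand
    never exceeds the breakpoint-region length (as validity guarantees).
    """
    br_start = int(rng.integers(0, window))
    br_len = int(rng.integers(40, 220))
    pad_l = int(rng.integers(10, 120))
    pad_r = int(rng.integers(10, 120))
    demand = int(rng.integers(1, br_len + 1))
    return Node(
        id=ident,
        kind="cluster",
        blocked=Interval(br_start - pad_l, br_start + br_len + pad_r),
        demand=demand,
        br=Interval(br_start, br_start + br_len),
    )


def random_concordant_node(
    rng: np.random.Generator, ident: str, window: int = 400
) -> Node:
    start = int(rng.integers(0, window))
    length = int(rng.integers(80, 250))
    return Node(id=ident, kind="concordant", blocked=Interval(start, start + length))


def random_haploid_config(
    rng: np.random.Generator,
    n_clusters: int,
    n_concordant: int = 0,
    window: int = 400,
) -> list[Node]:
    nodes = [random_cluster_node(rng, f"c{i}", window) for i in range(n_clusters)]
    nodes += [random_concordant_node(rng, f"s{i}", window) for i in range(n_concordant)]
    return nodes


def supporting_mapping(
    rng: np.random.Generator,
    ident: str,
    segment: Interval,
    lib: LibraryStats = TEST_LIB,
    read_len: int = 20,
    source: str = "tumor",
) -> PairedMapping:
    """A mapping whose implied deletion is exactly ``segment``."""
    flen = int(rng.integers(lib.min_len, lib.max_len + 1))
    off = int(rng.integers(read_len, flen - read_len + 1))
    span_start = segment.start - off
    span_len = flen + segment.length
    return deletion_mapping(ident, span_start, span_len, read_len, source=source)


def random_component(
    rng: np.random.Generator,
    max_tumor: int = 8,
    lib: LibraryStats = TEST_LIB,
) -> tuple[DeletionCluster, list[PairedMapping]]:
    """A normal deletion cluster plus a mixed bag of tumor deletion mappings.

    The tumor mappings are a mixture of supporters of the normal deletion,
    mappings calling nearby or overlapping deletions, and unconstrained
    discordant mappings — enough structure that some instances need discards
    and others do not.
    """
    seg_len = int(rng.integers(120, 320))
    segment = Interval(600, 600 + seg_len)
    normal = [
        supporting_mapping(rng, f"n{i}", segment, lib, source="normal")
        for i in range(int(rng.integers(1, 4)))
    ]
    c = cluster_from_mappings("c", normal, lib)

    k = int(rng.integers(1, max_tumor + 1))
    tumor: list[PairedMapping] = []
    for i in range(k):
        kind = rng.random()
        if kind < 0.4:  # supporter
            tumor.append(supporting_mapping(rng, f"t{i}", segment, lib))
        elif kind < 0.8:  # nearby or overlapping second deletion
            gap = int(rng.integers(-seg_len // 2, 250))
            size2 = int(rng.integers(120, 320))
            s2 = Interval(segment.end + gap, segment.end + gap + size2)
            tumor.append(supporting_mapping(rng, f"t{i}", s2, lib))
        else:  # unconstrained discordant mapping over the same region
            span_len = int(lib.max_len + rng.integers(1, 400))
            start = int(segment.start - rng.integers(0, 300))
            tumor.append(deletion_mapping(f"t{i}", start, span_len, source="tumor"))
    return c, tumor
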