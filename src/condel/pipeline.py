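"""End-to-end orchestration: estimate -> cluster -> conflicts -> assign -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from intervaltree import IntervalTree

from . import conflicts as cf
from .assignment import (
    AssignmentResult,
    OverlappingComponent,
    build_components,
    assign_component,
)
from .clustering import DEFAULT_MAX_CLUSTERS, enumerate_maximal_valid_clusters
from .core import DeletionCluster, LibraryStats, PairedMapping, classify_mapping
from .io import estimate_insert_bounds

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "normal_conflict_summary"]

DEFAULT_SUPPORT_THRESHOLD = 20


@dataclass
class PipelineResult:
    """Artifacts of one matched normal/tumor analysis."""

    lib: LibraryStats
    normal_clusters: list[DeletionCluster]
    clustering_skipped: dict[str, str]
    conflicting_cluster_ids: set[str]
    conflict_triplets: list[frozenset[str]]
    components: list[OverlappingComponent]
    dropped_components: list[tuple[str, str]]
    assignments: list[AssignmentResult]
    summary: dict[str, object] = field(default_factory=dict)


def normal_conflict_summary(
    clusters: Sequence[DeletionCluster],
    concordant: Sequence[PairedMapping],
) -> tuple[list[frozenset[str]], set[str]]:
    """Diploid-level conflicts among clusters, per chromosome.

    Uses the pairwise-conflicting-triplet certificate (complete diploid
    checking is NP-hard): a cluster is counted as conflicting when it appears
    in a triple of nodes — at most one of them a concordant mapping — whose
    three pairs each conflict on one chromosome copy.  Concordant mappings
    not overlapping any cluster's read footprint cannot participate and are
    filtered out first.
    """
    by_chrom: dict[str, list[DeletionCluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, []).append(c)
    conc_by_chrom: dict[str, list[PairedMapping]] = {}
    for m in concordant:
        conc_by_chrom.setdefault(m.chrom, []).append(m)

    triplets: list[frozenset[str]] = []
    involved: set[str] = set()
    for chrom, cl in by_chrom.items():
        tree = IntervalTree()
        for c in cl:
            tree.addi(c.span_hull.start, c.span_hull.end, c.id)
        nodes_conc = []
        for m in conc_by_chrom.get(chrom, ()):
            if tree.overlap(m.span.start, m.span.end):
                nodes_conc.append(cf.Node.from_concordant(m))
        nodes_cl = [cf.Node.from_cluster(c) for c in cl]
        trips = cf.diploid_conflict_triplets(nodes_cl, nodes_conc)
        triplets.extend(trips)
        cluster_ids = {c.id for c in cl}
        for t in trips:
            involved.update(t & cluster_ids)
    return triplets, involved


def run_pipeline(
    normal_mappings: Sequence[PairedMapping],
    tumor_mappings: Sequence[PairedMapping],
    lib: Optional[LibraryStats] = None,
    q_low: float = 0.001,
    q_high: float = 0.999,
    max_clusters: int = DEFAULT_MAX_CLUSTERS,
    time_limit: float = 600.0,
    overlap_on: str = "span",
    support_threshold: int = DEFAULT_SUPPORT_THRESHOLD,
    concordant_constrain: bool = False,
) -> PipelineResult:
    """Run the full matched-pair analysis on already-loaded mappings.

    When ``lib`` is not given, insert-size cutoffs are estimated from the
    properly oriented pairs of the normal sample as nearest-rank
    ``q_low``/``q_high`` quantiles.  All stages sort internally, so the
    result is invariant to input record order.
    """
    if lib is None:
        inserts = [m.insert for m in normal_mappings if m.proper_orientation]
        lib = estimate_insert_bounds(inserts, q_low=q_low, q_high=q_high)
        logger.info("estimated insert bounds: min_len=%d max_len=%d", lib.min_len, lib.max_len)

    normal_del = [m for m in normal_mappings if classify_mapping(m, lib) == "deletion"]
    normal_conc = [m for m in normal_mappings if classify_mapping(m, lib) == "concordant"]
    clustering = enumerate_maximal_valid_clusters(normal_del, lib, max_clusters=max_clusters)
    for chrom, msg in clustering.skipped.items():
        logger.warning("clustering %s: %s", chrom, msg)

    triplets, conflicting = normal_conflict_summary(clustering.clusters, normal_conc)

    components, dropped = build_components(
        clustering.clusters, tumor_mappings, lib, overlap_on=overlap_on
    )
    by_id = {c.id: c for c in clustering.clusters}
    assignments = []
    for comp in components:
        r = assign_component(
            comp,
            by_id[comp.normal_cluster_id],
            lib,
            time_limit=time_limit,
            concordant_constrain=concordant_constrain,
        )
        logger.info(
            "%s: |M|=%d |S|=%d l=%d |D|=%d %s",
            comp.id,
            len(comp.deletion_mappings),
            len(r.support_ids),
            len(r.tumor_clusters),
            r.n_discarded,
            r.status,
        )
        assignments.append(r)

    n_cl = len(clustering.clusters)
    big = [c for c in clustering.clusters if c.support >= support_threshold]
    n_subset = sum(len(c.deletion_mappings) for c in components)
    n_support = sum(len(r.support_ids) for r in assignments)
    n_disc = sum(r.n_discarded for r in assignments)
    tumor_specific = [tc for r in assignments for tc in r.tumor_clusters]
    summary: dict[str, object] = {
        "min_len": lib.min_len,
        "max_len": lib.max_len,
        "normal_deletion_mappings": len(normal_del),
        "normal_clusters": n_cl,
        "normal_conflicting": len(conflicting),
        "normal_conflicting_pct": 100.0 * len(conflicting) / n_cl if n_cl else 0.0,
        f"normal_clusters_ge_{support_threshold}": len(big),
        f"normal_conflicting_ge_{support_threshold}": sum(
            1 for c in big if c.id in conflicting
        ),
        "components": len(components),
        "components_dropped": len({cid for cid, _ in dropped}),
        "tumor_subset_mappings": n_subset,
        "supporting_mappings": n_support,
        "discarded_mappings": n_disc,
        "discarded_pct": 100.0 * n_disc / n_subset if n_subset else 0.0,
        "refined_normal_clusters": sum(1 for r in assignments if r.support_ids),
        "tumor_specific_clusters": len(tumor_specific),
        "time_limited_components": sum(1 for r in assignments if r.status == "time_limited"),
    }
    return PipelineResult(
        lib=lib,
        normal_clusters=clustering.clusters,
        clustering_skipped=clustering.skipped,
        conflicting_cluster_ids=conflicting,
        conflict_triplets=triplets,
        components=components,
        dropped_components=dropped,
        assignments=assignments,
        summary=summary,
    )
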