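"""Reading and writing mappings, clusters and assignment reports.

Two mapping dialects are supported:

* **SAM/BAM** (via :mod:`pysam`): properly paired primary alignments are
  joined by query name; coordinates are converted from SAM to the package's
  0-based half-open convention at this boundary.
* **ESP-TSV**: one pair per line, tab-separated —
  ``id  chrom  left_start  left_end  left_orient  right_start  right_end
  right_orient  quality`` — a plain-text exchange format mirroring the
  paired-end support files produced by classical SV preprocessors.

Cluster and assignment reports are TSV, with a companion BED file of
breakpoint regions for clusters.
"""

from __future__ import annotations

import logging
import math
import os
from typing import Iterable, Optional, Sequence

from .core import DeletionCluster, Interval, LibraryStats, PairedMapping

logger = logging.getLogger(__name__)

__all__ = [
    "read_mappings",
    "read_esp",
    "write_esp",
    "estimate_insert_bounds",
    "write_clusters",
    "read_clusters",
    "write_assignment",
]

_ESP_COLUMNS = 9


def read_esp(path: str, min_quality: int = 20, source: str = "normal") -> list[PairedMapping]:
    """Read ESP-TSV mappings, dropping pairs below ``min_quality``.

    Lines starting with ``#`` are comments.  Malformed lines raise
    ``ValueError`` naming the line number.  Reads are normalized so the left
    read is the leftmost one.
    """
    mappings: list[PairedMapping] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _ESP_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_ESP_COLUMNS} tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                pid, chrom = fields[0], fields[1]
                ls, le = int(fields[2]), int(fields[3])
                lo = fields[4]
                rs, re_ = int(fields[5]), int(fields[6])
                ro = fields[7]
                qual = int(fields[8])
                if min(ls, le, rs, re_) < 0:
                    raise ValueError("negative coordinate")
                if rs < ls:  # normalize read order
                    (ls, le, lo), (rs, re_, ro) = (rs, re_, ro), (ls, le, lo)
                m = PairedMapping(
                    id=pid, chrom=chrom,
                    left=Interval(ls, le), right=Interval(rs, re_),
                    left_orient=lo, right_orient=ro,
                    quality=qual, source=source,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed ESP record: {exc}") from exc
            if m.quality < min_quality:
                n_dropped += 1
                continue
            mappings.append(m)
    if n_dropped:
        logger.info("%s: dropped %d pairs below quality %d", path, n_dropped, min_quality)
    if not mappings:
        logger.warning("%s: no mappings passed the filters", path)
    return mappings


def _read_sam(path: str, mode: str, min_quality: int, source: str) -> list[PairedMapping]:
    import pysam

    mappings: list[PairedMapping] = []
    n_dropped = n_unpaired = n_interchrom = 0
    pending: dict[str, object] = {}
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if (
                rec.is_unmapped
                or rec.mate_is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or not rec.is_paired
            ):
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            a, b = (mate, rec) if mate.reference_start <= rec.reference_start else (rec, mate)
            if a.reference_id != b.reference_id:
                n_interchrom += 1
                continue
            qual = min(a.mapping_quality, b.mapping_quality)
            m = PairedMapping(
                id=a.query_name,
                chrom=a.reference_name,
                left=Interval(a.reference_start, a.reference_end),
                right=Interval(b.reference_start, b.reference_end),
                left_orient="-" if a.is_reverse else "+",
                right_orient="-" if b.is_reverse else "+",
                quality=qual,
                source=source,
            )
            if qual < min_quality:
                n_dropped += 1
                continue
            mappings.append(m)
    n_unpaired = len(pending)
    if n_unpaired:
        logger.warning("%s: skipped %d records without a primary mate", path, n_unpaired)
    if n_interchrom:
        logger.info("%s: skipped %d inter-chromosomal pairs", path, n_interchrom)
    if n_dropped:
        logger.info("%s: dropped %d pairs below quality %d", path, n_dropped, min_quality)
    return mappings


def read_mappings(
    path: str, format: str = "esp", min_quality: int = 20, source: str = "normal"
) -> list[PairedMapping]:
    """Read paired-end mappings from ``sam``, ``bam`` or ``esp`` input.

    Returns one :class:`PairedMapping` per properly paired record with mapping
    quality at or above ``min_quality``; dropped pairs are counted in the log.
    """
    if format == "esp":
        return read_esp(path, min_quality=min_quality, source=source)
    if format == "sam":
        return _read_sam(path, "r", min_quality, source)
    if format == "bam":
        return _read_sam(path, "rb", min_quality, source)
    raise ValueError(f"unknown mapping format {format!r}")


def write_esp(mappings: Iterable[PairedMapping], path: str) -> None:
    """Write mappings as ESP-TSV (inverse of :func:`read_esp`)."""
    with open(path, "w") as fh:
        for m in mappings:
            fh.write(
                f"{m.id}\t{m.chrom}\t{m.left.start}\t{m.left.end}\t{m.left_orient}\t"
                f"{m.right.start}\t{m.right.end}\t{m.right_orient}\t{m.quality}\n"
            )


def estimate_insert_bounds(
    inserts: Sequence[int],
    q_low: float = 0.001,
    q_high: float = 0.999,
    quality_min: int = 20,
) -> LibraryStats:
    """Estimate concordance cutoffs as nearest-rank quantiles of insert sizes.

    ``min_len`` is the ``q_low``-quantile and ``max_len`` the ``q_high``-
    quantile of the given insert lengths (nearest-rank: the value at 1-based
    rank ``ceil(q * n)``), keeping the cutoffs on observed integer values.

    Raises ``ValueError`` on empty input.
    """
    if not len(inserts):
        raise ValueError("cannot estimate insert bounds from an empty sample")
    if not (0.0 <= q_low < q_high <= 1.0):
        raise ValueError(f"need 0 <= q_low < q_high <= 1, got ({q_low}, {q_high})")
    xs = sorted(int(x) for x in inserts)
    n = len(xs)

    def nearest_rank(q: float) -> int:
        return xs[max(1, math.ceil(q * n)) - 1]

    return LibraryStats(
        min_len=nearest_rank(q_low),
        max_len=nearest_rank(q_high),
        quality_min=quality_min,
        q_low=q_low,
        q_high=q_high,
    )


_CLUSTER_HEADER = (
    "cluster_id\tchrom\tbr_start\tbr_end\tdel_min\tdel_max\tsupport\t"
    "n_normal\tn_tumor\thull_start\thull_end\tconflict_flag\tmembers"
)


def write_clusters(
    clusters: Sequence[DeletionCluster],
    path: str,
    bed_path: Optional[str] = None,
    conflict_flags: Optional[dict[str, bool]] = None,
) -> None:
    """Write clusters as TSV plus a companion BED file of breakpoint regions.

    ``conflict_flags`` optionally marks clusters involved in at least one
    conflict.  ``bed_path`` defaults to ``path`` with a ``.bed`` suffix.
    """
    flags = conflict_flags or {}
    if bed_path is None:
        bed_path = os.path.splitext(path)[0] + ".bed"
    with open(path, "w") as fh:
        fh.write(_CLUSTER_HEADER + "\n")
        for c in clusters:
            fh.write(
                f"{c.id}\t{c.chrom}\t{c.br.start}\t{c.br.end}\t{c.del_min}\t{c.del_max}\t"
                f"{c.support}\t{c.n_normal}\t{c.n_tumor}\t"
                f"{c.span_hull.start}\t{c.span_hull.end}\t"
                f"{int(bool(flags.get(c.id, False)))}\t{','.join(c.member_ids)}\n"
            )
    with open(bed_path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.chrom}\t{c.br.start}\t{c.br.end}\t{c.id}\n")


def read_clusters(path: str) -> list[DeletionCluster]:
    """Read a cluster TSV written by :func:`write_clusters`."""
    clusters: list[DeletionCluster] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _CLUSTER_HEADER:
            raise ValueError(f"{path}: unrecognized cluster TSV header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(_CLUSTER_HEADER.split("\t")):
                raise ValueError(f"{path}:{lineno}: malformed cluster row")
            clusters.append(
                DeletionCluster(
                    id=f[0], chrom=f[1],
                    br=Interval(int(f[2]), int(f[3])),
                    del_min=int(f[4]), del_max=int(f[5]),
                    member_ids=tuple(f[12].split(",")) if f[12] else (),
                    n_normal=int(f[7]), n_tumor=int(f[8]),
                    span_hull=Interval(int(f[9]), int(f[10])),
                )
            )
    return clusters


def write_assignment(results: Sequence["AssignmentResult"], path: str) -> None:
    """Write per-component assignment results as a mapping-level TSV.

    One row per mapping involved in a component, labeled ``refined_normal``
    (supports the patient deletion), ``tumor_specific:<k>`` (member of the
    k-th tumor-specific cluster, with its tumor chromosome copy),
    ``concordant_normal`` or ``discarded``.
    """
    with open(path, "w") as fh:
        fh.write("component\tmapping_id\tlabel\tcluster_id\tcopy\tstatus\n")
        for r in results:
            comp = r.component_id
            for mid in r.refined_normal.member_ids:
                fh.write(f"{comp}\t{mid}\trefined_normal\t{r.refined_normal.id}\t.\t{r.status}\n")
            for k, tc in enumerate(r.tumor_clusters, start=1):
                copy = r.copy_of[tc.id]
                for mid in tc.member_ids:
                    fh.write(f"{comp}\t{mid}\ttumor_specific:{k}\t{tc.id}\t{copy}\t{r.status}\n")
            for mid in r.normal_concordant_ids:
                fh.write(f"{comp}\t{mid}\tconcordant_normal\t.\t.\t{r.status}\n")
            for mid in r.discarded_ids:
                fh.write(f"{comp}\t{mid}\tdiscarded\t.\t.\t{r.status}\n")
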