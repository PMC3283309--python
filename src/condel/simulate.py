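"""Synthetic matched normal/tumor paired-end mappings with ground truth.

The generator emulates the data model the detector assumes: a diploid normal
genome (heterozygous patient deletions on one copy), a diploid tumor genome
derived from the normal copies plus heterozygous tumor-specific deletions,
and a contaminated tumor specimen whose fragments are drawn from all four
chromosome copies.  Fragment lengths follow a truncated normal distribution;
mapping coordinates are computed directly from the planted truth (the method
under test begins after read mapping, so no alignment is simulated).  Reads
that would cross a deletion junction (split reads) are dropped rather than
modeled.

Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import Interval, PairedMapping

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "RecoveryReport",
    "simulate_dataset",
    "evaluate_recovery",
]

COPIES = ("normal_1", "normal_2", "tumor_1", "tumor_2")


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of one simulated matched-pair experiment.

    Defaults model a small genomic region sequenced the way the detector
    expects: 0.5 Mb of reference, ten heterozygous patient deletions of
    500-2000 bases, five tumor-specific deletions planted next to patient
    ones, a 300 +/- 30 base insert library with 50-base reads, 20x physical
    coverage for the normal sample and 40x for the tumor sample, and a tumor
    specimen containing 30% normal cells.
    """

    ref_length: int = 500_000
    n_normal_deletions: int = 10
    n_tumor_deletions: int = 5
    deletion_size_range: tuple[int, int] = (500, 2000)
    frag_mean: float = 300.0
    frag_sd: float = 30.0
    read_len: int = 50
    coverage_normal: float = 20.0
    coverage_tumor: float = 40.0
    contamination: float = 0.3
    proximity_bias: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.ref_length, self.read_len) <= 0 or self.frag_mean <= 0 or self.frag_sd < 0:
            raise ValueError("sizes must be positive")
        if self.deletion_size_range[0] <= 0 or (
            self.deletion_size_range[0] > self.deletion_size_range[1]
        ):
            raise ValueError("bad deletion size range")
        if not (0.0 <= self.contamination <= 1.0):
            raise ValueError("contamination must be in [0, 1]")
        if not (0.0 <= self.proximity_bias <= 1.0):
            raise ValueError("proximity_bias must be in [0, 1]")
        if self.frag_mean <= 2 * self.read_len:
            raise ValueError("frag_mean must exceed twice the read length")


@dataclass
class SimulationTruth:
    """Planted deletions per chromosome copy and per-mapping provenance."""

    params: SimulationParams
    deletions: dict[str, list[Interval]]  # reference coordinates, per copy
    mapping_origin: dict[str, str]  # mapping id -> copy name
    frag_len_min: int  # extremes over all fragments kept, both samples
    frag_len_max: int

    @property
    def normal_deletions(self) -> list[Interval]:
        """Patient deletions (present on normal copy 2 and tumor copy 2)."""
        return list(self.deletions["normal_2"])

    @property
    def tumor_specific_deletions(self) -> list[Interval]:
        """Deletions present only in the tumor genome (on tumor copy 1)."""
        return [d for d in self.deletions["tumor_1"] if d not in self.deletions["normal_1"]]


def _place_intervals(
    rng: np.random.Generator,
    ref_length: int,
    n: int,
    size_range: tuple[int, int],
    margin: int,
    avoid: Sequence[Interval],
) -> list[Interval]:
    """Plant n non-overlapping intervals, each >= margin away from everything."""
    placed: list[Interval] = []
    taken = list(avoid)
    for _ in range(n):
        for _attempt in range(10_000):
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            if ref_length - size - 2 * margin <= 0:
                raise ValueError("deletions do not fit into the reference")
            start = int(rng.integers(margin, ref_length - size - margin))
            cand = Interval(start, start + size)
            pad = Interval(max(0, start - margin), min(ref_length, cand.end + margin))
            if all(not pad.overlaps(t) for t in taken):
                placed.append(cand)
                taken.append(cand)
                break
        else:
            raise ValueError("could not place deletions; reference too crowded")
    return placed


def _place_tumor_deletions(
    rng: np.random.Generator, params: SimulationParams, normal_dels: list[Interval]
) -> list[Interval]:
    """Tumor-specific deletions, planted next to patient deletions with
    probability ``proximity_bias`` (gap of one to three read lengths), else
    placed independently far from everything."""
    p = params
    placed: list[Interval] = []
    taken = list(normal_dels)
    far_margin = int(4 * p.frag_mean)
    anchors = list(normal_dels)
    rng.shuffle(anchors)
    for k in range(p.n_tumor_deletions):
        size = int(rng.integers(p.deletion_size_range[0], p.deletion_size_range[1] + 1))
        cand: Optional[Interval] = None
        if anchors and rng.random() < p.proximity_bias:
            for _attempt in range(200):
                anchor = anchors[k % len(anchors)]
                gap = int(rng.integers(p.read_len, 3 * p.read_len + 1))
                if rng.random() < 0.5:
                    start = anchor.end + gap
                else:
                    start = anchor.start - gap - size
                if start < 0 or start + size > p.ref_length:
                    continue
                c = Interval(start, start + size)
                if all(not c.overlaps(t) for t in placed) and all(
                    not c.overlaps(t) for t in taken
                ):
                    cand = c
                    break
        if cand is None:
            cand = _place_intervals(
                rng, p.ref_length, 1, (size, size), far_margin, taken + placed
            )[0]
        placed.append(cand)
    return sorted(placed, key=lambda d: d.start)


def _donor_junctions(dels: Sequence[Interval]) -> tuple[np.ndarray, np.ndarray, int]:
    """Donor-coordinate junction positions and post-junction offsets.

    A donor position d maps to reference position d + offset[k] where k is
    the number of junctions at or before d.
    """
    dels = sorted(dels, key=lambda d: d.start)
    junctions = []
    offsets = [0]
    removed = 0
    for d in dels:
        junctions.append(d.start - removed)
        removed += d.length
        offsets.append(removed)
    total_removed = removed
    return np.asarray(junctions, dtype=np.int64), np.asarray(offsets, dtype=np.int64), total_removed


def _fragments_from_copy(
    rng: np.random.Generator,
    params: SimulationParams,
    dels: Sequence[Interval],
    n_frags: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mapped read coordinates for fragments drawn from one chromosome copy.

    Returns (left_start, left_end, right_start, right_end, frag_len) arrays in
    reference coordinates, with junction-crossing reads dropped.
    """
    p = params
    junc, offs, removed = _donor_junctions(dels)
    donor_len = p.ref_length - removed
    flen = np.rint(rng.normal(p.frag_mean, p.frag_sd, size=n_frags)).astype(np.int64)
    flen = np.maximum(flen, 2 * p.read_len)
    flen = np.minimum(flen, donor_len)
    start = rng.integers(0, donor_len - flen + 1)
    a1, b1 = start, start + p.read_len  # left read, donor coords
    a2, b2 = start + flen - p.read_len, start + flen  # right read

    def ref(pos: np.ndarray) -> np.ndarray:
        return pos + offs[np.searchsorted(junc, pos, side="right")]

    # a read [a, b) crosses a junction j iff a < j < b
    def crosses(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        lo = np.searchsorted(junc, a, side="right")
        hi = np.searchsorted(junc, b - 1, side="right")
        return hi > lo

    keep = ~(crosses(a1, b1) | crosses(a2, b2))
    a1, b1, a2, b2, flen = a1[keep], b1[keep], a2[keep], b2[keep], flen[keep]
    ls = ref(a1)
    le = ref(b1 - 1) + 1
    rs = ref(a2)
    re_ = ref(b2 - 1) + 1
    return ls, le, rs, re_, flen


def _sample(
    rng: np.random.Generator,
    params: SimulationParams,
    copy_dels: dict[str, list[Interval]],
    weights: dict[str, float],
    coverage: float,
    prefix: str,
    source: str,
    origin: dict[str, str],
) -> tuple[list[PairedMapping], list[int]]:
    p = params
    n_total = int(round(coverage * p.ref_length / p.frag_mean))
    copies = [c for c in COPIES if c in weights]
    counts = rng.multinomial(n_total, [weights[c] for c in copies])
    mappings: list[PairedMapping] = []
    flens: list[int] = []
    serial = 0
    for copy_name, cnt in zip(copies, counts):
        if cnt == 0:
            continue
        ls, le, rs, re_, fl = _fragments_from_copy(rng, p, copy_dels[copy_name], int(cnt))
        flens.extend(int(x) for x in fl)
        for i in range(len(ls)):
            mid = f"{prefix}{serial:07d}"
            serial += 1
            mappings.append(
                PairedMapping(
                    id=mid,
                    chrom="chr1",
                    left=Interval(int(ls[i]), int(le[i])),
                    right=Interval(int(rs[i]), int(re_[i])),
                    left_orient="+",
                    right_orient="-",
                    quality=60,
                    source=source,
                )
            )
            origin[mid] = copy_name
    mappings.sort(key=lambda m: (m.span.start, m.id))
    return mappings, flens


def simulate_dataset(
    params: SimulationParams,
) -> tuple[list[PairedMapping], list[PairedMapping], SimulationTruth]:
    """Generate matched normal and tumor mapping sets plus ground truth.

    Patient deletions are planted heterozygously on normal copy 2 (inherited
    by tumor copy 2); tumor-specific deletions go on tumor copy 1.  The
    normal sample mixes its two copies evenly; the tumor sample draws a
    fraction ``contamination`` of its fragments from the normal copies.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    margin = int(4 * p.frag_mean)
    normal_dels = sorted(
        _place_intervals(rng, p.ref_length, p.n_normal_deletions, p.deletion_size_range,
                         margin, []),
        key=lambda d: d.start,
    )
    tumor_dels = _place_tumor_deletions(rng, p, normal_dels)

    copy_dels = {
        "normal_1": [],
        "normal_2": list(normal_dels),
        "tumor_1": list(tumor_dels),
        "tumor_2": list(normal_dels),
    }
    origin: dict[str, str] = {}
    normal_maps, flens_n = _sample(
        rng, p, copy_dels, {"normal_1": 0.5, "normal_2": 0.5},
        p.coverage_normal, "n", "normal", origin,
    )
    w = {
        "normal_1": p.contamination / 2,
        "normal_2": p.contamination / 2,
        "tumor_1": (1 - p.contamination) / 2,
        "tumor_2": (1 - p.contamination) / 2,
    }
    tumor_maps, flens_t = _sample(
        rng, p, copy_dels, w, p.coverage_tumor, "t", "tumor", origin
    )
    flens = flens_n + flens_t
    truth = SimulationTruth(
        params=p,
        deletions=copy_dels,
        mapping_origin=origin,
        frag_len_min=min(flens),
        frag_len_max=max(flens),
    )
    return normal_maps, tumor_maps, truth


@dataclass
class RecoveryReport:
    """How well a pipeline run recovered the planted truth."""

    n_tumor_specific_true: int
    n_tumor_specific_recovered: int
    n_deletion_mappings: int
    n_discarded: int
    n_normal_true: int
    n_normal_refined: int

    @property
    def tumor_recovery(self) -> float:
        if self.n_tumor_specific_true == 0:
            return 1.0
        return self.n_tumor_specific_recovered / self.n_tumor_specific_true

    @property
    def discarded_fraction(self) -> float:
        if self.n_deletion_mappings == 0:
            return 0.0
        return self.n_discarded / self.n_deletion_mappings

    @property
    def refined_fraction(self) -> float:
        if self.n_normal_true == 0:
            return 1.0
        return self.n_normal_refined / self.n_normal_true


def evaluate_recovery(
    truth: SimulationTruth, results: Sequence["AssignmentResult"]
) -> RecoveryReport:
    """Score assignment results against the planted truth.

    A tumor-specific deletion counts as recovered when some reported
    tumor-specific cluster's breakpoint region overlaps it and the cluster's
    deletion-size bracket covers its size.  A patient deletion counts as
    refined when the refined cluster overlapping it gained supporting tumor
    mappings.
    """
    tumor_clusters = [tc for r in results for tc in r.tumor_clusters]
    recovered = 0
    for d in truth.tumor_specific_deletions:
        if any(tc.br.overlaps(d) and tc.del_min <= d.length <= tc.del_max
               for tc in tumor_clusters):
            recovered += 1
    n_mappings = sum(
        len(r.support_ids)
        + sum(tc.support for tc in r.tumor_clusters)
        + r.n_discarded
        for r in results
    )
    n_discarded = sum(r.n_discarded for r in results)
    refined = 0
    for d in truth.normal_deletions:
        if any(
            r.refined_normal.br.overlaps(d) and len(r.support_ids) > 0 for r in results
        ):
            refined += 1
    return RecoveryReport(
        n_tumor_specific_true=len(truth.tumor_specific_deletions),
        n_tumor_specific_recovered=recovered,
        n_deletion_mappings=n_mappings,
        n_discarded=n_discarded,
        n_normal_true=len(truth.normal_deletions),
        n_normal_refined=refined,
    )
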