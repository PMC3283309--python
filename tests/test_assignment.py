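"""Overlapping components and the four-copy assignment optimization."""

import numpy as np
import pytest

from condel.assignment import (
    OverlappingComponent,
    assign_component,
    build_components,
    max_supporting_subset,
    refinement_ratios,
)
from condel.conflicts import Node, is_consistent_haploid
from condel.core import DeletionCluster, Interval, cluster_from_mappings
from .generators import (
    TEST_LIB,
    deletion_mapping,
    random_component,
    supporting_mapping,
)
from .oracles import max_support_exhaustive, min_discards_exhaustive


def make_component(c, tumor, concordant=()):
    foot = c.br
    for m in tumor:
        foot = foot.hull(m.span)
    return OverlappingComponent(
        id=f"comp_{c.id}", normal_cluster_id=c.id, chrom=c.chrom,
        deletion_mappings=tuple(tumor), concordant_mappings=tuple(concordant),
        footprint=foot,
    )


@pytest.fixture
def normal_cluster(rng):
    seg = Interval(600, 800)
    ms = [supporting_mapping(rng, f"n{i}", seg, source="normal") for i in range(2)]
    return cluster_from_mappings("c", ms, TEST_LIB), seg


class TestBuildComponents:
    def test_transitive_closure(self, rng, normal_cluster):
        c, seg = normal_cluster
        t1 = supporting_mapping(rng, "t1", seg)
        t2 = supporting_mapping(rng, "t2", seg)
        # t3 overlaps t1/t2 spans but not br(c)
        far_seg = Interval(seg.end + 150, seg.end + 400)
        t3 = deletion_mapping("t3", seg.end + 30, 520, source="tumor")
        lonely = deletion_mapping("t4", 5000, 400, source="tumor")
        comps, dropped = build_components([c], [t1, t2, t3, lonely], TEST_LIB)
        assert dropped == []
        (comp,) = comps
        ids = {m.id for m in comp.deletion_mappings}
        assert "t4" not in ids
        assert {"t1", "t2"} <= ids

    def test_far_mapping_in_no_component(self, rng, normal_cluster):
        c, seg = normal_cluster
        lonely = deletion_mapping("t", 9000, 400, source="tumor")
        comps, _ = build_components([c], [lonely], TEST_LIB)
        assert comps[0].deletion_mappings == ()

    def test_components_sharing_mapping_are_dropped(self, rng):
        seg_a, seg_b = Interval(600, 800), Interval(900, 1100)
        ca = cluster_from_mappings(
            "ca", [supporting_mapping(rng, "na", seg_a)], TEST_LIB)
        cb = cluster_from_mappings(
            "cb", [supporting_mapping(rng, "nb", seg_b)], TEST_LIB)
        # one tumor mapping overlapping both breakpoint regions
        bridge = deletion_mapping("tb", 500, 700, source="tumor")
        comps, dropped = build_components([ca, cb], [bridge], TEST_LIB)
        assert comps == []
        assert {cid for cid, _ in dropped} == {"ca", "cb"}

    def test_concordant_collected_by_footprint(self, rng, normal_cluster):
        c, seg = normal_cluster
        near = deletion_mapping("conc1", seg.start - 100, 150)
        far = deletion_mapping("conc2", 9000, 150)
        comps, _ = build_components([c], [near, far], TEST_LIB)
        assert [m.id for m in comps[0].concordant_mappings] == ["conc1"]


class TestMaxSupportingSubset:
    def test_examples(self, rng, normal_cluster):
        c, seg = normal_cluster
        good = supporting_mapping(rng, "ta", seg)
        # del_min far above c.del_max: span much longer
        bad = deletion_mapping("tb", seg.start - 100, seg.length + 800, source="tumor")
        assert [m.id for m in max_supporting_subset(c, [good, bad], TEST_LIB)] == ["ta"]
        assert max_supporting_subset(c, [], TEST_LIB) == []
        all_good = [supporting_mapping(rng, f"t{i}", seg) for i in range(4)]
        got = max_supporting_subset(c, all_good, TEST_LIB)
        assert {m.id for m in got} == {m.id for m in all_good}

    def test_matches_exhaustive(self, rng):
        for _ in range(40):
            c, tumor = random_component(rng, max_tumor=6)
            got = [m.id for m in max_supporting_subset(c, tumor, TEST_LIB)]
            assert got == max_support_exhaustive(c, tumor, TEST_LIB)


class TestAssignComponent:
    def test_all_supporting_means_no_tumor_clusters(self, rng, normal_cluster):
        c, seg = normal_cluster
        tumor = [supporting_mapping(rng, f"t{i}", seg) for i in range(5)]
        r = assign_component(make_component(c, tumor), c, TEST_LIB)
        assert r.tumor_clusters == ()
        assert r.discarded_ids == ()
        assert set(r.support_ids) == {m.id for m in tumor}
        assert r.status == "optimal"

    def test_incompatible_mappings_form_tumor_clusters(self, rng, normal_cluster):
        c, seg = normal_cluster
        # deletion size far outside c's bracket, so nothing can support c
        other = Interval(seg.end + 60, seg.end + 860)
        tumor = [supporting_mapping(rng, f"t{i}", other) for i in range(3)]
        r = assign_component(make_component(c, tumor), c, TEST_LIB)
        assert r.support_ids == ()
        assert len(r.tumor_clusters) == 1
        assert r.discarded_ids == ()
        tc = r.tumor_clusters[0]
        assert tc.br.contains(other) or tc.br.overlaps(other)
        assert tc.del_min <= other.length <= tc.del_max

    def test_validation_errors(self, rng, normal_cluster):
        c, seg = normal_cluster
        comp = make_component(c, [])
        with pytest.raises(ValueError):
            assign_component(comp, c, TEST_LIB, time_limit=0)
        broken = DeletionCluster(
            id="bad", chrom=c.chrom, member_ids=("x",),
            br=Interval(0, 10), del_min=50, del_max=40, span_hull=Interval(0, 100),
        )
        with pytest.raises(ValueError):
            assign_component(comp, broken, TEST_LIB)

    def test_partition_and_soundness_on_random_components(self, rng):
        for _ in range(25):
            c, tumor = random_component(rng)
            r = assign_component(make_component(c, tumor), c, TEST_LIB)
            # the deletion mappings are partitioned
            placed = set(r.support_ids) | set(r.discarded_ids)
            for tc in r.tumor_clusters:
                assert set(tc.member_ids).isdisjoint(placed)
                placed |= set(tc.member_ids)
            assert placed == {m.id for m in tumor}
            # every cluster is valid and each tumor copy is consistent
            for tc in r.tumor_clusters:
                assert tc.del_min <= tc.del_max <= tc.del_min + 10**9
                assert tc.del_min <= tc.br.length
            copy1 = [Node.from_cluster(r.refined_normal)] + [
                Node.from_cluster(tc) for tc in r.tumor_clusters
                if r.copy_of[tc.id] == 1
            ]
            copy2 = [
                Node.from_cluster(tc) for tc in r.tumor_clusters
                if r.copy_of[tc.id] == 2
            ]
            assert is_consistent_haploid(copy1)
            assert is_consistent_haploid(copy2)

    def test_discard_count_matches_exhaustive(self, rng):
        n_with_discards = 0
        for _ in range(30):
            c, tumor = random_component(rng, max_tumor=6)
            r = assign_component(make_component(c, tumor), c, TEST_LIB)
            assert r.status == "optimal"
            keep = set(r.support_ids)
            R = [m for m in tumor if m.id not in keep]
            want = min_discards_exhaustive(r.refined_normal, R, TEST_LIB)
            assert r.n_discarded == want
            n_with_discards += r.n_discarded > 0
        assert n_with_discards > 0  # the generator must exercise discards

    def test_determinism(self, rng):
        c, tumor = random_component(rng)
        comp = make_component(c, tumor)
        r1 = assign_component(comp, c, TEST_LIB)
        r2 = assign_component(comp, c, TEST_LIB)
        assert r1 == r2


def test_refinement_ratios(rng, normal_cluster):
    c, seg = normal_cluster
    assert refinement_ratios(c, c) == (1.0, 1.0)
    a = DeletionCluster(id="a", chrom="chr1", member_ids=("x",),
                        br=Interval(0, 380), del_min=220, del_max=320,
                        span_hull=Interval(0, 500))
    b = DeletionCluster(id="b", chrom="chr1", member_ids=("x", "y"),
                        br=Interval(40, 340), del_min=237, del_max=280,
                        span_hull=Interval(0, 500))
    del_ratio, br_ratio = refinement_ratios(a, b)
    assert del_ratio == pytest.approx(43 / 100)
    assert br_ratio == pytest.approx(300 / 380)


def test_refinement_shrinks_on_random_support(rng):
    for _ in range(20):
        c, tumor = random_component(rng)
        r = assign_component(make_component(c, tumor), c, TEST_LIB)
        d, b = refinement_ratios(
            DeletionCluster(id=c.id, chrom=c.chrom, member_ids=c.member_ids,
                            br=c.br, del_min=c.del_min, del_max=c.del_max,
                            span_hull=c.span_hull),
            r.refined_normal,
        )
        assert 0.0 <= d <= 1.0
        assert 0.0 < b <= 1.0
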