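"""Clustering, support thresholds, artifact filters and cross-sample merge."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longsv.germline import (
    DepthIndex,
    GermlineConfig,
    RepeatIndex,
    SegdupIndex,
    apply_region_filters,
    apply_support_filters,
    cluster_signatures,
    is_candidate,
    merge_across_samples,
    merge_candidate_breakpoints,
    required_support,
)
from longsv.model import (
    FilterFlag,
    ReadAlignment,
    RepeatInterval,
    SvCall,
    SvCluster,
    SvType,
)
from .conftest import make_signature

CFG = GermlineConfig()


def cluster_of(sv_type, pos1, length, read_ids, mapq=60, **kw):
    members = [
        make_signature(sv_type, pos1=pos1, length=length, read_id=r, mapq=mapq, **kw)
        for r in read_ids
    ]
    return SvCluster(sv_type=sv_type, members=members)


class TestClustering:
    def test_deletions_within_window_cluster_together(self):
        sigs = [
            make_signature(pos1=1000, read_id="a"),
            make_signature(pos1=1049, read_id="b"),
        ]
        assert len(cluster_signatures(sigs)) == 1

    def test_deletions_beyond_window_split(self):
        sigs = [
            make_signature(pos1=1000, read_id="a"),
            make_signature(pos1=1051, read_id="b"),
        ]
        assert len(cluster_signatures(sigs)) == 2

    def test_inversions_use_wider_window(self):
        sigs = [
            make_signature(SvType.INV, pos1=1000, length=5000, read_id="a"),
            make_signature(SvType.INV, pos1=1090, length=5000, read_id="b"),
        ]
        assert len(cluster_signatures(sigs)) == 1

    def test_singleton_is_not_a_candidate(self):
        clusters = cluster_signatures([make_signature(read_id="a")])
        assert len(clusters) == 1
        assert clusters[0].support == 1
        assert not is_candidate(clusters[0])

    def test_candidate_needs_two_confident_reads(self):
        low = cluster_of(SvType.DEL, 1000, 300, ["a", "b"], mapq=19)
        high = cluster_of(SvType.DEL, 1000, 300, ["a", "b"], mapq=20)
        assert not is_candidate(low)
        assert is_candidate(high)

    def test_representative_is_member_median(self):
        sigs = [
            make_signature(pos1=p, length=300, read_id=f"r{i}")
            for i, p in enumerate([1000, 1010, 1020])
        ]
        c = cluster_signatures(sigs)[0]
        assert c.pos1 == 1010

    @settings(max_examples=50, deadline=None)
    @given(st.permutations(list(range(8))))
    def test_clustering_is_order_invariant(self, order):
        base = [
            make_signature(pos1=1000 + 500 * (i // 2) + 7 * i, read_id=f"r{i}")
            for i in range(8)
        ]
        ref = cluster_signatures(base)
        permuted = cluster_signatures([base[i] for i in order])
        key = lambda cs: sorted(
            (c.pos1, tuple(sorted(m.read_id for m in c.members))) for c in cs
        )
        assert key(ref) == key(permuted)


class TestMerging:
    def test_close_overlapping_clusters_merge(self):
        a = cluster_of(SvType.DEL, 10_000, 6000, ["a", "b"])
        b = cluster_of(SvType.DEL, 10_900, 6000, ["c", "d"])
        merged = merge_candidate_breakpoints([a, b])
        assert len(merged) == 1
        assert merged[0].read_ids == {"a", "b", "c", "d"}

    def test_distant_clusters_stay_separate(self):
        a = cluster_of(SvType.DEL, 10_000, 8000, ["a", "b"])
        b = cluster_of(SvType.DEL, 11_100, 8000, ["c", "d"])
        assert len(merge_candidate_breakpoints([a, b])) == 2

    def test_low_overlap_prevents_merge(self):
        a = cluster_of(SvType.DEL, 10_000, 500, ["a", "b"])
        b = cluster_of(SvType.DEL, 10_400, 500, ["c", "d"])  # 20% overlap
        assert len(merge_candidate_breakpoints([a, b])) == 2

    def test_insertions_merge_by_length_ratio(self):
        a = cluster_of(SvType.INS, 10_000, 1000, ["a", "b"])
        b = cluster_of(SvType.INS, 10_200, 850, ["c", "d"])
        c = cluster_of(SvType.INS, 10_250, 500, ["e", "f"])  # ratio 0.5
        merged = merge_candidate_breakpoints([a, b, c])
        assert sorted(len(m.read_ids) for m in merged) == [2, 4]

    def test_insertion_window_is_300(self):
        a = cluster_of(SvType.INS, 10_000, 1000, ["a", "b"])
        b = cluster_of(SvType.INS, 10_350, 1000, ["c", "d"])
        assert len(merge_candidate_breakpoints([a, b])) == 2

    def test_merge_is_idempotent(self):
        a = cluster_of(SvType.DEL, 10_000, 600, ["a", "b"])
        b = cluster_of(SvType.DEL, 10_000, 600, ["a", "b"])
        once = merge_candidate_breakpoints([a, b])
        twice = merge_candidate_breakpoints(once)
        assert len(once) == len(twice) == 1
        assert once[0].read_ids == {"a", "b"}


class TestSupportFilters:
    @pytest.mark.parametrize(
        "sv_type,length,expected",
        [
            (SvType.DEL, 300, 4),
            (SvType.DEL, 500, 4),
            (SvType.DEL, 501, 3),
            (SvType.DEL, 1000, 3),
            (SvType.DEL, 1001, 2),
            (SvType.INS, 800, 3),
            (SvType.INS, 1001, 2),
            (SvType.INV, 2000, 2),
            (SvType.TRA_INTRA, 2000, 2),
        ],
    )
    def test_required_support_bands(self, sv_type, length, expected):
        assert required_support(sv_type, length, CFG) == expected

    def test_short_deletion_three_reads_fail_four_pass(self):
        three = apply_support_filters(cluster_of(SvType.DEL, 1000, 300, "abc"))
        four = apply_support_filters(cluster_of(SvType.DEL, 1000, 300, "abcd"))
        assert FilterFlag.LOW_SUPPORT in three.filter_flags
        assert FilterFlag.LOW_SUPPORT not in four.filter_flags

    def test_edge_of_read_support_discarded(self):
        # 4 reads, one with the event in the first 10% of the read
        members = [
            make_signature(pos1=1000, read_id=r, offset=off)
            for r, off in zip("abcd", [0.5, 0.5, 0.5, 0.05])
        ]
        call = apply_support_filters(SvCluster(SvType.DEL, members))
        assert call.support == 3
        assert FilterFlag.LOW_SUPPORT in call.filter_flags

    def test_deletion_with_nearby_insertion_discarded(self):
        # 800 bp deletion; one read carries an 85 bp insertion near the
        # breakpoint (85 >= 10% of 800) and is dropped
        members = [
            make_signature(pos1=1000, length=800, read_id=r,
                           nearby_ins_len=ins)
            for r, ins in zip("abcd", [0, 0, 0, 85])
        ]
        call = apply_support_filters(SvCluster(SvType.DEL, members))
        assert call.support == 3

    def test_long_deletion_tolerates_proportional_insertion(self):
        # 29% insertion on a >= 1000 bp deletion stays below the 30% bar
        members = [
            make_signature(pos1=1000, length=2000, read_id=r,
                           nearby_ins_len=580)
            for r in "ab"
        ]
        call = apply_support_filters(SvCluster(SvType.DEL, members))
        assert call.support == 2
        assert call.passes

    def test_large_insertion_rescued_by_clips_on_both_sides(self):
        members = [
            make_signature(SvType.INS, pos1=5000, length=1500, read_id="a")
        ]
        clips = [
            make_signature(SvType.CLIP, pos1=5000, length=0, read_id=r,
                           clip_side=side, offset=0.0)
            for r, side in [
                ("c1", "right"), ("c2", "right"), ("c3", "left"), ("c4", "left"),
            ]
        ]
        for c in clips:
            c.pos2 = c.pos1
        call = apply_support_filters(
            SvCluster(SvType.INS, members), clip_signatures=clips
        )
        assert FilterFlag.LOW_SUPPORT not in call.filter_flags


def flat_alignment(read_id, start, end, mapq=60):
    return ReadAlignment(
        read_id=read_id,
        chrom="chr1",
        start=start,
        end=end,
        strand="+",
        mapq=mapq,
        cigar=[("M", end - start)],
        read_length=end - start,
    )


def call_at(pos1=5000, pos2=5300, sv_type=SvType.DEL, support=4):
    return SvCall(
        id="c1",
        sample_id="S1",
        sv_type=sv_type,
        chrom1="chr1",
        pos1=pos1,
        chrom2="chr1",
        pos2=pos2,
        length=pos2 - pos1 if sv_type is not SvType.INS else 300,
        support=support,
    )


class TestRegionFilters:
    def test_vaf_computed_from_spanning_depth(self):
        depth = DepthIndex([flat_alignment(f"r{i}", 0, 10_000) for i in range(10)])
        call = apply_region_filters(call_at(support=4), depth)
        assert call.depth_at_breakpoint == 10
        assert call.vaf == pytest.approx(0.4)
        assert call.passes

    def test_low_vaf_flagged(self):
        depth = DepthIndex([flat_alignment(f"r{i}", 0, 10_000) for i in range(50)])
        call = apply_region_filters(call_at(support=1), depth)
        assert call.vaf == pytest.approx(0.02)
        assert FilterFlag.LOW_VAF in call.filter_flags

    def test_low_mapping_quality_region_flagged(self):
        # 10 spanning reads, 4 with MAPQ 20 -> 40% below MAPQ 30
        alns = [
            flat_alignment(f"r{i}", 0, 10_000, mapq=20 if i < 4 else 60)
            for i in range(10)
        ]
        call = apply_region_filters(call_at(support=4), DepthIndex(alns))
        assert FilterFlag.LOW_MQ_REGION in call.filter_flags

    def test_low_mq_under_threshold_passes(self):
        alns = [
            flat_alignment(f"r{i}", 0, 10_000, mapq=20 if i < 2 else 60)
            for i in range(10)
        ]
        call = apply_region_filters(call_at(support=4), DepthIndex(alns))
        assert FilterFlag.LOW_MQ_REGION not in call.filter_flags

    def test_inversion_in_tandem_repeat_flagged(self):
        depth = DepthIndex([flat_alignment(f"r{i}", 0, 20_000) for i in range(10)])
        repeats = RepeatIndex(
            [RepeatInterval("chr1", 4900, 9200, "Simple/Tandem", "(AT)n")]
        )
        call = apply_region_filters(
            call_at(5000, 10_000, SvType.INV, support=4), depth,
            repeat_index=repeats,
        )
        assert FilterFlag.REPEAT80 in call.filter_flags

    def test_deletion_exempt_from_repeat_filter_at_germline_stage(self):
        depth = DepthIndex([flat_alignment(f"r{i}", 0, 20_000) for i in range(10)])
        repeats = RepeatIndex(
            [RepeatInterval("chr1", 4900, 10_200, "Simple/Tandem", "(AT)n")]
        )
        call = apply_region_filters(
            call_at(5000, 10_000, SvType.DEL, support=4), depth,
            repeat_index=repeats,
        )
        assert FilterFlag.REPEAT80 not in call.filter_flags

    def test_breakpoints_in_same_segdup_flagged(self):
        depth = DepthIndex([flat_alignment(f"r{i}", 0, 40_000) for i in range(10)])
        segdup = SegdupIndex(
            [("chr1", 4000, 6000, "dup1"), ("chr1", 19_000, 21_000, "dup1")]
        )
        call = apply_region_filters(
            call_at(5000, 20_000, SvType.INV, support=4), depth,
            segdup_index=segdup,
        )
        assert FilterFlag.SEGDUP in call.filter_flags

    def test_different_segdups_not_flagged(self):
        depth = DepthIndex([flat_alignment(f"r{i}", 0, 40_000) for i in range(10)])
        segdup = SegdupIndex(
            [("chr1", 4000, 6000, "dup1"), ("chr1", 19_000, 21_000, "dup2")]
        )
        call = apply_region_filters(
            call_at(5000, 20_000, SvType.INV, support=4), depth,
            segdup_index=segdup,
        )
        assert FilterFlag.SEGDUP not in call.filter_flags


def sample_call(sample_id, vaf, pos1=5000, length=300):
    call = call_at(pos1, pos1 + length, SvType.DEL, support=5)
    call.sample_id = sample_id
    call.vaf = vaf
    return call


class TestPopulationMerge:
    def test_three_het_carriers_of_eleven_retained(self):
        callsets = {f"S{i}": [] for i in range(11)}
        for sid in ("S0", "S1", "S2"):
            callsets[sid] = [sample_call(sid, vaf=0.5)]
        pop = merge_across_samples(callsets, n_samples=11)
        assert len(pop) == 1
        assert pop[0].allele_count == 3
        assert pop[0].allele_frequency == pytest.approx(3 / 22)

    def test_two_het_carriers_dropped(self):
        callsets = {f"S{i}": [] for i in range(11)}
        for sid in ("S0", "S1"):
            callsets[sid] = [sample_call(sid, vaf=0.5)]
        assert merge_across_samples(callsets, n_samples=11) == []

    def test_single_homozygous_carrier_dropped(self):
        callsets = {f"S{i}": [] for i in range(11)}
        callsets["S0"] = [sample_call("S0", vaf=0.95)]
        assert merge_across_samples(callsets, n_samples=11) == []

    def test_homozygous_counts_two_alleles(self):
        callsets = {f"S{i}": [] for i in range(11)}
        callsets["S0"] = [sample_call("S0", vaf=0.95)]
        callsets["S1"] = [sample_call("S1", vaf=0.5)]
        pop = merge_across_samples(callsets, n_samples=11)
        assert len(pop) == 1 and pop[0].allele_count == 3

    def test_failing_calls_excluded_from_merge(self):
        bad = sample_call("S0", vaf=0.5)
        bad.filter_flags.add(FilterFlag.LOW_SUPPORT)
        pop = merge_across_samples({"S0": [bad]}, n_samples=1)
        assert pop == []


class TestEndToEnd:
    def test_all_spiked_svs_recovered(self, small_scenario, small_calls):
        """Spiked SVs at >= 10x with paper-like error are all called."""
        from longsv.evaluate import match_callsets

        sc, _ = small_scenario
        passing = [c for c in small_calls if c.passes]
        res = match_callsets(passing, sc.spike.truth)
        assert res.recall >= 0.9
        assert res.precision >= 0.9

    def test_support_reads_exist_in_input(self, small_scenario, small_calls):
        _, alignments = small_scenario
        known = {a.read_id for a in alignments}
        for call in small_calls:
            assert call.support_read_ids <= known

    def test_raising_min_vaf_never_grows_pass_set(self, small_scenario):
        from longsv.germline import call_sample

        _, alignments = small_scenario
        lax = {
            c.id for c in call_sample(alignments, GermlineConfig(min_vaf=0.03))
            if c.passes
        }
        strict = {
            c.id for c in call_sample(alignments, GermlineConfig(min_vaf=0.2))
            if c.passes
        }
        assert strict <= lax
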