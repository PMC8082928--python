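"""Repeat-annotation parsing and insertion-content classification."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longsv.model import RepeatInterval
from longsv.repeats import (
    classify_nonrepeat_insertion,
    classify_sv_sequence,
    parse_repeat_files,
    parse_repeatmasker_out,
    parse_trf_dat,
    union_covered,
)
from longsv.vcfio import Bed12Gene, PslRecord

RM_LINE = (
    " 1000  2.0  0.0  0.0  cons_01       11      300      (0) + AluYa5"
    "             SINE/Alu             1    290    (10)     1\n"
)
RM_COMPLEMENT_LINE = (
    "  900  3.1  0.1  0.0  cons_02        5     6000      (0) C L1HS"
    "               LINE/L1             (0)   6000    501     2\n"
)


class TestParsers:
    def test_empty_files(self, tmp_path):
        rm = tmp_path / "e.out"
        trf = tmp_path / "e.dat"
        rm.write_text("")
        trf.write_text("")
        assert parse_repeat_files(rm, trf) == []

    def test_repeatmasker_line(self, tmp_path):
        p = tmp_path / "r.out"
        p.write_text("header\nheader\n\n" + RM_LINE)
        (iv,) = parse_repeatmasker_out(p)
        assert iv.seq_id == "cons_01"
        assert (iv.start, iv.end) == (10, 300)
        assert iv.repeat_class == "SINE" and iv.family == "AluYa5"
        assert iv.consensus_start == 0  # hit starts at repeat base 1

    def test_repeatmasker_complement_strand(self, tmp_path):
        p = tmp_path / "r.out"
        p.write_text(RM_COMPLEMENT_LINE)
        (iv,) = parse_repeatmasker_out(p)
        assert iv.strand == "-"
        assert iv.repeat_class == "LINE"
        assert iv.consensus_start == 500  # 5'-truncated by 500 bases

    def test_trf_record(self, tmp_path):
        p = tmp_path / "t.dat"
        p.write_text(
            "Tandem Repeats Finder\n\nSequence: cons_03\n\n"
            "101 400 2 150.0 2 95 0 600 25 25 25 25 1.5 AT ATATAT\n"
        )
        (iv,) = parse_trf_dat(p)
        assert iv.seq_id == "cons_03"
        assert (iv.start, iv.end) == (100, 400)
        assert iv.repeat_class == "Simple/Tandem"
        assert iv.family == "(AT)n"

    def test_unparseable_lines_skipped(self, tmp_path):
        p = tmp_path / "r.out"
        p.write_text(RM_LINE + "garbage line that is not a hit\n" + RM_LINE)
        assert len(parse_repeatmasker_out(p)) == 2

    def test_simulator_output_parses_back(self, tmp_path):
        from longsv.sim.reference import (
            build_reference,
            write_repeatmasker_out,
            write_trf_dat,
        )

        build = build_reference(length=100_000, n_repeat_copies=10, seed=3)
        rm = tmp_path / "sim.out"
        trf = tmp_path / "sim.dat"
        write_repeatmasker_out(build.repeats, rm)
        write_trf_dat(build.tandem_sites, trf)
        parsed = parse_repeat_files(rm, trf)
        truth = sorted(
            (r.start, r.end, r.repeat_class, r.family) for r in build.repeats
        )
        got = sorted((r.start, r.end, r.repeat_class, r.family) for r in parsed)
        assert got == truth


def iv(start, end, klass="SINE", family="AluYa5", strand="+", cs=0):
    return RepeatInterval(
        seq_id="c", start=start, end=end, repeat_class=klass, family=family,
        strand=strand, consensus_start=cs,
    )


class TestClassification:
    def test_single_sine_covering_most_of_sequence(self):
        prof = classify_sv_sequence("A" * 300, [iv(5, 295)])
        assert prof.category == "single_SINE"
        assert prof.families == ["AluYa5"]

    def test_single_line(self):
        prof = classify_sv_sequence(
            "A" * 1000, [iv(10, 990, "LINE", "L1HS", cs=5000)]
        )
        assert prof.category == "single_LINE"
        assert prof.truncation_5prime == 5000

    def test_two_elements_jointly_covering(self):
        prof = classify_sv_sequence(
            "A" * 1000,
            [iv(0, 450, "LINE", "L1HS", "+"), iv(450, 900, "LINE", "L1HS", "-")],
        )
        assert prof.category == "multi_repeat"
        assert prof.twin_priming  # two LINE segments on opposite strands

    def test_same_strand_lines_not_twin_priming(self):
        prof = classify_sv_sequence(
            "A" * 1000,
            [iv(0, 450, "LINE", "L1HS", "+"), iv(450, 900, "LINE", "L1P1", "+")],
        )
        assert not prof.twin_priming

    def test_partial_overlap_is_repeat_included(self):
        prof = classify_sv_sequence("A" * 1000, [iv(0, 500)])
        assert prof.category == "repeat_included"

    def test_no_repeats_is_non_repeat(self):
        prof = classify_sv_sequence("ACGT" * 100, [])
        assert prof.category == "non_repeat"

    def test_half_tandem_covered_excluded(self):
        prof = classify_sv_sequence(
            "ACGT" * 100, [iv(0, 240, "Simple/Tandem", "(AT)n")]
        )
        assert prof.category == "short_repeat_excluded"

    def test_under_half_tandem_not_excluded(self):
        prof = classify_sv_sequence(
            "ACGT" * 100, [iv(0, 190, "Simple/Tandem", "(AT)n")]
        )
        assert prof.category != "short_repeat_excluded"

    def test_boundary_eighty_percent_single_element(self):
        assert classify_sv_sequence("A" * 1000, [iv(0, 800)]).category == "single_SINE"
        assert classify_sv_sequence("A" * 1000, [iv(0, 799)]).category == "repeat_included"

    def test_polyA_tail_detected(self):
        seq = "CGTCGTACGATCGTACGTACGTTGCA" * 10 + "A" * 12
        prof = classify_sv_sequence(seq, [])
        assert prof.polyA_tail

    def test_polyA_in_reference_flank_not_counted(self):
        seq = "CGTCGTACGATCGTACGTACGTTGCA" * 10 + "A" * 12
        prof = classify_sv_sequence(seq, [], ref_flank="A" * 20)
        assert not prof.polyA_tail

    def test_every_sequence_gets_exactly_one_category(self):
        cats = {
            "single_SINE", "single_LINE", "multi_repeat", "repeat_included",
            "non_repeat", "short_repeat_excluded",
        }
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(100, 2000))
            reps = [
                iv(
                    int(rng.integers(0, n)),
                    int(rng.integers(0, n)) + 1,
                    ["SINE", "LINE", "Simple/Tandem"][int(rng.integers(0, 3))],
                )
                for _ in range(int(rng.integers(0, 4)))
            ]
            reps = [r for r in reps if r.end > r.start]
            prof = classify_sv_sequence("A" * n, reps)
            assert prof.category in cats


class TestCoverageOracle:
    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 999), st.integers(1, 400)),
            min_size=0,
            max_size=12,
        )
    )
    def test_union_coverage_matches_bitmap(self, spans):
        """Interval-union coverage equals a per-base bitmap count."""
        n = 1000
        intervals = [(s, min(n, s + l)) for s, l in spans]
        bitmap = np.zeros(n, dtype=bool)
        for s, e in intervals:
            bitmap[s:e] = True
        assert union_covered(intervals, 0, n) == int(bitmap.sum())


def psl_hit(t_start, t_end, blocks=None, q_name="c", matches=None, t_name="chr1"):
    blocks = blocks or [(t_start, t_end - t_start)]
    total = sum(sz for _s, sz in blocks)
    return PslRecord(
        matches=matches if matches is not None else total,
        mismatches=0,
        strand="+",
        q_name=q_name,
        q_size=total,
        q_start=0,
        q_end=total,
        t_name=t_name,
        t_size=1_000_000,
        t_start=t_start,
        t_end=t_end,
        block_count=len(blocks),
        block_sizes=[sz for _s, sz in blocks],
        q_starts=list(np.cumsum([0] + [sz for _s, sz in blocks[:-1]])),
        t_starts=[s for s, _sz in blocks],
    )


class TestNonRepeatInsertions:
    def test_adjacent_remap_is_tandem_duplication(self):
        hit = psl_hit(9800, 10_000)
        out = classify_nonrepeat_insertion("G" * 200, "chr1", 10_000, [hit])
        assert out == "tandem_dup"

    def test_distant_contiguous_remap_is_template_insertion(self):
        hit = psl_hit(500_000, 500_200)
        out = classify_nonrepeat_insertion("G" * 200, "chr1", 10_000, [hit])
        assert out == "template_insertion"

    def test_split_exon_remap_is_processed_pseudogene(self):
        gene = Bed12Gene(
            name="TDG_like", chrom="chr1", start=700_000, end=710_000,
            strand="+",
            exons=[(700_000, 700_300), (704_000, 704_250), (709_000, 709_400)],
        )
        hit = psl_hit(
            700_100, 704_200, blocks=[(700_100, 200), (704_000, 200)]
        )
        out = classify_nonrepeat_insertion(
            "G" * 400, "chr2", 10_000, [hit], genes=[gene]
        )
        assert out == "processed_pseudogene"

    def test_exonic_hit_with_polyA_is_processed_pseudogene(self):
        gene = Bed12Gene(
            name="g", chrom="chr1", start=700_000, end=702_000, strand="+",
            exons=[(700_000, 701_000)],
        )
        hit = psl_hit(700_100, 700_500)
        seq = "CGTAGCTAGCATCAGTTGCACGTAGCAT" * 10 + "A" * 15
        out = classify_nonrepeat_insertion(
            seq, "chr2", 10_000, [hit], genes=[gene]
        )
        assert out == "processed_pseudogene"

    def test_no_confident_hit_is_none(self):
        weak = psl_hit(500_000, 500_200, matches=100)  # 50% identity
        weak.mismatches = 100
        out = classify_nonrepeat_insertion("G" * 200, "chr1", 10_000, [weak])
        assert out == "none"

    def test_no_hits_is_none(self):
        assert classify_nonrepeat_insertion("G" * 200, "chr1", 0, []) == "none"
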