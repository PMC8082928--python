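"""Alignment parsing and per-read SV signature extraction."""

from __future__ import annotations

import pysam
import pytest

from longsv.ingest import (
    extract_signatures,
    parse_alignments,
    parse_cigar_string,
    signatures_to_bedpe,
)
from longsv.model import ReadAlignment, SplitSegment, SvType

HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n@SQ\tSN:chr2\tLN:100000\n"


def write_sam_text(tmp_path, body: str, name="t.sam"):
    p = tmp_path / name
    p.write_text(HEADER + body)
    return p


class TestParseAlignments:
    def test_empty_sam_with_header(self, tmp_path):
        assert parse_alignments(write_sam_text(tmp_path, "")) == []

    def test_missing_header_is_fatal(self, tmp_path):
        p = tmp_path / "nohdr.sam"
        p.write_text("")
        with pytest.raises(ValueError):
            parse_alignments(p)

    def test_single_primary_record(self, tmp_path):
        body = "r1\t0\tchr1\t1001\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
        alns = parse_alignments(write_sam_text(tmp_path, body))
        assert len(alns) == 1
        a = alns[0]
        assert (a.read_id, a.chrom, a.start, a.end) == ("r1", "chr1", 1000, 1100)
        assert a.mapq == 60 and a.strand == "+" and not a.split_segments
        assert a.cigar == [("M", 100)]

    def test_supplementary_attached_via_sa_tag(self, tmp_path):
        # primary: read bases 0-100 on chr1; supplementary: bases 100-200
        # on chr2, described by the SA tag of the primary
        seq = "A" * 200
        body = (
            "r1\t0\tchr1\t1001\t60\t100M100S\t*\t0\t0\t" + seq
            + "\t*\tSA:Z:chr2,5001,+,100S100M,60,0;\n"
            "r1\t2048\tchr2\t5001\t60\t100H100M\t*\t0\t0\t" + "A" * 100
            + "\t*\tSA:Z:chr1,1001,+,100M100S,60,0;\n"
        )
        alns = parse_alignments(write_sam_text(tmp_path, body))
        assert len(alns) == 1
        segs = alns[0].split_segments
        assert len(segs) == 2
        assert [s.chrom for s in segs] == ["chr1", "chr2"]
        assert segs[0].read_start == 0 and segs[0].read_end == 100
        assert segs[1].read_start == 100 and segs[1].read_end == 200

    def test_secondary_records_dropped(self, tmp_path):
        body = (
            "r1\t0\tchr1\t1001\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
            "r1\t256\tchr1\t2001\t0\t100M\t*\t0\t0\t*\t*\n"
        )
        assert len(parse_alignments(write_sam_text(tmp_path, body))) == 1

    def test_low_mapq_retained(self, tmp_path):
        body = "r1\t0\tchr1\t1001\t5\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
        alns = parse_alignments(write_sam_text(tmp_path, body), min_mapq=20)
        assert len(alns) == 1 and alns[0].mapq == 5

    def test_roundtrip_identity(self, tmp_path, small_scenario):
        """Writing parsed alignments back to SAM and re-parsing is identity."""
        sc, alignments = small_scenario
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [
                    {"SN": n, "LN": len(s)} for n, s in sc.build.seqs.items()
                ],
            }
        )
        out = tmp_path / "rt.sam"
        with pysam.AlignmentFile(out, "w", header=header) as fh:
            for a in alignments[:200]:
                rec = pysam.AlignedSegment(header)
                rec.query_name = a.read_id
                rec.reference_id = 0
                rec.reference_start = a.start
                rec.mapping_quality = a.mapq
                rec.flag = 16 if a.strand == "-" else 0
                rec.cigarstring = "".join(f"{n}{op}" for op, n in a.cigar)
                rec.query_sequence = a.query_sequence
                fh.write(rec)
        back = parse_alignments(out)
        for orig, rt in zip(alignments[:200], back):
            assert (orig.read_id, orig.chrom, orig.start, orig.end) == (
                rt.read_id, rt.chrom, rt.start, rt.end,
            )
            assert orig.cigar == rt.cigar
            assert orig.query_sequence == rt.query_sequence


def aln_with_cigar(cigar: str, pos=1000, seq=None, mapq=60, strand="+"):
    ops = parse_cigar_string(cigar)
    qlen = sum(n for op, n in ops if op in "MIS=X")
    rlen = sum(n for op, n in ops if op in "MD=X")
    left = ops[0][1] if ops[0][0] in "SH" else 0
    right = ops[-1][1] if ops[-1][0] in "SH" else 0
    return ReadAlignment(
        read_id="r1",
        chrom="chr1",
        start=pos,
        end=pos + rlen,
        strand=strand,
        mapq=mapq,
        cigar=ops,
        read_length=qlen,
        left_clip=left,
        right_clip=right,
        query_sequence=seq or ("A" * qlen),
    )


class TestExtractSignatures:
    def test_plain_match_has_no_event(self):
        assert extract_signatures(aln_with_cigar("500M")) == []

    def test_cigar_insertion(self):
        sigs = extract_signatures(aln_with_cigar("200M150I200M"))
        assert len(sigs) == 1
        s = sigs[0]
        assert s.sv_type is SvType.INS
        assert (s.pos1, s.length) == (1200, 150)
        assert len(s.inserted_seq) == 150
        assert s.qpos1 == 200

    def test_cigar_deletion(self):
        sigs = extract_signatures(aln_with_cigar("200M300D200M"))
        assert len(sigs) == 1
        s = sigs[0]
        assert s.sv_type is SvType.DEL
        assert (s.pos1, s.pos2, s.length) == (1200, 1500, 300)

    def test_small_indels_ignored(self):
        assert extract_signatures(aln_with_cigar("200M99I200M99D100M")) == []

    def test_deletion_records_nearby_insertion(self):
        # an 85 bp insertion 20 bp before an 800 bp deletion
        sigs = extract_signatures(aln_with_cigar("200M85I20M800D200M"))
        dels = [s for s in sigs if s.sv_type is SvType.DEL]
        assert len(dels) == 1 and dels[0].nearby_ins_len == 85

    def test_split_opposite_strands_is_inversion(self):
        aln = aln_with_cigar("100M900S", pos=1000)
        aln.split_segments = [
            SplitSegment("chr1", 1000, 1100, "+", 0, 100, 60),
            SplitSegment("chr1", 3000, 3900, "-", 100, 1000, 60),
        ]
        sigs = extract_signatures(aln)
        inv = [s for s in sigs if s.sv_type is SvType.INV]
        assert len(inv) == 1
        assert (inv[0].pos1, inv[0].pos2) == (1100, 3900)

    def test_split_different_chroms_is_inter(self):
        aln = aln_with_cigar("100M900S", pos=1000)
        aln.split_segments = [
            SplitSegment("chr1", 1000, 1100, "+", 0, 100, 60),
            SplitSegment("chr2", 5000, 5900, "+", 100, 1000, 60),
        ]
        sigs = extract_signatures(aln)
        tra = [s for s in sigs if s.sv_type is SvType.TRA_INTER]
        assert len(tra) == 1
        assert (tra[0].chrom1, tra[0].pos1, tra[0].chrom2, tra[0].pos2) == (
            "chr1", 1100, "chr2", 5000,
        )

    def test_order_inverted_split_is_duplication_junction(self):
        # read runs past a tandem-duplication boundary: second segment
        # starts before the first one ends on the reference
        aln = aln_with_cigar("500M500S", pos=2000)
        aln.split_segments = [
            SplitSegment("chr1", 2000, 2500, "+", 0, 500, 60),
            SplitSegment("chr1", 1500, 2000, "+", 500, 1000, 60),
        ]
        sigs = extract_signatures(aln)
        dup = [s for s in sigs if s.sv_type is SvType.TRA_INTRA]
        assert len(dup) == 1
        assert (dup[0].pos1, dup[0].pos2) == (1500, 2500)

    def test_long_unexplained_clip_is_breakend(self):
        sigs = extract_signatures(aln_with_cigar("600S400M", pos=5000))
        clips = [s for s in sigs if s.sv_type is SvType.CLIP]
        assert len(clips) == 1
        assert clips[0].pos1 == 5000 and clips[0].clip_side == "left"

    def test_short_clip_ignored(self):
        assert extract_signatures(aln_with_cigar("400S400M")) == []

    def test_extraction_is_order_independent(self, small_scenario):
        sc, alignments = small_scenario
        fwd = [
            tuple(vars(s).values())
            for a in alignments[:300]
            for s in extract_signatures(a)
        ]
        rev = [
            tuple(vars(s).values())
            for a in reversed(alignments[:300])
            for s in extract_signatures(a)
        ]
        assert sorted(map(str, fwd)) == sorted(map(str, rev))

    def test_simulated_deletion_recovered_exactly(self):
        """Error-free read over one spiked deletion yields one exact DEL."""
        from longsv.model import SvType
        from longsv.sim.reads import ErrorModel, simulate_sample, write_sam
        from longsv.sim.reference import build_reference
        from longsv.sim.spike import SvSpec, plan_svs, spike_svs

        build = build_reference(length=60_000, n_repeat_copies=0, seed=5)
        specs = plan_svs(
            build, [SvSpec(SvType.DEL, 400, vaf=1.0, pos=30_000)], seed=5
        )
        res = spike_svs(build, specs, seed=5)
        reads = simulate_sample(
            res.haplotypes["S1"], build.seqs, coverage=5,
            model=ErrorModel.perfect(), seed=5, sample_id="S1",
        )
        found = []
        for read in reads:
            for seg in read.segments:
                aln = ReadAlignment(
                    read_id=read.read_id,
                    chrom=seg.chrom,
                    start=seg.ref_start,
                    end=seg.ref_start + sum(n for o, n in seg.cigar if o in "MD"),
                    strand=seg.strand,
                    mapq=60,
                    cigar=seg.cigar,
                    read_length=len(read.sequence),
                    query_sequence=read.sequence,
                )
                found.extend(extract_signatures(aln))
        dels = [s for s in found if s.sv_type is SvType.DEL]
        assert dels and all(
            (s.pos1, s.pos2, s.length) == (30_000, 30_400, 400) for s in dels
        )

    def test_bedpe_dump(self):
        sigs = extract_signatures(aln_with_cigar("200M300D200M"))
        text = signatures_to_bedpe(sigs)
        assert text.startswith("chr1\t1200\t1201\tchr1\t1500\t1501\t")
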