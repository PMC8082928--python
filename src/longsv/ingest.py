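"""Parse SAM/BAM into the internal alignment model and extract SV signatures.

Signature extraction looks at three sources of evidence in a long-read
alignment:

* CIGAR ``I``/``D`` operations of at least ``min_indel`` bp (insertions and
  deletions contained within one aligned segment);
* pairs of adjacent split-alignment segments of the same read (deletions and
  insertions too large for one segment, inversions, intra- and
  inter-chromosomal junctions);
* long unresolved soft clips, reported as one-sided CLIP breakends that can
  corroborate large insertions.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict

import pysam

from .model import ReadAlignment, SplitSegment, SvSignature, SvType

log = logging.getLogger(__name__)

_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: split segments overlapping by more than this many bases on the read are
#: trimmed back before adjacency analysis
MAX_SPLIT_OVERLAP_TRIM = 20

#: reference gap beyond which a colinear same-strand split is treated as an
#: intra-chromosomal translocation rather than a deletion
MAX_COLINEAR_GAP = 100_000


def parse_cigar_string(cigar: str) -> list[tuple[str, int]]:
    if cigar == "*":
        return []
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return ops


def _clips(cigar: list[tuple[str, int]]) -> tuple[int, int]:
    left = cigar[0][1] if cigar and cigar[0][0] in "SH" else 0
    right = cigar[-1][1] if cigar and cigar[-1][0] in "SH" else 0
    return left, right


def _query_span(cigar: list[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in "MI=X")


def _ref_span(cigar: list[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in _REF_OPS)


def _read_interval(
    cigar: list[tuple[str, int]], strand: str, read_length: int
) -> tuple[int, int]:
    """Interval of the original (as-sequenced) read covered by an alignment."""
    left, right = _clips(cigar)
    qspan = _query_span(cigar)
    if strand == "+":
        return left, left + qspan
    return read_length - left - qspan, read_length - left


def segment_from_sa_field(read_id: str, sa_field: str, read_length: int) -> SplitSegment:
    """Build a SplitSegment from one entry of a SAM ``SA`` tag."""
    chrom, pos, strand, cigar_str, mapq, _nm = sa_field.split(",")[:6]
    cigar = parse_cigar_string(cigar_str)
    start = int(pos) - 1
    rs, re_ = _read_interval(cigar, strand, read_length)
    return SplitSegment(
        chrom=chrom,
        start=start,
        end=start + _ref_span(cigar),
        strand=strand,
        read_start=rs,
        read_end=re_,
        mapq=int(mapq),
    )


def parse_alignments(
    sam_source,
    min_mapq: int = 0,
    sample_id: str = "",
) -> list[ReadAlignment]:
    """Read a SAM/BAM file into ``ReadAlignment`` records.

    One record is produced per primary alignment; supplementary alignments
    are folded into the primary's ``split_segments`` (reconstructed from the
    ``SA`` tag, so hard-clipped supplementaries need no special casing).
    Secondary and unmapped records are dropped. Records below ``min_mapq``
    are retained — the low-mapping-quality region filter needs them — but
    callers may check ``mapq`` themselves.

    Raises ``ValueError`` if the file has no sequence header.
    """
    mode = "rb" if str(sam_source).endswith(".bam") else "r"
    skipped = 0
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(sam_source), mode, check_sq=False) as fh:
        if not fh.header.get("SQ"):
            raise ValueError(f"{sam_source}: SAM header has no @SQ lines")
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            try:
                cigar = parse_cigar_string(rec.cigarstring or "*")
            except ValueError:
                skipped += 1
                continue
            if not cigar:
                skipped += 1
                continue
            left, right = _clips(cigar)
            strand = "-" if rec.is_reverse else "+"
            read_length = rec.infer_read_length() or (_query_span(cigar) + 0)
            aln = ReadAlignment(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand=strand,
                mapq=rec.mapping_quality,
                cigar=cigar,
                read_length=read_length,
                left_clip=left,
                right_clip=right,
                query_sequence=rec.query_sequence,
                sample_id=sample_id,
            )
            segments = []
            if rec.has_tag("SA"):
                for part in rec.get_tag("SA").rstrip(";").split(";"):
                    try:
                        segments.append(
                            segment_from_sa_field(rec.query_name, part, read_length)
                        )
                    except (ValueError, IndexError):
                        skipped += 1
                rs, re_ = _read_interval(cigar, strand, read_length)
                segments.append(
                    SplitSegment(
                        chrom=aln.chrom,
                        start=aln.start,
                        end=aln.end,
                        strand=strand,
                        read_start=rs,
                        read_end=re_,
                        mapq=aln.mapq,
                    )
                )
                segments.sort(key=lambda s: s.read_start)
                aln.split_segments = segments
            out.append(aln)
    if skipped:
        log.warning("%s: skipped %d malformed records/SA entries", sam_source, skipped)
    return out


def _trim_split_overlaps(segments: list[SplitSegment]) -> list[SplitSegment]:
    """Trim small read-interval overlaps between adjacent split segments.

    Overlaps up to ``MAX_SPLIT_OVERLAP_TRIM`` bp are shaved off the second
    segment (alignment-boundary fuzz); larger overlaps are left intact and
    flagged later by the chimeric-read heuristic.
    """
    trimmed = []
    prev_end = None
    for seg in sorted(segments, key=lambda s: (s.read_start, s.read_end)):
        seg = SplitSegment(**vars(seg))
        if prev_end is not None and seg.read_start < prev_end:
            overlap = prev_end - seg.read_start
            if overlap <= MAX_SPLIT_OVERLAP_TRIM:
                frac_keep = (seg.read_end - prev_end) / max(
                    1, seg.read_end - seg.read_start
                )
                ref_len = seg.end - seg.start
                cut = ref_len - int(round(ref_len * frac_keep))
                if seg.strand == "+":
                    seg.start += cut
                else:
                    seg.end -= cut
                seg.read_start = prev_end
        trimmed.append(seg)
        prev_end = max(prev_end or 0, seg.read_end)
    return trimmed


def segments_read_overlap_fraction(a: SplitSegment, b: SplitSegment) -> float:
    """Fraction of the shorter segment's read interval shared with the other."""
    ov = min(a.read_end, b.read_end) - max(a.read_start, b.read_start)
    shorter = min(a.read_end - a.read_start, b.read_end - b.read_start)
    return max(0.0, ov / max(1, shorter))


def _forward_breakend(seg: SplitSegment) -> int:
    """Reference coordinate where the read leaves this segment."""
    return seg.end if seg.strand == "+" else seg.start


def _entry_breakend(seg: SplitSegment) -> int:
    """Reference coordinate where the read enters this segment."""
    return seg.start if seg.strand == "+" else seg.end


def extract_signatures(
    aln: ReadAlignment,
    min_indel: int = 100,
    min_clip: int = 500,
    nearby_ins_window: int = 30,
) -> list[SvSignature]:
    """Extract all SV signatures supported by one read alignment."""
    sigs: list[SvSignature] = []
    rl = max(1, aln.read_length)

    # --- CIGAR walk: indels within the primary segment -------------------
    ref = aln.start
    q = 0
    indel_events: list[tuple[str, int, int, int]] = []  # (op, refpos, qpos, length)
    for op, n in aln.cigar:
        if op == "I":
            indel_events.append(("I", ref, q, n))
        elif op in "DN":
            indel_events.append(("D", ref, q, n))
        if op in _QUERY_OPS:
            q += n
        if op in _REF_OPS:
            ref += n
    for op, refpos, qpos, n in indel_events:
        if n < min_indel:
            continue
        if op == "I":
            seq = ""
            if aln.query_sequence:
                seq = aln.query_sequence[qpos : qpos + n]
            sigs.append(
                SvSignature(
                    sv_type=SvType.INS,
                    chrom1=aln.chrom,
                    pos1=refpos,
                    chrom2=aln.chrom,
                    pos2=refpos,
                    length=n,
                    inserted_seq=seq,
                    read_id=aln.read_id,
                    read_offset_fraction=(qpos + n / 2) / rl,
                    source="cigar",
                    mapq=aln.mapq,
                    qpos1=qpos,
                    qpos2=qpos + n,
                    sample_id=aln.sample_id,
                )
            )
        else:
            near = 0
            for op2, refpos2, _q2, n2 in indel_events:
                if op2 != "I":
                    continue
                d = min(abs(refpos2 - refpos), abs(refpos2 - (refpos + n)))
                if d <= nearby_ins_window:
                    near = max(near, n2)
            sigs.append(
                SvSignature(
                    sv_type=SvType.DEL,
                    chrom1=aln.chrom,
                    pos1=refpos,
                    chrom2=aln.chrom,
                    pos2=refpos + n,
                    length=n,
                    read_id=aln.read_id,
                    read_offset_fraction=qpos / rl,
                    source="cigar",
                    mapq=aln.mapq,
                    qpos1=qpos,
                    qpos2=qpos,
                    nearby_ins_len=near,
                    sample_id=aln.sample_id,
                )
            )

    # --- split-segment adjacency -----------------------------------------
    covered: list[tuple[int, int]] = []
    if aln.split_segments:
        segs = _trim_split_overlaps(aln.split_segments)
        covered = [(s.read_start, s.read_end) for s in segs]
        for a, b in zip(segs, segs[1:]):
            if segments_read_overlap_fraction(a, b) > 0.5:
                continue  # chimeric-artifact fingerprint, handled upstream
            mid = (a.read_end + b.read_start) / 2
            frac = min(1.0, max(0.0, mid / rl))
            mapq = min(a.mapq, b.mapq)
            read_gap = b.read_start - a.read_end
            if a.chrom != b.chrom:
                sigs.append(
                    SvSignature(
                        sv_type=SvType.TRA_INTER,
                        chrom1=a.chrom,
                        pos1=_forward_breakend(a),
                        chrom2=b.chrom,
                        pos2=_entry_breakend(b),
                        length=0,
                        read_id=aln.read_id,
                        read_offset_fraction=frac,
                        source="split",
                        mapq=mapq,
                        qpos1=a.read_end,
                        qpos2=b.read_start,
                        sample_id=aln.sample_id,
                    )
                )
                continue
            if a.strand != b.strand:
                p1, p2 = _forward_breakend(a), _entry_breakend(b)
                lo, hi = min(p1, p2), max(p1, p2)
                sigs.append(
                    SvSignature(
                        sv_type=SvType.INV,
                        chrom1=a.chrom,
                        pos1=lo,
                        chrom2=a.chrom,
                        pos2=hi,
                        length=hi - lo,
                        read_id=aln.read_id,
                        read_offset_fraction=frac,
                        source="split",
                        mapq=mapq,
                        qpos1=a.read_end,
                        qpos2=b.read_start,
                        sample_id=aln.sample_id,
                    )
                )
                continue
            # same chromosome, same strand
            if a.strand == "+":
                ref_gap = b.start - a.end
                dup_like = ref_gap < -MAX_SPLIT_OVERLAP_TRIM
                p_del = (a.end, b.start)
                p_dup = (b.start, a.end)
            else:
                ref_gap = a.start - b.end
                dup_like = ref_gap < -MAX_SPLIT_OVERLAP_TRIM
                p_del = (b.end, a.start)
                p_dup = (a.start, b.end)
            if dup_like or ref_gap > MAX_COLINEAR_GAP:
                lo, hi = (p_dup if dup_like else p_del)
                lo, hi = min(lo, hi), max(lo, hi)
                sigs.append(
                    SvSignature(
                        sv_type=SvType.TRA_INTRA,
                        chrom1=a.chrom,
                        pos1=lo,
                        chrom2=a.chrom,
                        pos2=hi,
                        length=hi - lo,
                        read_id=aln.read_id,
                        read_offset_fraction=frac,
                        source="split",
                        mapq=mapq,
                        qpos1=a.read_end,
                        qpos2=b.read_start,
                        sample_id=aln.sample_id,
                    )
                )
            elif ref_gap >= min_indel and read_gap < min_indel:
                sigs.append(
                    SvSignature(
                        sv_type=SvType.DEL,
                        chrom1=a.chrom,
                        pos1=p_del[0],
                        pos2=p_del[1],
                        chrom2=a.chrom,
                        length=ref_gap,
                        read_id=aln.read_id,
                        read_offset_fraction=frac,
                        source="split",
                        mapq=mapq,
                        qpos1=a.read_end,
                        qpos2=b.read_start,
                        sample_id=aln.sample_id,
                    )
                )
            elif read_gap >= min_indel and ref_gap < min_indel:
                seq = ""
                if aln.query_sequence is not None:
                    qs, qe = a.read_end, b.read_start
                    if aln.strand == "-":
                        qs2 = rl - qe
                        qe2 = rl - qs
                        seq = _revcomp(aln.query_sequence)[qs:qe]
                        seq = _revcomp(seq)
                        qs, qe = qs2, qe2
                    else:
                        seq = aln.query_sequence[qs:qe]
                sigs.append(
                    SvSignature(
                        sv_type=SvType.INS,
                        chrom1=a.chrom,
                        pos1=p_del[0],
                        chrom2=a.chrom,
                        pos2=p_del[0],
                        length=read_gap,
                        inserted_seq=seq,
                        read_id=aln.read_id,
                        read_offset_fraction=frac,
                        source="split",
                        mapq=mapq,
                        qpos1=a.read_end,
                        qpos2=b.read_start,
                        sample_id=aln.sample_id,
                    )
                )

    # --- long unresolved clips -------------------------------------------
    for side, clip in (("left", aln.left_clip), ("right", aln.right_clip)):
        if clip < min_clip:
            continue
        if side == "left":
            c_read = (0, clip) if aln.strand == "+" else (rl - clip, rl)
            pos = aln.start
        else:
            c_read = (rl - clip, rl) if aln.strand == "+" else (0, clip)
            pos = aln.end
        cov = sum(
            max(0, min(c_read[1], e) - max(c_read[0], s)) for s, e in covered
        )
        if cov / clip > 0.5:
            continue  # clip explained by a split segment
        sigs.append(
            SvSignature(
                sv_type=SvType.CLIP,
                chrom1=aln.chrom,
                pos1=pos,
                chrom2=aln.chrom,
                pos2=pos,
                length=0,
                read_id=aln.read_id,
                read_offset_fraction=(0.0 if side == "left" else 1.0)
                if aln.strand == "+"
                else (1.0 if side == "left" else 0.0),
                source="cigar",
                mapq=aln.mapq,
                clip_side=side,
                sample_id=aln.sample_id,
            )
        )
    return sigs


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def extract_all_signatures(
    alignments: list[ReadAlignment],
    min_indel: int = 100,
    min_clip: int = 500,
) -> list[SvSignature]:
    """Signatures for every alignment; per-read and order-independent."""
    out: list[SvSignature] = []
    for aln in alignments:
        out.extend(extract_signatures(aln, min_indel=min_indel, min_clip=min_clip))
    return out


def signatures_to_bedpe(signatures: list[SvSignature]) -> str:
    """Dump signatures as BEDPE text for debugging."""
    lines = []
    for s in signatures:
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    s.chrom1,
                    s.pos1,
                    s.pos1 + 1,
                    s.chrom2,
                    s.pos2,
                    s.pos2 + 1,
                    f"{s.sv_type}:{s.read_id}",
                    s.length,
                    s.source,
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def group_by_type(
    signatures: list[SvSignature],
) -> dict[SvType, list[SvSignature]]:
    grouped: dict[SvType, list[SvSignature]] = defaultdict(list)
    for s in signatures:
        grouped[s.sv_type].append(s)
    return grouped
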