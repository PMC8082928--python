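"""Simulate noisy long reads from donor haplotypes with truth alignments.

Reads are sampled uniformly along each haplotype with log-normally
distributed lengths (mean ~5.5 kb, matching typical nanopore genomic
libraries). Per-base errors are injected with independent substitution,
insertion and deletion probabilities; the defaults reproduce the error
profile of nanopore data (~4.4% insertions, ~6.6% deletions). Because each
read's donor interval maps deterministically onto reference blocks, the
simulator writes SAM records with exact CIGARs, split records at SV
junctions and SA tags, without running an aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .reference import revcomp
from .spike import Block, DonorHaplotype

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_LUT = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i

#: colinear reference gaps up to this size stay inside one record as a D op
MAX_DEL_IN_CIGAR = 50_000


@dataclass
class ErrorModel:
    sub: float = 0.052
    ins: float = 0.044
    dele: float = 0.066

    @classmethod
    def perfect(cls) -> "ErrorModel":
        return cls(0.0, 0.0, 0.0)


def noisy_copy(
    seq: str, model: ErrorModel, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int]]]:
    """Copy ``seq`` with errors; return the copy and a CIGAR mapping it back.

    The CIGAR is relative to ``seq`` as the reference: M consumes both, D a
    base of ``seq`` only (deletion error), I a base of the copy only
    (insertion error). Substitutions stay M.
    """
    n = len(seq)
    if n == 0:
        return "", []
    if model.sub == model.ins == model.dele == 0.0:
        return seq, [("M", n)]
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    idx = _LUT[arr]
    r = rng.random(n)
    del_mask = r < model.dele
    sub_mask = (r >= model.dele) & (r < model.dele + model.sub)
    ins_mask = rng.random(n) < model.ins

    out_idx = idx.copy()
    nsub = int(sub_mask.sum())
    if nsub:
        out_idx[sub_mask] = (idx[sub_mask] + rng.integers(1, 4, size=nsub)) % 4
    keep = ~del_mask

    counts = keep.astype(np.int64) + ins_mask
    starts = np.cumsum(counts) - counts
    total = int(counts.sum())
    out = np.zeros(total, dtype=np.int64)
    out[starts[keep]] = out_idx[keep]
    ins_pos = starts + keep
    nins = int(ins_mask.sum())
    if nins:
        out[ins_pos[ins_mask]] = rng.integers(0, 4, size=nins)
    new_seq = _BASES[out].tobytes().decode()

    # op stream: one M/D per original base, then I where an error inserts
    op_counts = 1 + ins_mask.astype(np.int64)
    op_starts = np.cumsum(op_counts) - op_counts
    ops = np.zeros(int(op_counts.sum()), dtype=np.uint8)
    ops[op_starts] = np.where(del_mask, 1, 0)  # 0=M, 1=D
    if nins:
        ops[(op_starts + 1)[ins_mask]] = 2  # 2=I
    chg = np.flatnonzero(np.diff(ops)) + 1
    bounds = np.concatenate(([0], chg, [ops.size]))
    letters = "MDI"
    cigar = [
        (letters[ops[bounds[k]]], int(bounds[k + 1] - bounds[k]))
        for k in range(bounds.size - 1)
    ]
    return new_seq, cigar


def _merge_cigar(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in ops:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


@dataclass
class _Piece:
    kind: str  # {"ref", "ins"}
    chrom: str = ""
    ref_start: int = 0
    ref_end: int = 0
    strand: str = "+"
    seq: str = ""  # noisy sequence of this piece (read orientation)
    cigar: list[tuple[str, int]] = field(default_factory=list)  # vs ref span
    mappable: bool = True


@dataclass
class ReadSegment:
    chrom: str
    ref_start: int
    strand: str
    cigar: list[tuple[str, int]]  # M/I/D only
    read_start: int
    read_end: int

    @property
    def aligned_len(self) -> int:
        return sum(n for op, n in self.cigar if op in "MI")


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    segments: list[ReadSegment]


def _block_offsets(blocks: list[Block], ref: dict[str, str]) -> np.ndarray:
    lens = [b.length(ref) for b in blocks]
    return np.concatenate(([0], np.cumsum(lens)))


def _extract_pieces(
    blocks: list[Block],
    offsets: np.ndarray,
    ref: dict[str, str],
    a: int,
    b: int,
) -> list[_Piece]:
    """Donor interval [a, b) as a list of reference/insertion pieces."""
    pieces = []
    i = int(np.searchsorted(offsets, a, side="right")) - 1
    while i < len(blocks) and offsets[i] < b:
        blk = blocks[i]
        o0 = max(0, a - int(offsets[i]))
        o1 = min(blk.length(ref), b - int(offsets[i]))
        if o1 > o0:
            if blk.kind == "ins":
                pieces.append(
                    _Piece(kind="ins", seq=blk.seq[o0:o1], mappable=blk.mappable)
                )
            elif blk.strand == "+":
                pieces.append(
                    _Piece(
                        kind="ref",
                        chrom=blk.chrom,
                        ref_start=blk.start + o0,
                        ref_end=blk.start + o1,
                        strand="+",
                    )
                )
            else:
                pieces.append(
                    _Piece(
                        kind="ref",
                        chrom=blk.chrom,
                        ref_start=blk.end - o1,
                        ref_end=blk.end - o0,
                        strand="-",
                    )
                )
        i += 1
    return pieces


def _colinear_gap(prev: _Piece, nxt: _Piece) -> int | None:
    """Reference gap if ``nxt`` continues ``prev`` colinearly, else None."""
    if prev.chrom != nxt.chrom or prev.strand != nxt.strand:
        return None
    if prev.strand == "+":
        gap = nxt.ref_start - prev.ref_end
    else:
        gap = prev.ref_start - nxt.ref_end
    return gap if 0 <= gap <= MAX_DEL_IN_CIGAR else None


def _pieces_to_segments(pieces: list[_Piece]) -> list[ReadSegment]:
    """Merge noisy pieces into aligned segments with soft-clip bookkeeping."""
    segments: list[ReadSegment] = []
    read_pos = 0
    cur: dict | None = None
    pending_ins: list[str] = []  # unmapped read bases awaiting attachment

    def close() -> None:
        nonlocal cur
        if cur is not None:
            cigar = _merge_cigar(cur["cigar"])
            # a segment cannot start or end on a deletion
            while cigar and cigar[-1][0] == "D":
                cigar.pop()
            while cigar and cigar[0][0] == "D":
                d = cigar.pop(0)
                if cur["strand"] == "+":
                    cur["ref_start"] += d[1]
                else:
                    cur["ref_start"] -= d[1]
            if cigar:
                segments.append(
                    ReadSegment(
                        chrom=cur["chrom"],
                        ref_start=cur["ref_start"],
                        strand=cur["strand"],
                        cigar=cigar,
                        read_start=cur["read_start"],
                        read_end=cur["read_end"],
                    )
                )
        cur = None

    for piece in pieces:
        plen = len(piece.seq)
        if piece.kind == "ins":
            if not piece.mappable:
                close()
                pending_ins = []
                read_pos += plen
                continue
            if cur is None:
                read_pos += plen
                continue  # leading unmapped bases become a clip
            pending_ins.append(piece.seq)
            read_pos += plen
            continue
        # reference piece
        if cur is not None:
            gap = _colinear_gap(
                _Piece(
                    kind="ref",
                    chrom=cur["chrom"],
                    ref_start=cur["ref_lo"],
                    ref_end=cur["ref_hi"],
                    strand=cur["strand"],
                ),
                piece,
            )
            if gap is None:
                close()
                pending_ins = []
            else:
                if pending_ins:
                    cur["cigar"].append(("I", sum(len(s) for s in pending_ins)))
                    pending_ins = []
                if gap:
                    cur["cigar"].append(("D", gap))
        if cur is None:
            cur = dict(
                chrom=piece.chrom,
                strand=piece.strand,
                ref_start=piece.ref_start if piece.strand == "+" else piece.ref_end,
                ref_lo=piece.ref_start,
                ref_hi=piece.ref_end,
                cigar=[],
                read_start=read_pos,
                read_end=read_pos,
            )
        cur["cigar"].extend(piece.cigar)
        cur["ref_lo"] = min(cur["ref_lo"], piece.ref_start)
        cur["ref_hi"] = max(cur["ref_hi"], piece.ref_end)
        read_pos += plen
        cur["read_end"] = read_pos
    close()
    # '-' segments: ref_start tracked the entry (high) end and the CIGAR was
    # accumulated in read order; convert to SAM's reference orientation
    for seg in segments:
        if seg.strand == "-":
            ref_span = sum(n for op, n in seg.cigar if op in "MD")
            seg.ref_start = seg.ref_start - ref_span
            seg.cigar = list(reversed(seg.cigar))
    return segments


def simulate_haplotype_reads(
    hap: DonorHaplotype,
    ref: dict[str, str],
    n_bases: int,
    model: ErrorModel,
    rng: np.random.Generator,
    mean_log_length: float = 8.42,
    sigma_log_length: float = 0.55,
    min_read_length: int = 600,
    read_prefix: str = "read",
) -> list[SimulatedRead]:
    """Sample reads from one haplotype until ``n_bases`` are emitted."""
    offsets = _block_offsets(hap.blocks, ref)
    hap_len = int(offsets[-1])
    reads: list[SimulatedRead] = []
    emitted = 0
    i = 0
    while emitted < n_bases:
        length = int(rng.lognormal(mean_log_length, sigma_log_length))
        length = max(min_read_length, min(length, hap_len))
        start = int(rng.integers(0, max(1, hap_len - length + 1)))
        pieces = _extract_pieces(hap.blocks, offsets, ref, start, start + length)
        noisy_pieces = []
        for p in pieces:
            clean = (
                p.seq
                if p.kind == "ins"
                else Block(
                    "ref", p.chrom, p.ref_start, p.ref_end, p.strand
                ).sequence(ref)
            )
            nseq, cigar = noisy_copy(clean, model, rng)
            noisy_pieces.append(
                _Piece(
                    kind=p.kind,
                    chrom=p.chrom,
                    ref_start=p.ref_start,
                    ref_end=p.ref_end,
                    strand=p.strand,
                    seq=nseq,
                    cigar=cigar if p.kind == "ref" else [],
                    mappable=p.mappable,
                )
            )
        full = "".join(p.seq for p in noisy_pieces)
        # orient: half the reads come off the opposite strand
        flip = rng.random() < 0.5
        if flip:
            pos = 0
            flipped = []
            for p in reversed(noisy_pieces):
                q = _Piece(
                    kind=p.kind,
                    chrom=p.chrom,
                    ref_start=p.ref_start,
                    ref_end=p.ref_end,
                    strand=("-" if p.strand == "+" else "+") if p.kind == "ref" else "+",
                    seq=revcomp(p.seq),
                    cigar=list(reversed(p.cigar)),
                    mappable=p.mappable,
                )
                flipped.append(q)
            noisy_pieces = flipped
            full = "".join(p.seq for p in noisy_pieces)
        segments = _pieces_to_segments(noisy_pieces)
        rid = f"{read_prefix}_{hap.sample_id}_h{hap.hap}_{i:06d}"
        reads.append(SimulatedRead(read_id=rid, sequence=full, segments=segments))
        emitted += len(full)
        i += 1
    return reads


def _cigar_str(ops: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def _record_cigar(
    seg: ReadSegment, read_len: int, hard: bool = False
) -> tuple[str, int, int]:
    """CIGAR string with clips for a segment record, plus clip lengths."""
    if seg.strand == "+":
        left, right = seg.read_start, read_len - seg.read_end
    else:
        left, right = read_len - seg.read_end, seg.read_start
    clip = "H" if hard else "S"
    parts = []
    if left:
        parts.append((clip, left))
    parts.extend(seg.cigar)
    if right:
        parts.append((clip, right))
    return _cigar_str(parts), left, right


def write_sam(
    reads: list[SimulatedRead],
    ref: dict[str, str],
    path,
    mapq: int = 60,
    sample_id: str = "",
) -> int:
    """Write simulated reads as a coordinate-sorted SAM file.

    The longest segment of each read is the primary record; the rest are
    supplementary. Every record carries an SA tag listing its siblings.
    Returns the number of records written.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": len(seq)} for name, seq in ref.items()],
            "RG": [{"ID": sample_id or "S", "SM": sample_id or "S"}],
        }
    )
    refs = list(ref)
    recs = []
    for read in reads:
        if not read.segments:
            continue
        read_len = len(read.sequence)
        order = sorted(
            range(len(read.segments)),
            key=lambda k: read.segments[k].aligned_len,
            reverse=True,
        )
        primary = order[0]
        sa_parts = []
        for k, seg in enumerate(read.segments):
            cig, _l, _r = _record_cigar(seg, read_len)
            sa_parts.append(
                f"{seg.chrom},{seg.ref_start + 1},{seg.strand},{cig},{mapq},0;"
            )
        for k, seg in enumerate(read.segments):
            a = pysam.AlignedSegment(header)
            a.query_name = read.read_id
            a.reference_id = refs.index(seg.chrom)
            a.reference_start = seg.ref_start
            a.mapping_quality = mapq
            flag = 0
            if seg.strand == "-":
                flag |= 16
            if k != primary:
                flag |= 2048
            a.flag = flag
            cig, _l, _r = _record_cigar(seg, read_len)
            a.cigarstring = cig
            seq = read.sequence if seg.strand == "+" else revcomp(read.sequence)
            a.query_sequence = seq
            a.set_tag("RG", sample_id or "S")
            if len(read.segments) > 1:
                others = "".join(
                    sa_parts[j] for j in range(len(read.segments)) if j != k
                )
                a.set_tag("SA", others)
            recs.append(a)
    recs.sort(key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in recs:
            out.write(r)
    return len(recs)


def write_fastq(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def simulate_sample(
    haps: list[DonorHaplotype],
    ref: dict[str, str],
    coverage: float,
    model: ErrorModel | None = None,
    seed: int = 0,
    sample_id: str = "",
    **kwargs,
) -> list[SimulatedRead]:
    """Simulate ``coverage``x total reads split evenly across haplotypes."""
    model = model or ErrorModel()
    rng = np.random.default_rng(seed)
    ref_len = sum(len(s) for s in ref.values())
    per_hap = coverage * ref_len / max(1, len(haps))
    reads: list[SimulatedRead] = []
    for hap in haps:
        reads.extend(
            simulate_haplotype_reads(
                hap,
                ref,
                n_bases=int(per_hap),
                model=model,
                rng=rng,
                read_prefix=sample_id or "read",
                **kwargs,
            )
        )
    return reads
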