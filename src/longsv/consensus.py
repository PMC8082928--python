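"""Majority-vote consensus sequences at SV breakpoints.

Nanopore reads carry ~10-15% errors, so the inserted sequence or junction
of an SV cannot be read off a single read. For each call we cut the event
plus flanking sequence (default ±500 bp in read coordinates) out of every
support read, align the segments with an internal star multiple alignment
(backbone = the median-length segment, pairwise global edit-distance
alignments against it), and emit the majority base per column. Columns
where a gap holds the majority are dropped, which removes most insertion
errors; the independent per-read errors are voted away.

The consensus is then validated by remapping: its flanks are aligned back
to the local reference window (or external PSL remap records are
consulted), and a consensus is accepted only when it maps where the call
was made — within 100 bp for insertions, overlapping the call interval
for deletions.
"""

from __future__ import annotations

from collections import Counter

import edlib

from .model import ConsensusSeq, ReadAlignment, SvCall, SvType
from .vcfio import PslRecord

_GAP = "-"
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def collect_segments(
    call: SvCall,
    alignments: dict[str, ReadAlignment] | list[ReadAlignment],
    flank: int = 500,
) -> list[str]:
    """Per-support-read sub-sequences spanning the event ± ``flank``.

    Segments are taken from the stored (reference-oriented) read sequence,
    so all segments share one strand. Reads not supporting the call are
    ignored; truncated segments (read ends inside the flank) are retained.
    """
    if isinstance(alignments, list):
        alignments = {a.read_id: a for a in alignments}
    segments: list[str] = []
    if call.cluster is None:
        return segments
    seen = set()
    for m in call.cluster.members:
        if m.read_id in seen:
            continue
        aln = alignments.get(m.read_id)
        if aln is None or aln.query_sequence is None:
            continue
        seen.add(m.read_id)
        q1, q2 = m.qpos1, m.qpos2
        if m.source == "split" and aln.strand == "-":
            # split coordinates are in as-sequenced orientation; the stored
            # sequence is reference-oriented
            n = len(aln.query_sequence)
            q1, q2 = n - m.qpos2, n - m.qpos1
        lo = max(0, min(q1, q2) - flank)
        hi = min(len(aln.query_sequence), max(q1, q2) + flank)
        if hi > lo:
            segments.append(aln.query_sequence[lo:hi])
    return segments


def _median_length_index(segments: list[str]) -> int:
    order = sorted(range(len(segments)), key=lambda i: (len(segments[i]), i))
    return order[len(order) // 2]


def _edlib_path(query: str, target: str) -> list[tuple[str, int]]:
    res = edlib.align(query, target, task="path", mode="NW")
    ops = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def build_consensus(
    segments: list[str],
    call_id: str = "",
    majority: float = 0.5,
    rounds: int = 2,
) -> ConsensusSeq:
    """Star-alignment majority consensus of support-read segments.

    With fewer than two segments the single segment is returned flagged
    low-confidence. Ties at a column resolve toward the backbone segment's
    symbol, then lexicographically. After the first vote, ``rounds - 1``
    refinement passes re-align all segments against the current consensus
    as the backbone, which removes the vote-splitting that alignment
    ambiguity around the initial backbone's own errors can cause.
    """
    if not segments:
        return ConsensusSeq(call_id=call_id, sequence="", n_support=0,
                            low_confidence=True)
    if len(segments) == 1:
        return ConsensusSeq(
            call_id=call_id,
            sequence=segments[0],
            n_support=1,
            column_depths=[1] * len(segments[0]),
            low_confidence=True,
        )
    bb_idx = _median_length_index(segments)
    backbone = segments[bb_idx]
    cons = _vote_round(segments, backbone, bb_idx, call_id)
    for _ in range(max(0, rounds - 1)):
        refined = _vote_round(segments, cons.sequence, None, call_id)
        if refined.sequence == cons.sequence:
            break
        cons = refined
    return cons


def _vote_round(
    segments: list[str],
    backbone: str,
    bb_idx: int | None,
    call_id: str,
) -> ConsensusSeq:
    """One majority vote of all segments against a backbone sequence.

    When ``bb_idx`` is given, that segment *is* the backbone and votes via
    its own bases; otherwise the backbone is an external sequence (a prior
    consensus) that seeds the columns but does not vote.
    """
    n = len(segments)
    m = len(backbone)
    # votes[t] counts symbols aligned to backbone column t
    votes: list[Counter] = [Counter() for _ in range(m)]
    # insertions[t] lists, per segment, bases inserted before column t
    insertions: list[dict[int, str]] = [dict() for _ in range(m + 1)]
    if bb_idx is not None:
        for t, base in enumerate(backbone):
            votes[t][base] += 1
    for si, seg in enumerate(segments):
        if si == bb_idx:
            continue
        t = q = 0
        for op, length in _edlib_path(seg, backbone):
            if op in "=XM":
                for k in range(length):
                    votes[t + k][seg[q + k]] += 1
                t += length
                q += length
            elif op == "D":  # consumes backbone only: segment has a gap
                for k in range(length):
                    votes[t + k][_GAP] += 1
                t += length
            else:  # I: consumes segment only
                insertions[t][si] = insertions[t].get(si, "") + seg[q : q + length]
                q += length

    out: list[str] = []
    depths: list[int] = []

    def emit_column(counter: Counter, backbone_symbol: str, total: int) -> None:
        best = max(counter.values())
        tied = [sym for sym, c in counter.items() if c == best]
        if backbone_symbol in tied:
            winner = backbone_symbol
        else:
            bases = sorted(s for s in tied if s != _GAP)
            winner = bases[0] if bases else _GAP
        if winner != _GAP:
            out.append(winner)
            depths.append(total - counter[_GAP])

    def emit_insertion_slot(slot: dict[int, str]) -> None:
        if not slot:
            return
        width = max(len(s) for s in slot.values())
        for k in range(width):
            counter: Counter = Counter()
            for si in range(n):
                if si == bb_idx:
                    counter[_GAP] += 1
                    continue
                s = slot.get(si, "")
                counter[s[k] if k < len(s) else _GAP] += 1
            emit_column(counter, _GAP, n)

    for t in range(m):
        emit_insertion_slot(insertions[t])
        emit_column(votes[t], backbone[t], n)
    emit_insertion_slot(insertions[m])

    return ConsensusSeq(
        call_id=call_id,
        sequence="".join(out),
        n_support=n,
        column_depths=depths,
    )


def validate_consensus(
    consensus: ConsensusSeq,
    call: SvCall,
    reference: dict[str, str] | None = None,
    psl_records: list[PslRecord] | None = None,
    max_ins_distance: int = 100,
    window_pad: int = 2000,
    flank_probe: int = 500,
    min_identity: float = 0.7,
) -> ConsensusSeq:
    """Accept or reject a consensus by remapping it near its call.

    A deletion consensus is accepted when its remapped span overlaps the
    call interval; an insertion consensus when the remapped insertion point
    lies within ``max_ins_distance`` of the original call position.
    External PSL remap records for this call take precedence; otherwise the
    consensus flanks are aligned to the local reference window.
    """
    consensus.accepted = False
    if not consensus.sequence or consensus.n_support < 1:
        return consensus
    lo, hi = call.interval

    if psl_records is not None:
        hits = [
            r
            for r in psl_records
            if r.q_name == consensus.call_id and r.identity >= min_identity
        ]
        if not hits:
            return consensus
        best = max(hits, key=lambda r: r.matches)
        if best.t_name != call.chrom1:
            return consensus
        if call.sv_type is SvType.DEL:
            ok = best.t_start < hi and best.t_end > lo
            consensus.remap_distance = 0 if ok else None
            consensus.accepted = bool(ok) and not consensus.low_confidence
        else:
            dist = int(min(abs(best.t_start - lo), abs(best.t_end - lo)))
            if best.t_start <= lo <= best.t_end:
                dist = 0
            consensus.remap_distance = dist
            consensus.accepted = (
                dist <= max_ins_distance and not consensus.low_confidence
            )
        return consensus

    if reference is None:
        raise ValueError("validate_consensus needs a reference or PSL records")
    from .mechanics import _align_flank, _local_aligner

    seq = reference[call.chrom1]
    w_lo = max(0, lo - window_pad)
    window = seq[w_lo : min(len(seq), hi + window_pad)]
    cons = consensus.sequence
    # probes anchored at the consensus ends: each covers one reference
    # flank plus a little event content, so its trimmed alignment end on
    # the window marks where the remap places the junction
    probe_len = min(flank_probe + 100, max(100, len(cons) // 2))
    up = _align_flank(_local_aligner(), cons[:probe_len], window, trim_end="high")
    down = _align_flank(_local_aligner(), cons[-probe_len:], window, trim_end="low")
    if up is None or down is None or up[2] < min_identity or down[2] < min_identity:
        return consensus
    up_end = w_lo + up[1]
    down_start = w_lo + down[0]
    if call.sv_type is SvType.DEL:
        ok = up_end < hi and down_start > lo
        consensus.remap_distance = (
            0 if ok else int(max(up_end - hi, lo - down_start))
        )
        consensus.accepted = bool(ok) and not consensus.low_confidence
    else:
        dist = int(min(abs(up_end - lo), abs(down_start - lo)))
        consensus.remap_distance = dist
        consensus.accepted = dist <= max_ins_distance and not consensus.low_confidence
    return consensus


def write_consensus_fasta(consensuses: list[ConsensusSeq], path) -> None:
    with open(path, "w") as fh:
        for c in consensuses:
            if not c.sequence:
                continue
            state = "accepted" if c.accepted else "unvalidated"
            fh.write(f">{c.call_id} n_support={c.n_support} {state}\n")
            for i in range(0, len(c.sequence), 80):
                fh.write(c.sequence[i : i + 80] + "\n")
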