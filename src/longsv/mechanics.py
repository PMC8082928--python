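"""Breakpoint anatomy, repair-mechanism classification and ancestral events.

Deletions (and somatic junctions generally) arise from distinct repair
pathways that leave measurable fingerprints at the junction:

* **NAHR** — non-allelic homologous recombination between long homologous
  tracts; the two reference flanks share > 100 bp across the junction.
* **alt-EJ** — microhomology-mediated end joining; short (2-100 bp)
  homology.
* **NHEJ** — blunt or near-blunt joins, possibly with a few untemplated
  bases.
* **FoSTeS/MMBIR** — replication-based template switching; longer (here
  >= 10 bp) templated insertions between the breakpoints.

Homology is measured as the overlap of the two reference-flank alignments
on the consensus (alignment overlap, not exact string match, since a
consensus retains residual errors); junction insertion is the consensus
interval covered by neither flank.

Ancestral inference compares breakpoint-anchor distances between the
reference and an outgroup (chimpanzee) genome: anchors are placed 100 bp
outside each breakpoint, so anchors flanking nothing lie 200 bp apart and
anchors flanking a retained segment lie ``length + 200`` bp apart. The
ratio of outgroup to reference anchor distance (after subtracting the
200 bp of anchor) places each indel in "outgroup has it" (~1) or
"outgroup lacks it" (~0) bands, from which the causal event (insertion or
deletion in the human lineage) follows.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio import Align

from .model import AncestralCall, BreakpointAnatomy, Mechanism, MechanismCall, SvType


@dataclass
class MechanismThresholds:
    """Band boundaries of the four-way junction classification."""

    nahr_min_homology: int = 101  # "> 100 bp homology"
    altej_min_homology: int = 2
    nhej_max_insertion: int = 9  # >= 10 bp insertion -> FoSTeS/MMBIR
    min_flank_identity: float = 0.8


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -2
    a.extend_gap_score = -1
    return a


#: the junction-facing end of a flank alignment is trimmed back to the last
#: run of this many consecutive matching columns, so short chance matches
#: past the true junction cannot inflate the measured homology (a chance
#: run of 10 arises with probability ~4^-10 per position pair)
MATCH_RUN = 10


def _align_flank(
    aligner: Align.PairwiseAligner,
    flank: str,
    consensus: str,
    trim_end: str = "none",  # {"none", "high", "low"}
) -> tuple[int, int, float] | None:
    """Consensus interval covered by the flank's best local alignment.

    ``trim_end`` selects which end abuts the junction: that end is trimmed
    back to the nearest ``MATCH_RUN`` consecutive exact matches.
    """
    if not flank or not consensus:
        return None
    alns = aligner.align(flank, consensus)
    if len(alns) == 0:
        return None
    best = alns[0]
    q_blocks, t_blocks = best.aligned
    if len(t_blocks) == 0:
        return None
    # (flank pos, consensus pos, is_match, starts_new_block); a match streak
    # must not survive a gap, or a gap-jump to a chance match would defeat
    # the trim
    cols: list[tuple[int, int, bool, bool]] = []
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        first = True
        for q, t in zip(range(qs, qe), range(ts, te)):
            cols.append((q, t, flank[q] == consensus[t], first))
            first = False
    matches = sum(1 for c in cols if c[2])
    identity = matches / len(cols) if cols else 0.0
    run = min(MATCH_RUN, max(1, len(cols) // 2))
    if trim_end == "high":
        last = None
        streak = 0
        for i, (_q, _t, m, nb) in enumerate(cols):
            if nb:
                streak = 0
            streak = streak + 1 if m else 0
            if streak >= run:
                last = i
        if last is None:
            return None
        cols = cols[: last + 1]
        # the optimal path may have routed true boundary bases into a
        # trimmed junk extension; recover them by exact greedy extension
        q, t = cols[-1][0] + 1, cols[-1][1] + 1
        while q < len(flank) and t < len(consensus) and flank[q] == consensus[t]:
            cols.append((q, t, True, False))
            q += 1
            t += 1
    elif trim_end == "low":
        first_i = None
        streak = 0
        for i in range(len(cols) - 1, -1, -1):
            streak = streak + 1 if cols[i][2] else 0
            if streak >= run:
                first_i = i
            if cols[i][3]:
                streak = 0
        if first_i is None:
            return None
        cols = cols[first_i:]
        q, t = cols[0][0] - 1, cols[0][1] - 1
        while q >= 0 and t >= 0 and flank[q] == consensus[t]:
            cols.insert(0, (q, t, True, False))
            q -= 1
            t -= 1
    start = cols[0][1]
    end = cols[-1][1] + 1
    return start, end, identity


def measure_breakpoint(
    consensus: str,
    ref_up_flank: str,
    ref_down_flank: str,
    call_id: str = "",
    thresholds: MechanismThresholds | None = None,
) -> BreakpointAnatomy:
    """Measure junction homology and inserted bases on a consensus.

    ``ref_up_flank`` covers the upstream breakpoint (ending past it),
    ``ref_down_flank`` the downstream one (starting before it). Both are
    locally aligned to the consensus; homology is the length of consensus
    covered by *both* alignments, and the junction insertion is the
    consensus interval covered by neither. If either flank aligns at under
    80% identity the anatomy is undefined and the mechanism later falls to
    unclassified.
    """
    th = thresholds or MechanismThresholds()
    aligner = _local_aligner()
    up = _align_flank(aligner, ref_up_flank, consensus, trim_end="high")
    down = _align_flank(aligner, ref_down_flank, consensus, trim_end="low")
    if up is None or down is None:
        return BreakpointAnatomy(call_id, 0, "", (0.0, 0.0), defined=False)
    if up[2] < th.min_flank_identity or down[2] < th.min_flank_identity:
        return BreakpointAnatomy(call_id, 0, "", (up[2], down[2]), defined=False)
    # a chance local hit of a handful of bases can reach 100% identity; a
    # genuine flank alignment covers hundreds of consensus bases
    min_cols = min(100, len(consensus) // 4)
    if (up[1] - up[0]) < min_cols or (down[1] - down[0]) < min_cols:
        return BreakpointAnatomy(call_id, 0, "", (up[2], down[2]), defined=False)
    up_end = up[1]
    down_start = down[0]
    homology = max(0, up_end - down_start)
    insertion = consensus[up_end:down_start] if down_start > up_end else ""
    if homology > 0:
        insertion = ""
    return BreakpointAnatomy(
        call_id=call_id,
        homology_len=homology,
        junction_insertion=insertion,
        flank_identities=(up[2], down[2]),
    )


def classify_mechanism(
    anatomy: BreakpointAnatomy, thresholds: MechanismThresholds | None = None
) -> MechanismCall:
    """Four-way junction classification from measured anatomy."""
    th = thresholds or MechanismThresholds()
    if not anatomy.defined:
        return MechanismCall(anatomy.call_id, Mechanism.UNCLASSIFIED)
    h = anatomy.homology_len
    ins = len(anatomy.junction_insertion)
    if h >= th.nahr_min_homology:
        mech = Mechanism.NAHR
    elif h >= th.altej_min_homology:
        mech = Mechanism.ALT_EJ
    elif ins > th.nhej_max_insertion:
        mech = Mechanism.FOSTES_MMBIR
    else:
        mech = Mechanism.NHEJ
    return MechanismCall(anatomy.call_id, mech)


#: ratio bands: the outgroup "has" the event when the ratio is near 0 or 1
BAND_ABSENT = (-0.3, 0.3)
BAND_PRESENT = (0.7, 1.3)
ANCHOR_SPAN = 200  # two 100 bp anchors


def ancestral_ratio(
    grch38_dist: int, pantro_dist: int, sv_length: int | None = None
) -> float:
    """Anchor-distance ratio (outgroup vs reference).

    The denominator is the reference anchor distance minus the 200 bp of
    anchors; for reference-based insertions the breakpoints coincide and
    the denominator degenerates to zero, in which case the SV length (the
    separation the breakpoints would have in the carrier genome) is used.
    """
    den = grch38_dist - ANCHOR_SPAN
    if den == 0:
        if not sv_length:
            return float("nan")
        den = sv_length
    return (pantro_dist - ANCHOR_SPAN) / den


def infer_ancestral_event(
    sv_type: SvType,
    grch38_dist: int,
    pantro_dist: int,
    sv_length: int | None = None,
    indel_id: str = "",
) -> AncestralCall:
    """Classify an indel as caused by an insertion or deletion event.

    Reference-based deletions present in the outgroup (ratio in the
    near-zero band) were in fact insertions on the reference lineage;
    deletions absent from the outgroup are true deletion events, and
    symmetrically for insertions. A ratio outside both bands leaves the
    indel unclassified.
    """
    r = ancestral_ratio(grch38_dist, pantro_dist, sv_length)
    in_absent = BAND_ABSENT[0] <= r <= BAND_ABSENT[1]
    in_present = BAND_PRESENT[0] <= r <= BAND_PRESENT[1]
    if sv_type is SvType.DEL:
        chimp_has = in_absent  # outgroup anchors flank nothing: deletion shared
        if chimp_has:
            event = "insertion_event"
        elif in_present:
            event = "deletion_event"
        else:
            event = "unclassified"
    elif sv_type is SvType.INS:
        chimp_has = in_present
        if chimp_has:
            event = "deletion_event"
        elif in_absent:
            event = "insertion_event"
        else:
            event = "unclassified"
    else:
        event = "unclassified"
    return AncestralCall(indel_id=indel_id, ratio=r, event=event)


def mechanism_summary(calls: list[MechanismCall]) -> dict[str, int]:
    counts = Counter(str(c.mechanism) for c in calls)
    return {str(m): counts.get(str(m), 0) for m in Mechanism}


def compare_mechanism_proportions(
    germline: list[MechanismCall], somatic: list[MechanismCall]
) -> tuple[float, float]:
    """Chi-square test of germline vs somatic mechanism proportions.

    Returns (statistic, p_value); categories empty in both sets are
    dropped.
    """
    from scipy.stats import chi2_contingency

    cats = [m for m in Mechanism if m is not Mechanism.UNCLASSIFIED]
    g = Counter(c.mechanism for c in germline)
    s = Counter(c.mechanism for c in somatic)
    table = [
        [g.get(m, 0), s.get(m, 0)]
        for m in cats
        if g.get(m, 0) + s.get(m, 0) > 0
    ]
    if len(table) < 2:
        return 0.0, 1.0
    stat, p, _dof, _exp = chi2_contingency(table)
    return float(stat), float(p)


def write_mechanism_table(
    rows: list[tuple[str, BreakpointAnatomy, MechanismCall, AncestralCall | None]],
    path,
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "call_id\thomology_len\tinsertion_len\tmechanism\tratio\tevent\n"
        )
        for call_id, anatomy, mech, anc in rows:
            fh.write(
                "\t".join(
                    [
                        call_id,
                        str(anatomy.homology_len),
                        str(len(anatomy.junction_insertion)),
                        str(mech.mechanism),
                        f"{anc.ratio:.3f}" if anc else "NA",
                        anc.event if anc else "NA",
                    ]
                )
                + "\n"
            )
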