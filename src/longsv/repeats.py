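"""Repeat annotation parsing and insertion-content classification.

Consumes RepeatMasker ``.out`` and Tandem Repeat Finder ``.dat`` files
(the two annotators' standard outputs; neither tool is run here) and
classifies SV consensus sequences by their repeat content:

* sequences >= 50% covered by short repeats (simple/tandem and low
  complexity) are excluded from event analysis — a single-mutation model
  cannot be assumed inside unstable tandem arrays;
* a single transposable element covering >= 80% makes a ``single_SINE`` /
  ``single_LINE`` insertion; two or more elements jointly covering >= 80%
  make ``multi_repeat``; any transposon overlap below 80% is
  ``repeat_included``; otherwise ``non_repeat``.

Additional features follow retrotransposition biology: 5' truncation of
the element, twin-priming (two inverted LINE segments from one
integration), poly(A) tails not templated by the reference, and — for
non-repeat insertions — tandem duplications, templated insertions and
processed pseudogenes identified from remap (PSL) hits and gene models.
"""

from __future__ import annotations

import logging

from .model import (
    RepeatInterval,
    SHORT_REPEAT_CLASSES,
    SvRepeatProfile,
    TRANSPOSON_CLASSES,
)
from .vcfio import Bed12Gene, PslRecord

log = logging.getLogger(__name__)

_CLASS_MAP = [
    ("SINE", "SINE"),
    ("LINE", "LINE"),
    ("LTR", "LTR"),
    ("DNA", "DNA"),
    ("Simple_repeat", "Simple/Tandem"),
    ("Satellite", "Simple/Tandem"),
    ("Low_complexity", "Low_complexity"),
]


def _normalize_class(raw: str) -> str:
    for prefix, name in _CLASS_MAP:
        if raw.startswith(prefix):
            return name
    return "Other"


def parse_repeatmasker_out(path) -> list[RepeatInterval]:
    """Parse RepeatMasker ``.out`` (1-based, inclusive) into intervals."""
    out: list[RepeatInterval] = []
    bad = 0
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if len(f) < 14 or not f[0].replace(".", "").isdigit():
                continue
            try:
                seq_id = f[4]
                start = int(f[5]) - 1
                end = int(f[6])
                strand = "+" if f[8] == "+" else "-"
                family = f[9]
                klass = _normalize_class(f[10])
                if strand == "+":
                    cons_start = int(f[11]) - 1
                    cons_end = int(f[12])
                else:
                    # complement hits list (left) end begin
                    cons_end = int(f[12])
                    cons_start = int(f[13]) - 1
                out.append(
                    RepeatInterval(
                        seq_id=seq_id,
                        start=start,
                        end=end,
                        repeat_class=klass,
                        family=family,
                        strand=strand,
                        consensus_start=cons_start,
                        consensus_end=cons_end,
                        source="repeatmasker",
                    )
                )
            except (ValueError, IndexError):
                bad += 1
    if bad:
        log.warning("%s: skipped %d unparseable lines", path, bad)
    return out


def parse_trf_dat(path) -> list[RepeatInterval]:
    """Parse Tandem Repeat Finder ``.dat`` into Simple/Tandem intervals."""
    out: list[RepeatInterval] = []
    seq_id = ""
    bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("Sequence:"):
                seq_id = line.split(None, 1)[1].split()[0]
                continue
            f = line.split()
            if len(f) < 14 or not f[0].isdigit():
                continue
            try:
                out.append(
                    RepeatInterval(
                        seq_id=seq_id,
                        start=int(f[0]) - 1,
                        end=int(f[1]),
                        repeat_class="Simple/Tandem",
                        family=f"({f[13]})n",
                        strand="+",
                        source="trf",
                    )
                )
            except (ValueError, IndexError):
                bad += 1
    if bad:
        log.warning("%s: skipped %d unparseable records", path, bad)
    return out


def parse_repeat_files(rm_out=None, trf_dat=None) -> list[RepeatInterval]:
    """Merged interval list from RepeatMasker and TRF outputs.

    Overlapping hits from the two annotators are kept separately; each
    interval records its provenance in ``source``.
    """
    repeats: list[RepeatInterval] = []
    if rm_out is not None:
        repeats.extend(parse_repeatmasker_out(rm_out))
    if trf_dat is not None:
        repeats.extend(parse_trf_dat(trf_dat))
    repeats.sort(key=lambda r: (r.seq_id, r.start, r.end))
    return repeats


def union_covered(
    intervals: list[tuple[int, int]], lo: int = 0, hi: int | None = None
) -> int:
    """Total bases covered by the union of intervals (clipped to [lo, hi))."""
    spans = []
    for s, e in intervals:
        s = max(s, lo)
        e = e if hi is None else min(e, hi)
        if e > s:
            spans.append((s, e))
    if not spans:
        return 0
    spans.sort()
    total = 0
    cs, ce = spans[0]
    for s, e in spans[1:]:
        if s > ce:
            total += ce - cs
            cs, ce = s, e
        else:
            ce = max(ce, e)
    total += ce - cs
    return total


def _polyA_tail(seq: str, min_len: int = 10, max_mismatch: int = 1,
                ref_flank: str = "") -> bool:
    """Terminal poly(A) (or leading poly(T)) run not present in the flank."""
    def run_ok(s: str, base: str) -> bool:
        window = s[:min_len + max_mismatch]
        if len(window) < min_len:
            return False
        return sum(1 for c in window[:min_len] if c != base) <= max_mismatch

    tail = run_ok(seq[::-1], "A")
    head = run_ok(seq, "T")
    if not (tail or head):
        return False
    if ref_flank:
        if tail and run_ok(ref_flank, "A"):
            return False
        if head and run_ok(ref_flank[::-1], "T"):
            return False
    return True


def classify_sv_sequence(
    consensus: str,
    repeats: list[RepeatInterval],
    call_id: str = "",
    short_repeat_fraction: float = 0.5,
    repeat_cover_fraction: float = 0.8,
    ref_flank: str = "",
) -> SvRepeatProfile:
    """Classify one consensus sequence by its repeat annotation.

    ``repeats`` holds the annotation of this sequence only (seq_id
    agreement is not checked). Categories are mutually exclusive and
    assigned in order: short-repeat exclusion, single element, multiple
    elements, partial overlap, none.
    """
    n = len(consensus)
    by_class: dict[str, float] = {}
    for klass in set(r.repeat_class for r in repeats) | {"SINE", "LINE"}:
        cov = union_covered(
            [(r.start, r.end) for r in repeats if r.repeat_class == klass],
            0,
            n,
        )
        by_class[klass] = cov / n if n else 0.0

    short_cov = union_covered(
        [(r.start, r.end) for r in repeats if r.repeat_class in SHORT_REPEAT_CLASSES],
        0,
        n,
    )
    transposons = [r for r in repeats if r.repeat_class in TRANSPOSON_CLASSES]
    trans_cov = union_covered([(r.start, r.end) for r in transposons], 0, n)

    lines = [r for r in transposons if r.repeat_class == "LINE"]
    twin = len(lines) >= 2 and len({r.strand for r in lines}) == 2
    polyA = _polyA_tail(consensus, ref_flank=ref_flank) if n else False

    if n and short_cov / n >= short_repeat_fraction:
        category = "short_repeat_excluded"
    elif n and trans_cov / n >= repeat_cover_fraction:
        singles = [
            r
            for r in transposons
            if (min(r.end, n) - max(r.start, 0)) / n >= repeat_cover_fraction
        ]
        if singles:
            best = max(singles, key=lambda r: r.span)
            category = (
                "single_SINE" if best.repeat_class == "SINE" else
                "single_LINE" if best.repeat_class == "LINE" else
                "multi_repeat"
            )
        else:
            category = "multi_repeat"
    elif trans_cov > 0:
        category = "repeat_included"
    else:
        category = "non_repeat"

    truncation = 0
    if category in ("single_SINE", "single_LINE"):
        best = max(transposons, key=lambda r: r.span)
        truncation = best.consensus_start

    return SvRepeatProfile(
        call_id=call_id,
        covered_fraction=by_class,
        category=category,
        families=sorted({r.family for r in transposons}),
        strands=[r.strand for r in transposons],
        truncation_5prime=truncation,
        twin_priming=twin,
        polyA_tail=polyA,
    )


def classify_nonrepeat_insertion(
    consensus: str,
    insertion_chrom: str,
    insertion_pos: int,
    psl_records: list[PslRecord],
    genes: list[Bed12Gene] | None = None,
    call_id: str = "",
    min_identity: float = 0.7,
    adjacency: int = 1000,
    polyA: bool | None = None,
) -> str:
    """Origin of a non-repeat insertion from remap hits.

    A hit adjacent to the insertion site (within ``adjacency``) is a
    tandem duplication; a contiguous hit elsewhere a templated insertion;
    a hit split across >= 2 exons of one gene — or an exonic hit together
    with a non-reference poly(A) tail — a processed pseudogene.
    """
    hits = [
        r
        for r in psl_records
        if (not call_id or r.q_name == call_id) and r.identity >= min_identity
    ]
    if not hits:
        return "none"
    if polyA is None:
        polyA = _polyA_tail(consensus)
    best = max(hits, key=lambda r: r.matches)

    if genes:
        for gene in genes:
            if gene.chrom != best.t_name:
                continue
            blocks = [
                (ts, ts + sz)
                for ts, sz in zip(best.t_starts, best.block_sizes)
            ]
            exon_hits = [
                (bs, be)
                for bs, be in blocks
                if any(bs < ee and be > es for es, ee in gene.exons)
            ]
            distinct_exons = {
                i
                for i, (es, ee) in enumerate(gene.exons)
                for bs, be in blocks
                if bs < ee and be > es
            }
            if len(distinct_exons) >= 2:
                return "processed_pseudogene"
            if exon_hits and polyA:
                return "processed_pseudogene"

    if best.t_name == insertion_chrom:
        dist = max(0, max(best.t_start - insertion_pos, insertion_pos - best.t_end))
        if dist <= adjacency:
            return "tandem_dup"
    if best.block_count <= 2:
        return "template_insertion"
    return "template_insertion"


def write_profiles_tsv(profiles: list[SvRepeatProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "call_id\tcategory\tfamilies\tstrands\ttruncation_5prime\t"
            "twin_priming\tpolyA_tail\tdup_or_pseudogene\n"
        )
        for p in profiles:
            fh.write(
                "\t".join(
                    [
                        p.call_id,
                        p.category,
                        ",".join(p.families) or ".",
                        ",".join(p.strands) or ".",
                        str(p.truncation_5prime),
                        str(int(p.twin_priming)),
                        str(int(p.polyA_tail)),
                        p.dup_or_pseudogene,
                    ]
                )
                + "\n"
            )
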