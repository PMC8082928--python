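"""Spike structural variants into donor genomes with exact truth records.

A donor haplotype is represented as an ordered list of blocks, each either
a (possibly reverse-complemented) reference interval or a novel inserted
sequence. Reads simulated from the block structure can therefore carry
exact truth alignments without running a mapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..model import RepeatInterval, SvType
from .reference import (
    HBV_LIKE_GENOME,
    L1_CONSENSUS,
    ReferenceBuild,
    SINE_FAMILIES,
    _random_seq,
    revcomp,
)


@dataclass
class SvSpec:
    """Specification of one SV to spike.

    ``vaf`` 1.0 plants the variant on both haplotypes (homozygous), 0.5 on
    one (heterozygous). ``homology``/``junction_insertion`` shape the
    breakpoint junction of deletions; they are mutually exclusive.
    ``content`` selects the inserted sequence of insertions: ``random``,
    ``alu_like``, ``line_like``, ``line_twin``, ``tandem_dup``,
    ``pseudogene_like`` or ``viral``.
    """

    sv_type: SvType
    length: int
    vaf: float = 0.5
    homology: int = 0
    junction_insertion: int = 0
    content: str = "random"
    samples: tuple[str, ...] = ("S1",)
    chrom: str = "chr1"
    pos: int | None = None  # chosen by the planner when None
    ancestral_event: str = ""  # intended label for the lifted table

    def __post_init__(self) -> None:
        if self.homology and self.junction_insertion:
            raise ValueError("homology and junction_insertion are exclusive")
        if self.sv_type in (SvType.INS, SvType.DEL) and self.length < 100:
            raise ValueError("INS/DEL spikes must be >= 100 bp")


@dataclass
class Block:
    """One building block of a donor haplotype."""

    kind: str  # {"ref", "ins"}
    chrom: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    seq: str = ""
    mappable: bool = True  # False: aligner would fail to place (viral DNA)

    def length(self, ref: dict[str, str]) -> int:
        return (self.end - self.start) if self.kind == "ref" else len(self.seq)

    def sequence(self, ref: dict[str, str]) -> str:
        if self.kind == "ins":
            return self.seq
        s = ref[self.chrom][self.start : self.end]
        return s if self.strand == "+" else revcomp(s)


@dataclass
class DonorHaplotype:
    blocks: list[Block]
    sample_id: str = ""
    hap: int = 0

    def total_length(self, ref: dict[str, str]) -> int:
        return sum(b.length(ref) for b in self.blocks)

    def sequence(self, ref: dict[str, str]) -> str:
        return "".join(b.sequence(ref) for b in self.blocks)


@dataclass
class TruthRecord:
    sv_id: str
    sv_type: SvType
    chrom: str
    pos1: int
    pos2: int
    length: int
    vaf: float
    content: str = "random"
    mechanism: str = ""
    ancestral_event: str = ""
    carriers: tuple[str, ...] = ()
    inserted_seq: str = ""
    insert_repeats: list[RepeatInterval] = field(default_factory=list)


@dataclass
class SpikeResult:
    haplotypes: dict[str, list[DonorHaplotype]]  # sample -> two haplotypes
    truth: list[TruthRecord]
    lifted: list[tuple[str, int, int]]  # (sv_id, ref_dist, chimp_dist)


def _mechanism_label(spec: SvSpec) -> str:
    if spec.sv_type is not SvType.DEL:
        return ""
    if spec.homology > 100:
        return "NAHR"
    if spec.homology >= 2:
        return "alt_EJ"
    if spec.junction_insertion >= 10:
        return "FoSTeS_MMBIR"
    return "NHEJ"


def _insertion_content(
    spec: SvSpec, ref: dict[str, str], pos: int, rng: np.random.Generator
) -> tuple[str, list[RepeatInterval], bool]:
    """Inserted sequence, its repeat annotation, and mappability."""
    L = spec.length
    reps: list[RepeatInterval] = []
    mappable = True
    if spec.content == "alu_like":
        fam = "AluYa5"
        body = SINE_FAMILIES[fam][:max(100, min(L - 12, 300))]
        seq = body + "A" * max(0, L - len(body))
        reps.append(
            RepeatInterval("", 0, len(body), "SINE", fam, "+", 0, 300, "repeatmasker")
        )
    elif spec.content == "line_like":
        trunc = max(0, len(L1_CONSENSUS) - max(100, L - 12))
        body = L1_CONSENSUS[trunc:]
        seq = body + "A" * max(0, L - len(body))
        seq = seq[:L] if len(seq) > L else seq
        reps.append(
            RepeatInterval(
                "", 0, len(body), "LINE", "L1HS", "+", trunc, 6000, "repeatmasker"
            )
        )
    elif spec.content == "line_twin":
        # twin-priming pattern: two inverted L1 pieces in one insertion
        half = max(100, (L - 10) // 2)
        p1 = L1_CONSENSUS[-half:]
        p2 = revcomp(L1_CONSENSUS[-(half + 200) : -200][:half])
        seq = p1 + p2 + "A" * 10
        reps.append(
            RepeatInterval("", 0, len(p1), "LINE", "L1HS", "+", 6000 - half, 6000,
                           "repeatmasker")
        )
        reps.append(
            RepeatInterval("", len(p1), len(p1) + len(p2), "LINE", "L1HS", "-",
                           6000 - half - 200, 6000 - 200, "repeatmasker")
        )
    elif spec.content == "tandem_dup":
        seq = ref[spec.chrom][pos - L : pos]
    elif spec.content == "pseudogene_like":
        # two spliced "exons" from a distant locus plus a poly(A) tail
        src = len(ref[spec.chrom]) // 3
        ex1 = ref[spec.chrom][src : src + max(60, (L - 20) // 2)]
        ex2 = ref[spec.chrom][src + 5000 : src + 5000 + max(60, (L - 20) // 2)]
        seq = ex1 + ex2 + "A" * 20
    elif spec.content == "viral":
        seq = HBV_LIKE_GENOME[: max(L, 500)]
        mappable = False
    else:
        seq = _random_seq(rng, L)
    return seq, reps, mappable


def plan_svs(
    build: ReferenceBuild,
    specs: list[SvSpec],
    seed: int = 0,
    margin: int = 3000,
    edge_margin: int | None = None,
) -> list[SvSpec]:
    """Assign non-overlapping reference positions to specs lacking one.

    Deletions requesting junction homology are routed to planted homology
    sites of matching length. SVs keep ``edge_margin`` away from the
    sequence ends, where read coverage tapers off.
    """
    rng = np.random.default_rng(seed + 7)
    chrom = next(iter(build.seqs))
    span = len(build.seqs[chrom])
    if edge_margin is None:
        edge_margin = max(margin, min(12_000, span // 10))
    margin = max(margin, 1)
    occupied: list[tuple[int, int]] = []
    for s in specs:
        if s.pos is not None:
            w = s.length if s.sv_type is not SvType.INS else 1
            occupied.append((s.pos - margin, s.pos + w + margin))
    planned = []
    for spec in specs:
        spec = SvSpec(**{**vars(spec)})
        if spec.pos is None:
            if spec.sv_type is SvType.DEL and spec.homology > 0:
                site = next(
                    (
                        h
                        for h in build.homology_sites
                        if not h.used
                        and h.homology == spec.homology
                        and h.pos2 - h.pos1 == spec.length
                    ),
                    None,
                )
                if site is None:
                    raise ValueError(
                        f"no planted homology site for h={spec.homology}, "
                        f"L={spec.length}"
                    )
                site.used = True
                spec.pos = site.pos1
                occupied.append((spec.pos - margin, spec.pos + spec.length + margin))
            else:
                w = spec.length if spec.sv_type is not SvType.INS else 1
                for _ in range(500):
                    pos = int(rng.integers(edge_margin, span - w - edge_margin))
                    if all(
                        pos + w + margin <= s or pos >= e + margin
                        for s, e in occupied
                    ):
                        occupied.append((pos - margin, pos + w + margin))
                        spec.pos = pos
                        break
                else:
                    raise ValueError("could not place SV; reference too crowded")
        planned.append(spec)
    planned.sort(key=lambda s: s.pos)
    return planned


def _apply_to_haplotype(
    specs: list[SvSpec],
    ref: dict[str, str],
    chrom: str,
    rng: np.random.Generator,
    contents: dict[str, tuple[str, list[RepeatInterval], bool]],
) -> list[Block]:
    """Build the block list of one haplotype carrying ``specs`` (sorted)."""
    blocks: list[Block] = []
    cursor = 0
    span = len(ref[chrom])
    for spec in specs:
        pos = spec.pos
        if spec.sv_type is SvType.DEL:
            blocks.append(Block("ref", chrom, cursor, pos))
            if spec.junction_insertion:
                key = _spec_key(spec)
                blocks.append(
                    Block("ins", seq=contents[key][0], mappable=True)
                )
            cursor = pos + spec.length
        elif spec.sv_type is SvType.INS:
            blocks.append(Block("ref", chrom, cursor, pos))
            seq, _reps, mappable = contents[_spec_key(spec)]
            blocks.append(Block("ins", seq=seq, mappable=mappable))
            cursor = pos
        elif spec.sv_type is SvType.INV:
            blocks.append(Block("ref", chrom, cursor, pos))
            blocks.append(Block("ref", chrom, pos, pos + spec.length, strand="-"))
            cursor = pos + spec.length
        elif spec.sv_type is SvType.TRA_INTRA:  # tandem duplication
            blocks.append(Block("ref", chrom, cursor, pos + spec.length))
            blocks.append(Block("ref", chrom, pos, pos + spec.length))
            cursor = pos + spec.length
        else:
            raise ValueError(f"unsupported spike type {spec.sv_type}")
    blocks.append(Block("ref", chrom, cursor, span))
    return [b for b in blocks if b.length(ref) > 0]


def _spec_key(spec: SvSpec) -> str:
    return f"{spec.sv_type}_{spec.chrom}_{spec.pos}_{spec.length}"


def spike_svs(
    build: ReferenceBuild, specs: list[SvSpec], seed: int = 0
) -> SpikeResult:
    """Apply planned SVs and emit truth records plus the lifted-anchor table.

    The lifted table encodes an ancestral genome consistent with each
    record's intended event label: breakpoint anchors are placed 100 bp
    outside each breakpoint, so two anchors flanking nothing are 200 bp
    apart and anchors flanking a retained segment are ``length + 200`` bp
    apart.
    """
    rng = np.random.default_rng(seed + 13)
    ref = build.seqs
    chrom = next(iter(ref))
    specs = [s if s.pos is not None else None for s in specs]
    if any(s is None for s in specs):
        raise ValueError("run plan_svs() first: every spec needs a position")
    specs = sorted(specs, key=lambda s: s.pos)

    contents: dict[str, tuple[str, list[RepeatInterval], bool]] = {}
    for spec in specs:
        if spec.sv_type is SvType.INS:
            contents[_spec_key(spec)] = _insertion_content(spec, ref, spec.pos, rng)
        elif spec.sv_type is SvType.DEL and spec.junction_insertion:
            j = list(_random_seq(rng, spec.junction_insertion))
            # guard the untemplated bases against the flank continuations so
            # the measured junction insertion matches the planted one exactly
            seq = ref[chrom]
            for k, guard in ((0, seq[spec.pos]),
                             (-1, seq[spec.pos + spec.length - 1])):
                if j[k] == guard:
                    j[k] = "ACGT"[("ACGT".index(j[k]) + 1) % 4]
            contents[_spec_key(spec)] = ("".join(j), [], True)

    samples = sorted({sid for s in specs for sid in s.samples})
    haplotypes: dict[str, list[DonorHaplotype]] = {}
    for sid in samples:
        haps = []
        for hap in (0, 1):
            mine = [
                s
                for s in specs
                if sid in s.samples and (s.vaf >= 1.0 or hap == 0)
            ]
            haps.append(
                DonorHaplotype(
                    blocks=_apply_to_haplotype(mine, ref, chrom, rng, contents),
                    sample_id=sid,
                    hap=hap,
                )
            )
        haplotypes[sid] = haps

    truth: list[TruthRecord] = []
    lifted: list[tuple[str, int, int]] = []
    for i, spec in enumerate(specs):
        sv_id = f"truth_{i:04d}_{spec.sv_type}"
        pos2 = (
            spec.pos + spec.length
            if spec.sv_type is not SvType.INS
            else spec.pos
        )
        key = _spec_key(spec)
        ins_seq, ins_reps, _m = contents.get(key, ("", [], True))
        rec = TruthRecord(
            sv_id=sv_id,
            sv_type=spec.sv_type,
            chrom=chrom,
            pos1=spec.pos,
            pos2=pos2,
            length=spec.length,
            vaf=spec.vaf,
            content=spec.content,
            mechanism=_mechanism_label(spec),
            ancestral_event=spec.ancestral_event,
            carriers=spec.samples,
            inserted_seq=ins_seq if spec.sv_type is SvType.INS else "",
            insert_repeats=[
                RepeatInterval(**{**vars(r), "seq_id": sv_id}) for r in ins_reps
            ],
        )
        truth.append(rec)
        if spec.sv_type in (SvType.DEL, SvType.INS) and spec.ancestral_event:
            ref_dist = 200 + (spec.length if spec.sv_type is SvType.DEL else 0)
            jitter = int(rng.integers(-spec.length // 20 - 1, spec.length // 20 + 2))
            if spec.sv_type is SvType.DEL:
                chimp_has_it = spec.ancestral_event == "insertion_event"
                chimp_dist = 200 + (0 if chimp_has_it else spec.length) + jitter
                chimp_dist = max(0, chimp_dist) if chimp_has_it else chimp_dist
            else:
                chimp_has_it = spec.ancestral_event == "deletion_event"
                chimp_dist = 200 + (spec.length if chimp_has_it else 0) + (
                    jitter if chimp_has_it else 0
                )
            lifted.append((sv_id, ref_dist, chimp_dist))
    return SpikeResult(haplotypes=haplotypes, truth=truth, lifted=lifted)


def write_truth_vcf(truth: list[TruthRecord], seqs: dict[str, str], path) -> None:
    from ..vcfio import write_vcf_records

    records = [
        dict(
            chrom=t.chrom,
            pos=t.pos1,
            id=t.sv_id,
            sv_type=t.sv_type,
            end=t.pos2,
            length=t.length,
            support=0,
            vaf=t.vaf,
            filters=[],
            seq=t.inserted_seq,
        )
        for t in truth
    ]
    write_vcf_records(records, seqs, path)


def write_lifted_table(lifted: list[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("indel_id\tgrch38_dist\tpantro_dist\n")
        for sv_id, d1, d2 in lifted:
            fh.write(f"{sv_id}\t{d1}\t{d2}\n")
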