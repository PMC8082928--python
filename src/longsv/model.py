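"""Core domain types for long-read structural-variant analysis.

All genomic coordinates are 0-based half-open internally; VCF export
converts to 1-based. Positions on reads ("query" coordinates) follow the
orientation of the stored sequence (SAM orientation, i.e. reference-forward
for mapped records).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class SvType(str, enum.Enum):
    """Structural-variant classes modeled by the pipeline.

    TRA_INTRA covers same-chromosome junctions whose segments are out of
    reference order (the signature left by tandem duplications) or separated
    by a very large gap. CLIP is a one-sided breakend from a long unresolved
    soft clip; it only corroborates large insertions.
    """

    INS = "INS"
    DEL = "DEL"
    INV = "INV"
    TRA_INTRA = "TRA_INTRA"
    TRA_INTER = "TRA_INTER"
    CLIP = "CLIP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: sv types whose breakpoints cluster with the wider (non-indel) window
NON_INDEL_TYPES = frozenset({SvType.INV, SvType.TRA_INTRA, SvType.TRA_INTER})


@dataclass
class SplitSegment:
    """One aligned segment of a split (supplementary) alignment."""

    chrom: str
    start: int
    end: int
    strand: str
    read_start: int
    read_end: int
    mapq: int = 0

    @property
    def ref_span(self) -> int:
        return self.end - self.start


@dataclass
class ReadAlignment:
    """A primary alignment together with its split-alignment siblings.

    ``split_segments`` holds every aligned segment of the read (including
    the primary one) ordered by read coordinate; it is empty when the read
    aligns in one piece.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    cigar: list[tuple[str, int]]
    read_length: int
    left_clip: int = 0
    right_clip: int = 0
    split_segments: list[SplitSegment] = field(default_factory=list)
    is_primary: bool = True
    query_sequence: str | None = None
    sample_id: str = ""

    def spans(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class SvSignature:
    """One read's evidence for one SV.

    ``qpos1``/``qpos2`` locate the event on the stored read sequence so
    that consensus building can cut out the event with its flanks.
    ``nearby_ins_len`` records, for deletion signatures, the longest
    insertion found in the same read within a fixed distance of the
    deletion breakpoints (used by the deletion-with-insertion artifact
    filter).
    """

    sv_type: SvType
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    length: int
    read_id: str
    read_offset_fraction: float
    source: str  # {"cigar", "split"}
    inserted_seq: str = ""
    mapq: int = 0
    qpos1: int = 0
    qpos2: int = 0
    nearby_ins_len: int = 0
    clip_side: str = ""  # {"left", "right"} for CLIP breakends
    sample_id: str = ""


@dataclass
class SvCluster:
    """Signatures from nearby breakpoints merged into one candidate event."""

    sv_type: SvType
    members: list[SvSignature]
    chrom1: str = ""
    pos1: int = 0
    chrom2: str = ""
    pos2: int = 0
    length: int = 0
    support: int = 0
    mean_mapq: float = 0.0

    def __post_init__(self) -> None:
        if self.members and not self.chrom1:
            self.refresh()

    def refresh(self) -> None:
        """Recompute representative coordinates (member medians)."""
        ms = self.members
        self.chrom1 = ms[0].chrom1
        self.chrom2 = ms[0].chrom2
        self.pos1 = _median_int(sorted(m.pos1 for m in ms))
        self.pos2 = _median_int(sorted(m.pos2 for m in ms))
        self.length = _median_int(sorted(m.length for m in ms))
        self.support = len({m.read_id for m in ms})
        self.mean_mapq = sum(m.mapq for m in ms) / len(ms)

    @property
    def read_ids(self) -> set[str]:
        return {m.read_id for m in self.members}


def _median_int(sorted_vals: list[int]) -> int:
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return sorted_vals[mid]
    return (sorted_vals[mid - 1] + sorted_vals[mid]) // 2


class FilterFlag(str, enum.Enum):
    LOW_SUPPORT = "low_support"
    EDGE_READS = "edge_reads"
    DEL_WITH_INS = "del_with_ins"
    LOW_MQ_REGION = "low_mq_region"
    LOW_VAF = "low_vaf"
    REPEAT80 = "repeat80"
    SEGDUP = "segdup"
    CHIMERIC = "chimeric"
    IN_NORMAL = "in_normal"
    IN_PANEL = "in_panel"
    LOW_NORMAL_DEPTH = "low_normal_depth"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class SvCall:
    """A clustered, filtered SV in one sample."""

    id: str
    sample_id: str
    sv_type: SvType
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    length: int
    support: int
    depth_at_breakpoint: int = 0
    vaf: float = 0.0
    filter_flags: set[FilterFlag] = field(default_factory=set)
    inserted_seq: str = ""
    support_read_ids: set[str] = field(default_factory=set)
    cluster: SvCluster | None = None

    @property
    def passes(self) -> bool:
        return not self.filter_flags

    @property
    def interval(self) -> tuple[int, int]:
        """Reference interval of the event (point interval for insertions)."""
        if self.sv_type is SvType.INS:
            return (self.pos1, self.pos1 + 1)
        lo, hi = min(self.pos1, self.pos2), max(self.pos1, self.pos2)
        return (lo, max(hi, lo + 1))


@dataclass
class PopulationSv:
    """A germline SV merged across samples with a population frequency."""

    call: SvCall
    carrier_sample_ids: list[str]
    allele_count: int
    allele_frequency: float
    per_sample_calls: dict[str, SvCall] = field(default_factory=dict)


@dataclass
class SomaticSvCall:
    """A tumor SV after matched-normal and panel subtraction."""

    call: SvCall
    normal_support: int = 0
    matched_normal_depth: int = 0

    @property
    def passes(self) -> bool:
        return self.call.passes


@dataclass
class IntegrationSite:
    """A clustered virus-host junction."""

    human_chrom: str
    human_pos: int
    virus_name: str
    virus_pos: int
    orientation: str
    support: int
    read_ids: set[str] = field(default_factory=set)


@dataclass
class ConsensusSeq:
    """Majority-vote consensus across support-read segments of one SV."""

    call_id: str
    sequence: str
    n_support: int
    column_depths: list[int] = field(default_factory=list)
    accepted: bool = False
    low_confidence: bool = False
    remap_distance: int | None = None


@dataclass
class RepeatInterval:
    """One annotated repeat on a reference or consensus sequence."""

    seq_id: str
    start: int
    end: int
    repeat_class: str  # SINE, LINE, LTR, DNA, Simple/Tandem, Low_complexity, Other
    family: str = ""
    strand: str = "+"
    # position of the hit on the repeat-family consensus (5' truncation)
    consensus_start: int = 0
    consensus_end: int = 0
    source: str = ""  # {"repeatmasker", "trf"}

    @property
    def span(self) -> int:
        return self.end - self.start


#: repeat classes counted as "short repeats" by the filters
SHORT_REPEAT_CLASSES = frozenset({"Simple/Tandem", "Low_complexity"})
TRANSPOSON_CLASSES = frozenset({"SINE", "LINE", "LTR", "DNA"})


@dataclass
class SvRepeatProfile:
    call_id: str
    covered_fraction: dict[str, float]
    category: str  # single_SINE, single_LINE, multi_repeat, repeat_included,
    #               non_repeat, short_repeat_excluded
    families: list[str] = field(default_factory=list)
    strands: list[str] = field(default_factory=list)
    truncation_5prime: int = 0
    twin_priming: bool = False
    polyA_tail: bool = False
    dup_or_pseudogene: str = "none"


@dataclass
class BreakpointAnatomy:
    """Junction measurements taken from a consensus and reference flanks.

    Exactly one of homology and junction insertion can be non-trivial:
    overlapping flank alignments imply homology and leave no unassigned
    consensus bases, and vice versa.
    """

    call_id: str
    homology_len: int
    junction_insertion: str
    flank_identities: tuple[float, float] = (1.0, 1.0)
    defined: bool = True


class Mechanism(str, enum.Enum):
    NAHR = "NAHR"
    ALT_EJ = "alt_EJ"
    NHEJ = "NHEJ"
    FOSTES_MMBIR = "FoSTeS_MMBIR"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class MechanismCall:
    call_id: str
    mechanism: Mechanism


@dataclass
class AncestralCall:
    indel_id: str
    ratio: float
    event: str  # {insertion_event, deletion_event, unclassified}


@dataclass
class MatchResult:
    """Outcome of matching a callset against a truth/benchmark set."""

    common: list[tuple[object, object]]
    truth_only: list[object]
    calls_only: list[object]
    precision: float
    recall: float
    f_measure: float
    degenerate: bool = False
    strata: dict[str, dict[str, int]] = field(default_factory=dict)
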