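"""Cluster SV signatures into calls and apply germline filters.

The calling logic follows a window-based single-linkage clustering of
per-read signatures, support thresholds that depend on SV type and size
(long deletions need fewer supporting reads than short ones because short
deletion errors dominate nanopore data), and a battery of artifact filters:
reads supporting an event near their own ends, deletions accompanied by a
nearby insertion in the same read, regions of unreliable mapping, very low
variant allele frequency, short-repeat-saturated spans, and segmental
duplications.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from intervaltree import IntervalTree

from .model import (
    NON_INDEL_TYPES,
    FilterFlag,
    PopulationSv,
    ReadAlignment,
    RepeatInterval,
    SHORT_REPEAT_CLASSES,
    SvCall,
    SvCluster,
    SvSignature,
    SvType,
)


@dataclass
class GermlineConfig:
    """Thresholds of the germline caller (defaults are the recommended set)."""

    min_indel: int = 100
    min_clip: int = 500
    min_mapq_candidate: int = 20
    cluster_window_indel: int = 50
    cluster_window_other: int = 100
    merge_window_ins: int = 300
    merge_window_other: int = 1000
    min_reciprocal_overlap: float = 0.8
    edge_fraction: float = 0.1
    del_ins_window: int = 30
    del_ins_fraction_small: float = 0.1
    del_ins_fraction_large: float = 0.3
    del_large_cutoff: int = 1000
    support_del_short: int = 4  # 100-500 bp
    support_del_mid: int = 3  # 501-1000 bp
    support_del_long: int = 2  # > 1000 bp
    support_ins_short: int = 3  # <= 1000 bp
    support_ins_long: int = 2  # > 1000 bp
    support_other: int = 2
    min_vaf: float = 0.03
    low_mq_mapq: int = 30
    low_mq_fraction: float = 0.3
    low_mq_flank: int = 500
    repeat_cover_fraction: float = 0.8
    hom_vaf: float = 0.7
    min_population_af: float = 0.1


def cluster_window(sv_type: SvType, cfg: GermlineConfig) -> int:
    if sv_type in NON_INDEL_TYPES:
        return cfg.cluster_window_other
    return cfg.cluster_window_indel


def merge_window(sv_type: SvType, cfg: GermlineConfig) -> int:
    return cfg.merge_window_ins if sv_type is SvType.INS else cfg.merge_window_other


def cluster_signatures(
    signatures: list[SvSignature], cfg: GermlineConfig | None = None
) -> list[SvCluster]:
    """Single-linkage clustering of same-type signatures along the genome.

    Two signatures are linked when both breakpoints lie within the
    type-specific window (50 bp for indels, 100 bp for inversions and
    translocations). Input may mix types and chromosomes; clustering is
    performed per (type, chrom pair) partition and is invariant to input
    order.
    """
    cfg = cfg or GermlineConfig()
    parts: dict[tuple, list[SvSignature]] = defaultdict(list)
    for s in signatures:
        parts[(s.sv_type, s.chrom1, s.chrom2)].append(s)

    clusters: list[SvCluster] = []
    for (sv_type, _c1, _c2), sigs in sorted(
        parts.items(), key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2])
    ):
        w = cluster_window(sv_type, cfg)
        sigs = sorted(sigs, key=lambda s: (s.pos1, s.pos2, s.read_id))
        current: list[SvSignature] = []
        for s in sigs:
            if current and (
                s.pos1 - current[-1].pos1 <= w and abs(s.pos2 - current[-1].pos2) <= w
            ):
                current.append(s)
            else:
                if current:
                    clusters.append(SvCluster(sv_type=sv_type, members=current))
                current = [s]
        if current:
            clusters.append(SvCluster(sv_type=sv_type, members=current))
    return clusters


def is_candidate(cluster: SvCluster, cfg: GermlineConfig | None = None) -> bool:
    """Candidate clusters have >= 2 reads with adequate mapping quality."""
    cfg = cfg or GermlineConfig()
    good = {
        m.read_id for m in cluster.members if m.mapq >= cfg.min_mapq_candidate
    }
    return len(good) >= 2


def reciprocal_overlap(a: SvCluster, b: SvCluster) -> float:
    """Reciprocal overlap of two SV intervals; insertions use length ratio."""
    if a.sv_type is SvType.INS:
        la, lb = max(1, a.length), max(1, b.length)
        return min(la, lb) / max(la, lb)
    a_lo, a_hi = sorted((a.pos1, a.pos2))
    b_lo, b_hi = sorted((b.pos1, b.pos2))
    ov = min(a_hi, b_hi) - max(a_lo, b_lo)
    if ov <= 0:
        return 0.0
    return min(ov / max(1, a_hi - a_lo), ov / max(1, b_hi - b_lo))


def same_sv(a: SvCluster, b: SvCluster, cfg: GermlineConfig | None = None) -> bool:
    """Identity rule used for merging and cross-sample/panel comparison."""
    cfg = cfg or GermlineConfig()
    if a.sv_type is not b.sv_type or a.chrom1 != b.chrom1 or a.chrom2 != b.chrom2:
        return False
    w = merge_window(a.sv_type, cfg)
    if abs(a.pos1 - b.pos1) > w or abs(a.pos2 - b.pos2) > w:
        return False
    return reciprocal_overlap(a, b) >= cfg.min_reciprocal_overlap


def merge_candidate_breakpoints(
    clusters: list[SvCluster], cfg: GermlineConfig | None = None
) -> list[SvCluster]:
    """Merge candidate clusters that describe the same SV.

    Same-type clusters are merged when their breakpoints lie within 300 bp
    (insertions) or 1000 bp (other types) *and* their SV intervals overlap
    reciprocally by at least 80% (insertions compared by length ratio).
    Merging is transitive (union-find) and idempotent.
    """
    cfg = cfg or GermlineConfig()
    n = len(clusters)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(n), key=lambda i: (clusters[i].chrom1, clusters[i].pos1))
    max_w = max(cfg.merge_window_ins, cfg.merge_window_other)
    for ii, i in enumerate(order):
        for j in order[ii + 1 :]:
            if clusters[j].chrom1 != clusters[i].chrom1:
                break
            if clusters[j].pos1 - clusters[i].pos1 > max_w:
                break
            if same_sv(clusters[i], clusters[j], cfg):
                union(i, j)

    groups: dict[int, list[SvCluster]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(clusters[i])
    merged = []
    for members in groups.values():
        sigs = [m for c in members for m in c.members]
        # deduplicate identical signature objects (idempotent re-merge)
        seen = set()
        uniq = []
        for s in sigs:
            key = (s.read_id, s.pos1, s.pos2, s.source, s.qpos1)
            if key not in seen:
                seen.add(key)
                uniq.append(s)
        merged.append(SvCluster(sv_type=members[0].sv_type, members=uniq))
    merged.sort(key=lambda c: (c.chrom1, c.pos1, c.chrom2, c.pos2))
    return merged


def _del_ins_artifact(sig: SvSignature, cfg: GermlineConfig) -> bool:
    """Deletion read carrying a suspicious nearby insertion."""
    if sig.sv_type is not SvType.DEL or sig.nearby_ins_len == 0:
        return False
    frac = (
        cfg.del_ins_fraction_small
        if sig.length < cfg.del_large_cutoff
        else cfg.del_ins_fraction_large
    )
    return sig.nearby_ins_len >= frac * sig.length


def _within_read_edge(sig: SvSignature, cfg: GermlineConfig) -> bool:
    f = sig.read_offset_fraction
    return f < cfg.edge_fraction or f > 1 - cfg.edge_fraction


def required_support(sv_type: SvType, length: int, cfg: GermlineConfig) -> int:
    if sv_type is SvType.DEL:
        if length <= 500:
            return cfg.support_del_short
        if length <= cfg.del_large_cutoff:
            return cfg.support_del_mid
        return cfg.support_del_long
    if sv_type is SvType.INS:
        return (
            cfg.support_ins_short
            if length <= cfg.del_large_cutoff
            else cfg.support_ins_long
        )
    return cfg.support_other


def has_two_sided_clip_support(
    cluster: SvCluster,
    clip_signatures: list[SvSignature],
    cfg: GermlineConfig | None = None,
) -> bool:
    """>= 2 reads clipped on each side of the cluster's breakpoint.

    A large insertion that few reads can span fully still leaves clusters
    of long soft clips pointing at the insertion point from both sides.
    """
    cfg = cfg or GermlineConfig()
    w = max(cluster_window(SvType.INS, cfg), cfg.merge_window_ins)
    left = {
        s.read_id
        for s in clip_signatures
        if s.clip_side == "right"
        and s.chrom1 == cluster.chrom1
        and abs(s.pos1 - cluster.pos1) <= w
    }
    right = {
        s.read_id
        for s in clip_signatures
        if s.clip_side == "left"
        and s.chrom1 == cluster.chrom1
        and abs(s.pos1 - cluster.pos1) <= w
    }
    return len(left) >= 2 and len(right) >= 2


def apply_support_filters(
    cluster: SvCluster,
    cfg: GermlineConfig | None = None,
    clip_signatures: list[SvSignature] | None = None,
    sample_id: str = "",
    call_id: str = "",
) -> SvCall:
    """Filter support reads and apply type/size support thresholds.

    Reads whose signature sits within the terminal 10% of the read are
    discarded before counting, as are deletion reads whose nearby insertion
    exceeds 10% (deletions < 1000 bp) or 30% (longer) of the deletion
    length. Insertions > 1000 bp may alternatively be supported by >= 2
    long-clipped reads on *each* side of the breakpoint.
    """
    cfg = cfg or GermlineConfig()
    kept = []
    edge_removed = ins_removed = 0
    for m in cluster.members:
        if _within_read_edge(m, cfg):
            edge_removed += 1
            continue
        if _del_ins_artifact(m, cfg):
            ins_removed += 1
            continue
        kept.append(m)

    flags: set[FilterFlag] = set()
    kept_cluster = SvCluster(sv_type=cluster.sv_type, members=kept or cluster.members)
    if not kept:
        kept_cluster = SvCluster(sv_type=cluster.sv_type, members=cluster.members)
        kept_cluster.refresh()
        support = 0
    else:
        kept_cluster.refresh()
        support = kept_cluster.support

    need = required_support(cluster.sv_type, kept_cluster.length, cfg)
    ok = support >= need
    if (
        not ok
        and cluster.sv_type is SvType.INS
        and kept_cluster.length > cfg.del_large_cutoff
        and clip_signatures
        and has_two_sided_clip_support(kept_cluster, clip_signatures, cfg)
    ):
        ok = True
    if not ok:
        flags.add(FilterFlag.LOW_SUPPORT)
        if edge_removed and support < need:
            flags.add(FilterFlag.EDGE_READS)
        if ins_removed and support < need:
            flags.add(FilterFlag.DEL_WITH_INS)

    best_seq = ""
    for m in kept or cluster.members:
        if len(m.inserted_seq) > len(best_seq):
            best_seq = m.inserted_seq
    return SvCall(
        id=call_id or f"{kept_cluster.sv_type}_{kept_cluster.chrom1}_{kept_cluster.pos1}",
        sample_id=sample_id,
        sv_type=kept_cluster.sv_type,
        chrom1=kept_cluster.chrom1,
        pos1=kept_cluster.pos1,
        chrom2=kept_cluster.chrom2,
        pos2=kept_cluster.pos2,
        length=kept_cluster.length,
        support=support,
        inserted_seq=best_seq,
        support_read_ids=kept_cluster.read_ids if kept else set(),
        filter_flags=flags,
        cluster=kept_cluster,
    )


class DepthIndex:
    """Breakpoint-spanning depth and mapping-quality lookups."""

    def __init__(self, alignments: list[ReadAlignment]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for aln in alignments:
            if aln.end > aln.start:
                self._trees[aln.chrom][aln.start : aln.end] = aln
            for seg in aln.split_segments:
                if seg is not None and seg.end > seg.start:
                    self._trees[seg.chrom][seg.start : seg.end] = aln

    def spanning_reads(self, chrom: str, pos: int) -> list[ReadAlignment]:
        seen = {}
        for iv in self._trees.get(chrom, IntervalTree()).at(pos):
            seen[iv.data.read_id] = iv.data
        return list(seen.values())

    def depth(self, chrom: str, pos: int) -> int:
        return len(self.spanning_reads(chrom, pos))

    def low_mq_fraction(self, chrom: str, pos: int, flank: int, mq: int) -> float:
        reads = {}
        for p in (pos - flank, pos, pos + flank):
            for r in self.spanning_reads(chrom, max(0, p)):
                reads[r.read_id] = r
        if not reads:
            return 0.0
        low = sum(1 for r in reads.values() if r.mapq < mq)
        return low / len(reads)


class RepeatIndex:
    """Interval lookups over a repeat annotation of the reference."""

    def __init__(self, repeats: list[RepeatInterval]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for r in repeats:
            if r.end > r.start:
                self._trees[r.seq_id][r.start : r.end] = r

    def covered_fraction(
        self, chrom: str, start: int, end: int, classes: frozenset | set | None = None
    ) -> float:
        """Fraction of [start, end) covered by the union of matching repeats."""
        if end <= start:
            return 0.0
        spans = []
        for iv in self._trees.get(chrom, IntervalTree()).overlap(start, end):
            if classes is None or iv.data.repeat_class in classes:
                spans.append((max(start, iv.begin), min(end, iv.end)))
        if not spans:
            return 0.0
        spans.sort()
        covered = 0
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
        return covered / (end - start)


class SegdupIndex:
    """Segmental-duplication BED with a name column identifying pairs."""

    def __init__(self, records: list[tuple[str, int, int, str]]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for chrom, start, end, name in records:
            if end > start:
                self._trees[chrom][start:end] = (name, start, end)

    @classmethod
    def from_bed(cls, path) -> "SegdupIndex":
        recs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                recs.append((f[0], int(f[1]), int(f[2]), name))
        return cls(recs)

    def hits(self, chrom: str, pos: int) -> set[tuple[str, int, int]]:
        return {iv.data for iv in self._trees.get(chrom, IntervalTree()).at(pos)}

    def both_breakpoints_in_same_dup(self, call: SvCall) -> bool:
        """True when the two breakpoints sit in *different* segments of one
        segmental duplication (same name, disjoint intervals)."""
        h1 = self.hits(call.chrom1, call.pos1)
        h2 = self.hits(call.chrom2, call.pos2)
        for name1, s1, e1 in h1:
            for name2, s2, e2 in h2:
                if name1 == name2 and (s1, e1) != (s2, e2):
                    return True
        return False


def apply_region_filters(
    call: SvCall,
    depth_index: DepthIndex,
    repeat_index: RepeatIndex | None = None,
    segdup_index: SegdupIndex | None = None,
    cfg: GermlineConfig | None = None,
    repeat80_types: frozenset = NON_INDEL_TYPES,
) -> SvCall:
    """VAF, unreliably-mapped-region, short-repeat and segdup filters.

    ``repeat80_types`` controls which SV types the >= 80% short-repeat
    cover filter applies to (inversions/translocations at the germline
    stage; deletions are added at the somatic stage).
    """
    cfg = cfg or GermlineConfig()
    depth = max(
        depth_index.depth(call.chrom1, call.pos1),
        depth_index.depth(call.chrom2, call.pos2),
    )
    call.depth_at_breakpoint = depth
    call.vaf = min(1.0, call.support / depth) if depth else 0.0
    if call.vaf < cfg.min_vaf:
        call.filter_flags.add(FilterFlag.LOW_VAF)
    low_frac = max(
        depth_index.low_mq_fraction(
            call.chrom1, call.pos1, cfg.low_mq_flank, cfg.low_mq_mapq
        ),
        depth_index.low_mq_fraction(
            call.chrom2, call.pos2, cfg.low_mq_flank, cfg.low_mq_mapq
        ),
    )
    if low_frac >= cfg.low_mq_fraction:
        call.filter_flags.add(FilterFlag.LOW_MQ_REGION)
    if (
        repeat_index is not None
        and call.sv_type in repeat80_types
        and call.chrom1 == call.chrom2
    ):
        lo, hi = call.interval
        frac = repeat_index.covered_fraction(
            call.chrom1, lo, hi, SHORT_REPEAT_CLASSES
        )
        if frac >= cfg.repeat_cover_fraction:
            call.filter_flags.add(FilterFlag.REPEAT80)
    if (
        segdup_index is not None
        and call.sv_type in repeat80_types
        and segdup_index.both_breakpoints_in_same_dup(call)
    ):
        call.filter_flags.add(FilterFlag.SEGDUP)
    return call


def flag_chimeric_signatures(signatures: list[SvSignature]) -> list[SvSignature]:
    """Drop split signatures bearing a ligation-artifact fingerprint.

    Heuristic: a split signature whose supporting segments overlap by more
    than half on the read is dropped at extraction time already; here we
    additionally drop groups of split signatures in which every supporting
    read shares the identical read-coordinate breakpoint and strand — real
    SVs are sampled at random read offsets.
    """
    by_locus: dict[tuple, list[SvSignature]] = defaultdict(list)
    keep: list[SvSignature] = []
    for s in signatures:
        if s.source != "split":
            keep.append(s)
            continue
        by_locus[(s.sv_type, s.chrom1, s.pos1 // 1000, s.chrom2, s.pos2 // 1000)].append(s)
    for group in by_locus.values():
        if len(group) >= 2 and len({(s.qpos1, s.qpos2) for s in group}) == 1:
            continue  # identical read-coordinate junction in every read
        keep.extend(group)
    return keep


def call_sample(
    alignments: list[ReadAlignment],
    cfg: GermlineConfig | None = None,
    repeat_index: RepeatIndex | None = None,
    segdup_index: SegdupIndex | None = None,
    sample_id: str = "",
    enable_inter: bool = False,
    repeat80_types: frozenset = NON_INDEL_TYPES,
) -> list[SvCall]:
    """Full single-sample detection: signatures -> clusters -> filtered calls.

    Returns every candidate call (passing and flagged); callers select with
    ``call.passes``. Inter-chromosomal junctions are only emitted when
    ``enable_inter`` is set (somatic mode).
    """
    from .ingest import extract_all_signatures

    cfg = cfg or GermlineConfig()
    sigs = extract_all_signatures(
        alignments, min_indel=cfg.min_indel, min_clip=cfg.min_clip
    )
    sigs = flag_chimeric_signatures(sigs)
    if not enable_inter:
        sigs = [s for s in sigs if s.sv_type is not SvType.TRA_INTER]
    clips = [s for s in sigs if s.sv_type is SvType.CLIP]
    sv_sigs = [s for s in sigs if s.sv_type is not SvType.CLIP]

    clusters = cluster_signatures(sv_sigs, cfg)
    candidates = [c for c in clusters if is_candidate(c, cfg)]
    # large insertions that almost no read spans: a lone insertion-bearing
    # read corroborated by clipped-read clusters on both sides still
    # qualifies as a candidate
    kept = {id(c) for c in candidates}
    for c in clusters:
        if (
            id(c) not in kept
            and c.sv_type is SvType.INS
            and c.length > cfg.del_large_cutoff
            and has_two_sided_clip_support(c, clips, cfg)
        ):
            candidates.append(c)
    merged = merge_candidate_breakpoints(candidates, cfg)

    depth_index = DepthIndex(alignments)
    calls = []
    for i, cluster in enumerate(merged):
        call = apply_support_filters(
            cluster,
            cfg,
            clip_signatures=clips,
            sample_id=sample_id,
            call_id=f"{sample_id or 'S'}.{i:05d}",
        )
        call = apply_region_filters(
            call,
            depth_index,
            repeat_index=repeat_index,
            segdup_index=segdup_index,
            cfg=cfg,
            repeat80_types=repeat80_types,
        )
        calls.append(call)
    return calls


def _call_as_cluster(call: SvCall) -> SvCluster:
    if call.cluster is not None:
        return call.cluster
    c = SvCluster(sv_type=call.sv_type, members=[])
    c.chrom1, c.pos1 = call.chrom1, call.pos1
    c.chrom2, c.pos2 = call.chrom2, call.pos2
    c.length = call.length
    c.support = call.support
    return c


def merge_across_samples(
    callsets: dict[str, list[SvCall]],
    n_samples: int | None = None,
    cfg: GermlineConfig | None = None,
) -> list[PopulationSv]:
    """Merge per-sample germline callsets into a population callset.

    Cross-sample identity uses the same window + 80% reciprocal-overlap
    rule as within-sample merging. Each carrier contributes 2 alleles when
    its VAF suggests homozygosity (>= ``hom_vaf``) and 1 otherwise; SVs
    with allele frequency below ``min_population_af`` are dropped.
    """
    cfg = cfg or GermlineConfig()
    n_samples = n_samples if n_samples is not None else len(callsets)
    entries = [
        (sid, call)
        for sid, calls in sorted(callsets.items())
        for call in calls
        if call.passes
    ]
    merged_groups: list[list[tuple[str, SvCall]]] = []
    for sid, call in sorted(
        entries, key=lambda e: (e[1].chrom1, e[1].pos1, e[1].chrom2, e[1].pos2)
    ):
        placed = False
        for group in merged_groups:
            rep = group[0][1]
            if same_sv(_call_as_cluster(rep), _call_as_cluster(call), cfg):
                group.append((sid, call))
                placed = True
                break
        if not placed:
            merged_groups.append([(sid, call)])

    out = []
    for group in merged_groups:
        carriers = sorted({sid for sid, _ in group})
        allele_count = 0
        per_sample = {}
        for sid, call in group:
            if sid in per_sample:
                continue
            per_sample[sid] = call
            allele_count += 2 if call.vaf >= cfg.hom_vaf else 1
        af = allele_count / (2 * n_samples)
        if af < cfg.min_population_af:
            continue
        rep = max(group, key=lambda e: e[1].support)[1]
        out.append(
            PopulationSv(
                call=rep,
                carrier_sample_ids=carriers,
                allele_count=allele_count,
                allele_frequency=af,
                per_sample_calls=per_sample,
            )
        )
    out.sort(key=lambda p: (p.call.chrom1, p.call.pos1, p.call.chrom2, p.call.pos2))
    return out
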