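"""Somatic SV calling by tumor/normal subtraction, and virus integration.

Tumor candidates are detected exactly as germline candidates (with
inter-chromosomal translocations enabled) and then subtracted: any
candidate with read-level evidence in the matched normal, any candidate
present in a panel of pooled germline calls from all normal samples, and
any candidate where the matched normal is too shallow to exclude a
germline variant (depth < 9) is removed. Region filters are re-applied
with somatic-specific scope: the >= 80% short-repeat cover filter extends
to deletions, and the segmental-duplication filter to all types.

Virus integration detection mirrors chimeric-read analysis: unmapped read
portions are aligned against a panel of small viral genomes, the genome
capturing the most reads becomes the per-sample best reference, and
human/virus junctions sharing a breakpoint within 500 bp with >= 2
supporting reads become integration sites.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib

from .germline import (
    DepthIndex,
    GermlineConfig,
    RepeatIndex,
    SegdupIndex,
    call_sample,
    same_sv,
    _call_as_cluster,
)
from .ingest import extract_all_signatures
from .model import (
    FilterFlag,
    IntegrationSite,
    ReadAlignment,
    SomaticSvCall,
    SvCall,
    SvCluster,
    SvType,
)


@dataclass
class SomaticConfig:
    germline: GermlineConfig
    min_normal_depth: int = 9
    tra_merge_window: int = 500

    def __init__(self, germline: GermlineConfig | None = None, **kw):
        self.germline = germline or GermlineConfig()
        self.min_normal_depth = kw.get("min_normal_depth", 9)
        self.tra_merge_window = kw.get("tra_merge_window", 500)


def _somatic_same_sv(a: SvCluster, b: SvCluster, cfg: SomaticConfig) -> bool:
    """Identity rule with the 500 bp window for translocation breakends."""
    if a.sv_type is SvType.TRA_INTER and b.sv_type is SvType.TRA_INTER:
        return (
            a.chrom1 == b.chrom1
            and a.chrom2 == b.chrom2
            and abs(a.pos1 - b.pos1) <= cfg.tra_merge_window
            and abs(a.pos2 - b.pos2) <= cfg.tra_merge_window
        )
    return same_sv(a, b, cfg.germline)


class NormalPanel:
    """Pooled germline calls from all normal samples, queryable by identity."""

    def __init__(self, calls: list[SvCall], cfg: SomaticConfig | None = None):
        self.cfg = cfg or SomaticConfig()
        self._by_type: dict[SvType, list[SvCluster]] = defaultdict(list)
        for c in calls:
            self._by_type[c.sv_type].append(_call_as_cluster(c))

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_type.values())

    def contains(self, call: SvCall) -> bool:
        probe = _call_as_cluster(call)
        return any(
            _somatic_same_sv(probe, entry, self.cfg)
            for entry in self._by_type.get(call.sv_type, [])
        )


def merge_translocation_breakends(
    calls: list[SvCall], window: int = 500
) -> list[SvCall]:
    """Merge inter-chromosomal breakend pairs within ``window`` on both ends."""
    tras = [c for c in calls if c.sv_type is SvType.TRA_INTER]
    others = [c for c in calls if c.sv_type is not SvType.TRA_INTER]
    merged: list[SvCall] = []
    for c in sorted(tras, key=lambda c: (c.chrom1, c.pos1, c.chrom2, c.pos2)):
        target = None
        for m in merged:
            if (
                m.chrom1 == c.chrom1
                and m.chrom2 == c.chrom2
                and abs(m.pos1 - c.pos1) <= window
                and abs(m.pos2 - c.pos2) <= window
            ):
                target = m
                break
        if target is None:
            merged.append(c)
        else:
            target.support_read_ids |= c.support_read_ids
            target.support = max(
                target.support, len(target.support_read_ids)
            )
            target.filter_flags &= c.filter_flags
    return others + merged


def normal_evidence_clusters(
    normal_alignments: list[ReadAlignment], cfg: GermlineConfig
) -> list[SvCluster]:
    """Per-read SV evidence in the normal, with no support threshold.

    Any single normal read showing the same SV disqualifies a somatic
    candidate, so clustering here keeps singletons.
    """
    from .germline import cluster_signatures

    sigs = extract_all_signatures(
        normal_alignments, min_indel=cfg.min_indel, min_clip=cfg.min_clip
    )
    sigs = [s for s in sigs if s.sv_type is not SvType.CLIP]
    return cluster_signatures(sigs, cfg)


def call_somatic(
    tumor_calls: list[SvCall],
    normal_clusters: list[SvCluster],
    panel: NormalPanel | None,
    normal_alignments: list[ReadAlignment],
    cfg: SomaticConfig | None = None,
    repeat_index: RepeatIndex | None = None,
    segdup_index: SegdupIndex | None = None,
) -> list[SomaticSvCall]:
    """Subtract matched-normal and panel evidence from tumor candidates.

    ``tumor_calls`` should come from the germline detection stages run on
    the tumor with inter-chromosomal junctions enabled; all tumor-side
    filters (support, VAF, low-MQ) are assumed applied there. Returns
    every candidate with somatic filter flags added; passing calls have no
    flags.
    """
    cfg = cfg or SomaticConfig()
    normal_depth = DepthIndex(normal_alignments)
    tumor_calls = merge_translocation_breakends(
        list(tumor_calls), cfg.tra_merge_window
    )
    out: list[SomaticSvCall] = []
    for call in tumor_calls:
        probe = _call_as_cluster(call)
        nsupport = 0
        for nc in normal_clusters:
            if nc.sv_type is call.sv_type and _somatic_same_sv(probe, nc, cfg):
                nsupport = max(nsupport, nc.support)
        ndepth = min(
            normal_depth.depth(call.chrom1, call.pos1),
            normal_depth.depth(call.chrom2, call.pos2),
        )
        sc = SomaticSvCall(
            call=call, normal_support=nsupport, matched_normal_depth=ndepth
        )
        if nsupport > 0:
            call.filter_flags.add(FilterFlag.IN_NORMAL)
        if panel is not None and panel.contains(call):
            call.filter_flags.add(FilterFlag.IN_PANEL)
        if ndepth < cfg.min_normal_depth:
            call.filter_flags.add(FilterFlag.LOW_NORMAL_DEPTH)
        if repeat_index is not None and call.chrom1 == call.chrom2:
            lo, hi = call.interval
            if call.sv_type in (SvType.DEL, SvType.INV, SvType.TRA_INTRA,
                                SvType.TRA_INTER):
                from .model import SHORT_REPEAT_CLASSES

                frac = repeat_index.covered_fraction(
                    call.chrom1, lo, hi, SHORT_REPEAT_CLASSES
                )
                if frac >= cfg.germline.repeat_cover_fraction:
                    call.filter_flags.add(FilterFlag.REPEAT80)
        if segdup_index is not None and segdup_index.both_breakpoints_in_same_dup(
            call
        ):
            call.filter_flags.add(FilterFlag.SEGDUP)
        out.append(sc)
    return out


def call_somatic_pair(
    tumor_alignments: list[ReadAlignment],
    normal_alignments: list[ReadAlignment],
    panel: NormalPanel | None = None,
    cfg: SomaticConfig | None = None,
    repeat_index: RepeatIndex | None = None,
    segdup_index: SegdupIndex | None = None,
    sample_id: str = "T",
) -> list[SomaticSvCall]:
    """Full tumor/normal somatic calling from alignments."""
    cfg = cfg or SomaticConfig()
    tumor_calls = call_sample(
        tumor_alignments,
        cfg=cfg.germline,
        repeat_index=repeat_index,
        segdup_index=segdup_index,
        sample_id=sample_id,
        enable_inter=True,
    )
    normal_clusters = normal_evidence_clusters(normal_alignments, cfg.germline)
    return call_somatic(
        tumor_calls,
        normal_clusters,
        panel,
        normal_alignments,
        cfg=cfg,
        repeat_index=repeat_index,
        segdup_index=segdup_index,
    )


def write_review_report(somatic: list[SomaticSvCall], path) -> None:
    """Machine-readable read-evidence table for manual review of candidates."""
    with open(path, "w") as fh:
        fh.write(
            "call_id\tsv_type\tchrom1\tpos1\tchrom2\tpos2\tlength\tsupport\t"
            "vaf\tnormal_support\tnormal_depth\tflags\tsupport_reads\n"
        )
        for sc in somatic:
            c = sc.call
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        c.id,
                        c.sv_type,
                        c.chrom1,
                        c.pos1,
                        c.chrom2,
                        c.pos2,
                        c.length,
                        c.support,
                        f"{c.vaf:.3f}",
                        sc.normal_support,
                        sc.matched_normal_depth,
                        ";".join(str(f) for f in sorted(c.filter_flags, key=str))
                        or "PASS",
                        ",".join(sorted(c.support_read_ids)) or ".",
                    )
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# virus integration
# --------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _unmapped_intervals(aln: ReadAlignment) -> list[tuple[int, int]]:
    """Maximal read intervals (as-sequenced orientation) with no alignment."""
    n = aln.read_length
    if aln.split_segments:
        covered = sorted((s.read_start, s.read_end) for s in aln.split_segments)
    else:
        from .ingest import _read_interval

        covered = [_read_interval(aln.cigar, aln.strand, n)]
    gaps = []
    cur = 0
    for s, e in covered:
        if s > cur:
            gaps.append((cur, s))
        cur = max(cur, e)
    if cur < n:
        gaps.append((cur, n))
    return gaps


def _original_read(aln: ReadAlignment) -> str | None:
    if aln.query_sequence is None:
        return None
    return aln.query_sequence if aln.strand == "+" else _revcomp(aln.query_sequence)


def map_reads_to_viruses(
    alignments: list[ReadAlignment],
    viral_refs: dict[str, str],
    min_fragment: int = 300,
    max_divergence: float = 0.3,
) -> dict[str, dict[str, list]]:
    """Map unmapped read portions against each viral reference.

    Returns ``{virus_name: {read_id: [(read_start, read_end, virus_start,
    virus_end, orientation), ...]}}`` for fragments aligning with edit
    distance below ``max_divergence``.
    """
    hits: dict[str, dict[str, list]] = {name: {} for name in viral_refs}
    for aln in alignments:
        read = _original_read(aln)
        if read is None:
            continue
        for rs, re_ in _unmapped_intervals(aln):
            if re_ - rs < min_fragment:
                continue
            frag = read[rs:re_]
            for name, genome in viral_refs.items():
                best = None
                for orient, probe in (("+", frag), ("-", _revcomp(frag))):
                    res = edlib.align(probe, genome, task="locations", mode="HW")
                    if res["editDistance"] < 0:
                        continue
                    if res["editDistance"] / len(frag) > max_divergence:
                        continue
                    if best is None or res["editDistance"] < best[0]:
                        loc = res["locations"][0]
                        best = (res["editDistance"], orient, loc[0], loc[1] + 1)
                if best is not None:
                    hits[name].setdefault(aln.read_id, []).append(
                        (rs, re_, best[2], best[3], best[1])
                    )
    return hits


def detect_virus_integrations(
    alignments: list[ReadAlignment],
    viral_refs: dict[str, str],
    min_support: int = 2,
    cluster_window: int = 500,
    min_fragment: int = 300,
) -> tuple[str | None, list[IntegrationSite]]:
    """Find virus integration sites from chimeric human/virus reads.

    The viral reference capturing the most reads is selected per sample
    (ties resolve to input order); junctions between a read's human
    alignment and its viral fragment are clustered within
    ``cluster_window`` bp, and clusters with >= ``min_support`` reads
    become integration sites. Returns (best_reference_name, sites).
    """
    if not viral_refs:
        return None, []
    hits = map_reads_to_viruses(alignments, viral_refs, min_fragment=min_fragment)
    counts = {name: len(reads) for name, reads in hits.items()}
    best = max(counts, key=lambda name: (counts[name], -list(viral_refs).index(name)))
    if counts[best] == 0:
        return None, []

    # (chrom, human pos, virus pos, orientation, side, read) where side
    # records whether the read runs human->virus or virus->human, so the
    # two junctions of one full-length integration stay distinct
    junctions: list[tuple[str, int, int, str, str, str]] = []
    by_read = {a.read_id: a for a in alignments}
    for read_id, frags in hits[best].items():
        aln = by_read[read_id]
        segs = aln.split_segments or []
        if not segs:
            from .ingest import _read_interval

            rs, re_ = _read_interval(aln.cigar, aln.strand, aln.read_length)
            segs = [
                type("S", (), dict(chrom=aln.chrom, start=aln.start, end=aln.end,
                                   strand=aln.strand, read_start=rs, read_end=re_))()
            ]
        for frs, fre, vs, ve, orient in frags:
            for seg in segs:
                if abs(seg.read_end - frs) <= 50:
                    hpos = seg.end if seg.strand == "+" else seg.start
                    vpos = vs if orient == "+" else ve
                    junctions.append((seg.chrom, hpos, vpos, orient, "HV", read_id))
                if abs(seg.read_start - fre) <= 50:
                    hpos = seg.start if seg.strand == "+" else seg.end
                    vpos = ve if orient == "+" else vs
                    junctions.append((seg.chrom, hpos, vpos, orient, "VH", read_id))

    sites: list[IntegrationSite] = []
    # one junction = one (human locus, virus locus) pair; a full-length
    # integration yields two junctions at the same human position but at
    # opposite ends of the viral genome
    junctions.sort(key=lambda j: (j[0], j[2] // max(1, cluster_window), j[1]))
    cluster: list[tuple[str, int, int, str, str, str]] = []

    def flush() -> None:
        if not cluster:
            return
        reads = {j[5] for j in cluster}
        if len(reads) >= min_support:
            mid = sorted(j[1] for j in cluster)[len(cluster) // 2]
            vmid = sorted(j[2] for j in cluster)[len(cluster) // 2]
            orient = cluster[0][3]
            sites.append(
                IntegrationSite(
                    human_chrom=cluster[0][0],
                    human_pos=mid,
                    virus_name=best,
                    virus_pos=vmid,
                    orientation=orient,
                    support=len(reads),
                    read_ids=reads,
                )
            )

    for j in junctions:
        if cluster and (
            j[0] != cluster[-1][0]
            or abs(j[2] - cluster[-1][2]) > cluster_window
            or abs(j[1] - cluster[-1][1]) > cluster_window
        ):
            flush()
            cluster = []
        cluster.append(j)
    flush()
    sites.sort(key=lambda s: (s.human_chrom, s.human_pos, s.virus_pos))
    return best, sites


def write_integration_tsv(sites: list[IntegrationSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("human_chrom\thuman_pos\tvirus_name\tvirus_pos\t"
                 "orientation\tsupport\n")
        for s in sites:
            fh.write(
                f"{s.human_chrom}\t{s.human_pos}\t{s.virus_name}\t"
                f"{s.virus_pos}\t{s.orientation}\t{s.support}\n"
            )
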