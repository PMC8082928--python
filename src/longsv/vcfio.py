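"""VCF / BEDPE / PSL / TSV input-output for SV calls.

VCF output uses VCF 4.2 with symbolic ALT alleles (<DEL>, <INS>, <INV>,
<DUP>) and paired breakend (BND) notation for inter-chromosomal
translocations. Coordinates convert from the internal 0-based half-open
convention to VCF's 1-based. Bodies are deterministic: no timestamps, and
provenance (tool version, config hash, seed) goes into fixed header lines.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import pysam

from .model import SvCall, SvType

_ALT = {
    SvType.DEL: "<DEL>",
    SvType.INS: "<INS>",
    SvType.INV: "<INV>",
    SvType.TRA_INTRA: "<DUP>",
}
_SVTYPE_STR = {
    SvType.DEL: "DEL",
    SvType.INS: "INS",
    SvType.INV: "INV",
    SvType.TRA_INTRA: "DUP",
    SvType.TRA_INTER: "BND",
}
_FROM_STR = {
    "DEL": SvType.DEL,
    "INS": SvType.INS,
    "INV": SvType.INV,
    "DUP": SvType.TRA_INTRA,
    "TRA": SvType.TRA_INTER,
    "BND": SvType.TRA_INTER,
}


def _header_lines(
    seqs: dict[str, str] | dict[str, int],
    provenance: dict | None = None,
) -> list[str]:
    lines = [
        "##fileformat=VCFv4.2",
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=INS,Description="Insertion">',
        '##ALT=<ID=INV,Description="Inversion">',
        '##ALT=<ID=DUP,Description="Tandem duplication">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
        '##INFO=<ID=SEQ,Number=1,Type=String,Description="Inserted sequence">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">',
        '##FILTER=<ID=low_support,Description="Insufficient supporting reads">',
        '##FILTER=<ID=edge_reads,Description="Support only near read ends">',
        '##FILTER=<ID=del_with_ins,Description="Deletion-with-insertion artifact">',
        '##FILTER=<ID=low_mq_region,Description="Unreliably mapped region">',
        '##FILTER=<ID=low_vaf,Description="Variant allele frequency < threshold">',
        '##FILTER=<ID=repeat80,Description="Span >=80% short repeat">',
        '##FILTER=<ID=segdup,Description="Breakpoints in one segmental duplication">',
        '##FILTER=<ID=chimeric,Description="Chimeric-read artifact">',
        '##FILTER=<ID=in_normal,Description="Present in matched normal">',
        '##FILTER=<ID=in_panel,Description="Present in normal panel">',
        '##FILTER=<ID=low_normal_depth,Description="Matched normal depth < 9">',
    ]
    for name, seq in seqs.items():
        ln = len(seq) if isinstance(seq, str) else int(seq)
        lines.append(f"##contig=<ID={name},length={ln}>")
    for key, val in (provenance or {}).items():
        lines.append(f"##{key}={val}")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return lines


def config_hash(obj) -> str:
    text = repr(sorted(vars(obj).items())) if hasattr(obj, "__dict__") else repr(obj)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_vcf_records(
    records: list[dict],
    seqs: dict[str, str] | dict[str, int],
    path,
    provenance: dict | None = None,
) -> None:
    """Write SV record dicts (internal 0-based coordinates) to a VCF file."""
    lines = _header_lines(seqs, provenance)
    body = []
    for r in records:
        sv_type = r["sv_type"]
        filt = ";".join(str(f) for f in sorted(r["filters"], key=str)) or "PASS"
        if sv_type is SvType.TRA_INTER:
            info1 = f"SVTYPE=BND;MATEID={r['id']}_2;SUPPORT={r['support']};VAF={r['vaf']:.4f}"
            info2 = f"SVTYPE=BND;MATEID={r['id']}_1;SUPPORT={r['support']};VAF={r['vaf']:.4f}"
            alt1 = f"N[{r['chrom2']}:{r['end'] + 1}["
            alt2 = f"]{r['chrom']}:{r['pos'] + 1}]N"
            body.append(
                (r["chrom"], r["pos"],
                 f"{r['chrom']}\t{r['pos'] + 1}\t{r['id']}_1\tN\t{alt1}\t.\t{filt}\t{info1}")
            )
            body.append(
                (r["chrom2"], r["end"],
                 f"{r['chrom2']}\t{r['end'] + 1}\t{r['id']}_2\tN\t{alt2}\t.\t{filt}\t{info2}")
            )
            continue
        svlen = -r["length"] if sv_type is SvType.DEL else r["length"]
        info = (
            f"SVTYPE={_SVTYPE_STR[sv_type]};END={max(r['end'], r['pos'] + 1)};SVLEN={svlen};"
            f"SUPPORT={r['support']};VAF={r['vaf']:.4f}"
        )
        if r.get("seq"):
            info += f";SEQ={r['seq']}"
        body.append(
            (r["chrom"], r["pos"],
             f"{r['chrom']}\t{r['pos'] + 1}\t{r['id']}\tN\t{_ALT[sv_type]}\t.\t{filt}\t{info}")
        )
    body.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for _c, _p, line in body:
            fh.write(line + "\n")


def calls_to_records(calls: list[SvCall]) -> list[dict]:
    recs = []
    for c in calls:
        recs.append(
            dict(
                chrom=c.chrom1,
                pos=c.pos1,
                chrom2=c.chrom2,
                id=c.id,
                sv_type=c.sv_type,
                end=c.pos2,
                length=c.length,
                support=c.support,
                vaf=c.vaf,
                filters=sorted(c.filter_flags, key=str),
                seq=c.inserted_seq if c.sv_type is SvType.INS else "",
            )
        )
    return recs


def write_calls_vcf(
    calls: list[SvCall],
    seqs: dict[str, str] | dict[str, int],
    path,
    provenance: dict | None = None,
) -> None:
    write_vcf_records(calls_to_records(calls), seqs, path, provenance)


def read_vcf_calls(path) -> list[SvCall]:
    """Read a (possibly symbolic-ALT) SV VCF back into SvCall records."""
    calls: list[SvCall] = []
    bnd_mates: dict[str, SvCall] = {}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            svtype = info.get("SVTYPE", "")
            sv_type = _FROM_STR.get(svtype)
            if sv_type is None:
                continue
            filters = set()
            pos = rec.pos - 1
            if sv_type is SvType.TRA_INTER:
                base = rec.id[:-2] if rec.id and rec.id[-2:] in ("_1", "_2") else rec.id
                if base in bnd_mates:
                    mate = bnd_mates.pop(base)
                    mate.chrom2 = rec.chrom
                    mate.pos2 = pos
                    continue
                call = SvCall(
                    id=base,
                    sample_id="",
                    sv_type=sv_type,
                    chrom1=rec.chrom,
                    pos1=pos,
                    chrom2=rec.chrom,
                    pos2=pos,
                    length=0,
                    support=int(info.get("SUPPORT", 0)),
                    vaf=float(info.get("VAF", 0.0)),
                )
                bnd_mates[base] = call
                calls.append(call)
                continue
            # htslib recomputes rec.stop from SVLEN (padding included), so
            # derive the end from SVLEN when present and END otherwise
            if "SVLEN" in info:
                svlen = abs(int(info["SVLEN"]))
                end = pos + (svlen if sv_type is not SvType.INS else 0)
            else:
                end = rec.stop if rec.stop is not None else pos
                svlen = abs(end - pos)
            call = SvCall(
                id=rec.id or f"{rec.chrom}:{rec.pos}",
                sample_id="",
                sv_type=sv_type,
                chrom1=rec.chrom,
                pos1=pos,
                chrom2=rec.chrom,
                pos2=pos if sv_type is SvType.INS else end,
                length=svlen,
                support=int(info.get("SUPPORT", 0)),
                vaf=float(info.get("VAF", 0.0)),
                inserted_seq=str(info.get("SEQ", "") or ""),
            )
            calls.append(call)
    return calls


def write_bedpe(calls: list[SvCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        c.chrom1,
                        c.pos1,
                        c.pos1 + 1,
                        c.chrom2,
                        c.pos2,
                        c.pos2 + 1,
                        c.id,
                        c.support,
                        _SVTYPE_STR.get(c.sv_type, str(c.sv_type)),
                        "PASS" if c.passes else ";".join(
                            str(f) for f in sorted(c.filter_flags, key=str)
                        ),
                    )
                )
                + "\n"
            )


@dataclass
class PslRecord:
    """One BLAT PSL alignment line (0-based half-open, per the PSL spec)."""

    matches: int
    mismatches: int
    strand: str
    q_name: str
    q_size: int
    q_start: int
    q_end: int
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    block_count: int
    block_sizes: list[int]
    q_starts: list[int]
    t_starts: list[int]

    @property
    def identity(self) -> float:
        aln = self.matches + self.mismatches
        return self.matches / aln if aln else 0.0

    @property
    def query_coverage(self) -> float:
        return (self.q_end - self.q_start) / self.q_size if self.q_size else 0.0


def read_psl(path) -> list[PslRecord]:
    """Parse a PSL file (with or without the 5-line header)."""
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 21 or not f[0].isdigit():
                continue
            out.append(
                PslRecord(
                    matches=int(f[0]),
                    mismatches=int(f[1]),
                    strand=f[8],
                    q_name=f[9],
                    q_size=int(f[10]),
                    q_start=int(f[11]),
                    q_end=int(f[12]),
                    t_name=f[13],
                    t_size=int(f[14]),
                    t_start=int(f[15]),
                    t_end=int(f[16]),
                    block_count=int(f[17]),
                    block_sizes=[int(x) for x in f[18].rstrip(",").split(",") if x],
                    q_starts=[int(x) for x in f[19].rstrip(",").split(",") if x],
                    t_starts=[int(x) for x in f[20].rstrip(",").split(",") if x],
                )
            )
    return out


def write_psl(records: list[PslRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.matches, r.mismatches, 0, 0, 0, 0, 0, 0,
                        r.strand, r.q_name, r.q_size, r.q_start, r.q_end,
                        r.t_name, r.t_size, r.t_start, r.t_end,
                        r.block_count,
                        ",".join(map(str, r.block_sizes)) + ",",
                        ",".join(map(str, r.q_starts)) + ",",
                        ",".join(map(str, r.t_starts)) + ",",
                    )
                )
                + "\n"
            )


def read_lifted_table(path) -> list[tuple[str, int, int]]:
    """Read an (indel_id, reference_dist, chimp_dist) anchor-distance TSV."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                out.append((f[0], int(f[1]), int(f[2])))
    return out


@dataclass
class Bed12Gene:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]


def read_bed12(path) -> list[Bed12Gene]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in f[11].rstrip(",").split(",") if x]
            genes.append(
                Bed12Gene(
                    name=f[3],
                    chrom=f[0],
                    start=start,
                    end=int(f[2]),
                    strand=f[5] if len(f) > 5 else "+",
                    exons=[(start + s, start + s + sz) for s, sz in zip(starts, sizes)],
                )
            )
    return genes
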