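"""Benchmark a callset against a truth set by breakpoint distance.

A call and a truth record match when they are the same SV type and their
breakpoints lie within 500 bp (both ends, by default; a start-only mode is
available). Matching is greedy one-to-one by increasing distance, which
prevents one call from absorbing several truth records. Matched pairs are
"common", unmatched truth records are false negatives and unmatched calls
false positives; precision, recall and the F-measure follow. Results can
be stratified by repeat context (tandem repeat, segmental duplication /
self-chain, both, neither).
"""

from __future__ import annotations

from typing import Sequence

from intervaltree import IntervalTree

from .model import MatchResult, SvType

#: duplication-signature intra-chromosomal junctions and explicit DUP
#: records describe the same event class
_TYPE_EQUIV = {
    SvType.TRA_INTRA: "DUP",
    SvType.DEL: "DEL",
    SvType.INS: "INS",
    SvType.INV: "INV",
    SvType.TRA_INTER: "TRA",
    SvType.CLIP: "CLIP",
}


def _type_key(rec) -> str:
    t = getattr(rec, "sv_type", None)
    if isinstance(t, SvType):
        return _TYPE_EQUIV[t]
    return str(t)


def _coords(rec) -> tuple[str, int, str, int]:
    chrom1 = getattr(rec, "chrom1", None) or getattr(rec, "chrom")
    chrom2 = getattr(rec, "chrom2", None) or chrom1
    return chrom1, int(rec.pos1), chrom2, int(rec.pos2)


def breakpoint_distance(a, b, both_ends: bool = True) -> float:
    """Distance between two SV records' breakpoints (inf across chroms)."""
    c1a, p1a, c2a, p2a = _coords(a)
    c1b, p1b, c2b, p2b = _coords(b)
    if c1a != c1b or c2a != c2b:
        return float("inf")
    if both_ends:
        return max(abs(p1a - p1b), abs(p2a - p2b))
    return abs(p1a - p1b)


def match_callsets(
    calls: Sequence,
    truth: Sequence,
    max_dist: int = 500,
    both_ends: bool = True,
    tandem_bed: list[tuple[str, int, int]] | None = None,
    segdup_bed: list[tuple[str, int, int]] | None = None,
) -> MatchResult:
    """Greedy one-to-one matching of ``calls`` against ``truth``.

    Records need ``sv_type``, ``pos1``/``pos2`` and ``chrom1``/``chrom2``
    (or ``chrom``) attributes; ``SvCall`` and the simulator's
    ``TruthRecord`` both qualify. With an empty callset precision is
    undefined and reported as 0 with ``degenerate`` set.
    """
    pairs = []
    for ti, t in enumerate(truth):
        for ci, c in enumerate(calls):
            if _type_key(t) != _type_key(c):
                continue
            d = breakpoint_distance(t, c, both_ends)
            if d < max_dist:
                pairs.append((d, ti, ci))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_t: set[int] = set()
    used_c: set[int] = set()
    common = []
    for d, ti, ci in pairs:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        common.append((truth[ti], calls[ci]))
    truth_only = [t for i, t in enumerate(truth) if i not in used_t]
    calls_only = [c for i, c in enumerate(calls) if i not in used_c]

    n_common = len(common)
    degenerate = len(calls) == 0 or len(truth) == 0
    precision = n_common / len(calls) if calls else 0.0
    recall = n_common / len(truth) if truth else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )

    strata: dict[str, dict[str, int]] = {}
    if tandem_bed is not None or segdup_bed is not None:
        tr_tree = _bed_tree(tandem_bed or [])
        sd_tree = _bed_tree(segdup_bed or [])

        def stratum(rec) -> str:
            c1, p1, c2, p2 = _coords(rec)
            in_tr = _hits(tr_tree, c1, p1) or _hits(tr_tree, c2, p2)
            in_sd = _hits(sd_tree, c1, p1) or _hits(sd_tree, c2, p2)
            if in_tr and in_sd:
                return "both"
            if in_tr:
                return "tandem_repeat"
            if in_sd:
                return "segdup"
            return "non_repeat"

        for name in ("tandem_repeat", "segdup", "both", "non_repeat"):
            strata[name] = {"common": 0, "truth_only": 0, "calls_only": 0}
        for t, _c in common:
            strata[stratum(t)]["common"] += 1
        for t in truth_only:
            strata[stratum(t)]["truth_only"] += 1
        for c in calls_only:
            strata[stratum(c)]["calls_only"] += 1

    return MatchResult(
        common=common,
        truth_only=truth_only,
        calls_only=calls_only,
        precision=precision,
        recall=recall,
        f_measure=f,
        degenerate=degenerate,
        strata=strata,
    )


def _bed_tree(records: list[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in records:
        if end > start:
            trees.setdefault(chrom, IntervalTree())[start:end] = True
    return trees


def _hits(trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
    tree = trees.get(chrom)
    return bool(tree is not None and tree.at(pos))


def read_bed3(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_report(result: MatchResult, path) -> None:
    import json

    payload = {
        "common": len(result.common),
        "truth_only": len(result.truth_only),
        "calls_only": len(result.calls_only),
        "precision": result.precision,
        "recall": result.recall,
        "f_measure": result.f_measure,
        "degenerate": result.degenerate,
        "strata": result.strata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
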