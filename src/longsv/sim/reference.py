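"""Synthetic reference genomes with planted repeat annotation truth.

The generator emulates, at desk scale, the genomic features the SV
pipeline interacts with: interspersed SINE-like (~300 bp) and LINE-like
(~6 kb) element copies drawn from fixed internal family consensus
sequences, tandem-repeat tracts, and optional pairs of identical tracts
(recombination substrates for homology-bearing deletions). RepeatMasker
``.out`` and Tandem Repeat Finder ``.dat`` files are written directly from
the planting truth, so downstream repeat-aware steps need no external
annotation run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..model import RepeatInterval

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    mask = rng.random(arr.size) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()))
    idx = lut[arr]
    idx[mask] = (idx[mask] + shift) % 4
    return _BASES[idx].tobytes().decode()


# Fixed internal element consensus sequences (constant across runs).
_CONS_RNG = np.random.default_rng(20210429)
ALU_CONSENSUS = _random_seq(_CONS_RNG, 300)
L1_CONSENSUS = _random_seq(_CONS_RNG, 6000)
HBV_LIKE_GENOME = _random_seq(_CONS_RNG, 3200)
AAV_LIKE_GENOME = _random_seq(_CONS_RNG, 4700)

SINE_FAMILIES = {
    "AluYa5": ALU_CONSENSUS,
    "AluYb8": _mutate(ALU_CONSENSUS, 0.03, _CONS_RNG),
    "AluY": _mutate(ALU_CONSENSUS, 0.05, _CONS_RNG),
}
LINE_FAMILIES = {
    "L1HS": L1_CONSENSUS,
    "L1P1": _mutate(L1_CONSENSUS, 0.05, _CONS_RNG),
}

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class HomologySite:
    """Two identical tracts of length ``homology`` at ``pos1`` and ``pos2``."""

    chrom: str
    pos1: int
    pos2: int
    homology: int
    used: bool = False


@dataclass
class TandemSite:
    chrom: str
    start: int
    end: int
    motif: str
    copies: float


@dataclass
class ReferenceBuild:
    seqs: dict[str, str]
    repeats: list[RepeatInterval]
    homology_sites: list[HomologySite]
    tandem_sites: list[TandemSite]

    def sequence(self, chrom: str) -> str:
        return self.seqs[chrom]


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    length: int,
    span: int,
    margin: int = 200,
    tries: int = 200,
) -> int | None:
    for _ in range(tries):
        pos = int(rng.integers(margin, span - length - margin))
        if all(pos + length + margin <= s or pos >= e + margin for s, e in occupied):
            occupied.append((pos, pos + length))
            return pos
    return None


def build_reference(
    length: int = 1_000_000,
    n_repeat_copies: int = 40,
    seed: int = 0,
    chrom: str = "chr1",
    n_tandem_tracts: int = 6,
    homology_pairs: list[tuple[int, int]] | None = None,
) -> ReferenceBuild:
    """Build a random reference with planted repeats.

    ``homology_pairs`` is a list of ``(homology_bp, separation_bp)`` tuples;
    for each, two identical tracts are planted that distance apart so a
    deletion between them forms a junction with that much homology.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    base = np.frombuffer(_random_seq(rng, length).encode(), dtype=np.uint8).copy()
    occupied: list[tuple[int, int]] = []
    repeats: list[RepeatInterval] = []

    sine_names = list(SINE_FAMILIES)
    line_names = list(LINE_FAMILIES)
    n_sine = int(round(n_repeat_copies * 0.6))
    for i in range(n_repeat_copies):
        if i < n_sine:
            fam = sine_names[int(rng.integers(0, len(sine_names)))]
            cons = SINE_FAMILIES[fam]
            klass = "SINE"
            trunc = 0
        else:
            fam = line_names[int(rng.integers(0, len(line_names)))]
            cons = LINE_FAMILIES[fam]
            klass = "LINE"
            # LINE copies are mostly 5'-truncated
            trunc = int(rng.integers(0, int(len(cons) * 0.8)))
        copy = _mutate(cons[trunc:], 0.02, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = copy if strand == "+" else revcomp(copy)
        pos = _place(rng, occupied, len(planted), length)
        if pos is None:
            continue
        base[pos : pos + len(planted)] = np.frombuffer(
            planted.encode(), dtype=np.uint8
        )
        repeats.append(
            RepeatInterval(
                seq_id=chrom,
                start=pos,
                end=pos + len(planted),
                repeat_class=klass,
                family=fam,
                strand=strand,
                consensus_start=trunc,
                consensus_end=len(cons),
                source="repeatmasker",
            )
        )

    tandem_sites: list[TandemSite] = []
    motifs = ["AT", "CAG", "ACGGT", "TTAGGG"]
    for i in range(n_tandem_tracts):
        motif = motifs[i % len(motifs)]
        copies = int(rng.integers(40, 120))
        tract = (motif * copies)[: copies * len(motif)]
        pos = _place(rng, occupied, len(tract), length)
        if pos is None:
            continue
        base[pos : pos + len(tract)] = np.frombuffer(tract.encode(), dtype=np.uint8)
        tandem_sites.append(
            TandemSite(chrom, pos, pos + len(tract), motif, float(copies))
        )
        repeats.append(
            RepeatInterval(
                seq_id=chrom,
                start=pos,
                end=pos + len(tract),
                repeat_class="Simple/Tandem",
                family=f"({motif})n",
                strand="+",
                source="trf",
            )
        )

    homology_sites: list[HomologySite] = []
    for h, sep in homology_pairs or []:
        tract = _random_seq(rng, h)
        pos = _place(rng, occupied, sep + h, length)
        if pos is None:
            continue
        arr = np.frombuffer(tract.encode(), dtype=np.uint8)
        base[pos : pos + h] = arr
        base[pos + sep : pos + sep + h] = arr
        # guard bases: the homologous tract must not extend by chance at
        # either end, or the measured homology would exceed the planted one
        for a, b in ((pos - 1, pos + sep - 1), (pos + h, pos + sep + h)):
            if base[a] == base[b]:
                base[b] = _BASES[(int(np.searchsorted(_BASES, base[b])) + 1) % 4]
        homology_sites.append(HomologySite(chrom, pos, pos + sep, h))

    repeats.sort(key=lambda r: r.start)
    return ReferenceBuild(
        seqs={chrom: base.tobytes().decode()},
        repeats=repeats,
        homology_sites=homology_sites,
        tandem_sites=tandem_sites,
    )


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_repeatmasker_out(repeats: list[RepeatInterval], path) -> None:
    """Write repeat intervals in RepeatMasker ``.out`` layout (1-based)."""
    class_map = {
        "SINE": "SINE/Alu",
        "LINE": "LINE/L1",
        "LTR": "LTR/ERV",
        "DNA": "DNA/hAT",
        "Simple/Tandem": "Simple_repeat",
        "Low_complexity": "Low_complexity",
        "Other": "Unknown",
    }
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query      position in query           matching"
            "       repeat              position in  repeat\n"
        )
        fh.write(
            "score  div. del. ins.  sequence    begin     end    (left)    repeat"
            "       class/family         begin  end (left)   ID\n\n"
        )
        for i, r in enumerate(
            [x for x in repeats if x.source != "trf"], start=1
        ):
            klass = class_map.get(r.repeat_class, r.repeat_class)
            rlen = r.consensus_end or (r.consensus_start + r.span)
            if r.strand == "+":
                rep_cols = f"{r.consensus_start + 1:7d} {rlen:6d} {'(0)':>6s}"
                strand = "+"
            else:
                strand = "C"
                rep_cols = f"{'(0)':>7s} {rlen:6d} {r.consensus_start + 1:6d}"
            fh.write(
                f"{1000:5d} {2.0:5.1f} {0.0:4.1f} {0.0:4.1f}  {r.seq_id:<10s}"
                f"{r.start + 1:9d} {r.end:8d} {'(0)':>9s} {strand} "
                f"{r.family or 'Unknown':<18s} {klass:<18s} {rep_cols} {i:5d}\n"
            )


def write_trf_dat(
    tandem_sites: list[TandemSite], path, seq_lengths: dict[str, int] | None = None
) -> None:
    """Write tandem tracts in Tandem Repeat Finder ``.dat`` layout (1-based)."""
    by_seq: dict[str, list[TandemSite]] = {}
    for t in tandem_sites:
        by_seq.setdefault(t.chrom, []).append(t)
    with open(path, "w") as fh:
        fh.write("Tandem Repeats Finder Program written by:\n\nBenson G.\n\n")
        fh.write("Parameters: 2 7 7 80 10 50 500\n\n")
        for chrom, sites in by_seq.items():
            fh.write(f"Sequence: {chrom}\n\n")
            for t in sorted(sites, key=lambda s: s.start):
                period = len(t.motif)
                tract = (t.end - t.start) and t.motif * int(t.copies)
                comp = {b: (tract.count(b) * 100 // max(1, len(tract))) for b in "ACGT"}
                fh.write(
                    f"{t.start + 1} {t.end} {period} {t.copies:.1f} {period} 95 0 "
                    f"{(t.end - t.start) * 2} {comp['A']} {comp['C']} {comp['G']} "
                    f"{comp['T']} 1.5 {t.motif} {t.motif * 3}\n"
                )
            fh.write("\n")
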