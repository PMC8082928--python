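"""Synthetic deletion junctions with exactly known homology or insertion.

Used to exercise breakpoint-anatomy measurement: a reference is built as
U + T + M + T + D, where T is a homologous tract planted at both deletion
ends, and the deleted-allele consensus joins U's tail to T + D's head,
optionally with untemplated bases in between. Guard bases at every
boundary prevent the planted homology or insertion from extending by a
chance match, so the measured values equal the planted ones exactly on
error-free sequence.
"""

from __future__ import annotations

import numpy as np

from .reference import _random_seq


def planted_junction(
    h: int, ins: int, seed: int = 0, flank: int = 500
) -> tuple[str, str, str]:
    """Return (consensus, upstream flank, downstream flank).

    ``h`` is the junction homology in bp, ``ins`` the untemplated junction
    insertion; they are mutually exclusive in real junctions but both may
    be zero (a blunt join).
    """
    rng = np.random.default_rng(seed)
    U = _random_seq(rng, flank + 100)
    T = _random_seq(rng, h)
    M = _random_seq(rng, 800)
    D = _random_seq(rng, flank + 100)
    ref = list(U + T + M + T + D)
    pos1 = len(U)
    pos2 = len(U) + h + len(M)
    for a, b in ((pos1 - 1, pos2 - 1), (pos1 + h, pos2 + h)):
        if b < len(ref) and ref[a] == ref[b]:
            ref[b] = "ACGT"[("ACGT".index(ref[b]) + 1) % 4]
    ref = "".join(ref)
    J = list(_random_seq(rng, ins))
    if ins:
        if J[0] == ref[pos1]:
            J[0] = "ACGT"[("ACGT".index(J[0]) + 1) % 4]
        if J[-1] == ref[pos2 - 1]:
            J[-1] = "ACGT"[("ACGT".index(J[-1]) + 1) % 4]
    consensus = ref[pos1 - flank : pos1] + "".join(J) + ref[pos2 : pos2 + flank]
    up = ref[pos1 - flank : pos1 + 200]
    down = ref[pos2 - 200 : pos2 + flank]
    return consensus, up, down
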