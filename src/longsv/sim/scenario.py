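"""Ready-made simulation scenarios used by tests, examples and the CLI.

The default spike-in recovery scenario is a 1 Mb reference carrying 60
SVs — 20 deletions, 20 insertions, 10 inversions and 10 tandem
duplications, a mix of heterozygous and homozygous — sequenced at 20x
with nanopore-like error rates. The somatic scenario shares 20 germline
SVs between a tumor and its matched normal and adds 10 tumor-private SVs.
These sizes keep every end-to-end run in the minutes range on one CPU
while still exercising each SV class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..model import SvType
from .reads import ErrorModel, SimulatedRead, simulate_sample
from .reference import ReferenceBuild, build_reference
from .spike import SpikeResult, SvSpec, plan_svs, spike_svs


@dataclass
class Scenario:
    build: ReferenceBuild
    spike: SpikeResult
    reads: dict[str, list[SimulatedRead]] = field(default_factory=dict)


_DEL_HOMOLOGY = [(150, 2000), (50, 1500), (120, 2500)]  # (homology, length)


def n_homology_pairs(scale: float) -> int:
    return max(1, min(len(_DEL_HOMOLOGY), int(round(len(_DEL_HOMOLOGY) * scale))))


def spikein_specs(
    seed: int,
    samples: tuple[str, ...] = ("S1",),
    scale: float = 1.0,
) -> list[SvSpec]:
    """The 60-SV spike-in panel: 20 DEL, 20 INS, 10 INV, 10 tandem dup.

    ``scale`` shrinks the panel proportionally for smaller references.
    """
    rng = np.random.default_rng(seed + 101)
    specs: list[SvSpec] = []
    n_del = max(2, int(round(20 * scale)))
    n_inv = max(1, int(round(10 * scale)))
    n_dup = max(1, int(round(10 * scale)))
    n_hom = n_homology_pairs(scale)

    def vaf(i: int) -> float:
        return 1.0 if i % 2 == 0 else 0.5

    del_lengths = [int(x) for x in rng.integers(150, 5000, size=n_del)]
    for i, L in enumerate(del_lengths):
        hom = junc = 0
        if i < n_hom:
            hom, L = _DEL_HOMOLOGY[i]
        elif i < 6:
            junc = int(rng.integers(10, 60))
        elif i < 9:
            junc = int(rng.integers(1, 9))
        specs.append(
            SvSpec(
                SvType.DEL,
                L,
                vaf=vaf(i),
                homology=hom,
                junction_insertion=junc,
                samples=samples,
                ancestral_event="deletion_event" if i % 3 else "insertion_event",
            )
        )
    ins_contents = (
        ["alu_like"] * 8 + ["line_like"] * 4 + ["line_twin"] * 2
        + ["tandem_dup"] * 2 + ["pseudogene_like"] * 1 + ["random"] * 3
    )
    n_ins = max(2, int(round(20 * scale)))
    ins_contents = (ins_contents * ((n_ins // 20) + 1))[:n_ins]
    ins_lengths = {
        "alu_like": lambda: int(rng.integers(280, 330)),
        "line_like": lambda: int(rng.integers(800, 2500)),
        "line_twin": lambda: int(rng.integers(600, 1200)),
        "tandem_dup": lambda: int(rng.integers(150, 600)),
        "pseudogene_like": lambda: int(rng.integers(300, 900)),
        "random": lambda: int(rng.integers(150, 2500)),
    }
    for i, content in enumerate(ins_contents):
        specs.append(
            SvSpec(
                SvType.INS,
                ins_lengths[content](),
                vaf=vaf(i),
                content=content,
                samples=samples,
                ancestral_event="insertion_event" if i % 3 else "deletion_event",
            )
        )
    for i in range(n_inv):
        specs.append(
            SvSpec(
                SvType.INV,
                int(rng.integers(1000, 3000)),
                vaf=vaf(i),
                samples=samples,
            )
        )
    for i in range(n_dup):
        specs.append(
            SvSpec(
                SvType.TRA_INTRA,
                int(rng.integers(1000, 3000)),
                vaf=vaf(i),
                samples=samples,
            )
        )
    return specs


def spikein_scenario(
    seed: int = 0,
    coverage: float = 20.0,
    reference_length: int = 1_000_000,
    error: ErrorModel | None = None,
    samples: tuple[str, ...] = ("S1",),
) -> Scenario:
    """Build the 60-SV spike-in recovery scenario end to end."""
    scale = min(1.0, reference_length / 1_000_000)
    specs = spikein_specs(seed, samples=samples, scale=scale)
    build = build_reference(
        length=reference_length,
        n_repeat_copies=40,
        seed=seed,
        homology_pairs=list(_DEL_HOMOLOGY[: n_homology_pairs(scale)]),
    )
    specs = plan_svs(build, specs, seed=seed)
    spike = spike_svs(build, specs, seed=seed)
    error = error if error is not None else ErrorModel()
    reads = {
        sid: simulate_sample(
            haps,
            build.seqs,
            coverage=coverage,
            model=error,
            seed=seed + 1000 + i,
            sample_id=sid,
        )
        for i, (sid, haps) in enumerate(spike.haplotypes.items())
    }
    return Scenario(build=build, spike=spike, reads=reads)


def somatic_scenario(
    seed: int = 0,
    coverage: float = 18.0,
    reference_length: int = 600_000,
    n_shared: int = 20,
    n_private: int = 10,
    error: ErrorModel | None = None,
) -> tuple[Scenario, list]:
    """Tumor/normal pair: ``n_shared`` germline + ``n_private`` tumor SVs.

    Returns the scenario (samples "T" for tumor, "N" for normal) and the
    list of private truth records.
    """
    rng = np.random.default_rng(seed + 77)
    specs: list[SvSpec] = []
    for i in range(n_shared):
        sv_type = [SvType.DEL, SvType.INS, SvType.INV][i % 3]
        L = int(rng.integers(300, 3000))
        specs.append(
            SvSpec(sv_type, L, vaf=1.0 if i % 2 else 0.5, samples=("N", "T"))
        )
    for i in range(n_private):
        sv_type = [SvType.DEL, SvType.INS, SvType.TRA_INTRA, SvType.INV][i % 4]
        L = int(rng.integers(300, 2500))
        specs.append(SvSpec(sv_type, L, vaf=0.5, samples=("T",)))
    build = build_reference(length=reference_length, n_repeat_copies=20, seed=seed)
    specs = plan_svs(build, specs, seed=seed)
    spike = spike_svs(build, specs, seed=seed)
    error = error if error is not None else ErrorModel()
    reads = {
        sid: simulate_sample(
            haps,
            build.seqs,
            coverage=coverage,
            model=error,
            seed=seed + 2000 + i,
            sample_id=sid,
        )
        for i, (sid, haps) in enumerate(spike.haplotypes.items())
    }
    private = [t for t in spike.truth if t.carriers == ("T",)]
    return Scenario(build=build, spike=spike, reads=reads), private


def virus_scenario(
    seed: int = 0,
    coverage: float = 25.0,
    reference_length: int = 200_000,
    error: ErrorModel | None = None,
) -> Scenario:
    """A single full-length viral genome integrated into the host genome."""
    build = build_reference(length=reference_length, n_repeat_copies=6, seed=seed)
    specs = plan_svs(
        build,
        [SvSpec(SvType.INS, 3200, vaf=1.0, content="viral", samples=("T",))],
        seed=seed,
    )
    spike = spike_svs(build, specs, seed=seed)
    error = error if error is not None else ErrorModel()
    reads = {
        "T": simulate_sample(
            spike.haplotypes["T"],
            build.seqs,
            coverage=coverage,
            model=error,
            seed=seed + 3000,
            sample_id="T",
        )
    }
    return Scenario(build=build, spike=spike, reads=reads)
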