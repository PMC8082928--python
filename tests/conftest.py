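"""Shared fixtures: small simulated datasets built once per session."""

from __future__ import annotations

import pytest

from longsv.germline import call_sample
from longsv.ingest import parse_alignments
from longsv.model import SvSignature, SvType
from longsv.sim.reads import write_sam
from longsv.sim.scenario import spikein_scenario


def make_signature(
    sv_type=SvType.DEL,
    pos1=1000,
    length=300,
    read_id="r1",
    mapq=60,
    offset=0.5,
    chrom="chr1",
    source="cigar",
    **kw,
) -> SvSignature:
    pos2 = pos1 + length if sv_type is not SvType.INS else pos1
    return SvSignature(
        sv_type=sv_type,
        chrom1=chrom,
        pos1=pos1,
        chrom2=chrom,
        pos2=pos2,
        length=length,
        read_id=read_id,
        read_offset_fraction=offset,
        source=source,
        mapq=mapq,
        **kw,
    )


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """A 300 kb, ~12x spike-in scenario parsed back through SAM."""
    sc = spikein_scenario(seed=11, coverage=12, reference_length=300_000)
    path = tmp_path_factory.mktemp("sim") / "S1.sam"
    write_sam(sc.reads["S1"], sc.build.seqs, path, sample_id="S1")
    alignments = parse_alignments(path, sample_id="S1")
    return sc, alignments


@pytest.fixture(scope="session")
def small_calls(small_scenario):
    sc, alignments = small_scenario
    return call_sample(alignments, sample_id="S1")
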