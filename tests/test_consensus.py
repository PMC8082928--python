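"""Consensus building, majority voting and remap validation."""

from __future__ import annotations

import edlib
import numpy as np
import pytest

from longsv.consensus import (
    build_consensus,
    collect_segments,
    validate_consensus,
)
from longsv.model import SvCall, SvType
from longsv.sim.reads import ErrorModel, noisy_copy
from longsv.sim.reference import _random_seq
from longsv.vcfio import PslRecord


class TestBuildConsensus:
    @pytest.mark.parametrize("k", [1, 2, 3, 7])
    def test_identical_segments_reproduce_input(self, k):
        seq = "ACGTGGCTAATCGATCGGCTA" * 10
        cons = build_consensus([seq] * k)
        assert cons.sequence == seq
        assert cons.low_confidence == (k == 1)

    def test_majority_base_wins(self):
        # column votes (A, A, C) -> A
        cons = build_consensus(["GGAGG", "GGAGG", "GGCGG"])
        assert cons.sequence == "GGAGG"

    def test_tie_resolves_toward_backbone(self):
        # two segments disagree at one column; the backbone (the upper
        # median by length, here the second segment) supplies the winner
        segs = ["GGAGG", "GGCGG"]
        cons = build_consensus(segs)
        assert cons.sequence == segs[1]

    def test_minority_insertion_removed(self):
        segs = ["AAATTT", "AAATTT", "AAAGGTTT"]
        cons = build_consensus(segs)
        assert cons.sequence == "AAATTT"

    def test_majority_deletion_removed_from_consensus(self):
        segs = ["AAATTT", "AAATTT", "AAACTTT"]
        cons = build_consensus(segs)
        assert cons.sequence == "AAATTT"

    def test_empty_input(self):
        cons = build_consensus([])
        assert cons.sequence == "" and cons.n_support == 0

    def test_length_bounded_by_segment_lengths(self):
        rng = np.random.default_rng(1)
        truth = _random_seq(rng, 800)
        segs = [noisy_copy(truth, ErrorModel(), rng)[0] for _ in range(9)]
        cons = build_consensus(segs)
        assert min(map(len, segs)) <= len(cons.sequence) <= max(map(len, segs))

    def test_truncated_segment_still_contributes(self):
        rng = np.random.default_rng(2)
        truth = _random_seq(rng, 600)
        segs = [truth, truth, truth[:380]]  # one read ends early
        cons = build_consensus(segs)
        assert cons.sequence == truth

    def test_noisy_recovery_close_to_truth(self):
        rng = np.random.default_rng(3)
        truth = _random_seq(rng, 1500)
        err = ErrorModel(0.033, 0.029, 0.044)  # ~10% aggregate
        segs = [noisy_copy(truth, err, rng)[0] for _ in range(10)]
        cons = build_consensus(segs)
        d = edlib.align(cons.sequence, truth)["editDistance"]
        assert d / len(truth) <= 0.02


def ins_call(pos=5000, length=300):
    return SvCall(
        id="c", sample_id="s", sv_type=SvType.INS, chrom1="chr1",
        pos1=pos, chrom2="chr1", pos2=pos, length=length, support=5,
    )


def del_call(pos1=5000, pos2=7000):
    return SvCall(
        id="c", sample_id="s", sv_type=SvType.DEL, chrom1="chr1",
        pos1=pos1, chrom2="chr1", pos2=pos2, length=pos2 - pos1, support=5,
    )


class TestValidateConsensus:
    @pytest.fixture()
    def genome(self):
        rng = np.random.default_rng(4)
        return {"chr1": _random_seq(rng, 20_000)}

    def consensus_for_ins(self, genome, pos, length, seed=5):
        rng = np.random.default_rng(seed)
        seq = genome["chr1"]
        cons_seq = seq[pos - 500 : pos] + _random_seq(rng, length) + seq[pos : pos + 500]
        from longsv.model import ConsensusSeq

        return ConsensusSeq(call_id="c", sequence=cons_seq, n_support=5)

    def test_insertion_mapping_at_call_site_accepted(self, genome):
        cons = self.consensus_for_ins(genome, 5000, 300)
        out = validate_consensus(cons, ins_call(5000, 300), reference=genome)
        assert out.accepted and out.remap_distance <= 100

    def test_insertion_mapping_nearby_accepted(self, genome):
        # consensus built 40 bp from the recorded call position
        cons = self.consensus_for_ins(genome, 5040, 300)
        out = validate_consensus(cons, ins_call(5000, 300), reference=genome)
        assert out.accepted
        assert 0 < out.remap_distance <= 100

    def test_insertion_mapping_far_away_rejected(self, genome):
        cons = self.consensus_for_ins(genome, 5250, 300)
        out = validate_consensus(cons, ins_call(5000, 300), reference=genome)
        assert not out.accepted
        assert out.remap_distance > 100

    def test_deletion_overlapping_call_accepted(self, genome):
        seq = genome["chr1"]
        from longsv.model import ConsensusSeq

        cons = ConsensusSeq(
            call_id="c", sequence=seq[4500:5000] + seq[7000:7500], n_support=5
        )
        out = validate_consensus(cons, del_call(5000, 7000), reference=genome)
        assert out.accepted

    def test_deletion_not_overlapping_rejected(self, genome):
        seq = genome["chr1"]
        from longsv.model import ConsensusSeq

        # junction sequence from a different locus entirely
        cons = ConsensusSeq(
            call_id="c", sequence=seq[11_000:11_500] + seq[15_000:15_500],
            n_support=5,
        )
        out = validate_consensus(cons, del_call(5000, 7000), reference=genome)
        assert not out.accepted

    def test_single_read_consensus_never_accepted(self, genome):
        cons = self.consensus_for_ins(genome, 5000, 300)
        cons.n_support = 1
        cons.low_confidence = True
        out = validate_consensus(cons, ins_call(5000, 300), reference=genome)
        assert not out.accepted

    def test_psl_validation_takes_precedence(self, genome):
        cons = self.consensus_for_ins(genome, 5000, 300)
        psl = [
            PslRecord(
                matches=1250, mismatches=5, strand="+", q_name="c",
                q_size=1300, q_start=0, q_end=1300, t_name="chr1",
                t_size=20_000, t_start=4460, t_end=5540, block_count=2,
                block_sizes=[540, 540], q_starts=[0, 760], t_starts=[4460, 5000],
            )
        ]
        out = validate_consensus(cons, ins_call(5000, 300), psl_records=psl)
        assert out.accepted

    def test_psl_far_hit_rejected(self, genome):
        cons = self.consensus_for_ins(genome, 5000, 300)
        psl = [
            PslRecord(
                matches=1000, mismatches=5, strand="+", q_name="c",
                q_size=1300, q_start=0, q_end=1300, t_name="chr1",
                t_size=20_000, t_start=9000, t_end=10_000, block_count=1,
                block_sizes=[1000], q_starts=[0], t_starts=[9000],
            )
        ]
        out = validate_consensus(cons, ins_call(5000, 300), psl_records=psl)
        assert not out.accepted


class TestCollectSegments:
    def test_segments_span_event_with_flanks(self, small_scenario, small_calls):
        sc, alignments = small_scenario
        by_read = {a.read_id: a for a in alignments}
        indels = [
            c for c in small_calls
            if c.passes and c.sv_type in (SvType.INS, SvType.DEL)
        ]
        assert indels
        for call in indels:
            segs = collect_segments(call, by_read, flank=500)
            assert len(segs) >= 2
            expect = 1000 + (call.length if call.sv_type is SvType.INS else 0)
            # truncation and read errors shrink some segments
            assert all(len(s) <= expect * 1.3 for s in segs)
            assert max(len(s) for s in segs) > expect * 0.5

    def test_non_support_reads_excluded(self, small_scenario, small_calls):
        _, alignments = small_scenario
        by_read = {a.read_id: a for a in alignments}
        call = next(c for c in small_calls if c.passes)
        segs = collect_segments(call, by_read)
        assert len(segs) == len({m.read_id for m in call.cluster.members})


class TestEndToEndRecovery:
    def test_insertion_consensus_matches_planted_sequence(
        self, small_scenario, small_calls
    ):
        """Accepted insertion consensuses recover the spiked sequence."""
        sc, alignments = small_scenario
        seqs = sc.build.seqs
        by_read = {a.read_id: a for a in alignments}
        truth_ins = {
            t.pos1: t for t in sc.spike.truth if t.sv_type is SvType.INS
        }
        checked = 0
        for call in small_calls:
            if not call.passes or call.sv_type is not SvType.INS:
                continue
            t = min(truth_ins.values(), key=lambda t: abs(t.pos1 - call.pos1))
            if abs(t.pos1 - call.pos1) > 100:
                continue
            segs = collect_segments(call, by_read)
            if len(segs) < 8:
                continue  # majority voting needs reasonable support
            cons = validate_consensus(
                build_consensus(segs, call.id), call, reference=seqs
            )
            if not cons.accepted:
                continue
            truth_seq = (
                seqs[t.chrom][t.pos1 - 500 : t.pos1]
                + t.inserted_seq
                + seqs[t.chrom][t.pos1 : t.pos1 + 500]
            )
            # full nanopore-like (~15%) read error and modest support
            # leave a few percent residual error; the check is that the
            # planted sequence, not something else, was recovered
            d = edlib.align(cons.sequence, truth_seq)["editDistance"]
            assert d / len(truth_seq) < 0.08
            checked += 1
        assert checked >= 2
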