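"""Cleavage inference, phase-register assignment and occupancy detection."""

import numpy as np
import pytest

from srnaome.core import SeqRecord, reverse_complement
from srnaome.synth import simulate_phased_reads, simulate_uniform_reads
from srnaome.targets import ScoringParams, score_sites
from srnaome.tasirna import (
    CleavageAmbiguous,
    PhasingConfig,
    assign_phase,
    detect_registers,
    infer_cleavage,
    scan_genomic_phasing,
)

MIRNA = SeqRecord("m", "TGACAGAAGAGAGTGAGCACA")
L = len(MIRNA.sequence)


def _hit_at(start=100, site=None):
    site = site or reverse_complement(MIRNA.sequence)
    tx = SeqRecord("t", "A" * start + site + "A" * 60)
    (hit,) = score_sites(MIRNA, tx, ScoringParams(candidate_floor=0.0))
    return hit


class TestInferCleavage:
    def test_cut_between_bases_pairing_10_and_11(self):
        # perfect site starting at 100: position 10 pairs coordinate 111,
        # position 11 pairs 110; the cut boundary index is 111
        assert infer_cleavage(_hit_at(100)) == 111

    def test_mismatch_at_10_still_inferable(self):
        site = list(reverse_complement(MIRNA.sequence))
        j = L - 10
        site[j] = "C" if site[j] != "C" else "A"
        assert infer_cleavage(_hit_at(100, "".join(site))) == 111

    def test_bulge_between_10_and_11_errors(self):
        # a transcript base bulged exactly between the bases pairing
        # positions 11 and 10 makes the cut coordinate ambiguous
        hit = _hit_at(100)
        pairing = []
        for mp, tp, state in hit.pairing:
            # entries pairing positions <= 10 lie 3' of the bulge on the
            # transcript, so their coordinates shift past it
            shifted = tp + 1 if (mp is not None and mp <= 10) else tp
            pairing.append((mp, shifted, state))
            if mp == 11:
                pairing.append((None, tp + 1, "bulge_t"))
        hit.pairing = pairing
        with pytest.raises(CleavageAmbiguous):
            infer_cleavage(hit)

    def test_bulged_mirna_base_at_10_errors(self):
        hit = _hit_at(100)
        hit.pairing = [
            (mp, None if mp == 10 else tp, "bulge_m" if mp == 10 else state)
            for mp, tp, state in hit.pairing
        ]
        with pytest.raises(CleavageAmbiguous):
            infer_cleavage(hit)


class TestAssignPhase:
    CFG = PhasingConfig()

    @pytest.mark.parametrize("k", [0, 1, 2, 5])
    def test_sense_multiples_of_period(self, k):
        assert assign_phase(500 + 21 * k, "+", 500, self.CFG) == 0

    def test_periodicity(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            pos = int(rng.integers(0, 10_000))
            k = int(rng.integers(-20, 20))
            assert assign_phase(pos, "+", 137, self.CFG) == assign_phase(
                pos + 21 * k, "+", 137, self.CFG
            )

    def test_antisense_offset(self):
        # antisense 5' end at cleavage + p - offset maps to register 0
        assert assign_phase(500 + 21 - 2, "-", 500, self.CFG) == 0


class TestDetectRegisters:
    def test_single_register(self):
        reads = [(100 + 21 * k, "+", 21, 1) for k in range(12)]
        res = detect_registers(reads, 100)
        assert res.occupied_registers == [0]
        assert res.in_phase_fraction == 1.0
        assert res.miRNA_anchored

    def test_jitter_collapse(self):
        reads = [(100 + 21 * k, "+", 21, 1) for k in range(10)]
        reads.append((100 + 22, "+", 21, 1))  # one read 1 nt off phase
        res = detect_registers(reads, 100)
        assert res.occupied_registers == [0]
        assert res.in_phase_fraction == 1.0

    def test_two_interleaved_registers(self):
        reads = [(100 + 21 * k, "+", 21, 1) for k in range(10)]
        reads += [(110 + 21 * k, "+", 21, 1) for k in range(10)]
        res = detect_registers(reads, 100)
        assert res.occupied_registers == [0, 10]

    def test_uniform_reads_no_register(self):
        rng = np.random.default_rng(99)
        res = detect_registers(simulate_uniform_reads(rng, 200), 0)
        assert res.occupied_registers == []

    def test_register_counts_partition_reads(self):
        rng = np.random.default_rng(3)
        reads = simulate_phased_reads(rng, n_phased=15, noise_fraction=0.2, register=4)
        res = detect_registers(reads, 0)
        assert sum(res.register_counts) == sum(c for _p, _s, _l, c in reads)

    def test_len21_fraction(self):
        reads = [(100 + 21 * k, "+", 21, 1) for k in range(9)] + [(105, "+", 24, 1)]
        res = detect_registers(reads, 100)
        assert res.len21_fraction == pytest.approx(0.9)


class TestPhasingPower:
    def test_planted_register_recovery(self):
        """>= 95% recovery with >= 10 phased reads and <= 20% noise."""
        rng = np.random.default_rng(42)
        recovered = 0
        for _ in range(200):
            reg = int(rng.integers(0, 21))
            reads = simulate_phased_reads(rng, n_phased=12, noise_fraction=0.2,
                                          register=reg)
            res = detect_registers(reads, 0)
            recovered += reg in res.occupied_registers
        assert recovered / 200 >= 0.95

    def test_false_register_rate(self):
        """<= 5% of uniform-read trials produce any occupied register."""
        rng = np.random.default_rng(43)
        false = sum(
            bool(detect_registers(simulate_uniform_reads(rng, 200), 0).occupied_registers)
            for _ in range(200)
        )
        assert false / 200 <= 0.05


class TestTASDetection:
    def test_synthetic_tas_locus(self, report):
        (cand,) = report.tas_candidates
        assert cand.transcript_id == "TAS_unigene"
        assert cand.clean_9_11 == (True, True)
        for ph in cand.phasing:
            assert ph.occupied_registers == [0, 10]
            assert ph.miRNA_anchored
            assert ph.len21_fraction > 0.92
            assert ph.sense_count > ph.antisense_count

    def test_single_site_transcripts_not_tas(self, report):
        ids = {c.transcript_id for c in report.tas_candidates}
        assert "unigene_mir159_target" not in ids

    def test_genomic_phasing_matches_planted_registers(self, report):
        # anchors are phased reads in the cleavage register, so any register
        # clearing the occupancy bar must be one of the two planted ones
        # (0 and +10 relative to the anchor)
        assert report.genomic_phasing
        for res in report.genomic_phasing:
            assert res.occupied_registers
            assert set(res.occupied_registers) <= {0, 10}


def test_scan_genomic_phasing_truncated_window():
    genome = SeqRecord("g", "ACGT" * 100)
    res = scan_genomic_phasing(genome, anchor=10, srnas=[], cfg=PhasingConfig())
    assert res.truncated
    assert res.occupied_registers == []
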