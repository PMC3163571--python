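"""Novel miRNA discovery: mapping, filters, star scan, precursor build,
exclusions and end-to-end calling on the synthetic genome."""

import numpy as np
import pytest

from srnaome.core import SeqRecord, UniqueSRNA, reverse_complement
from srnaome.novel import (
    GenomeIndex,
    NovelConfig,
    apply_exclusions,
    build_precursor,
    call_candidates,
    count_genome_hits,
    evaluate_locus,
    scan_flanks_for_star,
    select_novel_candidates,
)
from srnaome.synth import score_recovery


def _srna(seq, total=1):
    return UniqueSRNA(seq, {"x": total})


def _rand(rng, n, gc=0.45):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(1234)
    unique = _rand(rng, 21)
    multi = _rand(rng, 21)
    parts = [_rand(rng, 300), unique, _rand(rng, 300)]
    for _ in range(7):
        parts += [multi, _rand(rng, 80)]
    genome = SeqRecord("chr", "".join(parts))
    return genome, unique, multi


class TestGenomeHits:
    def test_unique_sequence_one_hit(self, toy_genome):
        genome, unique, _ = toy_genome
        assert count_genome_hits(_srna(unique), GenomeIndex([genome])) == 1

    def test_seven_copies_counted(self, toy_genome):
        genome, _, multi = toy_genome
        assert count_genome_hits(_srna(multi), GenomeIndex([genome])) == 7

    def test_absent_sequence_zero(self, toy_genome):
        genome, _, _ = toy_genome
        assert count_genome_hits(_srna("G" * 21), GenomeIndex([genome])) == 0

    def test_inverted_repeat_copies_count_separately(self):
        arm = "ATCGGCTAGCTAGGCTAGCTT"
        genome = SeqRecord("c", "A" * 50 + arm + "AAAGA" + reverse_complement(arm) + "A" * 50)
        assert count_genome_hits(_srna(arm), GenomeIndex([genome])) == 2


class TestSelection:
    def test_filters(self, toy_genome):
        genome, unique, multi = toy_genome
        index = GenomeIndex([genome])
        cfg = NovelConfig()
        wrong_len = _srna(unique + "AC")  # 23 nt: disallowed length
        absent = _srna("GCGCGCGCGCGCGCGCGCGCG")
        selected = select_novel_candidates(
            [_srna(unique), _srna(multi), wrong_len, absent], index, cfg
        )
        assert [s.sequence for s, _p in selected] == [unique]


class TestPrecursorBuild:
    def test_long_enough_kept(self):
        assert build_precursor((0, 21), (74, 95), 70) == (0, 95)

    def test_short_rejected(self):
        assert build_precursor((0, 21), (39, 60), 70) is None

    def test_star_upstream_normalized(self):
        assert build_precursor((80, 101), (0, 21), 70) == (0, 101)


class TestStarScan:
    def test_planted_star_found_at_coordinates(self):
        rng = np.random.default_rng(5)
        mirna = _rand(rng, 21, gc=0.5)
        star = reverse_complement(mirna)
        frame = _rand(rng, 200) + mirna + _rand(rng, 35) + star + _rand(rng, 200)
        span = (200, 221)
        hit = scan_flanks_for_star(frame, span, _srna(mirna), NovelConfig())
        assert hit is not None
        site, score = hit
        assert abs(site[0] - 256) <= 2 and abs(site[1] - 277) <= 2

    def test_random_flanks_no_star(self):
        rng = np.random.default_rng(6)
        mirna = _rand(rng, 21, gc=0.5)
        frame = _rand(rng, 200) + mirna + _rand(rng, 200)
        assert scan_flanks_for_star(frame, (200, 221), _srna(mirna), NovelConfig()) is None

    def test_self_overlap_ignored(self):
        # the only complementary stretch overlaps the sRNA's own site
        rng = np.random.default_rng(7)
        mirna = _rand(rng, 21, gc=0.5)
        frame = _rand(rng, 100) + mirna + _rand(rng, 100)
        span = (100, 121)
        hit = scan_flanks_for_star(frame, span, _srna(reverse_complement(mirna)),
                                   NovelConfig())
        assert hit is None or not (hit[0][0] < span[1] and span[0] < hit[0][1])


class TestExclusions:
    def _passing_locus(self, rng):
        from srnaome.synth import _make_hairpin_element

        element, mirna, star, span = _make_hairpin_element(rng, 21)
        genome = SeqRecord("chr", _rand(rng, 700) + element + _rand(rng, 700))
        index = GenomeIndex([genome])
        return genome, index, _srna(mirna, 5), element

    def test_transposon_exclusion(self):
        rng = np.random.default_rng(11)
        genome, index, srna, element = self._passing_locus(rng)
        placement = index.placements(srna.sequence)[0]
        locus = evaluate_locus(
            srna, placement, index, NovelConfig(), [srna],
            exclusion_sets={"transposon": [SeqRecord("tp1", element)]},
        )
        assert locus.status == "rejected"
        assert "transposon" in locus.reject_reason

    def test_foldback_antisense_threshold(self):
        rng = np.random.default_rng(12)
        genome, index, srna, element = self._passing_locus(rng)
        placement = index.placements(srna.sequence)[0]
        # 12 distinct sRNAs mapping antisense over the precursor region
        start = genome.sequence.find(element)
        anti = [
            _srna(reverse_complement(genome.sequence[start + o : start + o + 21]))
            for o in range(0, 60, 5)
        ]
        locus = evaluate_locus(srna, placement, index, NovelConfig(), [srna] + anti)
        assert locus.status == "rejected"
        assert "foldback" in locus.reject_reason

    def test_known_mirna_star_exclusion(self):
        rng = np.random.default_rng(13)
        genome, index, srna, element = self._passing_locus(rng)
        placement = index.placements(srna.sequence)[0]
        # pretend a known miRNA whose star (2-nt shifted RC) is our sRNA
        known = SeqRecord("miR-known", reverse_complement(srna.sequence)[2:] + "CA")
        locus = evaluate_locus(srna, placement, index, NovelConfig(), [srna],
                               known_mirnas=[known])
        assert locus.status == "rejected"
        assert "known miRNA" in locus.reject_reason

    def test_clean_locus_passes(self):
        rng = np.random.default_rng(14)
        genome, index, srna, element = self._passing_locus(rng)
        placement = index.placements(srna.sequence)[0]
        locus = evaluate_locus(srna, placement, index, NovelConfig(), [srna])
        assert locus.status == "candidate_mirna"


class TestEndToEnd:
    def test_planted_recovery(self, dataset, report):
        """Every conforming hairpin recovered with the expected status;
        every decoy yields no passing call."""
        sc = score_recovery(dataset.truth, report.novel_loci)
        assert sc["n_correct"] == sc["n_elements"]
        assert sc["false_calls"] == 0

    def test_decoy_reject_reasons(self, dataset, report, species_class):
        """Decoys that reach locus evaluation carry their planted reason."""
        reasons = {
            "short_precursor": "short",
            "foldback": "foldback",
        }
        for locus in report.novel_loci:
            cls = species_class.get(locus.srna.sequence, "")
            if cls.startswith("decoy:"):
                kind = cls.split(":")[1].rsplit("_", 1)[0]
                if locus.status == "rejected" and kind in reasons:
                    assert (
                        reasons[kind] in locus.reject_reason
                        or "opposite arm" in locus.reject_reason
                    ), (cls, locus.reject_reason)

    def test_status_partition(self, report):
        assert all(
            l.status in ("confirmed_mirna", "candidate_mirna", "rejected")
            for l in report.novel_loci
        )
        assert all(l.reject_reason for l in report.novel_loci if l.status == "rejected")

    def test_strand_invariance(self):
        """Planting the locus on the minus strand yields the same call."""
        rng = np.random.default_rng(21)
        from srnaome.synth import _make_hairpin_element

        element, mirna, _star, _span = _make_hairpin_element(rng, 21)
        left, right = _rand(rng, 700), _rand(rng, 700)
        fwd = SeqRecord("chr", left + element + right)
        rev = SeqRecord("chr", reverse_complement(left + element + right))
        srna = _srna(mirna, 5)
        out_f = call_candidates([srna], GenomeIndex([fwd]), all_srnas=[srna])
        out_r = call_candidates([srna], GenomeIndex([rev]), all_srnas=[srna])
        assert [l.status for l in out_f] == [l.status for l in out_r]
        assert out_f[0].precursor.mfei == pytest.approx(out_r[0].precursor.mfei)
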