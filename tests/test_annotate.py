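"""Classification cascade, known-miRNA assignment, variant rule,
normalization and organelle profiling."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnaome.annotate import (
    ClassifierConfig,
    KnownMiRNAAssignment,
    ReferenceSet,
    assign_known_mirnas,
    classify_cascade,
    expression_profile,
    mirna_family,
    near_match,
    normalize_per10k,
    organelle_profile,
    variant_filter,
)
from srnaome.core import SeqRecord, UniqueSRNA, reverse_complement

MIR159A = "TTTGGATTGAAGGGAGCTCTA"   # melon miR159a, DNA form
MIR397_MELON = "CATTGAGTGCAGCGTTGATGT"  # reported at 95% similarity


def _srna(seq, total=1, lib="x"):
    return UniqueSRNA(seq, {lib: total})


class TestNearMatch:
    def test_exact_match_zero_mismatches(self):
        refs = ReferenceSet("miRNA", [SeqRecord("ath-miR159a", MIR159A)])
        hits = near_match(MIR159A, refs, 2)
        assert hits == [("ath-miR159a", 0, "+")]

    def test_one_mismatch_reference(self):
        # a reference differing from the melon sequence at one site
        ref_seq = MIR397_MELON[:-1] + ("A" if MIR397_MELON[-1] != "A" else "C")
        refs = ReferenceSet("miRNA", [SeqRecord("bna-miR397a", ref_seq)])
        hits = near_match(MIR397_MELON, refs, 2)
        assert hits == [("bna-miR397a", 1, "+")]

    def test_absent_query(self):
        refs = ReferenceSet("miRNA", [SeqRecord("r", "A" * 40)])
        assert near_match("GCGCGCGCGCGCGCGCGCGCG", refs, 2) == []

    def test_query_found_inside_longer_reference(self):
        refs = ReferenceSet("rRNA_LSU", [SeqRecord("r", "TTTT" + MIR159A + "GGGG")])
        assert near_match(MIR159A, refs, 0) == [("r", 0, "+")]

    @given(st.text(alphabet="ACGT", min_size=18, max_size=24))
    @settings(max_examples=30, deadline=None)
    def test_reverse_complement_symmetry(self, query):
        ref = "ACGT" * 5 + query + "TGCA" * 5
        fwd = near_match(query, ReferenceSet("c", [SeqRecord("r", ref)]), 1)
        rev = near_match(query, ReferenceSet("c", [SeqRecord("r", reverse_complement(ref))]), 1)
        assert [(h[0], h[1]) for h in fwd] == [(h[0], h[1]) for h in rev]


class TestCascade:
    def _refsets(self):
        return [
            ReferenceSet("rRNA_LSU", [SeqRecord("rrna", "A" * 10 + MIR159A + "C" * 10)]),
            ReferenceSet("transposon", [SeqRecord("tp", "G" * 10 + MIR159A + "T" * 10)]),
        ]

    def test_precedence_decides_category_but_hits_retained(self):
        cfg = ClassifierConfig(precedence=["rRNA_LSU", "transposon"])
        cat, hits = classify_cascade(_srna(MIR159A), self._refsets(), cfg)
        assert cat == "rRNA_LSU"
        assert set(hits) == {"rRNA_LSU", "transposon"}

    def test_precedence_reversed(self):
        cfg = ClassifierConfig(precedence=["transposon", "rRNA_LSU"])
        cat, _ = classify_cascade(_srna(MIR159A), self._refsets(), cfg)
        assert cat == "transposon"

    def test_no_hits_unclassified(self):
        cfg = ClassifierConfig()
        cat, hits = classify_cascade(_srna("GC" * 11), self._refsets(), cfg)
        assert cat == "unclassified" and hits == {}


class TestKnownAssignment:
    def test_exact_and_variant_similarity(self):
        refs = ReferenceSet("miRNA", [SeqRecord("miR159|a", MIR159A)])
        cfg = ClassifierConfig()
        one_mm = "A" + MIR159A[1:]
        out = assign_known_mirnas([_srna(MIR159A), _srna(one_mm)], refs, cfg)
        by_seq = {a.srna.sequence: a for a in out}
        assert by_seq[MIR159A].similarity == 100
        assert by_seq[MIR159A].is_variant is False
        # 1 mismatch over 21 nt: 100*20/21 = 95.2 -> printed as 95
        assert by_seq[one_mm].similarity == 95
        assert by_seq[one_mm].is_variant is True

    def test_three_mismatches_not_assigned(self):
        refs = ReferenceSet("miRNA", [SeqRecord("miR159|a", MIR159A)])
        bad = "AAA" + MIR159A[3:]
        assert assign_known_mirnas([_srna(bad)], refs, ClassifierConfig()) == []

    def test_family_extraction(self):
        assert mirna_family("miR159|a") == "159"
        assert mirna_family("bna-miR397a") == "397"
        assert mirna_family("osa-miR167d") == "167"


class TestVariantRule:
    def _group(self, variant_reads, ref_reads=97):
        refs = ReferenceSet("miRNA", [SeqRecord("miR159|a", MIR159A)])
        cfg = ClassifierConfig()
        variant = "A" + MIR159A[1:]
        return assign_known_mirnas(
            [_srna(MIR159A, ref_reads), _srna(variant, variant_reads)], refs, cfg
        )

    def test_two_percent_variant_merged(self):
        kept = variant_filter(self._group(2, 98))
        assert len(kept) == 1
        assert kept[0].srna.sequence == MIR159A
        assert kept[0].merged_reads == 2

    def test_five_percent_variant_retained(self):
        kept = variant_filter(self._group(5, 95))
        assert len(kept) == 2

    def test_exactly_three_percent_merged(self):
        # strictly "more than 3%": 3 of 100 is merged
        kept = variant_filter(self._group(3, 97))
        assert len(kept) == 1

    def test_reads_conserved(self):
        for v in (1, 3, 10, 40):
            group = self._group(v, 100 - v)
            kept = variant_filter(group)
            total = sum(a.srna.total + a.merged_reads for a in kept)
            assert total == 100

    def test_threshold_zero_retains_all(self):
        kept = variant_filter(self._group(1, 99), threshold=0.0)
        assert len(kept) == 2


class TestNormalization:
    @pytest.mark.parametrize(
        "count,total,expect",
        [(50, 20_000, 25.0), (0, 123, 0.0), (33_123, 33_123, 10_000.0)],
    )
    def test_per10k(self, count, total, expect):
        assert normalize_per10k(count, total) == pytest.approx(expect)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            normalize_per10k(1, 0)

    def test_expression_profile(self):
        prof = expression_profile("miR159|a", {"A": 50}, {"A": 20_000, "B": 500})
        assert prof.per_library == {"A": 25.0, "B": 0.0}


class TestOrganelleProfile:
    def test_inverted_repeat_gives_two_mirrored_clusters(self, dataset):
        profile = organelle_profile(
            [UniqueSRNA(p["sequence"], {"x": p["count"]})
             for p in dataset.truth["species_plan"] if p["class"] == "rRNA_LSU"],
            dataset.chloroplast,
        )
        spans = dataset.truth["organelles"]["cp_rrna_spans"]
        per_span = []
        for s, e in spans:
            cl = [c for c in profile.clusters if c.start < e and s < c.end]
            assert cl, f"no cluster over planted rRNA span {s}-{e}"
            per_span.append(
                (sum(c.sense_reads for c in cl), sum(c.antisense_reads for c in cl))
            )
        # inverted repeats mirror the strand composition of the two copies
        (s1, a1), (s2, a2) = per_span
        assert (s1, a1) == (a2, s2)
        assert s1 > 0 and a1 > 0

    def test_no_matching_reads_empty_profile(self):
        genome = SeqRecord("g", "ACGT" * 100)
        profile = organelle_profile([_srna("G" * 21)], genome)
        assert profile.sense == {} and profile.clusters == []

    def test_antisense_reported_negative(self):
        genome = SeqRecord("g", "AAAACCCCGGGGTTTTACGTACGTACGT" * 4)
        read = reverse_complement(genome.sequence[10:31])
        profile = organelle_profile([_srna(read, 7)], genome, min_cov=5)
        rows = list(profile.to_rows())
        assert any(r[2] <= -7 for r in rows)
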