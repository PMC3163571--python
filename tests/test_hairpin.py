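"""Folding engine, MFEI, duplex extraction and structural criteria.

The folding oracle enumerates every nested single-stem pair chain
explicitly (no dynamic programming) and evaluates it with the shared
energy model, so the DP search path is checked against an independent
search over the full structure space.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnaome.core import UniqueSRNA, reverse_complement
from srnaome.hairpin import (
    MIN_HAIRPIN_LOOP,
    StructuralCriteria,
    check_structural_criteria,
    compute_mfei,
    duplex_consistent,
    extract_duplex,
    find_star_in_reads,
    fold_stemloop,
    pair_ok,
    structure_energy,
)


def enumerate_chains(seq, i=0, j=None):
    """All nested single-stem pair chains of seq[i..j] (brute force)."""
    if j is None:
        j = len(seq) - 1
    chains = [[]]
    for a in range(i, j + 1):
        for b in range(a + MIN_HAIRPIN_LOOP + 1, j + 1):
            if not pair_ok(seq[a], seq[b]):
                continue
            for inner in enumerate_chains(seq, a + 1, b - 1):
                chains.append([(a, b)] + inner)
    return chains


def brute_force_mfe(seq):
    best = 0.0
    for chain in enumerate_chains(seq):
        if chain:
            best = min(best, structure_energy(seq, chain))
    return best


class TestFoldOracle:
    def test_matches_exhaustive_enumeration(self):
        """DP energy equals brute-force search for 200 random short sequences."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(8, 15))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            padded = seq + "A" * max(0, 20 - n)  # meet the engine's minimum length
            assert fold_stemloop(padded).mfe == pytest.approx(
                brute_force_mfe(padded), abs=1e-9
            ), seq

    def test_polya_has_no_structure(self):
        res = fold_stemloop("A" * 22)
        assert res.pairs == frozenset() and res.mfe == 0.0

    def test_simple_stem(self):
        seq = "GGGGGAAAACCCCC" + "A" * 6
        res = fold_stemloop(seq)
        assert res.mfe == pytest.approx(brute_force_mfe(seq), abs=1e-9)
        assert res.mfe < 0
        assert len(res.pairs) == 5

    def test_gc_stem_beats_au_stem_of_same_shape(self):
        gc = fold_stemloop("GGGGG" + "AAAA" + "CCCCC" + "T" * 6)
        au = fold_stemloop("AAAAA" + "GGGG" + "TTTTT" + "C" * 6)
        assert gc.mfe < au.mfe

    def test_flank_translation_invariance(self):
        stem = "GGCGGCGG" + "ATAA" + "CCGCCGCC"
        bare = fold_stemloop(stem)
        embedded = fold_stemloop("A" * 15 + stem + "A" * 15)
        assert embedded.mfe <= bare.mfe + 1e-9

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            fold_stemloop("ACGT")

    def test_mfe_zero_iff_no_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=24))
            res = fold_stemloop(seq)
            assert (res.mfe == 0.0) == (not res.pairs)


class TestMFEI:
    def test_worked_example(self):
        # MFE -50 kcal/mol, 100 nt, GC 50% -> AMFE -50, MFEI -1.0
        seq = "GC" * 25 + "AT" * 25
        rec = compute_mfei(seq, -50.0)
        assert rec.amfe == pytest.approx(-50.0)
        assert rec.mfei == pytest.approx(-1.0)

    def test_zero_mfe(self):
        assert compute_mfei("GCAT" * 10, 0.0).mfei == 0.0

    def test_gc_zero_errors(self):
        with pytest.raises(ValueError):
            compute_mfei("AT" * 20, -5.0)

    def test_lower_gc_more_negative_mfei(self):
        lo = compute_mfei("GC" * 20 + "AT" * 30, -40.0)  # GC 40%
        hi = compute_mfei("GC" * 30 + "AT" * 20, -40.0)  # GC 60%
        assert lo.mfei < hi.mfei

    @given(
        st.floats(min_value=-200, max_value=0),
        st.integers(min_value=1, max_value=50),
        st.integers(min_value=0, max_value=50),
    )
    @settings(max_examples=100, deadline=None)
    def test_closed_form(self, mfe, gc_pairs, at_pairs):
        seq = "GC" * gc_pairs + "AT" * at_pairs
        rec = compute_mfei(seq, mfe)
        L = len(seq)
        gc_pct = 100.0 * 2 * gc_pairs / L
        assert rec.mfei == pytest.approx((100.0 * mfe / L) / gc_pct, abs=1e-9)


def _perfect_hairpin(mirna, loop="AATAATAA", flank="AAAAA"):
    # poly-A flanks cannot pair with each other, so the fold's stem ends
    # exactly at the planted duplex
    seq = flank + mirna + loop + reverse_complement(mirna) + flank
    span = (len(flank), len(flank) + len(mirna))
    return seq, span


class TestDuplex:
    MIRNA = "TGACAGAAGAGAGTGAGCACA"

    def test_perfect_duplex_is_typical(self):
        seq, span = _perfect_hairpin(self.MIRNA)
        d = extract_duplex(fold_stemloop(seq), span)
        assert d.typing == "typical"
        assert d.overhang_mirna_3p == 2 and d.overhang_star_3p == 2
        assert d.mismatched_bases == 0 and d.largest_asymmetric_bulge == 0

    def test_shifted_star_is_non_typical(self):
        seq, span = _perfect_hairpin(self.MIRNA)
        fold = fold_stemloop(seq)
        canonical = extract_duplex(fold, span).star_span
        shifted = (canonical[0] - 1, canonical[1] - 1)  # 3-nt overhang one side
        d = extract_duplex(fold, span, star_span=shifted)
        assert d.typing == "non_typical"

    def test_arm_swap_preserves_typing(self):
        seq, span = _perfect_hairpin(self.MIRNA)
        fold = fold_stemloop(seq)
        d = extract_duplex(fold, span)
        swapped = extract_duplex(fold, d.star_span)
        assert swapped.typing == d.typing == "typical"

    def test_asymmetric_bulge_measured(self):
        # delete 3 bases from the middle of the star arm
        star = reverse_complement(self.MIRNA)
        star = star[:9] + star[12:]
        seq = "AAAAA" + self.MIRNA + "AATAATAA" + star + "AAAAA"
        d = extract_duplex(fold_stemloop(seq), (5, 5 + len(self.MIRNA)))
        assert d.largest_asymmetric_bulge == 3

    def test_unpaired_mirna_errors(self):
        seq = "AAAAA" + self.MIRNA + "A" * 40
        with pytest.raises(ValueError, match="stem"):
            extract_duplex(fold_stemloop(seq), (5, 5 + len(self.MIRNA)))


class TestStructuralCriteria:
    def test_strict_pass(self):
        v = check_structural_criteria(_hp(90, -1.2), _dx(mism=2, bulge=1), StructuralCriteria())
        assert v.status == "pass_strict"

    def test_three_base_bulge_is_relaxed(self):
        v = check_structural_criteria(_hp(90, -1.2), _dx(mism=2, bulge=3), StructuralCriteria())
        assert v.status == "pass_relaxed"

    def test_short_precursor_fails(self):
        v = check_structural_criteria(_hp(60, -1.2), _dx(mism=2, bulge=1), StructuralCriteria())
        assert v.status == "fail"
        assert any("short" in r for r in v.reasons)

    def test_all_violations_listed(self):
        v = check_structural_criteria(_hp(60, -0.2), _dx(mism=9, bulge=5), StructuralCriteria())
        assert len(v.reasons) == 4


def _hp(length, mfei):
    from srnaome.hairpin import HairpinRecord

    seq = ("GCAT" * 200)[:length]
    gc = 50.0
    amfe = mfei * gc
    return HairpinRecord(seq, amfe * length / 100.0, gc, amfe, mfei)


def _dx(mism=0, bulge=0):
    from srnaome.hairpin import DuplexRecord

    return DuplexRecord((0, 21), (40, 61), mism, bulge, 2, 2)


class TestStarSearch:
    MIRNA = "TGACAGAAGAGAGTGAGCACA"

    def test_exact_shifted_rc_found(self):
        star = reverse_complement(self.MIRNA)[2:] + "GT"
        hits = find_star_in_reads(
            UniqueSRNA(self.MIRNA, {"x": 5}), [UniqueSRNA(star, {"x": 1})]
        )
        assert len(hits) == 1

    def test_unrelated_pool_empty(self):
        pool = [UniqueSRNA("GATTACA" * 3, {"x": 1})]
        assert find_star_in_reads(UniqueSRNA(self.MIRNA, {"x": 1}), pool) == []

    def test_predicted_star_identity_mode(self):
        predicted = reverse_complement(self.MIRNA)
        near = predicted[:10] + ("A" if predicted[10] != "A" else "C") + predicted[11:]
        hits = find_star_in_reads(
            UniqueSRNA(self.MIRNA, {"x": 1}),
            [UniqueSRNA(near, {"x": 1})],
            predicted_star=predicted,
        )
        assert len(hits) == 1 and hits[0][1] == 1

    def test_duplex_consistent_rejects_far_shift(self):
        star = reverse_complement(self.MIRNA)[8:] + "ACGTACGT"
        assert duplex_consistent(self.MIRNA, star, max_mm=4, max_offset=4) is None
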