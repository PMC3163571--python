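"""Stem-loop folding, MFE/AMFE/MFEI computation and duplex typing.

The folding engine implements a minimum-energy search restricted to single
stem-loops: a totally nested chain of Watson-Crick / G:U pairs with bulges
and internal loops, closed by one terminal hairpin loop of at least 3 nt.
Multibranch loops and pseudoknots are outside the model, which matches the
only shapes the miRNA-precursor pipeline ever evaluates.  The energy is a
simplified nearest-neighbour sum: a bond term per pair, a stacking bonus
for directly stacked pairs, and affine penalties for loops.  Absolute
kcal/mol agreement with full thermodynamic folders is a non-goal; what
drives precursor selection is the MFEI ordering (the more negative the
index, the better the precursor), which the simplified model preserves.

The engine is pluggable: any callable returning a :class:`FoldResult` can
stand in for :func:`fold_stemloop`, and all downstream logic depends only
on the FoldResult contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import gc_percent

# --- energy parameters (kcal/mol); simplified nearest-neighbour model -----
BOND_ENERGY = {
    ("G", "C"): -3.4, ("C", "G"): -3.4,
    ("A", "T"): -2.2, ("T", "A"): -2.2,
    ("G", "T"): -1.1, ("T", "G"): -1.1,
}
STACK_BONUS = -1.0          # two pairs with no intervening unpaired bases
HAIRPIN_BASE = 4.0          # terminal loop: HAIRPIN_BASE + HAIRPIN_EXT*(n-3)
HAIRPIN_EXT = 0.25
INTERIOR_BASE = 2.5         # bulge/internal loop: INTERIOR_BASE + INTERIOR_EXT*n
INTERIOR_EXT = 0.45
MAX_INTERIOR = 30           # total unpaired bases in one bulge/internal loop
MIN_HAIRPIN_LOOP = 3

MIN_FOLD_LEN = 20
MAX_FOLD_LEN = 2000

_EPS = 1e-9


def pair_ok(x: str, y: str) -> bool:
    """True for Watson-Crick or G:U (DNA form: G:T) pairs."""
    return (x, y) in BOND_ENERGY


def hairpin_penalty(n: int) -> float:
    return HAIRPIN_BASE + HAIRPIN_EXT * (n - MIN_HAIRPIN_LOOP)


def interior_penalty(n: int) -> float:
    return INTERIOR_BASE + INTERIOR_EXT * n


@dataclass(frozen=True)
class FoldResult:
    """A nested single-stem secondary structure with its energy."""

    pairs: frozenset[tuple[int, int]]
    mfe: float
    structure_string: str

    def partner_map(self) -> dict[int, int]:
        m: dict[int, int] = {}
        for i, j in self.pairs:
            m[i] = j
            m[j] = i
        return m


def _dot_bracket(n: int, pairs) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def structure_energy(seq: str, pairs) -> float:
    """Energy of a given nested single-stem pair chain (oracle-style evaluation).

    *pairs* must be a chain of strictly nested (i, j) pairs.  Used both by
    the traceback sanity check and as the shared energy model for the
    exhaustive-enumeration oracle in the test suite.
    """
    if not pairs:
        return 0.0
    chain = sorted(pairs)
    e = 0.0
    for i, j in chain:
        e += BOND_ENERGY[(seq[i], seq[j])]
    for (i, j), (k, l) in zip(chain, chain[1:]):
        d1, d2 = k - i - 1, j - l - 1
        if d1 == 0 and d2 == 0:
            e += STACK_BONUS
        else:
            e += interior_penalty(d1 + d2)
    i, j = chain[-1]
    e += hairpin_penalty(j - i - 1)
    return e


def fold_stemloop(sequence: str) -> FoldResult:
    """Minimum-energy single stem-loop structure of *sequence*.

    Dynamic program over closed intervals: ``E(i, j)`` is the best energy of
    a stem-loop closed by pair (i, j); the pair either closes the terminal
    hairpin loop or is extended by an inner pair across a stack, bulge or
    internal loop (total loop size <= 30).  The reported MFE is
    ``min(0, min E)``; the empty structure wins ties, so ``mfe == 0`` iff
    no pairs are reported.  Traceback prefers outer pairs with the smallest
    5' index and, inside, the smallest loop offsets, which makes the
    reported pair set deterministic.
    """
    n = len(sequence)
    if not (MIN_FOLD_LEN <= n <= MAX_FOLD_LEN):
        raise ValueError(f"fold_stemloop: length {n} outside [{MIN_FOLD_LEN}, {MAX_FOLD_LEN}]")
    seq = sequence

    # bond[i] along each diagonal; NaN-free: +inf where unpairable
    INF = np.inf
    bond = np.full((n, n), INF)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            b = BOND_ENERGY.get((seq[i], seq[j]))
            if b is not None:
                bond[i, j] = b

    # diags[s][i] = E(i, i+s)
    diags: list[np.ndarray | None] = [None] * n
    min_span = MIN_HAIRPIN_LOOP + 1
    for s in range(min_span, n):
        m = n - s
        ii = np.arange(m)
        bvec = bond[ii, ii + s]
        best = np.full(m, hairpin_penalty(s - 1))
        for d1 in range(0, MAX_INTERIOR + 1):
            sp_max = s - 2 - d1
            if sp_max < min_span:
                break
            for d2 in range(0, MAX_INTERIOR + 1 - d1):
                sp = s - 2 - d1 - d2
                if sp < min_span:
                    break
                inner = diags[sp]
                if inner is None:
                    continue
                pen = STACK_BONUS if (d1 == 0 and d2 == 0) else interior_penalty(d1 + d2)
                cand = pen + inner[1 + d1 : 1 + d1 + m]
                np.minimum(best, cand, out=best)
        diags[s] = bvec + best

    # global minimum over all closing pairs (outer unpaired flanks are free)
    mfe = 0.0
    best_ij: tuple[int, int] | None = None
    for s in range(min_span, n):
        d = diags[s]
        if d is None or not len(d):
            continue
        i = int(np.argmin(d))
        if d[i] < mfe - _EPS:
            mfe = float(d[i])
            best_ij = (i, i + s)
        elif best_ij is not None and abs(d[i] - mfe) <= _EPS:
            # tie: prefer smaller 5' index, then smaller span
            cand = (i, i + s)
            if cand < best_ij:
                best_ij = cand

    if best_ij is None:
        return FoldResult(frozenset(), 0.0, "." * n)

    # traceback
    pairs: list[tuple[int, int]] = []
    i, j = best_ij
    e = mfe
    while True:
        pairs.append((i, j))
        b = BOND_ENERGY[(seq[i], seq[j])]
        remaining = e - b
        if abs(remaining - hairpin_penalty(j - i - 1)) <= _EPS:
            break
        found = False
        for d1 in range(0, MAX_INTERIOR + 1):
            if found:
                break
            for d2 in range(0, MAX_INTERIOR + 1 - d1):
                sp = j - i - 2 - d1 - d2
                if sp < min_span:
                    break
                inner = diags[sp]
                if inner is None:
                    continue
                k, l = i + 1 + d1, j - 1 - d2
                pen = STACK_BONUS if (d1 == 0 and d2 == 0) else interior_penalty(d1 + d2)
                if abs(remaining - (pen + inner[k])) <= 1e-6:
                    i, j, e = k, l, float(inner[k])
                    found = True
                    break
        if not found:  # pragma: no cover - defensive
            raise AssertionError("fold traceback failed")
    return FoldResult(frozenset(pairs), mfe, _dot_bracket(n, pairs))


# ---------------------------------------------------------------------------
# MFEI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinRecord:
    """A candidate precursor with its fold statistics.

    AMFE is the MFE adjusted to 100 nt (100*MFE/L); MFEI is AMFE divided by
    the GC percentage.  Strongly negative MFEI separates miRNA precursors
    from other coding and non-coding RNAs.
    """

    sequence: str
    mfe: float
    gc: float
    amfe: float
    mfei: float

    @property
    def length(self) -> int:
        return len(self.sequence)


def compute_mfei(sequence: str, mfe: float) -> HairpinRecord:
    gc = gc_percent(sequence)
    if gc == 0:
        raise ValueError("mfei undefined: GC content is zero")
    amfe = 100.0 * mfe / len(sequence)
    return HairpinRecord(sequence, mfe, gc, amfe, amfe / gc)


# ---------------------------------------------------------------------------
# miRNA/miRNA* duplexes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplexRecord:
    """A miRNA/miRNA* pairing extracted from a precursor fold.

    ``typing`` is "typical" iff both strands carry the canonical 2-nt
    3' overhang left by DCL processing; any other number of protruding
    nucleotides is "non_typical".
    """

    mirna_span: tuple[int, int]
    star_span: tuple[int, int]
    mismatched_bases: int
    largest_asymmetric_bulge: int
    overhang_mirna_3p: int
    overhang_star_3p: int

    @property
    def typing(self) -> str:
        return "typical" if (self.overhang_mirna_3p == 2 and self.overhang_star_3p == 2) else "non_typical"


def extract_duplex(
    fold: FoldResult,
    mirna_span: tuple[int, int],
    star_span: tuple[int, int] | None = None,
    min_paired_frac: float = 0.6,
) -> DuplexRecord:
    """Locate the miRNA* arm for *mirna_span* and measure the duplex.

    Without an explicit *star_span* the star is placed canonically: the
    bases pairing the miRNA, with each strand's 3' end extended 2 nt past
    its partner's 5' end.  Overhangs are then measured from the geometry
    actually present, so a caller-supplied (e.g. sequenced) star with a
    shifted end yields a non-typical duplex.
    """
    a, b = mirna_span
    partner = fold.partner_map()
    paired = [i for i in range(a, b) if i in partner]
    if len(paired) < min_paired_frac * (b - a):
        raise ValueError("miRNA not on a stem: too few paired bases")
    a1, b1 = paired[0], paired[-1]
    jhi, jlo = partner[a1], partner[b1]
    if a <= jlo < b or a <= jhi < b:
        raise ValueError("miRNA not on a stem: pairs fall inside the miRNA span")
    # miRNA assumed on the 5' arm when jlo > b; otherwise mirror the logic
    n = len(fold.structure_string)
    if star_span is None:
        # Antiparallel pairing: the partner index decreases as the miRNA
        # index increases regardless of which arm the miRNA occupies, so the
        # canonical star span (2-nt 3' overhangs on both strands) is
        # [partner(b-3), partner(a) + 2] on either geometry.
        lo = jlo + (b1 - (b - 3))
        hi = jhi + 2 + (a1 - a)
        star_span = (max(0, lo), min(n, hi + 1))
    s0, s1 = star_span

    if jlo < b:
        # miRNA sits on the 3' arm: the geometry is the mirror image of the
        # downstream case, so measure with the roles swapped and swap the
        # overhangs back (duplex typing is symmetric under arm exchange).
        mirror = extract_duplex(fold, (s0, s1), (a, b), min_paired_frac=0.0)
        return DuplexRecord(
            mirna_span=(a, b), star_span=(s0, s1),
            mismatched_bases=mirror.mismatched_bases,
            largest_asymmetric_bulge=mirror.largest_asymmetric_bulge,
            overhang_mirna_3p=mirror.overhang_star_3p,
            overhang_star_3p=mirror.overhang_mirna_3p,
        )

    # star on the 3' arm: star 5' end is s0 (low index), star 3' end is s1-1
    star_paired = [k for k in range(s0, s1) if k in partner and a <= partner[k] < b]
    if not star_paired:
        raise ValueError("star span does not pair with the miRNA span")
    k0, k1 = star_paired[0], star_paired[-1]
    overhang_m = (b - 1) - partner[k0] - (k0 - s0)
    overhang_s = (s1 - 1) - k1 + (partner[k1] - a)

    # internal mismatches and bulges over consecutive paired miRNA positions
    mism = a1 - a + max(0, (b - 3) - b1)
    bulge = 0
    for x, y in zip(paired, paired[1:]):
        gm = y - x - 1
        gs = partner[x] - partner[y] - 1
        mism += min(gm, gs)
        bulge = max(bulge, abs(gm - gs))
    return DuplexRecord(
        mirna_span=(a, b), star_span=(s0, s1),
        mismatched_bases=mism, largest_asymmetric_bulge=bulge,
        overhang_mirna_3p=overhang_m, overhang_star_3p=overhang_s,
    )


# ---------------------------------------------------------------------------
# Structural criteria
# ---------------------------------------------------------------------------

@dataclass
class StructuralCriteria:
    """Thresholds for annotating a locus as a plausible plant miRNA precursor."""

    min_precursor_len: int = 70
    max_duplex_mismatches: int = 4
    max_asym_bulge_strict: int = 2
    max_asym_bulge_relaxed: int = 3
    max_mfei: float = -0.85
    max_antisense_srnas: int = 10


@dataclass(frozen=True)
class Verdict:
    status: str  # pass_strict | pass_relaxed | fail
    reasons: tuple[str, ...] = ()


def check_structural_criteria(
    hairpin: HairpinRecord, duplex: DuplexRecord, criteria: StructuralCriteria
) -> Verdict:
    """Evaluate a folded precursor against the annotation criteria.

    A locus passing every threshold with the strict bulge bound is
    ``pass_strict``; exceeding only the bulge bound, up to the relaxed
    3-base limit, is ``pass_relaxed``; anything else fails with every
    violated criterion listed.
    """
    reasons = []
    if hairpin.length < criteria.min_precursor_len:
        reasons.append(f"precursor too short ({hairpin.length} < {criteria.min_precursor_len} nt)")
    if duplex.mismatched_bases > criteria.max_duplex_mismatches:
        reasons.append(f"too many duplex mismatches ({duplex.mismatched_bases})")
    if hairpin.mfei > criteria.max_mfei:
        reasons.append(f"mfei too high ({hairpin.mfei:.4f} > {criteria.max_mfei})")
    bulge_strict_ok = duplex.largest_asymmetric_bulge <= criteria.max_asym_bulge_strict
    bulge_relaxed_ok = duplex.largest_asymmetric_bulge <= criteria.max_asym_bulge_relaxed
    if not bulge_relaxed_ok:
        reasons.append(f"asymmetric bulge too large ({duplex.largest_asymmetric_bulge})")
    if reasons:
        return Verdict("fail", tuple(reasons))
    return Verdict("pass_strict" if bulge_strict_ok else "pass_relaxed")


# ---------------------------------------------------------------------------
# miRNA* search in the sequenced reads
# ---------------------------------------------------------------------------

def duplex_consistent(mirna: str, candidate: str, max_mm: int = 4, max_offset: int = 4) -> int | None:
    """Best mismatch count if *candidate* can be the miRNA* of *mirna*.

    Tries antiparallel pairings with end offsets within +/- *max_offset* nt;
    a position pairs if Watson-Crick or G:U.  Returns the minimal number of
    non-pairing positions (None when no offset satisfies ``<= max_mm``).
    """
    lm, lc = len(mirna), len(candidate)
    best: int | None = None
    for shift in range(-max_offset, max_offset + 1):
        mm = 0
        overlap = 0
        for i in range(lm):
            k = lc - 1 - i - shift
            if 0 <= k < lc:
                overlap += 1
                if not pair_ok(mirna[i], candidate[k]):
                    mm += 1
        if overlap < max(lm, lc) - max_offset:
            continue
        if mm <= max_mm and (best is None or mm < best):
            best = mm
    return best


def sequence_near_identical(a: str, b: str, max_mm: int = 2, max_offset: int = 4,
                            min_overlap: int = 15) -> int | None:
    """Minimal substitution count between *a* and *b* allowing shifted ends.

    Both ends may be offset by up to *max_offset* nt (length/positional
    polymorphism of cloned sRNAs); positions outside the overlap do not
    count.  The overlap must cover the shorter sequence to within the
    offset and never drop below *min_overlap* (identity over fewer bases
    stops being informative).  None when no shift satisfies ``<= max_mm``.
    """
    la, lb = len(a), len(b)
    floor = max(min(la, lb) - max_offset, min_overlap)
    best: int | None = None
    for shift in range(-max_offset, max_offset + 1):
        overlap = 0
        mm = 0
        for i in range(la):
            k = i + shift
            if 0 <= k < lb:
                overlap += 1
                if a[i] != b[k]:
                    mm += 1
        if overlap < floor:
            continue
        if mm <= max_mm and (best is None or mm < best):
            best = mm
    return best


def find_star_in_reads(mirna, pool, max_mm: int = 4, max_offset: int = 4,
                       predicted_star: str | None = None):
    """Pool members that could be the sequenced miRNA* of *mirna*.

    *mirna* and pool entries are :class:`~srnaome.core.UniqueSRNA`.  With
    *predicted_star* (the star-arm sequence read off a precursor fold) the
    search is a near-identity match against that sequence — the most
    specific test, since a cloned star is a genomic subsequence.  Without
    fold context, candidates are screened for duplex consistency with the
    miRNA (reverse-complement alignment with shifted ends).  Hits are
    ranked by mismatch count, then abundance (descending), then sequence.
    """
    hits = []
    for cand in pool:
        if cand.sequence == mirna.sequence:
            continue
        if predicted_star is not None:
            mm = sequence_near_identical(cand.sequence, predicted_star,
                                         max_mm=2, max_offset=max_offset)
        else:
            mm = duplex_consistent(mirna.sequence, cand.sequence, max_mm, max_offset)
        if mm is not None:
            hits.append((mm, -cand.total, cand.sequence, cand))
    hits.sort(key=lambda h: h[:3])
    return [(h[3], h[0]) for h in hits]
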