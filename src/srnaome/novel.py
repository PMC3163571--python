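"""Novel miRNA discovery from genome-mapped unclassified sRNAs.

The pipeline mirrors how species-specific plant miRNAs are called from a
sequenced sRNA set and a genome:

1. keep unclassified sRNAs of 21/22/24 nt with 1-6 exact genome hits;
2. scan 600 nt of flanking sequence on each side of every placement for a
   near-reverse-complement (miRNA*) site with the complementarity scorer;
3. the smallest region covering the sRNA and its star site is the
   candidate precursor (>= 70 nt);
4. exclude loci matching transposon/coding sets, loci with the
   foldback-transposon signature (many distinct sRNAs mapping antisense),
   and sRNAs that are merely the star strand of a known miRNA;
5. fold the precursor, evaluate the structural criteria, and call the
   locus a confirmed miRNA when the star strand itself was sequenced,
   otherwise a candidate miRNA.  Output is sorted by MFEI ascending (the
   more negative, the better the precursor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import SeqRecord, UniqueSRNA, reverse_complement
from .hairpin import (
    DuplexRecord,
    HairpinRecord,
    StructuralCriteria,
    check_structural_criteria,
    compute_mfei,
    duplex_consistent,
    extract_duplex,
    find_star_in_reads,
    fold_stemloop,
)
from .targets import ScoringParams, score_sites

Placement = tuple[str, int, int, str]  # contig, start, end (half-open), strand


class GenomeIndex:
    """Exact-match lookup of short sequences on both strands of a genome."""

    def __init__(self, contigs: list[SeqRecord]):
        self.contigs = list(contigs)
        self._by_id = {c.id: c for c in self.contigs}

    def contig(self, contig_id: str) -> SeqRecord:
        return self._by_id[contig_id]

    def placements(self, query: str) -> list[Placement]:
        """All exact full-length placements of *query*, both strands.

        Overlapping placements (e.g. the two copies inside an inverted
        repeat) count separately.
        """
        out: list[Placement] = []
        rc = reverse_complement(query)
        L = len(query)
        for contig in self.contigs:
            seq = contig.sequence
            for strand, q in (("+", query), ("-", rc)):
                start = seq.find(q)
                while start != -1:
                    out.append((contig.id, start, start + L, strand))
                    start = seq.find(q, start + 1)
        out.sort()
        return out


def count_genome_hits(srna: UniqueSRNA, index: GenomeIndex) -> int:
    return len(index.placements(srna.sequence))


@dataclass
class NovelConfig:
    allowed_lengths: frozenset[int] = frozenset({21, 22, 24})
    max_genome_hits: int = 6
    flank_window: int = 600
    criteria: StructuralCriteria = field(default_factory=StructuralCriteria)
    #: absolute alignment-score threshold for the flanking miRNA* scan;
    #: None derives it from the sRNA length as match*L - star_scan_slack
    complementarity_min_score: float | None = None
    #: score slack below a perfect unscaled complement still accepted as a
    #: star site (20 admits ~2 mismatches plus a wobble)
    star_scan_slack: float = 20.0
    #: shared exact k-mer length that flags similarity to a long exclusion element
    exclusion_kmer: int = 20
    #: exclusion-set members up to this length are scanned sRNA-style (<=2 mm)
    short_element_len: int = 35
    #: flanking sequence (each side of the precursor) included when counting
    #: antisense-mapping sRNAs for the foldback signature
    antisense_flank: int = 150
    max_duplex_mismatches: int = 4
    #: duplex-consistency bounds for the "star of a known miRNA" exclusion
    known_star_max_mm: int = 3
    known_star_max_offset: int = 2


@dataclass
class CandidateLocus:
    srna: UniqueSRNA
    placement: Placement
    status: str = "pending"  # confirmed_mirna | candidate_mirna | rejected
    reject_reason: str | None = None
    star_site: tuple[int, int] | None = None        # genome coords on the contig
    precursor_interval: tuple[int, int] | None = None
    precursor: HairpinRecord | None = None
    duplex: DuplexRecord | None = None
    star_scan_score: float | None = None
    star_read_support: bool = False
    star_reads: list = field(default_factory=list)
    window_truncated: bool = False
    # precursor-frame bookkeeping (sRNA-sense orientation)
    frame_seq: str = ""
    frame_mirna_span: tuple[int, int] | None = None
    frame_star_span: tuple[int, int] | None = None

    def reject(self, reason: str) -> "CandidateLocus":
        self.status = "rejected"
        self.reject_reason = reason
        return self


def select_novel_candidates(
    unclassified: list[UniqueSRNA], index: GenomeIndex, cfg: NovelConfig
) -> list[tuple[UniqueSRNA, list[Placement]]]:
    """Length and genome-hit filters over cascade-unmatched sRNAs."""
    out = []
    for srna in unclassified:
        if srna.length not in cfg.allowed_lengths:
            continue
        placements = index.placements(srna.sequence)
        if 1 <= len(placements) <= cfg.max_genome_hits:
            out.append((srna, placements))
    return out


def _frame_window(index: GenomeIndex, placement: Placement, window: int):
    """Extract the flank window around a placement in sRNA-sense orientation.

    Returns (frame_seq, mirna_span_in_frame, to_genome) where *to_genome*
    maps a frame interval back to contig coordinates, plus a truncation flag.
    """
    contig_id, start, end, strand = placement
    seq = index.contig(contig_id).sequence
    lo = max(0, start - window)
    hi = min(len(seq), end + window)
    truncated = lo > start - window or hi < end + window
    win = seq[lo:hi]
    if strand == "+":
        frame = win
        span = (start - lo, end - lo)

        def to_genome(iv: tuple[int, int]) -> tuple[int, int]:
            return (lo + iv[0], lo + iv[1])
    else:
        frame = reverse_complement(win)
        span = (hi - end, hi - start)

        def to_genome(iv: tuple[int, int]) -> tuple[int, int]:
            return (hi - iv[1], hi - iv[0])
    return frame, span, to_genome, truncated


def scan_flanks_for_star(
    frame_seq: str,
    mirna_span: tuple[int, int],
    srna: UniqueSRNA,
    cfg: NovelConfig,
) -> tuple[tuple[int, int], float] | None:
    """Best complementarity hit of the sRNA in its flanking window.

    The star of a genuine miRNA is a near-reverse-complement on the same
    precursor strand, which is exactly a target-like site for the sRNA, so
    the search reuses the target-prediction aligner — but without the 5'
    seed scaling (a star must pair along its whole length, not just the
    seed) and with a length-relative threshold.  Sites overlapping the
    sRNA's own placement are self-hits and ignored.
    """
    params = ScoringParams(scale_factor=1.0)
    min_score = cfg.complementarity_min_score
    if min_score is None:
        min_score = params.match * srna.length - cfg.star_scan_slack
    params.min_site_score = min_score
    params.candidate_floor = min_score
    mirna_rec = SeqRecord("query", srna.sequence)
    window_rec = SeqRecord("window", frame_seq)
    hits = score_sites(mirna_rec, window_rec, params)
    a, b = mirna_span
    for hit in hits:
        s0, s1 = hit.site
        if s0 < b and a < s1:  # self-overlap
            continue
        if hit.score >= min_score:
            return hit.site, hit.score
    return None


def build_precursor(
    mirna_span: tuple[int, int],
    star_site: tuple[int, int],
    min_precursor_len: int,
) -> tuple[int, int] | None:
    """Smallest interval covering the sRNA and its star site.

    Orientation is normalized (the star may lie upstream of the miRNA);
    intervals shorter than the minimum precursor length are discarded.
    """
    lo = min(mirna_span[0], star_site[0])
    hi = max(mirna_span[1], star_site[1])
    if hi - lo < min_precursor_len:
        return None
    return (lo, hi)


def apply_exclusions(
    locus: CandidateLocus,
    cfg: NovelConfig,
    all_srnas: list[UniqueSRNA],
    exclusion_sets: dict[str, list[SeqRecord]] | None = None,
    known_mirnas: list[SeqRecord] | None = None,
) -> CandidateLocus:
    """Reject transposon-like, foldback-like and known-star loci.

    (a) similarity of the precursor region to any exclusion set member:
    short elements by a full-length <=2-mismatch scan, long elements by a
    shared exact k-mer; (b) >= max_antisense_srnas distinct sRNAs mapping
    antisense to the precursor (the foldback-transposon signature); (c) the
    sRNA being duplex-consistent with a known miRNA (it is that miRNA's
    star, not a novel gene).
    """
    assert locus.precursor_interval is not None
    region = locus.frame_seq  # precursor plus its scanned flanks
    if exclusion_sets:
        for name, records in exclusion_sets.items():
            for rec in records:
                if _similar(region, rec.sequence, cfg):
                    return locus.reject(f"matches exclusion set {name} ({rec.id})")
    # foldback signature: distinct sRNAs mapping antisense to the precursor
    # (plus short flanks, so reads straddling the precursor edge count too)
    lo = min(locus.frame_mirna_span[0], locus.frame_star_span[0])
    hi = max(locus.frame_mirna_span[1], locus.frame_star_span[1])
    prec = region[max(0, lo - cfg.antisense_flank) : hi + cfg.antisense_flank]
    antisense = {
        s.sequence for s in all_srnas if reverse_complement(s.sequence) in prec
    }
    if len(antisense) >= cfg.criteria.max_antisense_srnas:
        return locus.reject(
            f"foldback-like: {len(antisense)} distinct antisense sRNAs on the precursor"
        )
    if known_mirnas:
        for rec in known_mirnas:
            mm = duplex_consistent(rec.sequence, locus.srna.sequence,
                                   cfg.known_star_max_mm, cfg.known_star_max_offset)
            if mm is not None:
                return locus.reject(f"star of known miRNA {rec.id}")
    return locus


def _similar(region: str, element: str, cfg: NovelConfig) -> bool:
    if len(element) <= cfg.short_element_len:
        return bool(_mismatch_scan(region, element, 2))
    k = cfg.exclusion_kmer
    kmers = {element[i : i + k] for i in range(len(element) - k + 1)}
    rc = reverse_complement(element)
    kmers |= {rc[i : i + k] for i in range(len(rc) - k + 1)}
    return any(region[i : i + k] in kmers for i in range(len(region) - k + 1))


def _mismatch_scan(text: str, query: str, max_mm: int) -> bool:
    L = len(query)
    for q in (query, reverse_complement(query)):
        for start in range(len(text) - L + 1):
            mm = 0
            for a, b in zip(q, text[start : start + L]):
                if a != b:
                    mm += 1
                    if mm > max_mm:
                        break
            if mm <= max_mm:
                return True
    return False


def evaluate_locus(
    srna: UniqueSRNA,
    placement: Placement,
    index: GenomeIndex,
    cfg: NovelConfig,
    all_srnas: list[UniqueSRNA],
    exclusion_sets: dict[str, list[SeqRecord]] | None = None,
    known_mirnas: list[SeqRecord] | None = None,
    read_pool: list[UniqueSRNA] | None = None,
) -> CandidateLocus:
    """Run one placement through star scan, precursor build, exclusions,
    folding and structural evaluation."""
    locus = CandidateLocus(srna=srna, placement=placement)
    frame, span, to_genome, truncated = _frame_window(index, placement, cfg.flank_window)
    locus.frame_seq = frame
    locus.frame_mirna_span = span
    locus.window_truncated = truncated

    star = scan_flanks_for_star(frame, span, srna, cfg)
    if star is None:
        return locus.reject("no miRNA* site in the flanking window")
    star_span, score = star
    locus.frame_star_span = star_span
    locus.star_site = to_genome(star_span)
    locus.star_scan_score = score

    prec_iv = build_precursor(span, star_span, cfg.criteria.min_precursor_len)
    if prec_iv is None:
        return locus.reject(
            f"precursor too short (< {cfg.criteria.min_precursor_len} nt)"
        )
    locus.precursor_interval = to_genome(prec_iv)

    locus = apply_exclusions(locus, cfg, all_srnas, exclusion_sets, known_mirnas)
    if locus.status == "rejected":
        return locus

    prec_seq = frame[prec_iv[0] : prec_iv[1]]
    fold = fold_stemloop(prec_seq)
    try:
        hp = compute_mfei(prec_seq, fold.mfe)
    except ValueError:
        return locus.reject("mfei undefined (zero GC precursor)")
    locus.precursor = hp
    mirna_in_prec = (span[0] - prec_iv[0], span[1] - prec_iv[0])
    try:
        duplex = extract_duplex(fold, mirna_in_prec)
    except ValueError as exc:
        return locus.reject(str(exc))
    locus.duplex = duplex

    verdict = check_structural_criteria(hp, duplex, cfg.criteria)
    if verdict.status == "fail":
        return locus.reject("; ".join(verdict.reasons))

    pool = read_pool if read_pool is not None else all_srnas
    s0, s1 = duplex.star_span
    predicted_star = prec_seq[s0:s1]
    stars = find_star_in_reads(srna, pool, cfg.max_duplex_mismatches,
                               predicted_star=predicted_star)
    locus.star_reads = stars
    locus.star_read_support = bool(stars)
    locus.status = "confirmed_mirna" if stars else "candidate_mirna"
    return locus


def call_candidates(
    unclassified: list[UniqueSRNA],
    index: GenomeIndex,
    cfg: NovelConfig | None = None,
    all_srnas: list[UniqueSRNA] | None = None,
    exclusion_sets: dict[str, list[SeqRecord]] | None = None,
    known_mirnas: list[SeqRecord] | None = None,
) -> list[CandidateLocus]:
    """End-to-end novel-miRNA calling over an unclassified sRNA set.

    Each placement of a selected sRNA is evaluated independently; the sRNA
    is reported once, with its best locus (passing status first, then most
    negative MFEI).  Output is sorted by MFEI ascending, rejected loci last.
    """
    cfg = cfg or NovelConfig()
    all_srnas = all_srnas if all_srnas is not None else unclassified
    results: list[CandidateLocus] = []
    for srna, placements in select_novel_candidates(unclassified, index, cfg):
        loci = [
            evaluate_locus(srna, pl, index, cfg, all_srnas, exclusion_sets, known_mirnas)
            for pl in placements
        ]
        results.append(min(loci, key=_locus_rank))
    _merge_opposite_arms(results)
    results.sort(key=_locus_rank)
    return results


def _merge_opposite_arms(results: list[CandidateLocus]) -> None:
    """One precursor, one call: when a sequenced miRNA* passes on its own,
    it rediscovers the locus from the other arm.  The more abundant arm is
    kept as the mature miRNA; the other is folded into it."""
    passing = [l for l in results if l.status in ("confirmed_mirna", "candidate_mirna")]
    passing.sort(key=lambda l: (-l.srna.total, l.srna.sequence))
    kept: list[CandidateLocus] = []
    for locus in passing:
        dup = None
        for other in kept:
            if other.placement[0] != locus.placement[0]:
                continue
            a = locus.precursor_interval
            b = other.precursor_interval
            if a and b and a[0] < b[1] and b[0] < a[1]:
                dup = other
                break
        if dup is None:
            kept.append(locus)
        else:
            locus.reject(
                f"opposite arm of an already-called precursor (miRNA* of {dup.srna.sequence})"
            )


_STATUS_ORDER = {"confirmed_mirna": 0, "candidate_mirna": 1, "rejected": 2}


def _locus_rank(locus: CandidateLocus):
    mfei = locus.precursor.mfei if locus.precursor is not None else 0.0
    return (_STATUS_ORDER.get(locus.status, 3), mfei, locus.srna.sequence)
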