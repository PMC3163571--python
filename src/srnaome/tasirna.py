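"""Phased 21-nt siRNA (ta-siRNA) detection.

TAS transcripts are cleaved by a guide miRNA between the target bases
pairing miRNA positions 10 and 11, then processed into 21-nt siRNAs in
register with the cleavage site.  Detection assigns each mapped read a
phase register (its 5'-end offset modulo the 21-nt period, with a 2-nt
shift for antisense reads to absorb the DCL duplex overhang and a +/-1 nt
jitter tolerance), and calls a register occupied when its read support is
both absolute (enough reads over enough distinct cycles) and statistically
enriched over a uniform-start background (binomial tail), so dense but
unphased read clouds do not trigger spurious registers.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from scipy.stats import binom

from .annotate import mirna_family
from .core import SeqRecord, UniqueSRNA, reverse_complement
from .targets import TargetHit, TranscriptReport


@dataclass
class PhasingConfig:
    period: int = 21
    antisense_offset: int = 2
    jitter: int = 1
    min_reads_per_register: int = 3
    min_cycles: int = 3
    window: int = 600
    #: binomial-tail significance for register occupancy (per register)
    alpha: float = 1e-3
    #: minimum distinct sRNAs recruited by a dual-site inter-site region
    min_recruited_srnas: int = 3
    max_map_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.period < 1 or self.jitter >= self.period / 2:
            raise ValueError("invalid period/jitter")


#: a mapped read: (five_prime_pos, strand '+'/'-', length, read_count)
MappedRead = tuple[int, str, int, int]


@dataclass
class PhasingResult:
    locus_id: str
    register_counts: list[int]
    occupied_registers: list[int]
    in_phase_fraction: float
    sense_count: int
    antisense_count: int
    len21_fraction: float
    miRNA_anchored: bool = False  # register 0 (cleavage-anchored) occupied
    truncated: bool = False


class CleavageAmbiguous(ValueError):
    """Raised when a bulge at miRNA positions 10/11 prevents cleavage inference."""


def infer_cleavage(hit: TargetHit) -> int:
    """Transcript coordinate of the slicing site of a target hit.

    Returns the 0-based boundary index between the transcript bases pairing
    miRNA positions 11 and 10 (the cut lies immediately 5' of the base
    pairing position 10).  Mismatches at 10/11 are tolerated; bulges are
    not, because they make the pairing geometry ambiguous.
    """
    coords: dict[int, int | None] = {}
    bulge_between = False
    for idx, (mp, tp, state) in enumerate(hit.pairing):
        if mp in (10, 11):
            coords[mp] = tp
            if state == "bulge_m":
                raise CleavageAmbiguous("miRNA base 10/11 is bulged")
        if state == "bulge_t" and idx > 0:
            prev_mp = next(
                (m for m, _t, _s in reversed(hit.pairing[:idx]) if m is not None), None
            )
            if prev_mp == 11:
                bulge_between = True
    if coords.get(10) is None or coords.get(11) is None:
        raise CleavageAmbiguous("pairing does not cover miRNA positions 10-11")
    if bulge_between or coords[10] - coords[11] != 1:
        raise CleavageAmbiguous("bulge between the bases pairing positions 10 and 11")
    return coords[10]


def assign_phase(read_start: int, strand: str, cleavage: int, cfg: PhasingConfig) -> int:
    """Raw phase register (0..period-1) of a read 5' end.

    Sense reads are phased directly against the cleavage site; antisense
    5' ends are shifted by the 2-nt duplex overhang before taking the
    residue.  Jitter is resolved at register-detection time, so shifting a
    read by any whole number of periods never changes its register.
    """
    p = cfg.period
    if strand == "+":
        return (read_start - cleavage) % p
    return (read_start + cfg.antisense_offset - cleavage) % p


def map_srnas_to_sequence(
    seq: str, srnas: list[UniqueSRNA], max_mm: int = 0
) -> list[MappedRead]:
    """Place sRNAs on a sequence (both strands), 5'-end coordinates.

    Exact placement by substring search when ``max_mm == 0``; otherwise a
    full sliding mismatch scan.
    """
    reads: list[MappedRead] = []
    for s in srnas:
        for strand, query in (("+", s.sequence), ("-", reverse_complement(s.sequence))):
            for pos in _occurrences(seq, query, max_mm):
                five_p = pos if strand == "+" else pos + len(query) - 1
                reads.append((five_p, strand, s.length, s.total))
    return reads


def _occurrences(text: str, query: str, max_mm: int) -> list[int]:
    if max_mm == 0:
        out = []
        start = text.find(query)
        while start != -1:
            out.append(start)
            start = text.find(query, start + 1)
        return out
    L = len(query)
    out = []
    for start in range(len(text) - L + 1):
        mm = 0
        for a, b in zip(query, text[start : start + L]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            out.append(start)
    return out


def detect_registers(
    reads: list[MappedRead],
    cleavage: int,
    cfg: PhasingConfig | None = None,
    locus_id: str = "locus",
    truncated: bool = False,
) -> PhasingResult:
    """Call occupied phase registers among mapped reads.

    A register is occupied when (a) at least ``min_reads_per_register``
    reads fall within the jitter window of the register, (b) those reads
    span at least ``min_cycles`` distinct 21-nt cycles, and (c) the support
    is larger than a uniform-start background would plausibly produce
    (binomial tail below ``alpha`` with success probability
    ``(2*jitter+1)/period``).  Adjacent registers are suppressed so one
    phased population yields one register.
    """
    cfg = cfg or PhasingConfig()
    p = cfg.period
    if not reads:
        raise ValueError("detect_registers requires at least one read")
    residues: list[tuple[int, int, int, str]] = []  # (residue, cycle, count, strand)
    total = 0
    len21 = 0
    sense = anti = 0
    for pos, strand, length, count in reads:
        r = assign_phase(pos, strand, cleavage, cfg)
        cycle = (pos - cleavage) // p
        residues.append((r, cycle, count, strand))
        total += count
        if length == 21:
            len21 += count
        if strand == "+":
            sense += count
        else:
            anti += count

    window = 2 * cfg.jitter + 1
    p_bg = window / p
    raw = [0] * p
    support = [0] * p
    for r, _cyc, count, _strand in residues:
        raw[r] += count
        for d in range(-cfg.jitter, cfg.jitter + 1):
            support[(r + d) % p] += count

    def dist(a: int, b: int) -> int:
        return min((a - b) % p, (b - a) % p)

    # Claim-and-remove peak picking: registers are visited in order of
    # exact-residue read count (windowed support breaks ties), each claiming
    # its jitter window of still-unclaimed reads.  This keeps a register
    # from being displaced by its own jitter shoulder or by nearby noise,
    # and prevents one phased population from occupying two registers.
    order = sorted((r for r in range(p) if raw[r] > 0),
                   key=lambda r: (-raw[r], -support[r], r))
    claimed = [False] * len(residues)
    occupied: list[int] = []
    for r in order:
        idxs = [i for i, (res, _c, _n, _s) in enumerate(residues)
                if not claimed[i] and dist(res, r) <= cfg.jitter]
        count_r = sum(residues[i][2] for i in idxs)
        cycles_r = {residues[i][1] for i in idxs}
        if (
            count_r >= cfg.min_reads_per_register
            and len(cycles_r) >= cfg.min_cycles
            and binom.sf(count_r - 1, total, p_bg) < cfg.alpha
        ):
            occupied.append(r)
            for i in idxs:
                claimed[i] = True
    occupied.sort()

    register_counts = [0] * p
    in_phase = 0
    for r, _cyc, count, _strand in residues:
        target = r
        for o in occupied:
            if min((r - o) % p, (o - r) % p) <= cfg.jitter:
                target = o
                in_phase += count
                break
        register_counts[target] += count

    return PhasingResult(
        locus_id=locus_id,
        register_counts=register_counts,
        occupied_registers=occupied,
        in_phase_fraction=in_phase / total if total else 0.0,
        sense_count=sense,
        antisense_count=anti,
        len21_fraction=len21 / total if total else 0.0,
        miRNA_anchored=0 in occupied,
        truncated=truncated,
    )


@dataclass
class TASCandidate:
    transcript_id: str
    sites: list[TargetHit]
    clean_9_11: tuple[bool, bool]
    recruited_srnas: int
    phasing: list[PhasingResult] = field(default_factory=list)


def find_dual_site_tas(
    reports: list[TranscriptReport],
    transcripts: dict[str, SeqRecord],
    srnas: list[UniqueSRNA],
    cfg: PhasingConfig | None = None,
) -> list[TASCandidate]:
    """Evaluate dual-site transcripts as ta-siRNA (TAS) producing loci.

    A dual-site transcript qualifies when the region between its two miRNA
    sites recruits mapped sRNAs; phase registers are then detected from
    each site's inferred cleavage.  Both sites' 9-11 pairing cleanliness is
    reported, since cleavage at both ends is what defines the phased
    interval.
    """
    cfg = cfg or PhasingConfig()
    out: list[TASCandidate] = []
    for rep in reports:
        if not rep.dual_site or rep.orientation != "forward":
            continue
        fam_hits = [h for h in rep.hits if mirna_family(h.mirna_id) == rep.dual_family]
        fam_hits.sort(key=lambda h: h.site)
        if len(fam_hits) < 2:
            continue
        left, right = fam_hits[0], fam_hits[-1]
        tx = transcripts[rep.transcript_id]
        inter = tx.sequence[left.site[1] : right.site[0]]
        mapped_inter = map_srnas_to_sequence(inter, srnas, cfg.max_map_mismatches)
        distinct = len({(pos, strand) for pos, strand, _l, _c in mapped_inter})
        if distinct < cfg.min_recruited_srnas:
            continue
        mapped_tx = map_srnas_to_sequence(tx.sequence, srnas, cfg.max_map_mismatches)
        phasings = []
        for site in (left, right):
            try:
                cleavage = infer_cleavage(site)
            except CleavageAmbiguous:
                continue
            if mapped_tx:
                phasings.append(
                    detect_registers(mapped_tx, cleavage, cfg, locus_id=rep.transcript_id)
                )
        out.append(
            TASCandidate(
                transcript_id=rep.transcript_id,
                sites=[left, right],
                clean_9_11=(left.clean_9_11, right.clean_9_11),
                recruited_srnas=distinct,
                phasing=phasings,
            )
        )
    return out


def scan_genomic_phasing(
    genome: SeqRecord,
    anchor: int,
    srnas: list[UniqueSRNA],
    cfg: PhasingConfig | None = None,
    locus_id: str | None = None,
) -> PhasingResult:
    """Phasing analysis of a +/- window genomic region around *anchor*.

    Without a known cleavage site, registers are reported relative to the
    anchor position; trying every phase offset is equivalent to reading off
    which residues are occupied.  Windows truncated at a contig edge are
    flagged and analysed with the available sequence.
    """
    cfg = cfg or PhasingConfig()
    lo = anchor - cfg.window
    hi = anchor + cfg.window
    truncated = lo < 0 or hi > len(genome.sequence)
    lo = max(0, lo)
    hi = min(len(genome.sequence), hi)
    region = genome.sequence[lo:hi]
    mapped = [
        (pos + lo, strand, length, count)
        for pos, strand, length, count in map_srnas_to_sequence(region, srnas, 0)
    ]
    if not mapped:
        return PhasingResult(
            locus_id or genome.id, [0] * cfg.period, [], 0.0, 0, 0, 0.0, truncated=truncated
        )
    return detect_registers(
        mapped, anchor, cfg, locus_id=locus_id or genome.id, truncated=truncated
    )
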