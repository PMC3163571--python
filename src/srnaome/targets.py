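"""miRNA target prediction with two independent scorers.

Plant miRNA targets are near-perfect complementary sites on transcripts.
Two complementarity scorers are run side by side:

* an alignment score S (higher is better): +5 per Watson-Crick match,
  +2 per G:U wobble, -3 per mismatch, affine bulge penalties (-9 open,
  -4 extend), with columns in the miRNA 5' seed multiplied by a scaling
  factor.  With the defaults a perfect 21-nt site scores 195 and a perfect
  22-nt site scores 200; the operative reporting cutoff is S >= 170.
* a position-weighted penalty P (lower is better): 1 per mismatch, 0.5 per
  G:U, 1 per bulged base, doubled at miRNA positions 2-13; a perfect site
  scores 0 and sites up to P = 4 are reported.

A site is reported when either scorer accepts it; both values are always
printed so the two columns can be compared.  Position numbering is 1-based
from the miRNA 5' end (the convention behind "no mismatches at
nucleotides 9-11").
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .annotate import mirna_family
from .core import SeqRecord, reverse_complement

NEG = -1e9
_MAX_BULGE = 3  # longest bulge considered per gap event


@dataclass
class ScoringParams:
    """Alignment-score (miRanda-style) parameters."""

    match: float = 5.0
    gu_wobble: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 9.0    # cost of a 1-nt bulge
    gap_extend: float = 4.0  # cost per additional bulged base
    scale_region: tuple[int, int] = (2, 7)  # miRNA positions, 1-based inclusive
    scale_factor: float = 4.0
    min_site_score: float = 170.0
    #: sites down to this floor are aligned so the penalty scorer can rescue them
    candidate_floor: float = 110.0

    def gap_cost(self, g: int) -> float:
        return self.gap_open + self.gap_extend * (g - 1)


@dataclass
class PenaltyParams:
    """Position-weighted penalty (plant-rubric) parameters."""

    mismatch_pen: float = 1.0
    gu_pen: float = 0.5
    bulge_pen: float = 1.0
    doubled_region: tuple[int, int] = (2, 13)  # miRNA positions, 1-based
    max_penalty: float = 4.0


#: one aligned column: (mirna_pos 1-based or None, target_pos or None, state)
PairState = tuple[int | None, int | None, str]


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    orientation: str  # forward | reverse_complement
    site: tuple[int, int]  # transcript interval, 0-based half-open
    score: float
    penalty: float
    pairing: list[PairState] = field(repr=False, default_factory=list)
    passes_score: bool = False
    passes_penalty: bool = False

    @property
    def clean_9_11(self) -> bool:
        states = {p: s for p, _t, s in self.pairing if p is not None}
        return all(states.get(p) == "match" for p in (9, 10, 11))

    @property
    def midpoint(self) -> float:
        return (self.site[0] + self.site[1]) / 2.0


def _code(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for k, base in enumerate(b"ACGT"):
        out[arr == base] = k
    return out


def _column_scores(q: str, target_codes: np.ndarray, params: ScoringParams) -> np.ndarray:
    """(L, N) per-column scores of RC(miRNA) characters vs target bases."""
    L = len(q)
    N = len(target_codes)
    lo, hi = params.scale_region
    cols = np.empty((L, N))
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for j, ch in enumerate(q):
        mirna_pos = L - j  # 1-based position from the miRNA 5' end
        w = params.scale_factor if lo <= mirna_pos <= hi else 1.0
        s = np.full(N, params.mismatch)
        qi = base_idx.get(ch)
        if qi is not None:
            s[target_codes == qi] = params.match
        # G:U wobble in RC space: (C vs T) and (A vs G)
        if ch == "C":
            s[target_codes == 3] = params.gu_wobble
        elif ch == "A":
            s[target_codes == 2] = params.gu_wobble
        cols[j] = s * w
    return cols


def _align(mirna_seq: str, transcript_seq: str, params: ScoringParams):
    """Global-in-miRNA, local-in-transcript DP with short affine bulges.

    Returns (final_row, rows, pointers) where pointers[j, i] encodes the
    move that produced best[j, i]: 0 diagonal, 1..3 bulged transcript bases,
    4..6 bulged miRNA bases, 7 local start.
    """
    q = reverse_complement(mirna_seq)
    L = len(q)
    t_codes = _code(transcript_seq)
    N = len(t_codes)
    cols = _column_scores(q, t_codes, params)
    rows = np.full((L, N), NEG)
    ptr = np.full((L, N), 7, dtype=np.int8)

    def shifted(arr: np.ndarray, k: int) -> np.ndarray:
        out = np.full(N, NEG)
        if k < N:
            out[k:] = arr[: N - k]
        return out

    rows[0] = cols[0]
    for j in range(1, L):
        best = shifted(rows[j - 1], 1)
        code = np.zeros(N, dtype=np.int8)
        for g in range(1, _MAX_BULGE + 1):
            cand = shifted(rows[j - 1], 1 + g) - params.gap_cost(g)
            mask = cand > best
            best[mask] = cand[mask]
            code[mask] = g
        for g in range(1, _MAX_BULGE + 1):
            if j - 1 - g < 0:
                break
            cand = shifted(rows[j - 1 - g], 1) - params.gap_cost(g)
            mask = cand > best
            best[mask] = cand[mask]
            code[mask] = 3 + g
        rows[j] = cols[j] + best
        ptr[j] = code
    return rows, ptr, q


def _traceback(rows, ptr, q, end_i: int, params: ScoringParams) -> tuple[int, list[PairState]]:
    """Recover the aligned columns ending at target index *end_i*."""
    L = rows.shape[0]
    j, i = L - 1, end_i
    events: list[PairState] = []
    while True:
        # state of the (j, i) column itself
        mirna_pos = L - j
        events.append((mirna_pos, i, "col"))
        if j == 0:
            break
        move = int(ptr[j, i])
        if move == 0:
            j, i = j - 1, i - 1
        elif 1 <= move <= _MAX_BULGE:  # bulged transcript bases
            for g in range(move):
                events.append((None, i - 1 - g, "bulge_t"))
            j, i = j - 1, i - 1 - move
        else:  # bulged miRNA bases
            g = move - 3
            for k in range(g):
                events.append((L - (j - 1 - k), None, "bulge_m"))
            j, i = j - 1 - g, i - 1
    events.reverse()
    start_i = events[0][1]
    return start_i, events


def _classify_columns(events: list[PairState], mirna_seq: str, transcript_seq: str) -> list[PairState]:
    """Replace placeholder 'col' states with match / GU / mismatch."""
    L = len(mirna_seq)
    rc = reverse_complement(mirna_seq)
    out: list[PairState] = []
    for mp, tp, state in events:
        if state != "col":
            out.append((mp, tp, state))
            continue
        qc = rc[L - mp]  # RC index for miRNA position mp
        tc = transcript_seq[tp]
        if qc == tc:
            out.append((mp, tp, "match"))
        elif (qc, tc) in (("C", "T"), ("A", "G")):
            out.append((mp, tp, "GU"))
        else:
            out.append((mp, tp, "mismatch"))
    return out


def penalty_score(pairing: list[PairState], params: PenaltyParams | None = None) -> float:
    """Position-weighted penalty P of an aligned site (0 = perfect)."""
    params = params or PenaltyParams()
    lo, hi = params.doubled_region
    total = 0.0
    last_pos = 1
    for mp, _tp, state in pairing:
        pos = mp if mp is not None else last_pos
        if mp is not None:
            last_pos = mp
        weight = 2.0 if lo <= pos <= hi else 1.0
        if state == "mismatch":
            total += params.mismatch_pen * weight
        elif state == "GU":
            total += params.gu_pen * weight
        elif state in ("bulge_m", "bulge_t"):
            total += params.bulge_pen * weight
    return total


def score_sites(
    mirna: SeqRecord,
    transcript: SeqRecord,
    params: ScoringParams | None = None,
    penalty_params: PenaltyParams | None = None,
    orientation: str = "forward",
    min_report: float | None = None,
) -> list[TargetHit]:
    """All non-overlapping complementary sites of *mirna* on *transcript*.

    Sites are found by aligning the miRNA's reverse complement against the
    transcript and kept when the alignment score reaches *min_report*
    (default: the candidate floor, so that penalty-only sites survive to
    the union filter).  Overlaps are resolved greedily by descending S.
    """
    params = params or ScoringParams()
    penalty_params = penalty_params or PenaltyParams()
    if len(transcript.sequence) < len(mirna.sequence):
        return []
    floor = params.candidate_floor if min_report is None else min_report
    rows, ptr, _q = _align(mirna.sequence, transcript.sequence, params)
    final = rows[-1]
    order = np.argsort(-final, kind="stable")
    hits: list[TargetHit] = []
    taken: list[tuple[int, int]] = []
    for end_i in order:
        s = float(final[end_i])
        if s < floor:
            break
        start_i, events = _traceback(rows, ptr, _q, int(end_i), params)
        site = (start_i, int(end_i) + 1)
        if any(site[0] < t1 and t0 < site[1] for t0, t1 in taken):
            continue
        pairing = _classify_columns(events, mirna.sequence, transcript.sequence)
        p = penalty_score(pairing, penalty_params)
        hit = TargetHit(
            mirna_id=mirna.id,
            transcript_id=transcript.id,
            orientation=orientation,
            site=site,
            score=s,
            penalty=p,
            pairing=pairing,
            passes_score=s >= params.min_site_score,
            passes_penalty=p <= penalty_params.max_penalty,
        )
        hits.append(hit)
        taken.append(site)
    hits.sort(key=lambda h: (-h.score, h.site))
    return hits


@dataclass
class TranscriptReport:
    transcript_id: str
    orientation: str
    hits: list[TargetHit]
    dual_site: bool = False
    dual_family: str | None = None
    inter_site_distance: float | None = None

    @property
    def total_score(self) -> float:
        return sum(h.score for h in self.hits)


def scan_transcriptome(
    mirnas: list[SeqRecord],
    transcripts: list[SeqRecord],
    params: ScoringParams | None = None,
    penalty_params: PenaltyParams | None = None,
    both_orientations: bool = True,
) -> list[TranscriptReport]:
    """Scan every (miRNA, transcript, orientation) with both scorers.

    A hit is kept when S >= min_site_score OR P <= max_penalty (union);
    both values are always carried so reports can print "--" for the
    scorer that missed.  Transcripts with no accepted hits are omitted.
    """
    params = params or ScoringParams()
    penalty_params = penalty_params or PenaltyParams()
    grouped: dict[tuple[str, str], list[TargetHit]] = defaultdict(list)
    for tx in transcripts:
        frames = [("forward", tx)]
        if both_orientations:
            frames.append(
                ("reverse_complement",
                 SeqRecord(tx.id, reverse_complement(tx.sequence), tx.description))
            )
        for orient, frame in frames:
            for mi in mirnas:
                for hit in score_sites(mi, frame, params, penalty_params, orient):
                    if hit.passes_score or hit.passes_penalty:
                        grouped[(tx.id, orient)].append(hit)
    reports = [
        detect_dual_sites(TranscriptReport(tid, orient, sorted(hits, key=lambda h: h.site)))
        for (tid, orient), hits in sorted(grouped.items())
    ]
    return reports


def detect_dual_sites(report: TranscriptReport) -> TranscriptReport:
    """Flag transcripts carrying two separate sites for one miRNA family."""
    by_family: dict[str, list[TargetHit]] = defaultdict(list)
    for h in report.hits:
        by_family[mirna_family(h.mirna_id)].append(h)
    best: tuple[float, str, float] | None = None
    for fam, hits in by_family.items():
        if len(hits) >= 2:
            hits.sort(key=lambda h: -h.score)
            top2 = hits[:2]
            dist = abs(top2[0].midpoint - top2[1].midpoint)
            total = sum(h.score for h in hits)
            if best is None or total > best[0]:
                best = (total, fam, dist)
    if best is not None:
        report.dual_site = True
        report.dual_family = best[1]
        report.inter_site_distance = best[2]
    return report
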