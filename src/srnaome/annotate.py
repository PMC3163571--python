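"""Classification of unique sRNAs against reference sets.

Small RNAs are compared with curated reference collections (miRNA, tRNA,
snoRNA, rRNA subunits, ta-siRNA, transposons, organelle genomes, virus
genomes) by an exact full-length ungapped scan allowing a small number of
substitutions on either strand.  For 18-30 nt queries this is exactly the
computation a short-word BLAST search approximates, and it is deterministic
and dependency-free.

Known-miRNA assignment names each melon sRNA after its closest reference
miRNA, reports an integer similarity percentage, and resolves low-frequency
variants: non-identical sequences representing no more than 3% of the read
population of a reference miRNA are treated as sequencing errors and merged
into the reference species.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .core import SeqRecord, UniqueSRNA, reverse_complement

CATEGORIES = (
    "miRNA", "taRNA", "tRNA", "snoRNA", "rRNA_LSU", "rRNA_SSU",
    "transposon", "chloroplast", "mitochondrion", "virus_MNSV", "virus_WMV",
    "other",
)

#: default cascade precedence; mirrors the narrative order in which sRNA
#: classes are identified (miRNAs first, "other" sRNA classes after)
DEFAULT_PRECEDENCE = list(CATEGORIES[:-1])


@dataclass
class ReferenceSet:
    category: str
    records: list[SeqRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"reference set {self.category!r} is empty")


@dataclass
class ClassifierConfig:
    max_mismatches: int = 2
    precedence: list[str] = field(default_factory=lambda: list(DEFAULT_PRECEDENCE))
    require_full_length: bool = True


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _scan_one(query: str, ref: str, max_mm: int) -> list[tuple[int, int]]:
    """Full-length ungapped placements of *query* in *ref*: (position, mm)."""
    L, R = len(query), len(ref)
    if L > R:
        return []
    ref_arr = _encode(ref)
    q_arr = _encode(query)
    n = R - L + 1
    mism = np.zeros(n, dtype=np.int32)
    for j in range(L):
        mism += ref_arr[j : j + n] != q_arr[j]
    pos = np.nonzero(mism <= max_mm)[0]
    return [(int(p), int(mism[p])) for p in pos]


def near_match(
    query: str, refset: ReferenceSet, max_mm: int = 2
) -> list[tuple[str, int, str]]:
    """Hits of *query* (or its reverse complement) within a reference set.

    Returns ``(reference_id, mismatches, strand)`` tuples, each reference
    reporting its minimal mismatch count, in deterministic order.
    """
    rc = reverse_complement(query)
    out = []
    for rec in refset.records:
        best: tuple[int, str] | None = None
        for strand, q in (("+", query), ("-", rc)):
            for _pos, mm in _scan_one(q, rec.sequence, max_mm):
                if best is None or mm < best[0]:
                    best = (mm, strand)
        if best is not None:
            out.append((rec.id, best[0], best[1]))
    return out


def classify_cascade(
    srna: UniqueSRNA, refsets: list[ReferenceSet], cfg: ClassifierConfig
) -> tuple[str, dict[str, list[tuple[str, int, str]]]]:
    """Assign an sRNA to the first category (in precedence order) it hits.

    All hits are retained so per-category totals can be tabulated
    independently of the precedence tie-break.
    """
    by_cat = {rs.category: rs for rs in refsets}
    all_hits: dict[str, list[tuple[str, int, str]]] = {}
    for rs in refsets:
        hits = near_match(srna.sequence, rs, cfg.max_mismatches)
        if hits:
            all_hits[rs.category] = hits
    for cat in cfg.precedence:
        if cat in all_hits:
            return cat, all_hits
    return "unclassified", all_hits


def category_tallies(
    classified: list[tuple[UniqueSRNA, str, dict]]
) -> dict[str, dict[str, int]]:
    """Per-category totals, counted both as unique sequences and as reads.

    Tallied over *all* hits (not just the assigned category), so a sequence
    similar to two reference classes contributes to both columns.
    """
    uniq: dict[str, int] = defaultdict(int)
    reads: dict[str, int] = defaultdict(int)
    for srna, _cat, hits in classified:
        for cat in hits:
            uniq[cat] += 1
            reads[cat] += srna.total
    return {c: {"unique": uniq[c], "reads": reads[c]} for c in sorted(uniq)}


# ---------------------------------------------------------------------------
# Known miRNA assignment
# ---------------------------------------------------------------------------

_FAMILY_RE = re.compile(r"miR[-]?(\d+)")


def mirna_family(reference_id: str) -> str:
    """Numeric family of a miRNA reference name (e.g. ``miR159|a`` -> ``159``)."""
    m = _FAMILY_RE.search(reference_id)
    return m.group(1) if m else reference_id


@dataclass
class KnownMiRNAAssignment:
    srna: UniqueSRNA
    reference_id: str
    family: str
    mismatches: int
    is_variant: bool = False
    merged_reads: int = 0  # reads folded in from sub-threshold variants

    @property
    def similarity(self) -> int:
        """Integer similarity percentage, 100*(L-mm)/L rounded down as printed."""
        L = self.srna.length
        return int(100.0 * (L - self.mismatches) / L)


def assign_known_mirnas(
    srnas: list[UniqueSRNA], mirna_refset: ReferenceSet, cfg: ClassifierConfig
) -> list[KnownMiRNAAssignment]:
    """Name sRNAs after their best (fewest-mismatch) reference miRNA.

    Ties are broken by the order of the reference file.  Sequences beyond
    the mismatch tolerance are not assigned.
    """
    ref_order = {rec.id: i for i, rec in enumerate(mirna_refset.records)}
    out = []
    for srna in srnas:
        hits = near_match(srna.sequence, mirna_refset, cfg.max_mismatches)
        if not hits:
            continue
        hits.sort(key=lambda h: (h[1], ref_order[h[0]]))
        ref_id, mm, _strand = hits[0]
        out.append(
            KnownMiRNAAssignment(
                srna, ref_id, mirna_family(ref_id), mm, is_variant=mm > 0
            )
        )
    return out


def variant_filter(
    assignments: list[KnownMiRNAAssignment], threshold: float = 0.03
) -> list[KnownMiRNAAssignment]:
    """Resolve sequence variants per reference miRNA by population fraction.

    For each reference, the population is the total read count of every
    assigned sRNA.  A non-identical sequence is kept as a distinct variant
    only when its reads exceed *threshold* (strictly more than 3% by
    default) of that population; otherwise its reads are merged into the
    exact-match species as presumed sequencing errors.  Total reads per
    reference group are conserved.
    """
    by_ref: dict[str, list[KnownMiRNAAssignment]] = defaultdict(list)
    for a in assignments:
        by_ref[a.reference_id].append(a)
    kept: list[KnownMiRNAAssignment] = []
    for ref_id, group in by_ref.items():
        population = sum(a.srna.total for a in group)
        exact = [a for a in group if a.mismatches == 0]
        merged = 0
        for a in group:
            if a.mismatches == 0 or (population and a.srna.total / population > threshold):
                kept.append(a)
            else:
                merged += a.srna.total
        if merged:
            if exact:
                exact[0].merged_reads += merged
            else:
                # no identical species to absorb into: keep the most abundant
                # variant as the representative of the reference
                rep = max(group, key=lambda a: a.srna.total)
                if rep not in kept:
                    kept.append(rep)
                    rep.merged_reads += merged - rep.srna.total
                else:
                    rep.merged_reads += merged
    return kept


# ---------------------------------------------------------------------------
# Expression normalization
# ---------------------------------------------------------------------------

def normalize_per10k(count: int, library_total: int) -> float:
    """Reads per 10,000 library reads."""
    if library_total <= 0:
        raise ValueError("library total must be positive for normalization")
    return 10000.0 * count / library_total


@dataclass
class ExpressionProfile:
    entity_id: str
    per_library: dict[str, float]
    library_totals: dict[str, int]


def expression_profile(
    entity_id: str, counts: dict[str, int], library_totals: dict[str, int]
) -> ExpressionProfile:
    per_lib = {
        lib: normalize_per10k(counts.get(lib, 0), tot)
        for lib, tot in library_totals.items()
    }
    return ExpressionProfile(entity_id, per_lib, dict(library_totals))


# ---------------------------------------------------------------------------
# Organelle profiling
# ---------------------------------------------------------------------------

@dataclass
class OrganelleCluster:
    start: int
    end: int  # half-open
    sense_reads: int
    antisense_reads: int
    sense_unique: int
    antisense_unique: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class OrganelleProfile:
    """Strand-resolved 5'-end coverage of an organelle genome.

    Antisense frequencies are reported as negative numbers in the TSV,
    matching the plotting convention for strand-split coverage.
    """

    genome_id: str
    sense: dict[int, int]
    antisense: dict[int, int]
    clusters: list[OrganelleCluster]

    def to_rows(self):
        positions = sorted(set(self.sense) | set(self.antisense))
        for pos in positions:
            yield (pos + 1, self.sense.get(pos, 0), -self.antisense.get(pos, 0))


def organelle_profile(
    srnas: list[UniqueSRNA],
    genome: SeqRecord,
    min_cov: int = 5,
    max_gap: int = 50,
) -> OrganelleProfile:
    """Map sRNAs exactly onto an organelle genome and call coverage clusters.

    Coverage is indexed by the 5'-end position of each placement on its
    strand.  Clusters are maximal runs of positions with combined coverage
    >= *min_cov*, allowing internal gaps of up to *max_gap* positions.
    """
    g = genome.sequence
    sense: dict[int, int] = defaultdict(int)
    anti: dict[int, int] = defaultdict(int)
    sense_u: dict[int, int] = defaultdict(int)
    anti_u: dict[int, int] = defaultdict(int)
    for srna in srnas:
        seq = srna.sequence
        start = g.find(seq)
        while start != -1:
            sense[start] += srna.total
            sense_u[start] += 1
            start = g.find(seq, start + 1)
        rc = reverse_complement(seq)
        start = g.find(rc)
        while start != -1:
            # 5' end of an antisense placement is its rightmost genome base
            five_p = start + len(seq) - 1
            anti[five_p] += srna.total
            anti_u[five_p] += 1
            start = g.find(rc, start + 1)

    combined = defaultdict(int)
    for pos, c in sense.items():
        combined[pos] += c
    for pos, c in anti.items():
        combined[pos] += c
    hot = sorted(pos for pos, c in combined.items() if c >= min_cov)
    clusters: list[OrganelleCluster] = []
    if hot:
        run_start = prev = hot[0]
        for pos in hot[1:] + [None]:
            if pos is not None and pos - prev <= max_gap:
                prev = pos
                continue
            clusters.append(_make_cluster(run_start, prev + 1, sense, anti, sense_u, anti_u))
            if pos is not None:
                run_start = prev = pos
    return OrganelleProfile(genome.id, dict(sense), dict(anti), clusters)


def _make_cluster(start, end, sense, anti, sense_u, anti_u) -> OrganelleCluster:
    sel = lambda d: sum(v for k, v in d.items() if start <= k < end)
    return OrganelleCluster(
        start, end,
        sense_reads=sel(sense), antisense_reads=sel(anti),
        sense_unique=sel(sense_u), antisense_unique=sel(anti_u),
    )
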