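"""Demultiplexing, adaptor trimming and sequencing-error estimation.

Raw pyrosequencing reads have the anatomy

    5'-adaptor-variant (with library barcode) + insert + 3'-adaptor + tail

The ten 5'-adaptor variants differ in a small internal window; each variant
identifies one library.  Trimming locates the 5' variant as a read prefix
and the 3' adaptor downstream of it, and the insert is the interval between
them.  Because both adaptors are known sequence, substitutions observed in
located adaptor copies provide a direct estimate of the per-base
sequencing error rate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .core import SRead, normalize_sequence

#: 3' adaptor (DNA form of the 5'-adenylated ligation oligo)
DEFAULT_3P_ADAPTOR = "CTGTAGGCACCATCAAT"

#: The ten chimeric 5'-adaptor variants (DNA form).  The four-base barcode
#: is embedded in the middle of the variant; whole variants are matched.
DEFAULT_5P_VARIANTS = {
    "1-1": "ATCGTAGGCACCTGATA",
    "1-2": "ATCGTAGGCCACTGATA",
    "1-3": "ATCGTAGGCTGCTGATA",
    "1-4": "ATCGTAGGCGTCTGATA",
    "2-1": "ATCGTAGCGACCTGATA",
    "2-2": "ATCGTAGCGCACTGATA",
    "2-3": "ATCGTAGCGTGCTGATA",
    "2-4": "ATCGTAGCGGTCTGATA",
    "3-1": "ATCGTAGACGCCTGATA",
    "3-2": "ATCGTAGACCGCTGATA",
}

TRIM_STATUSES = ("useful", "no_3p", "no_5p", "adaptor_dimer", "ambiguous_barcode")


@dataclass
class AdaptorSpec:
    """Adaptor sequences, barcode-to-library mapping and mismatch tolerances."""

    three_prime: str = DEFAULT_3P_ADAPTOR
    five_prime_variants: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_5P_VARIANTS)
    )
    variant_to_library: dict[str, str] = field(default_factory=dict)
    max_mismatches_3p: int = 1
    max_mismatches_5p: int = 1
    #: tolerance used when re-locating adaptors for error counting
    inspection_ceiling: int = 3

    def __post_init__(self) -> None:
        self.three_prime = normalize_sequence(self.three_prime)
        self.five_prime_variants = {
            k: normalize_sequence(v) for k, v in self.five_prime_variants.items()
        }
        lengths = {len(v) for v in self.five_prime_variants.values()}
        if len(lengths) > 1:
            raise ValueError("5' adaptor variants must all have the same length")
        if self.max_mismatches_3p < 0 or self.max_mismatches_5p < 0:
            raise ValueError("mismatch tolerances must be >= 0")
        if not self.variant_to_library:
            # identity mapping by default: variant id doubles as library id
            self.variant_to_library = {k: k for k in self.five_prime_variants}
        unknown = set(self.variant_to_library) - set(self.five_prime_variants)
        if unknown:
            raise ValueError(f"variant_to_library references unknown variants {sorted(unknown)}")


@dataclass
class TrimResult:
    """Outcome of demultiplexing/trimming one read."""

    read_id: str
    status: str
    library_id: str | None = None
    insert: str = ""
    adaptor_mismatches: int = 0
    #: substitutions / bases observed in adaptors located at the inspection
    #: ceiling, used by :func:`estimate_error_rate`
    inspected_mismatches: int = 0
    inspected_bases: int = 0

    def __post_init__(self) -> None:
        if self.status not in TRIM_STATUSES:
            raise ValueError(f"unknown trim status {self.status!r}")
        if self.status == "useful" and (self.library_id is None or not self.insert):
            raise ValueError("useful read requires a library and a non-empty insert")
        if self.status == "adaptor_dimer" and self.insert:
            raise ValueError("adaptor dimer must have an empty insert")


def _hamming_capped(a: str, b: str, cap: int) -> int:
    """Mismatches between equal-length strings, early exit above *cap*."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return mm
    return mm


def locate_adaptor(
    read: str, adaptor: str, max_mm: int, anchor: str = "internal"
) -> tuple[int, int, int] | None:
    """Find an adaptor copy in *read* with at most *max_mm* substitutions.

    ``anchor="prefix"`` tests position 0 only; ``anchor="internal"`` returns
    the best full-length ungapped occurrence, ties broken by smaller
    mismatch count then leftmost position.  Returns ``(start, end,
    mismatches)`` with a 0-based half-open interval, or None.
    """
    L = len(adaptor)
    if anchor == "prefix":
        if len(read) < L:
            return None
        mm = _hamming_capped(read[:L], adaptor, max_mm)
        return (0, L, mm) if mm <= max_mm else None
    if anchor != "internal":
        raise ValueError(f"unknown anchor {anchor!r}")
    best: tuple[int, int, int] | None = None
    for start in range(len(read) - L + 1):
        mm = _hamming_capped(read[start : start + L], adaptor, max_mm)
        if mm <= max_mm and (best is None or mm < best[2]):
            best = (start, start + L, mm)
            if mm == 0:
                break
    return best


def demultiplex_and_trim(read: SRead, spec: AdaptorSpec) -> TrimResult:
    """Assign a read to its library and extract the insert.

    The 5' variant is matched as a read prefix; ties at the minimum mismatch
    count between two variants make the barcode ambiguous.  The 3' adaptor
    is then located downstream of the 5' adaptor.  Reads whose 5' adaptor is
    immediately followed by the 3' adaptor are adaptor-dimer artifacts.
    """
    seq = normalize_sequence(read.sequence)
    vlen = len(next(iter(spec.five_prime_variants.values())))

    # --- 5' variant as prefix, scored at the inspection ceiling so that
    # error counting sees reads rejected at the working tolerance too
    ceiling = max(spec.inspection_ceiling, spec.max_mismatches_5p)
    scored = sorted(
        (
            (_hamming_capped(seq[:vlen], var, ceiling), vid)
            for vid, var in spec.five_prime_variants.items()
        )
    ) if len(seq) >= vlen else []
    insp_mm = 0
    insp_bases = 0
    best_vid: str | None = None
    mm5 = 0
    ambiguous = False
    if scored:
        mm5, best_vid = scored[0]
        if mm5 <= ceiling:
            insp_mm += mm5
            insp_bases += vlen
        if len(scored) > 1 and scored[1][0] == mm5:
            ambiguous = True

    # --- 3' adaptor downstream of the 5' variant (internal search)
    down = seq[vlen:] if len(seq) > vlen else ""
    hit3_ceiling = locate_adaptor(down, spec.three_prime, max(spec.inspection_ceiling, spec.max_mismatches_3p))
    if hit3_ceiling is not None:
        insp_mm += hit3_ceiling[2]
        insp_bases += len(spec.three_prime)

    def result(status: str, lib: str | None = None, insert: str = "", mm: int = 0) -> TrimResult:
        return TrimResult(
            read.read_id, status, lib, insert, mm,
            inspected_mismatches=insp_mm, inspected_bases=insp_bases,
        )

    if best_vid is None or mm5 > spec.max_mismatches_5p:
        return result("no_5p")
    if ambiguous:
        return result("ambiguous_barcode")
    if hit3_ceiling is None or hit3_ceiling[2] > spec.max_mismatches_3p:
        return result("no_3p")
    start3, _, mm3 = hit3_ceiling
    insert = down[:start3]
    lib = spec.variant_to_library.get(best_vid, best_vid)
    if not insert:
        return result("adaptor_dimer", mm=mm5 + mm3)
    return result("useful", lib, insert, mm5 + mm3)


def estimate_error_rate(results: list[TrimResult], spec: AdaptorSpec) -> float:
    """Per-base substitution rate from mismatches in located adaptor copies.

    Adaptors are known sequence, so every located copy is an error counter:
    rate = (total substitutions) / (total adaptor bases inspected), with
    location performed at the inspection ceiling so that errors beyond the
    working tolerance are still countable.
    """
    mm = sum(r.inspected_mismatches for r in results)
    bases = sum(r.inspected_bases for r in results)
    if bases == 0:
        raise ValueError("no located adaptors to estimate an error rate from")
    return mm / bases


def filter_useful(results: list[TrimResult]) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Keep useful reads as ``(library_id, insert)``; return a status manifest."""
    manifest = Counter(r.status for r in results)
    kept = [(r.library_id, r.insert) for r in results if r.status == "useful"]
    return kept, dict(manifest)
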