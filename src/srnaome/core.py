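"""Shared domain types, sequence handling and FASTA/TSV I/O.

The internal alphabet is DNA: ``U`` is mapped to ``T`` on input and all
comparisons downstream happen over {A, C, G, T}.  Writers can render RNA
(``T`` -> ``U``) on request, since mature small RNAs are conventionally
printed as RNA while genomes are printed as DNA.

Genomic and transcript coordinates are 0-based half-open internally;
report writers convert to 1-based inclusive (GFF3 convention).
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

CANONICAL = frozenset("ACGT")
#: characters accepted in reference/genome sequences (IUPAC ambiguity codes)
IUPAC = frozenset("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed (bad header / empty sequence)."""


def normalize_sequence(seq: str) -> str:
    """Upper-case a nucleotide string and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_canonical(seq: str) -> bool:
    """True when *seq* contains only unambiguous A/C/G/T characters."""
    return bool(seq) and set(seq) <= CANONICAL


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence (genome contig, reference RNA, transcript)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC
        if bad:
            raise ValueError(f"record {self.id!r}: non-nucleotide characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SRead:
    """A raw sequencing read (~100 bases: adaptors plus insert) before trimming."""

    read_id: str
    sequence: str
    source_file: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")


@dataclass
class UniqueSRNA:
    """A collapsed distinct sRNA with per-library read counts.

    This is the unit of all downstream analysis: classification, miRNA
    assignment, genome mapping and phasing all operate on unique sequences
    while abundance (``total``) carries the read-count evidence.
    """

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("UniqueSRNA with empty sequence")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative library count")


# ---------------------------------------------------------------------------
# FASTA / TSV / JSON I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, normalize: bool = True) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects, order preserved.

    Sequences are normalized to the canonical DNA alphabet (U -> T,
    upper-case) unless *normalize* is False.  Malformed entries raise
    :class:`FastaParseError` naming the offending record.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        seq = str(bio.seq)
        if normalize:
            seq = normalize_sequence(seq)
        if not seq:
            raise FastaParseError(f"{path}: record {bio.id!r} has an empty sequence")
        if bio.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {bio.id!r}")
        seen.add(bio.id)
        try:
            records.append(SeqRecord(bio.id, seq, bio.description))
        except ValueError as exc:
            raise FastaParseError(f"{path}: {exc}") from exc
    if not records:
        # distinguish empty file from a lone header with no sequence
        text = path.read_text()
        if text.strip().startswith(">"):
            raise FastaParseError(f"{path}: header without sequence")
    return records


def write_fasta(path: str | Path, records: Iterable[SeqRecord], as_rna: bool = False) -> None:
    """Write records to FASTA; ``as_rna=True`` renders T as U."""
    bio_records = []
    for rec in records:
        seq = rec.sequence.replace("T", "U") if as_rna else rec.sequence
        bio_records.append(_BioSeqRecord(Seq(seq), id=rec.id, description=rec.description))
    SeqIO.write(bio_records, str(path), "fasta")


def write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Read collapsing and summaries
# ---------------------------------------------------------------------------

def collapse_reads(reads: Iterable[tuple[SRead | str, str]]) -> list[UniqueSRNA]:
    """Collapse trimmed inserts into unique sRNAs with per-library counts.

    *reads* yields ``(read, library_id)`` pairs where *read* is either an
    :class:`SRead` or a bare insert string.  The sum of all ``total`` fields
    equals the number of input reads.  Output order is by decreasing total
    then sequence (deterministic).
    """
    table: dict[str, Counter] = defaultdict(Counter)
    for read, lib in reads:
        seq = read.sequence if isinstance(read, SRead) else read
        table[seq][lib] += 1
    srnas = [UniqueSRNA(seq, dict(cnt)) for seq, cnt in table.items()]
    srnas.sort(key=lambda s: (-s.total, s.sequence))
    return srnas


def length_histogram(
    srnas: Iterable[UniqueSRNA], weighted: bool, as_percent: bool = False
) -> dict[int, float]:
    """Length distribution of a collapsed sRNA set.

    ``weighted=True`` sums read totals per length (redundant set);
    ``weighted=False`` counts distinct sequences (non-redundant set).
    With ``as_percent=True`` values are scaled to sum to 100.
    """
    hist: Counter = Counter()
    for s in srnas:
        hist[s.length] += s.total if weighted else 1
    if as_percent:
        grand = sum(hist.values())
        if grand:
            return {k: 100.0 * v / grand for k, v in sorted(hist.items())}
        return {}
    return {k: float(v) for k, v in sorted(hist.items())}


def gc_percent(sequence: str) -> float:
    """GC content as a percentage in [0, 100]."""
    if not sequence:
        raise ValueError("gc_percent of empty sequence")
    gc = sequence.count("G") + sequence.count("C")
    return 100.0 * gc / len(sequence)


def to_gff3_coords(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive (GFF3)."""
    return start + 1, end
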