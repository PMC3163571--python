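"""Seeded synthetic data emulating a plant small-RNA sequencing study.

The generator builds, from one integer seed, every input the pipeline
consumes: a nuclear genome with planted miRNA hairpins and decoy elements,
organelle genomes with inverted-repeat rRNA regions, reference sets for
the classification cascade, a transcript set with miRNA target sites and a
two-site TAS locus, and barcoded adaptor-flanked ~100-base raw reads with
per-base substitution error, adaptor-dimer and missing-adaptor artifacts,
and a strongly skewed abundance distribution.  A truth manifest records
every planted element with its expected pipeline verdict, each read's true
library, and the number of substitution errors injected, so tests can
score recovery against ground truth.

Planted hairpins are verified at generation time with the same folding and
structural machinery the pipeline uses; decoys violate exactly their
labelled criterion.  All outputs are pure functions of the configuration
(same seed, byte-identical files).

Transcriptions of the study's printed summary tables (libraries, known
miRNAs, novel miRNA candidates) are packaged as TSV fixtures and loadable
through :func:`load_fixture`.
"""

from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core import SRead, SeqRecord, reverse_complement
from .hairpin import StructuralCriteria, check_structural_criteria, compute_mfei, extract_duplex, fold_stemloop
from .novel import NovelConfig, scan_flanks_for_star
from .readproc import DEFAULT_5P_VARIANTS, AdaptorSpec

BASES = "ACGT"

#: conserved plant miRNAs used as the known-miRNA reference
#: (DNA form of the melon orthologue sequences)
KNOWN_MIRNAS = {
    "miR156|a": "TGACAGAAGAGAGTGAGCAC",
    "miR159|a": "TTTGGATTGAAGGGAGCTCTA",
    "miR160|a": "TGCCTGGCTCCCTGTATGCCA",
    "miR162|a": "TCGATAAACCTCTGCATCCAG",
    "miR166|a": "TCGGACCAGGCTTCATTCCCC",
    "miR167|a": "TGAAGCTGCCAGCATGATCTA",
    "miR168|a": "TCGCTTGGTGCAGGTCGGGAA",
    "miR390|a": "AAGCTCAGGAGGGATAGCGCC",
    "miR396|a": "TTCCACAGCTTTCTTGAACTG",
    "miR397|a": "TCATTGAGTGCAGCGTTGATG",
}

MIR390 = KNOWN_MIRNAS["miR390|a"]


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic data set.

    Defaults emulate the sequencing design at desk scale: ten barcoded
    libraries, ~10,000 useful reads, a 3.7% per-base substitution rate,
    log-uniform sRNA abundance skew, ten conforming miRNA hairpins and
    eight decoys planted in a 200 kb genome, and one two-site TAS locus
    with its miR390 complementary sites ~200 nt apart.
    """

    seed: int = 1
    genome_length: int = 200_000
    gc_content: float = 0.42
    n_hairpins: int = 10
    n_decoys: dict[str, int] = field(
        default_factory=lambda: {
            "transposon_like": 2,
            "foldback": 2,
            "short_precursor": 2,
            "multi_copy": 2,
        }
    )
    n_tas_loci: int = 1
    chloroplast_length: int = 12_000
    mitochondrion_length: int = 8_000
    rrna_span: int = 300
    per_base_error: float = 0.037
    total_useful_reads: int = 10_000
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: {"adaptor_dimer": 0.005, "missing_3p": 0.02}
    )
    #: abundance skew: per-species counts drawn log-uniformly on [1, 10^4]
    #: then scaled into each class budget
    abundance_log_max: float = 4.0
    read_length: int = 100
    #: reads planted for each novel miRNA / its star (clean-copy head-room
    #: against the error channel)
    novel_mirna_reads: int = 15
    star_reads: int = 6

    def library_sizes(self) -> dict[str, int]:
        """Ten libraries with the study's relative sizes, scaled to the total."""
        raw = {
            "Wtm": 33123, "Wt": 35860, "Cwm": 41039, "Cw": 36330,
            "15d": 21662, "45d": 9942, "c1": 18764, "c5": 14529,
            "Ta5": 43170, "3'T": 56425,
        }
        scale = self.total_useful_reads / sum(raw.values())
        return {k: max(1, int(round(v * scale))) for k, v in raw.items()}

    def barcode_map(self) -> dict[str, str]:
        variants = list(DEFAULT_5P_VARIANTS)
        return {v: lib for v, lib in zip(variants, self.library_sizes())}


def _rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=n, p=p))


def _mutate(rng: np.random.Generator, seq: str, positions: list[int]) -> str:
    out = list(seq)
    for pos in positions:
        out[pos] = rng.choice([b for b in BASES if b != out[pos]])
    return "".join(out)


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _make_hairpin_element(rng, mirna_len: int, loop_len: int = 32, flank: int = 18):
    """A conforming precursor: flank + miRNA + loop + star-with-2-mismatches + flank.

    The loop is long enough that the minimal miRNA..star region exceeds the
    70-nt precursor bound.  Verified by folding before planting.
    """
    criteria = StructuralCriteria()
    novel_cfg = NovelConfig(criteria=criteria)
    for _attempt in range(60):
        mirna = _rand_seq(rng, mirna_len, gc=0.5)
        star_core = reverse_complement(mirna)
        # two internal mismatches away from both ends
        pos = sorted(rng.choice(np.arange(4, mirna_len - 4), size=2, replace=False))
        star = _mutate(rng, star_core, [int(p) for p in pos])
        loop = _rand_seq(rng, loop_len, gc=0.35)
        left = _rand_seq(rng, flank)
        right = _rand_seq(rng, flank)
        element = left + mirna + loop + star + right
        mirna_span = (flank, flank + mirna_len)
        # generation-time verification with the pipeline's own machinery
        star_hit = scan_flanks_for_star(element, mirna_span, _AsSRNA(mirna), novel_cfg)
        if star_hit is None:
            continue
        prec = element[mirna_span[0] : star_hit[0][1]]
        if len(prec) < criteria.min_precursor_len:
            continue
        try:
            fold = fold_stemloop(prec)
            hp = compute_mfei(prec, fold.mfe)
            duplex = extract_duplex(fold, (0, mirna_len))
        except ValueError:
            continue
        if not check_structural_criteria(hp, duplex, criteria).status.startswith("pass"):
            continue
        # a cloned star must be recoverable from the fold's predicted star arm
        from .hairpin import sequence_near_identical

        s0, s1 = duplex.star_span
        if sequence_near_identical(star, prec[s0:s1]) is None:
            continue
        return element, mirna, star, mirna_span
    raise RuntimeError("could not construct a conforming hairpin")


class _AsSRNA:
    """Minimal stand-in exposing .sequence/.length/.total for generator checks."""

    def __init__(self, sequence: str):
        self.sequence = sequence
        self.length = len(sequence)
        self.total = 1


def _make_short_precursor(rng, mirna_len: int = 21):
    """Decoy: miRNA and star separated by a short loop -> precursor < 70 nt."""
    mirna = _rand_seq(rng, mirna_len, gc=0.5)
    star = _mutate(rng, reverse_complement(mirna), [8, 12])
    loop = _rand_seq(rng, 8, gc=0.3)
    flank = 18
    element = _rand_seq(rng, flank) + mirna + loop + star + _rand_seq(rng, flank)
    return element, mirna, (flank, flank + mirna_len)


def _make_foldback(rng, arm_len: int = 60):
    """Decoy: near-perfect long inverted repeat (foldback-transposon-like)."""
    arm = _rand_seq(rng, arm_len, gc=0.55)
    loop = _rand_seq(rng, 10, gc=0.3)
    flank = 15
    element = _rand_seq(rng, flank) + arm + loop + reverse_complement(arm) + _rand_seq(rng, flank)
    trigger = arm[10:31]  # a 21-nt sRNA from the 5' arm
    # distinct sRNAs tiling both strands of the repeat (foldback elements
    # attract dense sense+antisense siRNA clouds)
    span = element[flank : flank + 2 * arm_len + 10]
    tiling = []
    for off in range(0, len(span) - 25, 6):
        tiling.append(span[off : off + 21])
        tiling.append(reverse_complement(span[off + 3 : off + 24]))
    return element, trigger, tiling


def _make_tas_site() -> str:
    """A miR390 complementary site with defects at miRNA positions 12/15/18.

    G:U wobbles at positions 12 and 15 and a mismatch at 18 leave positions
    9-11 perfectly paired; with the default scorer the site scores 181
    (two such sites on one transcript total 362) and carries a pairing
    penalty of 2.5.
    """
    L = len(MIR390)
    site = list(reverse_complement(MIR390))
    # G:U at miRNA position p: miRNA G pairs target T / miRNA T pairs target G
    for p in (12, 15):
        m = MIR390[p - 1]
        site[L - p] = "T" if m == "G" else "G"
    site[L - 18] = "A"  # mismatch (miRNA C vs target A)
    return "".join(site)


@dataclass
class PlantedElement:
    name: str
    kind: str
    contig: str = "chr1"
    start: int = -1
    end: int = -1
    sequence: str = ""
    mirna: str = ""
    star: str = ""
    expected: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def make_genome(cfg: SynthConfig, rng: np.random.Generator | None = None):
    """Synthesize the nuclear genome with planted elements and a truth manifest."""
    rng = rng or np.random.default_rng(cfg.seed)
    elements: list[PlantedElement] = []
    pieces: list[str] = []
    spacer = 800  # keeps each element's 600-nt flank windows free of neighbours

    def plant(el: PlantedElement, seq: str):
        el.sequence = seq
        pieces.append(_rand_seq(rng, spacer, cfg.gc_content))
        el.start = sum(len(p) for p in pieces)
        pieces.append(seq)
        el.end = el.start + len(seq)
        elements.append(el)

    mirna_lengths = [21, 21, 21, 21, 21, 22, 22, 22, 24, 24]
    for i in range(cfg.n_hairpins):
        mlen = mirna_lengths[i % len(mirna_lengths)]
        seq, mirna, star, _span = _make_hairpin_element(rng, mlen)
        expected = "confirmed_mirna" if i < cfg.n_hairpins // 2 else "candidate_mirna"
        el = PlantedElement(name=f"hairpin_{i}", kind="hairpin", mirna=mirna,
                            star=star, expected=expected)
        plant(el, seq)

    foldback_tilings: dict[str, list[str]] = {}
    for kind, count in cfg.n_decoys.items():
        for i in range(count):
            name = f"{kind}_{i}"
            if kind == "transposon_like":
                seq, mirna, _span = (lambda e: (e[0], e[1], e[3]))(_make_hairpin_element(rng, 21))
                el = PlantedElement(name=name, kind=kind, mirna=mirna,
                                    expected="rejected:transposon")
                plant(el, seq)
            elif kind == "foldback":
                seq, trigger, tiling = _make_foldback(rng)
                el = PlantedElement(name=name, kind=kind, mirna=trigger,
                                    expected="rejected:foldback")
                plant(el, seq)
                foldback_tilings[name] = tiling
            elif kind == "short_precursor":
                seq, mirna, _span = _make_short_precursor(rng)
                el = PlantedElement(name=name, kind=kind, mirna=mirna,
                                    expected="rejected:short_precursor")
                plant(el, seq)
            elif kind == "multi_copy":
                mirna = _rand_seq(rng, 21, gc=0.5)
                el = PlantedElement(name=name, kind=kind, mirna=mirna,
                                    expected="filtered:too_many_hits")
                # seven tandem-ish copies separated by random spacers
                copies = mirna
                for _ in range(6):
                    copies += _rand_seq(rng, 60, cfg.gc_content) + mirna
                plant(el, copies)
            else:
                raise ValueError(f"unknown decoy class {kind}")

    # TAS loci: two miR390 sites separated by 9 phasing cycles
    tas_elements = []
    for i in range(cfg.n_tas_loci):
        site = _make_tas_site()
        spacer_len = 9 * 21  # 189 nt between the two sites
        tas_seq = (
            _rand_seq(rng, 30, cfg.gc_content)
            + site
            + _rand_seq(rng, spacer_len, cfg.gc_content)
            + site
            + _rand_seq(rng, 30, cfg.gc_content)
        )
        el = PlantedElement(name=f"tas_{i}", kind="tas", expected="phased_locus")
        plant(el, tas_seq)
        tas_elements.append(el)

    used = sum(len(p) for p in pieces)
    if used > cfg.genome_length:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small for planted span {used}"
        )
    pieces.append(_rand_seq(rng, cfg.genome_length - used, cfg.gc_content))
    genome = SeqRecord("chr1", "".join(pieces), "synthetic nuclear genome")

    truth = {
        "elements": [el.as_dict() for el in elements],
        "foldback_tilings": foldback_tilings,
        "tas": [
            {
                "name": el.name,
                "start": el.start,
                "end": el.end,
                "site_len": len(MIR390),
                "site5_start": el.start + 30,
                "site3_start": el.start + 30 + len(MIR390) + 9 * 21,
            }
            for el in tas_elements
        ],
    }
    return genome, truth


# ---------------------------------------------------------------------------
# Organelles, references, transcripts
# ---------------------------------------------------------------------------

def make_organelles(cfg: SynthConfig, rng: np.random.Generator):
    """Chloroplast (inverted-repeat rRNA) and mitochondrial genomes."""
    rrna = _rand_seq(rng, cfg.rrna_span, gc=0.52)
    cp_len = cfg.chloroplast_length
    q1, q3 = cp_len // 4, 3 * cp_len // 4
    cp = (
        _rand_seq(rng, q1, gc=0.37)
        + rrna
        + _rand_seq(rng, q3 - q1 - cfg.rrna_span, gc=0.37)
        + reverse_complement(rrna)
        + _rand_seq(rng, cp_len - q3 - cfg.rrna_span, gc=0.37)
    )
    chloroplast = SeqRecord("chloroplast", cp, "synthetic plastid genome")
    mt_rrna = _rand_seq(rng, cfg.rrna_span, gc=0.5)
    mt = (
        _rand_seq(rng, cfg.mitochondrion_length // 2, gc=0.44)
        + mt_rrna
        + _rand_seq(rng, cfg.mitochondrion_length // 2 - cfg.rrna_span, gc=0.44)
    )
    mito = SeqRecord("mitochondrion", mt, "synthetic mitochondrial genome")
    truth = {
        "cp_rrna_spans": [[q1, q1 + cfg.rrna_span], [q3, q3 + cfg.rrna_span]],
        "mt_rrna_span": [cfg.mitochondrion_length // 2,
                         cfg.mitochondrion_length // 2 + cfg.rrna_span],
    }
    return chloroplast, mito, rrna, mt_rrna, truth


def make_references(cfg: SynthConfig, rng, genome_truth, chloroplast, mito,
                    cp_rrna, mt_rrna):
    """Category reference sets consistent with the planted truth.

    The ta-siRNA references derive from planted phased reads, which only
    exist once the species plan is built, so they are attached afterwards
    by :func:`attach_tarna_references`.
    """
    refs: dict[str, list[SeqRecord]] = {}
    refs["miRNA"] = [SeqRecord(name, seq) for name, seq in KNOWN_MIRNAS.items()]
    refs["tRNA"] = [SeqRecord(f"tRNA_{i}", _rand_seq(rng, 75, gc=0.55)) for i in range(3)]
    refs["snoRNA"] = [SeqRecord(f"snoRNA_{i}", _rand_seq(rng, 120, gc=0.45)) for i in range(2)]
    refs["rRNA_LSU"] = [SeqRecord("LSU_rRNA", cp_rrna), SeqRecord("LSU_rRNA_mt", mt_rrna)]
    refs["rRNA_SSU"] = [SeqRecord("SSU_rRNA", _rand_seq(rng, 250, gc=0.5))]
    transposons = [SeqRecord(f"transposon_{i}", _rand_seq(rng, 300, gc=0.4)) for i in range(2)]
    for el in genome_truth["elements"]:
        if el["kind"] == "transposon_like":
            transposons.append(SeqRecord(f"transposon_{el['name']}", el["sequence"]))
    refs["transposon"] = transposons
    refs["chloroplast"] = [chloroplast]
    refs["mitochondrion"] = [mito]
    refs["virus_MNSV"] = [SeqRecord("MNSV", _rand_seq(rng, 600, gc=0.45))]
    refs["virus_WMV"] = [SeqRecord("WMV", _rand_seq(rng, 600, gc=0.42))]
    return refs


def attach_tarna_references(refs, tas_reads: list[str], rng) -> None:
    """Near-copies (1 mismatch) of two planted phased species as ta-siRNA refs."""
    ta = [
        SeqRecord(f"TAS3a_D{7 + i}(+)", _mutate(rng, read, [int(rng.integers(3, 18))]))
        for i, read in enumerate(tas_reads[:2])
    ]
    refs["taRNA"] = ta or [SeqRecord("TAS3a_D7(+)", _rand_seq(rng, 21))]


def make_transcripts(cfg: SynthConfig, rng, genome: SeqRecord, genome_truth):
    """Unigene-like transcripts: the TAS transcript plus target-bearing and
    background unigenes."""
    transcripts: list[SeqRecord] = []
    for tas in genome_truth["tas"]:
        transcripts.append(
            SeqRecord("TAS_unigene", genome.sequence[tas["start"] : tas["end"]],
                      "two-site TAS transcript")
        )
    # one perfect miR159a site (scores 195 with the default scorer)
    t1 = (_rand_seq(rng, 180, 0.45)
          + reverse_complement(KNOWN_MIRNAS["miR159|a"])
          + _rand_seq(rng, 180, 0.45))
    transcripts.append(SeqRecord("unigene_mir159_target", t1, "MYB-like target"))
    # one miR156 site with a single non-seed G:U (scores 192)
    site = list(reverse_complement(KNOWN_MIRNAS["miR156|a"]))
    L = len(site)
    p = 14  # miRNA position outside seed and outside 9-11
    m = KNOWN_MIRNAS["miR156|a"][p - 1]
    if m in "GT":
        site[L - p] = "T" if m == "G" else "G"
    t2 = _rand_seq(rng, 150, 0.45) + "".join(site) + _rand_seq(rng, 150, 0.45)
    transcripts.append(SeqRecord("unigene_spl_target", t2, "SPL-like target"))
    # a mis-oriented EST: the target site only on the reverse complement
    t3 = _rand_seq(rng, 120, 0.45) + KNOWN_MIRNAS["miR167|a"] + _rand_seq(rng, 120, 0.45)
    transcripts.append(SeqRecord("unigene_revcomp_target", t3, "mis-oriented EST"))
    for i in range(6):
        transcripts.append(SeqRecord(f"unigene_bg_{i}", _rand_seq(rng, 400, 0.45)))
    return transcripts


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SpeciesPlan:
    sequence: str
    count: int
    true_class: str


def _skewed_counts(rng, n_species: int, budget: int, log_max: float) -> list[int]:
    """Log-uniform abundance skew scaled into a read budget (each >= 1)."""
    raw = 10 ** rng.uniform(0, log_max, size=n_species)
    counts = np.maximum(1, np.round(raw * budget / raw.sum())).astype(int)
    return counts.tolist()


def build_species_plan(cfg: SynthConfig, rng, genome, genome_truth, refs,
                       cp_rrna: str, mt_rrna: str):
    """The true sRNA species table: sequence, abundance and class of origin."""
    plan: list[SpeciesPlan] = []

    def add(seq, count, cls):
        plan.append(SpeciesPlan(seq, max(1, int(count)), cls))

    # --- known miRNAs (miR159a dominant, as in real data)
    mirna_budget = {"miR159|a": 1100, "miR156|a": 130, "miR160|a": 90,
                    "miR162|a": 160, "miR166|a": 40, "miR167|a": 60,
                    "miR168|a": 200, "miR390|a": 30, "miR396|a": 70, "miR397|a": 26}
    for name, seq in KNOWN_MIRNAS.items():
        add(seq, mirna_budget[name], f"known_miRNA:{name}")
    # a retained variant (>3% of the miR397a population) and a discarded one
    v_keep = _mutate(rng, KNOWN_MIRNAS["miR397|a"], [5])
    add(v_keep, 6, "known_miRNA_variant_keep:miR397|a")
    v_drop = _mutate(rng, KNOWN_MIRNAS["miR159|a"], [7])
    add(v_drop, 4, "known_miRNA_variant_drop:miR159|a")
    # sequenced miRNA* of miR396a (2-nt shifted reverse complement)
    star396 = reverse_complement(KNOWN_MIRNAS["miR396|a"])[2:] + _rand_seq(rng, 2)
    add(star396, 40, "known_miRNA_star:miR396|a")

    # --- structural RNAs, transposons, organelles, viruses
    # fragment lengths follow the 21-dominant size distribution of cloned sRNAs
    frag_lengths = (20, 21, 22, 24)
    frag_length_p = (0.15, 0.5, 0.15, 0.2)

    def sample_fragments(source: str, n: int, cls: str, budget: int,
                         both_strands=False):
        counts = _skewed_counts(rng, n, budget, cfg.abundance_log_max)
        for c in counts:
            ln = int(rng.choice(frag_lengths, p=frag_length_p))
            pos = int(rng.integers(0, len(source) - ln))
            frag = source[pos : pos + ln]
            if both_strands and rng.random() < 0.4:
                frag = reverse_complement(frag)
            add(frag, c, cls)

    sample_fragments(refs["rRNA_LSU"][0].sequence, 18, "rRNA_LSU", 2600, both_strands=True)
    sample_fragments(refs["rRNA_SSU"][0].sequence, 8, "rRNA_SSU", 500, both_strands=True)
    sample_fragments(refs["tRNA"][0].sequence + refs["tRNA"][1].sequence, 6, "tRNA", 200)
    sample_fragments(refs["snoRNA"][0].sequence, 4, "snoRNA", 90)
    sample_fragments(refs["transposon"][0].sequence, 7, "transposon", 180, both_strands=True)
    sample_fragments(refs["virus_MNSV"][0].sequence, 20, "virus_MNSV", 1500, both_strands=True)
    sample_fragments(refs["virus_WMV"][0].sequence, 10, "virus_WMV", 420, both_strands=True)
    sample_fragments(mt_rrna, 8, "mitochondrion", 330, both_strands=True)
    # an abundant plastid intergenic sRNA plus minor plastid species
    cp = refs["chloroplast"][0].sequence
    inter_pos = len(cp) // 2  # between the two inverted-repeat copies
    add(cp[inter_pos : inter_pos + 22], 950, "chloroplast_intergenic")
    sample_fragments(cp[: len(cp) // 4 - 30], 8, "chloroplast", 240)

    # --- novel miRNA hairpins, decoys, TAS phasing
    tas_reads: list[str] = []
    for el in genome_truth["elements"]:
        kind = el["kind"]
        if kind == "hairpin":
            add(el["mirna"], cfg.novel_mirna_reads, f"novel_miRNA:{el['name']}")
            if el["expected"] == "confirmed_mirna":
                # sequenced star with the canonical 2-nt offset
                star_read = el["star"]
                add(star_read, cfg.star_reads, f"novel_star:{el['name']}")
        elif kind in ("transposon_like", "short_precursor", "multi_copy"):
            add(el["mirna"], 5, f"decoy:{el['name']}")
        elif kind == "foldback":
            add(el["mirna"], 5, f"decoy:{el['name']}")
    for name, tiling in genome_truth["foldback_tilings"].items():
        for frag in tiling:
            add(frag, 3, f"foldback_tiling:{name}")

    genome_seq = genome.sequence
    for tas in genome_truth["tas"]:
        # cleavage after the base pairing miRNA position 10 of the 5' site
        site5_start = tas["site5_start"]
        L = tas["site_len"]
        cleavage = site5_start + (L - 10)  # boundary between bases pairing 11 and 10
        tas["cleavage"] = cleavage
        registers = {0: 10, 10: 9}  # anchored + one alternative register
        for offset, n_positions in registers.items():
            for k in range(n_positions):
                start = cleavage + offset + 21 * k
                frag = genome_seq[start : start + 21]
                tas_reads.append(frag)
                add(frag, 3, f"tas_phased:{tas['name']}:reg{offset}")
                if k % 3 == 0:  # antisense partner with the 2-nt duplex offset
                    five_p = start + 21 - 1 - 2
                    anti = reverse_complement(genome_seq[five_p - 20 : five_p + 1])
                    add(anti, 2, f"tas_phased_anti:{tas['name']}:reg{offset}")
        # unphased noise inside the locus, and one non-21-nt read
        noise_pos = cleavage + 5
        add(genome_seq[noise_pos : noise_pos + 21], 2, f"tas_noise:{tas['name']}")
        add(genome_seq[cleavage + 40 : cleavage + 60], 2, f"tas_len20:{tas['name']}")

    # --- background: genome-derived singletons and non-genomic junk
    for i in range(25):
        ln = int(rng.choice([21, 22, 23, 24]))
        pos = int(rng.integers(0, len(genome_seq) - ln))
        add(genome_seq[pos : pos + ln], int(rng.integers(1, 3)), "background_genomic")
    for i in range(160):
        ln = int(rng.choice([19, 20, 21, 22, 24, 26]))
        add(_rand_seq(rng, ln, 0.48), int(rng.integers(1, 5)), "background_random")

    return plan, tas_reads


def simulate_reads(cfg: SynthConfig, plan: list[SpeciesPlan],
                   rng: np.random.Generator):
    """Raw barcoded adaptor-flanked reads with substitution errors and artifacts.

    Returns ``(reads, adaptor_spec, read_truth)`` where *read_truth* records
    each read's true library, species class and injected error count, plus
    the generator's total substitution tally (the oracle for the error-rate
    estimator).
    """
    spec = AdaptorSpec(variant_to_library=cfg.barcode_map())
    lib_sizes = cfg.library_sizes()
    libs = list(lib_sizes)
    lib_p = np.array([lib_sizes[l] for l in libs], dtype=float)
    lib_p /= lib_p.sum()
    variant_of = {lib: v for v, lib in spec.variant_to_library.items()}

    reads: list[SRead] = []
    read_truth: list[dict] = []
    total_sub = 0
    total_bases = 0
    idx = 0

    def emit(insert: str, cls: str, artifact: str | None = None):
        nonlocal total_sub, total_bases, idx
        lib = libs[int(rng.choice(len(libs), p=lib_p))]
        variant = spec.five_prime_variants[variant_of[lib]]
        if artifact == "adaptor_dimer":
            body = variant + spec.three_prime
        elif artifact == "missing_3p":
            body = variant + insert
        else:
            body = variant + insert + spec.three_prime
        tail_len = max(0, cfg.read_length - len(body))
        seq = body + _rand_seq(rng, tail_len, 0.5)
        n_err = int(rng.binomial(len(seq), cfg.per_base_error))
        if n_err:
            pos = rng.choice(len(seq), size=n_err, replace=False)
            seq = _mutate(rng, seq, [int(p) for p in pos])
        total_sub += n_err
        total_bases += len(seq)
        rid = f"read_{idx:06d}"
        idx += 1
        reads.append(SRead(rid, seq, "synthetic"))
        read_truth.append(
            {"read_id": rid, "library": lib, "class": cls,
             "artifact": artifact, "n_errors": n_err}
        )

    for sp in plan:
        for _ in range(sp.count):
            emit(sp.sequence, sp.true_class)
    n_normal = idx
    for artifact, rate in cfg.artifact_rates.items():
        for _ in range(int(rng.binomial(n_normal, rate))):
            emit(_rand_seq(rng, 21, 0.5), "artifact", artifact)

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    read_truth = [read_truth[i] for i in order]
    truth = {
        "reads": read_truth,
        "error_rate_true": cfg.per_base_error,
        "total_substitutions": total_sub,
        "total_bases": total_bases,
    }
    return reads, spec, truth


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SynthDataset:
    config: SynthConfig
    genome: SeqRecord
    chloroplast: SeqRecord
    mitochondrion: SeqRecord
    references: dict[str, list[SeqRecord]]
    transcripts: list[SeqRecord]
    reads: list[SRead]
    adaptor_spec: AdaptorSpec
    truth: dict


def make_dataset(cfg: SynthConfig | None = None) -> SynthDataset:
    """Generate the full synthetic study from one seed."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    genome, genome_truth = make_genome(cfg, rng)
    chloroplast, mito, cp_rrna, mt_rrna, org_truth = make_organelles(cfg, rng)
    refs = make_references(cfg, rng, genome_truth, chloroplast, mito,
                           cp_rrna, mt_rrna)
    plan, tas_reads = build_species_plan(cfg, rng, genome, genome_truth, refs,
                                         cp_rrna, mt_rrna)
    attach_tarna_references(refs, tas_reads, rng)
    transcripts = make_transcripts(cfg, rng, genome, genome_truth)
    reads, spec, read_truth = simulate_reads(cfg, plan, rng)
    truth = {
        "genome": genome_truth,
        "organelles": org_truth,
        "species_plan": [
            {"sequence": sp.sequence, "count": sp.count, "class": sp.true_class}
            for sp in plan
        ],
        **read_truth,
    }
    return SynthDataset(cfg, genome, chloroplast, mito, refs, transcripts,
                        reads, spec, truth)


# ---------------------------------------------------------------------------
# Truth-manifest scoring
# ---------------------------------------------------------------------------

def score_recovery(truth: dict, loci) -> dict:
    """Compare novel-miRNA calls with the planted truth, by genomic interval.

    A planted hairpin is recovered when a passing locus overlaps its
    genomic footprint with the expected status (either arm may name the
    locus: when both strands of the duplex were sequenced, the more
    abundant arm is reported as the mature miRNA).  A decoy is correctly
    handled when no passing locus overlaps it — whether it was rejected
    with a reason or filtered out before locus evaluation.
    """
    def overlapping(start, end, statuses):
        out = []
        for l in loci:
            if l.status not in statuses:
                continue
            iv = l.precursor_interval or (l.placement[1], l.placement[2])
            if iv[0] < end and start < iv[1]:
                out.append(l)
        return out

    passing = ("confirmed_mirna", "candidate_mirna")
    per_element = {}
    n_ok = 0
    n_elements = 0
    for el in truth["genome"]["elements"]:
        kind, exp = el["kind"], el["expected"]
        if kind == "tas":
            continue
        n_elements += 1
        hits = overlapping(el["start"], el["end"], passing)
        if kind == "hairpin":
            ok = any(l.status == exp for l in hits) and all(l.status == exp for l in hits)
        else:
            ok = not hits  # decoys must produce no passing call
        per_element[el["name"]] = {
            "expected": exp,
            "observed": sorted({l.status for l in hits}) or ["none"],
            "ok": ok,
        }
        n_ok += ok
    planted_spans = [
        (el["start"], el["end"]) for el in truth["genome"]["elements"]
    ] + [(t["start"], t["end"]) for t in truth["genome"].get("tas", [])]
    false_calls = [
        l for l in loci
        if l.status in passing
        and not any(
            (l.precursor_interval or (l.placement[1], l.placement[2]))[0] < e
            and s < (l.precursor_interval or (l.placement[1], l.placement[2]))[1]
            for s, e in planted_spans
        )
    ]
    return {
        "per_element": per_element,
        "n_elements": n_elements,
        "n_correct": n_ok,
        "false_calls": len(false_calls),
    }


# ---------------------------------------------------------------------------
# Phasing trial generator (register-recovery experiments)
# ---------------------------------------------------------------------------

def simulate_phased_reads(
    rng: np.random.Generator,
    n_phased: int = 12,
    noise_fraction: float = 0.2,
    window: int = 600,
    period: int = 21,
    register: int = 0,
    cleavage: int = 0,
):
    """Mapped reads for one phasing trial: phased sense reads plus uniform noise.

    Returns a list of (pos5, strand, length, count) tuples suitable for
    :func:`srnaome.tasirna.detect_registers`.
    """
    reads = []
    cycles = rng.choice(window // period - 1, size=n_phased, replace=True)
    for c in cycles:
        reads.append((cleavage + register + int(c) * period, "+", period, 1))
    n_noise = int(round(n_phased * noise_fraction / max(1e-9, 1 - noise_fraction)))
    for _ in range(n_noise):
        reads.append((cleavage + int(rng.integers(0, window)), "+", period, 1))
    return reads


def simulate_uniform_reads(rng, n: int = 200, window: int = 600, cleavage: int = 0):
    """Uniform-start mapped reads (no phasing signal)."""
    return [(cleavage + int(p), "+", 21, 1) for p in rng.integers(0, window, size=n)]


# ---------------------------------------------------------------------------
# Dinucleotide shuffle (negative-control genomes)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Eulerian-walk method)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    first, last = seq[0], seq[-1]
    vertices = sorted(set(seq))
    for _ in range(10_000):
        last_edge = {}
        for v in vertices:
            if v == last or not edges[v]:
                continue
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in last_edge:
            cur, seen = v, set()
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover
        raise RuntimeError("dinucleotide shuffle failed to connect")
    out_edges = {}
    for v in vertices:
        lst = list(edges[v])
        if v in last_edge:
            lst.remove(last_edge[v])
        rng.shuffle(lst)
        if v in last_edge:
            lst.append(last_edge[v])
        out_edges[v] = lst[::-1]  # pop() from the end = consume in order
    walk = [first]
    cur = first
    for _ in range(len(seq) - 1):
        nxt = out_edges[cur].pop()
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


# ---------------------------------------------------------------------------
# Packaged fixture tables
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "table1": "library_summary.tsv",
    "table2": "known_mirnas.tsv",
    "table3": "novel_mirna_candidates.tsv",
}

#: guards against accidental edits of the transcribed tables
_FIXTURE_SHA256 = {
    "library_summary.tsv": "09a25808d478d5cdef533d87177669234408b8b946ff09bf171f9b8c30843450",
    "known_mirnas.tsv": "de0743247f6e770db33d77a29fad2f1d67a9676ad0130fa281872fa2e05ae42e",
    "novel_mirna_candidates.tsv": "8aedbc3fbae7002d3708c0ccaa46d48c38b6afa3c2d5b55ae158737c8feb3845",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged summary-table transcription as a typed DataFrame."""
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_FILES)}")
    fname = _FIXTURE_FILES[name]
    ref = resources.files("srnaome.data").joinpath(fname)
    with ref.open("rb") as fh:
        payload = fh.read()
    expected = _FIXTURE_SHA256.get(fname)
    if expected is not None:
        digest = hashlib.sha256(payload).hexdigest()
        if digest != expected:
            raise ValueError(f"fixture {fname} checksum mismatch (edited?)")
    from io import BytesIO

    return pd.read_csv(BytesIO(payload), sep="\t")
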