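# Methods

`srnaome` re-implements, as a tested library, the analysis chain used to
catalogue a plant small-RNA transcriptome from multiplexed 454
pyrosequencing reads: adaptor trimming and barcode demultiplexing,
classification of unique sRNAs against reference collections, known-miRNA
assignment with a population variant rule, novel miRNA discovery by genome
mapping and hairpin evaluation, miRNA target prediction with two scorers,
and phased (ta-si)RNA detection.  This note records the models, the
parameters that matter, and the design choices made where the procedure
was genuinely open.

## Read processing

Raw reads have the anatomy `5'-adaptor-variant + insert + 3'-adaptor +
tail` (~100 bases).  The ten 5'-adaptor variants embed a four-base library
barcode; because the variants differ over a multi-base window, whole
variants are matched as read prefixes rather than isolated 4-mers, which
is unambiguous.  The 3' adaptor (`CTGTAGGCACCATCAAT`) is located as the
leftmost full-length ungapped occurrence downstream.  Default mismatch
tolerance is 1 per adaptor (configurable); reads tying two variants at the
minimal mismatch count are `ambiguous_barcode`, and a 5' variant
immediately followed by the 3' adaptor is an adaptor-dimer artifact.

**Error rate.**  Adaptors are known sequence, so substitutions observed in
located adaptor copies estimate the per-base substitution rate directly:
`rate = mismatches / adaptor bases inspected`, with location performed at
an inspection ceiling of 3 mismatches so that errors beyond the working
tolerance remain countable.  Truncation at the ceiling biases the
estimate down by < 0.002 at a true rate of 5%; the estimator recovers
rates of 1–5% to within ±0.005 on 10,000 simulated reads.

## Classification cascade

Queries of 18–30 nt are compared with each reference set by an exact
full-length ungapped scan over both strands allowing ≤ 2 substitutions —
for words this short, exactly the computation a BLAST search approximates,
but deterministic and dependency-free.  An sRNA's category is the first
hit in a configurable precedence order (miRNA → taRNA → tRNA → snoRNA →
rRNA subunits → transposon → organelles → viruses); all hits are retained
so per-category totals (as unique sequences *and* as reads) are
independent of the tie-break.

**Known miRNAs.**  Each sRNA hitting the miRNA reference is named after
its fewest-mismatch reference, with similarity printed as an integer
percentage (`100·(L−mm)/L`, truncated — 1 mismatch over 21 nt prints 95).
Within each reference's read population, non-identical sequences are kept
as distinct variants only when they exceed **3% of the population**
(strict inequality: exactly 3% merges); sub-threshold variants merge into
the exact species as presumed sequencing errors, conserving read totals.
Expression is normalized to reads per 10,000 library reads.

## Hairpin folding and MFEI

The folding engine performs a minimum-energy search restricted to single
stem-loops: nested Watson–Crick/G:U pairs with bulges and internal loops
(≤ 30 unpaired bases per loop) closed by one terminal loop of ≥ 3 nt; no
multibranch loops or pseudoknots.  The energy model is a simplified
nearest-neighbour sum — bond terms per pair (G:C −3.4, A:T −2.2, G:T −1.1
kcal/mol), a −1.0 stacking bonus for directly stacked pairs, and affine
loop penalties (hairpin 4.0 + 0.25/nt, interior 2.5 + 0.45/nt).  A full
thermodynamic parameterization is deliberately out of proportion here:
precursor selection is driven by the *ordering* of the MFE index, not by
absolute kcal/mol, and the engine is pluggable (anything returning a
`FoldResult` can replace it).  The dynamic program is verified against
exhaustive enumeration of all nested structures for sequences ≤ 14 nt.

For a precursor of length L, `AMFE = 100·MFE/L` and `MFEI = AMFE / GC%`.
The default MFEI ceiling is **−0.85**, chosen because the
smallest-magnitude MFEI among the study's accepted precursors is −0.8587.

**Duplexes.**  Given a fold and a mature-miRNA span, the star span is the
pairing region extended so each strand's 3' end overhangs its partner's 5'
end; with a caller-supplied (sequenced) star the overhangs are measured
from the actual geometry.  A duplex is *typical* iff both 3' overhangs are
exactly 2 nt.  Structural criteria for annotating a locus: precursor
≥ 70 nt, ≤ 4 duplex mismatches, MFEI ≤ −0.85, asymmetric bulge ≤ 2 nt
(strict) or 3 nt (relaxed class).

## Novel miRNA discovery

Cascade-unmatched sRNAs of 21/22/24 nt with 1–6 exact genome hits are
candidate mature sequences.  For each placement, 600 nt on each side is
scanned for a miRNA* site with the target-prediction aligner run
*without* seed scaling (a star must pair along its whole length) and a
length-relative threshold of `5·L − 20` (≈ 2 mismatches of slack).  The
smallest region covering the sRNA and its star is the precursor (≥ 70 nt).
Exclusions: (a) similarity of the precursor region to transposon/coding
sets — short elements by a ≤ 2-mismatch scan, long elements by a shared
exact 20-mer; (b) ≥ 10 distinct sRNAs mapping antisense over the precursor
± 150 nt (the foldback-transposon signature); (c) the sRNA being
duplex-consistent with a known miRNA (≤ 3 non-pairing positions, end
offsets ≤ 2 nt) — it is that miRNA's star, not a novel gene.  Surviving
loci are folded and checked; a locus whose predicted star arm is matched
by a sequenced read (near-identity, ≤ 2 substitutions, end offsets ≤ 4 nt,
≥ 15 nt overlap) is a **confirmed** miRNA, otherwise a **candidate**.
When both arms were sequenced, the locus is reported once under its more
abundant arm.  Output is sorted by MFEI ascending.

The coding-sequence exclusion is nucleotide-level against a user-supplied
FASTA; translated six-frame search is out of scope.

## Target prediction

Two independent scorers run over every (miRNA, transcript, orientation):

* **Alignment score S** — the miRNA's reverse complement aligned to the
  transcript (global in the miRNA, local in the transcript, bulges ≤ 3 nt
  with affine cost 9 + 4/nt): match +5, G:U +2, mismatch −3, with columns
  at miRNA positions 2–7 scaled ×4.  A perfect 21-nt site scores 195 and
  a perfect 22-nt site 200, matching the score scale on which the
  operative reporting cutoff **S ≥ 170** was defined.
* **Penalty P** — mismatch 1, G:U 0.5, bulged base 1, doubled at miRNA
  positions 2–13, reported to halves; perfect = 0, cutoff **P ≤ 4**.

A site is reported when either scorer accepts it (union), with both values
carried.  Position numbering is 1-based from the miRNA 5' end;
`clean_9_11` flags sites with perfect pairing at positions 9–11 (the
slicing window).  Transcripts with two sites for one miRNA family are
flagged dual-site with the summed score and inter-site distance.
Bit-compatibility with any historical scoring binary is a non-goal; the
parameters were calibrated once so that perfect complements land on the
published score scale.

## ta-siRNA phasing

Cleavage is inferred between the transcript bases pairing miRNA positions
10 and 11 (bulges there make it ambiguous).  Each mapped read's register
is its 5'-end residue modulo the 21-nt period — antisense 5' ends shifted
by 2 nt for the DCL duplex overhang — with ±1 nt jitter.  Register calling
is claim-and-remove peak picking: registers are visited by exact-residue
read count, each claiming its jitter window of unclaimed reads, and a
claimed register is *occupied* when it has ≥ 3 reads over ≥ 3 distinct
cycles **and** its support beats a uniform-start background at a binomial
tail of 10⁻³ (success probability 3/21).  The absolute thresholds alone
cannot separate a phased register from a dense unphased read cloud — 200
uniform starts put ~28 reads in every jitter window — so the enrichment
test is what carries the specificity (family-wise false-register rate ≈ 2%
over the 21 registers).  Dual-site transcripts whose inter-site region
recruits ≥ 3 mapped sRNAs are analysed from both cleavage sites; genomic
windows (± 600 nt around an anchor) are analysed relative to the anchor,
which is equivalent to trying all phase offsets.

## Synthetic data

The generator emulates the study's inputs at desk scale from one seed:

* **Libraries/reads** — ten barcoded libraries with the study's relative
  sizes, ~10,200 reads total, per-base substitution error 0.037 (the
  study's estimated rate), adaptor-dimer (0.5%) and missing-3'-adaptor
  (2%) artifacts, and log-uniform abundance skew on [1, 10⁴] mimicking the
  extreme observed skew (one dominant miRNA species ≫ singletons).
* **Genome (200 kb)** — ten conforming hairpins (5 with sequenced stars →
  expected confirmed, 5 without → expected candidate; miRNA lengths
  21/22/24), plus eight decoys in four classes: transposon-like (precursor
  present in the transposon reference), foldback (near-perfect 60-bp
  inverted repeat with a dense sense+antisense siRNA cloud),
  short-precursor (< 70 nt), and multi-copy (7 genome occurrences,
  exceeding the 6-hit cap).  Hairpins are verified at generation time with
  the pipeline's own folding, criteria and star-recovery machinery.
* **TAS locus** — two identical miR390 complementary sites ~210 nt apart,
  each with G:U wobbles at miRNA positions 12/15 and a mismatch at 18
  (clean 9–11; S = 181 per site, so the dual-site total is 362 and the
  penalty 2.5), with two interleaved phased registers (the
  cleavage-anchored one and one at +10) in sense and antisense, ≥ 92% of
  reads 21 nt.
* **Organelles** — a 12-kb plastid genome with an rRNA span duplicated as
  an inverted repeat (mirrored sense/antisense clusters) and an abundant
  intergenic sRNA; an 8-kb mitochondrial genome with one rRNA region.
* **Negative control** — an exact-dinucleotide-count shuffle
  (Eulerian-walk method) of the genome; the same reads on the shuffled
  genome must yield ≤ 1 spurious call.

Planted novel miRNAs carry 15 reads and stars 6, giving the error channel
(54% chance a given read acquires ≥ 1 substitution in its insert)
head-room so every planted mature sequence is observed error-free; the
study's novel miRNAs were often singletons, so recovery rates measured
here say nothing about singleton sensitivity under sequencing error.
Other real-data features the generator does not emulate: 454 homopolymer
indel errors (substitutions only), quality values, spliced transcripts,
and genuine genomic repeat families beyond the planted decoys.

Transcriptions of the study's printed summary tables (libraries, 46 known
miRNA species, 84 novel candidates) are packaged as TSV fixtures with
SHA-256 guards; `load_fixture` returns typed DataFrames.

## Problem sizes and determinism

Default test and acceptance runs use the 200-kb genome, ~10,200 reads and
200-trial phasing experiments; the full suite runs in about a minute and
`scripts/acceptance.py` in under two.  Every stochastic component draws
from a NumPy generator seeded from the single run seed, so all outputs are
byte-identical across runs with the same seed.

## Known limitations

* The fold model's energies are on a simplified scale; MFEI values are
  comparable within this engine but not numerically interchangeable with
  thermodynamic folders.
* Family counting for known miRNAs follows the unprefixed-annotation
  convention of the summary table; other tallying conventions would give
  different family totals.
* Exactly reproducing the original study's 77-strict/7-relaxed precursor
  split would require its unpublished genome and its manual-inspection
  step; the codified criteria replace that inspection.
* The antisense-offset convention for phasing (2 nt) and the jitter (±1)
  are configurable; other conventions shift register labels by a constant.
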