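"""End-to-end orchestration of the sRNA-ome analysis stages.

Stage order follows the analysis narrative: demultiplex/trim -> collapse ->
classification cascade -> known-miRNA assignment (with the population
variant rule and per-10,000 normalization) -> novel-miRNA discovery ->
target prediction -> ta-siRNA phasing -> organelle profiling.  Each stage's
outputs are plain data objects collected into a :class:`RunReport`, whose
counts are internally consistent (status partitions sum to the input
sizes).
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from . import annotate, novel, readproc, targets, tasirna
from .core import UniqueSRNA, collapse_reads, length_histogram
from .synth import SynthDataset


@dataclass
class RunReport:
    """Aggregated per-stage results and provenance of one pipeline run."""

    seed: int | None = None
    config_hash: str = ""
    demux_counts: dict[str, int] = field(default_factory=dict)
    error_rate: float | None = None
    n_raw_reads: int = 0
    n_useful_reads: int = 0
    n_unique_srnas: int = 0
    srnas: list = field(default_factory=list, repr=False)
    length_hist_redundant: dict[int, float] = field(default_factory=dict)
    length_hist_unique: dict[int, float] = field(default_factory=dict)
    category_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    known_assignments: list = field(default_factory=list)
    known_expression: list = field(default_factory=list)
    known_duplexes: dict[str, list] = field(default_factory=dict)
    novel_loci: list = field(default_factory=list)
    target_reports: list = field(default_factory=list)
    tas_candidates: list = field(default_factory=list)
    genomic_phasing: list = field(default_factory=list)
    organelle_profiles: dict[str, object] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        status = Counter(l.status for l in self.novel_loci)
        return {
            "raw_reads": self.n_raw_reads,
            "useful_reads": self.n_useful_reads,
            "unique_srnas": self.n_unique_srnas,
            "error_rate": self.error_rate,
            "demux": dict(self.demux_counts),
            "known_mirna_species": len(self.known_assignments),
            "known_mirna_families": len({a.family for a in self.known_assignments}),
            "novel_status": dict(status),
            "target_transcripts": len({r.transcript_id for r in self.target_reports}),
            "tas_candidates": len(self.tas_candidates),
        }


def run_pipeline(
    dataset: SynthDataset,
    classifier_cfg: annotate.ClassifierConfig | None = None,
    novel_cfg: novel.NovelConfig | None = None,
    scoring: targets.ScoringParams | None = None,
    penalties: targets.PenaltyParams | None = None,
    phasing_cfg: tasirna.PhasingConfig | None = None,
    variant_threshold: float = 0.03,
) -> RunReport:
    """Run every stage over an in-memory dataset (synthetic or loaded)."""
    classifier_cfg = classifier_cfg or annotate.ClassifierConfig()
    novel_cfg = novel_cfg or novel.NovelConfig()
    scoring = scoring or targets.ScoringParams()
    penalties = penalties or targets.PenaltyParams()
    phasing_cfg = phasing_cfg or tasirna.PhasingConfig()

    report = RunReport(seed=getattr(dataset.config, "seed", None))
    report.config_hash = hashlib.sha256(
        json.dumps(str(dataset.config), sort_keys=True).encode()
    ).hexdigest()[:16]

    # --- stage 1: demultiplex and trim
    results = [readproc.demultiplex_and_trim(r, dataset.adaptor_spec) for r in dataset.reads]
    useful, manifest = readproc.filter_useful(results)
    report.demux_counts = manifest
    report.n_raw_reads = len(results)
    report.n_useful_reads = len(useful)
    report.error_rate = readproc.estimate_error_rate(results, dataset.adaptor_spec)

    # --- stage 2: collapse
    srnas = collapse_reads((insert, lib) for lib, insert in useful)
    srnas = [s for s in srnas if set(s.sequence) <= set("ACGT")]
    report.srnas = srnas
    report.n_unique_srnas = len(srnas)
    report.length_hist_redundant = length_histogram(srnas, weighted=True, as_percent=True)
    report.length_hist_unique = length_histogram(srnas, weighted=False, as_percent=True)
    library_totals: dict[str, int] = defaultdict(int)
    for s in srnas:
        for lib, c in s.counts.items():
            library_totals[lib] += c

    # --- stage 3: classification cascade
    refsets = [annotate.ReferenceSet(cat, recs) for cat, recs in dataset.references.items()]
    classified = []
    for s in srnas:
        cat, hits = annotate.classify_cascade(s, refsets, classifier_cfg)
        classified.append((s, cat, hits))
    report.category_counts = annotate.category_tallies(classified)

    # --- stage 4: known miRNAs
    mirna_refset = next((rs for rs in refsets if rs.category == "miRNA"), None)
    if mirna_refset is not None:
        mirna_srnas = [s for s, cat, _h in classified if cat == "miRNA"]
        assignments = annotate.assign_known_mirnas(mirna_srnas, mirna_refset, classifier_cfg)
        assignments = annotate.variant_filter(assignments, variant_threshold)
        report.known_assignments = assignments
        report.known_expression = [
            annotate.expression_profile(a.reference_id, a.srna.counts, dict(library_totals))
            for a in assignments
        ]
        # sequenced miRNA* species for each assigned miRNA
        from .hairpin import find_star_in_reads

        for a in assignments:
            stars = find_star_in_reads(a.srna, srnas)
            if stars:
                report.known_duplexes[a.reference_id] = stars

    # --- stage 5: novel miRNA discovery
    index = novel.GenomeIndex([dataset.genome])
    unclassified = [s for s, cat, _h in classified if cat == "unclassified"]
    exclusions = {"transposon": dataset.references.get("transposon", [])}
    known_recs = dataset.references.get("miRNA", [])
    report.novel_loci = novel.call_candidates(
        unclassified, index, novel_cfg, all_srnas=srnas,
        exclusion_sets=exclusions, known_mirnas=known_recs,
    )

    # --- stage 6: target prediction
    if dataset.transcripts:
        report.target_reports = targets.scan_transcriptome(
            known_recs, dataset.transcripts, scoring, penalties
        )
    else:
        report.skipped.append("targets")

    # --- stage 7: ta-siRNA phasing
    if dataset.transcripts:
        tx_by_id = {t.id: t for t in dataset.transcripts}
        report.tas_candidates = tasirna.find_dual_site_tas(
            report.target_reports, tx_by_id, srnas, phasing_cfg
        )
    else:
        report.skipped.append("phasing")
    # genomic phasing around ta-siRNA-classified anchors
    ta_anchors = []
    for s, cat, _h in classified:
        if cat == "taRNA":
            for _c, start, _e, _s in index.placements(s.sequence)[:1]:
                ta_anchors.append(start)
    for anchor in sorted(set(ta_anchors))[:3]:
        report.genomic_phasing.append(
            tasirna.scan_genomic_phasing(dataset.genome, anchor, srnas, phasing_cfg)
        )

    # --- stage 8: organelle profiling
    for organelle in (dataset.chloroplast, dataset.mitochondrion):
        if organelle is not None:
            report.organelle_profiles[organelle.id] = annotate.organelle_profile(
                srnas, organelle
            )
    return report


def validate_dataset(dataset: SynthDataset) -> list[str]:
    """Structural problems that would prevent a pipeline run (empty = runnable)."""
    problems = []
    if not dataset.reads:
        problems.append("no reads")
    if dataset.genome is None or not dataset.genome.sequence:
        problems.append("missing genome")
    if not dataset.references:
        problems.append("no reference sets")
    if dataset.adaptor_spec.max_mismatches_3p < 0 or dataset.adaptor_spec.max_mismatches_5p < 0:
        problems.append("negative adaptor mismatch tolerance")
    return problems
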