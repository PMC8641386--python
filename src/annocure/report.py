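"""Pipeline orchestration and summary tables.

Wires the post-prediction workflow end to end — validate → curate
(split/merge) → rescue → TE-label → rename → version-map → AS-classify —
and renders the summary tables: an AS table (event totals with canonical
and UTR percentages) and a versions table (raw genes, interrupted ORFs,
putative TEs, total correct).  All percentages go through
:func:`annocure.version_map.percent`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .curate import CurationConfig, CurationLog, curate
from .gff3 import (
    RepeatFeature,
    read_evidence_gff3,
    read_gff3,
    read_repeats_gff3,
    write_gff3,
)
from .model import AnnotationSet, EvidenceAlignment, read_fasta
from .naming import NamingScheme, assign_locus_names, write_mapping_tsv
from .repeats_te import TEConfig, label_putative_tes, read_domains_tsv, write_te_summary_tsv
from .splice_events import (
    ASEvent,
    SpliceSiteRules,
    annotate_events,
    group_loci,
    write_events_tsv,
)
from .validate import validate_set, write_report_tsv
from .version_map import map_versions, percent, summarize_mapping, write_map_tsv


@dataclass
class RunConfig:
    gff: str | Path
    fasta: str | Path
    evidence: str | Path | None = None
    prior: str | Path | None = None
    repeats: str | Path | None = None
    domains: str | Path | None = None
    isoforms: str | Path | None = None
    out_dir: str | Path = "annocure_out"
    curation: CurationConfig = field(default_factory=CurationConfig)
    splice_rules: SpliceSiteRules = field(default_factory=SpliceSiteRules)
    naming: NamingScheme = field(default_factory=NamingScheme)
    te: TEConfig = field(default_factory=TEConfig)
    treat_incomplete_as_errors: bool = True


@dataclass
class ReportBundle:
    validation_summary: dict
    curation_counts: dict
    te_summary: dict
    naming_map_size: int
    version_map_summary: dict
    as_table: dict | None
    versions_table: dict

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def build_as_table(events: list[ASEvent]) -> dict:
    """AS summary row: totals, canonical and UTR counts with percentages.

    "Classified" means one of the five elementary types (ES/AA/AD/MX/IR);
    COMPLEX events count only toward the totals.
    """
    classified_types = {"ES", "AA", "AD", "MX", "IR"}
    total = len(events)
    canonical = sum(1 for e in events if e.canonical)
    classified = [e for e in events if e.event_type in classified_types]
    classified_canonical = sum(1 for e in classified if e.canonical)
    canonical_utr = sum(1 for e in events if e.canonical and e.in_utr)
    return as_table_from_counts(
        total, canonical, len(classified), classified_canonical, canonical_utr
    )


def as_table_from_counts(
    total: int,
    canonical: int,
    classified: int,
    classified_canonical: int,
    canonical_utr: int | None = None,
) -> dict:
    row = {
        "total_events": total,
        "canonical": canonical,
        "canonical_percent": percent(canonical, total, 1) if total else 0.0,
        "classified": classified,
        "classified_canonical": classified_canonical,
        "classified_canonical_percent": (
            percent(classified_canonical, classified, 1) if classified else 0.0
        ),
    }
    if canonical_utr is not None:
        row["canonical_in_utr"] = canonical_utr
        row["canonical_in_utr_percent"] = (
            percent(canonical_utr, canonical, 1) if canonical else 0.0
        )
    return row


def build_versions_table(
    raw_genes: int, interrupted_orfs: int, putative_tes: int
) -> dict:
    """One column of the version-comparison table; totals reconcile by
    construction: correct-in-GFF = raw − interrupted, total-correct =
    correct-in-GFF − putative TEs."""
    correct_in_gff = raw_genes - interrupted_orfs
    return {
        "raw_genes": raw_genes,
        "interrupted_orfs": interrupted_orfs,
        "correct_in_gff": correct_in_gff,
        "putative_tes": putative_tes,
        "total_correct": correct_in_gff - putative_tes,
    }


def run_pipeline(config: RunConfig):
    """Execute the full curation workflow; returns (final set, report bundle).

    Stage outputs are written under ``config.out_dir``.  The curation log's
    bookkeeping identity is asserted inside :func:`annocure.curate.curate`.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    genome = stage("load-fasta", read_fasta, config.fasta)
    annotation = stage("load-gff", read_gff3, config.gff, "lenient")

    reports, summary = stage("validate", validate_set, annotation, genome)
    write_report_tsv(reports, out_dir / "validation.tsv")

    evidences: list[EvidenceAlignment] = []
    if config.evidence:
        evidences = stage("load-evidence", read_evidence_gff3, config.evidence)
    prior = None
    if config.prior:
        prior = stage("load-prior", read_gff3, config.prior, "lenient")

    curated, log = stage(
        "curate", curate, annotation, evidences, prior, genome, config.curation
    )
    log.write_tsv(out_dir / "actions.tsv")

    repeats: list[RepeatFeature] = []
    if config.repeats:
        repeats = stage("load-repeats", read_repeats_gff3, config.repeats)
    domains = read_domains_tsv(config.domains) if config.domains else {}
    labeled, te_summary = stage(
        "te-label", label_putative_tes, curated, repeats, domains, config.te
    )
    write_te_summary_tsv(te_summary, out_dir / "te_summary.tsv")

    renamed, mapping = stage("rename", assign_locus_names, labeled, config.naming)
    write_mapping_tsv(mapping, out_dir / "idmap.tsv")
    write_gff3(renamed, out_dir / "curated.gff3")

    vm_summary_dict: dict = {}
    if prior is not None:
        entries = stage("version-map", map_versions, prior, renamed)
        write_map_tsv(entries, out_dir / "version_map.tsv")
        prior_reports, _ = validate_set(prior, genome)
        vm_summary = summarize_mapping(entries, prior_reports)
        vm_summary_dict = {
            "counts_by_relation": vm_summary.counts_by_relation,
            "mapped_old": vm_summary.mapped_old,
            "mapped_old_percent": vm_summary.mapped_old_percent,
            "novel_new": vm_summary.novel_new,
            "broken_recovered": vm_summary.broken_recovered,
        }

    as_table = None
    if config.isoforms:
        iso_set = stage("load-isoforms", read_gff3, config.isoforms, "lenient")
        transcripts = [t for g in iso_set for t in g.transcripts]
        loci = stage("as-classify", group_loci, transcripts)
        events = annotate_events(loci, genome, config.splice_rules)
        write_events_tsv(events, out_dir / "as_events.tsv")
        as_table = build_as_table(events)

    te_labels = {g.gene_id for g in labeled if g.attributes.get("putative_te") == "true"}
    versions_table = build_versions_table(
        raw_genes=len(renamed),
        interrupted_orfs=sum(1 for r in reports if r.flags),
        putative_tes=len(te_labels),
    )
    bundle = ReportBundle(
        validation_summary={
            "n_genes": summary.n_genes,
            "n_flagged": summary.n_flagged,
            "per_flag": {f.value: n for f, n in summary.per_flag.items() if n},
        },
        curation_counts=log.counts(),
        te_summary={
            "n_labeled": te_summary.n_labeled,
            "by_coverage": te_summary.n_by_coverage,
            "by_domain": te_summary.n_by_domain,
            "by_category": te_summary.by_sequence_category,
        },
        naming_map_size=len(mapping),
        version_map_summary=vm_summary_dict,
        as_table=as_table,
        versions_table=versions_table,
    )
    (out_dir / "report.json").write_text(bundle.to_json() + "\n")
    return renamed, bundle


__all__ = [
    "RunConfig",
    "ReportBundle",
    "StageError",
    "run_pipeline",
    "build_as_table",
    "as_table_from_counts",
    "build_versions_table",
]
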