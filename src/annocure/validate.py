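"""Structural validation of gene models.

Detects the error classes that make a predicted gene model unusable as
evidence: missing exon/CDS features, coding length not a multiple of three,
premature (internal) stop codons, missing start or terminal stop codons, and
coordinate problems (out of sequence bounds, CDS outside exons).  A gene
with an empty flag set counts as "correct"; an incomplete gene (missing
start/stop only) can optionally be kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

from .model import (
    AnnotationSet,
    GeneModel,
    PartialCodonWarning,
    extract_spliced_sequence,
    translate,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}


class ValidationFlag(str, Enum):
    MISSING_FEATURE = "MISSING_FEATURE"
    CDS_NOT_MULTIPLE_OF_THREE = "CDS_NOT_MULTIPLE_OF_THREE"
    PREMATURE_STOP = "PREMATURE_STOP"
    MISSING_START = "MISSING_START"
    MISSING_STOP = "MISSING_STOP"
    OUT_OF_BOUNDS = "OUT_OF_BOUNDS"
    CDS_OUTSIDE_EXON = "CDS_OUTSIDE_EXON"


#: flags that mark an incomplete—but not otherwise broken—gene model
INCOMPLETE_FLAGS = {ValidationFlag.MISSING_START, ValidationFlag.MISSING_STOP}


@dataclass
class ValidationReport:
    gene_id: str
    flags: set[ValidationFlag] = field(default_factory=set)
    details: dict[ValidationFlag, str] = field(default_factory=dict)

    @property
    def is_clean(self) -> bool:
        return not self.flags

    def passes(self, treat_incomplete_as_errors: bool = True) -> bool:
        effective = (
            self.flags if treat_incomplete_as_errors else self.flags - INCOMPLETE_FLAGS
        )
        return not effective


def check_gene(gene: GeneModel, genome: dict[str, str]) -> ValidationReport:
    """Validate one gene against the genome; flags any-transcript failures."""
    if gene.seq_id not in genome:
        raise KeyError(f"genome lacks sequence {gene.seq_id} for gene {gene.gene_id}")
    seq_len = len(genome[gene.seq_id])
    report = ValidationReport(gene_id=gene.gene_id)

    def add(flag: ValidationFlag, message: str) -> None:
        report.flags.add(flag)
        if flag in report.details:
            report.details[flag] += "; " + message
        else:
            report.details[flag] = message

    if not gene.transcripts:
        add(ValidationFlag.MISSING_FEATURE, "gene has no transcripts")
        return report

    for t in gene.transcripts:
        if not t.exons or not t.cds_segments:
            missing = []
            if not t.exons:
                missing.append("exons")
            if not t.cds_segments:
                missing.append("CDS")
            add(
                ValidationFlag.MISSING_FEATURE,
                f"{t.transcript_id} lacks {' and '.join(missing)}",
            )
            continue

        structural_ok = True
        for part in t.exons + t.cds_segments:
            if part.start < 0 or part.end > seq_len:
                add(
                    ValidationFlag.OUT_OF_BOUNDS,
                    f"{t.transcript_id} segment [{part.start},{part.end}) outside "
                    f"{gene.seq_id} (length {seq_len})",
                )
                structural_ok = False
        for cds in t.cds_segments:
            if not any(exon.contains(cds) for exon in t.exons):
                add(
                    ValidationFlag.CDS_OUTSIDE_EXON,
                    f"{t.transcript_id} CDS [{cds.start},{cds.end}) not inside an exon",
                )
        if not structural_ok:
            continue

        cds_len = t.cds_length
        if cds_len % 3 != 0:
            add(
                ValidationFlag.CDS_NOT_MULTIPLE_OF_THREE,
                f"{t.transcript_id} CDS length {cds_len} mod 3 = {cds_len % 3}",
            )
        cds_seq = extract_spliced_sequence(t, genome, which="cds")
        if len(cds_seq) < 3:
            add(ValidationFlag.MISSING_START, f"{t.transcript_id} CDS shorter than one codon")
            continue
        if cds_seq[:3] != "ATG":
            add(ValidationFlag.MISSING_START, f"{t.transcript_id} first codon {cds_seq[:3]}")
        n_codons = len(cds_seq) // 3
        final_codon = cds_seq[(n_codons - 1) * 3 : n_codons * 3]
        if final_codon not in STOP_CODONS:
            add(ValidationFlag.MISSING_STOP, f"{t.transcript_id} final codon {final_codon}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PartialCodonWarning)
            protein = translate(cds_seq)
        internal = protein[:-1] if protein else ""
        if "*" in internal:
            add(
                ValidationFlag.PREMATURE_STOP,
                f"{t.transcript_id} internal stop at codon {internal.index('*') + 1}",
            )
    return report


@dataclass
class ValidationSummary:
    n_genes: int
    n_flagged: int
    per_flag: dict[ValidationFlag, int]

    @property
    def n_clean(self) -> int:
        return self.n_genes - self.n_flagged


def validate_set(
    annotation_set: AnnotationSet, genome: dict[str, str]
) -> tuple[list[ValidationReport], ValidationSummary]:
    """One report per gene plus summary counts."""
    reports = [check_gene(gene, genome) for gene in annotation_set]
    per_flag: dict[ValidationFlag, int] = {flag: 0 for flag in ValidationFlag}
    n_flagged = 0
    for report in reports:
        if report.flags:
            n_flagged += 1
        for flag in report.flags:
            per_flag[flag] += 1
    return reports, ValidationSummary(
        n_genes=len(reports), n_flagged=n_flagged, per_flag=per_flag
    )


def export_clean(
    annotation_set: AnnotationSet,
    reports: list[ValidationReport],
    treat_incomplete_as_errors: bool = True,
) -> AnnotationSet:
    """Subset of genes whose reports pass, in the original order.

    With ``treat_incomplete_as_errors=False``, genes whose only flags are
    MISSING_START/MISSING_STOP are kept (the strict default excludes them,
    matching an evidence-grade filter).
    """
    by_id = {r.gene_id: r for r in reports}
    missing = [g.gene_id for g in annotation_set if g.gene_id not in by_id]
    extra = [gid for gid in by_id if gid not in annotation_set]
    if missing or extra:
        raise ValueError(
            f"reports do not match annotation set (missing {missing}, extra {extra})"
        )
    clean = AnnotationSet(version_tag=annotation_set.version_tag)
    for gene in annotation_set:
        if by_id[gene.gene_id].passes(treat_incomplete_as_errors):
            clean.add(gene)
    return clean


def write_report_tsv(reports: list[ValidationReport], path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\tn_flags\tflags\tdetails\n")
        for r in reports:
            flags = sorted(f.value for f in r.flags)
            details = " | ".join(
                f"{f.value}: {r.details[f]}" for f in sorted(r.flags, key=lambda x: x.value)
            )
            handle.write(f"{r.gene_id}\t{len(r.flags)}\t{','.join(flags)}\t{details}\n")
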