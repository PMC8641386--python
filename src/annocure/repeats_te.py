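"""Putative transposable-element gene labeling.

A gene is labeled a putative TE when repeat annotation covers at least half
of its genomic span (strand-agnostic), or when it carries a protein domain
from the TE-associated Pfam families (reverse transcriptase, integrase,
retrotransposon, LTR).  Both criteria are reported separately; labeling
only touches gene attributes, never structures.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

from .gff3 import RepeatFeature
from .model import AnnotationSet, GeneModel, intersect_union_length

#: Pfam families treated as diagnostic for transposable elements:
#: reverse transcriptase, integrase, retrotransposon and LTR domains.
TE_PFAM_DOMAINS: frozenset[str] = frozenset(
    {
        "PF00078", "PF07727", "PF13456", "PF13966",  # reverse transcriptase
        "PF00665", "PF13976",  # integrase
        "PF03732", "PF08284",  # retrotransposon
        "PF14223", "PF14244",  # LTR
    }
)

_PFAM_RE = re.compile(r"^PF\d{5}$")


@dataclass
class TEConfig:
    coverage_threshold: float = 0.5
    te_domains: frozenset[str] = TE_PFAM_DOMAINS
    lg_pattern: str = r"LG(\d+)"
    scaffold_pattern: str = r"(?:sc|scaffold)_?(\d+)"

    def __post_init__(self) -> None:
        if not (0 < self.coverage_threshold <= 1):
            raise ValueError("coverage_threshold must be in (0, 1]")
        bad = [d for d in self.te_domains if not _PFAM_RE.match(d)]
        if bad:
            raise ValueError(f"invalid Pfam accessions: {bad}")


def te_coverage(gene: GeneModel, repeats: list[RepeatFeature]) -> float:
    """Fraction of the gene span covered by the union of repeat intervals."""
    span = gene.span
    if span.length == 0:
        raise ValueError(f"gene {gene.gene_id} has zero-length span")
    blocks = [
        (r.interval.start, r.interval.end)
        for r in repeats
        if r.interval.seq_id == span.seq_id
    ]
    return intersect_union_length([(span.start, span.end)], blocks) / span.length


@dataclass
class TESummary:
    n_genes: int
    n_labeled: int
    n_by_coverage: int
    n_by_domain: int
    n_by_both: int
    by_sequence_category: dict[str, int] = field(default_factory=dict)


def read_domains_tsv(path) -> dict[str, set[str]]:
    """Read gene→Pfam assignments from a TSV (gene_id, pfam_accession, ...)."""
    assignments: dict[str, set[str]] = {}
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "gene_id":
                continue
            assignments.setdefault(row[0], set()).add(row[1])
    return assignments


def label_putative_tes(
    annotation_set: AnnotationSet,
    repeats: list[RepeatFeature],
    domain_assignments: dict[str, set[str]] | None = None,
    config: TEConfig | None = None,
) -> tuple[AnnotationSet, TESummary]:
    """OR-combine the coverage and domain criteria into ``putative_te`` labels."""
    config = config or TEConfig()
    domain_assignments = domain_assignments or {}
    lg_re = re.compile(config.lg_pattern)
    sc_re = re.compile(config.scaffold_pattern)
    n_cov = n_dom = n_both = n_labeled = 0
    category_counts: dict[str, int] = {"LG": 0, "scaffold": 0, "other": 0}
    labeled = AnnotationSet(version_tag=annotation_set.version_tag)
    for gene in annotation_set:
        coverage = te_coverage(gene, repeats)
        by_cov = coverage >= config.coverage_threshold
        by_dom = bool(domain_assignments.get(gene.gene_id, set()) & config.te_domains)
        attrs = dict(gene.attributes)
        if by_cov or by_dom:
            n_labeled += 1
            n_cov += by_cov
            n_dom += by_dom
            n_both += by_cov and by_dom
            attrs["putative_te"] = "true"
            attrs["te_coverage"] = f"{coverage:.3f}"
            if lg_re.search(gene.seq_id):
                category_counts["LG"] += 1
            elif sc_re.search(gene.seq_id):
                category_counts["scaffold"] += 1
            else:
                category_counts["other"] += 1
        labeled.add(
            GeneModel(
                gene_id=gene.gene_id,
                span=gene.span,
                transcripts=gene.transcripts,
                attributes=attrs,
            )
        )
    summary = TESummary(
        n_genes=len(annotation_set),
        n_labeled=n_labeled,
        n_by_coverage=n_cov,
        n_by_domain=n_dom,
        n_by_both=n_both,
        by_sequence_category=category_counts,
    )
    return labeled, summary


def write_te_summary_tsv(summary: TESummary, path) -> None:
    with open(path, "w") as handle:
        handle.write("metric\tcount\n")
        handle.write(f"genes_total\t{summary.n_genes}\n")
        handle.write(f"putative_te_total\t{summary.n_labeled}\n")
        handle.write(f"by_coverage\t{summary.n_by_coverage}\n")
        handle.write(f"by_domain\t{summary.n_by_domain}\n")
        handle.write(f"by_both\t{summary.n_by_both}\n")
        for category, count in summary.by_sequence_category.items():
            handle.write(f"in_{category}\t{count}\n")
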