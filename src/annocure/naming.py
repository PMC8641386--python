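"""Systematic locus nomenclature.

Locus names follow ``<prefix><version><LG|sc><seq-number>G<gene-number>``,
e.g. ``Aa31LG1G10`` for the first gene on linkage group 1 of annotation
version 3.1.  Numbering starts at 10 at the left (5') end of each linkage
group or scaffold and increases by 10 per gene, leaving free numbers for
future insertions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .model import AnnotationSet, GeneModel, TranscriptModel


class NamingError(Exception):
    pass


@dataclass
class NamingScheme:
    species_prefix: str = "Aa"
    version_digits: str = "31"
    lg_pattern: str = r"LG(\d+)"
    scaffold_pattern: str = r"(?:sc|scaffold)_?(\d+)"
    start_number: int = 10
    step: int = 10

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be ≥ 1")

    def sequence_label(self, seq_id: str) -> str:
        lg = re.search(self.lg_pattern, seq_id)
        sc = re.search(self.scaffold_pattern, seq_id)
        if lg and sc:
            raise NamingError(
                f"sequence {seq_id!r} matches both the LG and scaffold patterns"
            )
        if lg:
            return f"LG{lg.group(1)}"
        if sc:
            return f"sc{sc.group(1)}"
        raise NamingError(f"sequence {seq_id!r} matches neither naming pattern")


def assign_locus_names(
    annotation_set: AnnotationSet, scheme: NamingScheme | None = None
) -> tuple[AnnotationSet, dict[str, str]]:
    """Rename genes to systematic locus names in coordinate order.

    Returns the renamed set (transcripts get ``<name>.<i>`` ids and the old
    gene id is kept in the ``original_id`` attribute) and the old→new
    mapping table.  Ties on start coordinate break by end then old id.
    """
    scheme = scheme or NamingScheme()
    mapping: dict[str, str] = {}
    renamed = AnnotationSet(version_tag=annotation_set.version_tag)
    for seq_id in annotation_set.seq_ids():
        label = scheme.sequence_label(seq_id)
        for i, gene in enumerate(annotation_set.genes_on(seq_id)):
            number = scheme.start_number + i * scheme.step
            name = f"{scheme.species_prefix}{scheme.version_digits}{label}G{number}"
            mapping[gene.gene_id] = name
            transcripts = [
                TranscriptModel(
                    transcript_id=f"{name}.{j}",
                    gene_id=name,
                    exons=list(t.exons),
                    cds_segments=list(t.cds_segments),
                    phases=list(t.phases) if t.phases else None,
                    attributes=dict(t.attributes),
                )
                for j, t in enumerate(gene.transcripts, start=1)
            ]
            renamed.add(
                GeneModel(
                    gene_id=name,
                    span=gene.span,
                    transcripts=transcripts,
                    attributes={**gene.attributes, "original_id": gene.gene_id},
                )
            )
    return renamed, mapping


def write_mapping_tsv(mapping: dict[str, str], path) -> None:
    with open(path, "w") as handle:
        handle.write("old_id\tlocus_name\n")
        for old, new in mapping.items():
            handle.write(f"{old}\t{new}\n")
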