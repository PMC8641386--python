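"""GFF3 reading and writing.

Line-level parsing (columns, attribute encoding) is delegated to
:mod:`gffutils`; hierarchy assembly, the 1-based→0-based coordinate
conversion, orphan policies and line-numbered error reporting live here.
Internally every coordinate is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils.feature

from .model import (
    AnnotationSet,
    EvidenceAlignment,
    EvidenceKind,
    GeneModel,
    Interval,
    TranscriptModel,
)

GENE_TYPES = {"gene", "pseudogene"}
TRANSCRIPT_TYPES = {"mRNA", "transcript", "ncRNA", "tRNA", "rRNA"}
UTR_TYPES = {"five_prime_UTR", "three_prime_UTR"}
_STRANDS = {"+", "-", ".", "?"}

# default mapping used when an evidence line carries no explicit kind attribute
_SOURCE_KINDS = {
    "cDNA_match": EvidenceKind.LONG_READ,
    "expressed_sequence_match": EvidenceKind.SHORT_READ_ASSEMBLY,
    "protein_match": EvidenceKind.PROTEIN,
    "match": EvidenceKind.SHORT_READ_ASSEMBLY,
}


class GFF3ParseError(Exception):
    """Raised for malformed GFF3 input; names the offending line."""


@dataclass
class _RawFeature:
    line_no: int
    seq_id: str
    source: str
    ftype: str
    start: int  # already 0-based half-open
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, str]

    @property
    def fid(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def parents(self) -> list[str]:
        parent = self.attributes.get("Parent")
        return parent.split(",") if parent else []

    def interval(self) -> Interval:
        strand = self.strand if self.strand in {"+", "-"} else "."
        return Interval(self.seq_id, self.start, self.end, strand)


def _parse_lines(path) -> list[_RawFeature]:
    features = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(
                    f"{path}:{line_no}: expected 9 columns, found {len(cols)}"
                )
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # pragma: no cover - gffutils detail
                raise GFF3ParseError(f"{path}:{line_no}: {exc}") from exc
            try:
                start = int(cols[3])
                end = int(cols[4])
            except ValueError:
                raise GFF3ParseError(
                    f"{path}:{line_no}: non-integer coordinates {cols[3]!r}/{cols[4]!r}"
                ) from None
            if end < start:
                raise GFF3ParseError(f"{path}:{line_no}: end {end} < start {start}")
            if cols[6] not in _STRANDS:
                raise GFF3ParseError(
                    f"{path}:{line_no}: unknown strand symbol {cols[6]!r}"
                )
            attrs = {k: ",".join(v) for k, v in feat.attributes.items()}
            features.append(
                _RawFeature(
                    line_no=line_no,
                    seq_id=feat.seqid,
                    source=feat.source,
                    ftype=feat.featuretype,
                    start=start - 1,
                    end=end,
                    score=cols[5],
                    strand=cols[6],
                    phase=cols[7],
                    attributes=attrs,
                )
            )
    return features


def _valid_phase(raw: str) -> int | None:
    return int(raw) if raw in {"0", "1", "2"} else None


def read_gff3(path, feature_policy: str = "strict") -> AnnotationSet:
    """Read a gene/mRNA/exon/CDS GFF3 file into an :class:`AnnotationSet`.

    ``feature_policy`` controls orphan handling: ``strict`` rejects features
    whose Parent is absent from the file; ``lenient`` keeps orphan
    transcripts as single-transcript genes and drops orphan exons/CDS,
    recording them in ``AnnotationSet.orphans``.  Genes carrying exon/CDS
    children but no explicit transcript get a synthetic single transcript,
    so structurally broken files remain loadable for validation.
    """
    if feature_policy not in {"strict", "lenient"}:
        raise ValueError(f"unknown feature_policy {feature_policy!r}")
    raws = _parse_lines(path)
    by_id: dict[str, _RawFeature] = {}
    counts: dict[str, int] = {}
    for raw in raws:
        counts[raw.ftype] = counts.get(raw.ftype, 0) + 1
        if raw.fid is not None and raw.ftype in GENE_TYPES | TRANSCRIPT_TYPES:
            by_id[raw.fid] = raw

    orphans: list[str] = []
    genes_raw: dict[str, _RawFeature] = {}
    transcripts_raw: dict[str, _RawFeature] = {}
    children: dict[str, list[_RawFeature]] = {}
    for raw in raws:
        if raw.ftype in GENE_TYPES:
            if raw.fid is None:
                raise GFF3ParseError(f"{path}:{raw.line_no}: gene without ID")
            genes_raw[raw.fid] = raw
        elif raw.ftype in TRANSCRIPT_TYPES:
            if raw.fid is None:
                raise GFF3ParseError(f"{path}:{raw.line_no}: transcript without ID")
            missing = [p for p in raw.parents if p not in by_id]
            if raw.parents and missing:
                if feature_policy == "strict":
                    raise GFF3ParseError(
                        f"{path}:{raw.line_no}: transcript {raw.fid} references "
                        f"missing parent(s) {', '.join(missing)}"
                    )
                orphans.append(raw.fid)
            transcripts_raw[raw.fid] = raw
        elif raw.ftype in {"exon", "CDS"}:
            missing = [p for p in raw.parents if p not in by_id]
            if not raw.parents or missing:
                label = raw.fid or f"{raw.ftype}@line{raw.line_no}"
                if feature_policy == "strict":
                    raise GFF3ParseError(
                        f"{path}:{raw.line_no}: {raw.ftype} {label} references "
                        f"missing parent(s) {', '.join(missing) or '(none)'}"
                    )
                orphans.append(label)
                continue
            for parent in raw.parents:
                children.setdefault(parent, []).append(raw)
        elif raw.ftype in UTR_TYPES:
            # accepted on input; exon−CDS difference is authoritative for UTRs
            continue
        # other feature types are counted but otherwise ignored

    genes: list[GeneModel] = []
    consumed_transcripts: set[str] = set()

    def build_transcript(traw: _RawFeature, gene_id: str) -> TranscriptModel:
        exon_raws = [c for c in children.get(traw.fid, []) if c.ftype == "exon"]
        cds_raws = [c for c in children.get(traw.fid, []) if c.ftype == "CDS"]
        exons = sorted((c.interval() for c in exon_raws), key=lambda iv: iv.start)
        cds_sorted = sorted(cds_raws, key=lambda c: c.start)
        cds = [c.interval() for c in cds_sorted]
        phases = [_valid_phase(c.phase) for c in cds_sorted]
        tm = TranscriptModel(
            transcript_id=traw.fid,
            gene_id=gene_id,
            exons=exons,
            cds_segments=cds,
            phases=None,  # recompute below if the file's phases are unusable
            attributes={
                k: v for k, v in traw.attributes.items() if k not in {"ID", "Parent"}
            },
        )
        if cds and all(p is not None for p in phases):
            tm.phases = phases  # trust the file when complete and valid
        return tm

    for gid, graw in genes_raw.items():
        traws = [t for t in transcripts_raw.values() if gid in t.parents]
        transcripts = []
        for traw in sorted(traws, key=lambda t: (t.start, t.fid)):
            transcripts.append(build_transcript(traw, gid))
            consumed_transcripts.add(traw.fid)
        direct = children.get(gid, [])
        if not transcripts and direct:
            # synthesize a transcript from exon/CDS children attached to the gene
            exons = sorted(
                (c.interval() for c in direct if c.ftype == "exon"),
                key=lambda iv: iv.start,
            )
            cds = sorted(
                (c.interval() for c in direct if c.ftype == "CDS"),
                key=lambda iv: iv.start,
            )
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gid}.t1",
                    gene_id=gid,
                    exons=exons,
                    cds_segments=cds,
                )
            )
        attrs = {k: v for k, v in graw.attributes.items() if k not in {"ID", "Parent"}}
        genes.append(
            GeneModel(gene_id=gid, span=graw.interval(), transcripts=transcripts, attributes=attrs)
        )

    # orphan transcripts under the lenient policy become their own genes
    for tid, traw in transcripts_raw.items():
        if tid in consumed_transcripts or (traw.parents and feature_policy == "strict"):
            continue
        if traw.parents and all(p in genes_raw for p in traw.parents):
            continue
        if not traw.parents or any(p not in by_id for p in traw.parents):
            tm = build_transcript(traw, gene_id=tid)
            genes.append(GeneModel(gene_id=tid, span=traw.interval(), transcripts=[tm]))

    aset = AnnotationSet(genes)
    aset.feature_counts = counts
    aset.orphans = orphans
    return aset


def read_evidence_gff3(path) -> list[EvidenceAlignment]:
    """Read evidence alignments from GFF3.

    Lines sharing an ID form the blocks of one alignment (the GFF3
    multi-line match convention).  The alignment kind comes from a ``kind``
    attribute when present, else from the feature type.
    """
    raws = _parse_lines(path)
    grouped: dict[str, list[_RawFeature]] = {}
    order: list[str] = []
    for raw in raws:
        if raw.ftype in {"match_part"}:
            key = raw.parents[0] if raw.parents else raw.fid
        else:
            key = raw.fid or f"ev@line{raw.line_no}"
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(raw)

    evidences = []
    for key in order:
        parts = grouped[key]
        # a parent match line with match_part children: keep only the parts
        blocks_raw = [p for p in parts if p.ftype == "match_part"] or parts
        head = parts[0]
        kind_label = head.attributes.get("kind")
        if kind_label is not None:
            kind = EvidenceKind(kind_label)
        else:
            kind = _SOURCE_KINDS.get(head.ftype, EvidenceKind.SHORT_READ_ASSEMBLY)
        evidences.append(
            EvidenceAlignment(
                evidence_id=key,
                kind=kind,
                blocks=[b.interval() for b in blocks_raw],
                source_label=head.source,
            )
        )
    return evidences


@dataclass
class RepeatFeature:
    """A repeat annotation interval with its repeat classification."""

    interval: Interval
    repeat_class: str = ""


def read_repeats_gff3(path) -> list[RepeatFeature]:
    """Read repeat features (any feature type) as strand-agnostic intervals."""
    return [
        RepeatFeature(
            interval=raw.interval(),
            repeat_class=raw.attributes.get("class", raw.ftype),
        )
        for raw in _parse_lines(path)
    ]


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items()) if attrs else "."


def write_gff3(annotation_set: AnnotationSet, path, source: str = "annocure") -> None:
    """Write an annotation set as sorted GFF3 (gene→mRNA→exon/CDS)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for gene in annotation_set.sorted_genes():
            g = gene.span
            attrs = {"ID": gene.gene_id, **gene.attributes}
            handle.write(
                f"{g.seq_id}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{_fmt_attrs(attrs)}\n"
            )
            for t in gene.transcripts:
                s = t.span
                tattrs = {"ID": t.transcript_id, "Parent": gene.gene_id, **t.attributes}
                handle.write(
                    f"{s.seq_id}\t{source}\tmRNA\t{s.start + 1}\t{s.end}\t.\t"
                    f"{s.strand}\t.\t{_fmt_attrs(tattrs)}\n"
                )
                for i, exon in enumerate(t.exons, start=1):
                    handle.write(
                        f"{exon.seq_id}\t{source}\texon\t{exon.start + 1}\t{exon.end}"
                        f"\t.\t{exon.strand}\t.\tID={t.transcript_id}.exon{i};"
                        f"Parent={t.transcript_id}\n"
                    )
                phases = t.phases or t.compute_phases()
                for i, (cds, phase) in enumerate(zip(t.cds_segments, phases), start=1):
                    handle.write(
                        f"{cds.seq_id}\t{source}\tCDS\t{cds.start + 1}\t{cds.end}"
                        f"\t.\t{cds.strand}\t{phase}\tID={t.transcript_id}.cds{i};"
                        f"Parent={t.transcript_id}\n"
                    )


def write_evidence_gff3(evidences: list[EvidenceAlignment], path, source: str = "annocure") -> None:
    """Write evidence alignments as multi-line GFF3 matches with kind tags."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for ev in evidences:
            for block in ev.blocks:
                handle.write(
                    f"{block.seq_id}\t{ev.source_label or source}\tmatch\t"
                    f"{block.start + 1}\t{block.end}\t.\t{block.strand}\t.\t"
                    f"ID={ev.evidence_id};kind={ev.kind.value}\n"
                )


def write_repeats_gff3(repeats: list[RepeatFeature], path, source: str = "annocure") -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for i, rep in enumerate(repeats, start=1):
            iv = rep.interval
            handle.write(
                f"{iv.seq_id}\t{source}\tdispersed_repeat\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{iv.strand}\t.\tID=rep{i};class={rep.repeat_class}\n"
            )
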