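"""Core data model for genomes, gene models and evidence alignments.

Coordinates are 0-based half-open throughout the package; GFF3 I/O (see
:mod:`annocure.gff3`) is the only place the 1-based inclusive convention
appears.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

from Bio.Seq import Seq


class AnnocureError(Exception):
    """Base class for package errors."""


class BoundsError(AnnocureError):
    """A feature lies outside its genome sequence."""


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval ``[start, end)`` on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end

    def overlap_length(self, other: "Interval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of ``(start, end)`` pairs."""
    total = 0
    last_end = None
    for start, end in sorted(intervals):
        if last_end is None or start > last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


def intersect_union_length(
    a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]
) -> int:
    """Length of ``union(a) ∩ union(b)`` for two interval collections."""
    events: list[tuple[int, int, int]] = []
    for start, end in a:
        events.append((start, 0, 1))
        events.append((end, 0, -1))
    for start, end in b:
        events.append((start, 1, 1))
        events.append((end, 1, -1))
    depth = [0, 0]
    total = 0
    prev = None
    for pos, which, delta in sorted(events):
        if prev is not None and depth[0] > 0 and depth[1] > 0:
            total += pos - prev
        depth[which] += delta
        prev = pos
    return total


@dataclass
class TranscriptModel:
    """One transcript: exon chain plus optional CDS segments.

    Exons are sorted, non-overlapping intervals on a single sequence and
    strand; every CDS segment must lie within one exon.  ``phases`` holds the
    GFF3 phase per CDS segment (in genomic order) and is recomputed from the
    segment lengths when absent.
    """

    transcript_id: str
    gene_id: str
    exons: list[Interval]
    cds_segments: list[Interval] = field(default_factory=list)
    phases: list[int] | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds_segments = sorted(self.cds_segments, key=lambda iv: iv.start)
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        parts = self.exons + self.cds_segments
        if parts:
            seq_ids = {iv.seq_id for iv in parts}
            strands = {iv.strand for iv in parts}
            if len(seq_ids) > 1 or len(strands) > 1:
                raise ValueError(
                    f"transcript {self.transcript_id} mixes sequences or strands"
                )
        if self.phases is None and self.cds_segments:
            self.phases = self.compute_phases()

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id if self.exons else self.cds_segments[0].seq_id

    @property
    def strand(self) -> str:
        return self.exons[0].strand if self.exons else self.cds_segments[0].strand

    @property
    def span(self) -> Interval:
        parts = self.exons or self.cds_segments
        return Interval(
            self.seq_id, min(p.start for p in parts), max(p.end for p in parts), self.strand
        )

    @property
    def cds_length(self) -> int:
        return sum(c.length for c in self.cds_segments)

    def introns(self) -> list[Interval]:
        """Intervals between consecutive exons, in genomic order."""
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start > left.end:
                out.append(Interval(self.seq_id, left.end, right.start, self.strand))
        return out

    def compute_phases(self) -> list[int]:
        """GFF3 phases from cumulative CDS length in translation order."""
        segs = self.cds_segments
        order = segs if self.strand != "-" else list(reversed(segs))
        phases_t = []
        consumed = 0
        for seg in order:
            phases_t.append((3 - consumed % 3) % 3)
            consumed += seg.length
        if self.strand == "-":
            phases_t.reverse()
        return phases_t


@dataclass
class GeneModel:
    """A gene: span plus one or more transcripts."""

    gene_id: str
    span: Interval
    transcripts: list[TranscriptModel] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def seq_id(self) -> str:
        return self.span.seq_id

    @property
    def strand(self) -> str:
        return self.span.strand

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged exonic intervals over all transcripts."""
        merged: list[tuple[int, int]] = []
        for start, end in sorted(
            (e.start, e.end) for t in self.transcripts for e in t.exons
        ):
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        return merged

    def exonic_length(self) -> int:
        return sum(end - start for start, end in self.exon_union())

    def longest_transcript(self) -> TranscriptModel:
        return max(self.transcripts, key=lambda t: (t.cds_length, t.transcript_id))


class EvidenceKind(str, Enum):
    LONG_READ = "LONG_READ"
    SHORT_READ_ASSEMBLY = "SHORT_READ_ASSEMBLY"
    PROTEIN = "PROTEIN"
    PRIOR_GENE = "PRIOR_GENE"


@dataclass
class EvidenceAlignment:
    """A blocked alignment supporting curation decisions."""

    evidence_id: str
    kind: EvidenceKind
    blocks: list[Interval]
    source_label: str = ""

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks, key=lambda iv: iv.start)
        for prev, cur in zip(self.blocks, self.blocks[1:]):
            if cur.start < prev.end:
                raise ValueError(f"overlapping blocks in evidence {self.evidence_id}")

    @property
    def seq_id(self) -> str:
        return self.blocks[0].seq_id

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def span(self) -> Interval:
        return Interval(
            self.seq_id, self.blocks[0].start, self.blocks[-1].end, self.strand
        )


class AnnotationSet:
    """An ordered, versioned collection of gene models."""

    def __init__(self, genes: Iterable[GeneModel] = (), version_tag: str = ""):
        self.version_tag = version_tag
        self._genes: dict[str, GeneModel] = {}
        self.feature_counts: dict[str, int] = {}
        for gene in genes:
            self.add(gene)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self._genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id}")
        self._genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def get(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def seq_ids(self) -> list[str]:
        return sorted({g.seq_id for g in self})

    def genes_on(self, seq_id: str) -> list[GeneModel]:
        """Genes on one sequence in coordinate order."""
        return sorted(
            (g for g in self if g.seq_id == seq_id),
            key=lambda g: (g.span.start, g.span.end, g.gene_id),
        )

    def sorted_genes(self) -> list[GeneModel]:
        return [g for seq_id in self.seq_ids() for g in self.genes_on(seq_id)]


# ---------------------------------------------------------------------------
# Sequence utilities
# ---------------------------------------------------------------------------

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file as ``{seq_id: upper-case residues}``."""
    from Bio import SeqIO

    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate sequence id {record.id}")
        genome[record.id] = str(record.seq).upper()
    return genome


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for seq_id, residues in genome.items():
            handle.write(f">{seq_id}\n")
            for i in range(0, len(residues), width):
                handle.write(residues[i : i + width] + "\n")


def extract_spliced_sequence(
    transcript: TranscriptModel, genome: dict[str, str], which: str = "exon"
) -> str:
    """Spliced sequence of a transcript's exons or CDS segments.

    Segments are concatenated in genomic order and the whole string is
    reverse-complemented for minus-strand transcripts, so the result always
    reads 5'→3' in transcript orientation.
    """
    if which == "exon":
        parts = transcript.exons
    elif which == "cds":
        parts = transcript.cds_segments
    else:
        raise ValueError(f"which must be 'exon' or 'cds', got {which!r}")
    if not parts:
        return ""
    seq = genome.get(transcript.seq_id)
    if seq is None:
        raise BoundsError(
            f"sequence {transcript.seq_id} absent for transcript {transcript.transcript_id}"
        )
    chunks = []
    for part in parts:
        if part.start < 0 or part.end > len(seq):
            raise BoundsError(
                f"segment [{part.start},{part.end}) of {transcript.transcript_id} "
                f"outside {transcript.seq_id} (length {len(seq)})"
            )
        chunks.append(seq[part.start : part.end])
    spliced = "".join(chunks).upper()
    if transcript.strand == "-":
        spliced = reverse_complement(spliced)
    return spliced


class PartialCodonWarning(UserWarning):
    """A CDS length not divisible by three left a trailing partial codon."""


def translate(cds_sequence: str, genetic_code: int = 1) -> str:
    """Translate a CDS; stops are ``*``, ambiguous codons ``X``.

    A trailing partial codon is ignored and reported via
    :class:`PartialCodonWarning`.
    """
    if not cds_sequence:
        raise ValueError("cannot translate an empty sequence")
    if len(cds_sequence) < 3:
        warnings.warn(
            f"sequence of length {len(cds_sequence)} has no complete codon",
            PartialCodonWarning,
            stacklevel=2,
        )
        return ""
    remainder = len(cds_sequence) % 3
    if remainder:
        warnings.warn(
            f"trailing partial codon of {remainder} nt ignored",
            PartialCodonWarning,
            stacklevel=2,
        )
        cds_sequence = cds_sequence[: len(cds_sequence) - remainder]
    protein = str(Seq(cds_sequence.upper()).translate(table=genetic_code))
    return protein
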