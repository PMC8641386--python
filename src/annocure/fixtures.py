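"""Deterministic synthetic genomes, annotations and evidence with ground truth.

Everything the curation toolkit consumes can be generated here: genome
sequences with linkage-group and scaffold names, clean gene models (ATG
start, single terminal stop, GT–AG introns), corrupted copies with known
error flags, fused and fissioned predictions with matching evidence tracks,
repeat annotations for TE labeling, and isoform sets realizing specific
alternative-splicing events.  A single seed fans out into per-operation
substreams, so adding one generator call never perturbs the output of
another.

The generators mutate the genome dict in place: planted genes write their
coding sequence into the chosen location, and isoform/corruption planting
edits splice-site dinucleotides or codons where an event requires it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gff3 import RepeatFeature
from .model import (
    AnnotationSet,
    EvidenceAlignment,
    EvidenceKind,
    GeneModel,
    Interval,
    TranscriptModel,
    reverse_complement,
)
from .validate import ValidationFlag

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *stream])


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def generate_genome(
    seed: int,
    n_sequences: int = 2,
    lengths: tuple[int, ...] | list[int] = (150_000, 150_000),
    gc: float = 0.36,
) -> dict[str, str]:
    """Random genome; first half of the sequences are LGs, the rest scaffolds."""
    lengths = list(lengths)
    if len(lengths) != n_sequences:
        raise ValueError("lengths must have one entry per sequence")
    if any(length < 5000 for length in lengths):
        raise ValueError("sequence lengths must be ≥ 5000")
    n_lg = (n_sequences + 1) // 2
    genome: dict[str, str] = {}
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for idx, length in enumerate(lengths):
        name = f"LG{idx + 1}" if idx < n_lg else f"sc{idx - n_lg + 1}"
        rng = _rng(seed, 11, idx)
        genome[name] = "".join(_BASES[rng.choice(4, size=length, p=p)])
    return genome


# ---------------------------------------------------------------------------
# Clean gene planting
# ---------------------------------------------------------------------------


@dataclass
class GeneParams:
    n_codons_range: tuple[int, int] = (40, 80)
    exons_per_gene_range: tuple[int, int] = (2, 5)
    min_exon_length: int = 30
    intron_length_range: tuple[int, int] = (80, 160)
    intergenic_gap_range: tuple[int, int] = (220, 420)
    strand_flip_prob: float = 0.35


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(
        _CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_codons - 2)
    )
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + body + stop


def _split_lengths(
    rng: np.random.Generator, total: int, n_parts: int, min_part: int
) -> list[int]:
    if n_parts * min_part > total:
        n_parts = max(1, total // min_part)
    extra = total - n_parts * min_part
    if n_parts == 1:
        return [total]
    cuts = np.sort(rng.integers(0, extra + 1, size=n_parts - 1))
    parts = []
    prev = 0
    for cut in cuts:
        parts.append(min_part + int(cut) - prev)
        prev = int(cut)
    parts.append(min_part + extra - prev)
    return parts


def _build_gene(
    rng: np.random.Generator,
    seq_id: str,
    strand: str,
    pos: int,
    gene_id: str,
    params: GeneParams,
) -> tuple[GeneModel, str]:
    """Construct one clean gene starting at genomic ``pos``.

    Returns the model and the region string to write into the genome
    (already in plus-strand orientation).
    """
    n_codons = int(rng.integers(*params.n_codons_range, endpoint=True))
    cds = _random_cds(rng, n_codons)
    n_ex = int(rng.integers(*params.exons_per_gene_range, endpoint=True))
    exon_lengths = _split_lengths(rng, len(cds), n_ex, params.min_exon_length)
    intron_lengths = [
        int(rng.integers(*params.intron_length_range, endpoint=True))
        for _ in range(len(exon_lengths) - 1)
    ]
    region_parts = []
    offsets: list[tuple[int, int]] = []  # exon offsets in transcription order
    offset = 0
    cds_pos = 0
    for i, ex_len in enumerate(exon_lengths):
        region_parts.append(cds[cds_pos : cds_pos + ex_len])
        offsets.append((offset, offset + ex_len))
        cds_pos += ex_len
        offset += ex_len
        if i < len(intron_lengths):
            interior = "".join(
                _BASES[rng.integers(0, 4, size=intron_lengths[i] - 4)]
            )
            region_parts.append("GT" + interior + "AG")
            offset += intron_lengths[i]
    region = "".join(region_parts)
    total = len(region)
    exons = []
    for off_s, off_e in offsets:
        if strand == "-":
            exons.append(Interval(seq_id, pos + total - off_e, pos + total - off_s, "-"))
        else:
            exons.append(Interval(seq_id, pos + off_s, pos + off_e, "+"))
    exons.sort(key=lambda iv: iv.start)
    transcript = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        exons=exons,
        cds_segments=list(exons),
    )
    gene = GeneModel(
        gene_id=gene_id,
        span=Interval(seq_id, pos, pos + total, strand),
        transcripts=[transcript],
    )
    written = region if strand == "+" else reverse_complement(region)
    return gene, written


def plant_genes(
    genome: dict[str, str],
    seed: int,
    n_genes: int,
    params: GeneParams | None = None,
) -> AnnotationSet:
    """Plant clean, non-overlapping genes; writes their sequence into the genome."""
    params = params or GeneParams()
    total_len = sum(len(s) for s in genome.values())
    seq_ids = list(genome)
    quotas = [round(n_genes * len(genome[s]) / total_len) for s in seq_ids]
    while sum(quotas) < n_genes:
        quotas[0] += 1
    while sum(quotas) > n_genes:
        quotas[int(np.argmax(quotas))] -= 1
    genes = []
    counter = 1
    for seq_idx, (seq_id, quota) in enumerate(zip(seq_ids, quotas)):
        rng = _rng(seed, 21, seq_idx)
        chars = list(genome[seq_id])
        pos = int(rng.integers(*params.intergenic_gap_range, endpoint=True))
        strand = "+" if rng.random() < 0.5 else "-"
        for _ in range(quota):
            gene_id = f"g{counter:04d}"
            gene, written = _build_gene(rng, seq_id, strand, pos, gene_id, params)
            if gene.span.end + params.intergenic_gap_range[0] > len(chars):
                raise ValueError(
                    f"insufficient space on {seq_id} for {quota} genes"
                )
            chars[gene.span.start : gene.span.end] = written
            genes.append(gene)
            counter += 1
            pos = gene.span.end + int(
                rng.integers(*params.intergenic_gap_range, endpoint=True)
            )
            if rng.random() < params.strand_flip_prob:
                strand = "-" if strand == "+" else "+"
        genome[seq_id] = "".join(chars)
    return AnnotationSet(genes, version_tag="true")


# ---------------------------------------------------------------------------
# Corruption
# ---------------------------------------------------------------------------


@dataclass
class CorruptionRecipe:
    premature_stop: int = 0
    cds_length: int = 0  # 1-bp shrink of the terminal CDS → not a multiple of 3
    missing_feature: int = 0
    fusion: int = 0
    fission: int = 0
    drop_gene: int = 0
    te_overlap: int = 0
    te_domain: int = 0


@dataclass
class FixtureTruth:
    true_genes: AnnotationSet
    planted_corruptions: dict[str, set[ValidationFlag]] = field(default_factory=dict)
    planted_fusions: list[dict] = field(default_factory=list)
    planted_fissions: list[dict] = field(default_factory=list)
    dropped_genes: list[str] = field(default_factory=list)
    planted_te_genes: set[str] = field(default_factory=set)
    te_domain_assignments: dict[str, set[str]] = field(default_factory=dict)
    planted_as_events: list[dict] = field(default_factory=list)


def _copy_gene(gene: GeneModel, new_id: str | None = None) -> GeneModel:
    gid = new_id or gene.gene_id
    return GeneModel(
        gene_id=gid,
        span=gene.span,
        transcripts=[
            TranscriptModel(
                transcript_id=f"{gid}.t{i}",
                gene_id=gid,
                exons=list(t.exons),
                cds_segments=list(t.cds_segments),
                phases=list(t.phases) if t.phases else None,
                attributes=dict(t.attributes),
            )
            for i, t in enumerate(gene.transcripts, start=1)
        ],
        attributes=dict(gene.attributes),
    )


def _write_genome(genome: dict[str, str], seq_id: str, start: int, text: str) -> None:
    seq = genome[seq_id]
    genome[seq_id] = seq[:start] + text + seq[start + len(text) :]


def _plant_premature_stop(
    gene: GeneModel, genome: dict[str, str], rng: np.random.Generator
) -> None:
    """Overwrite one mid-CDS codon with TAA (mutates the genome)."""
    t = gene.transcripts[0]
    order = t.cds_segments if t.strand != "-" else list(reversed(t.cds_segments))
    n_codons = t.cds_length // 3
    consumed = 0
    # pick a codon away from both ends, fully inside one segment
    target = int(rng.integers(2, n_codons - 2))
    for seg in order:
        seg_codon_lo = consumed
        seg_codon_hi = consumed + seg.length
        t_start = target * 3
        if not (seg_codon_lo <= t_start and t_start + 3 <= seg_codon_hi):
            consumed += seg.length
            continue
        off = t_start - seg_codon_lo
        if t.strand == "-":
            gpos = seg.end - off - 3
            _write_genome(genome, seg.seq_id, gpos, reverse_complement("TAA"))
        else:
            gpos = seg.start + off
            _write_genome(genome, seg.seq_id, gpos, "TAA")
        return
    # codon straddles a junction: fall back to the first fully-contained codon
    consumed = 0
    for seg in order:
        first = (3 - consumed % 3) % 3
        if seg.length >= first + 3 and consumed + first >= 6:
            off = first
            if t.strand == "-":
                _write_genome(genome, seg.seq_id, seg.end - off - 3, reverse_complement("TAA"))
            else:
                _write_genome(genome, seg.seq_id, seg.start + off, "TAA")
            return
        consumed += seg.length
    raise ValueError(f"no codon fully inside a CDS segment of {gene.gene_id}")


def _shrink_terminal_cds(gene: GeneModel) -> GeneModel:
    """Remove 1 bp from the transcription-terminal CDS/exon end."""
    out = _copy_gene(gene)
    t = out.transcripts[0]
    if t.strand == "-":
        seg = t.cds_segments[0]
        new_seg = Interval(seg.seq_id, seg.start + 1, seg.end, seg.strand)
        t.cds_segments[0] = new_seg
        exon = t.exons[0]
        t.exons[0] = Interval(exon.seq_id, exon.start + 1, exon.end, exon.strand)
    else:
        seg = t.cds_segments[-1]
        t.cds_segments[-1] = Interval(seg.seq_id, seg.start, seg.end - 1, seg.strand)
        exon = t.exons[-1]
        t.exons[-1] = Interval(exon.seq_id, exon.start, exon.end - 1, exon.strand)
    t.phases = t.compute_phases()
    span = out.span
    out.span = Interval(
        span.seq_id,
        min(e.start for e in t.exons),
        max(e.end for e in t.exons),
        span.strand,
    )
    return out


def _join_pair(left: GeneModel, right: GeneModel, new_id: str) -> GeneModel:
    """Read-through join of two adjacent same-strand genes.

    The upstream (5') gene loses its stop codon so translation runs through
    into the downstream gene in frame; the result is structurally clean.
    """
    strand = left.strand
    exons = sorted(
        [*left.transcripts[0].exons, *right.transcripts[0].exons],
        key=lambda iv: iv.start,
    )
    cds = sorted(
        [*left.transcripts[0].cds_segments, *right.transcripts[0].cds_segments],
        key=lambda iv: iv.start,
    )
    if strand == "-":
        # upstream gene is the genomically-right one; its stop codon sits at
        # the genomic start of its first CDS segment
        upstream_first = next(i for i, c in enumerate(cds) if c.start >= right.span.start)
        seg = cds[upstream_first]
        cds[upstream_first] = Interval(seg.seq_id, seg.start + 3, seg.end, seg.strand)
    else:
        upstream_last = max(i for i, c in enumerate(cds) if c.end <= left.span.end)
        seg = cds[upstream_last]
        cds[upstream_last] = Interval(seg.seq_id, seg.start, seg.end - 3, seg.strand)
    transcript = TranscriptModel(
        transcript_id=f"{new_id}.t1", gene_id=new_id, exons=exons, cds_segments=cds
    )
    return GeneModel(
        gene_id=new_id,
        span=Interval(left.seq_id, left.span.start, right.span.end, strand),
        transcripts=[transcript],
    )


def _adjacent_same_strand_pairs(
    annotation_set: AnnotationSet, used: set[str]
) -> list[tuple[GeneModel, GeneModel]]:
    pairs = []
    for seq_id in annotation_set.seq_ids():
        genes = annotation_set.genes_on(seq_id)
        i = 0
        while i < len(genes) - 1:
            a, b = genes[i], genes[i + 1]
            if (
                a.strand == b.strand
                and a.gene_id not in used
                and b.gene_id not in used
                and b.span.start - a.span.end >= 50
            ):
                pairs.append((a, b))
                i += 2  # keep pairs disjoint
            else:
                i += 1
    return pairs


def corrupt(
    annotation_set: AnnotationSet,
    genome: dict[str, str],
    seed: int,
    recipe: CorruptionRecipe,
) -> tuple[AnnotationSet, FixtureTruth]:
    """Apply the recipe's corruptions to distinct genes.

    Returns the corrupted ("predicted") set and the ground truth.  Fusions
    replace two true genes by one read-through model in the prediction;
    fissions replace two planted genes by one read-through gene in the
    *truth* while the prediction keeps the two fragments.  Premature stops
    mutate the genome, so the corresponding truth gene is equally affected.
    """
    rng = _rng(seed, 31)
    truth = FixtureTruth(true_genes=AnnotationSet(version_tag="true"))
    predicted: dict[str, GeneModel] = {g.gene_id: _copy_gene(g) for g in annotation_set}
    true_out: dict[str, GeneModel] = {g.gene_id: _copy_gene(g) for g in annotation_set}
    used: set[str] = set()

    n_pairs = recipe.fusion + recipe.fission
    pairs = _adjacent_same_strand_pairs(annotation_set, used)
    if len(pairs) < n_pairs:
        raise ValueError(
            f"need {n_pairs} adjacent same-strand gene pairs, found {len(pairs)}"
        )
    pick = rng.choice(len(pairs), size=n_pairs, replace=False)
    for k, pair_idx in enumerate(sorted(int(i) for i in pick)):
        a, b = pairs[pair_idx]
        used.update((a.gene_id, b.gene_id))
        if k < recipe.fusion:
            fused = _join_pair(a, b, f"{a.gene_id}f")
            del predicted[a.gene_id]
            del predicted[b.gene_id]
            predicted[fused.gene_id] = fused
            truth.planted_fusions.append(
                {
                    "predicted_id": fused.gene_id,
                    "true_ids": [a.gene_id, b.gene_id],
                    "true_spans": [
                        (a.span.start, a.span.end),
                        (b.span.start, b.span.end),
                    ],
                    "seq_id": a.seq_id,
                }
            )
        else:
            composite = _join_pair(a, b, f"{a.gene_id}x")
            del true_out[a.gene_id]
            del true_out[b.gene_id]
            true_out[composite.gene_id] = composite
            truth.planted_fissions.append(
                {
                    "true_id": composite.gene_id,
                    "fragment_ids": [a.gene_id, b.gene_id],
                    "true_span": (composite.span.start, composite.span.end),
                    "seq_id": a.seq_id,
                }
            )

    singles_needed = (
        recipe.premature_stop
        + recipe.cds_length
        + recipe.missing_feature
        + recipe.drop_gene
        + recipe.te_overlap
        + recipe.te_domain
    )
    pool = [g.gene_id for g in annotation_set.sorted_genes() if g.gene_id not in used]
    if len(pool) < singles_needed:
        raise ValueError(
            f"recipe needs {singles_needed} unused genes, only {len(pool)} left"
        )
    chosen = [pool[int(i)] for i in rng.choice(len(pool), size=singles_needed, replace=False)]
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = chosen[cursor : cursor + n]
        cursor += n
        return out

    for gid in take(recipe.premature_stop):
        _plant_premature_stop(predicted[gid], genome, rng)
        truth.planted_corruptions[gid] = {ValidationFlag.PREMATURE_STOP}
    for gid in take(recipe.cds_length):
        predicted[gid] = _shrink_terminal_cds(predicted[gid])
        truth.planted_corruptions[gid] = {
            ValidationFlag.CDS_NOT_MULTIPLE_OF_THREE,
            ValidationFlag.MISSING_STOP,
        }
    for gid in take(recipe.missing_feature):
        predicted[gid].transcripts[0].cds_segments = []
        predicted[gid].transcripts[0].phases = None
        truth.planted_corruptions[gid] = {ValidationFlag.MISSING_FEATURE}
    for gid in take(recipe.drop_gene):
        del predicted[gid]
        truth.dropped_genes.append(gid)
    truth.planted_te_genes.update(take(recipe.te_overlap))
    for gid in take(recipe.te_domain):
        truth.planted_te_genes.add(gid)
        truth.te_domain_assignments[gid] = {"PF03732"}

    truth.true_genes = AnnotationSet(
        sorted(true_out.values(), key=lambda g: (g.seq_id, g.span.start)),
        version_tag="true",
    )
    corrupted = AnnotationSet(
        sorted(predicted.values(), key=lambda g: (g.seq_id, g.span.start)),
        version_tag="predicted",
    )
    return corrupted, truth


# ---------------------------------------------------------------------------
# Evidence and repeats
# ---------------------------------------------------------------------------


@dataclass
class EvidenceProfile:
    protein_coverage: float = 1.0
    long_read_coverage: float = 1.0
    short_read_coverage: float = 0.0
    prior_genes: bool = True
    long_read_truncation_prob: float = 0.0


def emit_evidence(
    true_genes: AnnotationSet, seed: int, profile: EvidenceProfile | None = None
) -> list[EvidenceAlignment]:
    """Evidence tracks mirroring the true genes.

    Long reads copy the exon chain (optionally 5'-truncated by whole
    exons), proteins copy the CDS extent, prior-version genes copy the exon
    chain under a recorded id mapping (``prior_<gene_id>``).
    """
    profile = profile or EvidenceProfile()
    rng = _rng(seed, 41)
    evidences: list[EvidenceAlignment] = []
    for gene in true_genes.sorted_genes():
        t = gene.transcripts[0] if gene.transcripts else None
        if t is None or not t.exons:
            continue
        if rng.random() < profile.protein_coverage and t.cds_segments:
            evidences.append(
                EvidenceAlignment(
                    evidence_id=f"p_{gene.gene_id}",
                    kind=EvidenceKind.PROTEIN,
                    blocks=list(t.cds_segments),
                    source_label="swissprot",
                )
            )
        if rng.random() < profile.long_read_coverage:
            exons = list(t.exons)
            if len(exons) > 1 and rng.random() < profile.long_read_truncation_prob:
                n_drop = int(rng.integers(1, len(exons)))
                # 5' exons are genomically first on + and last on −
                exons = exons[n_drop:] if t.strand != "-" else exons[: len(exons) - n_drop]
            evidences.append(
                EvidenceAlignment(
                    evidence_id=f"lr_{gene.gene_id}",
                    kind=EvidenceKind.LONG_READ,
                    blocks=exons,
                    source_label="isoseq",
                )
            )
        if rng.random() < profile.short_read_coverage:
            evidences.append(
                EvidenceAlignment(
                    evidence_id=f"sr_{gene.gene_id}",
                    kind=EvidenceKind.SHORT_READ_ASSEMBLY,
                    blocks=list(t.exons),
                    source_label="scallop",
                )
            )
        if profile.prior_genes:
            evidences.append(
                EvidenceAlignment(
                    evidence_id=f"prior_{gene.gene_id}",
                    kind=EvidenceKind.PRIOR_GENE,
                    blocks=list(t.exons),
                    source_label="v_prior",
                )
            )
    return evidences


def generate_repeats(
    annotation_set: AnnotationSet,
    te_gene_ids: set[str],
    seed: int,
    coverage: float = 0.6,
) -> list[RepeatFeature]:
    """Repeats covering the selected genes by ``coverage`` of their span,
    plus short background repeats midway between genes."""
    rng = _rng(seed, 51)
    classes = ["LTR/Gypsy", "LTR/Copia", "LINE", "DNA", "Helitron"]
    repeats = []
    for gene in annotation_set.sorted_genes():
        if gene.gene_id in te_gene_ids:
            span = gene.span
            length = int(span.length * coverage)
            repeats.append(
                RepeatFeature(
                    interval=Interval(span.seq_id, span.start, span.start + length, "."),
                    repeat_class=classes[int(rng.integers(0, len(classes)))],
                )
            )
    for seq_id in annotation_set.seq_ids():
        genes = annotation_set.genes_on(seq_id)
        for a, b in zip(genes, genes[1:]):
            gap = b.span.start - a.span.end
            if gap >= 120 and rng.random() < 0.1:
                mid = a.span.end + gap // 2
                repeats.append(
                    RepeatFeature(
                        interval=Interval(seq_id, mid - 40, mid + 40, "."),
                        repeat_class="SSR",
                    )
                )
    return repeats


# ---------------------------------------------------------------------------
# Isoforms with planted AS events
# ---------------------------------------------------------------------------


@dataclass
class EventSpec:
    event_type: str  # ES | AA | AD | MX | IR
    canonical: bool = True
    in_utr: bool = False
    gene_id: str | None = None
    exon_index: int | None = None  # transcription-order index of the affected exon


def _set_dinuc(
    genome: dict[str, str], seq_id: str, pos: int, mer: str
) -> None:
    _write_genome(genome, seq_id, pos, mer)


def _write_intron_sites(
    genome: dict[str, str],
    seq_id: str,
    intron: tuple[int, int],
    strand: str,
    donor: str = "GT",
    acceptor: str = "AG",
    which: str = "both",
) -> None:
    """Write donor/acceptor 2-mers of an intron onto the plus strand."""
    start, end = intron
    if strand == "-":
        left, right = reverse_complement(acceptor), reverse_complement(donor)
    else:
        left, right = donor, acceptor
    if which in {"both", "left"}:
        _set_dinuc(genome, seq_id, start, left)
    if which in {"both", "right"}:
        _set_dinuc(genome, seq_id, end - 2, right)


def _transcription_order(exons: list[Interval], strand: str) -> list[Interval]:
    return list(reversed(exons)) if strand == "-" else list(exons)


class IsoformPlantingError(ValueError):
    pass


def plant_isoforms(
    annotation_set: AnnotationSet,
    genome: dict[str, str],
    seed: int,
    recipe: list[EventSpec] | dict[str, int],
) -> tuple[AnnotationSet, list[dict]]:
    """Add isoforms realizing the requested AS events; one event per gene.

    CDS-located events modify the intron structure over the coding exons;
    UTR-located events (supported for ES and IR) extend the transcript
    3' of the stop codon with extra untranslated exons.  The genome is
    edited to carry the needed splice-site dinucleotides.  Returns a new
    annotation set (all genes, isoforms added) and the list of planted
    events ``{gene_id, event_type, canonical, in_utr}``.
    """
    if isinstance(recipe, dict):
        specs = [EventSpec(etype) for etype, n in recipe.items() for _ in range(n)]
    else:
        specs = list(recipe)
    rng = _rng(seed, 61)
    out = {g.gene_id: _copy_gene(g) for g in annotation_set}
    used: set[str] = set()
    truth_events: list[dict] = []

    def eligible(spec: EventSpec) -> GeneModel:
        if spec.gene_id is not None:
            gene = out[spec.gene_id]
            used.add(gene.gene_id)
            return gene
        candidates = []
        for gene in annotation_set.sorted_genes():
            if gene.gene_id in used:
                continue
            n_ex = len(gene.transcripts[0].exons)
            if spec.in_utr:
                ok = n_ex >= 1 and spec.event_type in {"ES", "IR"}
            elif spec.event_type == "ES" or spec.event_type == "MX":
                ok = n_ex >= 3
            else:
                ok = n_ex >= 2
            if ok:
                candidates.append(gene)
        if not candidates:
            raise IsoformPlantingError(
                f"no eligible gene left for event {spec.event_type}"
            )
        gene = candidates[int(rng.integers(0, len(candidates)))]
        used.add(gene.gene_id)
        return gene

    for spec in specs:
        gene = out[eligible(spec).gene_id]
        base = gene.transcripts[0]
        iso_id = f"{gene.gene_id}.iso{len(gene.transcripts) + 1}"
        if spec.in_utr:
            _plant_utr_event(gene, base, spec, genome, rng)
        else:
            _plant_cds_event(gene, base, spec, genome, rng, iso_id)
        truth_events.append(
            {
                "gene_id": gene.gene_id,
                "event_type": spec.event_type,
                "canonical": spec.canonical,
                "in_utr": spec.in_utr,
            }
        )
    result = AnnotationSet(
        sorted(out.values(), key=lambda g: (g.seq_id, g.span.start)),
        version_tag=annotation_set.version_tag,
    )
    return result, truth_events


def _add_isoform(gene: GeneModel, iso_id: str, exons: list[Interval], cds: list[Interval]) -> None:
    gene.transcripts.append(
        TranscriptModel(
            transcript_id=iso_id, gene_id=gene.gene_id, exons=exons, cds_segments=cds
        )
    )
    span = gene.span
    lo = min(span.start, min(e.start for e in exons))
    hi = max(span.end, max(e.end for e in exons))
    gene.span = Interval(span.seq_id, lo, hi, span.strand)


def _plant_cds_event(
    gene: GeneModel,
    base: TranscriptModel,
    spec: EventSpec,
    genome: dict[str, str],
    rng: np.random.Generator,
    iso_id: str,
) -> None:
    strand = base.strand
    seq_id = base.seq_id
    exons = list(base.exons)  # genomic order
    n_ex = len(exons)
    etype = spec.event_type

    if etype == "ES":
        if n_ex < 3:
            raise IsoformPlantingError(f"{gene.gene_id}: ES needs ≥3 exons")
        if spec.exon_index is not None:
            t_order = _transcription_order(exons, strand)
            target = t_order[spec.exon_index]
            k = exons.index(target)
            if k in (0, n_ex - 1):
                raise IsoformPlantingError("ES exon must be internal")
        else:
            k = int(rng.integers(1, n_ex - 1))
        new_exons = exons[:k] + exons[k + 1 :]
        new_cds = [c for c in base.cds_segments if not c.overlaps(exons[k])]
        if not spec.canonical:
            # spoil the merged intron's donor (shared with the left flank intron)
            merged = (exons[k - 1].end, exons[k + 1].start)
            _write_intron_sites(
                genome, seq_id, merged, strand, donor="CT", acceptor="AG",
                which="left" if strand != "-" else "right",
            )
        _add_isoform(gene, iso_id, new_exons, new_cds)

    elif etype == "IR":
        if n_ex < 2:
            raise IsoformPlantingError(f"{gene.gene_id}: IR needs ≥2 exons")
        k = int(rng.integers(0, n_ex - 1))
        intron = (exons[k].end, exons[k + 1].start)
        merged_exon = Interval(seq_id, exons[k].start, exons[k + 1].end, strand)
        new_exons = exons[:k] + [merged_exon] + exons[k + 2 :]
        new_cds = []
        for c in base.cds_segments:
            if c.overlaps(exons[k]) or c.overlaps(exons[k + 1]):
                continue
            new_cds.append(c)
        lo = min(c.start for c in base.cds_segments if c.overlaps(exons[k]))
        hi = max(c.end for c in base.cds_segments if c.overlaps(exons[k + 1]))
        new_cds.append(Interval(seq_id, lo, hi, strand))
        if not spec.canonical:
            _write_intron_sites(genome, seq_id, intron, strand, donor="CT", acceptor="AC")
        _add_isoform(gene, iso_id, sorted(new_exons, key=lambda iv: iv.start),
                     sorted(new_cds, key=lambda iv: iv.start))

    elif etype in {"AA", "AD"}:
        if n_ex < 2:
            raise IsoformPlantingError(f"{gene.gene_id}: {etype} needs ≥2 exons")
        k = int(rng.integers(0, n_ex - 1))
        start, end = exons[k].end, exons[k + 1].start
        shift = int(rng.integers(9, 16)) // 3 * 3  # keep downstream CDS in frame
        if end - start - shift < 24:
            shift = 9
        # transcription-orientation: acceptor is the intron's 3' boundary
        move_right_end = (etype == "AA") == (strand != "-")
        if move_right_end:
            new_intron = (start, end - shift)
            absorbed = Interval(seq_id, end - shift, end, strand)
            grown = exons[k + 1]
            new_neighbor = Interval(seq_id, absorbed.start, grown.end, strand)
            new_exons = exons[:k + 1] + [new_neighbor] + exons[k + 2 :]
            mer = "AG" if strand != "-" else reverse_complement("GT")
            if not spec.canonical:
                mer = "CC"
            _set_dinuc(genome, seq_id, new_intron[1] - 2, mer)
        else:
            new_intron = (start + shift, end)
            grown = exons[k]
            new_neighbor = Interval(seq_id, grown.start, start + shift, strand)
            new_exons = exons[:k] + [new_neighbor] + exons[k + 1 :]
            mer = "GT" if strand != "-" else reverse_complement("AG")
            if not spec.canonical:
                mer = "CC"
            _set_dinuc(genome, seq_id, new_intron[0], mer)
        new_cds = []
        for c in base.cds_segments:
            if move_right_end and c.start == end:
                new_cds.append(Interval(seq_id, absorbed.start, c.end, strand))
            elif (not move_right_end) and c.end == start:
                new_cds.append(Interval(seq_id, c.start, start + shift, strand))
            else:
                new_cds.append(c)
        _add_isoform(gene, iso_id, sorted(new_exons, key=lambda iv: iv.start),
                     sorted(new_cds, key=lambda iv: iv.start))

    elif etype == "MX":
        if n_ex < 3:
            raise IsoformPlantingError(f"{gene.gene_id}: MX needs ≥3 exons")
        ks = [
            k for k in range(1, n_ex - 1)
            if exons[k + 1].start - exons[k].end >= 60
        ]
        if not ks:
            raise IsoformPlantingError(f"{gene.gene_id}: no intron long enough for MX")
        k = ks[int(rng.integers(0, len(ks)))]
        gap_start, gap_end = exons[k].end, exons[k + 1].start
        alt_len = 21
        alt_start = gap_start + 8
        alt = Interval(seq_id, alt_start, alt_start + alt_len, strand)
        if gap_end - alt.end < 22:
            raise IsoformPlantingError(f"{gene.gene_id}: intron too short for MX")
        new_exons = exons[:k] + [alt] + exons[k + 1 :]
        new_cds = [c for c in base.cds_segments if not c.overlaps(exons[k])] + [alt]
        left_intron = (exons[k - 1].end, alt.start)
        right_intron = (alt.end, gap_end)
        donor = "GT" if spec.canonical else "CT"
        _write_intron_sites(genome, seq_id, left_intron, strand, which="right")
        _write_intron_sites(
            genome, seq_id, right_intron, strand, donor=donor, which="left"
        )
        if strand == "-" and not spec.canonical:
            # on the minus strand the right boundary of the left intron is
            # the transcript's acceptor; spoil that one instead
            _write_intron_sites(
                genome, seq_id, left_intron, strand, acceptor="CC", which="right"
            )
            _write_intron_sites(genome, seq_id, right_intron, strand, which="left")
        _add_isoform(gene, iso_id, sorted(new_exons, key=lambda iv: iv.start),
                     sorted(new_cds, key=lambda iv: iv.start))
    else:
        raise IsoformPlantingError(f"unknown event type {etype}")


def _plant_utr_event(
    gene: GeneModel,
    base: TranscriptModel,
    spec: EventSpec,
    genome: dict[str, str],
    rng: np.random.Generator,
) -> None:
    """Plant an ES or IR event in a 3'UTR extension shared by two isoforms."""
    strand = base.strand
    seq_id = base.seq_id
    exons = list(base.exons)
    if spec.event_type == "IR":
        lead, intron_len, tail = 30, 40, 30
        total = lead + intron_len + tail
    elif spec.event_type == "ES":
        lead, i1, mid, i2, tail = 20, 30, 24, 30, 24
        total = lead + i1 + mid + i2 + tail
    else:
        raise IsoformPlantingError(
            f"UTR placement is supported for ES and IR, not {spec.event_type}"
        )
    seq = genome[seq_id]
    if strand != "-":
        anchor = exons[-1].end
        if anchor + total + 20 > len(seq):
            raise IsoformPlantingError(f"{gene.gene_id}: no room for UTR extension")
        ext = lambda a, b: Interval(seq_id, anchor + a, anchor + b, strand)  # noqa: E731
        grown_last = Interval(seq_id, exons[-1].start, anchor + lead, strand)
        head = exons[:-1] + [grown_last]
    else:
        anchor = exons[0].start
        if anchor - total - 20 < 0:
            raise IsoformPlantingError(f"{gene.gene_id}: no room for UTR extension")
        ext = lambda a, b: Interval(seq_id, anchor - b, anchor - a, strand)  # noqa: E731
        grown_last = Interval(seq_id, anchor - lead, exons[0].end, strand)
        head = [grown_last] + exons[1:]

    cds = list(base.cds_segments)
    if spec.event_type == "IR":
        iv_intron = ext(lead, lead + intron_len)
        tail_exon = ext(lead + intron_len, total)
        spliced = sorted(head + [tail_exon], key=lambda iv: iv.start)
        if strand != "-":
            retained_last = Interval(seq_id, exons[-1].start, anchor + total, strand)
            retained = exons[:-1] + [retained_last]
        else:
            retained_last = Interval(seq_id, anchor - total, exons[0].end, strand)
            retained = [retained_last] + exons[1:]
        donor, acceptor = ("GT", "AG") if spec.canonical else ("CT", "AC")
        _write_intron_sites(
            genome, seq_id, (iv_intron.start, iv_intron.end), strand, donor, acceptor
        )
        n = len(gene.transcripts)
        _add_isoform(gene, f"{gene.gene_id}.iso{n + 1}a", spliced, cds)
        _add_isoform(
            gene,
            f"{gene.gene_id}.iso{n + 1}b",
            sorted(retained, key=lambda iv: iv.start),
            cds,
        )
    else:  # ES in UTR
        mid_exon = ext(lead + i1, lead + i1 + mid)
        tail_exon = ext(lead + i1 + mid + i2, total)
        with_mid = sorted(head + [mid_exon, tail_exon], key=lambda iv: iv.start)
        without_mid = sorted(head + [tail_exon], key=lambda iv: iv.start)
        # genomic coordinates of the two introns around the middle exon
        if strand != "-":
            intron1 = (anchor + lead, mid_exon.start)
            intron2 = (mid_exon.end, tail_exon.start)
        else:
            intron1 = (tail_exon.end, mid_exon.start)
            intron2 = (mid_exon.end, anchor - lead)
        donor = "GT" if spec.canonical else "CT"
        _write_intron_sites(genome, seq_id, intron1, strand)
        _write_intron_sites(genome, seq_id, intron2, strand)
        if not spec.canonical:
            # spoil the donor of the transcript-first intron
            first = intron1 if strand != "-" else intron2
            _write_intron_sites(genome, seq_id, first, strand, donor="CT",
                                which="left" if strand != "-" else "right")
        n = len(gene.transcripts)
        _add_isoform(gene, f"{gene.gene_id}.iso{n + 1}a", with_mid, cds)
        _add_isoform(gene, f"{gene.gene_id}.iso{n + 1}b", without_mid, cds)


# ---------------------------------------------------------------------------
# Full fixture bundle
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    genome: dict[str, str]
    predicted: AnnotationSet
    truth: FixtureTruth
    evidences: list[EvidenceAlignment]
    repeats: list[RepeatFeature]

    @property
    def true_genes(self) -> AnnotationSet:
        return self.truth.true_genes


def generate_bundle(
    seed: int,
    n_genes: int = 200,
    n_fusions: int | None = None,
    n_fissions: int | None = None,
    corruption_recipe: CorruptionRecipe | None = None,
    sequence_lengths: tuple[int, ...] = (150_000, 120_000),
    gene_params: GeneParams | None = None,
) -> FixtureBundle:
    """Generate the standard study bundle: genome, clean truth, corrupted
    prediction, matching evidence tracks and repeat annotation.

    At the default size (200 genes) the corruption mix plants 20 fusions,
    20 fissions, 12 validation errors (4 premature stops, 4 length errors,
    4 missing-feature genes), drops 5 genes for the rescue path, and marks
    12 putative-TE genes (8 by repeat coverage, 4 by Pfam domain).  Smaller
    bundles scale these counts down proportionally.
    """
    if n_fusions is None:
        n_fusions = max(1, n_genes // 10)
    if n_fissions is None:
        n_fissions = max(1, n_genes // 10)
    scale = n_genes / 200

    def sc(n: int) -> int:
        return max(1, round(n * scale))

    recipe = corruption_recipe or CorruptionRecipe(
        premature_stop=sc(4),
        cds_length=sc(4),
        missing_feature=sc(4),
        fusion=n_fusions,
        fission=n_fissions,
        drop_gene=sc(5),
        te_overlap=sc(8),
        te_domain=sc(4),
    )
    recipe.fusion = n_fusions
    recipe.fission = n_fissions
    genome = generate_genome(seed, len(sequence_lengths), sequence_lengths)
    clean = plant_genes(genome, seed, n_genes, gene_params)
    predicted, truth = corrupt(clean, genome, seed, recipe)
    evidences = emit_evidence(truth.true_genes, seed)
    coverage_te = truth.planted_te_genes - set(truth.te_domain_assignments)
    repeats = generate_repeats(truth.true_genes, coverage_te, seed)
    return FixtureBundle(
        genome=genome,
        predicted=predicted,
        truth=truth,
        evidences=evidences,
        repeats=repeats,
    )
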