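"""Evidence-driven split/merge curation and gene rescue.

Gene predictors sometimes fuse tandem genes into one model or fragment one
gene into several.  This module detects both failure modes from evidence
alignments (long-read transcripts, assembled short reads, protein
alignments, prior-version gene models) and repairs them:

* a gene whose overlapping evidence falls into two or more well-separated
  clusters — each anchored by a protein or prior-version gene, with no
  single alignment bridging the clusters — is split;
* a run of adjacent same-strand genes that are each well covered by the
  same spanning alignments is merged, and the merged coding region is
  re-derived as the longest ATG-initiated ORF of the combined exon chain;
* prior-version genes that are structurally clean, covered by protein
  evidence, and absent from the new prediction are rescued wholesale.

All thresholds live in :class:`CurationConfig`; every action is recorded in
an ordered :class:`CurationLog` whose bookkeeping identity
``n_out = n_in − split_in + split_out − merge_in + merge_out + rescues``
is asserted after every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    AnnotationSet,
    EvidenceAlignment,
    EvidenceKind,
    GeneModel,
    Interval,
    TranscriptModel,
    extract_spliced_sequence,
    intersect_union_length,
)
from .validate import check_gene

ANCHOR_KINDS = {EvidenceKind.PROTEIN, EvidenceKind.PRIOR_GENE}
MERGE_KINDS = {EvidenceKind.PROTEIN, EvidenceKind.LONG_READ}


@dataclass
class CurationConfig:
    """Tunable thresholds for split/merge/rescue decisions."""

    min_reciprocal_overlap_fraction: float = 0.5
    min_cluster_gap: int = 1
    required_split_support: int = 1  # PROTEIN/PRIOR_GENE anchors per cluster
    required_merge_support: int = 2  # spanning evidences, ≥1 PROTEIN or LONG_READ
    rescue_min_protein_coverage: float = 0.5
    same_strand_required: bool = True

    def __post_init__(self) -> None:
        for name in ("min_reciprocal_overlap_fraction", "rescue_min_protein_coverage"):
            value = getattr(self, name)
            if not (0 < value <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.required_split_support < 1 or self.required_merge_support < 1:
            raise ValueError("support counts must be ≥ 1")


@dataclass
class EvidenceCluster:
    members: list[EvidenceAlignment]

    @property
    def extent(self) -> tuple[int, int]:
        return (
            min(ev.span.start for ev in self.members),
            max(ev.span.end for ev in self.members),
        )

    @property
    def kinds(self) -> set[EvidenceKind]:
        return {ev.kind for ev in self.members}

    @property
    def evidence_ids(self) -> list[str]:
        return [ev.evidence_id for ev in self.members]


@dataclass
class SplitCandidate:
    gene_id: str
    boundaries: list[int]  # proposed cut positions, midpoints of cluster gaps
    clusters: list[EvidenceCluster]


@dataclass
class MergeCandidate:
    gene_ids: list[str]
    supporting_evidence: list[EvidenceAlignment]


@dataclass
class CurationAction:
    action: str  # SPLIT | MERGE | RESCUE | UNRESOLVED
    input_gene_ids: list[str]
    output_gene_ids: list[str]
    supporting_evidence_ids: list[str]
    region: Interval | None = None

    def __post_init__(self) -> None:
        if self.action == "SPLIT" and not (
            len(self.input_gene_ids) == 1 and len(self.output_gene_ids) >= 2
        ):
            raise ValueError("SPLIT requires 1 input and ≥2 outputs")
        if self.action == "MERGE" and not (
            len(self.input_gene_ids) >= 2 and len(self.output_gene_ids) == 1
        ):
            raise ValueError("MERGE requires ≥2 inputs and 1 output")
        if self.action == "RESCUE" and not (
            len(self.input_gene_ids) == 0 and len(self.output_gene_ids) == 1
        ):
            raise ValueError("RESCUE requires 0 inputs and 1 output")


class BookkeepingError(Exception):
    """Gene counts do not reconcile with the curation log."""


@dataclass
class CurationLog:
    actions: list[CurationAction] = field(default_factory=list)

    def append(self, action: CurationAction) -> None:
        self.actions.append(action)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for action in self.actions:
            out[action.action] = out.get(action.action, 0) + 1
        return out

    def expected_delta(self) -> int:
        delta = 0
        for a in self.actions:
            if a.action in {"SPLIT", "MERGE"}:
                delta += len(a.output_gene_ids) - len(a.input_gene_ids)
            elif a.action == "RESCUE":
                delta += 1
        return delta

    def verify(self, n_in: int, n_out: int) -> None:
        expected = n_in + self.expected_delta()
        if expected != n_out:
            raise BookkeepingError(
                f"log predicts {expected} genes, annotation has {n_out}"
            )

    def write_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("action\tinputs\toutputs\tevidence_ids\tseq_id\tstart\tend\n")
            for a in self.actions:
                region = a.region
                seq_id = region.seq_id if region else ""
                start = region.start if region else ""
                end = region.end if region else ""
                handle.write(
                    f"{a.action}\t{','.join(a.input_gene_ids)}\t"
                    f"{','.join(a.output_gene_ids)}\t"
                    f"{','.join(a.supporting_evidence_ids)}\t{seq_id}\t{start}\t{end}\n"
                )


# ---------------------------------------------------------------------------
# Evidence clustering
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _blocks_connect(a: EvidenceAlignment, b: EvidenceAlignment, gap: int) -> bool:
    for ba in a.blocks:
        for bb in b.blocks:
            if ba.start < bb.end + gap and bb.start < ba.end + gap:
                return True
    return False


def cluster_evidence(
    evidences: list[EvidenceAlignment],
    config: CurationConfig | None = None,
    region: Interval | None = None,
) -> list[EvidenceCluster]:
    """Connected components of evidences whose blocks overlap or abut.

    Two alignments connect when any pair of blocks overlaps or lies within
    ``min_cluster_gap`` bp; with ``same_strand_required`` alignments on
    different strands never connect.  Restricting to ``region`` keeps only
    evidences overlapping it.  Clusters come back sorted by extent start.
    """
    config = config or CurationConfig()
    if region is not None:
        evidences = [ev for ev in evidences if ev.span.overlaps(region)]
    if not evidences:
        return []
    uf = _UnionFind(len(evidences))
    for i in range(len(evidences)):
        for j in range(i + 1, len(evidences)):
            a, b = evidences[i], evidences[j]
            if a.seq_id != b.seq_id:
                continue
            if config.same_strand_required and a.strand != b.strand:
                continue
            if _blocks_connect(a, b, config.min_cluster_gap):
                uf.union(i, j)
    groups: dict[int, list[EvidenceAlignment]] = {}
    for i, ev in enumerate(evidences):
        groups.setdefault(uf.find(i), []).append(ev)
    clusters = [EvidenceCluster(members=members) for members in groups.values()]
    clusters.sort(key=lambda c: c.extent)
    return clusters


# ---------------------------------------------------------------------------
# Candidate detection
# ---------------------------------------------------------------------------


def _evidence_for_gene(
    gene: GeneModel, evidences: list[EvidenceAlignment], config: CurationConfig
) -> list[EvidenceAlignment]:
    out = []
    for ev in evidences:
        if ev.seq_id != gene.seq_id:
            continue
        if config.same_strand_required and ev.strand != gene.strand:
            continue
        if ev.span.overlaps(gene.span):
            out.append(ev)
    return out


def detect_split_candidates(
    annotation_set: AnnotationSet,
    evidences: list[EvidenceAlignment],
    config: CurationConfig | None = None,
) -> list[SplitCandidate]:
    """Genes whose evidence separates into ≥2 anchored, unbridged clusters."""
    config = config or CurationConfig()
    candidates = []
    for gene in annotation_set.sorted_genes():
        overlapping = _evidence_for_gene(gene, evidences, config)
        clusters = cluster_evidence(overlapping, config)
        if len(clusters) < 2:
            continue
        if not all(
            sum(1 for ev in c.members if ev.kind in ANCHOR_KINDS)
            >= config.required_split_support
            for c in clusters
        ):
            continue
        # veto: any single alignment overlapping two cluster extents bridges them
        extents = [c.extent for c in clusters]
        bridged = False
        for ev in overlapping:
            touched = sum(
                1
                for start, end in extents
                if ev.span.start < end and start < ev.span.end
            )
            if touched >= 2:
                bridged = True
                break
        if bridged:
            continue
        boundaries = []
        for (_, left_end), (right_start, _) in zip(extents, extents[1:]):
            boundaries.append((left_end + right_start) // 2)
        candidates.append(
            SplitCandidate(gene_id=gene.gene_id, boundaries=boundaries, clusters=clusters)
        )
    return candidates


def _gene_coverage(gene: GeneModel, ev: EvidenceAlignment) -> float:
    exonic = gene.exon_union()
    denom = sum(end - start for start, end in exonic)
    if denom == 0:
        return 0.0
    covered = intersect_union_length(
        exonic, [(b.start, b.end) for b in ev.blocks]
    )
    return covered / denom


def detect_merge_candidates(
    annotation_set: AnnotationSet,
    evidences: list[EvidenceAlignment],
    config: CurationConfig | None = None,
) -> list[MergeCandidate]:
    """Maximal runs of adjacent same-strand genes jointly covered by evidence.

    A run qualifies when at least ``required_merge_support`` alignments each
    cover every gene in the run by ``min_reciprocal_overlap_fraction`` of
    its exonic length, at least one of them a protein or long read.
    Overlapping runs are all reported; resolution happens at apply time.
    """
    config = config or CurationConfig()
    candidates = []
    for seq_id in annotation_set.seq_ids():
        genes = annotation_set.genes_on(seq_id)
        supporters: list[set[int]] = []
        ev_pool = [ev for ev in evidences if ev.seq_id == seq_id]
        for gene in genes:
            ids = set()
            for idx, ev in enumerate(ev_pool):
                if config.same_strand_required and ev.strand != gene.strand:
                    continue
                if _gene_coverage(gene, ev) >= config.min_reciprocal_overlap_fraction:
                    ids.add(idx)
            supporters.append(ids)

        def window_support(i: int, j: int) -> set[int]:
            common = set(supporters[i])
            for k in range(i + 1, j + 1):
                common &= supporters[k]
            return common

        def qualifies(common: set[int]) -> bool:
            if len(common) < config.required_merge_support:
                return False
            return any(ev_pool[idx].kind in MERGE_KINDS for idx in common)

        prev_max_j = -1
        for i in range(len(genes) - 1):
            j = i
            while (
                j + 1 < len(genes)
                and genes[j + 1].strand == genes[i].strand
                and qualifies(window_support(i, j + 1))
            ):
                j += 1
            if j > i and j > prev_max_j:
                common = window_support(i, j)
                candidates.append(
                    MergeCandidate(
                        gene_ids=[g.gene_id for g in genes[i : j + 1]],
                        supporting_evidence=sorted(
                            (ev_pool[idx] for idx in common),
                            key=lambda ev: ev.evidence_id,
                        ),
                    )
                )
                prev_max_j = j
    return candidates


# ---------------------------------------------------------------------------
# ORF search and structure rebuilding
# ---------------------------------------------------------------------------


def find_longest_orf(seq: str) -> tuple[int, int] | None:
    """Longest ATG-initiated, stop-terminated ORF; ties go to the 5'-most."""
    stops = {"TAA", "TAG", "TGA"}
    best: tuple[int, int] | None = None
    for frame in range(3):
        open_start: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in stops:
                if open_start is not None:
                    length = pos + 3 - open_start
                    if best is None or length > best[1] - best[0] or (
                        length == best[1] - best[0] and open_start < best[0]
                    ):
                        best = (open_start, pos + 3)
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = pos
    return best


def _spliced_to_genomic(
    exons: list[tuple[int, int]], strand: str, spliced_start: int, spliced_end: int
) -> list[tuple[int, int]]:
    """Map a spliced-coordinate range back to genomic segments."""
    total = sum(end - start for start, end in exons)
    if strand == "-":
        spliced_start, spliced_end = total - spliced_end, total - spliced_start
    segments = []
    offset = 0
    for start, end in exons:
        length = end - start
        lo = max(spliced_start, offset)
        hi = min(spliced_end, offset + length)
        if lo < hi:
            segments.append((start + lo - offset, start + hi - offset))
        offset += length
    return segments


def _copy_gene_structure(prior: GeneModel, new_id: str) -> GeneModel:
    transcripts = [
        TranscriptModel(
            transcript_id=f"{new_id}.t{i}",
            gene_id=new_id,
            exons=list(t.exons),
            cds_segments=list(t.cds_segments),
            phases=list(t.phases) if t.phases else None,
        )
        for i, t in enumerate(prior.transcripts, start=1)
    ]
    return GeneModel(
        gene_id=new_id,
        span=prior.span,
        transcripts=transcripts,
        attributes={"curated_from": prior.gene_id},
    )


class _UnresolvedSplit(Exception):
    pass


def _trim_transcript(
    t: TranscriptModel, seg_start: int, seg_end: int, new_id: str
) -> TranscriptModel:
    """Restrict a transcript to [seg_start, seg_end); CDS cuts must fall on
    codon boundaries (raises :class:`_UnresolvedSplit` otherwise)."""
    exons = []
    for exon in t.exons:
        lo, hi = max(exon.start, seg_start), min(exon.end, seg_end)
        if lo < hi:
            exons.append(Interval(exon.seq_id, lo, hi, exon.strand))
    cds_order = t.cds_segments if t.strand != "-" else list(reversed(t.cds_segments))
    consumed = 0
    kept: list[Interval] = []
    for cds in cds_order:
        lo, hi = max(cds.start, seg_start), min(cds.end, seg_end)
        if lo < hi:
            cut_before = (lo - cds.start) if t.strand != "-" else (cds.end - hi)
            cut_after = (cds.end - hi) if t.strand != "-" else (lo - cds.start)
            if cut_before and (consumed + cut_before) % 3 != 0:
                raise _UnresolvedSplit(
                    f"cut at {lo if t.strand != '-' else hi} inside a codon"
                )
            if cut_after and (consumed + cds.length - cut_after) % 3 != 0:
                raise _UnresolvedSplit(
                    f"cut at {hi if t.strand != '-' else lo} inside a codon"
                )
            kept.append(Interval(cds.seq_id, lo, hi, cds.strand))
        consumed += cds.length
    if not exons:
        raise _UnresolvedSplit("no exonic sequence in split segment")
    return TranscriptModel(
        transcript_id=f"{new_id}.t1",
        gene_id=new_id,
        exons=exons,
        cds_segments=sorted(kept, key=lambda iv: iv.start),
    )


def _merge_exons(genes: list[GeneModel]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(
        (e.start, e.end) for g in genes for t in g.transcripts for e in t.exons
    ):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _build_merged_gene(
    genes: list[GeneModel], genome: dict[str, str] | None, new_id: str
) -> GeneModel:
    seq_id, strand = genes[0].seq_id, genes[0].strand
    exon_pairs = _merge_exons(genes)
    exons = [Interval(seq_id, s, e, strand) for s, e in exon_pairs]
    cds: list[Interval] = []
    if genome is not None and seq_id in genome:
        transcript = TranscriptModel(
            transcript_id=f"{new_id}.t1", gene_id=new_id, exons=exons
        )
        spliced = extract_spliced_sequence(transcript, genome, which="exon")
        orf = find_longest_orf(spliced)
        if orf is not None:
            cds = [
                Interval(seq_id, s, e, strand)
                for s, e in _spliced_to_genomic(exon_pairs, strand, orf[0], orf[1])
            ]
    if not cds:
        # fall back to the union of input CDS segments
        merged_cds: list[tuple[int, int]] = []
        for start, end in sorted(
            (c.start, c.end) for g in genes for t in g.transcripts for c in t.cds_segments
        ):
            if merged_cds and start <= merged_cds[-1][1]:
                merged_cds[-1] = (merged_cds[-1][0], max(merged_cds[-1][1], end))
            else:
                merged_cds.append((start, end))
        cds = [Interval(seq_id, s, e, strand) for s, e in merged_cds]
    transcript = TranscriptModel(
        transcript_id=f"{new_id}.t1", gene_id=new_id, exons=exons, cds_segments=cds
    )
    span = Interval(seq_id, exon_pairs[0][0], exon_pairs[-1][1], strand)
    return GeneModel(
        gene_id=new_id,
        span=span,
        transcripts=[transcript],
        attributes={"curated_from": ",".join(g.gene_id for g in genes)},
    )


# ---------------------------------------------------------------------------
# Applying actions
# ---------------------------------------------------------------------------


def _best_prior(
    prior_set: AnnotationSet | None, seq_id: str, strand: str, start: int, end: int
) -> GeneModel | None:
    if prior_set is None:
        return None
    region = Interval(seq_id, start, end, strand)
    best, best_overlap = None, 0
    for gene in prior_set.genes_on(seq_id):
        if gene.strand != strand:
            continue
        ov = gene.span.overlap_length(region)
        if ov > best_overlap:
            best, best_overlap = gene, ov
    return best


def apply_actions(
    annotation_set: AnnotationSet,
    candidates: list[SplitCandidate | MergeCandidate],
    prior_set: AnnotationSet | None = None,
    genome: dict[str, str] | None = None,
    config: CurationConfig | None = None,
) -> tuple[AnnotationSet, CurationLog]:
    """Apply split and merge candidates; untouched genes pass through.

    Candidates are processed left-to-right per sequence; when two claim the
    same gene the earlier-starting one wins.  A split whose boundary falls
    inside a CDS codon with no prior model to copy is skipped and logged as
    UNRESOLVED.
    """
    log = CurationLog()
    genes_by_id = {g.gene_id: g for g in annotation_set}

    def candidate_key(c):
        ids = c.gene_ids if isinstance(c, MergeCandidate) else [c.gene_id]
        spans = [genes_by_id[g].span for g in ids if g in genes_by_id]
        return (spans[0].seq_id, min(s.start for s in spans)) if spans else ("", 0)

    claimed: set[str] = set()
    replacements: dict[str, list[GeneModel]] = {}  # first input id -> outputs
    removed: set[str] = set()

    for cand in sorted(candidates, key=candidate_key):
        if isinstance(cand, SplitCandidate):
            gid = cand.gene_id
            if gid in claimed or gid not in genes_by_id:
                continue
            gene = genes_by_id[gid]
            outputs: list[GeneModel] = []
            used_priors: set[str] = set()
            try:
                cuts = [gene.span.start] + cand.boundaries + [gene.span.end]
                for k, cluster in enumerate(cand.clusters, start=1):
                    new_id = f"{gid}_s{k}"
                    ext = cluster.extent
                    prior = _best_prior(prior_set, gene.seq_id, gene.strand, *ext)
                    if prior is not None and prior.gene_id not in used_priors:
                        used_priors.add(prior.gene_id)
                        outputs.append(_copy_gene_structure(prior, new_id))
                    else:
                        seg_start, seg_end = cuts[k - 1], cuts[k]
                        t = _trim_transcript(
                            gene.longest_transcript(), seg_start, seg_end, new_id
                        )
                        outputs.append(
                            GeneModel(
                                gene_id=new_id,
                                span=t.span,
                                transcripts=[t],
                                attributes={"curated_from": gid},
                            )
                        )
            except _UnresolvedSplit as exc:
                log.append(
                    CurationAction(
                        action="UNRESOLVED",
                        input_gene_ids=[gid],
                        output_gene_ids=[],
                        supporting_evidence_ids=[
                            eid for c in cand.clusters for eid in c.evidence_ids
                        ],
                        region=gene.span,
                    )
                )
                claimed.add(gid)
                continue
            claimed.add(gid)
            removed.add(gid)
            replacements[gid] = outputs
            log.append(
                CurationAction(
                    action="SPLIT",
                    input_gene_ids=[gid],
                    output_gene_ids=[g.gene_id for g in outputs],
                    supporting_evidence_ids=[
                        eid for c in cand.clusters for eid in c.evidence_ids
                    ],
                    region=gene.span,
                )
            )
        else:
            ids = cand.gene_ids
            if any(g in claimed or g not in genes_by_id for g in ids):
                continue
            genes = [genes_by_id[g] for g in ids]
            merged = _build_merged_gene(genes, genome, f"{ids[0]}_m")
            claimed.update(ids)
            removed.update(ids)
            replacements[ids[0]] = [merged]
            log.append(
                CurationAction(
                    action="MERGE",
                    input_gene_ids=ids,
                    output_gene_ids=[merged.gene_id],
                    supporting_evidence_ids=[
                        ev.evidence_id for ev in cand.supporting_evidence
                    ],
                    region=merged.span,
                )
            )

    out = AnnotationSet(version_tag=annotation_set.version_tag)
    for gene in annotation_set:
        if gene.gene_id in replacements:
            for new_gene in replacements[gene.gene_id]:
                out.add(new_gene)
        elif gene.gene_id not in removed:
            out.add(gene)
    log.verify(len(annotation_set), len(out))
    return out, log


def rescue_missing(
    prior_set: AnnotationSet,
    new_set: AnnotationSet,
    protein_evidences: list[EvidenceAlignment],
    genome: dict[str, str],
    config: CurationConfig | None = None,
) -> tuple[list[GeneModel], list[CurationAction]]:
    """Prior-version genes to add: clean, protein-supported, not re-predicted.

    A prior gene is rescued when its validation flag set is empty, it
    overlaps no new gene on the same strand, and protein evidence covers at
    least ``rescue_min_protein_coverage`` of its span.
    """
    config = config or CurationConfig()
    proteins = [ev for ev in protein_evidences if ev.kind == EvidenceKind.PROTEIN]
    added: list[GeneModel] = []
    actions: list[CurationAction] = []
    for prior in prior_set.sorted_genes():
        report = check_gene(prior, genome)
        if not report.is_clean:
            continue
        overlapped = any(
            g.strand == prior.strand and g.span.overlaps(prior.span)
            for g in new_set.genes_on(prior.seq_id)
        )
        if overlapped:
            continue
        blocks = [
            (b.start, b.end)
            for ev in proteins
            if ev.seq_id == prior.seq_id
            and (not config.same_strand_required or ev.strand == prior.strand)
            for b in ev.blocks
        ]
        # coverage over the exonic union: protein alignments can only ever
        # cover exons, so a span denominator would penalize intron-rich genes
        exonic = prior.exon_union()
        denom = sum(end - start for start, end in exonic)
        coverage = intersect_union_length(exonic, blocks) / denom if denom else 0.0
        if coverage < config.rescue_min_protein_coverage:
            continue
        new_id = f"{prior.gene_id}_r"
        gene = _copy_gene_structure(prior, new_id)
        gene.attributes["rescued_from"] = gene.attributes.pop("curated_from")
        added.append(gene)
        actions.append(
            CurationAction(
                action="RESCUE",
                input_gene_ids=[],
                output_gene_ids=[new_id],
                supporting_evidence_ids=sorted(
                    ev.evidence_id
                    for ev in proteins
                    if ev.seq_id == prior.seq_id and ev.span.overlaps(prior.span)
                ),
                region=prior.span,
            )
        )
    return added, actions


def curate(
    annotation_set: AnnotationSet,
    evidences: list[EvidenceAlignment],
    prior_set: AnnotationSet | None = None,
    genome: dict[str, str] | None = None,
    config: CurationConfig | None = None,
) -> tuple[AnnotationSet, CurationLog]:
    """Full curation pass: detect and apply splits and merges, then rescue."""
    config = config or CurationConfig()
    splits = detect_split_candidates(annotation_set, evidences, config)
    merges = detect_merge_candidates(annotation_set, evidences, config)
    curated, log = apply_actions(
        annotation_set, [*splits, *merges], prior_set=prior_set, genome=genome, config=config
    )
    if prior_set is not None and genome is not None:
        added, actions = rescue_missing(prior_set, curated, evidences, genome, config)
        for gene in added:
            curated.add(gene)
        for action in actions:
            log.append(action)
    log.verify(len(annotation_set), len(curated))
    return curated, log
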