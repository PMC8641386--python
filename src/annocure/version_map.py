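"""Cross-version gene correspondence by strand-aware coordinate overlap.

Two genes from different annotation versions are linked when they lie on
the same sequence and strand and overlap by at least half the span of the
shorter gene.  Connected components of the resulting bipartite graph give
one-to-one, split (one-to-many), merged (many-to-one), many-to-many, lost
and novel relations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .model import AnnotationSet, GeneModel
from .validate import ValidationReport


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """``100·numerator/denominator`` rounded half-away-from-zero."""
    if denominator == 0:
        raise ZeroDivisionError("percent() denominator is zero")
    if digits < 0:
        raise ValueError("digits must be ≥ 0")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-digits)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


RELATIONS = (
    "ONE_TO_ONE",
    "ONE_TO_MANY",
    "MANY_TO_ONE",
    "MANY_TO_MANY",
    "OLD_ONLY",
    "NEW_ONLY",
)


@dataclass
class VersionMapEntry:
    old_ids: list[str]
    new_ids: list[str]
    relation: str
    overlap_fraction_of_shorter: float = 0.0

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation}")


def _edge_fraction(old: GeneModel, new: GeneModel) -> float:
    overlap = old.span.overlap_length(new.span)
    shorter = min(old.span.length, new.span.length)
    return overlap / shorter if shorter else 0.0


def map_versions(
    old_set: AnnotationSet,
    new_set: AnnotationSet,
    min_fraction: float = 0.5,
) -> list[VersionMapEntry]:
    """Bipartite overlap mapping between two annotation versions.

    Every gene of either set lands in exactly one entry; unmatched genes
    become OLD_ONLY/NEW_ONLY singletons.
    """
    edges: list[tuple[str, str, float]] = []
    new_by_seq: dict[str, list[GeneModel]] = {
        seq_id: new_set.genes_on(seq_id) for seq_id in new_set.seq_ids()
    }
    for old in old_set.sorted_genes():
        for new in new_by_seq.get(old.seq_id, []):
            if new.span.start >= old.span.end:
                break
            if new.strand != old.strand or not new.span.overlaps(old.span):
                continue
            fraction = _edge_fraction(old, new)
            if fraction >= min_fraction:
                edges.append((old.gene_id, new.gene_id, fraction))

    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(node):
        root = node
        while parent.setdefault(root, root) != root:
            root = parent[root]
        while parent[node] != root:
            parent[node], node = root, parent[node]
        return root

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for old_id, new_id, _ in edges:
        union(("old", old_id), ("new", new_id))

    components: dict[tuple[str, str], dict[str, list[str]]] = {}
    matched_old = {e[0] for e in edges}
    matched_new = {e[1] for e in edges}
    for old_id in matched_old:
        components.setdefault(find(("old", old_id)), {"old": [], "new": []})[
            "old"
        ].append(old_id)
    for new_id in matched_new:
        components.setdefault(find(("new", new_id)), {"old": [], "new": []})[
            "new"
        ].append(new_id)

    fractions: dict[tuple[str, str], float] = {}
    best_fraction: dict[tuple[str, str], float] = {}
    for old_id, new_id, fraction in edges:
        root = find(("old", old_id))
        best_fraction[root] = max(best_fraction.get(root, 0.0), fraction)
        fractions[(old_id, new_id)] = fraction

    entries: list[VersionMapEntry] = []
    for root, sides in components.items():
        olds = sorted(sides["old"])
        news = sorted(sides["new"])
        if len(olds) == 1 and len(news) == 1:
            relation = "ONE_TO_ONE"
        elif len(olds) == 1:
            relation = "ONE_TO_MANY"
        elif len(news) == 1:
            relation = "MANY_TO_ONE"
        else:
            relation = "MANY_TO_MANY"
        entries.append(
            VersionMapEntry(
                old_ids=olds,
                new_ids=news,
                relation=relation,
                overlap_fraction_of_shorter=best_fraction.get(root, 0.0),
            )
        )
    for old in old_set.sorted_genes():
        if old.gene_id not in matched_old:
            entries.append(
                VersionMapEntry(old_ids=[old.gene_id], new_ids=[], relation="OLD_ONLY")
            )
    for new in new_set.sorted_genes():
        if new.gene_id not in matched_new:
            entries.append(
                VersionMapEntry(old_ids=[], new_ids=[new.gene_id], relation="NEW_ONLY")
            )
    entries.sort(key=lambda e: (e.old_ids or e.new_ids))
    return entries


@dataclass
class MappingSummary:
    n_old: int
    n_new: int
    counts_by_relation: dict[str, int]
    mapped_old: int
    mapped_old_percent: float | None
    novel_new: int
    novel_new_percent: float | None
    broken_recovered: int | None = None
    broken_recovered_one_to_one: int | None = None
    broken_recovered_multi: int | None = None
    rows: list[tuple[str, str]] = field(default_factory=list)


def summarize_mapping(
    entries: list[VersionMapEntry],
    old_reports: list[ValidationReport] | None = None,
    te_labels: set[str] | None = None,
) -> MappingSummary:
    """Counts and percentages over a version mapping.

    With validation reports for the old set, additionally counts broken old
    genes recovered in the new version, stratified into one-to-one versus
    multi-gene relations.  TE-labeled new genes can be excluded from the
    novel-gene count.
    """
    counts = {rel: 0 for rel in RELATIONS}
    old_ids: set[str] = set()
    new_ids: set[str] = set()
    for entry in entries:
        counts[entry.relation] += 1
        old_ids.update(entry.old_ids)
        new_ids.update(entry.new_ids)
    n_old, n_new = len(old_ids), len(new_ids)
    mapped_old = sum(
        len(e.old_ids) for e in entries if e.relation not in {"OLD_ONLY", "NEW_ONLY"}
    )
    novel = [
        nid
        for e in entries
        if e.relation == "NEW_ONLY"
        for nid in e.new_ids
        if not (te_labels and nid in te_labels)
    ]
    summary = MappingSummary(
        n_old=n_old,
        n_new=n_new,
        counts_by_relation=counts,
        mapped_old=mapped_old,
        mapped_old_percent=percent(mapped_old, n_old, 1) if n_old else None,
        novel_new=len(novel),
        novel_new_percent=percent(len(novel), n_new, 1) if n_new else None,
    )
    if old_reports is not None:
        broken = {r.gene_id for r in old_reports if r.flags}
        recovered = one2one = multi = 0
        for entry in entries:
            if entry.relation in {"OLD_ONLY", "NEW_ONLY"}:
                continue
            hit = [oid for oid in entry.old_ids if oid in broken]
            recovered += len(hit)
            if entry.relation == "ONE_TO_ONE":
                one2one += len(hit)
            else:
                multi += len(hit)
        summary.broken_recovered = recovered
        summary.broken_recovered_one_to_one = one2one
        summary.broken_recovered_multi = multi
    return summary


def write_map_tsv(entries: list[VersionMapEntry], path) -> None:
    with open(path, "w") as handle:
        handle.write("relation\told_ids\tnew_ids\tfraction\n")
        for e in entries:
            handle.write(
                f"{e.relation}\t{','.join(e.old_ids)}\t{','.join(e.new_ids)}\t"
                f"{e.overlap_fraction_of_shorter:.3f}\n"
            )
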