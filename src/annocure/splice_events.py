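"""Alternative-splicing event extraction and classification.

Transcripts are grouped into loci by same-strand exonic overlap; within a
locus every transcript pair is compared over its common genomic extent and
each maximal region of differing intron structure becomes one elementary
event, classified as exon skipping (ES), alternative acceptor (AA),
alternative donor (AD), mutually exclusive exons (MX) or intron retention
(IR); anything more involved is COMPLEX.  Events are deduplicated across
pairs by their two variant intron structures.  An event is canonical when
every participating intron obeys the canonical donor/acceptor dinucleotides
and the minimum intron length, and UTR-localized when its variable region
overlaps no transcript's CDS in the locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .model import (
    BoundsError,
    Interval,
    TranscriptModel,
    reverse_complement,
)

EVENT_TYPES = ("ES", "AA", "AD", "MX", "IR", "COMPLEX")


@dataclass
class SpliceSiteRules:
    canonical_donors: frozenset[str] = frozenset({"GT"})
    canonical_acceptors: frozenset[str] = frozenset({"AG"})
    min_intron_length: int = 20

    def __post_init__(self) -> None:
        for mer in self.canonical_donors | self.canonical_acceptors:
            if len(mer) != 2 or set(mer) - set("ACGT"):
                raise ValueError(f"invalid splice-site 2-mer {mer!r}")


@dataclass
class ASEvent:
    event_type: str
    locus_id: str
    transcripts_a: frozenset[str]
    transcripts_b: frozenset[str]
    variable_region: Interval
    flank_left: int
    flank_right: int
    introns_a: tuple[tuple[int, int], ...]
    introns_b: tuple[tuple[int, int], ...]
    canonical: bool | None = None
    in_utr: bool | None = None


@dataclass
class Locus:
    locus_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def seq_id(self) -> str:
        return self.transcripts[0].seq_id

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand


def group_loci(transcripts: list[TranscriptModel]) -> list[Locus]:
    """Group transcripts into loci by same-strand exonic overlap (transitive)."""
    n = len(transcripts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
        if a.seq_id != b.seq_id or a.strand != b.strand:
            return False
        return any(ea.overlaps(eb) for ea in a.exons for eb in b.exons)

    for i in range(n):
        for j in range(i + 1, n):
            if exonic_overlap(transcripts[i], transcripts[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[TranscriptModel]] = {}
    for i, t in enumerate(transcripts):
        groups.setdefault(find(i), []).append(t)
    loci = []
    ordered = sorted(
        groups.values(), key=lambda ts: (ts[0].seq_id, min(t.span.start for t in ts))
    )
    for k, members in enumerate(ordered, start=1):
        members = sorted(members, key=lambda t: (t.span.start, t.transcript_id))
        loci.append(Locus(locus_id=f"locus{k}", transcripts=members))
    return loci


# ---------------------------------------------------------------------------
# Pairwise event extraction
# ---------------------------------------------------------------------------


def _introns(t: TranscriptModel) -> list[tuple[int, int]]:
    return [(iv.start, iv.end) for iv in t.introns()]


def _classify(
    side_a: list[tuple[int, int]],
    side_b: list[tuple[int, int]],
    strand: str,
    a_exonic: list[tuple[int, int]],
    b_exonic: list[tuple[int, int]],
) -> str | None:
    """Classify one bubble from the two sides' differing introns.

    ``side_a``/``side_b`` are the differing introns of each transcript in
    the bubble region; the exonic interval lists are used to verify intron
    retention (the intron-free side must be exonic across the intron).
    """

    def exonic_across(exons: list[tuple[int, int]], intron: tuple[int, int]) -> bool:
        return any(s <= intron[0] and intron[1] <= e for s, e in exons)

    if not side_a or not side_b:
        intron_side, exon_side = (side_a, b_exonic) if side_a else (side_b, a_exonic)
        region = (min(iv[0] for iv in intron_side), max(iv[1] for iv in intron_side))
        if not exonic_across(exon_side, region):
            # the intron-free side is not contiguous exon here, so its own
            # intron must cross the common-extent boundary: an alternative
            # start/end, not an elementary event
            return None
        if len(intron_side) == 1:
            return "IR"
        return "COMPLEX"

    if len(side_a) == 1 and len(side_b) == 1:
        (a_start, a_end), (b_start, b_end) = side_a[0], side_b[0]
        if a_start == b_start and a_end != b_end:
            # shared left boundary: donor on +, acceptor on −
            return "AA" if strand != "-" else "AD"
        if a_end == b_end and a_start != b_start:
            return "AD" if strand != "-" else "AA"
        return "COMPLEX"

    one, two = sorted((side_a, side_b), key=len)
    if len(one) == 1 and len(two) == 2:
        (s1, e1), (s2, e2) = two
        if one[0] == (s1, e2) and e1 < s2:
            # the two-intron side keeps an exon [e1, s2) that the other skips
            exon_holder = a_exonic if two is side_a else b_exonic
            if any(s <= e1 and s2 <= e for s, e in exon_holder):
                return "ES"
        return "COMPLEX"

    if len(side_a) == 2 and len(side_b) == 2:
        (a_s1, a_e1), (a_s2, a_e2) = side_a
        (b_s1, b_e1), (b_s2, b_e2) = side_b
        if a_s1 == b_s1 and a_e2 == b_e2:
            exon_a = (a_e1, a_s2)
            exon_b = (b_e1, b_s2)
            if exon_a != exon_b and (exon_a[1] <= exon_b[0] or exon_b[1] <= exon_a[0]):
                return "MX"
    return "COMPLEX"


def _pair_events(
    t1: TranscriptModel, t2: TranscriptModel
) -> list[tuple[tuple, dict]]:
    """Event bubbles between one transcript pair, as (dedup_key, payload)."""
    lo = max(t1.span.start, t2.span.start)
    hi = min(t1.span.end, t2.span.end)
    if lo >= hi:
        return []
    in1 = [iv for iv in _introns(t1) if lo <= iv[0] and iv[1] <= hi]
    in2 = [iv for iv in _introns(t2) if lo <= iv[0] and iv[1] <= hi]
    set1, set2 = set(in1), set(in2)
    diff1 = sorted(set1 - set2)
    diff2 = sorted(set2 - set1)
    if not diff1 and not diff2:
        return []

    # bubbles: connected components of differing introns under genomic overlap
    tagged = [(iv, 0) for iv in diff1] + [(iv, 1) for iv in diff2]
    tagged.sort()
    bubbles: list[list[tuple[tuple[int, int], int]]] = []
    cur: list[tuple[tuple[int, int], int]] = []
    cur_end = -1
    for iv, side in tagged:
        if cur and iv[0] >= cur_end:
            bubbles.append(cur)
            cur = []
            cur_end = -1
        cur.append((iv, side))
        cur_end = max(cur_end, iv[1])
    if cur:
        bubbles.append(cur)

    shared_bounds = sorted(
        {lo, hi}
        | {p for iv in (set1 & set2) for p in iv}
    )
    exonic1 = [(e.start, e.end) for e in t1.exons]
    exonic2 = [(e.start, e.end) for e in t2.exons]

    events = []
    for bubble in bubbles:
        side_a = sorted(iv for iv, side in bubble if side == 0)
        side_b = sorted(iv for iv, side in bubble if side == 1)
        region_start = min(iv[0] for iv, _ in bubble)
        region_end = max(iv[1] for iv, _ in bubble)
        event_type = _classify(side_a, side_b, t1.strand, exonic1, exonic2)
        if event_type is None:
            continue
        flank_left = max((p for p in shared_bounds if p < region_start), default=lo)
        flank_right = min((p for p in shared_bounds if p > region_end), default=hi)
        key = (tuple(sorted((tuple(side_a), tuple(side_b)))),)
        events.append(
            (
                key,
                {
                    "event_type": event_type,
                    "region": (region_start, region_end),
                    "flanks": (flank_left, flank_right),
                    "sides": (tuple(side_a), tuple(side_b)),
                    "pair": (t1.transcript_id, t2.transcript_id),
                },
            )
        )
    return events


def extract_events(locus: Locus) -> list[ASEvent]:
    """All deduplicated elementary AS events among a locus's isoforms."""
    transcripts = sorted(locus.transcripts, key=lambda t: t.transcript_id)
    if len(transcripts) < 2:
        return []
    collected: dict[tuple, dict] = {}
    sides_by_key: dict[tuple, tuple] = {}
    members_a: dict[tuple, set[str]] = {}
    members_b: dict[tuple, set[str]] = {}
    for i in range(len(transcripts)):
        for j in range(i + 1, len(transcripts)):
            for key, payload in _pair_events(transcripts[i], transcripts[j]):
                if key not in collected:
                    collected[key] = payload
                    sides_by_key[key] = payload["sides"]
                    members_a[key] = set()
                    members_b[key] = set()
                canon_a, _ = sides_by_key[key]
                t1_id, t2_id = payload["pair"]
                if payload["sides"][0] == canon_a:
                    members_a[key].add(t1_id)
                    members_b[key].add(t2_id)
                else:
                    members_a[key].add(t2_id)
                    members_b[key].add(t1_id)
    events = []
    for key, payload in collected.items():
        region_start, region_end = payload["region"]
        flank_left, flank_right = payload["flanks"]
        side_a, side_b = sides_by_key[key]
        events.append(
            ASEvent(
                event_type=payload["event_type"],
                locus_id=locus.locus_id,
                transcripts_a=frozenset(members_a[key]),
                transcripts_b=frozenset(members_b[key]),
                variable_region=Interval(
                    locus.seq_id, region_start, region_end, locus.strand
                ),
                flank_left=flank_left,
                flank_right=flank_right,
                introns_a=side_a,
                introns_b=side_b,
            )
        )
    events.sort(key=lambda e: (e.variable_region.start, e.event_type))
    return events


# ---------------------------------------------------------------------------
# Canonical splice sites and UTR localization
# ---------------------------------------------------------------------------


def intron_dinucleotides(
    seq_id: str, intron: tuple[int, int], strand: str, genome: dict[str, str]
) -> tuple[str, str]:
    """(donor, acceptor) 2-mers of an intron, strand-aware."""
    seq = genome.get(seq_id)
    if seq is None:
        raise BoundsError(f"sequence {seq_id} absent from genome")
    start, end = intron
    if start < 0 or end > len(seq) or end - start < 4:
        raise BoundsError(f"intron [{start},{end}) outside {seq_id} or too short")
    left = seq[start : start + 2].upper()
    right = seq[end - 2 : end].upper()
    if strand == "-":
        return reverse_complement(right), reverse_complement(left)
    return left, right


def is_canonical(
    event_or_intron: ASEvent | Interval,
    genome: dict[str, str],
    rules: SpliceSiteRules | None = None,
) -> bool:
    """True iff every participating intron is canonical and long enough."""
    rules = rules or SpliceSiteRules()

    def intron_ok(seq_id: str, intron: tuple[int, int], strand: str) -> bool:
        if intron[1] - intron[0] < rules.min_intron_length:
            return False
        donor, acceptor = intron_dinucleotides(seq_id, intron, strand, genome)
        return donor in rules.canonical_donors and acceptor in rules.canonical_acceptors

    if isinstance(event_or_intron, Interval):
        iv = event_or_intron
        return intron_ok(iv.seq_id, (iv.start, iv.end), iv.strand)
    event = event_or_intron
    seq_id = event.variable_region.seq_id
    strand = event.variable_region.strand
    return all(
        intron_ok(seq_id, intron, strand)
        for intron in (*event.introns_a, *event.introns_b)
    )


def localize_event(event: ASEvent, locus: Locus) -> bool:
    """True iff the variable region overlaps no transcript's CDS in the locus."""
    cds = [
        (c.start, c.end) for t in locus.transcripts for c in t.cds_segments
    ]
    if not cds:
        warnings.warn(
            f"locus {locus.locus_id} has no CDS; event treated as UTR-localized",
            stacklevel=2,
        )
        return True
    region = event.variable_region
    return not any(start < region.end and region.start < end for start, end in cds)


def annotate_events(
    loci: list[Locus],
    genome: dict[str, str] | None = None,
    rules: SpliceSiteRules | None = None,
) -> list[ASEvent]:
    """Extract, canonical-flag and UTR-localize events across loci."""
    events = []
    for locus in loci:
        for event in extract_events(locus):
            if genome is not None:
                event.canonical = is_canonical(event, genome, rules)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                event.in_utr = localize_event(event, locus)
            events.append(event)
    return events


def count_by_type(events: list[ASEvent]) -> dict[str, int]:
    counts = {etype: 0 for etype in EVENT_TYPES}
    for event in events:
        counts[event.event_type] += 1
    return counts


def write_events_tsv(events: list[ASEvent], path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "locus_id\tevent_type\tseq_id\tflank_left\tflank_right\t"
            "transcripts_a\ttranscripts_b\tcanonical\tin_utr\n"
        )
        for e in events:
            handle.write(
                f"{e.locus_id}\t{e.event_type}\t{e.variable_region.seq_id}\t"
                f"{e.flank_left}\t{e.flank_right}\t"
                f"{','.join(sorted(e.transcripts_a))}\t"
                f"{','.join(sorted(e.transcripts_b))}\t"
                f"{e.canonical}\t{e.in_utr}\n"
            )
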