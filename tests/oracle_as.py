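"""Independent brute-force AS-event enumerator used as a test oracle.

Works from per-base exonic masks rather than intron sets, so it shares no
code path with the package's classifier.  For each transcript pair over
their common genomic extent it finds maximal runs of differing exonic
status, groups runs separated by gaps that are intronic in both
transcripts, and classifies each group from its flanking context:

* run flanked by exon on both sides in both transcripts → intron retention
* run flanked by intron on both sides in both transcripts → exon skipping
* one exon-exon flank and one intron-intron flank → alternative acceptor
  or donor, decided by which side holds the shared splice boundary and the
  strand
* two runs, exonic in opposite transcripts, separated and flanked by
  both-intron context → mutually exclusive exons
* anything else → COMPLEX
"""

from __future__ import annotations


def _mask(transcript, lo: int, hi: int) -> list[bool]:
    m = [False] * (hi - lo)
    for e in transcript.exons:
        for p in range(max(e.start, lo), min(e.end, hi)):
            m[p - lo] = True
    return m


def _runs(m1: list[bool], m2: list[bool]) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, (a, b) in enumerate(zip(m1, m2)):
        if a != b:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(m1)))
    return runs


def _pure_side(m1, m2, run) -> int | None:
    """0 if transcript 1 is exonic throughout the run, 1 for transcript 2,
    None if the exonic side switches inside the run."""
    s, e = run
    if all(m1[i] for i in range(s, e)):
        return 0
    if all(m2[i] for i in range(s, e)):
        return 1
    return None


def oracle_pair_events(t1, t2) -> list[tuple[str, tuple]]:
    """(event_type, dedup_key) for every event between two transcripts."""
    lo = max(t1.span.start, t2.span.start)
    hi = min(t1.span.end, t2.span.end)
    if lo >= hi:
        return []
    m1 = _mask(t1, lo, hi)
    m2 = _mask(t2, lo, hi)
    runs = _runs(m1, m2)
    if not runs:
        return []

    def both_intron_gap(a_end: int, b_start: int) -> bool:
        return all(not m1[i] and not m2[i] for i in range(a_end, b_start))

    groups: list[list[tuple[int, int]]] = []
    current = [runs[0]]
    for run in runs[1:]:
        if both_intron_gap(current[-1][1], run[0]):
            current.append(run)
        else:
            groups.append(current)
            current = [run]
    groups.append(current)

    def context(pos: int) -> str:
        if pos < 0 or pos >= hi - lo:
            return "edge"
        a, b = m1[pos], m2[pos]
        if a and b:
            return "exon"
        if not a and not b:
            return "intron"
        return "edge"  # unreachable at a run boundary

    events = []
    strand = t1.strand
    for group in groups:
        left = context(group[0][0] - 1)
        right = context(group[-1][1])
        if left == "edge" or right == "edge":
            # differing region touching the common-extent boundary: an
            # alternative start/end, not an elementary AS event (no shared
            # flank on that side)
            continue
        sides = [_pure_side(m1, m2, run) for run in group]
        # relabel sides so the first run's exonic transcript is side 0,
        # making the dedup key independent of pair ordering
        anchor_side = sides[0] if sides[0] is not None else 0
        key_runs = tuple(
            (lo + s, lo + e, side ^ anchor_side if side is not None else -1)
            for (s, e), side in zip(group, sides)
        )
        etype = "COMPLEX"
        if len(group) == 1 and sides[0] is not None:
            if left == "exon" and right == "exon":
                etype = "IR"
            elif left == "intron" and right == "intron":
                etype = "ES"
            elif {left, right} == {"exon", "intron"}:
                # the intron-context side holds the shared splice boundary
                if left == "intron":
                    etype = "AA" if strand != "-" else "AD"
                else:
                    etype = "AD" if strand != "-" else "AA"
        elif (
            len(group) == 2
            and None not in sides
            and sides[0] != sides[1]
            and left == "intron"
            and right == "intron"
        ):
            etype = "MX"
        events.append((etype, key_runs))
    return events


def oracle_locus_counts(transcripts) -> dict[str, int]:
    """Deduplicated per-type event counts for one locus."""
    seen: dict[tuple, str] = {}
    ordered = sorted(transcripts, key=lambda t: t.transcript_id)
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            for etype, key in oracle_pair_events(ordered[i], ordered[j]):
                seen.setdefault(key, etype)
    counts: dict[str, int] = {}
    for etype in seen.values():
        counts[etype] = counts.get(etype, 0) + 1
    return counts
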