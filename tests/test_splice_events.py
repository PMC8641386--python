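import itertools

import numpy as np
import pytest

from annocure.fixtures import EventSpec, GeneParams, generate_genome, plant_genes, plant_isoforms
from annocure.model import Interval
from annocure.splice_events import (
    Locus,
    SpliceSiteRules,
    annotate_events,
    count_by_type,
    extract_events,
    group_loci,
    is_canonical,
    localize_event,
)

from conftest import make_transcript
from oracle_as import oracle_locus_counts


class TestGroupLoci:
    def test_overlapping_same_strand_one_locus(self):
        t1 = make_transcript([(0, 100), (200, 300)], tid="a")
        t2 = make_transcript([(50, 100), (200, 280)], tid="b")
        assert len(group_loci([t1, t2])) == 1

    def test_opposite_strands_stay_apart(self):
        t1 = make_transcript([(0, 100)], tid="a")
        t2 = make_transcript([(0, 100)], strand="-", tid="b")
        assert len(group_loci([t1, t2])) == 2

    def test_transitive_closure(self):
        a = make_transcript([(0, 100)], tid="a")
        b = make_transcript([(80, 200)], tid="b")
        c = make_transcript([(180, 300)], tid="c")  # no overlap with a
        assert len(group_loci([a, b, c])) == 1

    def test_intron_only_overlap_is_not_exonic(self):
        a = make_transcript([(0, 50), (500, 550)], tid="a")
        b = make_transcript([(100, 200)], tid="b")  # inside a's intron
        assert len(group_loci([a, b])) == 2


def locus_of(*transcripts):
    return Locus(locus_id="L", transcripts=list(transcripts))


class TestExtractEvents:
    def test_exon_skipping(self):
        full = make_transcript([(0, 100), (200, 300), (400, 500)], tid="full")
        skip = make_transcript([(0, 100), (400, 500)], tid="skip")
        events = extract_events(locus_of(full, skip))
        assert [e.event_type for e in events] == ["ES"]
        assert (events[0].variable_region.start, events[0].variable_region.end) == (100, 400)

    def test_intron_retention(self):
        spliced = make_transcript([(0, 100), (200, 300)], tid="s")
        retained = make_transcript([(0, 300)], tid="r")
        events = extract_events(locus_of(spliced, retained))
        assert [e.event_type for e in events] == ["IR"]

    @pytest.mark.parametrize(
        "strand,alt_exons,expected",
        [
            ("+", [(0, 100), (250, 300)], "AA"),  # shared donor at 100
            ("+", [(0, 150), (200, 300)], "AD"),  # shared acceptor at 200
            ("-", [(0, 100), (250, 300)], "AD"),  # minus strand swaps roles
            ("-", [(0, 150), (200, 300)], "AA"),
        ],
    )
    def test_alternative_sites_strand_aware(self, strand, alt_exons, expected):
        base = make_transcript([(0, 100), (200, 300)], strand=strand, tid="base")
        alt = make_transcript(alt_exons, strand=strand, tid="alt")
        events = extract_events(locus_of(base, alt))
        assert [e.event_type for e in events] == [expected]

    def test_mutually_exclusive_exons(self):
        a = make_transcript([(0, 100), (200, 240), (400, 500)], tid="a")
        b = make_transcript([(0, 100), (300, 340), (400, 500)], tid="b")
        events = extract_events(locus_of(a, b))
        assert [e.event_type for e in events] == ["MX"]

    def test_single_transcript_locus_empty(self):
        t = make_transcript([(0, 100), (200, 300)], tid="only")
        assert extract_events(locus_of(t)) == []

    def test_permutation_invariance(self):
        full = make_transcript([(0, 100), (200, 300), (400, 500)], tid="full")
        skip = make_transcript([(0, 100), (400, 500)], tid="skip")
        ret = make_transcript([(0, 100), (200, 500)], tid="ret")
        reference = None
        for perm in itertools.permutations([full, skip, ret]):
            counts = count_by_type(extract_events(locus_of(*perm)))
            if reference is None:
                reference = counts
            assert counts == reference

    def test_events_deduplicated_across_pairs(self):
        # the same skipped exon seen against two identical long isoforms
        full1 = make_transcript([(0, 100), (200, 300), (400, 500)], tid="f1")
        full2 = make_transcript([(0, 100), (200, 300), (400, 510)], tid="f2")
        skip = make_transcript([(0, 100), (400, 500)], tid="skip")
        events = extract_events(locus_of(full1, full2, skip))
        assert count_by_type(events)["ES"] == 1
        es = next(e for e in events if e.event_type == "ES")
        assert es.transcripts_a | es.transcripts_b == {"f1", "f2", "skip"}


class TestCanonical:
    GENOME = {"chr1": "A" * 10 + "GT" + "C" * 86 + "AG" + "A" * 10}

    def test_gt_ag_long_intron_is_canonical(self):
        intron = Interval("chr1", 10, 100, "+")
        assert is_canonical(intron, self.GENOME)

    def test_wrong_dinucleotides_not_canonical(self):
        genome = {"chr1": "A" * 10 + "CT" + "C" * 86 + "AC" + "A" * 10}
        assert not is_canonical(Interval("chr1", 10, 100, "+"), genome)

    def test_minus_strand_reads_reverse_complement(self):
        # plus strand CT...AC reads GT...AG on the minus strand
        genome = {"chr1": "A" * 10 + "CT" + "C" * 86 + "AC" + "A" * 10}
        assert is_canonical(Interval("chr1", 10, 100, "-"), genome)

    def test_short_intron_fails_basic_rules(self):
        genome = {"chr1": "GT" + "C" * 6 + "AG" + "A" * 10}
        intron = Interval("chr1", 0, 10, "+")
        assert not is_canonical(intron, genome, SpliceSiteRules(min_intron_length=20))
        assert is_canonical(intron, genome, SpliceSiteRules(min_intron_length=4))


class TestLocalize:
    def test_event_beyond_stop_is_utr(self):
        t1 = make_transcript([(0, 100), (200, 300)], cds_pairs=[(0, 90)], tid="a")
        t2 = make_transcript([(0, 300)], cds_pairs=[(0, 90)], tid="b")
        locus = locus_of(t1, t2)
        events = extract_events(locus)
        assert localize_event(events[0], locus)

    def test_event_in_cds_is_not_utr(self):
        t1 = make_transcript([(0, 100), (200, 300)], cds_pairs=[(0, 100), (200, 300)], tid="a")
        t2 = make_transcript([(0, 300)], cds_pairs=[(0, 300)], tid="b")
        locus = locus_of(t1, t2)
        assert not localize_event(extract_events(locus)[0], locus)

    def test_cdsless_locus_warns_and_returns_true(self):
        t1 = make_transcript([(0, 100), (200, 300)], tid="a")
        t2 = make_transcript([(0, 300)], tid="b")
        locus = locus_of(t1, t2)
        with pytest.warns(UserWarning):
            assert localize_event(extract_events(locus)[0], locus)


class TestPlantedEventsAgreement:
    def test_full_recipe_matches_truth(self):
        genome = generate_genome(7, 2, (60_000, 60_000))
        params = GeneParams(exons_per_gene_range=(3, 6), intron_length_range=(100, 180))
        aset = plant_genes(genome, 7, 30, params)
        specs = [
            EventSpec(t, canonical=c, in_utr=u)
            for t, c, u in [
                ("ES", True, False), ("IR", True, False), ("AA", True, False),
                ("AD", True, False), ("MX", True, False), ("ES", False, False),
                ("IR", False, False), ("AA", False, False), ("AD", False, False),
                ("MX", False, False), ("IR", True, True), ("ES", True, True),
                ("IR", False, True), ("ES", False, True),
            ]
        ]
        iso, truth = plant_isoforms(aset, genome, 7, specs)
        transcripts = [t for g in iso for t in g.transcripts]
        events = annotate_events(group_loci(transcripts), genome)
        found = sorted((e.event_type, e.canonical, e.in_utr) for e in events)
        expected = sorted((t["event_type"], t["canonical"], t["in_utr"]) for t in truth)
        assert found == expected

    def test_filter_nesting(self):
        genome = generate_genome(9, 2, (60_000, 60_000))
        params = GeneParams(exons_per_gene_range=(3, 6), intron_length_range=(100, 180))
        aset = plant_genes(genome, 9, 20, params)
        iso, _ = plant_isoforms(
            aset, genome, 9, {"ES": 3, "IR": 3, "AA": 2, "AD": 2, "MX": 2}
        )
        transcripts = [t for g in iso for t in g.transcripts]
        events = annotate_events(group_loci(transcripts), genome)
        counts = count_by_type(events)
        classified = sum(counts[t] for t in ("ES", "AA", "AD", "MX", "IR"))
        assert sum(1 for e in events if e.canonical) <= len(events)
        assert classified <= len(events)


class TestOracleEquivalence:
    def test_random_loci_match_brute_force(self):
        """Typed event counts equal the mask-based enumerator on random
        planted loci with up to 5 isoforms and 10 exons."""
        rng = np.random.default_rng(1234)
        types = ["ES", "IR", "AA", "AD", "MX"]
        n_loci = 0
        for seed in range(1, 4):
            genome = generate_genome(seed, 2, (80_000, 80_000))
            params = GeneParams(exons_per_gene_range=(3, 7), intron_length_range=(100, 200))
            aset = plant_genes(genome, seed, 30, params)
            specs = []
            for gene in aset:
                for _ in range(int(rng.integers(1, 3))):
                    t = types[int(rng.integers(0, 5))]
                    specs.append(
                        EventSpec(
                            t,
                            canonical=bool(rng.random() < 0.7),
                            in_utr=bool(rng.random() < 0.2 and t in ("ES", "IR")),
                            gene_id=gene.gene_id,
                        )
                    )
            iso, _ = plant_isoforms(aset, genome, seed, specs)
            for locus in group_loci([t for g in iso for t in g.transcripts]):
                n_loci += 1
                impl = {k: v for k, v in count_by_type(extract_events(locus)).items() if v}
                assert impl == oracle_locus_counts(locus.transcripts), locus.locus_id
        assert n_loci >= 60
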