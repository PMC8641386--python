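import pytest

from annocure.model import AnnotationSet
from annocure.validate import ValidationFlag, ValidationReport
from annocure.version_map import map_versions, percent, summarize_mapping

from conftest import make_gene


class TestPercent:
    @pytest.mark.parametrize(
        "num,den,digits,expected",
        [
            (589, 789, 1, 74.7),
            (0, 7, 1, 0.0),
            (721, 1772, 2, 40.69),
            (17639, 18018, 1, 97.9),
            (1, 8, 1, 12.5),
            (1, 16, 1, 6.3),  # rounds half away from zero
        ],
    )
    def test_values(self, num, den, digits, expected):
        assert percent(num, den, digits) == expected

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)


def one_exon_gene(gene_id, start, end, seq_id="chr1", strand="+"):
    return make_gene(
        [(start, end)], seq_id=seq_id, strand=strand,
        cds_pairs=[(start, end)], gene_id=gene_id,
    )


class TestMapVersions:
    def test_identical_sets_all_one_to_one(self):
        old = AnnotationSet([one_exon_gene(f"o{i}", i * 100, i * 100 + 60) for i in range(5)])
        new = AnnotationSet([one_exon_gene(f"n{i}", i * 100, i * 100 + 60) for i in range(5)])
        entries = map_versions(old, new)
        assert all(e.relation == "ONE_TO_ONE" for e in entries)
        assert all(e.overlap_fraction_of_shorter == 1.0 for e in entries)

    def test_one_old_split_into_four_new(self):
        old = AnnotationSet([one_exon_gene("big", 0, 4000)])
        new = AnnotationSet(
            [one_exon_gene(f"n{i}", i * 1000, i * 1000 + 800) for i in range(4)]
        )
        entries = map_versions(old, new)
        assert len(entries) == 1
        assert entries[0].relation == "ONE_TO_MANY"
        assert len(entries[0].new_ids) == 4

    def test_nine_old_fragments_joined_into_one_new(self):
        old = AnnotationSet(
            [one_exon_gene(f"o{i}", i * 500, i * 500 + 400) for i in range(9)]
        )
        new = AnnotationSet([one_exon_gene("joined", 0, 4400)])
        entries = map_versions(old, new)
        assert entries[0].relation == "MANY_TO_ONE"
        assert len(entries[0].old_ids) == 9

    def test_opposite_strand_never_maps(self):
        old = AnnotationSet([one_exon_gene("o", 0, 600)])
        new = AnnotationSet([one_exon_gene("n", 0, 600, strand="-")])
        relations = {e.relation for e in map_versions(old, new)}
        assert relations == {"OLD_ONLY", "NEW_ONLY"}

    def test_every_gene_in_exactly_one_entry(self, bundle42):
        entries = map_versions(bundle42.truth.true_genes, bundle42.predicted)
        olds = [oid for e in entries for oid in e.old_ids]
        news = [nid for e in entries for nid in e.new_ids]
        assert sorted(olds) == sorted(bundle42.truth.true_genes.gene_ids())
        assert sorted(news) == sorted(bundle42.predicted.gene_ids())

    def test_symmetry_swaps_relations(self, bundle42):
        fwd = map_versions(bundle42.truth.true_genes, bundle42.predicted)
        rev = map_versions(bundle42.predicted, bundle42.truth.true_genes)
        swap = {"ONE_TO_MANY": "MANY_TO_ONE", "MANY_TO_ONE": "ONE_TO_MANY",
                "OLD_ONLY": "NEW_ONLY", "NEW_ONLY": "OLD_ONLY"}

        def canon(entries, flip):
            out = set()
            for e in entries:
                rel = swap.get(e.relation, e.relation) if flip else e.relation
                olds, news = (e.new_ids, e.old_ids) if flip else (e.old_ids, e.new_ids)
                out.add((rel, tuple(sorted(olds)), tuple(sorted(news))))
            return out

        assert canon(fwd, False) == canon(rev, True)

    def test_raising_threshold_never_adds_edges(self, bundle42):
        def mapped_pairs(min_fraction):
            pairs = set()
            for e in map_versions(
                bundle42.truth.true_genes, bundle42.predicted, min_fraction
            ):
                for o in e.old_ids:
                    for n in e.new_ids:
                        pairs.add((o, n))
            return pairs

        p3, p5, p7 = (mapped_pairs(f) for f in (0.3, 0.5, 0.7))
        assert p7 <= p5 <= p3


class TestSummarize:
    def test_planted_novel_genes_counted(self):
        old = AnnotationSet([one_exon_gene(f"o{i}", i * 1000, i * 1000 + 600) for i in range(3)])
        new_genes = [one_exon_gene(f"n{i}", i * 1000, i * 1000 + 600) for i in range(3)]
        new_genes += [one_exon_gene(f"novel{i}", 10_000 + i * 1000, 10_000 + i * 1000 + 400)
                      for i in range(5)]
        entries = map_versions(old, AnnotationSet(new_genes))
        summary = summarize_mapping(entries)
        assert summary.counts_by_relation["NEW_ONLY"] == 5
        assert summary.novel_new == 5

    def test_broken_gene_recovery_stratified(self):
        old = AnnotationSet([
            one_exon_gene("broken1", 0, 600),
            one_exon_gene("broken2", 1000, 1600),
            one_exon_gene("ok", 3000, 3600),
        ])
        new = AnnotationSet([
            one_exon_gene("n1", 0, 600),
            one_exon_gene("n2a", 1000, 1300),
            one_exon_gene("n2b", 1301, 1600),
            one_exon_gene("n3", 3000, 3600),
        ])
        reports = [
            ValidationReport("broken1", {ValidationFlag.PREMATURE_STOP}),
            ValidationReport("broken2", {ValidationFlag.MISSING_STOP}),
            ValidationReport("ok", set()),
        ]
        entries = map_versions(old, new)
        summary = summarize_mapping(entries, reports)
        assert summary.broken_recovered == 2
        assert summary.broken_recovered_one_to_one == 1
        assert summary.broken_recovered_multi == 1
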