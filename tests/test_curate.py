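import pytest

from annocure.curate import (
    BookkeepingError,
    CurationAction,
    CurationConfig,
    CurationLog,
    MergeCandidate,
    apply_actions,
    cluster_evidence,
    curate,
    detect_merge_candidates,
    detect_split_candidates,
    find_longest_orf,
    rescue_missing,
)
from annocure.model import (
    AnnotationSet,
    EvidenceAlignment,
    EvidenceKind,
    Interval,
)

from conftest import make_gene


def ev(eid, kind, blocks, seq_id="chr1", strand="+"):
    return EvidenceAlignment(
        evidence_id=eid,
        kind=kind,
        blocks=[Interval(seq_id, s, e, strand) for s, e in blocks],
    )


class TestClusterEvidence:
    def test_disjoint_proteins_make_two_clusters(self):
        evidences = [
            ev("p1", EvidenceKind.PROTEIN, [(0, 900)]),
            ev("p2", EvidenceKind.PROTEIN, [(1100, 2000)]),
        ]
        assert len(cluster_evidence(evidences)) == 2

    def test_bridging_long_read_joins_clusters(self):
        evidences = [
            ev("p1", EvidenceKind.PROTEIN, [(0, 900)]),
            ev("p2", EvidenceKind.PROTEIN, [(1100, 2000)]),
            ev("lr", EvidenceKind.LONG_READ, [(800, 1300)]),
        ]
        clusters = cluster_evidence(evidences)
        assert len(clusters) == 1 and len(clusters[0].members) == 3

    def test_empty_input(self):
        assert cluster_evidence([]) == []

    def test_opposite_strands_never_connect(self):
        evidences = [
            ev("p1", EvidenceKind.PROTEIN, [(0, 900)]),
            ev("p2", EvidenceKind.PROTEIN, [(500, 2000)], strand="-"),
        ]
        assert len(cluster_evidence(evidences)) == 2


class TestDetectSplitCandidates:
    def fused_gene_set(self):
        gene = make_gene([(0, 2000)], cds_pairs=[(0, 2000)], gene_id="fused")
        return AnnotationSet([gene])

    def test_two_anchored_clusters_propose_midpoint(self):
        evidences = [
            ev("p1", EvidenceKind.PROTEIN, [(0, 900)]),
            ev("p2", EvidenceKind.PROTEIN, [(1100, 2000)]),
        ]
        cands = detect_split_candidates(self.fused_gene_set(), evidences)
        assert len(cands) == 1
        assert cands[0].gene_id == "fused"
        assert cands[0].boundaries == [1000]

    def test_bridging_evidence_vetoes(self):
        evidences = [
            ev("p1", EvidenceKind.PROTEIN, [(0, 900)]),
            ev("p2", EvidenceKind.PROTEIN, [(1100, 2000)]),
            ev("lr", EvidenceKind.LONG_READ, [(500, 1500)]),
        ]
        assert detect_split_candidates(self.fused_gene_set(), evidences) == []

    def test_single_cluster_not_a_candidate(self):
        evidences = [ev("p1", EvidenceKind.PROTEIN, [(0, 1800)])]
        assert detect_split_candidates(self.fused_gene_set(), evidences) == []

    def test_unanchored_cluster_not_a_candidate(self):
        # two clusters but one holds only a short-read assembly
        evidences = [
            ev("p1", EvidenceKind.PROTEIN, [(0, 900)]),
            ev("sr", EvidenceKind.SHORT_READ_ASSEMBLY, [(1100, 2000)]),
        ]
        assert detect_split_candidates(self.fused_gene_set(), evidences) == []


class TestDetectMergeCandidates:
    def two_fragments(self):
        a = make_gene([(0, 500)], cds_pairs=[(0, 500)], gene_id="a")
        b = make_gene([(700, 1200)], cds_pairs=[(700, 1200)], gene_id="b")
        return AnnotationSet([a, b])

    def test_two_spanning_evidences_qualify(self):
        evidences = [
            ev("p", EvidenceKind.PROTEIN, [(0, 500), (700, 1200)]),
            ev("lr", EvidenceKind.LONG_READ, [(0, 1200)]),
        ]
        cands = detect_merge_candidates(self.two_fragments(), evidences)
        assert [c.gene_ids for c in cands] == [["a", "b"]]

    def test_opposite_strand_genes_not_merged(self):
        a = make_gene([(0, 500)], cds_pairs=[(0, 500)], gene_id="a")
        b = make_gene([(700, 1200)], strand="-", cds_pairs=[(700, 1200)], gene_id="b")
        evidences = [
            ev("p", EvidenceKind.PROTEIN, [(0, 1200)]),
            ev("lr", EvidenceKind.LONG_READ, [(0, 1200)]),
        ]
        assert detect_merge_candidates(AnnotationSet([a, b]), evidences) == []

    def test_pairwise_chains_stay_pairwise(self):
        # evidence covers a+b and b+c but nothing covers all three
        a = make_gene([(0, 400)], cds_pairs=[(0, 400)], gene_id="a")
        b = make_gene([(600, 1000)], cds_pairs=[(600, 1000)], gene_id="b")
        c = make_gene([(1200, 1600)], cds_pairs=[(1200, 1600)], gene_id="c")
        evidences = [
            ev("p_ab", EvidenceKind.PROTEIN, [(0, 1000)]),
            ev("lr_ab", EvidenceKind.LONG_READ, [(0, 1000)]),
            ev("p_bc", EvidenceKind.PROTEIN, [(600, 1600)]),
            ev("lr_bc", EvidenceKind.LONG_READ, [(600, 1600)]),
        ]
        cands = detect_merge_candidates(AnnotationSet([a, b, c]), evidences)
        assert sorted(tuple(c.gene_ids) for c in cands) == [("a", "b"), ("b", "c")]

    def test_insufficient_support_count(self):
        evidences = [ev("p", EvidenceKind.PROTEIN, [(0, 1200)])]
        assert detect_merge_candidates(self.two_fragments(), evidences) == []


class TestApplyActions:
    def test_split_copies_prior_structures(self):
        fused = make_gene([(0, 2000)], cds_pairs=[(0, 2000)], gene_id="fused")
        aset = AnnotationSet([fused])
        prior_a = make_gene([(0, 300), (600, 900)], cds_pairs=[(0, 300), (600, 900)], gene_id="pa")
        prior_b = make_gene([(1100, 2000)], cds_pairs=[(1100, 2000)], gene_id="pb")
        prior = AnnotationSet([prior_a, prior_b])
        evidences = [
            ev("p1", EvidenceKind.PROTEIN, [(0, 900)]),
            ev("p2", EvidenceKind.PROTEIN, [(1100, 2000)]),
        ]
        cands = detect_split_candidates(aset, evidences)
        out, log = apply_actions(aset, cands, prior_set=prior)
        assert len(out) == 2
        spans = sorted((g.span.start, g.span.end) for g in out)
        assert spans == [(0, 900), (1100, 2000)]
        assert log.counts() == {"SPLIT": 1}

    def test_merge_recovers_true_cds(self):
        # one true gene ATG...TAA split into two fragment models, the first
        # of which lacks a stop codon; the merged ORF equals the true CDS
        cds = "ATG" + "GCA" * 20 + "TAA"  # 66 nt
        genome = {"chr1": "C" * 10 + cds + "C" * 30}
        a = make_gene([(10, 40)], cds_pairs=[(10, 40)], gene_id="a")
        b = make_gene([(40, 76)], cds_pairs=[(40, 76)], gene_id="b")
        aset = AnnotationSet([a, b])
        cand = MergeCandidate(
            gene_ids=["a", "b"],
            supporting_evidence=[ev("p", EvidenceKind.PROTEIN, [(10, 76)])],
        )
        out, log = apply_actions(aset, [cand], genome=genome)
        merged = next(iter(out))
        assert [(c.start, c.end) for c in merged.transcripts[0].cds_segments] == [(10, 76)]
        assert log.counts() == {"MERGE": 1}

    def test_empty_candidates_is_identity(self, bundle42):
        out, log = apply_actions(bundle42.predicted, [])
        assert out.gene_ids() == bundle42.predicted.gene_ids()
        assert log.actions == []

    def test_unresolved_split_is_logged_not_applied(self):
        # boundary at 1000 cuts the CDS mid-codon and no prior model exists
        fused = make_gene([(0, 2000)], cds_pairs=[(0, 2000)], gene_id="fused")
        aset = AnnotationSet([fused])
        evidences = [
            ev("p1", EvidenceKind.PROTEIN, [(0, 900)]),
            ev("p2", EvidenceKind.PROTEIN, [(1100, 2000)]),
        ]
        cands = detect_split_candidates(aset, evidences)
        out, log = apply_actions(aset, cands, prior_set=None)
        assert out.gene_ids() == ["fused"]
        assert log.counts() == {"UNRESOLVED": 1}


class TestRescue:
    def make_world(self, new_gene=False, coverage_end=12):
        cds = "ATGAAAGGGTAG"  # 12 nt, structurally clean
        genome = {"chr1": cds + "G" * 100}
        prior = AnnotationSet(
            [make_gene([(0, 12)], cds_pairs=[(0, 12)], gene_id="old1")]
        )
        new_genes = []
        if new_gene:
            new_genes.append(make_gene([(0, 12)], cds_pairs=[(0, 12)], gene_id="new1"))
        new = AnnotationSet(new_genes)
        proteins = [ev("p", EvidenceKind.PROTEIN, [(0, coverage_end)])]
        return prior, new, proteins, genome

    def test_clean_supported_gene_rescued(self):
        prior, new, proteins, genome = self.make_world()
        added, actions = rescue_missing(prior, new, proteins, genome)
        assert [g.attributes["rescued_from"] for g in added] == ["old1"]
        assert actions[0].action == "RESCUE"

    def test_overlap_with_new_gene_blocks_rescue(self):
        prior, new, proteins, genome = self.make_world(new_gene=True)
        added, _ = rescue_missing(prior, new, proteins, genome)
        assert added == []

    def test_coverage_exactly_at_threshold_rescued(self):
        # protein covers 6/12 = exactly the 0.5 default (≥ semantics); 5/12 fails
        prior, new, proteins, genome = self.make_world(coverage_end=6)
        assert len(rescue_missing(prior, new, proteins, genome)[0]) == 1
        prior, new, proteins, genome = self.make_world(coverage_end=5)
        assert rescue_missing(prior, new, proteins, genome)[0] == []


class TestBookkeepingAndIdempotence:
    def test_log_identity_violation_raises(self):
        log = CurationLog()
        log.append(
            CurationAction("RESCUE", [], ["x"], [])
        )
        with pytest.raises(BookkeepingError):
            log.verify(10, 10)  # one rescue must yield 11 genes

    def test_full_curation_recovers_planted_errors(self, bundle42):
        curated, log = curate(
            bundle42.predicted,
            bundle42.evidences,
            bundle42.truth.true_genes,
            bundle42.genome,
        )
        counts = log.counts()
        assert counts.get("SPLIT") == len(bundle42.truth.planted_fusions)
        assert counts.get("MERGE") == len(bundle42.truth.planted_fissions)
        assert counts.get("RESCUE") == len(bundle42.truth.dropped_genes)
        log.verify(len(bundle42.predicted), len(curated))

    def test_second_pass_is_noop(self, bundle42):
        curated, _ = curate(
            bundle42.predicted,
            bundle42.evidences,
            bundle42.truth.true_genes,
            bundle42.genome,
        )
        again, log2 = curate(
            curated, bundle42.evidences, bundle42.truth.true_genes, bundle42.genome
        )
        assert log2.actions == []
        assert again.gene_ids() == curated.gene_ids()


class TestLongestOrf:
    def test_finds_orf_and_prefers_longest(self):
        seq = "CCATGAAATAACCATGGCAGCAGCATAGCC"
        start, end = find_longest_orf(seq)
        assert seq[start:end] == "ATGGCAGCAGCATAG"

    def test_no_orf(self):
        assert find_longest_orf("CCCCCCCC") is None
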