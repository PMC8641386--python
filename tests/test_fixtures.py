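import numpy as np
import pytest

from annocure.fixtures import (
    CorruptionRecipe,
    EvidenceProfile,
    GeneParams,
    corrupt,
    emit_evidence,
    generate_bundle,
    generate_genome,
    plant_genes,
)
from annocure.model import EvidenceKind, extract_spliced_sequence, translate
from annocure.validate import validate_set


class TestGenerateGenome:
    def test_deterministic(self):
        a = generate_genome(1, 2, (10_000, 10_000))
        b = generate_genome(1, 2, (10_000, 10_000))
        assert a == b

    def test_names_cover_lg_and_scaffold(self):
        genome = generate_genome(1, 4, (10_000,) * 4)
        assert list(genome) == ["LG1", "LG2", "sc1", "sc2"]

    def test_gc_zero_is_at_only(self):
        genome = generate_genome(3, 1, (10_000,), gc=0.0)
        assert set(genome["LG1"]) <= {"A", "T"}

    def test_stream_stability_across_n(self):
        two = generate_genome(5, 2, (10_000, 10_000))
        three = generate_genome(5, 3, (10_000, 10_000, 10_000))
        assert two["LG1"] == three["LG1"]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(1, 1, (100,))


class TestPlantGenes:
    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_clean_generation_guarantee(self, seed):
        genome = generate_genome(seed, 2, (50_000, 50_000))
        aset = plant_genes(genome, seed, 40)
        _, summary = validate_set(aset, genome)
        assert summary.n_flagged == 0

    def test_single_exon_genes_have_no_introns(self):
        genome = generate_genome(2, 1, (50_000,))
        aset = plant_genes(
            genome, 2, 20, GeneParams(exons_per_gene_range=(1, 1))
        )
        assert all(not g.transcripts[0].introns() for g in aset)

    def test_both_strands_used(self):
        genome = generate_genome(4, 2, (80_000, 80_000))
        aset = plant_genes(genome, 4, 80)
        strands = [g.strand for g in aset]
        assert 0.2 < strands.count("-") / len(strands) < 0.8

    def test_translated_cds_is_clean_orf(self):
        genome = generate_genome(8, 1, (30_000,))
        aset = plant_genes(genome, 8, 5)
        for gene in aset:
            protein = translate(
                extract_spliced_sequence(gene.transcripts[0], genome, "cds")
            )
            assert protein.startswith("M")
            assert protein.endswith("*") and "*" not in protein[:-1]

    def test_insufficient_space_raises(self):
        genome = generate_genome(1, 1, (6_000,))
        with pytest.raises(ValueError):
            plant_genes(genome, 1, 100)


class TestCorrupt:
    def test_empty_recipe_is_identity(self):
        genome = generate_genome(6, 1, (40_000,))
        aset = plant_genes(genome, 6, 10)
        corrupted, truth = corrupt(aset, genome, 6, CorruptionRecipe())
        assert corrupted.gene_ids() == aset.gene_ids()
        assert truth.planted_corruptions == {}

    def test_premature_stop_count_matches_validator(self):
        genome = generate_genome(6, 1, (60_000,))
        aset = plant_genes(genome, 6, 20)
        corrupted, truth = corrupt(
            aset, genome, 6, CorruptionRecipe(premature_stop=3)
        )
        reports, summary = validate_set(corrupted, genome)
        assert summary.n_flagged == 3
        assert {r.gene_id: r.flags for r in reports if r.flags} == truth.planted_corruptions

    def test_fusion_models_span_two_true_genes(self, bundle42):
        for fusion in bundle42.truth.planted_fusions:
            fused = bundle42.predicted.get(fusion["predicted_id"])
            (a_start, _), (_, b_end) = fusion["true_spans"]
            assert (fused.span.start, fused.span.end) == (a_start, b_end)
            for tid in fusion["true_ids"]:
                assert tid not in bundle42.predicted
                assert tid in bundle42.truth.true_genes

    def test_fusion_and_fission_models_validate_clean(self, bundle42):
        fused_ids = [f["predicted_id"] for f in bundle42.truth.planted_fusions]
        reports, _ = validate_set(bundle42.predicted, bundle42.genome)
        by_id = {r.gene_id: r for r in reports}
        assert all(by_id[gid].is_clean for gid in fused_ids)

    def test_too_many_corruptions_rejected(self):
        genome = generate_genome(6, 1, (40_000,))
        aset = plant_genes(genome, 6, 5)
        with pytest.raises(ValueError):
            corrupt(aset, genome, 6, CorruptionRecipe(premature_stop=10))


class TestEmitEvidence:
    def test_full_coverage_every_gene_supported(self):
        genome = generate_genome(9, 1, (40_000,))
        aset = plant_genes(genome, 9, 10)
        evidences = emit_evidence(aset, 9)
        kinds_per_gene = {}
        for ev in evidences:
            gid = ev.evidence_id.split("_", 1)[1]
            kinds_per_gene.setdefault(gid, set()).add(ev.kind)
        for gene in aset:
            assert {EvidenceKind.PROTEIN, EvidenceKind.LONG_READ} <= kinds_per_gene[gene.gene_id]

    def test_zero_coverage_empty(self):
        genome = generate_genome(9, 1, (40_000,))
        aset = plant_genes(genome, 9, 5)
        profile = EvidenceProfile(
            protein_coverage=0.0, long_read_coverage=0.0, prior_genes=False
        )
        assert emit_evidence(aset, 9, profile) == []

    def test_truncated_long_reads_drop_five_prime_exons(self):
        genome = generate_genome(9, 1, (60_000,))
        aset = plant_genes(genome, 9, 15, GeneParams(exons_per_gene_range=(3, 5)))
        profile = EvidenceProfile(long_read_truncation_prob=1.0, prior_genes=False,
                                  protein_coverage=0.0)
        evidences = emit_evidence(aset, 9, profile)
        by_gene = {ev.evidence_id.split("_", 1)[1]: ev for ev in evidences}
        for gene in aset:
            lr = by_gene[gene.gene_id]
            exons = gene.transcripts[0].exons
            assert len(lr.blocks) < len(exons)
            # the 3'-most exon always survives
            terminal = exons[-1] if gene.strand != "-" else exons[0]
            assert any(b.start == terminal.start and b.end == terminal.end for b in lr.blocks)


class TestBundleDeterminism:
    def test_same_seed_same_bundle(self, bundle42):
        other = generate_bundle(42)
        assert other.genome == bundle42.genome
        assert other.predicted.gene_ids() == bundle42.predicted.gene_ids()
        assert [e.evidence_id for e in other.evidences] == [
            e.evidence_id for e in bundle42.evidences
        ]
        assert other.truth.planted_corruptions == bundle42.truth.planted_corruptions

    def test_evidence_reflects_truth_not_prediction(self, bundle42):
        # fission fragments share one evidence cluster spanning both
        by_id = {e.evidence_id: e for e in bundle42.evidences}
        for fission in bundle42.truth.planted_fissions:
            assert f"p_{fission['true_id']}" in by_id
            for frag in fission["fragment_ids"]:
                assert f"p_{frag}" not in by_id
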