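from __future__ import annotations

import pytest

from annocure.fixtures import generate_bundle
from annocure.model import GeneModel, Interval, TranscriptModel


@pytest.fixture(scope="session")
def bundle42():
    """The standard study bundle: 200 genes, 20 fusions, 20 fissions,
    12 validation corruptions, 5 dropped genes, 12 TE genes."""
    return generate_bundle(42)


def make_transcript(
    exon_pairs,
    seq_id="chr1",
    strand="+",
    cds_pairs=None,
    tid="t1",
    gene_id="g1",
):
    exons = [Interval(seq_id, s, e, strand) for s, e in exon_pairs]
    cds = [Interval(seq_id, s, e, strand) for s, e in (cds_pairs or [])]
    return TranscriptModel(transcript_id=tid, gene_id=gene_id, exons=exons, cds_segments=cds)


def make_gene(exon_pairs, seq_id="chr1", strand="+", cds_pairs=None, gene_id="g1"):
    t = make_transcript(
        exon_pairs, seq_id, strand, cds_pairs, tid=f"{gene_id}.t1", gene_id=gene_id
    )
    span = t.span
    return GeneModel(gene_id=gene_id, span=span, transcripts=[t])


@pytest.fixture
def transcript_factory():
    return make_transcript


@pytest.fixture
def gene_factory():
    return make_gene
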