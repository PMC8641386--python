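# Methods

## Coordinate model

All internal coordinates are 0-based half-open on a named sequence;
GFF3 I/O is the only place the 1-based inclusive convention appears.
Gene models are `gene → transcript → exon/CDS` hierarchies; exons are
sorted and non-overlapping, every CDS segment must lie inside one exon,
and all parts of a transcript share one sequence and strand. CDS phases
are read from GFF3 when complete and valid, otherwise recomputed from
segment lengths in translation order. Genes carrying exon/CDS children
but no explicit mRNA get a synthetic single transcript, so structurally
broken files (the situation the validator exists for) remain loadable;
the `lenient` orphan policy additionally keeps parentless transcripts as
single-transcript genes, while `strict` rejects them with the offending
IDs. Five/three-prime-UTR features are accepted on input but ignored
structurally: the exon − CDS difference is authoritative for UTRs.

## Validation

A gene is "correct" iff its flag set is empty. Flags: missing exon/CDS
features; total CDS length not divisible by three; an internal stop codon
before the final codon; first codon ≠ ATG; final codon ∉ {TAA, TAG, TGA};
coordinates outside the sequence; CDS outside every exon. Every
transcript of a multi-transcript gene is checked and any failure flags
the gene, with per-transcript detail messages. Frameshifts are detected
only through their observable symptoms (length mod 3, premature stop);
no alignment-based frameshift calling is attempted. `export_clean`
treats the two incompleteness flags (missing start/stop) as errors by
default — the strict evidence-grade filter — with a switch to keep
incomplete-but-otherwise-sound models. Codons containing N translate to
`X`; a trailing partial codon is ignored but reported as a warning.

## Curation

The split/merge criteria in the source material for this design are
qualitative ("several proteins and full-length transcripts supported
splitting"); this package fixes them as explicit, tunable rules in
`CurationConfig`:

* **Clustering.** Evidence alignments on one sequence connect when any
  two blocks overlap or abut within `min_cluster_gap` (default 1 bp),
  same strand required by default; clusters are the connected components.
* **Split.** A gene is split iff its overlapping evidence forms ≥ 2
  clusters, each containing at least one protein or prior-version gene
  (`required_split_support`, default 1), and no single alignment overlaps
  two cluster extents (the bridging veto). Cut positions are the
  midpoints of inter-cluster gaps — symmetric and deterministic. Each
  output copies the exon/CDS structure of the best-overlapping
  prior-version gene when one exists; otherwise the original transcript
  is trimmed at the cuts, and a cut falling inside a codon makes the
  whole split an `UNRESOLVED` log entry rather than a broken model.
* **Merge.** A maximal run of adjacent same-strand genes is merged iff at
  least `required_merge_support` (default 2) alignments each cover every
  gene in the run by `min_reciprocal_overlap_fraction` (default 0.5) of
  its exonic length, at least one of them a protein or long read. The
  merged transcript is the union of exons; its CDS is recomputed as the
  longest ATG-initiated, stop-terminated ORF of the spliced sequence
  (ties to the 5'-most), since no rule for rebuilding a merged CDS is
  given by the workflow this reimplements.
* **Rescue.** A prior-version gene is added iff it validates clean,
  overlaps no new gene on the same strand, and protein evidence covers
  ≥ `rescue_min_protein_coverage` (default 0.5) of it. The coverage
  denominator is the exonic union, not the genomic span: protein
  alignments can only ever cover exons, so a span denominator would
  reject every intron-rich gene regardless of support.
* **Determinism.** Candidates are processed left-to-right per sequence;
  when candidates claim the same gene the earlier-starting one wins.
  The bookkeeping identity is asserted after every run, and a second
  curation pass over its own output performs zero actions on the
  synthetic bundle (regression-tested).

## TE labeling, naming, version mapping

TE coverage is computed over the genomic gene span, strand-agnostic
(matching a plain interval-intersection workflow); the domain criterion
uses the ten TE-associated Pfam families and is OR-combined with
coverage but reported separately. Raising the coverage threshold can
only shrink the labeled set (tested at 0.3/0.5/0.7).

Locus naming orders genes by genomic start within each sequence — the
"5' end" of a linkage group is interpreted as its left end, the only
well-defined order for mixed-strand gene sets — with ties broken by end
coordinate then old id. Numbering starts at 10 and steps by 10, leaving
free numbers for future insertions; reuse of freed numbers is out of
scope.

Version mapping links genes of two annotation versions when they share
sequence and strand and overlap by ≥ `min_fraction` (default 0.5) of the
shorter gene's genomic span (span, not exonic length, matching a
span-level interval intersection). Connected components of the bipartite
link graph become entries; relations follow component shape, and
unlinked genes become OLD_ONLY/NEW_ONLY. Homology-based mapping is out
of scope. The `percent()` formatter used by every report rounds
half-away-from-zero via exact decimal arithmetic, reproducing printed
table percentages bit-for-bit from their integer inputs.

## Alternative-splicing events

Transcripts group into loci by same-strand exonic overlap (transitive
closure); sense/antisense pairs therefore fall into separate loci. For
each transcript pair, introns fully inside the pair's common genomic
extent are compared; maximal groups of overlapping differing introns
("bubbles") become events:

* one intron vs. contiguous exon across it → IR;
* two introns vs. one intron with the same outer boundaries, the middle
  exon present on the two-intron side → ES;
* single introns sharing the donor (strand-aware) → AA; sharing the
  acceptor → AD;
* two non-overlapping middle exons, each on exactly one side, same outer
  intron boundaries → MX;
* anything else → COMPLEX.

A differing region touching the common-extent boundary has no shared
flank on that side; it is an alternative start/end, not an elementary AS
event, and is skipped. Events are defined pairwise and deduplicated
across pairs by their two variant intron structures — simpler and
directly checkable against a brute-force enumerator, though counts may
differ from full splicing-graph grouping on deeply nested loci; this is
a declared design choice. An event is *canonical* iff every
participating intron has its donor/acceptor dinucleotides in the
configured sets (GT/AG only by default; GC–AG and AT–AC can be added via
`SpliceSiteRules`) and length ≥ `min_intron_length` (default 20 bp — the
"basic splicing rules" check, together with donor-before-acceptor
ordering). An event is *UTR-localized* iff its variable region overlaps
no transcript's CDS in the locus; a CDS-less locus localizes to UTR with
a warning.

The test oracle is an independent mask-based enumerator (per-base exonic
masks, runs of differing status, classification from flanking context);
it shares no code with the classifier and agrees with it on 100 % of
the random planted loci exercised by the suite and the acceptance
script.

## Synthetic data generator

The generator emulates the study conditions the toolkit was built for: a
small Brassicaceae-like genome (GC 0.36, cosmetic), half linkage groups
and half scaffolds so naming and TE summaries exercise both categories,
and clean gene models — ATG start, single terminal stop, no internal
stops, GT–AG introns, exons ≥ 30 bp, introns 80–160 bp, intergenic gaps
220–420 bp, strand runs via a 0.35 flip probability. Genes are written
into the genome sequence, so validation, translation and splice-site
checks are real, not mocked. A single seed fans out into fixed
per-operation substreams (`default_rng([seed, stream, …])`), so adding a
generator call never perturbs other outputs and all outputs are
byte-reproducible.

Corruptions with recorded ground truth: premature stops (a mid-CDS codon
overwritten with TAA in the genome — the matching truth gene is equally
affected, which the tests account for); CDS-length errors (1 bp shrink
of the terminal CDS, yielding exactly {length, missing-stop} flags);
feature deletion; gene drops (for the rescue path); TE genes (repeat
tracks covering 60 % of the span, or a TE Pfam assignment). Fusions and
fissions are both built as read-through joins of adjacent same-strand
gene pairs — the upstream gene loses its stop codon so the joined model
is itself structurally clean: a fusion puts the joined model in the
*prediction* (truth keeps the pair), a fission puts it in the *truth*
(prediction keeps the fragments). Evidence tracks (proteins over CDS,
long reads over exon chains, prior-version gene copies) always mirror
the *truth*, which is what makes the planted errors recoverable and
leaves clean genes untouched. The default bundle is 200 genes on 270 kb
with 20 fusions, 20 fissions, 12 corruptions, 5 drops and 12 TE genes —
small enough that the full suite runs in seconds while every code path
is exercised; smaller bundles scale the counts proportionally.

What the generator does not emulate: sequencing errors and read-level
artifacts (evidence is emitted at alignment-block level), alignment
ambiguity and spurious mappings, nested/overlapping real gene
structures, pseudogenes, and repeat families with realistic length
distributions. Passing tests therefore demonstrate correctness of the
decision rules under unambiguous evidence, not robustness to noisy
alignments.

## Known limitations

* Split boundaries between evidence clusters are midpoints; with no
  prior model to copy, trimmed models can be incomplete at the cut (by
  design they are only emitted when the cut is codon-aligned).
* Merged CDSs assume the true ORF is the longest one in the exon union;
  read-through constructs with internal stops retained in a UTR-like
  segment will yield a shorter ORF (the gene span is still correct).
* Pairwise AS-event dedup can under- or over-count relative to
  splicing-graph tools on loci with many mutually nested variants.
* The curation rules are a reproducible stand-in for what was originally
  a manual, browser-assisted procedure; thresholds are exposed rather
  than fitted.
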