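# annocure

Evidence-driven curation toolkit for draft genome annotations.

Automated gene predictors (MAKER-style pipelines) leave systematic damage
behind: coding sequences with premature stop codons or lengths not
divisible by three, missing exon/CDS features, tandem genes fused into one
model, single genes fragmented into several, well-supported genes dropped
entirely, and transposable-element ORFs masquerading as host genes.
`annocure` implements the post-prediction stages that turn such a draft
into a release-grade annotation, for annotation engineers and comparative
genomicists who would otherwise script this with BedTools + AWK:

* **validate** — flag interrupted ORFs and formatting errors per gene:
  `MISSING_FEATURE`, `CDS_NOT_MULTIPLE_OF_THREE`, `PREMATURE_STOP`,
  `MISSING_START`, `MISSING_STOP`, `OUT_OF_BOUNDS`, `CDS_OUTSIDE_EXON`;
  export the error-free subset usable as evidence.
* **curate** — split a model whose overlapping evidence (long-read
  transcripts, protein alignments, prior-version genes) forms ≥ 2
  well-separated clusters, each anchored by a protein or prior gene, with
  no alignment bridging them; merge a run of adjacent same-strand models
  that the same spanning alignments each cover by ≥ 50 % of exonic
  length, re-deriving the merged CDS as the longest ATG-initiated ORF;
  rescue clean prior-version genes with ≥ 50 % protein coverage that the
  new prediction missed. Every action is logged and the identity
  `n_out = n_in − split_in + split_out − merge_in + merge_out + rescues`
  is asserted on every run.
* **te-label** — mark putative TE genes: repeat coverage ≥ 50 % of the
  gene span, OR a TE-associated Pfam domain (reverse transcriptase
  PF00078/PF07727/PF13456/PF13966, integrase PF00665/PF13976,
  retrotransposon PF03732/PF08284, LTR PF14223/PF14244).
* **rename** — systematic locus names `<prefix><version><LG|sc><n>G<num>`
  (e.g. `Aa31LG1G10`), numbering from 10 in steps of 10 along each
  linkage group or scaffold.
* **as-classify** — Astalavista-style elementary alternative-splicing
  events between isoforms: exon skipping (ES), alternative acceptor (AA),
  alternative donor (AD), mutually exclusive exons (MX), intron retention
  (IR); canonical-splice-site flag (GT…AG by default, minimum intron
  length 20 bp) and UTR/CDS localization per event.
* **version-map** — cross-version gene correspondence by same-strand
  overlap of ≥ 50 % of the shorter gene span: one-to-one, split, merged,
  lost, novel.
* **simulate** — a deterministic generator of genomes, clean gene models,
  corrupted predictions, matching evidence tracks, repeats and isoform
  sets with full ground truth, so every stage is testable end to end
  without external data.

## Worked example

```bash
annocure simulate --seed 42 --n-genes 200 --out-dir fx/
annocure run --gff fx/predicted.gff3 --fasta fx/genome.fa \
    --evidence fx/evidence.gff3 --prior fx/true.gff3 \
    --repeats fx/repeats.gff3 --domains fx/domains.tsv --out-dir out/
```

The simulated prediction contains 20 fused models, 20 fissioned gene
pairs, 12 single-gene corruptions, 5 dropped genes and 12 TE genes. The
run prints (abridged):

```json
{
  "validation_summary": {"n_genes": 175, "n_flagged": 12},
  "curation_counts": {"SPLIT": 20, "MERGE": 20, "RESCUE": 5},
  "te_summary": {"n_labeled": 12, "by_coverage": 8, "by_domain": 4},
  "version_map_summary": {"mapped_old_percent": 100.0},
  "versions_table": {"raw_genes": 180, "interrupted_orfs": 12,
                     "correct_in_gff": 168, "putative_tes": 12,
                     "total_correct": 156}
}
```

Reading: all 12 planted corruptions were flagged (and nothing else); the
20 fusions were split back into their 40 constituent genes, the 40
fission fragments merged into 20, and the 5 dropped genes rescued from
the prior version, so every prior gene maps one-to-one into the curated
set. The versions table reconciles by construction: 180 raw genes − 12
interrupted ORFs = 168 correct in GFF, minus 12 putative TEs = 156 fully
correct genes.

Each stage is also available as a library function
(`annocure.validate_set`, `annocure.curate`, `annocure.map_versions`, …)
and as an individual subcommand (`validate`, `curate`, `te-label`,
`rename`, `as-classify`, `version-map`).

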