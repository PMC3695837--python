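# envpath

A modular pipeline for turning environmental shotgun sequence data into
pathway/genome-database inputs and pathway predictions, plus a
simulation-based evaluation harness.

The pipeline runs five stages:

1. **QC & ORF prediction** — length filtering, non-ACGT → `N` conversion,
   sequential renaming (`<sample>_0`, `<sample>_1`, …) with a mapping
   file, and length-distribution summaries.  ORF calls are consumed from
   an external gene-caller GFF3, or produced by a built-in six-frame scan
   (translation table 11, ATG/GTG/TTG starts, edge-partial handling).
   ORFs shorter than 60 aa are removed by default.
2. **Annotation** — self-alignment bit scores (BLOSUM62 diagonal with
   gapped Karlin–Altschul constants, or a precomputed `.refscores`
   table), BLAST-score-ratio filtering (BSR ≥ 0.4 by default, boundary
   inclusive), and consensus product naming by an *information score*
   (distinct enzymatic words, +10 for an EC number).  ORFs with no
   surviving hit become "hypothetical protein".  KEGG/COG-style
   hierarchy summaries and rRNA hit tables are also produced.
3. **Analysis** — lowest-common-ancestor taxonomic binning from
   protein-database hits within a bit-score window (default 0.9 of the
   best hit), preferring official taxonomy names over synonyms.
4. **PGDB construction** — contigs are concatenated into one composite
   "chromosomal" element with a coordinate lift-over table, and the four
   PathoLogic input files (`.pf`, FASTA, genetic-elements,
   organism-params) plus a GenBank flat file and a gene feature table
   are emitted.
5. **Pathway export** — a rule-based pathway inference stand-in
   (coverage ≥ τ of a pathway's reactions plus at least one key
   reaction) with `.pathways.txt` / `pathway_rxns.txt` tables and a
   run receipt (`.run_parameters.txt`).

A MetaSim-like shotgun simulator (normal read lengths, weighted genome
mixtures, coverage-fraction budgets) and a synthetic-community generator
(genomes with planted EC-carrying ORFs, reference tables, toy taxonomy,
gold-standard pathway sets, homology-hit emulator) make every stage
testable without external databases or binaries.

## CLI

```sh
# full pipeline on one sample
envpath run contigs.fasta --out results/ --params run.parameters.txt \
    --orfs calls.gff --hits kegg=kegg.blastout --hits refseq=refseq.blastout \
    --taxonomy taxonomy.tsv --catalog pathway_catalog.tsv

# fixtures and simulated reads
envpath simulate community --out fixture/ --genomes 10 --pathways 40 --seed 0
envpath simulate reads fixture/genomes.fasta --out reads --gm 0.25 --seed 1

# coverage-gradient evaluation (JSON of confusion/statistics per Gm)
envpath evaluate --genomes 10 --pathways 40 --skew 20 --seed 0

# GFF + FASTA -> GenBank conversion
envpath convert contigs.fasta calls.gff --out sample.gbk
```

The parameters file is line-oriented (`key value` or `key: value`,
case-insensitive, `#` comments).  Stage flags (`qc`, `annotation`,
`analysis`, `pgdb`, `export`) take `yes`, `skip` (reuse prior outputs)
or `grid` (accepted; runs locally).  Thresholds include
`min_nucleotide_length` (180), `min_orf_aa` (60), `max_evalue` (1e-5),
`min_bsr` (0.4), `pathway_tau` (0.5), `lca_top_fraction` (0.9).

## Layout

```
src/envpath/
  core_formats.py   FASTA / tabular-hit / GFF3 / parameters I/O
  qc.py             stage 1: filtering, renaming, length stats
  orfcall.py        translation + six-frame ORF scan fallback
  annotate.py       stage 2: self-scores, BSR, information score
  taxonomy.py       stage 3: LCA binning
  pgdb_export.py    stage 4: composite genome, .pf / GenBank emission
  pathways.py       stage 5: inference, export, classification stats
  simulate.py       shotgun simulator + synthetic community + harness
  pipeline.py       stage orchestration, run receipt
  cli.py            click entry points
tests/              pytest suite; test_acceptance.py holds the
                    acceptance criteria
scripts/acceptance.py
```
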