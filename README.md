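# plastodecay

Comparative chloroplast-genome (plastome) analysis as a tested, reusable
pipeline:

- **Synthetic plastomes with ground truth** — circular quadripartite genomes
  (LSC + IRa + SSC + IRb, IRb the exact reverse complement of IRa) carrying
  the 11 *ndh* genes, planted SSRs and long repeats, Jukes–Cantor sequence
  evolution along a known tree, and scripted gene-degradation lesions
  (start/stop ablation, premature stop, frameshift, truncation, excision).
- **Structure & composition** — inverted-repeat detection and region
  boundary calling, GC content, codon usage (translation table 11),
  FASTA/GFF3/GenBank I/O.
- **Gene degradation-state calling** — Smith–Waterman genome scans against
  reference coding sequences, four-state classification
  (complete / pseudogene / fragment / deleted; fragments ≥ 25 bp,
  pseudogene coverage floor 20%), and the 22-character *ndh*
  presence/degradation matrix (characters 12–22 inapplicable `-` when a
  gene is deleted).
- **Maximum parsimony** — Fitch lengths, exhaustive and exact
  branch-and-bound search, random-addition + TBR heuristic, strict
  consensus, CI/RI, nonparametric bootstrap, and ACCTRAN character-change
  mapping on an outgroup-rooted tree.
- **Divergence hotspots** — p-distances with pairwise deletion,
  variable/parsimony-informative site counts, per-partition statistics,
  Spearman correlation, top-k marker ranking.
- **Repeats** — MISA-style SSR detection (mono ≥ 10, di ≥ 6, tri–hexa ≥ 5
  copies) and REPuter-style direct/palindromic repeats (≥ 30 bp,
  ≤ 3 mismatches, ≥ 90% identity), genomic-context annotation and
  cross-species shared-locus intersection.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria. Criteria 1–6 are
self-contained property checks against brute-force oracles. Criteria 7–9
reproduce published numbers and require external inputs that cannot be
fetched offline; they fail with an explanatory message unless you provide:

- `data/s3_ndh_matrix.tsv` — the supplementary 22-character matrix
  (TSV: `taxon` column + 22 single-symbol character columns), and
- `data/accessions/<ACC>.fasta` — plastome FASTA files for MF593121–MF593126,
  NC025652.1 and NC023463 (whole-plastome alignment uses the `mafft`
  executable on PATH).

## CLI

```sh
plastodecay run --config config.yaml --outdir out --seed 1   # full pipeline
plastodecay simulate --outdir sim --seed 1                   # genomes + truth
plastodecay structure genome.fasta --min-ir 1000
plastodecay stats genome.fasta --annotations genome.gff3
plastodecay classify --query genome.fasta --refs refs.fasta --out calls.tsv
plastodecay ndh-matrix --calls calls.tsv --out ndh.nex
plastodecay repeats genome.fasta --annotations genome.gff3
plastodecay divergence aln.fasta --partitions parts.txt --top 10
plastodecay parsimony matrix.tsv --method bb --outgroup OUT --bootstrap 100
```

The pipeline writes `calls/`, `matrix/`, `trees/`, `divergence/`,
`repeats/` and `manifest/` (run manifest with config echo, per-stage
timings and SHA-256 checksums; re-running the same config reproduces
byte-identical outputs). All thresholds are plain YAML keys in the config
with the published values as defaults.

## Layout

```
src/plastodecay/
  simulate.py    blueprints, tree generation, JC evolution, degradation
  plastome.py    records, FASTA/GFF3/GenBank I/O, IR detection, GC, codons
  genestate.py   local alignment, four-state calls, ndh matrix encoding
  repeats.py     SSRs, long direct/palindromic repeats, contexts, sharing
  divergence.py  p-distance, site classes, partition stats, hotspots
  parsimony.py   Fitch, exact/heuristic search, consensus, CI/RI, ACCTRAN
  trees.py       tree structure, Newick, bipartitions, consensus building
  pipeline.py    end-to-end orchestration + reproducibility manifest
  cli.py         click command-line interface
tests/           unit + property tests, brute-force oracles, acceptance
scripts/         acceptance.py
```
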