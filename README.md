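# pirnakit

A toolkit for PIWI-interacting RNA (piRNA) analysis:

- **Density-based cluster discovery** — per-chromosome DBSCAN on read 5'
  positions, with the neighbourhood radius (Eps) estimated from the
  k-th-nearest-neighbour distance distribution (modal k-dist), cluster
  enrichment scoring (reads / MinReads) and uni-/dual-strand
  classification.
- **Ping-pong signature detection** — cross-strand read pairs with a
  given 5'-to-5' overlap (default 10 nt) and the full overlap-length
  histogram for signature plots.
- **Genomic-context annotation** — primary-category classification of
  loci (CDS > 5'UTR > 3'UTR > exon > intron > intergenic), independent
  repeat/pseudogene/lncRNA overlap reports, cluster–feature overlap
  with union semantics, and remapping of cluster coordinates through
  user-supplied synteny blocks.
- **Expression screening** — counts-per-million normalization, per-sample
  z-score screening (retain −3 ≤ z ≤ +3), top-abundance ranking, and
  anticorrelated (piRNA, target) candidate pairing from differential
  expression summaries.
- **Target prediction** — a wobble-aware Smith–Waterman duplex scorer
  (reverse-complemented piRNA vs. target, 5'-end positions 2–8
  up-weighted) with a nearest-neighbour stacking energy model; targets
  pass at score ≥ 170 and energy ≤ −20 kcal/mol by default.
- **Simulator** — deterministic synthetic reads, count matrices and
  sequences with planted ground truth for every module.

Sequence collapse (U/T-equivalent), `[abbr]_piRNA_[number]` ID
assignment and BED/FASTA/TSV plumbing live in `pirnakit.io_model`.

## CLI

All functionality is exposed through the `pq2` entry point:

```sh
pq2 simulate clusters --seed 1 --out reads.bed --truth-out truth.json
pq2 cluster --reads reads.bed --k 4 --out clusters.tsv --bed-out clusters.bed
pq2 pingpong --reads reads.bed --overlap 10 \
    --pairs-out pairs.tsv --signature-out signature.tsv
pq2 collapse --fasta small_rna.fa --species-abbr hsa --out pirnas.tsv
pq2 annotate --loci loci.bed --cds-bed cds.bed --repeat-bed rpt.bed --out cls.tsv
pq2 express --counts counts.tsv --cpm-out cpm.tsv --top-out top200.tsv
pq2 pairs --pirna-de pirna_de.tsv --target-de mrna_de.tsv --out candidates.tsv
pq2 targets --pairs candidates.tsv --pirna-fasta p.fa --target-fasta t.fa \
    --score-min 170 --energy-max -20 --out hits.tsv
```

`pq2 cluster` writes a TSV (and optionally a BED with the score in
column 5 and strandedness in column 6 as `+`/`-`/`.` for
uni-plus/uni-minus/dual). Cluster detection without `--eps` estimates
Eps per chromosome from the k-dist mode; MinReads defaults to k+1.

## Layout

```
src/pirnakit/
  io_model.py    data types, BED/FASTA IO, collapse + ID assignment
  cluster.py     k-dist, Eps estimation, 1-D DBSCAN, scoring
  pingpong.py    5' overlap rule, pair finder, signature
  annotate.py    locus/cluster classification, synteny remap
  expression.py  CPM, z-screen, ranking, anticorrelation pairing
  targets.py     duplex aligner, energy model, target gates
  simulate.py    planted-truth generators
  cli.py         pq2 command line
  data/nn_stack.json  pinned nearest-neighbour stacking table
tests/           unit, property (hypothesis) and acceptance suites
scripts/acceptance.py
```
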