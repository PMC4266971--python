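# chromobin

Query, bin and visualize chromosome-anchored genes of one or more genomes —
fully offline.

A genome is a collection of gene models, each optionally *anchored* to a
chromosome at a physical (bp) or genetic (cM) position. chromobin lets you

- **tag genes** by identifier list, exact functional annotation term
  (GO/PFAM-style), or sequence homology from precomputed 12-column tabular
  hit files (BLAST `-outfmt 6` dialect) with e-value/identity thresholds and
  an optional **best-bidirectional-hit (BBH)** requirement;
- **bin** anchored genes into non-overlapping intervals (e.g. 1 Mb, 10 Mb or
  5 cM per bin) and render all-vs-tagged gene densities as SVG **heat maps**
  with per-bin tooltips;
- test **chromosome(-arm) enrichment** of the tagged set with a one-sided
  Fisher's exact test and Bonferroni adjustment;
- **filter candidates** with uploaded expression matrices (coefficient of
  variation, minimum expression), differential-expression lists and
  gene-to-group mappings, including group-wise heat-map panels;
- **export** any bin's tagged genes as FASTA, plus TSV reports that
  round-trip losslessly;
- generate complete, seeded **synthetic fixtures** (genomes, sequences,
  annotations, hit tables with planted ortholog ground truth, expression
  uploads) so every workflow runs with no downloads.

A lightweight built-in nucleotide search (k-mer seeded, ungapped) stands in
for an external aligner in self-contained runs; its surrogate e-values are
not comparable to BLAST's. Imported hit tables are the production path.

## CLI

```sh
# write a complete synthetic dataset
chromobin simulate --seed 7 --out fixture/

# tag genes by id list, bin them, test arm enrichment, draw the heat map
chromobin query --genome fixture/genome.yaml --ids my_ids.txt \
    --unit arm --out run/

# homology query with thresholds and BBH
chromobin query --genome fixture/genome.yaml \
    --hits fwd.tsv --hits-rev rev.tsv --evalue 1e-5 --identity 70 --bbh \
    --out run/

# expression-based filtering (uploads are validated first)
chromobin query --genome fixture/genome.yaml --ids my_ids.txt \
    --expr expression.tsv --min-cv 0.5 --deg deg.txt --deg-only \
    --groups groups.tsv --out run/

# export one bin's tagged genes as FASTA
chromobin export-fasta --genome fixture/genome.yaml \
    --tagged run/tagged.tsv --chromosome chr1 --bin 9 --out bin9.fa
```

Each `query` run writes `tagged.tsv`, `density.tsv`, `enrichment.tsv`,
`heatmap.svg` and a `manifest.json` with all parameters and input checksums.
A YAML run config (`--config run.yaml`) can pre-set any option; explicit
flags win. Errors exit non-zero with a single-line `error: ...` on stderr.

## File formats

- **genome config** (YAML/JSON): `genome_id`, `unit` (bp|cM), `bin_width`,
  chromosome list with lengths and optional arm boundaries, optional
  `files:` section pointing at the tables below.
- **anchor table** (TSV): `gene_id  chromosome  arm  position  anchored`;
  positions 1-based for bp genomes, real-valued for cM; unanchored rows
  leave chromosome/position empty. A GFF3 reader (`gene` features, midpoint
  position) is available as an alternative.
- **annotations** (TSV): `gene_id  term`.
- **hit tables**: 12-column tabular, `#` comments ignored, malformed rows
  reported with line numbers.
- **uploads**: expression TSV (`gene_id` + one column per condition), DEG
  list (one id per line), group map (`gene_id  group`, one group per gene).

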