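# famkit

A gene-family characterization toolkit for plant transcription-factor
families, built around five analysis stages plus seeded synthetic-data
generators so the whole pipeline runs and tests offline:

- **Family-table genomics** (`famkit.genome`): chromosomal
  distribution, isoform census, tandem-cluster detection
  (end-to-start gap < 250 kb by default), Ka/Ks selection-mode calls
  and divergence dating `T = Ks / (2 * 6.1e-9)`.
- **Protein features** (`famkit.proteins`): molecular weight,
  isoelectric point (Bjellqvist pKa set, bisection), domain
  architecture classes (canonical / CTD-truncated / DBD-only), middle
  region extraction and composition-based activator/repressor calling.
- **Distance phylogeny** (`famkit.phylo`): pairwise-deletion
  p-distances, Poisson correction, deterministic neighbor-joining,
  column-resampling bootstrap, sister-pair (cherry) calling, Welch
  contrast of exon counts between groups.
- **Promoter cis-element enrichment** (`famkit.cre`): IUPAC motif
  scanning, zero-order GC background expectation, enrichment factors,
  add-one-corrected Monte-Carlo p-values from simulated control
  promoter sets, 100-bp positional density with a null envelope.
- **RT-qPCR analytics** (`famkit.qpcr`): amplification efficiency from
  regression slope, geNorm M / CV reference stability, multi-reference
  efficiency-corrected NRQs with pooled-replicate error propagation,
  3':5' RNA-integrity QC, log2 expression matrix with hierarchical
  clustering and SVD ordination.
- **Synthetic data** (`famkit.simulate`): seeded generators for
  promoter sets (with motif planting), protein families with
  prescribed architectures, alignments evolved on trees under the
  uniform-exchange model, Cq tables inverted from known NRQs, and
  Ka/Ks pair collections.

Two hand-curated plain-text fixtures ship inside the package
(`famkit.fixtures`): the 24-row family annotation table and the
10-motif cis-element table with its published occurrence statistics,
so all reference analyses run without network access.

## CLI

The `famkit` command exposes the pipeline; all inputs and outputs are
plain text (TSV/CSV/FASTA/Newick). Examples:

```sh
famkit family-stats genes.tsv
famkit tandem genes.tsv --window 250000
famkit kaks-date pairs.tsv --gamma 6.1e-9
famkit protein-stats proteins.fa
famkit classify-mr proteins.fa domains.tsv
famkit nj-tree alignment.fa --bootstrap 1000 --seed 7 --threshold 65
famkit cre-enrich promoters.fa --gc 0.28 --sims 2000 --seed 7
famkit cre-density promoters.fa --bin 100 --top 5 --seed 7
famkit qpcr-norm cq.csv --refs PP2A,TFIIA --calibrator ControlR
famkit qpcr-stability cq.csv
famkit qpcr-qc --cq5 24.59 --cq3 24.0
famkit simulate promoters --n 23 --length 1500 --seed 7 --out sim.fa
```

Defaults (GC background, simulation counts, seeds, windows) can be set
in a YAML config passed as `famkit --config famkit.yaml <cmd>`; see
`famkit.config` for the schema. `--verbose` enables debug logging to
stderr.

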