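# mitotyper

Heteroplasmy-aware divergence profiling, McDonald–Kreitman selection tests,
Tajima's D and conservative distance phylogenies for alignments of two
intraspecific mitochondrial haplotypes (mitotypes, labelled TNP and ENA),
driven by a synthetic two-clade mitogenome generator.

## What it does

- **`mitotyper.mitomodel`** — annotated mitogenome model (13 CDS, 22 tRNA,
  2 rRNA on the standard vertebrate gene order, 65 bp intergenic), IUPAC
  ambiguity algebra, the vertebrate mitochondrial genetic code (NCBI table 2),
  FASTA/GFF3/BED/sample-sheet IO, control-region trimming and stranded
  element extraction.
- **`mitotyper.mitosim`** — simulator producing a codon-valid reference and
  two mitotype clades with controlled between-clade divergence (default
  0.033 per site), within-clade polymorphism (star genealogy), per-OXPHOS-
  complex selection skew (Complex I elevated by default) and optional
  heteroplasmy emitted as two-base IUPAC symbols, plus a machine-checkable
  truth record.
- **`mitotyper.divergence`** — ambiguity-aware percent identity
  (`|Sa∩Sb|/(|Sa||Sb|)` per site, so Y scores 0.5 against C or T and 0
  against A or G) and per-element / per-complex / genome-wide identity
  profiles with a genome-mean baseline.
- **`mitotyper.popgen`** — conservative ambiguity masking (every column with
  an ambiguous symbol in any sample is dropped), fixed/polymorphic site
  partitioning per element, MK 2×2 tests with Neutrality Index
  `NI = (P_N/P_S)/(D_N/D_S)`, Yates-corrected chi-square and Fisher exact
  p-values, and Tajima's D.
- **`mitotyper.phylo`** — conservative p-distances (a site counts as
  divergent only when the two base sets are disjoint) and neighbor joining
  with Newick export. **Note:** NJ deliberately replaces maximum-likelihood
  tree search; the claim it supports (reciprocal mitotype monophyly) is
  topological, and NJ is exact on additive distances.
- **`mitotyper.analyze_cli`** — ANOVA + Tukey HSD across elements/complexes,
  identity~length regression, the end-to-end pipeline and the CLI.

## CLI

```sh
mitotype simulate --seed 7 --out data/           # synthetic dataset (FASTA/GFF3/TSV/truth JSON)
mitotype profile  --fasta data/alignment.fasta --samples data/samples.tsv \
                  --gff3 data/annotation.gff3 --pairing between-mitotypes --out profile.tsv
mitotype mktest   --fasta ... --samples ... --gff3 ... --out mk.tsv
mitotype tajima   --fasta ... --samples ... --gff3 ... --population pop-ENA
mitotype tree     --fasta ... --samples ... [--drop-heteroplasmic] --out tree.nwk
mitotype report   --config config.yaml --out report/   # full pipeline bundle
```

`report` takes a YAML config with either a `simulate:` block (any
`SimulationConfig` field) or an `inputs:` block (`fasta`, `samples`,
`gff3`), and writes identity profiles, divergence summary, MK and
non-coding tables, Tajima's D per population, a Newick tree, group
statistics and a run log. Exit codes: 0 ok, 2 input error, 3 stats error.

## Notes on conventions

- Coordinates are 0-based half-open internally; GFF3 is written 1-based
  inclusive, BED 0-based half-open.
- ND6 and the light-strand tRNAs are minus-strand and are
  reverse-complemented before codon work.
- Multi-position codon differences are classified per differing position in
  the reference-codon context.
- CDSs whose length is not a codon multiple (e.g. ND4, 1,381 bp) have their
  trailing 1–2 bases excluded from synonymous/nonsynonymous classification
  (they are completed by polyadenylation in vivo) but included in identity.
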