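# kcurate

Comparative curation of an ion-channel gene family, end to end: a
validated registry of the curated gene catalog (orthology class, dN/dS
versus chicken, allelic-variant codes, in situ expression scores),
synteny-based classification of candidate loci (ortholog / duplication /
allele / pseudogene), single-gain (Dollo) gain/loss reconciliation on a
species tree, quality-masked NG86 dN/dS estimation with a two-stage
high-selective-pressure screen, substitution and indel classification,
PROSITE-style motif fingerprint scoring, and song-system expression
marker calling. A synthetic-data module generates multi-species bundles
with planted events and full ground truth so every stage is testable
offline.

## Layout

- `src/kcurate/registry.py` — gene-table data model, packaged fixtures
  (`data/gene_table.tsv`, `data/missing_genes.tsv`), declarative
  predicates, reconciliation report
- `src/kcurate/genome.py` — GFF3 gene maps, FASTA/FASTQ, Newick trees,
  flanking-gene neighborhoods (1-based inclusive coordinates)
- `src/kcurate/homology.py` — Smith-Waterman / Needleman-Wunsch with
  affine gaps (Biopython `PairwiseAligner` backend), identity and
  similarity statistics, exact k-mer seed-and-extend locus search
- `src/kcurate/synteny.py` — shared-flank evidence, ordered
  classification rules, presence/absence matrix, Dollo reconciliation
- `src/kcurate/variants.py` — Phred/assembly-gap quality masks,
  conservative vs non-conservative substitution classing, allele
  calling, indel detection with domain overlap
- `src/kcurate/selection.py` — NG86 site counts and path-averaged
  differences with Jukes-Cantor correction, two-stage dN/dS flagging,
  lineage-acceleration assignment
- `src/kcurate/motifs.py` — PROSITE-style pattern compiler and
  fingerprint-fraction scanner
- `src/kcurate/expression.py` — o/+/++/+++ and arrow parsing, AFP/DMP
  marker calls, song-system summary
- `src/kcurate/simulate.py` — seeded synthetic bundles (duplications,
  losses, alleles, pseudogenes, indels, per-gene omega)
- `src/kcurate/pipeline.py`, `src/kcurate/cli.py` — orchestration and
  the `kcurate` command

## CLI

```sh
kcurate curate                          # registry totals + reconciliation
kcurate expression                      # song-system summary counts
kcurate simulate --seed 1 --out bundle/ # synthetic fixture bundle
kcurate report bundle/ --out report.json  # full pipeline over a bundle
kcurate dnds pair.fasta                 # NG86 dN/dS for a coding pair
kcurate alleles primary.fa secondary.fa # allele call + substitution classes
kcurate indels pair.fasta --domains domains.tsv
kcurate motifs proteins.fasta motifs.tsv
```

## Conventions worth knowing

- Percent identity/similarity exclude gap columns from the denominator;
  this changes all percentages and is deliberate.
- The dN/dS qualifier "<0.01" is kept as a qualifier, not a float;
  numeric predicates skip it unless coercion is requested explicitly.
- Side-chain groups for "conservative": {AVLIM} {FWY} {STCNQ} {KRH}
  {DE} {G} {P}.
- Dollo reconciliation places the single gain at the deepest node that
  adds no losses beyond the minimum; unknown-gap cells are
  unconstrained.
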