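# haploweb

Species delimitation from co-dominant nuclear markers, the haploweb way.

Many groups of organisms — reef corals prominently among them — cannot be
delimited reliably from morphology: phenotypic plasticity, morphological
stasis and convergence all blur species boundaries. Single-locus barcoding
helps, but a clonally inherited marker alone cannot distinguish deep
intraspecific structure from species boundaries, nor rule out hybridization.
A *haploweb* addresses this with a biparentally inherited nuclear marker: a
haplotype tree is augmented with curves connecting haplotypes found
co-occurring in heterozygous individuals. Alleles linked through shared
carriers form a **field for recombination (FFR)** — a pool of alleles
demonstrably segregating within one reproductive community. Under the
**mutual allelic exclusivity** criterion, each pool delimits a candidate
species: no individual carries alleles from two different pools. Congruence
of the nuclear pools with clades of a clonally inherited mitochondrial
marker then rejects hybridization as an explanation for morphological
mismatches.

This package implements the complete chain for diploid Sanger-type data:

- **Phasing of degenerate reads** (`haploweb.phasing`). A direct read of a
  heterozygote superposes its two alleles; each disagreement shows as a
  two-base IUPAC double peak. Four routes resolve the two alleles:
  enumeration for single-double-peak reads; **forward/reverse deconvolution
  of length-variant heterozygotes** (the frame shift between the
  start-aligned forward and end-aligned reverse read yields two coupled
  constraint systems solved exactly by propagation); peak-height separation
  for clear-cut amplification bias; and **Clark's parsimony method**
  (iterative subtraction of known haplotypes) for the remainder.
- **Haplotype trees** (`haploweb.phylo`): identical-sequence collapsing,
  Kimura two-parameter distances `d = -½ ln(1-2P-Q) - ¼ ln(1-2Q)` with
  pairwise or complete deletion, Saitou–Nei neighbor-joining, nonparametric
  bootstrap on bipartitions, outgroup rooting, and barcode-gap distance
  clustering for the mitochondrial clades.
- **Haploweb and delimitation** (`haploweb.webs`): co-occurrence graph,
  FFR pools as connected components of the individual–allele incidence
  graph, cross-pool heterozygote counting, Rand-index congruence between
  the nuclear and mitochondrial partitions, and SVG/JSON haploweb export.
- **Synthetic data** (`haploweb.simdata`): a generator for multi-species
  diploid datasets — private allele pools per species, indel-bearing
  alleles producing length-variant read pairs, species-concordant
  mitochondrial haplotypes, optional hybrids — so every stage is testable
  against a known truth.
- **Pipeline and CLI** (`haploweb.pipeline`, `haploweb.cli`): an
  end-to-end, fully seeded run (`phase → trees → haploweb → congruence →
  report`) and thin subcommands `simulate | phase | tree | haploweb |
  congruence | run`.

## Worked example

`examples/04_full_pipeline.py` simulates three species (15 diploid
individuals each), writes the dataset to disk and runs the full pipeline:

```
individuals analysed:        45
phasing routes:              {'clark': 16, 'deconvolution': 19, 'homozygote': 10}
distinct nuclear haplotypes: 15
allele pools (FFRs):         3
mitochondrial clusters:      3
heterozygous individuals:    35
cross-pool heterozygotes:    0
partitions identical:        True  (Rand index 1.000)
```

Three allele pools emerge and match the three mitochondrial clusters
exactly; zero cross-pool heterozygotes means no individual bridges two
pools — the signature that delimits three species and rejects
hybridization. The other examples demonstrate single capabilities:
`01_simulate_and_delimit.py` (haploweb delimitation in memory),
`02_deconvolve_length_variant.py` (the two-read deconvolution, worked by
hand), `03_haplotype_tree.py` (K2P + NJ + bootstrap + distance clades).

## File formats

FASTA for sequences (aligned haplotypes; phased output with `_a`/`_b`
suffixes per heterozygote), newick for trees (bootstrap percentages as
internal node labels), TSV for tables. Mixed reads travel as one row per
read: `individual, marker, orientation, IUPAC string, heights`, where
`heights` optionally records `position:taller_base:relative_height` for
every double peak (e.g. `37:T:0.80;112:C:0.75`). The package ships a
70-row sample table (`haploweb/data/samples.tsv`: id, location,
coordinates, depth) describing the coral collection that motivates the
defaults.

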