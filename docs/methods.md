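# Methods

This note documents the models, algorithms and numerical choices behind
the package, what the synthetic-data generator does and does not
emulate, and the known limitations.

## The superposition model of diploid reads

A direct Sanger read of a diploid PCR product is modelled as the
position-wise union of the individual's two alleles. For alleles `s1`
(length `L`) and `s2` (length `L-k`, `k ≥ 0`):

- the **forward** read is start-aligned: position `i` shows
  `{s1[i]} ∪ {s2[i]}` while both alleles extend that far, then `{s1[i]}`;
- the **reverse** read, reported in forward coordinates, is end-aligned:
  position `i` shows `{s1[i]} ∪ {s2[i-k]}` for `i ≥ k`, else `{s1[i]}`.

Positions where the union has two members are double peaks, written as
two-base IUPAC codes (R, Y, S, W, K, M). Three- and four-base codes are
rejected on input: a diploid superposition cannot produce them, and a
read containing one indicates more than two sequence variants in the
individual (such individuals are excluded with a warning). Coordinates
are 0-based and half-open throughout. Optionally each position carries
the relative height of the taller peak, in (0.5, 1.0].

For equal-length alleles (`k = 0`) the two reads carry identical base
content; a placement difference between the forward and reverse
double-peak patterns is therefore a reliable signature of length-variant
heterozygosity and is what routes an individual to deconvolution.

## Length-variant deconvolution

Given both reads and a candidate offset `k`, every observed cell is an
exact constraint: singleton cells fix their variables; a double cell
`{a, b}` is an exclusive-or between its two variables (both bases must
appear). Constraint propagation to fixpoint solves the system.

A structural observation drives the design: each variable `s1[i]`
appears in exactly two cells (forward `i`, reverse `i`), and each
`s2[j]` in exactly two (forward `j`, reverse `j+k`), so the constraint
graph is a union of index-increasing chains. Every chain terminates at
a cell that the model forces to be a singleton — the reverse head
(`i < k`) or the forward tail (`i ≥ L-k`) — which anchors it. A
structurally valid read pair therefore has either a unique solution or
a contradiction; genuine ambiguity cannot arise under the single-offset
model. The implementation nevertheless reports ambiguity (with the
unresolved positions) rather than guessing if propagation ever stalls,
as a defensive guarantee, and reports contradictions when the reads do
not fit the model at the given `k`. Correctness is validated against an
independent exhaustive-enumeration oracle on small instances and by
exact recovery of simulated 300-bp pairs.

The offset itself is estimated by trying `k = 1, 2, …` and scoring the
number of consistently fixed positions; a complete consistent solve at
offset `k` scores `2L - k`, which no larger offset can exceed, so the
search returns the first complete solve and otherwise the most
consistent offset. Homozygote-patterned read pairs are rejected (no
`k ≥ 1` is consistent).

The single-offset model assumes at most one indel difference between
the two alleles. Alleles differing by two or more separate indels
produce read pairs the model flags as inconsistent; such individuals
fall through to the unresolved route rather than being mis-phased.

## Clark's parsimony phasing

Unphased equal-length heterozygotes are resolved by Clark's subtraction
method: haplotypes known from homozygotes and from individuals resolved
by the direct routes are subtracted from compatible genotypes, each
subtraction adding the complementary haplotype to the known set, until
a fixpoint. A haplotype is compatible with a genotype when it matches
one base of every site pair.

Resolution order matters for parsimony, so subtractions are applied in
three tiers, re-entering the first tier after every change:

1. genotypes for which some compatible known haplotype has an
   already-known complement — these create no new haplotype;
2. genotypes with exactly one compatible known haplotype — the
   subtraction is forced;
3. otherwise the lexicographically smallest pending genotype is
   resolved against the most frequent compatible haplotype
   (lexicographic tie-break), inventing a complement.

Genotypes with zero or one heterozygous site are resolved up front
(their phasing is unconditional). Genotypes sharing no haplotype with
the known set at fixpoint are returned unresolved — the method's
documented "orphan" limitation — and are excluded from the haploweb
with a logged count rather than guessed.

Against an exhaustive minimum-haplotype-set search on small instances
(≤ 8 individuals, ≤ 12 sites), the tiered strategy matches the unique
minimal solution in ≈ 99% of instances, versus ≈ 90% for a flat
most-frequent-first rule; the residual failures are orphan instances
(no output, correctly reported unresolved) and rare greedy guesses in
tier 3 that exceed the minimum. Like any Clark-style greedy, the method
is a heuristic for the minimum-haplotype problem, not an exact solver.

Bayesian statistical phasing with coalescent priors is intentionally
out of scope; in a dataset where some individuals would be phased that
way, those individuals fall to the Clark route here, and the per-route
tags in the phase report keep the provenance of every genotype honest.

## Trees, distances, clades

**K2P distance.** For each sequence pair, transitions `P` and
transversions `Q` are proportions over comparable sites — those where
both sequences (pairwise deletion) or all sequences (complete deletion)
are ungapped and non-N — and `d = -½ ln(1-2P-Q) - ¼ ln(1-2Q)`.
Saturated pairs (either logarithm undefined) are capped at `d = 5.0`
with a logged warning rather than failing the whole matrix; the cap
only matters for sequence pairs far beyond the divergences the
delimitation operates at. The implementation is cross-checked in the
tests against R `ape::dist.dna(model="K80", pairwise.deletion=TRUE)` to
machine precision.

**Neighbor-joining.** Standard Saitou–Nei agglomeration with the Q
criterion, made deterministic by lexicographic tie-breaking on cluster
labels (a cluster is labelled by its smallest leaf id). Negative branch
lengths are clamped to zero with the deficit moved to the sister branch,
preserving path lengths through the joined pair. On additive matrices
the implementation recovers the generating topology and branch lengths
exactly (tested on random 5–8 taxon trees) and matches scikit-bio's
`nj` topology on distance matrices from simulated alignments.

**Bootstrap.** Alignment columns are resampled with replacement; each
replicate is run through the same K2P + NJ path; the support of an
original internal bipartition is the percentage of replicates containing
it. Internal edges of length zero in a replicate are treated as
unresolved and do not count. Supports are attached as integer internal
node labels. Trees with fewer than four taxa have no internal
bipartition and are returned unannotated.

**Outgroup rooting** places the root mid-edge on the bipartition
separating the outgroup; a non-monophyletic outgroup is an error naming
the smallest containing bipartition.

**Distance clades.** The mitochondrial partition is operationalized as
single-linkage components of the graph joining haplotype pairs closer
than a threshold `t`. With `t="auto"`, `t` is the midpoint of the
largest gap in the sorted pairwise distances (barcode-gap heuristic);
all-identical distances make the heuristic meaningless and demand an
explicit `t`. This is a surrogate for delimiting clades by inspecting a
strongly supported tree: it reproduces the intended partition whenever
between-group divergence clearly exceeds within-group variation, which
is exactly the regime in which mitochondrial clades are meaningful
delimitation evidence.

## Haploweb and fields for recombination

Pools are connected components of the *bipartite individual–allele
incidence graph*, not merely of the allele co-occurrence graph: a
haplotype observed only in homozygotes still joins a pool when one of
its carriers also carries a pooled allele. Each individual is assigned
to the component holding its alleles, so mutual allelic exclusivity of
the resulting pools is structural — counting cross-pool heterozygotes
against the FFR partition returns zero for any input, which the tests
assert. Counted against an *independent* partition (the mitochondrial
clades), cross-pool heterozygotes are informative: hybrids appear there,
and each hybrid injected between two pools merges them (pool count
drops by exactly one per bridged pair).

Singleton pools — one allele, homozygous carriers only — are reported
but flagged as weak evidence: the exclusivity criterion is vacuous for
a pool no heterozygote touches. How such an allele should be pooled
when it is phylogenetically nested inside another pool is left flagged,
not guessed.

Partition congruence is summarized by the Rand index (pairwise
agreement over individuals; 1.0 iff identical, computed via
scikit-learn, brute-forced in tests) plus an explicit conflict list. In
the pipeline, each nuclear haplotype inherits the mitochondrial clade
of the majority of its carriers (ties by clade label); haplotypes whose
carriers span clades are logged — they are themselves evidence of
mixing.

Rendering is a tree-plus-curves layout: tips in ladderized order
(clade size, then id, so output is deterministic), curves between
co-occurring tips with stroke width proportional to the co-occurrence
weight (1.5 px per heterozygote), pools colour-coded; exported as JSON
and SVG.

## Synthetic data: what it emulates, what it does not

The generator produces `n_species` reproductively isolated species.
Nuclear alleles derive from a common root mutated to one ancestor per
species (divergence `subs_divergence_between`, default 0.2
substitutions/site) and then to `alleles_per_species` variants
(`subs_divergence_within`, default 0.01); substitutions are independent
per site with equal base frequencies (Jukes–Cantor-like), the simplest
model that yields recoverable clade structure. Each allele carries at
most one deletion (probability `indel_prob`, default 0.3; length 1–5,
uniform interior placement) — one deletion per allele keeps the
two-read deconvolution model exact, and at the default roughly 40% of
heterozygotes are length-variant, a substantial fraction as observed in
real direct-sequencing datasets of indel-prone spacers. Mitochondrial
haplotypes are species-private (one ancestor per species, three
variants, no indels), mirroring clonally inherited clades; hybrids
receive the mitochondrion of a randomly chosen parent species.

Defaults: `seq_length=500`, 15 diploid individuals per species,
`het_fraction=0.8`, `hybrid_fraction=0`. The heterozygote fraction
deserves a note: the delimitation criterion can only pool an allele
that at least one heterozygote connects, so the generator's default
operating point is chosen to keep orphan alleles (observed only in
homozygotes) rare — at 0.8, the probability that some observed allele
is never seen in a heterozygote is a few percent per benchmark dataset,
and the truth-recovery benchmark (pools equal to simulation truth in
≥ 95% of replicates at 3 species × 5 alleles × 15 individuals) reflects
exactly this residue: its failures are replicates with an orphan allele
(reported as an extra weak singleton pool) or with a species whose
heterozygotes happen to be seedless for Clark's method. Analyses at
lower heterozygosity are fully supported; the study-scale emulation in
the acceptance script runs at a 43/70 fraction with per-species sample
sizes 12/7/51 and allele richness (3, 2, 5) scaled to sample size.

The generator does **not** emulate: coalescent genealogies (no shared
polymorphism or incomplete lineage sorting across species),
recombination within the marker, concerted evolution of ribosomal
arrays (alleles are truly Mendelian here, whereas real ITS-like markers
may harbour intragenomic variants), sequencing noise (base-calling
errors, quality trimming), or missing data. Passing tests therefore
demonstrate correctness of the algorithms under clean Mendelian
assumptions, not robustness to every artefact of real chromatograms;
on real data the unresolved/excluded routes and the weak-pool flags are
the honesty valves.

## Pipeline and reproducibility

The pipeline consumes pre-aligned FASTA (alignment itself is upstream
glue, not reimplemented), a mixed-read table and a per-individual
mitochondrial FASTA. Phased sequences are mapped onto the aligned
haplotype catalogue by exact match after degapping; a phased sequence
absent from the catalogue aborts the run naming the individuals, since
a tree cannot be built for an unaligned novel haplotype. All
randomness (bootstrap, simulation) flows from explicit seeds in the
configuration; two runs with the same config are byte-identical, which
the tests assert. Stage-level logging mirrors the accounting a careful
direct-sequencing study reports (how many individuals each phasing
route handled).

Problem sizes in the shipped tests and acceptance script — 100
benchmark replicates, 100–200 bootstrap replicates, 200 deconvolution
pairs, 30 oracle instances — are chosen so the whole suite runs in
well under a minute each while keeping the binomial noise on every
reported rate a few percent at most.

## Known limitations

- Clark phasing is a greedy heuristic (see above); deep-coalescent or
  recombinant data would need statistical phasing, which is out of
  scope by design.
- The barcode-gap threshold assumes a clear gap; continuous divergence
  gradients defeat it, and the error message demands an explicit
  threshold in that case.
- Distinguishing true alleles from intragenomic paralogues of multi-copy
  markers is not attempted; individuals with more than two variants are
  excluded, not interpreted.
- The K2P saturation cap (5.0) biases extremely divergent comparisons
  downward; such pairs should be outgroups, not delimitation subjects.
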