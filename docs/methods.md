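# Methods

## Region gene maps

Coordinates are 1-based, fully closed intervals (NCBI convention). A gene
belongs to a region when its interval shares **at least one base** with
it; containment is not required. The proximal nested deletion is handled
by the same overlap rule applied to a sub-interval, which must be
contained in the outer region. Overlap filtering is idempotent and the
biotype census always sums to the gene count.

Brain expression is a per-gene flag resolved from two sources, mirroring
how such maps are assembled in practice: when per-region mRNA signal
values are available the flag is *signal ≥ threshold* (default 6,
inclusive) in **any** brain region or timepoint; genes absent from the
signal table keep a directly supplied flag from a secondary expression
database. `decreased_in_deletion` is three-valued: True (demonstrated
reduction in deletion carriers), False (tested, not reduced — including
genes not expressed in the assayed tissue), None (unstudied). Summaries
count only protein-coding genes and report percentages rounded half-up
to one decimal.

### Packaged 22q11.2 tables

The shipped fixtures reproduce the published comparative map of the
typical 22q11.2 deletion: 90 genes (46 protein-coding, 27 pseudogenes, 9
ncRNAs, 1 read-through transcript, 7 miRNAs), the 55-gene proximal
subset (30 protein-coding), the gene × species conservation table with
per-homologue similarity percentages and knockout/knockdown codes, and
homologue placements for synteny. Real base-pair coordinates are not
part of those source tables, so fixture coordinates are synthesized
within the published breakpoints, preserving gene order and the proximal
boundary (placed between the 55th and 56th genes; the published proximal
breakpoint is not given at base resolution). Names of pseudogene/ncRNA
entries are likewise synthesized placeholders; protein-coding gene names,
homologue names, similarities and model codes are transcribed. miRNA
conservation (two of seven conserved, in mouse only) is carried as a
curated table, not computed. The segment that moves out of the region in
genome build GRCh38 is honored by fixture content, not by code.

## Local alignment and significance

The hit generator is exact Smith–Waterman local alignment with affine
gaps — no heuristic seeding, so scores are optimal by construction —
scored with BLOSUM62 and NCBI-convention gap costs (a gap of length k
costs open + k·extend; defaults 11/1). The dynamic programming itself is
delegated to Biopython's `PairwiseAligner` (C implementation); this
package defines the hit model on top of it:

- **coverage** per sequence = (last − first aligned residue + 1) / full
  length, the blastp span convention;
- **identity** and **positives** ("similarity") are computed over
  gap-free alignment columns; a positive column is one whose
  substitution score is > 0. Published conservation tables print a
  single integer "% similarity" without a formula; this package reports
  both fractions and uses positives, rounded half-up, for table output —
  a documented assumption.
- **X** (unknown residue) scores 0 against everything.
- A pair with no positively scoring alignment yields an explicit empty
  hit (score 0, zero coverage).

Significance uses fixed gapped Karlin–Altschul constants λ = 0.267,
K = 0.041 (BLOSUM62, 11/1) with search space m·n and no edge-effect
length correction: bit = (λS − ln K)/ln 2, E = K·m·n·e^(−λS). This
orders and thresholds hits exactly as a blastp search would, but the
absolute E-values are a simplification and are not meant to reproduce
blastp output; the RBH criteria below depend only on ordering and the
10⁻⁶ threshold's scale. An adapter ingests externally produced 12-column
tabular hits so a real blastp run can replace the internal aligner
without changing anything downstream.

When an optimal alignment is not unique, reported spans (hence coverage)
come from one optimum; scores are invariant across co-optima.

## Reciprocal best hits

Directed hits are filtered to E ≤ 10⁻⁶ and coverage ≥ 50 % of **either**
sequence (the "any of the protein sequences" reading; a both-sequences
mode exists for sensitivity analysis). Each direction applies its own
filter, and reciprocity requires surviving both. Best-hit sets keep
every subject whose bit score ties the top hit — exact equality by
default, which is how multi-ortholog assignments arise. In **duplicate
mode**, intended for genomes with recent whole-genome duplication, the
tie is relative: bit ≥ top·(1 − tol), default tol = 0.02, chosen as a
small "very similar" margin since no numeric criterion is published.
Output ordering is deterministic (bit score, then lexicographic gene id),
so identical inputs give byte-identical tables regardless of input order.

Canonical isoform selection, when a gene has several sequences and no
canonical flag: longest sequence, then lexicographically smallest
accession.

Curated **functional-homology overrides** add assignments that sequence
filters reject (the packaged example: worm *mdt-15* for *MED15*, which
fails the 50 % coverage rule at 26 % similarity but is an experimentally
confirmed functional homologue). Overrides are additive only: they never
replace or modify an RBH assignment, and re-applying them is a no-op.

## Synteny clusters

A cluster is a maximal run of ≥ 2 region genes, consecutive in region
order *among conserved genes*, whose homologues share one target
chromosome with at most `max_gap` intervening genes (measured in gene
ordinals, not base pairs, because fixture coordinates are synthetic;
default `max_gap` = 3). Orientation is ignored for membership — observed
conserved clusters show minor order shuffling — and monotone homologue
order is reported as a `collinear` flag instead. For tied multi-copy
assignments a cluster may use whichever copy satisfies the constraints;
the chosen copy is recorded. Detection enumerates, per chromosome, all
maximal chain-feasible intervals (checked by dynamic programming over
copy choices), so overlapping clusters on different chromosomes are all
reported; every reported cluster is re-validated against its own
invariants. The published clustering criterion is a drawn map, not an
algorithm; the gap-bounded adjacency rule is this package's explicit
operationalization of it.

## Synthetic proteomes

The simulator emulates exactly the structure the RBH method assumes:

- ancestral proteins drawn residue-wise from Robinson–Robinson
  background frequencies (lengths uniform in `length_range`, default
  80–200 residues — short single-domain scale, chosen to keep all-vs-all
  exact alignment fast while leaving E-values far below threshold for
  true pairs);
- per species: each gene retained with `retention_prob`; retained copies
  mutated by per-site substitution at rate `divergence` (replacement
  drawn from the background, never the same residue); duplicated with
  `duplication_prob`, the duplicate diverging from its sibling by
  `duplicate_divergence`; genes placed on one chromosome in ancestral
  order with each adjacent pair swapped with `order_shuffle_prob`.

There is **no indel process** — a deliberate choice that keeps coverage
near 1 and the brute-force alignment oracle exact; consequences for
interpretation are below. Randomness is one seed per run with per-species
substreams derived from (seed, species name), so adding a species does
not perturb the others and equal configurations are byte-identical.

Recovery is scored against the truth map at the level of
(query gene, target gene) pairs: precision = correct/assigned, recall =
correct/retained-true (all cross pairs of copies retained in both
species), and tie-accuracy = fraction of duplicated ancestral genes
whose full copy set was returned as a tie. Degenerate denominators
report None rather than raising.

The reference recovery experiment runs an undiverged query proteome
(the "human" role) against a target evolved at retention 0.8,
divergence 0.2, duplication 0.1, duplicate divergence 0.01, with 40
ancestral genes, in duplicate mode, averaged over 20 seeds; mean
precision and recall both exceed 0.95. Recall losses come from duplicate
copies whose bit score falls just outside the 2 % tie window.

## What the tests do and do not show

Passing the synthetic end-to-end tests demonstrates that the RBH logic,
tie handling, filters and synteny detection implement their definitions
correctly (they are checked for exact equality against independent
brute-force oracles on small instances). The simulation omits indels,
domain shuffling, rate heterogeneity and compositional bias, so it does
not certify recovery rates on real proteomes; the published similarity
percentages derive from full UniProtKB searches and are shipped as data,
not recomputed. Conservation and model-availability statistics are exact
arithmetic over the packaged tables.

## Numerical conventions

- Percentages: rounded half-up (ties away from zero) to one decimal,
  everywhere. Recomputing a printed percentage from its count and
  denominator is therefore reproducible. Two published percentages are
  inconsistent with their own printed counts under any fixed rounding
  rule; counts are the contract in such cases.
- Similarity percentages in tables: 100·positives, rounded half-up to
  integers.
- Bit-score ties: exact float equality by default. Identical sequences
  produce identical scores, so exact ties are well defined; near-ties
  are only recognized in duplicate mode.
- Degenerate inputs: empty annotation/hit lists/tables yield empty or
  zero-valued results, not errors; malformed records raise `InputError`
  naming the offending gene; unknown matrices, species or policies raise
  `ConfigError`.

## Known limitations

- E-values are desk-scale approximations (fixed λ, K; no length
  adjustment, no composition-based statistics).
- The proximal breakpoint and all fixture coordinates are synthetic;
  base-pair-resolution analyses of the region are out of scope.
- Cluster detection considers only the region's homologue set, not
  whole-genome synteny, and does not infer rearrangement distances.
- Ortholog assignment is per species pair; cross-species groups come
  from intersecting per-pair assignments, not from tree-based orthology.
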