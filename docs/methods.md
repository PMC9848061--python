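# Methods

This note documents the models, conventions and design choices behind
`orthosignal`: what each operation computes, the parameters that matter, what
the synthetic generators do and do not emulate, and known limitations.

## The clan test

A clan is a taxon set separable from all other leaves of an unrooted tree by
removing one edge.  Given a gene tree with leaf set L and a clan with
dataset-wide membership C, let P = C ∩ L (present members) and Q = L \ C.

- |P| < 2 → **insufficient**: the test cannot apply.
- Some edge has exactly P on one side → **recovered**.
- Otherwise → **violated**.

Two edge cases are resolved by explicit convention:

- **|Q| ≤ 1**: status is *recovered*.  Any single leaf hangs on its own
  pendant edge, so the exclusion requirement is vacuously (|Q| = 0) or
  trivially (|Q| = 1) satisfiable.  Real datasets essentially never hit this
  case (it requires an orthogroup sampled almost exclusively from one
  phylum), but the convention is documented because tools differ silently
  here.
- **Polytomies**: by default a multifurcation mixing clan and non-clan
  children is a violation — an edge must actually realize the split.  A
  `soft_polytomies` mode instead refines each polytomy in the clan's favour
  (recovered if P is the union of a subset of the subtrees meeting at some
  node), for gene trees whose polytomies encode uncertainty rather than
  resolved conflict.

Taxa in a tree that belong to no clan definition count as non-clan taxa for
every clan: exclusion means exclusion of *all* other leaves.

The per-orthogroup recovered-clan count runs over **countable** clans only —
those with ≥ 2 members dataset-wide.  A singleton clan (a phylum represented
by one species) can never be recovered or violated, so it is reported but
excluded from counts; including it would deflate every orthogroup's count by
a constant and shift the filter threshold's meaning.

The filter retains orthogroups with count ≥ `min_clans` (default 3, the
conventional "most major relationships" threshold); the threshold is
inclusive, and the retained set is monotonically shrinking in `min_clans`.

## Concordance factors

For species tree T and gene trees S, per nontrivial branch x of T:

- a gene tree is **decisive** for x iff the bipartition of x restricted to
  the tree's taxa has ≥ 2 taxa on both sides;
- it is **concordant** iff that restricted bipartition is realized by one of
  its own edges;
- gCF(x) = 100 · concordant / decisive (undefined if no tree is decisive).

The ≥2/≥2 decisiveness rule is fixed; where the restricted split is trivial
on exactly one side the tree is simply not decisive.  When a clan's
membership coincides with one side of x, recovered/violated statuses map
exactly onto concordant/discordant decisive trees, which is the consistency
the test suite asserts.

sCF(x) is estimated from `n_quartets` sampled quartets (default 100, seeded;
the seed is mandatory because the estimate is a Monte-Carlo mean): one taxon
from each of two distinct subtree groups on each side of x.  Per quartet, a
site is decisive iff all four residues are present (no gap/X) and the
pattern is two-states-two-and-two; it is concordant iff the matched pair
straddles x as in T.  Per-quartet percentages are averaged over quartets
with ≥ 1 decisive site; the two discordant pairings are reported as sDF1 and
sDF2.  Branches where a side contributes fewer than two groups, or where
every quartet lacks decisive sites, are reported missing rather than zero.

## Information and bias metrics

All metrics exclude gaps (`-`) and ambiguity (`X`) from state counts; all
are invariant to taxon order, and the site-level ones to column order.

- **Variable / parsimony-informative sites**: ≥ 2 distinct residues; ≥ 2
  residues each in ≥ 2 sequences.
- **Treeness** = internal branch length / total branch length; undefined on
  a zero-length tree.
- **RCV** = Σᵢⱼ |countᵢⱼ − mean countⱼ| / (n_taxa · length) over residue
  counts; **treeness/RCV** is the composition-aware signal ratio, undefined
  when RCV = 0.
- **RCFV** = Σⱼ Σᵢ |fᵢⱼ − f̄ⱼ| / n over per-taxon residue *frequencies*
  (absolute deviations, divided by taxon count).  Zero iff all rows have
  identical composition.  Taxa with no residues are excluded with a warning.
- **Long-branch score** per taxon: 100 · (mean patristic distance to all
  others / grand mean pairwise distance − 1).  The scores are centred, so
  their plain mean is ~0 by construction and the tail carries the signal;
  both the plain mean and the upper-decile mean are reported, the former as
  the headline value.
- **Saturation**: slope of the through-origin regression of uncorrected
  pairwise p-distance on patristic distance; 1 means unsaturated, smaller
  means identity has plateaued.  Reported as the slope itself (higher =
  less saturated).  Pairwise p-distances skip columns with a gap/X in either
  sequence.
- **Chi-square homogeneity**: contingency test of per-taxon residue counts
  against the pooled expectation (no continuity correction), df =
  (taxa − 1)(observed states − 1); degenerate single-state tables are
  reported missing.
- **Group comparison**: two-sided Wilcoxon rank-sum (Mann–Whitney) per
  metric with stars at 0.05 / 0.01 / 0.001 / 0.0001.

## Posterior-predictive statistics

- **DIV**: mean over columns of the number of distinct residues (all-gap
  columns skipped); ranges over [1, 20].
- **MAX / MEAN**: per-taxon heterogeneity hᵢ = Σⱼ |fᵢⱼ − f̄ⱼ| ∈ [0, 2],
  summarized by its maximum and mean.
- **|Z|** = |observed − replicate mean| / replicate sd (sd with n − 1);
  verdicts are *adequate* (|Z| < 2), *rejected* (|Z| > 5), *intermediate*
  between — both inequalities strict, so an observation exactly 2 (or 5) sd
  away is intermediate.  A zero-spread replicate set is an error
  (degenerate simulation), not a verdict.

The built-in replicate generator keeps the observed matrix's gap pattern and
redraws residues i.i.d. from the pooled frequencies — a site- and
lineage-homogeneous null.  It screens matrices for compositional structure;
it does **not** simulate from a fitted phylogenetic model, so its |Z| values
are not comparable to posterior-predictive output of Bayesian software.  For
that use, externally computed observed/replicate values (including CONV and
VAR statistics, whose formulas live in the software that produces them) can
be read from files and scored with the same rule, which is scale-invariant.

## Chain diagnostics

Two tree samples are compared by bipartition frequencies after burn-in and
thinning: maxdiff and meandiff are the maximum and mean absolute frequency
difference over the union of nontrivial bipartitions observed in either
chain (a bipartition absent from one chain contributes its full frequency).
Averaging over the union is the most inclusive consistent convention; tools
that average only over high-frequency bipartitions will report smaller
meandiff on the same input.  Normalized RF uses the 2(N − 3) denominator
even for multifurcating trees so values stay comparable along a trace.

## Alignment choice

Three candidate alignments of the same sequences are compared by a
homology-statement distance: for each sequence pair and column, aligned
residue–residue index pairs plus residue–gap statements tagged with the
gap's column index (so shifting a gap changes the set).  The distance is
1 − |H_a ∩ H_b| / max(|H_a|, |H_b|) ∈ [0, 1].  This is an approximation of
published positional-gap alignment metrics and is pluggable.  If all three
pairwise distances are strictly below the threshold (default 0.15) the
candidates agree and one is chosen uniformly at random (seeded); otherwise
the candidate with the highest column score wins, ties broken by input
order.  The column score is a normalized mean sum-of-pairs similarity under
BLOSUM62 (each residue pair mapped to [0, 1] by the 20×20 table's min/max;
gap pairs contribute 0) — a surrogate for column-based similarity scores
used with multiple aligners, and labelled as such in output.

## Synthetic data

Defaults emulate a scaled-down animal-phylogeny dataset: clans Bilateria
(8 taxa), Cnidaria (5), Ctenophora (4), Porifera (5), Outgroup (5) and a
singleton Placozoa (1) — 28 taxa, five countable clans.  Branch lengths are
exponential with mean 0.1 substitutions/site; `stem_stretch` multiplies the
designated fast clan's stem (Ctenophora-like long-stem behaviour);
per-taxon dropout defaults to 0.2 per clan; `violation_rate` (default 0.3)
is the probability an orthogroup's tree receives `n_violating_moves`
(default 1) clan-breaking relocations.

- **Violations** are single-leaf subtree-prune-regraft moves that reattach
  one clan member as a cherry with a member of a different clan, violating
  both clans by construction (verified before recording); this mimics
  hidden paralogy's topological signature without simulating its mechanism.
  Each move is recorded in a truth table sufficient to recompute every
  downstream expectation.
- **Alignments** evolve under an equal-exchangeability process: on an edge
  of length t a site substitutes with probability 1 − exp(−rt), r gamma
  (shape 0.5, mean 1), redrawing from the edge's stationary frequencies —
  uniform, except inside the fast clan where they are (1 − s)·uniform +
  s·(five-residue spike) for shift s.  Exchangeability structure of real
  proteins is deliberately absent: the metrics under test depend on
  frequencies and rates, not on the exchange matrix.  No indels are
  simulated beyond optional uniform gap injection for occupancy tests.
- **Exact-profile datasets** place n randomly chosen clans as intact
  subtrees on a caterpillar backbone and interleave the remaining clans'
  members so no edge separates them; every emitted tree is re-verified with
  the clan test (hard postcondition).  This rebuilds any per-n histogram —
  including the five published animal-dataset profiles shipped in
  `ANIMAL_DATASET_PROFILES` — so filter arithmetic can be checked exactly.

Because gene trees here are species-tree copies with dropout plus injected
violations, passing tests demonstrate that the pipeline measures what the
generator controls (violation rates, composition shifts, rate settings);
they do not demonstrate robustness to coalescent gene-tree heterogeneity,
alignment error, or model misspecification in real data.

## Numerical and problem-size choices

Trees are stored unrooted; rooted newick input is collapsed (merging the two
root edges, keeping either edge's support).  Numeric internal-node labels
are supports; bracketed comments are ignored.  Partition coordinates are
1-based inclusive in files, 0-based half-open internally, converted in one
place.  Constant-site removal treats a column as constant when its non-gap,
non-X residues are a single state (or none).

Test-suite problem sizes are chosen to keep the full suite under a minute
while leaving the checks sharp: oracle sweeps use all-tree comparisons at
≤ 8 leaves (1,000 random labelings), parameter recovery uses 400 gene trees
for the binomial check and 50 paired simulations of 300-site alignments per
shift level, and the posterior-predictive calibration uses 50 trials of 100
replicates on a 500-site template.

## Known limitations

- No coalescent or duplication-loss simulation; violations are topological
  stand-ins.
- The homogeneous null in `ppa` is a screening device, not a substitute for
  model-based posterior simulation.
- The alignment distance and column score approximate their published
  counterparts up to normalization; decisions (agree/discord, argmax) are
  faithful, raw values may differ.
- Site-concordance quartet sampling follows the standard group-per-side
  scheme; branches adjacent to sparse regions can be reported missing
  where sample-based tools would output a low-support value.
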