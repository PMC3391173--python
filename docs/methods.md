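# Methods

## Data model

All statistics operate on a rooted tree over uniquely labelled tips
(`PhyloTree`, polytomies allowed) and a taxon table mapping each tip to an
avian **host group** (order or family) and a **microhabitat niche** — one of
`wing`, `body`, `head`, `generalist`, or missing for taxa without a niche
(mammal-louse outgroups). Branch lengths and internal labels are carried
through Newick I/O but ignored by every statistic: all methods here are
topology-only.

Tip labels are matched to table rows after trimming and collapsing internal
whitespace; an optional two-column alias map (`tree_label`, `table_taxon`)
reconciles figure-style abbreviations with table spellings. The packaged
fixture transcribes the source specimen table verbatim, including the
"Alcidinidae" spelling of the kingfisher family (evidently Alcedinidae);
we document rather than correct it so the fixture remains a faithful
transcription.

## Parsimony step counts

The minimum number of state changes of an unordered multistate character is
computed with Hartigan's downpass, which is exact on arbitrary rooted trees,
including multifurcations: at each internal node the children's state sets
vote, the node keeps the majority states, and the deficit (children minus
maximal vote) is added to the cost. Polytomies are **hard** — scored as
simultaneous divergence with no search over resolutions — which keeps the
statistic well defined on consensus trees and matches the common interactive
implementations. A missing-state tip carries the full alphabet and can
always copy its parent, so it never forces a change; this makes "drop the
outgroups from the character" and "keep them as missing" provably
equivalent, and is why the pipeline simply keeps them. The consistency
index is CI = (k−1)/s for k observed states and s steps; it is reported as
undefined when s = 0.

Correctness is established against an independent oracle that enumerates
every assignment of observed states to internal nodes (valid for the
minimum; vectorized so thousands of instances are cheap) and cross-checked
against an external Fitch implementation on binary trees.

## Tip-permutation test of signal

The Maddison–Slatkin test holds the topology fixed and permutes the
multiset of assigned states uniformly across the assigned tips; missing
tips stay missing. The observed step count is compared to the permutation
null with a **lower-tail** p-value (fewer steps = more conserved). Ties
count as as-extreme. Two conventions are reported: `plus_one`,
p = (1+r)/(n+1), which treats the observed arrangement as one more
permutation and never returns 0; and `raw`, p = r/n, under which zero
exceedances at 1,000 permutations prints as p < 0.001. Replicate i draws
its permutation from an independent stream keyed by (seed, i), so results
are reproducible under any execution order.

Because the step count is integer-valued, the permutation p-value is
slightly super-uniform; calibration is checked at the empirical design size
(39 tips, 4 states), where the rejection rate at α = 0.05 over 2,000
simulated no-signal datasets falls in the accepted [0.03, 0.07] band.
Smaller trees are noticeably more conservative (≈ 0.02 at 16 tips) purely
through discreteness.

## Convergent sister pairs

A **convergent pair** is a cherry (two tips sharing a parent) whose taxa
share a host group but carry different non-missing niches. In `strict` mode
only true two-child cherries count; in `matched` mode the tip children of
each polytomy form a pool and the maximum number of disjoint qualifying
pairs within each pool (maximum matching) is added. The default is strict,
reading sister pairs off the rooted topology as drawn.

The ceiling of the statistic over *all* possible trees on a table
decomposes by host group (qualifying pairs never cross groups): within a
group with niche-class sizes n_1…n_k (n total, n_max largest), the complete
multipartite graph has maximum matching min(⌊n/2⌋, n − n_max); the ceiling
is the sum across groups. For the packaged ingroup this gives 14. The
closed form is verified against exhaustive matching enumeration and a
general-purpose matching algorithm.

### Null model

The test randomizes **topology**, keeping annotations attached to their
taxa: null trees are drawn uniformly over all labelled binary topologies
("PDA"; grown by uniform random-edge leaf attachment, then rooted on a
uniform edge — each (tree, edge) extension is unique, so uniformity holds by
induction), with upper-tail p-values under the same conventions as above. A
Yule option (random sequential pair joining) and a `label_shuffle`
sensitivity mode (observed topology, permuted tip labels) are provided and
recorded in the result. Taxa with missing niche can never qualify, so they
are excluded from null trees by default; a flag retains them. The default
of 100 null trees reflects the protocol this pipeline reproduces; the
permutation default is 1,000.

## Tree comparisons

The partition metric between two trees on the same tips is the symmetric
difference of their non-trivial unrooted bipartitions (each stored
canonically as the block not containing the lexicographically smallest
tip, making the set rooting-invariant; a two-child root contributes no
extra split). Missing resolution simply yields fewer splits — a split
present in only one tree counts once, with no partial credit.

Principal coordinates uses classical scaling: square the distances, Gower
double-center, eigendecompose symmetrically, scale eigenvectors by the
square root of their (positive) eigenvalues. Axis signs are fixed by making
the largest-magnitude loading positive, so coordinates are reproducible
across platforms. Negative eigenvalues (the partition metric need not be
Euclidean) are reported and flagged but excluded from coordinates and from
the percent-variance denominator; no Cailliez/Lingoes correction is
applied.

## Synthetic data

* **Characters**: an Mk-style event process — a Poisson(rate) number of
  change events per branch, each to a uniformly chosen different state —
  rather than a transition-matrix simulation, because validation needs the
  *true number of changes*, which parsimony can never exceed. At roughly
  one expected event per tree, steps equal the true count in ≥ 95% of
  replicates; undercounting comes from reversals and parallel changes on
  adjacent branches.
* **Planted convergence**: k disjoint qualifying pairs (taken from a
  maximum matching) are made cherries; all other taxa attach pectinately,
  one unit per join, so no unplanned cherry between two loose taxa can
  arise. When k = 0 the single bottom cherry is chosen non-qualifying; the
  degenerate case where *every* pair qualifies and none can be avoided is
  rejected with the computed maximum in the error.
* **Tables**: group sizes and niche frequencies are free parameters, so
  tables with the empirical marginal structure (19 groups, 39 taxa) can be
  emulated.

These generators reproduce the *combinatorial* structure of real data —
labelled topology, group/niche marginals, planted cherry counts — but not
its evolutionary covariances (no host–parasite cospeciation, no correlated
characters, no rate heterogeneity). Passing tests therefore demonstrate the
statistics and their nulls are computed correctly, not that any empirical
dataset will show the planted effect sizes.

## Problem sizes and numerical choices

Validation suites use trees of 4–16 tips where an exhaustive oracle is
feasible (≤ 8 tips for internal-labeling enumeration, ≤ 12 taxa for
matching enumeration), 2,000 instances for the parsimony oracle, 500 tables
for the matching oracle, 15,000 draws for topology-uniformity chi-square
checks, 2,000 simulations for test calibration, and 5,000 replicates for
the parsimony-versus-truth bound. Eigenvalues within 1e-9 (relative) of
zero are treated as zero in PCoA; PCoA reconstruction of Euclidean inputs
is exact to 1e-9. All stochastic results record their seed; pipeline
sub-seeds are derived from the base seed via SHA-256 of the component name
fed into numpy's `SeedSequence`, keeping every derived seed below 2^31.

## Analysis drivers

The study's empirical topologies exist only as published figures, so the
`analysis/` drivers rebuild the *pattern* with synthetic stand-ins over the
packaged taxa: a host-structured tree with seven planted convergent
cherries (repeated divergence within host groups, weak niche signal) and a
niche-structured tree grouping taxa by microhabitat (perfect niche fit,
CI = 1, no convergent pairs) — the two qualitative regimes the molecular
and morphological data sets display. Their outputs under `results/` are
produced entirely by the package and regenerate deterministically from the
seeds embedded in the scripts.

## Known limitations

* Parsimony only: no likelihood or Bayesian character mapping, no ordered
  states or step matrices, no ancestral-state output.
* The random-tree null is agnostic (uniform or Yule topologies); it does
  not condition on clade sizes or branching times of the observed tree.
* Strict-mode convergence ignores near-cherry structure (e.g. a tip sister
  to a two-tip clade); `matched` mode only extends to polytomy pools.
* The partition metric saturates quickly for comb-like trees, compressing
  long distances in the PCoA embedding.
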