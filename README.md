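# phyloconverge

Comparative-phylogenetics tools for detecting **repeated adaptive divergence**
of host-associated ecomorphs — built around the avian feather-louse system,
where genera specialize on microhabitats of the host's body (*wing*, *body*,
*head*, *generalist*) to escape preening, and lice from the *same* group of
birds repeatedly diverge into *different* microhabitats.

The package asks, for any rooted phylogeny over annotated taxa:

1. **How conserved is a character on the tree?** Minimum parsimony steps
   *s* of an unordered multistate character (Hartigan downpass, exact on
   multifurcating trees), with the consistency index CI = (k−1)/s for k
   observed states, and a tip-permutation (Maddison–Slatkin) test: shuffle
   states across tips, re-count steps, and report the lower-tail p-value.
2. **How often are same-host, different-niche taxa each other's closest
   relatives?** The *convergent sister-pair* statistic counts cherries whose
   two taxa share a host group but differ in niche. Its theoretical ceiling
   for a taxon table is a maximum matching computed per host group
   (min(⌊n/2⌋, n − n_max) for niche-class sizes summing to n), and its null
   distribution comes from topologies drawn uniformly from all labelled
   binary trees (PDA), with Yule and label-shuffle alternatives.
3. **How different are competing trees?** Pairwise partition metric
   (Robinson–Foulds symmetric difference) and a principal-coordinates
   embedding of the resulting distance matrix.

A synthetic-data module generates trees, Mk-style characters with known
true change counts, and annotation tables with a planted number of
convergent cherries, so every statistic is validated against ground truth.
The packaged specimen table (39 ingroup louse genera across 19 avian host
groups, plus 4 mammal-louse outgroups) ships as a fixture.

## Worked example

```python
import numpy as np
import phyloconverge as pc
from phyloconverge.synthetic import plant_pairs_on_table

table = pc.table1_fixture().annotated          # 39 niche-annotated genera
print(pc.max_convergent_pairs(table))          # -> 14

# a tree with 7 planted same-group/different-niche cherries
tree = plant_pairs_on_table(table, 7, rng=np.random.default_rng(2012))

count, pairs = pc.convergent_pair_count(tree, table)
res = pc.convergence_null_test(table, tree, n_trees=100, seed=4120)
print(count, res.p_plus_one)                   # -> 7 0.009900990099009901
```

The observed 7 pairs sit far above the random-topology null (mean ≈ 0.3
pairs across 100 uniform topologies), so the plus-one permutation p-value is
1/101 ≈ 0.0099: repeated divergence within host groups, not chance
arrangement. The same analysis from the shell:

```bash
phyloconverge max-pairs --fixture-table1
phyloconverge run-all --tree mytree.nwk --fixture-table1 --seed 1 --out report.json
```

## Analysis scripts

The `analysis/` drivers re-create the full study pattern end to end with
synthetic stand-ins for the unpublished empirical topologies, writing their
tables under `results/`:

| script | what it does |
| --- | --- |
| `01_specimen_table.py` | tallies the packaged table; computes the 14-pair ceiling |
| `02_signal_tests.py` | steps/CI + permutation signal tests on a host-structured and a niche-structured tree |
| `03_convergence_null.py` | convergent-pair counts vs 100 uniform random topologies |
| `04_tree_space.py` | partition-metric matrix + PCoA of competing trees |

Run them in order (`python analysis/01_specimen_table.py`, …).

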