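"""Convergent terminal sister pairs and their random-tree null.

The central statistic: the number of cherries (terminal sister pairs) whose
two taxa share a host group but occupy *different* microhabitat niches.
Each such pair is one instance of repeated adaptive divergence — close
relatives on the same hosts that have split into different ecomorphs.

Because a qualifying pair never crosses host groups, the theoretical maximum
of the statistic over all possible trees decomposes by host group: within a
group it is a maximum matching on the complete multipartite graph whose
parts are the niche classes.  For part sizes n_1..n_k with n = sum n_i and
n_max = max n_i, that matching has size min(floor(n/2), n - n_max).

The null model randomizes *topology* while keeping annotations attached to
their taxa: by default trees are drawn uniformly from all labelled binary
topologies (PDA / equiprobable-trees model), with a Yule (random sequential
joining) option and a label-shuffle mode (fixed observed topology, permuted
tip labels) for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .chardata import TaxonTable, _norm_label
from .randomization import RandomizationResult
from .treeio import Node, PhyloTree, cherries

__all__ = [
    "ConvergentPair",
    "convergent_pair_count",
    "max_convergent_pairs",
    "random_topology",
    "convergence_null_test",
]


@dataclass(frozen=True)
class ConvergentPair:
    taxon_a: str
    taxon_b: str
    host_group: str
    niche_a: str
    niche_b: str


def _resolve(tip: str, table: TaxonTable, alias: Optional[dict]) -> str:
    name = _norm_label(tip)
    if alias and name in alias:
        name = alias[name]
    if name not in table:
        raise KeyError(f"tree tip {tip!r} not found in taxon table")
    return name


def _qualifies(ra, rb) -> bool:
    return (
        ra.host_group == rb.host_group
        and ra.niche is not None
        and rb.niche is not None
        and ra.niche != rb.niche
    )


def convergent_pair_count(
    tree: PhyloTree,
    table: TaxonTable,
    polytomy_mode: str = "strict",
    alias: Optional[dict] = None,
) -> tuple[int, list[ConvergentPair]]:
    """Count terminal sister pairs sharing a host group but differing in niche.

    strict mode scores only true two-tip cherries.  matched mode additionally
    pools the tip children of each polytomy and takes the maximum number of
    disjoint qualifying pairs within each pool.  A cherry with a missing
    niche on either member simply never qualifies.
    """
    pairs: list[ConvergentPair] = []
    for group in cherries(tree, polytomy_mode=polytomy_mode):
        members = sorted(group)
        recs = {t: table.get(_resolve(t, table, alias)) for t in members}
        if len(members) == 2:
            a, b = members
            if _qualifies(recs[a], recs[b]):
                pairs.append(
                    ConvergentPair(a, b, recs[a].host_group, recs[a].niche, recs[b].niche)
                )
            continue
        # polytomy pool: maximum matching restricted to qualifying edges
        g = nx.Graph()
        g.add_nodes_from(members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if _qualifies(recs[a], recs[b]):
                    g.add_edge(a, b)
        for a, b in nx.max_weight_matching(g, maxcardinality=True):
            a, b = sorted((a, b))
            pairs.append(
                ConvergentPair(a, b, recs[a].host_group, recs[a].niche, recs[b].niche)
            )
    return len(pairs), pairs


def max_convergent_pairs(table: TaxonTable) -> int:
    """Largest value the pair statistic can take on *any* binary tree over
    the table's taxa.

    Per host group, the maximum matching of same-group different-niche pairs
    on niche classes of sizes n_1..n_k is min(floor(n/2), n - max n_i);
    groups are independent, so the totals add.
    """
    annotated = [r for r in table if r.niche is not None]
    if not annotated:
        raise ValueError("table has no niche-annotated records")
    total = 0
    by_group: dict[str, list[str]] = {}
    for rec in annotated:
        by_group.setdefault(rec.host_group, []).append(rec.niche)
    for niches in by_group.values():
        n = len(niches)
        n_max = max(niches.count(s) for s in set(niches))
        total += min(n // 2, n - n_max)
    return total


# ---------------------------------------------------------------------------
# Random labelled topologies
# ---------------------------------------------------------------------------


def _root_adjacency(adj: dict, root_id, parent=None) -> Node:
    label = root_id[1] if isinstance(root_id, tuple) else None
    node = Node(label=label)
    for nb in adj[root_id]:
        if nb != parent:
            node.add_child(_root_adjacency(adj, nb, root_id))
    return node


def _pda_tree(taxa: list[str], rng: np.random.Generator) -> PhyloTree:
    # Sequential uniform-edge leaf attachment on the growing unrooted tree
    # gives the uniform (PDA) distribution over labelled binary topologies;
    # the result is then rooted on a uniformly chosen edge.
    leaves = [("L", t) for t in taxa]
    if len(taxa) == 2:
        root = Node()
        root.add_child(Node(label=taxa[0]))
        root.add_child(Node(label=taxa[1]))
        return PhyloTree(root)
    next_internal = 0
    edges = [(next_internal, leaves[0]), (next_internal, leaves[1]), (next_internal, leaves[2])]
    for leaf in leaves[3:]:
        next_internal += 1
        w = next_internal
        i = int(rng.integers(len(edges)))
        u, v = edges[i]
        edges[i] = (u, w)
        edges.append((w, v))
        edges.append((w, leaf))
    # root on a uniformly chosen edge
    i = int(rng.integers(len(edges)))
    u, v = edges.pop(i)
    root_id = "ROOT"
    edges.append((root_id, u))
    edges.append((root_id, v))
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    return PhyloTree(_root_adjacency(adj, root_id))


def _yule_tree(taxa: list[str], rng: np.random.Generator) -> PhyloTree:
    lineages = [Node(label=t) for t in taxa]
    while len(lineages) > 1:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        parent = Node()
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        lineages[j:j + 1] = []
        lineages[i] = parent
    return PhyloTree(lineages[0])


def random_topology(
    taxa,
    model: str = "pda_uniform",
    rng: Optional[np.random.Generator] = None,
) -> PhyloTree:
    """Draw a rooted binary labelled topology on ``taxa``.

    ``pda_uniform`` is uniform over unrooted labelled binary topologies
    (rooted afterwards on a uniform edge); ``yule`` joins random lineage
    pairs sequentially.
    """
    taxa = list(taxa)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(taxa)) != len(taxa):
        raise ValueError("taxa must be unique")
    if rng is None:
        rng = np.random.default_rng()
    if model == "pda_uniform":
        return _pda_tree(taxa, rng)
    if model == "yule":
        return _yule_tree(taxa, rng)
    raise ValueError(f"unknown random-tree model: {model!r}")


def _shuffled_labels_tree(
    tree: PhyloTree, shuffle_set: set[str], rng: np.random.Generator
) -> PhyloTree:
    from .treeio import parse_newick, write_newick

    clone = parse_newick(write_newick(tree))
    targets = [n for n in clone.tips() if n.label in shuffle_set]
    labels = [n.label for n in targets]
    perm = rng.permutation(len(labels))
    for node, k in zip(targets, perm):
        node.label = labels[k]
    return clone


def convergence_null_test(
    table: TaxonTable,
    observed_tree: PhyloTree,
    n_trees: int = 100,
    model: str = "pda_uniform",
    seed: int = 0,
    polytomy_mode: str = "strict",
    include_unannotated: bool = False,
    alias: Optional[dict] = None,
    convention: str = "plus_one",
) -> RandomizationResult:
    """Upper-tail test: are there more convergent pairs on the observed tree
    than on random topologies over the same taxa?

    Taxa with a missing niche can never form a qualifying pair, so they are
    left out of the null trees by default (``include_unannotated`` retains
    them); ``model='label_shuffle'`` instead permutes tip labels on the
    observed topology.
    """
    observed, obs_pairs = convergent_pair_count(
        observed_tree, table, polytomy_mode=polytomy_mode, alias=alias
    )
    resolved = {t: _resolve(t, table, alias) for t in observed_tree.tip_labels}
    null_taxa = [
        t
        for t in observed_tree.tip_labels
        if include_unannotated or table.get(resolved[t]).niche is not None
    ]
    if len(null_taxa) < 2:
        raise ValueError("fewer than 2 taxa available for null trees")
    null = []
    for rep in range(n_trees):
        rng = np.random.default_rng([seed, rep])
        if model == "label_shuffle":
            t = _shuffled_labels_tree(observed_tree, set(null_taxa), rng)
        else:
            t = random_topology(null_taxa, model=model, rng=rng)
        c, _ = convergent_pair_count(t, table, polytomy_mode=polytomy_mode, alias=alias)
        null.append(float(c))
    return RandomizationResult(
        observed=float(observed),
        null_sample=null,
        n_reps=n_trees,
        tail="upper",
        seed=seed,
        convention=convention,
        statistic="convergent_pairs",
        extra={
            "model": model,
            "polytomy_mode": polytomy_mode,
            "pairs": [vars(p) for p in obs_pairs],
            "max_possible": max_convergent_pairs(table),
        },
    )
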