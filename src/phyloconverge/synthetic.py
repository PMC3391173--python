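"""Synthetic trees, characters and annotation tables with known ground truth.

Every generator is deterministic given its parameters and seed, so each
pipeline stage can be validated without external data:

* discrete characters evolve by an Mk-style event process — a Poisson number
  of change events per branch, each to a uniformly chosen *different* state —
  so the true number of change events is known exactly and parsimony step
  counts can be checked against it (parsimony is a lower bound);
* convergence scenarios plant a known number of qualifying cherries in an
  otherwise random topology, so the pair statistic and its null test have a
  known answer;
* host-group tables with configurable group sizes and niche frequencies
  emulate the marginal structure of real specimen tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chardata import NICHES, CharacterMap, TaxonRecord, TaxonTable
from .convergence import max_convergent_pairs, random_topology
from .treeio import Node, PhyloTree

__all__ = [
    "SyntheticScenario",
    "simulate_mk_character",
    "plant_convergent_scenario",
    "plant_pairs_on_table",
    "table1_like_table",
]


@dataclass
class SyntheticScenario:
    tree: PhyloTree
    table: TaxonTable
    planted_pairs: int
    seed: int
    parameters: dict = field(default_factory=dict)
    true_change_events: Optional[int] = None


def simulate_mk_character(
    tree: PhyloTree,
    n_states: int,
    rate: float,
    rng: np.random.Generator,
) -> tuple[CharacterMap, int]:
    """Evolve one unordered character down ``tree``.

    The root state is uniform over ``n_states``; each branch receives a
    Poisson(``rate``) number of change events, each replacing the current
    state by a uniformly chosen different one.  Returns the tip character
    and the total realized number of change events (the parsimony truth).
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    states = [f"s{i}" for i in range(n_states)]
    total_events = 0
    assignments: dict[str, str] = {}
    stack = [(tree.root, int(rng.integers(n_states)))]
    while stack:
        node, state = stack.pop()
        if node is not tree.root:
            for _ in range(rng.poisson(rate)):
                shift = 1 + int(rng.integers(n_states - 1))
                state = (state + shift) % n_states
                total_events += 1
        if node.is_tip:
            assignments[node.label] = states[state]
        else:
            for child in node.children:
                stack.append((child, state))
    return CharacterMap(assignments), total_events


def _join(a: Node, b: Node) -> Node:
    parent = Node()
    parent.add_child(a)
    parent.add_child(b)
    return parent


def plant_pairs_on_table(
    table: TaxonTable,
    k_pairs: int,
    rng: Optional[np.random.Generator] = None,
) -> PhyloTree:
    """Binary tree over ``table``'s taxa with exactly ``k_pairs`` convergent
    cherries and no other qualifying cherry.

    ``k_pairs`` disjoint same-group different-niche pairs (taken from a
    maximum matching) become cherries; every other taxon is attached
    pectinately, one at a time, so no further cherry between two loose taxa
    can arise — except the very first join when no pair is planted, which is
    chosen non-qualifying.
    """
    import networkx as nx

    if rng is None:
        rng = np.random.default_rng()
    cap = max_convergent_pairs(table)
    if k_pairs < 0 or k_pairs > cap:
        raise ValueError(
            f"k_pairs={k_pairs} infeasible; maximum for this table is {cap}"
        )

    def qualifies(a: TaxonRecord, b: TaxonRecord) -> bool:
        return (
            a.host_group == b.host_group
            and a.niche is not None
            and b.niche is not None
            and a.niche != b.niche
        )

    recs = list(table)
    graph = nx.Graph()
    graph.add_nodes_from(r.taxon for r in recs)
    for i, a in enumerate(recs):
        for b in recs[i + 1 :]:
            if qualifies(a, b):
                graph.add_edge(a.taxon, b.taxon)
    matching = sorted(tuple(sorted(e)) for e in nx.max_weight_matching(
        graph, maxcardinality=True
    ))
    planted = matching[:k_pairs]

    paired = {t for p in planted for t in p}
    singles = [r.taxon for r in recs if r.taxon not in paired]
    units = [_join(Node(label=a), Node(label=b)) for a, b in planted]
    single_nodes = [Node(label=t) for t in singles]
    order = rng.permutation(len(single_nodes))
    single_nodes = [single_nodes[i] for i in order]

    if units:
        backbone = units.pop(int(rng.integers(len(units))))
    else:
        start = None
        for i in range(len(single_nodes)):
            for j in range(i + 1, len(single_nodes)):
                a = table.get(single_nodes[i].label)
                b = table.get(single_nodes[j].label)
                if not qualifies(a, b):
                    start = (i, j)
                    break
            if start:
                break
        if start is None:
            raise ValueError(
                "cannot build a 0-pair tree: every pair of taxa forms a "
                "qualifying cherry"
            )
        i, j = start
        backbone = _join(single_nodes[i], single_nodes[j])
        del single_nodes[j], single_nodes[i]

    remaining = units + single_nodes
    for i in rng.permutation(len(remaining)):
        backbone = _join(remaining[int(i)], backbone)
    return PhyloTree(backbone)


def plant_convergent_scenario(
    n_groups: int,
    taxa_per_group: int,
    k_pairs: int,
    niches: Sequence[str] = NICHES,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> SyntheticScenario:
    """Build a table and binary tree with exactly ``k_pairs`` convergent
    cherries and no other qualifying cherry.

    Each host group gets ``taxa_per_group`` taxa with niches cycling through
    ``niches`` (so same-group different-niche pairs exist whenever the group
    has >= 2 taxa and >= 2 niches).  ``k_pairs`` disjoint qualifying pairs
    are planted as cherries; all remaining taxa are attached pectinately to
    the backbone, one at a time, so no accidental cherry can form between
    two of them — except possibly the very first join, which is chosen
    non-qualifying.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    niches = list(niches)
    records = []
    for g in range(n_groups):
        for i in range(taxa_per_group):
            records.append(
                TaxonRecord(
                    taxon=f"G{g + 1}_t{i + 1}",
                    host_group=f"group{g + 1}",
                    niche=niches[i % len(niches)],
                )
            )
    table = TaxonTable(records, provenance="synthetic")
    tree = plant_pairs_on_table(table, k_pairs, rng=rng)
    return SyntheticScenario(
        tree=tree,
        table=table,
        planted_pairs=k_pairs,
        seed=seed,
        parameters={
            "n_groups": n_groups,
            "taxa_per_group": taxa_per_group,
            "k_pairs": k_pairs,
            "niches": niches,
        },
    )


def table1_like_table(
    n_groups: int,
    group_size_distribution,
    niche_distribution,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> TaxonTable:
    """Random annotation table with requested marginal structure.

    ``group_size_distribution`` is either a sequence of ``n_groups`` sizes or
    a single int applied to every group; ``niche_distribution`` maps niche
    name to sampling probability (need not cover all four canonical states).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(group_size_distribution, int):
        sizes = [group_size_distribution] * n_groups
    else:
        sizes = list(group_size_distribution)
        if len(sizes) != n_groups:
            raise ValueError("group_size_distribution length must equal n_groups")
    if any(s < 1 for s in sizes):
        raise ValueError("group sizes must be positive")
    niche_names = list(niche_distribution)
    probs = np.array([niche_distribution[n] for n in niche_names], dtype=float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValueError("niche probabilities must be non-negative and sum > 0")
    probs = probs / probs.sum()
    unknown = [n for n in niche_names if n not in NICHES]
    if unknown:
        raise ValueError(f"unknown niches: {unknown}")
    records = []
    for g, size in enumerate(sizes):
        for i in range(size):
            niche = niche_names[int(rng.choice(len(niche_names), p=probs))]
            records.append(
                TaxonRecord(
                    taxon=f"G{g + 1}_t{i + 1}",
                    host_group=f"group{g + 1}",
                    niche=niche,
                )
            )
    return TaxonTable(records, provenance="synthetic")
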