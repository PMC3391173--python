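"""Minimum-change (parsimony) step counts for unordered multistate characters.

The step count is the minimum number of state changes over all assignments of
states to internal nodes, computed by Hartigan's downpass, which is exact for
unordered characters on arbitrary (multifurcating) rooted trees.  Polytomies
are treated as *hard* — scored as simultaneous divergence, with no search
over resolutions — matching the usual treatment in interactive parsimony
software.  A tip with a missing state is compatible with every state and
never forces a change, which is why including or excluding unannotated
outgroups leaves the count unchanged.

The consistency index CI = (observed states - 1) / steps measures homoplasy:
CI = 1 means each state arose exactly once on the tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .chardata import CharacterMap
from .treeio import PhyloTree

__all__ = [
    "StepCount",
    "TreeIndex",
    "fitch_steps",
    "min_steps",
    "consistency_index",
]


@dataclass(frozen=True)
class StepCount:
    steps: int
    min_possible: int
    consistency_index: Optional[float]

    def __post_init__(self):
        if self.steps < self.min_possible:
            raise ValueError("steps below the k-1 lower bound")


class TreeIndex:
    """Array form of a rooted tree for repeated parsimony evaluation.

    Nodes are numbered in postorder (children before parents); tips first in
    ``tip_labels`` order is *not* guaranteed, so use ``tip_index`` to place
    states.
    """

    def __init__(self, tree: PhyloTree):
        nodes = list(tree.postorder())
        idx = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.children: list[tuple[int, ...]] = [
            tuple(idx[id(c)] for c in n.children) for n in nodes
        ]
        self.is_tip = np.array([n.is_tip for n in nodes])
        self.tip_index: dict[str, int] = {
            n.label: i for i, n in enumerate(nodes) if n.is_tip
        }
        self.internal: list[int] = [
            i for i, ch in enumerate(self.children) if ch
        ]


def _index_for(tree: PhyloTree) -> TreeIndex:
    cached = getattr(tree, "_parsimony_index", None)
    if cached is None:
        cached = TreeIndex(tree)
        tree._parsimony_index = cached
    return cached


def hartigan_steps(index: TreeIndex, tip_states: np.ndarray, n_states: int) -> int:
    """Hartigan downpass on integer-coded tip states (-1 = missing).

    ``tip_states`` holds a code per *node* slot (entries for internal nodes
    are ignored).  Missing tips carry the full state set and therefore add
    no cost anywhere.
    """
    full_mask = (1 << n_states) - 1
    masks = np.zeros(index.n_nodes, dtype=np.int64)
    tip_nodes = np.flatnonzero(index.is_tip)
    codes = tip_states[tip_nodes]
    masks[tip_nodes] = np.where(codes >= 0, 1 << np.maximum(codes, 0), full_mask)
    cost = 0
    for i in index.internal:
        counts = [0] * n_states
        ch = index.children[i]
        for c in ch:
            m = int(masks[c])
            s = 0
            while m:
                if m & 1:
                    counts[s] += 1
                m >>= 1
                s += 1
        best = max(counts)
        node_mask = 0
        for s in range(n_states):
            if counts[s] == best:
                node_mask |= 1 << s
        masks[i] = node_mask
        cost += len(ch) - best
    return cost


def _encode(tree: PhyloTree, char: CharacterMap):
    index = _index_for(tree)
    labels = set(tree.tip_labels)
    alphabet = sorted(
        {s for t, s in char.assignments.items() if t in labels and s is not None}
    )
    if not alphabet:
        raise ValueError("all tips have missing states")
    code = {s: i for i, s in enumerate(alphabet)}
    tip_states = np.full(index.n_nodes, -1, dtype=np.int64)
    for label, node_i in index.tip_index.items():
        if label not in char.assignments:
            raise KeyError(
                f"tip {label!r} absent from character map (mark it missing "
                "explicitly if it has no state)"
            )
        state = char.assignments[label]
        if state is not None:
            tip_states[node_i] = code[state]
    return index, tip_states, alphabet


def fitch_steps(tree: PhyloTree, char: CharacterMap) -> StepCount:
    """Exact minimum number of state changes of ``char`` on ``tree``.

    Every tip must appear in the character map (possibly as missing) and at
    least one tip must carry a state.
    """
    index, tip_states, alphabet = _encode(tree, char)
    steps = hartigan_steps(index, tip_states, len(alphabet))
    min_possible = len(alphabet) - 1
    ci = min_possible / steps if steps > 0 else None
    return StepCount(steps=steps, min_possible=min_possible, consistency_index=ci)


def min_steps(char: CharacterMap) -> int:
    """Lower bound on steps for any tree: (observed states) - 1."""
    if char.n_states == 0:
        raise ValueError("character has no assigned states")
    return char.n_states - 1


def consistency_index(tree: PhyloTree, char: CharacterMap) -> Optional[float]:
    """min_steps / fitch_steps, or None when the character is constant
    (0 steps) and the index is undefined."""
    return fitch_steps(tree, char).consistency_index
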