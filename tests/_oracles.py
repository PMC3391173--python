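"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with the package's algorithms: parsimony
steps are found by enumerating *every* assignment of states to internal
nodes, and the maximum pair count by enumerating every matching of the
qualifying-pair graph.
"""

from __future__ import annotations

import numpy as np


def exhaustive_fitch(tree, char) -> int:
    """Minimum changes by enumerating all internal-node labelings.

    Internal states range over the observed alphabet (sufficient for the
    minimum).  Tips with a missing state can copy their parent, so their
    edges are skipped.
    """
    labels = set(tree.tip_labels)
    alphabet = sorted(
        {s for t, s in char.assignments.items() if t in labels and s is not None}
    )
    k = len(alphabet)
    code = {s: i for i, s in enumerate(alphabet)}
    internals = list(tree.internal_nodes())
    m = len(internals)
    idx = {id(n): i for i, n in enumerate(internals)}
    labelings = np.indices((k,) * m).reshape(m, -1)
    cost = np.zeros(labelings.shape[1], dtype=np.int64)
    for node in internals:
        i = idx[id(node)]
        for child in node.children:
            if child.is_tip:
                s = char.assignments.get(child.label)
                if s is None:
                    continue
                cost += labelings[i] != code[s]
            else:
                cost += labelings[i] != labelings[idx[id(child)]]
    return int(cost.min())


def enumerate_matchings_max(vertices, qualifies) -> int:
    """Size of a maximum matching by exhaustive enumeration.

    ``qualifies(a, b)`` says whether the pair may be matched.  Memoized on
    the remaining vertex set; exact for small inputs (<= ~14 vertices).
    """
    verts = tuple(sorted(vertices))
    memo: dict[frozenset, int] = {}

    def rec(remaining: frozenset) -> int:
        if len(remaining) < 2:
            return 0
        if remaining in memo:
            return memo[remaining]
        v = min(remaining)
        rest = remaining - {v}
        best = rec(rest)  # leave v unmatched
        for u in rest:
            if qualifies(v, u):
                best = max(best, 1 + rec(rest - {u}))
        memo[remaining] = best
        return best

    return rec(frozenset(verts))


def brute_force_max_pairs(table) -> int:
    """Maximum convergent-pair count over all trees, by matching enumeration."""
    recs = {r.taxon: r for r in table if r.niche is not None}

    def qualifies(a, b):
        ra, rb = recs[a], recs[b]
        return ra.host_group == rb.host_group and ra.niche != rb.niche

    return enumerate_matchings_max(recs, qualifies)


def unrooted_signature(tree) -> frozenset:
    """Canonical identity of the unrooted topology: its non-trivial splits."""
    from phyloconverge.treeio import bipartitions

    return frozenset(bipartitions(tree))
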