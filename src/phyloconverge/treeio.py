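"""Rooted phylogenies in Newick format.

Trees are stored rooted, exactly as read.  Every statistic in this package is
topology-only: branch lengths and internal node labels (support values) are
parsed and carried through I/O but never consulted.  Bipartitions are always
taken in the unrooted sense (the root is suppressed), because partition-metric
comparisons between trees are conventionally made on unrooted topologies;
cherry (terminal sister pair) detection, by contrast, reads the rooted
structure as drawn.
"""

from __future__ import annotations

import io
from typing import Iterator, Optional

import dendropy

__all__ = [
    "Node",
    "PhyloTree",
    "NewickError",
    "parse_newick",
    "read_newick_file",
    "write_newick",
    "cherries",
    "tip_sibling_groups",
    "bipartitions",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


class Node:
    """A node of a rooted tree; tips carry a label, internal nodes may too."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {kind} {self.label!r}>"


class PhyloTree:
    """A rooted, possibly multifurcating tree over uniquely labelled tips."""

    def __init__(self, root: Node):
        self.root = root
        self._splice_unifurcations()
        self._validate()

    # -- construction -----------------------------------------------------

    def _splice_unifurcations(self) -> None:
        # A chain of single-child internal nodes carries no topological
        # information; splice it out so that every internal node has >= 2
        # children (root included, unless the tree is a single tip).
        for node in list(self.preorder()):
            while len(node.children) == 1:
                (only,) = node.children
                node.label = only.label if only.is_tip else node.label
                node.children = only.children
                for c in node.children:
                    c.parent = node
                if only.is_tip:
                    break

    def _validate(self) -> None:
        labels = [tip.label for tip in self.tips()]
        if not labels:
            raise NewickError("tree has no tips")
        seen: set[str] = set()
        for lab in labels:
            if lab is None or lab == "":
                raise NewickError("tip without a label")
            if lab in seen:
                raise NewickError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
        self._tip_labels = labels

    # -- traversal --------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> Iterator[Node]:
        return (n for n in self.preorder() if n.is_tip)

    def internal_nodes(self) -> Iterator[Node]:
        return (n for n in self.preorder() if not n.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    # -- comparisons ------------------------------------------------------

    def topology_equal(self, other: "PhyloTree") -> bool:
        """Same tip set and same unrooted split set (clades below the root
        compared on the rooted structure are deliberately not used here)."""
        return (
            set(self._tip_labels) == set(other._tip_labels)
            and _rooted_clades(self) == _rooted_clades(other)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree n_tips={self.n_tips}>"


def _rooted_clades(tree: PhyloTree) -> set[frozenset[str]]:
    clades = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            clades.add(below[id(node)])
    return clades


# ---------------------------------------------------------------------------
# Newick I/O (parsing is delegated to dendropy; the writer is a direct
# serialization of the Node structure)
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def parse_newick(text: str) -> PhyloTree:
    """Parse a single-tree Newick string.

    Polytomies are retained; quoted labels and branch lengths are accepted.
    Raises :class:`NewickError` on malformed input or duplicate tip labels.
    """
    if not text or not text.strip():
        raise NewickError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        if dtree.seed_node is not None and dtree.seed_node.taxon is not None:
            return _from_dendropy(dtree)  # single-tip tree "A;"
        raise NewickError("empty tree")
    return _from_dendropy(dtree)


def read_newick_file(path) -> list[PhyloTree]:
    """Read one or more ';'-separated trees from a Newick file."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    try:
        dtrees = dendropy.TreeList.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"malformed Newick in {path}: {exc}") from exc
    if len(dtrees) == 0:
        raise NewickError(f"no trees found in {path}")
    return [_from_dendropy(t) for t in dtrees]


_NEEDS_QUOTING = set("()[]{}:;,'\" \t\n")


def _format_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTING for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree, include_lengths: bool = True) -> str:
    """Serialize to Newick; ``parse_newick(write_newick(T))`` preserves
    topology and labels exactly."""

    def fmt(node: Node) -> str:
        if node.is_tip:
            s = _format_label(node.label)
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                s += _format_label(node.label)
        if include_lengths and node.length is not None:
            s += f":{node.length:g}"
        return s

    return fmt(tree.root) + ";"


def write_newick_file(trees, path, include_lengths: bool = True) -> None:
    if isinstance(trees, PhyloTree):
        trees = [trees]
    with open(path, "w", encoding="utf-8") as fh:
        for t in trees:
            fh.write(write_newick(t, include_lengths=include_lengths) + "\n")


# ---------------------------------------------------------------------------
# Topological queries
# ---------------------------------------------------------------------------


def tip_sibling_groups(tree: PhyloTree) -> list[frozenset[str]]:
    """Maximal groups of >= 2 tip children sharing one parent node.

    For a binary node whose two children are both tips this is exactly the
    cherry; for a polytomy it is the pool of tips available for matching.
    """
    groups = []
    for node in tree.internal_nodes():
        tips = [c.label for c in node.children if c.is_tip]
        if len(tips) >= 2:
            groups.append(frozenset(tips))
    return groups


def cherries(tree: PhyloTree, polytomy_mode: str = "strict"):
    """Terminal sister pairs of the rooted tree.

    strict
        Only pairs of tips whose shared parent has exactly those two tips as
        its only children; pairs are mutually disjoint.
    matched
        Returns every maximal tip-sibling group (size >= 2), including the
        tip children of polytomies, as candidate pools for downstream
        pair matching.
    """
    if polytomy_mode == "matched":
        return tip_sibling_groups(tree)
    if polytomy_mode != "strict":
        raise ValueError(f"unknown polytomy_mode: {polytomy_mode!r}")
    pairs = []
    for node in tree.internal_nodes():
        if len(node.children) == 2 and all(c.is_tip for c in node.children):
            pairs.append(frozenset(c.label for c in node.children))
    return pairs


def bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial splits of the unrooted topology, one per internal edge.

    Each split is stored canonically as the block NOT containing the
    lexicographically smallest tip label, so the set is identical however the
    source tree is rooted.  A root with two children contributes no extra
    split, and trees with < 4 tips have none.
    """
    all_tips = frozenset(tree._tip_labels)
    n = len(all_tips)
    if n < 4:
        return set()
    ref = min(all_tips)
    splits: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            below[id(node)] = frozenset([node.label])
            continue
        clade = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = clade
        if node is tree.root:
            continue
        if 2 <= len(clade) <= n - 2:
            block = all_tips - clade if ref in clade else clade
            splits.add(block)
    return splits
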