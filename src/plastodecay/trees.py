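"""Phylogenetic tree structure and topology utilities.

Trees are stored as rooted ``Node`` structures. An *unrooted* tree is
represented, as usual, by a root of degree three (or a star for three
leaves); identity of unrooted topologies is decided by their set of
non-trivial bipartitions, never by the arbitrary rooting.
"""

from __future__ import annotations

import io
import itertools
from typing import Iterator, Optional, Sequence

import dendropy
import numpy as np


class Node:
    """Tree node; leaves carry a label, edges carry the length to the parent."""

    __slots__ = ("label", "length", "children")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None,
                 children: Optional[list["Node"]] = None):
        self.label = label
        self.length = length
        self.children: list[Node] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(self.label, self.length, [c.copy() for c in self.children])

    def walk(self) -> Iterator["Node"]:
        """Pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.walk() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {to_newick(PhyloTree(self))}>"


class PhyloTree:
    """A phylogeny over uniquely labelled leaves.

    ``rooted=False`` marks the conventional degree-three root of an
    unrooted binary tree; ``rooted=True`` marks a genuinely rooted tree
    (e.g. after outgroup rooting) whose root has degree two.
    """

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted

    # -- basic accessors -------------------------------------------------
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), self.rooted)

    def n_leaves(self) -> int:
        return len(self.root.leaves())

    # -- bipartitions ----------------------------------------------------
    def splits(self, nontrivial_only: bool = True) -> frozenset:
        """Canonical set of bipartitions (each a frozenset of two frozensets)."""
        all_leaves = frozenset(self.leaf_labels())
        out = set()

        def clade(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(clade(c) for c in node.children))
            if node is not self.root:
                other = all_leaves - below
                if not nontrivial_only or (len(below) >= 2 and len(other) >= 2):
                    out.add(frozenset([below, other]))
            return below

        clade(self.root)
        return frozenset(out)

    def topology_key(self) -> frozenset:
        """Hashable identifier of the unrooted topology."""
        return self.splits(nontrivial_only=True)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return (frozenset(self.leaf_labels()) == frozenset(other.leaf_labels())
                and self.topology_key() == other.topology_key())

    def __hash__(self) -> int:
        return hash((frozenset(self.leaf_labels()), self.topology_key()))


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy; writing is a plain formatter)
# ---------------------------------------------------------------------------

def from_newick(newick: str) -> PhyloTree:
    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)

    def convert(dnode) -> Node:
        label = None
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.children.append(convert(child))
        return node

    root = convert(dtree.seed_node)
    return PhyloTree(root, rooted=(len(root.children) == 2))


def to_newick(tree: PhyloTree | Node, lengths: bool = True,
              support: Optional[dict] = None, precision: int = 6) -> str:
    """Serialize to Newick. ``support`` maps canonical splits to labels."""
    root = tree.root if isinstance(tree, PhyloTree) else tree
    all_leaves = frozenset(n.label for n in root.leaves())

    def fmt(node: Node) -> str:
        if node.is_leaf:
            body = node.label or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            body = f"({inner})"
            if support is not None and node is not root:
                below = frozenset(n.label for n in node.leaves())
                key = frozenset([below, all_leaves - below])
                if key in support:
                    body += str(support[key])
        if lengths and node.length is not None:
            body += f":{node.length:.{precision}g}"
        return body

    return fmt(root) + ";"


# ---------------------------------------------------------------------------
# Topology generation
# ---------------------------------------------------------------------------

def _attach_on_edge(root: Node, parent: Node, child_idx: int, leaf: Node) -> None:
    """Split edge (parent -> parent.children[child_idx]) with a new node."""
    old = parent.children[child_idx]
    mid = Node(children=[old, leaf])
    if old.length is not None:
        mid.length = old.length / 2.0
        old.length = old.length / 2.0
    parent.children[child_idx] = mid


def _edge_list(root: Node) -> list[tuple[Node, int]]:
    edges = []
    for node in root.walk():
        for i in range(len(node.children)):
            edges.append((node, i))
    return edges


def star3(labels: Sequence[str]) -> PhyloTree:
    """The unique unrooted topology for three leaves."""
    return PhyloTree(Node(children=[Node(label=l) for l in labels]))


def all_topologies(labels: Sequence[str]) -> Iterator[PhyloTree]:
    """Enumerate all (2n-5)!! unrooted binary topologies by leaf insertion."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")

    def expand(root: Node, remaining: list[str]) -> Iterator[Node]:
        if not remaining:
            yield root
            return
        label, rest = remaining[0], remaining[1:]
        for edge_idx in range(len(_edge_list(root))):
            new_root = root.copy()
            parent, cidx = _edge_list(new_root)[edge_idx]
            _attach_on_edge(new_root, parent, cidx, Node(label=label))
            yield from expand(new_root, rest)

    base = star3(labels[:3]).root
    for topo in expand(base, labels[3:]):
        yield PhyloTree(topo)


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! for n >= 3."""
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


def random_topology(labels: Sequence[str], rng: np.random.Generator,
                    branch_lengths: Optional[tuple[float, float]] = None) -> PhyloTree:
    """Random unrooted binary topology via sequential random edge insertion."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    root = star3(labels[:3]).root
    for label in labels[3:]:
        edges = _edge_list(root)
        parent, cidx = edges[int(rng.integers(len(edges)))]
        _attach_on_edge(root, parent, cidx, Node(label=label))
    tree = PhyloTree(root)
    if branch_lengths is not None:
        lo, hi = branch_lengths
        for node in root.walk():
            if node is not root:
                node.length = float(rng.uniform(lo, hi))
    return tree


# ---------------------------------------------------------------------------
# Rerooting
# ---------------------------------------------------------------------------

def root_on_leaf_edge(tree: PhyloTree, leaf_label: str) -> PhyloTree:
    """Root the (unrooted) tree on the pendant edge of ``leaf_label``.

    Returns a rooted binary tree whose root has two children: the named
    leaf and the rest of the tree. Branch lengths are preserved; the
    pendant edge's length is carried entirely by the leaf child.
    """
    adjacency: dict[int, list[tuple[int, Optional[float]]]] = {}
    nodes: dict[int, Node] = {}

    def index(node: Node, parent: Optional[Node]) -> None:
        nodes[id(node)] = node
        adjacency.setdefault(id(node), [])
        if parent is not None:
            adjacency[id(parent)].append((id(node), node.length))
            adjacency[id(node)].append((id(parent), node.length))
        for c in node.children:
            index(c, node)

    index(tree.root, None)
    target = next((n for n in nodes.values()
                   if n.is_leaf and n.label == leaf_label), None)
    if target is None:
        raise ValueError(f"leaf {leaf_label!r} not in tree")

    def build(nid: int, avoid: int, length: Optional[float]) -> Node:
        src = nodes[nid]
        children = [build(cid, nid, clen) for cid, clen in adjacency[nid]
                    if cid != avoid]
        if not children:
            return Node(label=src.label, length=length)
        if len(children) == 1:
            # suppress the degree-2 node left by removing the old root
            child = children[0]
            child.length = ((child.length or 0.0) + (length or 0.0)) or length
            return child
        return Node(label=src.label, length=length, children=children)

    tid = id(target)
    (other_id, pend_len), = [e for e in adjacency[tid]]
    leaf_child = Node(label=leaf_label, length=pend_len)
    rest = build(other_id, tid, None)
    return PhyloTree(Node(children=[leaf_child, rest]), rooted=True)


def root_on_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    if outgroup not in tree.leaf_labels():
        raise ValueError(f"outgroup {outgroup!r} absent from tree")
    return root_on_leaf_edge(tree, outgroup)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def tree_from_splits(splits: frozenset, leaf_labels: Sequence[str]) -> PhyloTree:
    """Build the (possibly multifurcating) tree displaying exactly ``splits``.

    Splits must be mutually compatible (e.g. the intersection of the split
    sets of several trees over one leaf set).
    """
    labels = sorted(leaf_labels)
    anchor = labels[0]
    # each split contributes the side not containing the anchor as a clade
    clades = []
    for split in splits:
        side_a, side_b = tuple(split)
        clades.append(side_b if anchor in side_a else side_a)
    clades.sort(key=len, reverse=True)

    top = frozenset(labels) - {anchor}
    rest = Node()
    root = Node(children=[Node(label=anchor), rest])
    owner: dict[frozenset, Node] = {top: rest}
    ordered = [top] + clades
    for clade in clades:
        owner[clade] = Node()
    # attach clade nodes, then leaves, under their minimal enclosing clade
    for clade in clades:
        parent = min((c for c in ordered if c != clade and clade <= c), key=len)
        owner[parent].children.append(owner[clade])
    for label in labels[1:]:
        parent = min((c for c in ordered if label in c), key=len)
        owner[parent].children.append(Node(label=label))
    return PhyloTree(root)


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the bipartitions shared by all inputs."""
    if not trees:
        raise ValueError("empty tree set")
    leafsets = {frozenset(t.leaf_labels()) for t in trees}
    if len(leafsets) != 1:
        raise ValueError("trees have different leaf sets")
    shared = trees[0].splits()
    for t in trees[1:]:
        shared = shared & t.splits()
    return tree_from_splits(shared, sorted(leafsets.pop()))
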