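"""Rooted phylogenetic trees with per-branch mutation annotations.

A :class:`PhyloTree` is a rooted tree (polytomies allowed) whose tips are
labeled by sample ids. Each non-root node owns the branch connecting it to
its parent; mutation events assigned to that branch live in ``node.events``
as ``(position, direction)`` pairs where direction is ``"gain"``
(ancestral -> derived) or ``"loss"``. Node ages, when present, are in years
before present (tips at 0), so a branch's duration is
``parent.age - node.age``.

Newick serialization goes through dendropy so that external topologies
(e.g. a maximum-likelihood tree computed elsewhere) can be loaded and
annotated.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import dendropy

from .errors import InputError


class Node:
    __slots__ = ("name", "parent", "children", "age", "events", "support")

    def __init__(self, name: str | None = None, age: float | None = None):
        self.name = name
        self.parent: "Node | None" = None
        self.children: list["Node"] = []
        self.age = age
        self.events: list[tuple[int, str]] = []
        self.support: float | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def branch_years(self) -> float | None:
        if self.parent is None or self.age is None or self.parent.age is None:
            return None
        return self.parent.age - self.age

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.name!r} {kind} events={len(self.events)}>"


class PhyloTree:
    """Rooted tree container with deterministic traversal order."""

    def __init__(self, root: Node):
        self.root = root
        #: positions flagged as recurrent (parsimony score >= 2) by the
        #: branch-assignment step, mapped to their score.
        self.recurrent: dict[int, int] = {}

    # -- traversal ---------------------------------------------------------

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

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    def find(self, name: str) -> Node:
        for n in self.preorder():
            if n.name == name:
                return n
        raise InputError(f"node {name!r} not in tree")

    def tipset(self, node: Node) -> frozenset[str]:
        """Names of tips descending from (and including) ``node``."""
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n.name)
            stack.extend(n.children)
        return frozenset(out)

    def clade_sets(self, supported_only: bool = False) -> set[frozenset[str]]:
        """Tip-sets of all internal non-root nodes; with ``supported_only``
        keep only clades whose stem branch carries >= 1 mutation event."""
        out = set()
        for n in self.preorder():
            if n.is_tip or n.parent is None:
                continue
            if supported_only and not n.events:
                continue
            out.add(self.tipset(n))
        return out

    def name_internal(self, prefix: str = "n") -> None:
        """Assign deterministic preorder names to unnamed internal nodes."""
        i = 0
        for n in self.preorder():
            if not n.is_tip and n.name is None:
                n.name = f"{prefix}{i}"
            if not n.is_tip:
                i += 1

    def clear_events(self) -> None:
        for n in self.preorder():
            n.events = []
        self.recurrent = {}

    def total_events(self) -> int:
        return sum(len(n.events) for n in self.preorder())

    # -- newick ------------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string; branch lengths emitted when node ages are set."""
        def fmt(node: Node) -> str:
            if node.is_tip:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner}){node.name or ''}"
            bl = node.branch_years
            return label if bl is None else f"{label}:{bl:.6f}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True)
        root = cls._from_dendropy_node(dtree.seed_node)
        tree = cls(root)
        for t in tree.tips():
            if not t.name:
                raise InputError("newick tree has an unlabeled tip")
        names = tree.tip_names
        if len(set(names)) != len(names):
            raise InputError("duplicate tip labels in newick tree")
        tree._ages_from_branch_lengths(dtree)
        return tree

    @staticmethod
    def _from_dendropy_node(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon else dnode.label
        node = Node(name=label)
        for child in dnode.child_nodes():
            node.add_child(PhyloTree._from_dendropy_node(child))
        return node

    def _ages_from_branch_lengths(self, dtree: dendropy.Tree) -> None:
        """If every branch has a length, interpret lengths as years and set
        node ages as (max root-to-tip depth) - depth."""
        lengths = [e.length for e in dtree.preorder_edge_iter()
                   if e.head_node is not dtree.seed_node]
        if not lengths or any(l is None for l in lengths):
            return
        depths: dict[Node, float] = {}

        def walk(node: Node, dnode, depth: float) -> None:
            depths[node] = depth
            for c, dc in zip(node.children, dnode.child_nodes()):
                walk(c, dc, depth + (dc.edge.length or 0.0))

        walk(self.root, dtree.seed_node, 0.0)
        height = max(depths.values())
        for node, d in depths.items():
            node.age = height - d


def cherry(tip_a: str, tip_b: str, root_age: float) -> PhyloTree:
    """Two-tip tree with both branches spanning ``root_age`` years."""
    root = Node("root", age=root_age)
    root.add_child(Node(tip_a, age=0.0))
    root.add_child(Node(tip_b, age=0.0))
    return PhyloTree(root)


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path) -> PhyloTree:
    try:
        with open(path) as fh:
            return PhyloTree.from_newick(fh.read())
    except OSError as exc:
        raise InputError(f"cannot read newick file {path}: {exc}") from exc
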