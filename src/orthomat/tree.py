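"""Lightweight unrooted phylogenetic tree container.

Trees are stored as rooted node structures; "unrooted" semantics are
obtained by keeping a trifurcating root and comparing topologies through
bipartitions (splits), which are invariant to root placement.  Branch
lengths are in expected substitutions per site.
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional, Sequence


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: float = 0.0,
        support: Optional[float] = None,
    ):
        self.name = name
        self.length = float(length)
        self.support = support
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length:g}, n_children={len(self.children)})"


class PhyloTree:
    """An (optionally unrooted) phylogeny with branch lengths and supports.

    Invariants: leaf names are unique and non-empty; branch lengths are
    >= 0; an unrooted binary tree over n leaves exposes 2n-3 edges.
    """

    def __init__(self, root: Node):
        self.root = root
        names = [leaf.name for leaf in self.leaves()]
        if any(n is None or n == "" for n in names):
            raise ValueError("every leaf must be named")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")

    # ------------------------------------------------------------------ #
    # traversal
    # ------------------------------------------------------------------ #
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[Node]:
        """Every node below the root owns the edge to its parent."""
        return [n for n in self.postorder() if n is not self.root]

    # ------------------------------------------------------------------ #
    # editing
    # ------------------------------------------------------------------ #
    def copy(self) -> "PhyloTree":
        def _copy(node: Node) -> Node:
            dup = Node(node.name, node.length, node.support)
            for child in node.children:
                dup.add_child(_copy(child))
            return dup

        return PhyloTree(_copy(self.root))

    def unroot(self) -> "PhyloTree":
        """Collapse a bifurcating root in place so the root trifurcates."""
        while len(self.root.children) == 2 and not all(
            c.is_leaf for c in self.root.children
        ):
            a, b = self.root.children
            donor = a if not a.is_leaf else b
            keeper = b if donor is a else a
            keeper.length += donor.length
            self.root.children = [keeper] + donor.children
            for c in donor.children:
                c.parent = self.root
            keeper.parent = self.root
        return self

    def prune_to(self, keep: Sequence[str]) -> "PhyloTree":
        """Return a copy restricted to ``keep``, suppressing unifurcations."""
        keep_set = set(keep)
        missing = keep_set - set(self.leaf_names())
        if missing:
            raise ValueError(f"taxa not in tree: {sorted(missing)}")

        def _prune(node: Node) -> Optional[Node]:
            if node.is_leaf:
                if node.name in keep_set:
                    return Node(node.name, node.length, node.support)
                return None
            kept = [c for c in (_prune(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                kept[0].length += node.length
                return kept[0]
            dup = Node(node.name, node.length, node.support)
            for c in kept:
                dup.add_child(c)
            return dup

        new_root = _prune(self.root)
        if new_root is None:
            raise ValueError("pruning removed every leaf")
        tree = PhyloTree(new_root)
        tree.root.length = 0.0
        return tree.unroot()

    # ------------------------------------------------------------------ #
    # topology comparison
    # ------------------------------------------------------------------ #
    def bipartitions(self, nontrivial_only: bool = True) -> set[frozenset[str]]:
        """Splits of the unrooted topology, each given as its canonical side.

        The canonical side of a split is the one NOT containing the
        lexicographically smallest leaf, so the representation is root- and
        orientation-invariant.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()
        below: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.name])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
            if node is self.root:
                continue
            side = below[node]
            if anchor in side:
                side = all_leaves - side
            if nontrivial_only and (len(side) < 2 or len(side) > len(all_leaves) - 2):
                continue
            splits.add(side)
        return splits

    def has_clade(self, ingroup: Sequence[str]) -> bool:
        """True iff ``ingroup`` is monophyletic on the unrooted topology."""
        all_leaves = frozenset(self.leaf_names())
        group = frozenset(ingroup)
        if not group <= all_leaves:
            raise ValueError(f"ingroup not a subset of leaves: {sorted(group - all_leaves)}")
        if len(group) <= 1 or len(group) >= len(all_leaves) - 1:
            return True  # trivial splits always exist on an unrooted tree
        anchor = min(all_leaves)
        canonical = group if anchor not in group else all_leaves - group
        return canonical in self.bipartitions(nontrivial_only=False)

    def symmetric_difference(self, other: "PhyloTree") -> int:
        """Robinson-Foulds distance (number of splits in exactly one tree)."""
        a, b = self.bipartitions(), other.bipartitions()
        return len(a ^ b)

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #
    def newick(self, precision: int = 6, include_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = ""
                if include_support and node.support is not None:
                    label = (
                        f"{node.support:g}"
                        if isinstance(node.support, float)
                        else str(node.support)
                    )
                body = f"({inner}){label}"
            if node is self.root:
                return body
            return f"{body}:{node.length:.{precision}f}"

        return fmt(self.root) + ";"

    def total_length(self) -> float:
        return sum(n.length for n in self.edges())

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({len(self.leaves())} leaves)"


def random_binary_tree(
    names: Sequence[str],
    rng,
    length_sampler: Optional[Callable[[], float]] = None,
) -> PhyloTree:
    """A uniformly assembled unrooted binary topology over ``names``.

    Built by sequential random attachment of each leaf onto a random edge;
    branch lengths drawn from ``length_sampler`` (default: Exp(0.1 mean)).
    """
    if len(names) < 2:
        raise ValueError("need at least two leaf names")
    draw = length_sampler or (lambda: float(rng.exponential(0.1)) + 1e-3)
    names = list(names)
    root = Node()
    for name in names[:3]:
        root.add_child(Node(name, draw()))
    if len(names) == 2:
        return PhyloTree(root)
    tree = PhyloTree(root)
    for name in names[3:]:
        edges = tree.edges()
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        mid = Node(length=draw())
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add_child(target)
        mid.add_child(Node(name, draw()))
    return tree
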