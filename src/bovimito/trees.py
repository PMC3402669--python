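"""Rooted trees with branch lengths, labels and optional node ages.

The internal representation is a plain node structure optimised for the
likelihood engine; newick text is parsed through dendropy and converted, so
any newick flavour dendropy accepts is accepted here.  Branch identifiers are
stable: a leaf branch is named after its leaf, an internal branch after the
sorted '+'-joined leaf set below it — independent of input rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import dendropy


@dataclass(eq=False)
class Node:
    label: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None
    age: float | None = None          # years before present
    support: float | None = None      # aLRT support on the branch above
    mutation_count: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class RootedTree:
    """Topology + branch lengths; the root's own ``length`` is ignored."""

    def __init__(self, root: Node):
        self.root = root
        labels = [leaf.label for leaf in self.leaves()]
        if None in labels:
            raise ValueError("every leaf must be labelled")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        dt = dendropy.Tree.get(data=text, schema="newick",
                               preserve_underscores=True)

        def convert(dnode) -> Node:
            n = Node(
                label=(dnode.taxon.label if dnode.taxon is not None
                       else dnode.label),
                length=float(dnode.edge.length or 0.0),
            )
            for c in dnode.child_nodes():
                n.add(convert(c))
            return n

        return cls(convert(dt.seed_node))

    def to_newick(self, lengths: bool = True, supports: bool = False,
                  ages: bool = False, precision: int = 6) -> str:
        """Serialize; optional internal-node labels carry aLRT supports or
        node ages (years) for dated trees."""
        def fmt(n: Node) -> str:
            if n.is_leaf:
                core = n.label or ""
            else:
                inner = ",".join(fmt(c) for c in n.children)
                lab = ""
                if ages and n.age is not None:
                    lab = f"{n.age:.6g}"
                elif supports and n.support is not None:
                    lab = f"{n.support:.4f}"
                elif n.label:
                    lab = n.label
                core = f"({inner}){lab}"
            if lengths and n.parent is not None:
                core += f":{n.length:.{precision}g}"
            return core

        return fmt(self.root) + ";"

    def copy(self) -> "RootedTree":
        def dup(n: Node) -> Node:
            m = Node(label=n.label, length=n.length, age=n.age,
                     support=n.support, mutation_count=n.mutation_count)
            for c in n.children:
                m.add(dup(c))
            return m

        return RootedTree(dup(self.root))

    # -- traversal ----------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        def walk(n: Node) -> Iterator[Node]:
            for c in n.children:
                yield from walk(c)
            yield n

        return walk(self.root)

    def preorder(self) -> Iterator[Node]:
        def walk(n: Node) -> Iterator[Node]:
            yield n
            for c in n.children:
                yield from walk(c)

        return walk(self.root)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]  # type: ignore[misc]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        return [n for n in self.postorder()
                if not n.is_leaf and (include_root or n is not self.root)]

    def clade_leaves(self, node: Node) -> frozenset[str]:
        return frozenset(l.label for l in _subtree_leaves(node))  # type: ignore

    def branch_id(self, node: Node) -> str:
        """Stable branch identifier for the edge above ``node``."""
        if node.is_leaf:
            return node.label  # type: ignore[return-value]
        return "+".join(sorted(self.clade_leaves(node)))

    def find_leaf(self, label: str) -> Node:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(f"leaf {label!r} not in tree")

    def mrca(self, labels: set[str] | frozenset[str]) -> Node:
        want = frozenset(labels)
        missing = want - self.clade_leaves(self.root)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        best = self.root
        improved = True
        while improved:
            improved = False
            for c in best.children:
                if want <= self.clade_leaves(c):
                    best = c
                    improved = True
                    break
        return best

    # -- metrics ------------------------------------------------------------

    def depths_to_tips(self, node: Node) -> list[float]:
        """Path lengths from ``node`` down to each descendant tip."""
        out: list[float] = []

        def walk(n: Node, acc: float) -> None:
            if n.is_leaf:
                out.append(acc)
            for c in n.children:
                walk(c, acc + c.length)

        walk(node, 0.0)
        return out

    def path_length(self, a: str, b: str) -> float:
        na, nb = self.find_leaf(a), self.find_leaf(b)
        anc_a = {}
        d = 0.0
        n: Node | None = na
        while n is not None:
            anc_a[id(n)] = d
            d += n.length
            n = n.parent
        d = 0.0
        n = nb
        while n is not None:
            if id(n) in anc_a:
                return d + anc_a[id(n)]
            d += n.length
            n = n.parent
        raise RuntimeError("disconnected tree")

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = self.depths_to_tips(self.root)
        return max(depths) - min(depths) <= tol * max(1.0, max(depths))


def _subtree_leaves(node: Node) -> list[Node]:
    if node.is_leaf:
        return [node]
    out: list[Node] = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out
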