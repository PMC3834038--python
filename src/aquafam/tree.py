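"""Phylogenetic tree container with Newick round-trip and bipartition tools.

The neighbor-joining builder emits an unrooted tree stored with a single
trifurcating root; bootstrap supports are integer replicate counts
attached to internal nodes.  Newick serialization is our own (supports
become internal node labels); parsing is delegated to scikit-bio and the
result converted back into this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def walk(self) -> Iterator["TreeNode"]:
        """Pre-order traversal."""
        yield self
        for c in self.children:
            yield from c.walk()


class PhyloTree:
    """An (optionally supported) tree over uniquely labeled leaves."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise ValueError("leaf labels must be unique")

    # -- basic queries ------------------------------------------------------

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name or "" for n in self.leaves()]

    def find_leaf(self, name: str) -> TreeNode:
        for n in self.leaves():
            if n.name == name:
                return n
        raise KeyError(f"leaf {name!r} not in tree")

    # -- bipartitions -------------------------------------------------------

    def bipartitions(self, nontrivial: bool = True) -> set[frozenset[str]]:
        """Edge-induced leaf bipartitions, each as its smaller/canonical side.

        Each edge splits the leaves into the clade below it and the rest;
        the side not containing the alphabetically first leaf is used as
        the canonical representative so the set is rooting-invariant.
        With ``nontrivial`` only splits with >= 2 leaves on both sides are
        returned (the ones that define topology).
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        parts: set[frozenset[str]] = set()
        for node in self.root.walk():
            if node is self.root:
                continue
            below = frozenset(n.name for n in node.walk() if n.is_leaf)
            side = below if anchor not in below else all_leaves - below
            if nontrivial and (len(side) < 2 or len(all_leaves - side) < 2):
                continue
            parts.add(side)
        return parts

    def clades(self) -> list[frozenset[str]]:
        """Both sides of every edge-induced bipartition (trivial included)."""
        all_leaves = frozenset(self.leaf_names())
        out: list[frozenset[str]] = []
        for node in self.root.walk():
            if node is self.root:
                continue
            below = frozenset(n.name for n in node.walk() if n.is_leaf)
            out.append(below)
            out.append(all_leaves - below)
        return out

    def robinson_foulds(self, other: "PhyloTree") -> int:
        """Symmetric-difference distance over nontrivial bipartitions."""
        if set(self.leaf_names()) != set(other.leaf_names()):
            raise ValueError("trees must share a leaf set")
        a, b = self.bipartitions(), other.bipartitions()
        return len(a ^ b)

    # -- patristic distances ------------------------------------------------

    def patristic_distance(self, a: str, b: str) -> float:
        na, nb = self.find_leaf(a), self.find_leaf(b)

        def path_to_root(n: TreeNode) -> list[TreeNode]:
            out = [n]
            while n.parent is not None:
                n = n.parent
                out.append(n)
            return out

        pa, pb = path_to_root(na), path_to_root(nb)
        ancestors = {id(n): i for i, n in enumerate(pa)}
        for j, n in enumerate(pb):
            if id(n) in ancestors:
                i = ancestors[id(n)]
                d = sum(x.length or 0.0 for x in pa[:i])
                d += sum(x.length or 0.0 for x in pb[:j])
                return d
        raise RuntimeError("disconnected tree")

    # -- Newick -------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner})"
                if node.support is not None:
                    label += str(node.support)
            if node.length is not None:
                label += f":{node.length:g}"
            return label

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        import io

        import skbio

        sk = skbio.TreeNode.read(io.StringIO(text))

        def convert(n) -> TreeNode:
            node = TreeNode(
                name=n.name if n.is_tip() else None,
                length=float(n.length) if n.length is not None else None,
            )
            if not n.is_tip() and n.name not in (None, ""):
                try:
                    node.support = int(float(n.name))
                except ValueError:
                    node.name = n.name
            for c in n.children:
                node.add(convert(c))
            return node

        return cls(convert(sk))
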