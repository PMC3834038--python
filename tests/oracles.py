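"""Independent oracles used by the test suite.

These deliberately avoid the implementation's code paths: alignment
scores come from explicit enumeration of every monotone alignment, and
tree fits from exhaustive topology search with ordinary least squares.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from aquafam.align import ScoringParams
from aquafam.tree import PhyloTree, TreeNode


def score_alignment(row_a: str, row_b: str, params: ScoringParams) -> float:
    """Score a finished alignment: affine gaps cost open + (L-1)*extend."""
    total = 0.0
    gap_a = gap_b = False
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            raise ValueError("double-gap column")
        if x == "-":
            total -= params.gap_extend if gap_a else params.gap_open
            gap_a, gap_b = True, False
        elif y == "-":
            total -= params.gap_extend if gap_b else params.gap_open
            gap_a, gap_b = False, True
        else:
            total += params.score(x, y)
            gap_a = gap_b = False
    return total


def enumerate_alignments(a: str, b: str):
    """Yield every monotone global alignment of a and b as row pairs."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def brute_force_best_score(a: str, b: str, params: ScoringParams) -> float:
    return max(score_alignment(ra, rb, params)
               for ra, rb in enumerate_alignments(a, b))


# ---------------------------------------------------------------------------
# exhaustive topology search


def all_unrooted_topologies(labels: list[str]) -> list[PhyloTree]:
    """All (2n-5)!! unrooted binary topologies, by sequential edge insertion."""

    def clone(node: TreeNode) -> TreeNode:
        c = TreeNode(name=node.name, length=node.length)
        for ch in node.children:
            c.add(clone(ch))
        return c

    base = TreeNode()
    for lb in labels[:3]:
        base.add(TreeNode(name=lb, length=1.0))
    trees = [base]
    for lb in labels[3:]:
        nxt = []
        for t in trees:
            edges = [n for n in t.walk() if n is not t]
            for k in range(len(edges)):
                c = clone(t)
                target = [n for n in c.walk() if n is not c][k]
                parent = target.parent
                mid = TreeNode(length=1.0)
                parent.children[parent.children.index(target)] = mid
                mid.parent = parent
                mid.add(target)
                mid.add(TreeNode(name=lb, length=1.0))
                nxt.append(c)
        trees = nxt
    return [PhyloTree(t) for t in trees]


def _edge_path_matrix(tree: PhyloTree, labels: list[str]) -> np.ndarray:
    """Design matrix: pairs x edges, 1 where the edge lies on the leaf path."""
    edges = [n for n in tree.root.walk() if n is not tree.root]
    below = []
    for e in edges:
        below.append(frozenset(x.name for x in e.walk() if x.is_leaf))
    pairs = list(combinations(labels, 2))
    X = np.zeros((len(pairs), len(edges)))
    for r, (a, b) in enumerate(pairs):
        for c, bl in enumerate(below):
            if (a in bl) != (b in bl):
                X[r, c] = 1.0
    return X


def least_squares_topology(dm_labels: list[str], d: np.ndarray) -> PhyloTree:
    """The topology minimizing OLS fit of path lengths to the distances."""
    pairs = list(combinations(range(len(dm_labels)), 2))
    y = np.array([d[i, j] for i, j in pairs])
    best = None
    for tree in all_unrooted_topologies(list(dm_labels)):
        X = _edge_path_matrix(tree, list(dm_labels))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((X @ beta - y) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, tree)
    return best[1]
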