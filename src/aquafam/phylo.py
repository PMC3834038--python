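"""Neighbor-joining trees, bootstrap support, and clade-based family calls.

NJ follows the Saitou-Nei agglomeration on the Q criterion with the
standard two-point branch-length formulas; it is exact on additive
matrices.  Determinism is pinned down everywhere: Q ties are broken by
the lexicographically smallest pair of cluster representative labels,
negative branch lengths are clamped to zero with the deficit shifted to
the sibling edge, and column resampling for the bootstrap uses a seeded
generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .align import Alignment, DistanceMatrix, distance_matrix_from_msa
from .tree import PhyloTree, TreeNode

_TIE = 1e-12


@dataclass(frozen=True)
class SubfamilyAssignment:
    query: str
    subfamily: str
    subgroup: str | None
    method: Literal["monophyletic_clade", "nearest_reference"]
    support: int | None = None

    def __post_init__(self) -> None:
        if self.subgroup is not None and not self.subgroup.startswith(self.subfamily):
            raise ValueError(
                f"subgroup {self.subgroup!r} inconsistent with subfamily {self.subfamily!r}"
            )


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; returns an unrooted tree stored with
    one trifurcating root.

    Branch lengths come from the two-point formulas; a negative length is
    clamped to 0 and its deficit moved to the sibling edge so the joined
    pair keeps its pairwise distance.
    """
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=lb) for lb in labels]
    reps: list[str] = list(labels)  # min leaf label per cluster, for tie-breaks
    D = dm.d.copy()
    active = list(range(len(labels)))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = []
        for i, j in np.argwhere(Q <= qmin + _TIE):
            if i < j:
                key = tuple(sorted((reps[active[i]], reps[active[j]])))
                cands.append((key, int(i), int(j)))
        _, i, j = min(cands)
        dij = sub[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ni, nj_ = nodes[active[i]], nodes[active[j]]
        ni.length, nj_.length = float(li), float(lj)
        parent = TreeNode()
        parent.add(ni)
        parent.add(nj_)
        # distances from the new node to every other active cluster
        new_d = np.zeros(D.shape[0] + 1)
        for t, idx in enumerate(active):
            if t in (i, j):
                continue
            new_d[idx] = (sub[i, t] + sub[j, t] - dij) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_d[:-1]
        D[:-1, -1] = new_d[:-1]
        nodes.append(parent)
        reps.append(min(reps[active[i]], reps[active[j]]))
        hi, lo = max(i, j), min(i, j)
        active.pop(hi)
        active.pop(lo)
        active.append(len(nodes) - 1)

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    root = TreeNode()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = float(max(ln, 0.0))
        root.add(nodes[idx])
    return PhyloTree(root)


def bootstrap_support(msa: Alignment, n: int = 1000, seed: int = 0,
                      correction: str = "p") -> PhyloTree:
    """NJ tree from ``msa`` with integer bootstrap supports on internal edges.

    Columns are resampled with replacement ``n`` times; each internal
    edge's support is the number of replicates whose NJ tree contains the
    same leaf bipartition.  Fully deterministic for a fixed seed.  For
    the degenerate all-identical alignment every resolution is arbitrary,
    so supports are pinned to 0.
    """
    base_dm = distance_matrix_from_msa(msa, correction=correction)
    tree = nj_tree(base_dm)
    degenerate = bool(np.all(base_dm.d == 0))

    enc = msa.to_int_matrix()
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    nseq = enc.shape[0]
    labels = list(msa.ids)
    for _ in range(n):
        cols = rng.integers(0, enc.shape[1], size=enc.shape[1])
        sub = enc[:, cols]
        d = np.zeros((nseq, nseq))
        for i in range(nseq):
            both = (sub[i] >= 0) & (sub[i + 1:] >= 0)
            shared = both.sum(axis=1)
            mism = ((sub[i] != sub[i + 1:]) & both).sum(axis=1)
            with np.errstate(invalid="ignore"):
                p = np.where(shared > 0, mism / np.maximum(shared, 1), 1.0)
            if correction == "poisson":
                p = -np.log(np.clip(1.0 - p, 1e-12, None))
            d[i, i + 1:] = p
            d[i + 1:, i] = p
        rep = nj_tree(DistanceMatrix(labels=labels, d=d))
        for part in rep.bipartitions():
            counts[part] = counts.get(part, 0) + 1

    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    for node in tree.root.walk():
        if node.is_leaf or node is tree.root:
            continue
        below = frozenset(x.name for x in node.walk() if x.is_leaf)
        side = below if anchor not in below else all_leaves - below
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        node.support = 0 if degenerate else counts.get(side, 0)
    return tree


def assign_subfamily(
    tree: PhyloTree,
    reference_labels: Mapping[str, tuple[str, str | None]],
    query: str,
) -> SubfamilyAssignment:
    """Classify one query leaf against labeled reference leaves.

    The smallest edge-induced clade containing the query and at least one
    reference, with all contained references from a single subfamily,
    decides the call (method ``monophyletic_clade``).  If no such clade
    exists the nearest reference by patristic distance decides (method
    ``nearest_reference``).  The subgroup is then resolved the same way
    among the assigned subfamily's references only.
    """
    leaves = set(tree.leaf_names())
    if query not in leaves:
        raise KeyError(f"query {query!r} not in tree")
    refs = {r: lab for r, lab in reference_labels.items() if r in leaves}
    if not refs:
        raise ValueError("no reference leaves present in tree")

    def smallest_pure_clade(label_of: Mapping[str, str]) -> tuple[str, frozenset[str], int | None] | None:
        """Smallest edge side holding query + >=1 labeled leaf, all one label."""
        all_leaves = frozenset(tree.leaf_names())
        best: tuple[int, tuple[str, ...], str, frozenset[str], int | None] | None = None
        for node in tree.root.walk():
            if node is tree.root:
                continue
            below = frozenset(x.name for x in node.walk() if x.is_leaf)
            for side in (below, all_leaves - below):
                if query not in side:
                    continue
                found = {label_of[r] for r in side if r in label_of}
                if len(found) != 1:
                    continue
                key = (len(side), tuple(sorted(side)))
                if best is None or key < best[:2]:
                    best = (*key, next(iter(found)), side, node.support)
        if best is None:
            return None
        return best[2], best[3], best[4]

    fam_of = {r: lab[0] for r, lab in refs.items()}
    hit = smallest_pure_clade(fam_of)
    if hit is not None:
        subfamily, _, support = hit
        method: str = "monophyletic_clade"
    else:
        nearest = min(
            (tree.patristic_distance(query, r), r) for r in sorted(refs)
        )[1]
        subfamily, support, method = fam_of[nearest], None, "nearest_reference"

    sub_of = {
        r: lab[1]
        for r, lab in refs.items()
        if lab[0] == subfamily and lab[1] is not None
    }
    subgroup: str | None = None
    if sub_of:
        sub_hit = smallest_pure_clade(sub_of)
        if sub_hit is not None:
            subgroup = sub_hit[0]
        else:
            nearest = min(
                (tree.patristic_distance(query, r), r) for r in sorted(sub_of)
            )[1]
            subgroup = sub_of[nearest]
    return SubfamilyAssignment(
        query=query, subfamily=subfamily, subgroup=subgroup,
        method=method, support=support,
    )
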