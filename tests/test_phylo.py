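from __future__ import annotations

import numpy as np
import pytest

from aquafam.align import Alignment, DistanceMatrix
from aquafam.phylo import assign_subfamily, bootstrap_support, nj_tree
from aquafam.synth import make_additive_matrix, random_additive_tree
from aquafam.tree import PhyloTree, TreeNode

from oracles import least_squares_topology


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = nj_tree(DistanceMatrix(labels=["A", "B", "C"], d=d))
        # branch lengths solve the three-point system exactly
        assert tree.patristic_distance("A", "B") == pytest.approx(3.0)
        assert tree.patristic_distance("A", "C") == pytest.approx(4.0)
        assert tree.patristic_distance("B", "C") == pytest.approx(5.0)
        assert len(tree.root.children) == 3

    def test_four_taxon_additive_exact(self):
        """NJ recovers both topology and branch lengths of the generating
        tree for an additive matrix."""
        gen = random_additive_tree(4, seed=3)
        dm = make_additive_matrix(gen)
        rec = nj_tree(dm)
        assert rec.robinson_foulds(gen) == 0
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1:]:
                assert rec.patristic_distance(a, b) == pytest.approx(
                    gen.patristic_distance(a, b))

    @pytest.mark.parametrize("seed", range(8))
    def test_six_taxon_matches_least_squares_search(self, seed):
        """On additive 6-taxon matrices the NJ topology equals the OLS
        minimizer over all 105 unrooted topologies."""
        dm = make_additive_matrix(6, seed=seed)
        rec = nj_tree(dm)
        best = least_squares_topology(dm.labels, dm.d)
        assert rec.robinson_foulds(best) == 0

    def test_label_permutation_invariance(self):
        dm = make_additive_matrix(6, seed=11)
        tree = nj_tree(dm)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(dm.labels))
        dm2 = DistanceMatrix(labels=[dm.labels[i] for i in perm],
                             d=dm.d[np.ix_(perm, perm)])
        tree2 = nj_tree(dm2)
        assert tree.robinson_foulds(tree2) == 0

    def test_negative_lengths_clamped(self):
        # a strongly non-additive matrix that drives a two-point formula negative
        d = np.array([
            [0.0, 0.1, 4.0, 4.0],
            [0.1, 0.0, 0.2, 4.0],
            [4.0, 0.2, 0.0, 0.1],
            [4.0, 4.0, 0.1, 0.0],
        ])
        tree = nj_tree(DistanceMatrix(labels=list("ABCD"), d=d))
        lengths = [n.length for n in tree.root.walk() if n.length is not None]
        assert all(ln >= 0 for ln in lengths)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=list("ABC"), d=d)

    def test_agrees_with_skbio_on_generic_matrix(self):
        """Independent cross-check against scikit-bio's NJ on a random
        distance matrix without ties."""
        import skbio

        rng = np.random.default_rng(5)
        n = 7
        m = rng.uniform(0.2, 1.0, size=(n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"T{i}" for i in range(n)]
        ours = nj_tree(DistanceMatrix(labels=labels, d=d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        their_parts = set()
        all_leaves = frozenset(labels)
        anchor = min(labels)
        for node in theirs.traverse(include_self=False):
            below = frozenset(t.name for t in node.tips()) if not node.is_tip() \
                else frozenset([node.name])
            side = below if anchor not in below else all_leaves - below
            if 2 <= len(side) <= len(all_leaves) - 2:
                their_parts.add(side)
        assert ours.bipartitions() == their_parts


class TestBootstrap:
    def _msa_two_clades(self) -> Alignment:
        rows = {
            "A1": "AAAAAAAAAACCCCCCCCCC",
            "A2": "AAAAAAAAAACCCCCCCCCG",
            "A3": "AAAAAAAAAGCCCCCCCCCC",
            "B1": "WWWWWWWWWWHHHHHHHHHH",
            "B2": "WWWWWWWWWWHHHHHHHHHY",
            "B3": "WWWWWWWWWYHHHHHHHHHH",
        }
        return Alignment(ids=list(rows), rows=list(rows.values()))

    def test_clade_separating_edge_strongly_supported(self):
        tree = bootstrap_support(self._msa_two_clades(), n=100, seed=0)
        parts = {}
        all_leaves = frozenset(tree.leaf_names())
        anchor = min(all_leaves)
        for node in tree.root.walk():
            if node.is_leaf or node is tree.root or node.support is None:
                continue
            below = frozenset(x.name for x in node.walk() if x.is_leaf)
            side = below if anchor not in below else all_leaves - below
            parts[side] = node.support
        split = frozenset({"B1", "B2", "B3"})
        assert parts[split] >= 95

    def test_supports_bounded_by_replicates(self):
        tree = bootstrap_support(self._msa_two_clades(), n=40, seed=1)
        for node in tree.root.walk():
            if node.support is not None:
                assert 0 <= node.support <= 40

    def test_same_seed_reproduces_supports(self):
        t1 = bootstrap_support(self._msa_two_clades(), n=50, seed=9)
        t2 = bootstrap_support(self._msa_two_clades(), n=50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_degenerate_identical_sequences_pinned_to_zero_support(self):
        msa = Alignment(ids=["a", "b", "c", "d"], rows=["MNPA"] * 4)
        tree = bootstrap_support(msa, n=10, seed=0)
        supports = [n.support for n in tree.root.walk() if n.support is not None]
        assert all(s == 0 for s in supports)
        lengths = [n.length for n in tree.root.walk() if n.length is not None]
        assert all(ln == 0 for ln in lengths)


class TestAssignSubfamily:
    def _tree_with_graft(self) -> PhyloTree:
        """Query grafted at zero distance onto a PIP2 reference."""
        graft = TreeNode(length=0.5)
        graft.add(TreeNode(name="query", length=0.0))
        graft.add(TreeNode(name="REF_PIP2", length=0.0))
        pip = TreeNode(length=0.5)
        pip.add(graft)
        pip.add(TreeNode(name="REF_PIP1", length=0.3))
        root = TreeNode()
        root.add(pip)
        root.add(TreeNode(name="REF_TIP1", length=1.0))
        root.add(TreeNode(name="REF_SIP1", length=1.0))
        return PhyloTree(root)

    REFS = {
        "REF_PIP1": ("PIP", "PIP1"),
        "REF_PIP2": ("PIP", "PIP2"),
        "REF_TIP1": ("TIP", "TIP1"),
        "REF_SIP1": ("SIP", "SIP1"),
    }

    def test_zero_length_graft_gives_subgroup_call(self):
        a = assign_subfamily(self._tree_with_graft(), self.REFS, "query")
        assert a.subfamily == "PIP"
        assert a.subgroup == "PIP2"
        assert a.method == "monophyletic_clade"

    def test_missing_query_errors(self):
        with pytest.raises(KeyError):
            assign_subfamily(self._tree_with_graft(), self.REFS, "ghost")

    def test_leave_one_out_on_synthetic_family(self, family, family_tree):
        """Every member is recovered into its planted subfamily and
        subgroup from the tree alone."""
        _, tree = family_tree
        truth = family.truth
        labels = family.panel.labels
        for entry in truth.values():
            if entry.is_decoy:
                continue
            a = assign_subfamily(tree, labels, entry.id)
            assert a.subfamily == entry.subfamily, entry.id
            assert a.subgroup == entry.subgroup, entry.id
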