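from __future__ import annotations

import numpy as np
import pytest

from aquafam.seqio import (
    AlphabetError,
    DuplicateIdError,
    FamilyReportRow,
    GeneModel,
    ProteinRecord,
    read_fasta,
    read_gff_gene_models,
    read_newick,
    write_fasta,
    write_feature_table,
    write_newick,
)
from aquafam.synth import random_additive_tree
from aquafam.tree import PhyloTree, TreeNode


class TestFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">a\nMNPA\n")
        (rec,) = read_fasta(path, "aa")
        assert rec.id == "a" and rec.sequence == "MNPA" and rec.length_aa == 4

    def test_lowercase_is_uppercased(self, tmp_path):
        path = tmp_path / "lc.fasta"
        path.write_text(">a\nmnpa\n")
        assert read_fasta(path, "aa")[0].sequence == "MNPA"

    def test_duplicate_id_is_hard_error(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nMN\n>a\nPA\n")
        with pytest.raises(DuplicateIdError, match="a"):
            read_fasta(path, "aa")

    def test_gap_characters_rejected_with_position(self, tmp_path):
        path = tmp_path / "gap.fasta"
        path.write_text(">a\nMN-PA\n")
        with pytest.raises(AlphabetError, match="position 3"):
            read_fasta(path, "aa")

    def test_proteome_round_trip(self, tmp_path, family):
        """Writing then re-reading the 247-record proteome loses nothing."""
        path = tmp_path / "proteome.fasta"
        write_fasta(family.proteome, path)
        back = read_fasta(path, "aa")
        assert [(r.id, r.sequence) for r in back] == [
            (r.id, r.sequence) for r in family.proteome
        ]


class TestGeneModel:
    def test_transcription_order_enforced_both_strands(self):
        exons = [(1, 10), (20, 30)]
        GeneModel(locus="p", chrom="c", strand="+", exons=exons)
        GeneModel(locus="m", chrom="c", strand="-", exons=exons[::-1])
        with pytest.raises(ValueError, match="transcription order"):
            GeneModel(locus="m", chrom="c", strand="-", exons=exons)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GeneModel(locus="x", chrom="c", strand="+", exons=[(1, 10), (5, 20)])

    def test_interval_orientation(self):
        with pytest.raises(ValueError, match="start > end"):
            GeneModel(locus="x", chrom="c", strand="+", exons=[(10, 1)])


class TestGff:
    def test_minus_strand_gene_in_transcription_order(self, tmp_path):
        gff = tmp_path / "toy.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\tsrc\tmRNA\t100\t400\t.\t-\t.\tID=m1\n"
            "c1\tsrc\texon\t100\t150\t.\t-\t.\tID=e1;Parent=m1\n"
            "c1\tsrc\texon\t200\t250\t.\t-\t.\tID=e2;Parent=m1\n"
            "c1\tsrc\texon\t300\t400\t.\t-\t.\tID=e3;Parent=m1\n"
        )
        (model,) = read_gff_gene_models(gff)
        assert model.strand == "-"
        assert model.exons == [(300, 400), (200, 250), (100, 150)]

    def test_orphan_exon_warns_and_is_skipped(self, tmp_path):
        gff = tmp_path / "orphan.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\tsrc\tmRNA\t1\t50\t.\t+\t.\tID=m1\n"
            "c1\tsrc\texon\t1\t50\t.\t+\t.\tID=e1;Parent=m1\n"
            "c1\tsrc\texon\t60\t90\t.\t+\t.\tID=e2\n"
        )
        with pytest.warns(UserWarning, match="no Parent"):
            (model,) = read_gff_gene_models(gff)
        assert model.exons == [(1, 50)]

    def test_synthetic_gff_exon_counts_match_planted_truth(self, tmp_path, family):
        from aquafam.synth import _write_gff

        gff = tmp_path / "synth.gff3"
        _write_gff(family.gene_models, gff)
        models = {m.locus: m for m in read_gff_gene_models(gff)}
        for entry in family.truth.values():
            if entry.is_decoy:
                continue
            assert models[entry.locus].n_exons == entry.exon_count
            assert models[entry.locus].chrom == entry.chrom


class TestNewick:
    def test_three_leaf_star(self, tmp_path):
        root = TreeNode()
        for name in "ABC":
            root.add(TreeNode(name=name, length=1.0))
        path = tmp_path / "star.nwk"
        write_newick(PhyloTree(root), path)
        assert path.read_text().strip() == "(A:1,B:1,C:1);"

    def test_supports_serialized_as_internal_labels(self, tmp_path):
        inner = TreeNode(length=0.5, support=998)
        inner.add(TreeNode(name="A", length=1.0))
        inner.add(TreeNode(name="B", length=1.0))
        root = TreeNode()
        root.add(inner)
        root.add(TreeNode(name="C", length=1.0))
        root.add(TreeNode(name="D", length=1.0))
        path = tmp_path / "sup.nwk"
        write_newick(PhyloTree(root), path)
        text = path.read_text()
        assert ")998:" in text
        back = read_newick(path)
        supports = [n.support for n in back.root.walk() if n.support is not None]
        assert supports == [998]

    @pytest.mark.parametrize("seed", range(5))
    def test_ten_leaf_round_trip_preserves_topology(self, tmp_path, seed):
        tree = random_additive_tree(10, seed)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert tree.robinson_foulds(back) == 0


class TestFeatureTable:
    def test_pip_row_renders_filter_letters(self, tmp_path):
        row = FamilyReportRow(
            gene_name="PIP1;1", locus="L1", subfamily="PIP", subgroup="PIP1",
            length_aa=288, n_tmd=6, npa_motifs=("NPA", "NPA"),
            arR=("F", "H", "T", "R"), froger=("M", "S", "A", "F", "W"),
            specificity="water",
        )
        path = tmp_path / "t.tsv"
        write_feature_table([row], path)
        assert "F\tH\tT\tR" in path.read_text()

    def test_truncated_protein_renders_dashes(self, tmp_path):
        row = FamilyReportRow(
            gene_name="NIP4;3", locus="L2", subfamily="NIP", subgroup=None,
            length_aa=138, n_tmd=5, npa_motifs=(None, None),
            arR=("W", None, None, None), froger=None, specificity="ambiguous",
        )
        path = tmp_path / "t.tsv"
        write_feature_table([row], path)
        line = path.read_text().splitlines()[1]
        assert line.split("\t")[8:13] == ["W", "-", "-", "-", "-"]

    def test_empty_rows_give_header_only(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_feature_table([], path)
        assert len(path.read_text().splitlines()) == 1


class TestRecords:
    def test_protein_rejects_empty_and_illegal(self):
        with pytest.raises(ValueError):
            ProteinRecord(id="x", sequence="")
        with pytest.raises(AlphabetError):
            ProteinRecord(id="x", sequence="MB1")

    def test_n_tmd_bounds(self):
        with pytest.raises(ValueError):
            FamilyReportRow(gene_name="g", locus="l", subfamily="PIP",
                            subgroup=None, length_aa=1, n_tmd=9)
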