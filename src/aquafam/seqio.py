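"""Domain types and file I/O for the aquaporin annotation pipeline.

Sequences travel as :class:`ProteinRecord` / :class:`NucleotideRecord`,
gene structure as :class:`GeneModel`, and the two summary reports (the
family feature table and the specificity-residue table) as lists of
:class:`FamilyReportRow`.  FASTA parsing is delegated to Biopython and
GFF3 parsing to :mod:`gffutils`; this module only enforces the pipeline's
invariants (unique ids, restricted alphabets, transcription-ordered
non-overlapping exons) on top of them.

All residue and genomic coordinates are 1-based inclusive throughout the
package, matching both GFF3 and the protein-position conventions used in
the aquaporin literature (e.g. the ar/R filter of human AQP1 written as
F58-H182-C191-R197).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
NT_ALPHABET = set("ACGTN")

Subfamily = Literal["PIP", "TIP", "NIP", "SIP", "XIP"]
SUBFAMILIES: tuple[str, ...] = ("PIP", "TIP", "NIP", "SIP", "XIP")


class DuplicateIdError(ValueError):
    """Raised when a sequence collection contains a repeated identifier."""


class AlphabetError(ValueError):
    """Raised when a sequence contains a character outside its alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with optional genomic / EST provenance."""

    id: str
    sequence: str
    locus: str | None = None
    est_accession: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        for i, c in enumerate(self.sequence):
            if c not in AA_ALPHABET:
                raise AlphabetError(
                    f"illegal amino-acid character {c!r} at position {i + 1} "
                    f"in record {self.id!r}"
                )

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NucleotideRecord:
    """A nucleotide sequence (EST, CDS or genomic fragment)."""

    id: str
    sequence: str
    source: Literal["est", "cds", "genomic"] = "cds"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        for i, c in enumerate(self.sequence):
            if c not in NT_ALPHABET:
                raise AlphabetError(
                    f"illegal nucleotide {c!r} at position {i + 1} "
                    f"in record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """Exon structure of one mRNA, in transcription order.

    ``exons`` are 1-based inclusive genomic intervals sorted in
    transcription order: ascending start on the + strand, descending on
    the - strand.  UTRs, when present, follow the same convention.
    """

    locus: str
    chrom: str
    strand: Literal["+", "-"]
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene model {self.locus!r} has no exons")
        for s, e in self.exons:
            if s > e:
                raise ValueError(
                    f"interval ({s},{e}) in {self.locus!r} has start > end"
                )
        by_start = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_start, by_start[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping exons ({s1},{e1})/({s2},{e2}) in {self.locus!r}"
                )
        expected = by_start if self.strand == "+" else by_start[::-1]
        if self.exons != expected:
            raise ValueError(
                f"exons of {self.locus!r} not in transcription order for "
                f"strand {self.strand!r}"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) covered by the model, strand-agnostic."""
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)


@dataclass(frozen=True)
class ReferenceAnnotation:
    """An annotated reference aquaporin used for position transfer.

    Carries 1-based positions of the two NPA motifs, the four ar/R
    selectivity-filter residues (helix 2, helix 5, loop E first/second)
    and the five Froger discriminant positions P1..P5, plus the six
    transmembrane spans of the canonical MIP fold.
    """

    protein: ProteinRecord
    npa1_pos: int
    npa2_pos: int
    arR_positions: dict[str, int]
    froger_positions: dict[str, int]
    tmd_spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        n = self.protein.length_aa
        if set(self.arR_positions) != {"H2", "H5", "LE1", "LE2"}:
            raise ValueError("ar/R labels must be exactly H2,H5,LE1,LE2")
        if set(self.froger_positions) != {f"P{i}" for i in range(1, 6)}:
            raise ValueError("Froger labels must be exactly P1..P5")
        for pos in (
            self.npa1_pos,
            self.npa2_pos,
            *self.arR_positions.values(),
            *self.froger_positions.values(),
        ):
            if not 1 <= pos <= n:
                raise ValueError(f"annotated position {pos} outside protein ({n} aa)")
        arr = [self.arR_positions[k] for k in ("H2", "H5", "LE1", "LE2")]
        fro = [self.froger_positions[f"P{i}"] for i in range(1, 6)]
        for group in (arr, fro):
            if any(a >= b for a, b in zip(group, group[1:])):
                raise ValueError("annotated position groups must be strictly increasing")

    def residue_at(self, pos: int) -> str:
        return self.protein.sequence[pos - 1]


@dataclass
class FamilyReportRow:
    """One row of the combined family feature report (Table-1/2 shape)."""

    gene_name: str
    locus: str
    subfamily: str
    subgroup: str | None
    length_aa: int
    n_tmd: int
    npa_motifs: tuple[str | None, str | None] | None = None
    arR: tuple[str | None, str | None, str | None, str | None] | None = None
    froger: tuple[str | None, ...] | None = None
    specificity: str = "ambiguous"
    comments: str = ""

    def __post_init__(self) -> None:
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(f"unknown subfamily {self.subfamily!r}")
        if not 0 <= self.n_tmd <= 8:
            raise ValueError(f"n_tmd {self.n_tmd} outside [0, 8]")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: Literal["aa", "nt"] = "aa"):
    """Read a FASTA file into protein or nucleotide records.

    Sequences are uppercased; duplicate ids and characters outside the
    declared alphabet (gap characters included) are hard errors.
    """
    records: list[ProteinRecord | NucleotideRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "aa":
            records.append(ProteinRecord(id=rec.id, sequence=seq))
        else:
            records.append(NucleotideRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(
    records: Iterable[ProteinRecord | NucleotideRecord],
    path: str | Path,
    width: int = 60,
) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# GFF3


def read_gff_gene_models(
    path: str | Path,
    feature_types: Sequence[str] = ("mRNA",),
    exon_type: str = "exon",
) -> list[GeneModel]:
    """Parse mRNA-level gene models from a GFF3 file.

    One :class:`GeneModel` per feature of a type in ``feature_types``;
    exons are collected through their ``Parent`` attribute and returned
    in transcription order (descending coordinates on the - strand).
    Exon features with no Parent are skipped with a warning; overlapping
    exons within one model are a hard error (via GeneModel validation).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    for exon in db.features_of_type(exon_type):
        if "Parent" not in exon.attributes:
            warnings.warn(
                f"{exon_type} feature at {exon.seqid}:{exon.start}-{exon.end} "
                "has no Parent attribute; skipped"
            )
    models: list[GeneModel] = []
    for ftype in feature_types:
        for mrna in db.features_of_type(ftype):
            exons = [
                (child.start, child.end)
                for child in db.children(mrna, featuretype=exon_type)
            ]
            if not exons:
                warnings.warn(f"model {mrna.id!r} has no {exon_type} children; skipped")
                continue
            exons.sort()
            if mrna.strand == "-":
                exons = exons[::-1]
            models.append(
                GeneModel(
                    locus=mrna.id,
                    chrom=mrna.seqid,
                    strand=mrna.strand,
                    exons=exons,
                )
            )
    return models


# ---------------------------------------------------------------------------
# Newick (serialization lives with the tree type; re-exported here)


def write_newick(tree, path: str | Path) -> None:
    """Serialize a :class:`aquafam.tree.PhyloTree` to a Newick file."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick())
        fh.write("\n")


def read_newick(path: str | Path):
    """Read a Newick file into a :class:`aquafam.tree.PhyloTree`."""
    from .tree import PhyloTree

    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


# ---------------------------------------------------------------------------
# Reports

FEATURE_TABLE_COLUMNS = [
    "gene_name",
    "locus",
    "subfamily",
    "subgroup",
    "length_aa",
    "n_tmd",
    "npa1",
    "npa2",
    "H2",
    "H5",
    "LE1",
    "LE2",
    "P1",
    "P2",
    "P3",
    "P4",
    "P5",
    "specificity",
    "comments",
]


def write_feature_table(rows: Sequence[FamilyReportRow], path: str | Path) -> None:
    """Write the combined feature report as TSV, rendering nulls as '-'.

    The '-' convention mirrors the field's printed tables, where
    truncated proteins leave selectivity-filter cells empty.
    """
    data = []
    for r in rows:
        npa = r.npa_motifs or (None, None)
        arr = r.arR or (None, None, None, None)
        fro = r.froger or (None,) * 5
        data.append(
            {
                "gene_name": r.gene_name,
                "locus": r.locus,
                "subfamily": r.subfamily,
                "subgroup": r.subgroup,
                "length_aa": r.length_aa,
                "n_tmd": r.n_tmd,
                "npa1": npa[0],
                "npa2": npa[1],
                "H2": arr[0],
                "H5": arr[1],
                "LE1": arr[2],
                "LE2": arr[3],
                **{f"P{i + 1}": fro[i] for i in range(5)},
                "specificity": r.specificity,
                "comments": r.comments,
            }
        )
    df = pd.DataFrame(data, columns=FEATURE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="-")


def read_reference_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a reference position-annotation table (columns: ref_id, label, position)."""
    df = pd.read_csv(path, sep="\t", dtype={"ref_id": str, "label": str, "position": int})
    required = {"ref_id", "label", "position"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    return df
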