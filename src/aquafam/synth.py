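"""Ground-truthed synthetic MIP families for pipeline testing.

The generator emulates the statistical structure a genome-wide aquaporin
survey relies on: five divergent subfamilies (PIP, TIP, NIP, SIP, XIP)
each descending from its own consensus scaffold with six planted
21-residue hydrophobic transmembrane segments; NPA-type motifs in loops
B and E with subfamily-specific degenerate variants and the XIP NPARC
extension; subfamily-specific ar/R filter and Froger letters at known
coordinates; subfamily-specific exon counts in the emitted GFF; a
tandem array of XIP loci on one chromosome; ESTs copied from the coding
sequences with optional planted 1-bp insertions (the cloning-artifact
frameshift case); and length-matched random decoy proteins.

Members of a subfamily are drawn by per-site substitution from the
subgroup consensus, with category-preserving substitutions (hydrophobic
positions stay hydrophobic) and planted positions protected at a
configurable conservation probability.  No indels are simulated within
a subfamily, so every planted coordinate is exact ground truth.
Everything is bit-reproducible from the mandatory seed.

The default configuration mirrors the size of the published tomato
family: 14 + 11 + 12 + 4 + 6 = 47 members plus 200 decoys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.Seq import Seq

from .align import DistanceMatrix
from .seqio import (
    GeneModel,
    NucleotideRecord,
    ProteinRecord,
    ReferenceAnnotation,
    write_fasta,
)
from .tree import PhyloTree, TreeNode

TM_ALPHABET = "LIVFAM"
LOOP_ALPHABET = "DENQKRSTGH"  # no P/C/W/Y: NPA-type motifs cannot arise by chance
AA20 = "ACDEFGHIKLMNPQRSTVWY"

_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
        for aa in _CODONS:
            _CODONS[aa].sort()
    return _CODONS


class ConfigError(ValueError):
    """Raised for internally inconsistent generator plans."""


@dataclass(frozen=True)
class SubfamilyPlan:
    """Planted-feature plan for one subfamily."""

    name: str
    n_members: int
    subgroups: tuple[tuple[str, int], ...]  # (subgroup name, member count)
    npa1: str = "NPA"
    npa2: str = "NPA"
    nparc: bool = False  # extend the loop-E motif with R,C (XIP style)
    arr: tuple[str, str, str, str] = ("F", "H", "T", "R")
    froger: tuple[str, str, str, str, str] = ("M", "S", "A", "F", "W")
    n_exons: int = 4
    pkc_site: bool = False  # plant C-terminal S-x-R
    cdpk_site: bool = False  # plant C-terminal R-x-x-S
    tandem: bool = False  # place all loci adjacently on one chromosome
    npa1_offset: int = 7  # 0-based offset of the motif within loop B
    npa2_offset: int = 9  # within loop E

    def __post_init__(self) -> None:
        if sum(n for _, n in self.subgroups) != self.n_members:
            raise ConfigError(f"{self.name}: subgroup sizes must sum to n_members")
        for g, _ in self.subgroups:
            if not g.startswith(self.name):
                raise ConfigError(f"subgroup {g!r} must extend subfamily name")


def default_plans() -> tuple[SubfamilyPlan, ...]:
    """The study-sized default: 47 members over five subfamilies.

    NPA variants, ar/R and Froger letters follow the per-subfamily
    consensus configurations reported for plant MIP families.
    """
    return (
        SubfamilyPlan("PIP", 14, (("PIP1", 5), ("PIP2", 9)),
                      arr=("F", "H", "T", "R"), froger=("M", "S", "A", "F", "W"),
                      n_exons=4, pkc_site=True),
        SubfamilyPlan("TIP", 11, (("TIP1", 5), ("TIP2", 6)),
                      arr=("H", "I", "A", "V"), froger=("T", "S", "A", "Y", "W"),
                      n_exons=3),
        SubfamilyPlan("NIP", 12, (("NIP1", 6), ("NIP2", 6)),
                      npa1="NPS", npa2="NPV",
                      arr=("W", "V", "A", "R"), froger=("F", "S", "A", "Y", "L"),
                      n_exons=5, cdpk_site=True),
        SubfamilyPlan("SIP", 4, (("SIP1", 3), ("SIP2", 1)),
                      npa1="NPT", npa2="NPA",
                      arr=("V", "T", "P", "N"), froger=("C", "A", "A", "Y", "W"),
                      n_exons=3),
        SubfamilyPlan("XIP", 6, (("XIP1", 6),),
                      npa1="NPV", npa2="NPA", nparc=True,
                      arr=("I", "T", "A", "R"), froger=("V", "C", "P", "F", "W"),
                      n_exons=3, tandem=True),
    )


@dataclass(frozen=True)
class FamilyConfig:
    seed: int
    plans: tuple[SubfamilyPlan, ...] = field(default_factory=default_plans)
    within_rate: float = 0.05  # per-site substitution, subgroup consensus -> member
    subgroup_divergence: float = 0.15  # subfamily consensus -> subgroup consensus
    conservation_prob: float = 1.0  # planted positions survive mutation
    n_decoys: int = 200
    est_coverage: float = 0.75
    est_error_prob: float = 0.05  # chance of a planted 1-bp insertion per EST
    n_refs_per_subgroup: int = 2
    tm_length: int = 21

    def __post_init__(self) -> None:
        for r in (self.within_rate, self.subgroup_divergence,
                  self.conservation_prob, self.est_coverage, self.est_error_prob):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")


@dataclass
class GroundTruthEntry:
    """Complete planted truth for one generated protein."""

    id: str
    gene_name: str | None
    locus: str | None
    subfamily: str | None
    subgroup: str | None
    is_decoy: bool
    tmd_spans: list[tuple[int, int]] = field(default_factory=list)
    npa: list[tuple[str, int, str, str | None]] = field(default_factory=list)
    arr_letters: tuple[str, ...] | None = None
    arr_positions: tuple[int, ...] | None = None
    froger_letters: tuple[str, ...] | None = None
    froger_positions: tuple[int, ...] | None = None
    exon_count: int | None = None
    chrom: str | None = None
    tandem_cluster: str | None = None
    phospho_positions: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class EstTruth:
    est_id: str
    locus: str
    edits: list[tuple[str, int, str]]  # (kind, 1-based position, base)


@dataclass
class ReferencePanel:
    """Labeled (and per-subfamily annotated) reference proteins.

    This panel is synthetic: it is generated alongside the queries from
    the same subfamily scaffolds and stands in for a curated panel of
    annotated plant MIPs, which the offline pipeline cannot download.
    """

    proteins: list[ProteinRecord]
    labels: dict[str, tuple[str, str | None]]
    annotations: dict[str, ReferenceAnnotation]  # subfamily -> annotated ref


@dataclass
class SyntheticFamily:
    config: FamilyConfig
    proteome: list[ProteinRecord]
    cds: list[NucleotideRecord]
    ests: list[NucleotideRecord]
    gene_models: list[GeneModel]
    panel: ReferencePanel
    truth: dict[str, GroundTruthEntry]
    est_truth: dict[str, EstTruth]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit proteome/CDS/EST FASTA, GFF3, panel files and truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": outdir / "proteome.fasta",
            "cds": outdir / "cds.fasta",
            "ests": outdir / "ests.fasta",
            "gff": outdir / "genes.gff3",
            "panel_fasta": outdir / "reference_panel.synthetic.fasta",
            "panel_labels": outdir / "reference_labels.synthetic.tsv",
            "panel_annotations": outdir / "reference_annotations.synthetic.tsv",
            "ground_truth": outdir / "ground_truth.tsv",
        }
        write_fasta(self.proteome, paths["proteome"])
        write_fasta(self.cds, paths["cds"])
        write_fasta(self.ests, paths["ests"])
        _write_gff(self.gene_models, paths["gff"])
        write_fasta(self.panel.proteins, paths["panel_fasta"])
        with open(paths["panel_labels"], "w") as fh:
            fh.write("ref_id\tsubfamily\tsubgroup\n")
            for rid, (fam, sub) in self.panel.labels.items():
                fh.write(f"{rid}\t{fam}\t{sub or '-'}\n")
        with open(paths["panel_annotations"], "w") as fh:
            fh.write("ref_id\tlabel\tposition\n")
            for fam, ann in self.panel.annotations.items():
                rid = ann.protein.id
                fh.write(f"{rid}\tNPA1\t{ann.npa1_pos}\n")
                fh.write(f"{rid}\tNPA2\t{ann.npa2_pos}\n")
                for lab, pos in ann.arR_positions.items():
                    fh.write(f"{rid}\t{lab}\t{pos}\n")
                for lab, pos in ann.froger_positions.items():
                    fh.write(f"{rid}\t{lab}\t{pos}\n")
                for k, (s, e) in enumerate(ann.tmd_spans, 1):
                    fh.write(f"{rid}\tTMD{k}\t{s}\n")
                    fh.write(f"{rid}\tTMD{k}_end\t{e}\n")
        _write_truth(self.truth, paths["ground_truth"])
        return paths


# ---------------------------------------------------------------------------
# scaffold construction


@dataclass
class _Scaffold:
    chars: list[str]
    is_tm: np.ndarray
    tmd_spans: list[tuple[int, int]]
    npa: list[tuple[str, int, str, str | None]]
    arr_positions: tuple[int, int, int, int]
    froger_positions: tuple[int, int, int, int, int]
    protected: set[int]  # 0-based indices never to mutate
    phospho: list[tuple[int, str]]


def _build_scaffold(rng: np.random.Generator, plan: SubfamilyPlan,
                    tm_len: int) -> _Scaffold:
    loop_b_len, loop_e_len = 24, 30
    seg_lens = {
        "nterm": int(rng.integers(12, 22)),
        "loopA": int(rng.integers(15, 20)),
        "loopC": int(rng.integers(15, 20)),
        "loopD": int(rng.integers(15, 20)),
        "cterm": int(rng.integers(18, 26)),
    }
    if plan.npa1_offset + 3 > loop_b_len:
        raise ConfigError(f"{plan.name}: loop-B NPA offset outside the loop")
    if plan.npa2_offset + (5 if plan.nparc else 3) > loop_e_len:
        raise ConfigError(f"{plan.name}: loop-E NPA offset outside the loop")

    order = [
        ("nterm", seg_lens["nterm"]), ("TM1", tm_len), ("loopA", seg_lens["loopA"]),
        ("TM2", tm_len), ("loopB", loop_b_len), ("TM3", tm_len),
        ("loopC", seg_lens["loopC"]), ("TM4", tm_len), ("loopD", seg_lens["loopD"]),
        ("TM5", tm_len), ("loopE", loop_e_len), ("TM6", tm_len),
        ("cterm", seg_lens["cterm"]),
    ]
    chars: list[str] = []
    is_tm_mask: list[bool] = []
    starts: dict[str, int] = {}
    for name, length in order:
        starts[name] = len(chars)  # 0-based segment start
        tm = name.startswith("TM")
        alphabet = TM_ALPHABET if tm else LOOP_ALPHABET
        chars.extend(rng.choice(list(alphabet), size=length))
        is_tm_mask.extend([tm] * length)

    protected: set[int] = set()

    def plant(idx0: int, letters: str) -> None:
        for k, c in enumerate(letters):
            chars[idx0 + k] = c
            protected.add(idx0 + k)

    tmd_spans = [(starts[f"TM{i}"] + 1, starts[f"TM{i}"] + tm_len)
                 for i in range(1, 7)]
    # NPA motifs
    npa1_idx = starts["loopB"] + plan.npa1_offset
    plant(npa1_idx, plan.npa1)
    npa2_idx = starts["loopE"] + plan.npa2_offset
    motif2 = plan.npa2 + ("RC" if plan.nparc else "")
    plant(npa2_idx, motif2)
    npa = [
        ("B", npa1_idx + 1, plan.npa1, None),
        ("E", npa2_idx + 1, plan.npa2, plan.npa2 + "RC" if plan.nparc else None),
    ]
    # ar/R filter: H2 in helix 2, H5 in helix 5, LE1/LE2 around the loop-E motif
    h2 = starts["TM2"] + 9
    h5 = starts["TM5"] + 17
    le1 = npa2_idx - 1
    le2 = npa2_idx + (5 if plan.nparc else 4) + 1
    for idx0, letter in zip((h2, h5, le1, le2), plan.arr):
        plant(idx0, letter)
    arr_positions = (h2 + 1, h5 + 1, le1 + 1, le2 + 1)
    # Froger positions: P1 in loop C, P2/P3 late in loop E, P4/P5 in helix 6
    p1 = starts["loopC"] + 5
    p2 = starts["loopE"] + loop_e_len - 6
    p3 = starts["loopE"] + loop_e_len - 4
    p4 = starts["TM6"] + 4
    p5 = starts["TM6"] + 11
    for idx0, letter in zip((p1, p2, p3, p4, p5), plan.froger):
        plant(idx0, letter)
    froger_positions = (p1 + 1, p2 + 1, p3 + 1, p4 + 1, p5 + 1)
    if le2 >= p2:
        raise ConfigError(f"{plan.name}: loop-E plan collides with Froger positions")
    # phosphorylation motifs in the C-terminal tail
    phospho: list[tuple[int, str]] = []
    total = len(chars)
    if plan.pkc_site:
        idx0 = total - 5  # S-x-R ending 3 residues before the terminus
        plant(idx0, "S")
        plant(idx0 + 2, "R")
        phospho.append((idx0 + 1, "PKC"))
    if plan.cdpk_site:
        idx0 = total - 9  # R-x-x-S
        plant(idx0, "R")
        plant(idx0 + 3, "S")
        phospho.append((idx0 + 1, "CDPK"))
    return _Scaffold(
        chars=chars, is_tm=np.array(is_tm_mask), tmd_spans=tmd_spans, npa=npa,
        arr_positions=arr_positions, froger_positions=froger_positions,
        protected=protected, phospho=phospho,
    )


def _mutate(chars: list[str], scaffold: _Scaffold, rate: float,
            conservation_prob: float, rng: np.random.Generator) -> list[str]:
    """Category-preserving per-site substitution away from a consensus."""
    out = list(chars)
    hits = rng.random(len(out)) < rate
    keep_planted = rng.random(len(out)) < conservation_prob
    for i in np.where(hits)[0]:
        if i in scaffold.protected and keep_planted[i]:
            continue
        alphabet = TM_ALPHABET if scaffold.is_tm[i] else LOOP_ALPHABET
        choices = [c for c in alphabet if c != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return out


# ---------------------------------------------------------------------------
# nucleotide layer


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice under the generator's seed."""
    table = _codon_table()
    return "".join(
        table[aa][int(rng.integers(len(table[aa])))] for aa in protein
    ) + "TAA"


def plant_frameshift(cds: NucleotideRecord, position: int,
                     seed: int) -> tuple[NucleotideRecord, tuple[str, int, str]]:
    """Insert one random base so it occupies ``position`` (1-based)."""
    if not 1 <= position <= len(cds.sequence) + 1:
        raise ValueError(f"insertion position {position} outside CDS")
    rng = np.random.default_rng(seed)
    base = "ACGT"[int(rng.integers(4))]
    seq = cds.sequence[: position - 1] + base + cds.sequence[position - 1:]
    edited = NucleotideRecord(id=cds.id, sequence=seq, source="est")
    return edited, ("ins", position, base)


def _split_exons(total: int, n_exons: int, rng: np.random.Generator,
                 min_exon: int = 30) -> list[int]:
    """Exon lengths summing to ``total``, each at least ``min_exon``."""
    if n_exons * min_exon > total:
        raise ConfigError("CDS too short for the exon plan")
    free = total - n_exons * min_exon
    cuts = np.sort(rng.integers(0, free + 1, size=n_exons - 1))
    parts = np.diff(np.concatenate([[0], cuts, [free]]))
    return [int(min_exon + p) for p in parts]


def _write_gff(models: Iterable[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            fh.write(f"{m.chrom}\taquafam\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                     f"ID=gene:{m.locus}\n")
            fh.write(f"{m.chrom}\taquafam\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                     f"ID={m.locus};Parent=gene:{m.locus}\n")
            for k, (s, e) in enumerate(sorted(m.exons), 1):
                fh.write(f"{m.chrom}\taquafam\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                         f"ID={m.locus}.exon{k};Parent={m.locus}\n")


def _write_truth(truth: dict[str, GroundTruthEntry], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgene_name\tlocus\tsubfamily\tsubgroup\tis_decoy\texon_count\t"
                 "chrom\ttandem_cluster\tnpa\tarr\tfroger\ttmd_spans\n")
        for e in truth.values():
            npa = ";".join(f"{lp}:{pos}:{mot}:{ext or '.'}" for lp, pos, mot, ext in e.npa)
            arr = (";".join(f"{l}@{p}" for l, p in
                            zip(e.arr_letters, e.arr_positions))
                   if e.arr_letters else "-")
            fro = (";".join(f"{l}@{p}" for l, p in
                            zip(e.froger_letters, e.froger_positions))
                   if e.froger_letters else "-")
            spans = ";".join(f"{s}-{t}" for s, t in e.tmd_spans) or "-"
            fh.write(
                f"{e.id}\t{e.gene_name or '-'}\t{e.locus or '-'}\t"
                f"{e.subfamily or '-'}\t{e.subgroup or '-'}\t"
                f"{int(e.is_decoy)}\t{e.exon_count or '-'}\t{e.chrom or '-'}\t"
                f"{e.tandem_cluster or '-'}\t{npa or '-'}\t{arr}\t{fro}\t{spans}\n"
            )


# ---------------------------------------------------------------------------
# main generator


def generate_family(cfg: FamilyConfig) -> SyntheticFamily:
    """Generate the full synthetic study and its complete ground truth.

    Outputs are self-audited on generation: planted letters, motif
    strings, exon sums and CDS translations are re-checked against the
    emitted sequences, so an inconsistent plan cannot produce silently
    wrong fixtures.
    """
    rng = np.random.default_rng(cfg.seed)
    proteome: list[ProteinRecord] = []
    cds_records: list[NucleotideRecord] = []
    ests: list[NucleotideRecord] = []
    models: list[GeneModel] = []
    truth: dict[str, GroundTruthEntry] = {}
    est_truth: dict[str, EstTruth] = {}
    panel_proteins: list[ProteinRecord] = []
    panel_labels: dict[str, tuple[str, str | None]] = {}
    panel_annotations: dict[str, ReferenceAnnotation] = {}

    chrom_cursor: dict[str, int] = {}
    other_chroms = [f"ch{i:02d}" for i in range(1, 10)]
    chrom_rr = 0

    for plan in cfg.plans:
        scaffold = _build_scaffold(rng, plan, cfg.tm_length)
        member_idx = 0
        for subgroup, count in plan.subgroups:
            sub_consensus = _mutate(scaffold.chars, scaffold,
                                    cfg.subgroup_divergence, 1.0, rng)
            # labeled references for this subgroup
            for r in range(cfg.n_refs_per_subgroup):
                ref_chars = _mutate(sub_consensus, scaffold, cfg.within_rate,
                                    cfg.conservation_prob, rng)
                rid = f"REF_{subgroup}_{r + 1}"
                rec = ProteinRecord(id=rid, sequence="".join(ref_chars))
                panel_proteins.append(rec)
                panel_labels[rid] = (plan.name, subgroup)
                if plan.name not in panel_annotations and r == 0:
                    panel_annotations[plan.name] = ReferenceAnnotation(
                        protein=rec,
                        npa1_pos=scaffold.npa[0][1],
                        npa2_pos=scaffold.npa[1][1],
                        arR_positions=dict(zip(("H2", "H5", "LE1", "LE2"),
                                               scaffold.arr_positions)),
                        froger_positions=dict(zip(("P1", "P2", "P3", "P4", "P5"),
                                                  scaffold.froger_positions)),
                        tmd_spans=tuple(scaffold.tmd_spans),
                    )
            for _ in range(count):
                member_idx += 1
                chars = _mutate(sub_consensus, scaffold, cfg.within_rate,
                                cfg.conservation_prob, rng)
                name = f"Sy{subgroup};{member_idx}"
                locus = f"synloc_{plan.name}_{member_idx:02d}"
                protein = ProteinRecord(id=locus, sequence="".join(chars),
                                        locus=locus)
                proteome.append(protein)
                cds = NucleotideRecord(
                    id=locus, sequence=back_translate(protein.sequence, rng),
                    source="cds",
                )
                cds_records.append(cds)
                # genomic placement
                if plan.tandem:
                    chrom = "ch10"
                    gap = int(rng.integers(3000, 8000))
                else:
                    chrom = other_chroms[chrom_rr % len(other_chroms)]
                    chrom_rr += 1
                    gap = 500_000
                start = chrom_cursor.get(chrom, 1000) + gap
                exon_lens = _split_exons(len(cds.sequence), plan.n_exons, rng)
                exons = []
                pos = start
                for L in exon_lens:
                    exons.append((pos, pos + L - 1))
                    pos += L + int(rng.integers(100, 500))
                chrom_cursor[chrom] = exons[-1][1]
                strand = "+" if rng.random() < 0.5 else "-"
                models.append(GeneModel(
                    locus=locus, chrom=chrom, strand=strand,
                    exons=exons if strand == "+" else exons[::-1],
                ))
                entry = GroundTruthEntry(
                    id=locus, gene_name=name, locus=locus, subfamily=plan.name,
                    subgroup=subgroup, is_decoy=False,
                    tmd_spans=list(scaffold.tmd_spans),
                    npa=list(scaffold.npa),
                    arr_letters=plan.arr,
                    arr_positions=scaffold.arr_positions,
                    froger_letters=plan.froger,
                    froger_positions=scaffold.froger_positions,
                    exon_count=plan.n_exons, chrom=chrom,
                    tandem_cluster="ch10_xip" if plan.tandem else None,
                    phospho_positions=list(scaffold.phospho),
                )
                truth[locus] = entry
                # EST layer
                if rng.random() < cfg.est_coverage:
                    est_id = f"{locus}_EST"
                    edits: list[tuple[str, int, str]] = []
                    est_seq = cds.sequence
                    if rng.random() < cfg.est_error_prob:
                        pos1 = int(rng.integers(1, len(est_seq) + 1))
                        edited, edit = plant_frameshift(
                            NucleotideRecord(id=est_id, sequence=est_seq),
                            pos1, int(rng.integers(2**31)),
                        )
                        est_seq = edited.sequence
                        edits.append(edit)
                    ests.append(NucleotideRecord(id=est_id, sequence=est_seq,
                                                 source="est"))
                    est_truth[est_id] = EstTruth(est_id=est_id, locus=locus,
                                                 edits=edits)

    # decoys: length-matched random proteins without any planted scaffold
    member_lengths = [p.length_aa for p in proteome]
    for d in range(cfg.n_decoys):
        length = int(rng.choice(member_lengths)) if member_lengths else 280
        seq = "".join(rng.choice(list(AA20), size=length))
        did = f"decoy_{d + 1:03d}"
        proteome.append(ProteinRecord(id=did, sequence=seq))
        truth[did] = GroundTruthEntry(id=did, gene_name=None, locus=None,
                                      subfamily=None, subgroup=None, is_decoy=True)

    # deterministic shuffle so family members are not a prefix block
    order = rng.permutation(len(proteome))
    proteome = [proteome[i] for i in order]

    fam = SyntheticFamily(
        config=cfg, proteome=proteome, cds=cds_records, ests=ests,
        gene_models=models,
        panel=ReferencePanel(proteins=panel_proteins, labels=panel_labels,
                             annotations=panel_annotations),
        truth=truth, est_truth=est_truth,
    )
    _audit(fam)
    return fam


def _audit(fam: SyntheticFamily) -> None:
    """Self-check: emitted content must match the recorded ground truth.

    Letter-level checks only apply at full conservation; in the stress
    mode (conservation_prob < 1) the truth intentionally records the
    *planted* letters so recovery degradation can be measured against
    them.
    """
    cds_by_locus = {c.id: c for c in fam.cds}
    models_by_locus = {m.locus: m for m in fam.gene_models}
    check_letters = fam.config.conservation_prob >= 1.0
    for entry in fam.truth.values():
        if entry.is_decoy:
            continue
        prot = next(p for p in fam.proteome if p.id == entry.id)
        seq = prot.sequence
        if check_letters:
            for loop, pos, motif, ext in entry.npa:
                planted = ext or motif
                if seq[pos - 1: pos - 1 + len(planted)] != planted:
                    raise AssertionError(
                        f"{entry.id}: planted NPA mismatch in loop {loop}")
            for letter, pos in zip(entry.arr_letters, entry.arr_positions):
                if seq[pos - 1] != letter:
                    raise AssertionError(
                        f"{entry.id}: planted ar/R letter mismatch at {pos}")
            for letter, pos in zip(entry.froger_letters, entry.froger_positions):
                if seq[pos - 1] != letter:
                    raise AssertionError(
                        f"{entry.id}: planted Froger letter mismatch at {pos}")
        cds = cds_by_locus[entry.locus]
        if str(Seq(cds.sequence).translate()) != seq + "*":
            raise AssertionError(f"{entry.id}: CDS does not translate to the protein")
        model = models_by_locus[entry.locus]
        if model.n_exons != entry.exon_count:
            raise AssertionError(f"{entry.id}: exon count mismatch")
        if sum(e - s + 1 for s, e in model.exons) != len(cds.sequence):
            raise AssertionError(f"{entry.id}: exon lengths do not sum to the CDS")


# ---------------------------------------------------------------------------
# additive matrices for NJ oracles


def random_additive_tree(n_leaves: int, seed: int,
                         min_len: float = 0.1, max_len: float = 1.0) -> PhyloTree:
    """Random unrooted binary topology with uniform branch lengths.

    Built by repeated leaf attachment to a uniformly chosen existing
    edge, which samples all unrooted topologies with positive support.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)

    def blen() -> float:
        return float(rng.uniform(min_len, max_len))

    labels = [f"T{i + 1}" for i in range(n_leaves)]
    root = TreeNode()
    for lb in labels[:3]:
        leaf = TreeNode(name=lb, length=blen())
        root.add(leaf)
    for lb in labels[3:]:
        edges = [n for n in root.walk() if n is not root]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        mid = TreeNode()
        split = target.length * float(rng.uniform(0.2, 0.8))
        rest = target.length - split
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.length = rest
        target.length = split
        mid.add(target)
        mid.add(TreeNode(name=lb, length=blen()))
    return PhyloTree(root)


def make_additive_matrix(tree_spec: PhyloTree | int, seed: int = 0) -> DistanceMatrix:
    """Path-length (additive) distance matrix from a tree.

    ``tree_spec`` may be a :class:`PhyloTree` with branch lengths, or an
    integer leaf count, in which case a random tree is drawn from
    ``seed`` first.
    """
    tree = (tree_spec if isinstance(tree_spec, PhyloTree)
            else random_additive_tree(tree_spec, seed))
    labels = sorted(tree.leaf_names())
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree.patristic_distance(labels[i], labels[j])
    return DistanceMatrix(labels=labels, d=d)
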