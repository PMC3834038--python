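"""End-to-end orchestration of the genome-wide MIP family study.

The stages mirror how such surveys are actually run: a seeded candidate
scan of the predicted proteome, EST-based verification of the gene
models (including correction of single-base cloning artifacts that
cause frameshifts and premature stops), progressive alignment and
neighbor-joining classification against a labeled reference panel,
hydropathy topology, specificity-residue extraction, exon-structure
summaries and tandem-duplication detection.  ``run_pipeline`` wires
them together and writes the tabular reports; every stage is also a
plain function usable on its own.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .align import (
    Alignment,
    ScoringParams,
    global_align,
    nucleotide_params,
    progressive_msa,
)
from .phylo import SubfamilyAssignment, assign_subfamily, bootstrap_support
from .residues import (
    ResidueParams,
    classify_specificity,
    find_npa_motifs,
    find_phospho_sites,
    transfer_positions,
)
from .seqio import (
    FamilyReportRow,
    GeneModel,
    NucleotideRecord,
    ProteinRecord,
    ReferenceAnnotation,
    read_fasta,
    read_gff_gene_models,
    write_feature_table,
    write_newick,
)
from .topology import HydropathyParams, predict_tmds


# ---------------------------------------------------------------------------
# candidate scan


@dataclass(frozen=True)
class ScanParams:
    threshold: float = 1.0  # accepted iff score per aligned column >= this
    kmer_size: int = 4
    min_shared_kmers: int = 10  # prefilter before full alignment
    scoring: ScoringParams = field(default_factory=ScoringParams)


@dataclass(frozen=True)
class CandidateHit:
    locus: str
    best_seed: str | None
    best_subfamily: str | None
    score: float
    normalized_score: float
    accepted: bool


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i: i + k] for i in range(len(seq) - k + 1)}


def scan_proteome(
    proteome: Sequence[ProteinRecord],
    seeds: Mapping[str, ProteinRecord],
    params: ScanParams | None = None,
) -> list[CandidateHit]:
    """Align every proteome entry against one seed per subfamily.

    A shared-k-mer prefilter skips full dynamic programming for entries
    unrelated to every seed; those are reported as rejected hits with
    score 0.  Acceptance uses the score per aligned (both-residue)
    column against the best seed.
    """
    params = params or ScanParams()
    seed_kmers = {name: _kmers(s.sequence, params.kmer_size)
                  for name, s in seeds.items()}
    hits: list[CandidateHit] = []
    for rec in proteome:
        rk = _kmers(rec.sequence, params.kmer_size)
        candidates = [name for name, sk in seed_kmers.items()
                      if len(rk & sk) >= params.min_shared_kmers]
        best: tuple[float, float, str] | None = None
        for name in candidates:
            aln = global_align(rec, seeds[name], params.scoring)
            cols = sum(1 for x, y in zip(*aln.rows) if x != "-" and y != "-")
            norm = aln.score / cols if cols else float("-inf")
            if best is None or norm > best[0]:
                best = (norm, aln.score, name)
        if best is None:
            hits.append(CandidateHit(locus=rec.id, best_seed=None,
                                     best_subfamily=None, score=0.0,
                                     normalized_score=0.0, accepted=False))
        else:
            norm, score, name = best
            hits.append(CandidateHit(
                locus=rec.id, best_seed=seeds[name].id, best_subfamily=name,
                score=score, normalized_score=norm,
                accepted=norm >= params.threshold,
            ))
    return hits


# ---------------------------------------------------------------------------
# EST reconciliation


@dataclass(frozen=True)
class EstReconciliation:
    locus: str
    est_id: str
    edits: tuple[tuple[str, int, str], ...]  # (kind, CDS coordinate, bases)
    frameshift_detected: bool
    premature_stop_at: int | None
    corrected_orf: NucleotideRecord | None
    verdict: Literal["confirms_model", "revises_model", "artifact_corrected"]


def _translate_has_internal_stop(seq: str) -> int | None:
    """1-based nucleotide position of the first internal stop codon, if any."""
    usable = len(seq) - len(seq) % 3
    aa = str(Seq(seq[:usable]).translate())
    idx = aa.find("*")
    if idx == -1 or idx == usable // 3 - 1:
        return None
    return idx * 3 + 1


def reconcile_est(model_cds: NucleotideRecord, est: NucleotideRecord,
                  params: ScoringParams | None = None) -> EstReconciliation:
    """Compare a sequenced EST against the model CDS.

    Indels are enumerated from a global nucleotide alignment; a net
    indel length not divisible by three flags a frameshift.  When the
    evidence is a single 1-bp insertion producing a premature stop, the
    insertion is treated as a cloning artifact and a corrected ORF with
    it removed is returned (it must translate without internal stops).
    """
    params = params or nucleotide_params()
    aln = global_align(_as_protein(model_cds), _as_protein(est), params)
    cds_row, est_row = aln.rows
    edits: list[tuple[str, int, str]] = []
    cds_pos = 0
    i = 0
    while i < len(cds_row):
        if cds_row[i] == "-":  # insertion in the EST
            j = i
            bases = []
            while j < len(cds_row) and cds_row[j] == "-":
                bases.append(est_row[j])
                j += 1
            edits.append(("ins", cds_pos + 1, "".join(bases)))
            i = j
        elif est_row[i] == "-":  # deletion in the EST
            j = i
            bases = []
            while j < len(cds_row) and est_row[j] == "-" and cds_row[j] != "-":
                cds_pos += 1
                bases.append(cds_row[j])
                j += 1
            edits.append(("del", cds_pos - len(bases) + 1, "".join(bases)))
            i = j
        else:
            cds_pos += 1
            i += 1
    net = sum(len(b) if k == "ins" else -len(b) for k, _, b in edits)
    frameshift = net % 3 != 0
    stop_at = _translate_has_internal_stop(est.sequence)

    corrected: NucleotideRecord | None = None
    verdict: str
    insertions = [e for e in edits if e[0] == "ins"]
    deletions = [e for e in edits if e[0] == "del"]
    if not edits:
        verdict = "confirms_model"
    elif (frameshift and len(insertions) == 1
          and len(insertions[0][2]) == 1 and not deletions):
        # a lone 1-bp insertion (typically producing a premature stop) is
        # treated as a cloning artifact if dropping it restores a clean ORF
        est_pos = _est_position_of_insertion(cds_row, est_row)
        fixed = est.sequence[: est_pos - 1] + est.sequence[est_pos:]
        if _translate_has_internal_stop(fixed) is None:
            corrected = NucleotideRecord(id=model_cds.id, sequence=fixed,
                                         source="cds")
            verdict = "artifact_corrected"
        else:
            verdict = "revises_model"
    else:
        verdict = "revises_model"
    return EstReconciliation(
        locus=model_cds.id, est_id=est.id, edits=tuple(edits),
        frameshift_detected=frameshift, premature_stop_at=stop_at,
        corrected_orf=corrected, verdict=verdict,
    )


def _as_protein(nt: NucleotideRecord) -> ProteinRecord:
    """Wrap a nucleotide sequence for the generic aligner (ACGTN are all
    valid amino-acid letters except handled by the nucleotide matrix)."""
    p = ProteinRecord.__new__(ProteinRecord)
    object.__setattr__(p, "id", nt.id)
    object.__setattr__(p, "sequence", nt.sequence)
    object.__setattr__(p, "locus", None)
    object.__setattr__(p, "est_accession", None)
    return p


def _est_position_of_insertion(cds_row: str, est_row: str) -> int:
    est_pos = 0
    for c, e in zip(cds_row, est_row):
        if e != "-":
            est_pos += 1
        if c == "-":
            return est_pos
    raise ValueError("no insertion column in alignment")


def match_ests_to_loci(
    cds_records: Sequence[NucleotideRecord],
    ests: Sequence[NucleotideRecord],
    k: int = 12,
    min_shared_frac: float = 0.2,
) -> dict[str, NucleotideRecord]:
    """Pick the most similar EST per locus by shared-k-mer count, ties to
    the longest EST (then lexicographic id for determinism).

    A locus with no EST sharing at least ``min_shared_frac`` of its
    k-mers stays unmatched (the "no EST found" case), so unrelated
    transcripts cannot masquerade as gene-model evidence.
    """
    cds_kmers = {c.id: _kmers(c.sequence, k) for c in cds_records}
    best: dict[str, tuple[int, int, str, NucleotideRecord]] = {}
    for est in ests:
        ek = _kmers(est.sequence, k)
        for locus, ck in cds_kmers.items():
            shared = len(ek & ck)
            if shared < max(1, int(min_shared_frac * len(ck))):
                continue
            key = (shared, len(est.sequence), est.id)
            if locus not in best or key > (best[locus][0], best[locus][1], best[locus][2]):
                best[locus] = (*key, est)
    return {locus: rec for locus, (_, _, _, rec) in best.items()}


# ---------------------------------------------------------------------------
# exon structure and tandem clusters


@dataclass(frozen=True)
class ExonStructureSummary:
    modal_counts: dict[str, int]
    exceptions: dict[str, tuple[tuple[str, int], ...]]


def summarize_exon_structure(
    models: Sequence[GeneModel],
    assignments: Mapping[str, str],
) -> ExonStructureSummary:
    """Modal exon count per subfamily (ties to the smaller mode) and the
    loci deviating from it."""
    by_fam: dict[str, list[GeneModel]] = {}
    for m in models:
        fam = assignments.get(m.locus)
        if fam is not None:
            by_fam.setdefault(fam, []).append(m)
    modal: dict[str, int] = {}
    exceptions: dict[str, tuple[tuple[str, int], ...]] = {}
    for fam, ms in sorted(by_fam.items()):
        counts = [m.n_exons for m in ms]
        values, freqs = np.unique(counts, return_counts=True)
        mode = int(values[np.argmax(freqs)])  # np.unique sorts: ties -> smaller
        modal[fam] = mode
        exceptions[fam] = tuple(
            (m.locus, m.n_exons) for m in sorted(ms, key=lambda x: x.locus)
            if m.n_exons != mode
        )
    return ExonStructureSummary(modal_counts=modal, exceptions=exceptions)


@dataclass(frozen=True)
class TandemCluster:
    chromosome: str
    loci: tuple[str, ...]
    max_gap: int

    def __post_init__(self) -> None:
        if len(self.loci) < 2:
            raise ValueError("a tandem cluster needs at least 2 loci")


def find_tandem_clusters(
    models: Sequence[GeneModel],
    accepted_loci: set[str],
    gap: int = 100_000,
) -> list[TandemCluster]:
    """Maximal runs of accepted loci on one chromosome with inter-locus
    gaps at most ``gap`` bp."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        if m.locus in accepted_loci:
            by_chrom.setdefault(m.chrom, []).append(m)
    clusters: list[TandemCluster] = []
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda m: m.span)
        run: list[GeneModel] = []
        for m in ms:
            if run and m.span[0] - run[-1].span[1] <= gap:
                run.append(m)
            else:
                if len(run) >= 2:
                    clusters.append(TandemCluster(
                        chromosome=chrom, loci=tuple(x.locus for x in run),
                        max_gap=gap))
                run = [m]
        if len(run) >= 2:
            clusters.append(TandemCluster(
                chromosome=chrom, loci=tuple(x.locus for x in run), max_gap=gap))
    return clusters


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineConfig:
    proteome: str
    gff: str
    panel_fasta: str
    panel_labels: str
    panel_annotations: str
    outdir: str
    cds: str | None = None
    ests: str | None = None
    skip_est: bool = False
    seed: int = 0
    bootstrap_n: int = 100
    tandem_gap: int = 100_000
    scan: ScanParams = field(default_factory=ScanParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    hydropathy: HydropathyParams = field(default_factory=HydropathyParams)
    residues: ResidueParams = field(default_factory=ResidueParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        nested = {
            "scan": ScanParams, "scoring": ScoringParams,
            "hydropathy": HydropathyParams, "residues": ResidueParams,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in nested and isinstance(value, dict):
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PipelineResult:
    hits: list[CandidateHit]
    assignments: dict[str, SubfamilyAssignment]
    reconciliations: dict[str, EstReconciliation]
    msa: Alignment
    tree: object
    exon_summary: ExonStructureSummary
    clusters: list[TandemCluster]
    rows: list[FamilyReportRow]
    outputs: dict[str, Path]


def load_panel(cfg: PipelineConfig):
    """Load the reference panel: proteins, labels and per-subfamily
    position annotations."""
    import pandas as pd

    proteins = {p.id: p for p in read_fasta(cfg.panel_fasta, "aa")}
    labels_df = pd.read_csv(cfg.panel_labels, sep="\t")
    labels: dict[str, tuple[str, str | None]] = {}
    for _, row in labels_df.iterrows():
        sub = None if row["subgroup"] in ("-", "", None) else str(row["subgroup"])
        labels[str(row["ref_id"])] = (str(row["subfamily"]), sub)
    ann_df = pd.read_csv(cfg.panel_annotations, sep="\t")
    annotations: dict[str, ReferenceAnnotation] = {}
    for rid, grp in ann_df.groupby("ref_id"):
        pos = dict(zip(grp["label"], grp["position"].astype(int)))
        spans = []
        for k in range(1, 7):
            if f"TMD{k}" in pos and f"TMD{k}_end" in pos:
                spans.append((pos[f"TMD{k}"], pos[f"TMD{k}_end"]))
        ann = ReferenceAnnotation(
            protein=proteins[str(rid)],
            npa1_pos=pos["NPA1"], npa2_pos=pos["NPA2"],
            arR_positions={k: pos[k] for k in ("H2", "H5", "LE1", "LE2")},
            froger_positions={k: pos[k] for k in ("P1", "P2", "P3", "P4", "P5")},
            tmd_spans=tuple(spans),
        )
        annotations[labels[str(rid)][0]] = ann
    return proteins, labels, annotations


def _gene_names(assignments: Mapping[str, SubfamilyAssignment]) -> dict[str, str]:
    """Published names from the packaged nomenclature table when the locus
    is known there; otherwise systematic subgroup-based names."""
    lookup: dict[str, str] = {}
    table = importlib.resources.files("aquafam.data") / "tomato_gene_names.tsv"
    with table.open() as fh:
        next(fh)
        for line in fh:
            locus, name = line.rstrip("\n").split("\t")
            lookup[locus] = name
    names: dict[str, str] = {}
    counters: dict[str, int] = {}
    for locus in sorted(assignments):
        if locus in lookup:
            names[locus] = lookup[locus]
            continue
        a = assignments[locus]
        group = a.subgroup or a.subfamily
        counters[group] = counters.get(group, 0) + 1
        names[locus] = f"{group};{counters[group]}"
    return names


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run scan -> EST reconciliation -> MSA -> NJ+bootstrap -> assignment
    -> topology -> residues -> exon summary -> tandem clusters, writing
    all reports under ``cfg.outdir``.

    Deterministic: rerunning with an identical config and seed produces
    byte-identical report files.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome = read_fasta(cfg.proteome, "aa")
    panel_proteins, panel_labels, panel_annotations = load_panel(cfg)

    seeds = {fam: ann.protein for fam, ann in sorted(panel_annotations.items())}
    hits = scan_proteome(proteome, seeds, cfg.scan)
    accepted = sorted(h.locus for h in hits if h.accepted)
    by_id = {p.id: p for p in proteome}

    # EST reconciliation (optional)
    reconciliations: dict[str, EstReconciliation] = {}
    corrected: dict[str, ProteinRecord] = {}
    if not cfg.skip_est and cfg.ests and cfg.cds:
        cds_records = [c for c in read_fasta(cfg.cds, "nt")
                       if c.id in set(accepted)]
        ests = read_fasta(cfg.ests, "nt")
        matched = match_ests_to_loci(cds_records, ests)
        for locus in sorted(matched):
            rec = reconcile_est(next(c for c in cds_records if c.id == locus),
                                matched[locus])
            reconciliations[locus] = rec
            if rec.verdict == "artifact_corrected":
                aa = str(Seq(rec.corrected_orf.sequence).translate()).rstrip("*")
                corrected[locus] = ProteinRecord(id=locus, sequence=aa,
                                                 locus=locus)

    queries = [corrected.get(locus, by_id[locus]) for locus in accepted]
    msa_input = queries + [panel_proteins[r] for r in sorted(panel_labels)]
    msa = progressive_msa(msa_input, cfg.scoring)
    tree = bootstrap_support(msa, n=cfg.bootstrap_n, seed=cfg.seed)

    assignments = {
        locus: assign_subfamily(tree, panel_labels, locus) for locus in accepted
    }
    names = _gene_names(assignments)

    models = read_gff_gene_models(cfg.gff)
    fam_of = {locus: a.subfamily for locus, a in assignments.items()}
    exon_summary = summarize_exon_structure(models, fam_of)
    clusters = find_tandem_clusters(models, set(accepted), cfg.tandem_gap)

    rows: list[FamilyReportRow] = []
    annotations_out: dict[str, dict] = {}
    default_ann = panel_annotations[sorted(panel_annotations)[0]]
    for locus in accepted:
        protein = corrected.get(locus, by_id[locus])
        a = assignments[locus]
        topo = predict_tmds(protein, cfg.hydropathy)
        npa = find_npa_motifs(protein, topo, cfg.residues)
        ann = panel_annotations.get(a.subfamily, default_ann)
        arr = transfer_positions(protein, ann, "arR", cfg.scoring)
        froger = transfer_positions(protein, ann, "froger", cfg.scoring)
        phospho = find_phospho_sites(protein, cfg.residues)
        spec = classify_specificity(arr, cfg.residues)
        npa_by_loop = {m.loop: m for m in npa}
        comments = []
        rec = reconciliations.get(locus)
        if rec is not None and rec.verdict == "artifact_corrected":
            comments.append("EST frameshift corrected")
        rows.append(FamilyReportRow(
            gene_name=names[locus], locus=locus, subfamily=a.subfamily,
            subgroup=a.subgroup, length_aa=protein.length_aa, n_tmd=topo.n_tmd,
            npa_motifs=(
                (npa_by_loop["B"].extended or npa_by_loop["B"].motif)
                if "B" in npa_by_loop else None,
                (npa_by_loop["E"].extended or npa_by_loop["E"].motif)
                if "E" in npa_by_loop else None,
            ),
            arR=arr.letters(), froger=froger.letters(),
            specificity=spec.call, comments="; ".join(comments),
        ))
        annotations_out[locus] = {
            "topology": topo, "npa": npa, "arr": arr, "froger": froger,
            "phospho": phospho, "specificity": spec,
        }

    outputs = _write_reports(cfg, outdir, hits, reconciliations, assignments,
                             names, rows, tree, exon_summary, clusters, by_id)
    return PipelineResult(
        hits=hits, assignments=assignments, reconciliations=reconciliations,
        msa=msa, tree=tree, exon_summary=exon_summary, clusters=clusters,
        rows=rows, outputs=outputs,
    )


def _write_reports(cfg, outdir, hits, reconciliations, assignments, names,
                   rows, tree, exon_summary, clusters, by_id) -> dict[str, Path]:
    outputs = {
        "family_table": outdir / "family_table.tsv",
        "residues": outdir / "residues.tsv",
        "tree": outdir / "tree.nwk",
        "exon_summary": outdir / "exon_summary.tsv",
        "clusters": outdir / "clusters.tsv",
        "scan": outdir / "scan_hits.tsv",
        "log": outdir / "run_log.txt",
    }
    with open(outputs["family_table"], "w") as fh:
        fh.write("gene_name\tlocus\tsubfamily\tsubgroup\tbest_hit_est\t"
                 "est_verdict\tlength_aa\tn_tmd\tcomments\n")
        for row in rows:
            rec = reconciliations.get(row.locus)
            est_id = rec.est_id if rec else "-"
            verdict = rec.verdict if rec else "-"
            fh.write(f"{row.gene_name}\t{row.locus}\t{row.subfamily}\t"
                     f"{row.subgroup or '-'}\t{est_id}\t{verdict}\t"
                     f"{row.length_aa}\t{row.n_tmd}\t{row.comments}\n")
    write_feature_table(rows, outputs["residues"])
    write_newick(tree, outputs["tree"])
    with open(outputs["exon_summary"], "w") as fh:
        fh.write("subfamily\tmodal_exons\texceptions\n")
        for fam in sorted(exon_summary.modal_counts):
            exc = ";".join(f"{l}:{n}" for l, n in exon_summary.exceptions[fam])
            fh.write(f"{fam}\t{exon_summary.modal_counts[fam]}\t{exc or '-'}\n")
    with open(outputs["clusters"], "w") as fh:
        fh.write("chromosome\tn_loci\tloci\tmax_gap\n")
        for c in clusters:
            fh.write(f"{c.chromosome}\t{len(c.loci)}\t{','.join(c.loci)}\t"
                     f"{c.max_gap}\n")
    with open(outputs["scan"], "w") as fh:
        fh.write("locus\tbest_seed\tbest_subfamily\tscore\tnormalized_score\t"
                 "accepted\n")
        for h in sorted(hits, key=lambda h: h.locus):
            fh.write(f"{h.locus}\t{h.best_seed or '-'}\t{h.best_subfamily or '-'}\t"
                     f"{h.score:g}\t{h.normalized_score:.4f}\t{int(h.accepted)}\n")
    with open(outputs["log"], "w") as fh:
        fh.write("aquafam pipeline run\n")
        fh.write(f"seed={cfg.seed}\nbootstrap_n={cfg.bootstrap_n}\n")
        fh.write(f"scan_threshold={cfg.scan.threshold}\n")
        fh.write(f"gap_open={cfg.scoring.gap_open}\n")
        fh.write(f"gap_extend={cfg.scoring.gap_extend}\n")
        fh.write(f"hydropathy_window={cfg.hydropathy.window}\n")
        fh.write(f"hydropathy_threshold={cfg.hydropathy.threshold}\n")
        fh.write(f"tandem_gap={cfg.tandem_gap}\n")
        fh.write(f"n_proteome={len(by_id)}\n")
        fh.write(f"n_accepted={len(assignments)}\n")
    return outputs
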