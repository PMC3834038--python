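# aquafam

Genome-wide identification and annotation of plant aquaporin (MIP)
families, packaged as a reusable, fully offline-testable pipeline.

Aquaporins — major intrinsic proteins (MIPs) — are six-transmembrane
channel proteins that move water and small solutes (glycerol, urea,
H₂O₂, B, Si) across membranes. Plant genomes carry 30–70 of them in
five subfamilies (PIP, TIP, NIP, SIP, XIP), and surveying a newly
sequenced genome for its MIP complement is a standard annotation task:
find every candidate locus in the predicted proteome, verify gene
models against EST/cDNA evidence, classify members phylogenetically,
and read off the residues that determine substrate specificity. This
package implements that entire workflow, plus a synthetic-data
generator that plants every feature with known ground truth so the
whole stack is testable without any downloads.

## What it computes

- **Candidate scan** — every proteome entry is globally aligned
  (BLOSUM62, affine gaps, Needleman–Wunsch/Gotoh) against one seed per
  subfamily after a shared-k-mer prefilter; a locus is accepted when its
  score per aligned column exceeds a threshold.
- **EST reconciliation** — global nucleotide alignment of the most
  similar EST to each model CDS; indels are enumerated, a net indel
  length ≢ 0 (mod 3) flags a frameshift, and a lone 1-bp insertion that
  breaks the ORF is corrected away as a cloning artifact.
- **Phylogenetic classification** — progressive multiple alignment on a
  neighbor-joining guide tree; NJ (Saitou–Nei Q-criterion, exact on
  additive distances) over p-distances; bootstrap support by column
  resampling; subfamily/subgroup assignment by the smallest
  monophyletic clade shared with a labeled reference panel, falling
  back to minimum patristic distance.
- **Topology** — Kyte–Doolittle hydropathy in a 19-residue sliding
  window (threshold 1.6) yields transmembrane spans; inter-helix loops
  are labeled A–E, exposing loop B (TMD2–3) and loop E (TMD5–6).
- **Specificity residues** — the two NPA motifs (with degenerate
  variants NPS/NPT/NPV/NPI/NPL/SPV and the XIP-type NPARC extension)
  are located inside loops B and E; the ar/R selectivity filter
  (H2, H5, LE1, LE2) and the five Froger positions P1–P5 are mapped by
  alignment transfer from an annotated reference; C-terminal S-x-R
  (PKC) and CDPK-style phosphorylation motifs are scanned; the filter's
  mean (hydropathy, side-chain volume) point is compared against a
  water-channel exemplar (F,H,T,R) and an aquaglyceroporin exemplar
  (T,G,F,R) to call water vs. solute transport.
- **Gene structure** — modal exon counts per subfamily with exceptions,
  and tandem-duplication clusters from inter-locus distances.

## Worked example

Generate a synthetic study (47 members sized 14/11/12/4/6 across the
five subfamilies, 200 decoys, ESTs with occasional planted 1-bp
insertions) and run the full pipeline on it:

```sh
aquafam synth --seed 3 --out data
aquafam run --config config.yaml      # paths to the generated files
```

which prints `accepted 47 loci; reports in out/` and writes
`family_table.tsv`, `residues.tsv`, `tree.nwk`, `exon_summary.tsv`,
`clusters.tsv` and `scan_hits.tsv`. The family table starts:

```
gene_name  locus           subfamily  subgroup  best_hit_est       est_verdict     length_aa  n_tmd
NIP1;1     synloc_NIP_01   NIP        NIP1      synloc_NIP_01_EST  confirms_model  277        6
NIP1;2     synloc_NIP_02   NIP        NIP1      synloc_NIP_02_EST  confirms_model  277        6
```

i.e. every accepted locus with its clade-derived subfamily/subgroup,
the EST verdict (`confirms_model`, `revises_model`, or
`artifact_corrected` for repaired frameshifts), and six detected
transmembrane helices. The exon summary reports the planted modal
counts (PIP 4, TIP 3, NIP 5, SIP 3, XIP 3) with no exceptions, and
`clusters.tsv` contains the one planted tandem array: six XIP loci
adjacent on chromosome `ch10`.

In the library, the classic structural anchors behave as the
literature describes: transferring the annotated ar/R positions of the
AQP1-style water exemplar onto itself returns F/H/C/R at residues
58/182/191/197, and

```python
>>> classify_specificity(arr_filter(("F", "H", "T", "R")))
SpecificityCall(call='water', score_water=0.0, score_solute=0.159, ...)
>>> classify_specificity(arr_filter(("I", "T", "A", "R")))   # XIP-style
SpecificityCall(call='solute', score_water=0.228, score_solute=0.109, ...)
```

## Layout

```
src/aquafam/
  seqio.py      domain types; FASTA/GFF3/Newick/TSV I/O
  align.py      Gotoh global alignment, p-distances, progressive MSA
  phylo.py      neighbor joining, bootstrap, clade assignment
  tree.py       tree container, bipartitions, Newick round-trip
  topology.py   hydropathy TMD prediction, loop labeling
  residues.py   NPA / ar/R / Froger / phospho / specificity
  pipeline.py   scan, EST reconciliation, exon & tandem analysis, orchestration
  hmm_scan.py   optional pyhmmer profile-search scan backend
  synth.py      ground-truthed synthetic family generator
  reference.py  synthetic annotated exemplar scaffolds
  cli.py        aquafam synth|run|scan|reconcile|classify|annotate
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
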