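# Methods

This note documents the models and procedures implemented in aquafam,
the parameter defaults and why they were chosen, what the synthetic
data does and does not emulate, and the numerical conventions that pin
down deterministic behavior.

## Pairwise alignment and distances

Global alignment uses the three-state affine-gap dynamic program
(match state plus one insertion state per sequence) with BLOSUM62 and
gap open 10 / gap extension 1 — the CLUSTAL-era defaults, configurable
via `ScoringParams`. A gap of length L costs `open + (L−1)·extend`.
Transitions between the two gap states are allowed at full opening
cost, so the optimum is taken over *all* monotone alignments; with a
large opening penalty this matters only in corner cases, but it is what
makes the aligner provably equal to exhaustive enumeration, which the
test suite checks on short sequences. Traceback tie-breaking is fixed:
diagonal, then vertical (gap in the second sequence), then horizontal.
Scores are integer-valued sums in double precision, so equality
comparisons in the traceback are exact.

Sequence distances are p-distances (mismatches over shared non-gap
columns). A Poisson correction `−ln(1−p)` is available but off by
default: at the divergences the pipeline operates on, the correction
changes no topology-level result, and the uncorrected distance is the
simplest reproducible choice. A pair with zero shared columns is an
error in direct use; inside bootstrap replicates it is assigned the
maximal distance 1 so a replicate cannot abort a run.

The progressive aligner builds an NJ guide tree from pairwise
p-distances and merges profiles leaf-to-root. Profile–profile column
scores are average-of-pairs substitution scores over the non-gap
residues (gap pairs contribute zero), with the same affine penalties.

## Neighbor joining and bootstrap

NJ follows the Saitou–Nei agglomeration on the Q criterion with the
standard two-point branch-length formulas. Determinism conventions:

- Q ties are broken by the lexicographically smallest pair of cluster
  representatives (a cluster is represented by its minimal leaf label).
- A negative branch length is clamped to zero and its deficit moved to
  the sibling edge, preserving the joined pair's distance.
- The output is unrooted, stored with one trifurcating root.

On additive matrices NJ is exact; the suite verifies recovery on random
additive matrices and, for six taxa, agreement with exhaustive ordinary
least-squares search over all 105 unrooted topologies.

Bootstrap support resamples alignment columns with replacement
(seeded generator), rebuilds the NJ tree per replicate, and counts how
many replicates contain each internal edge's leaf bipartition. For the
degenerate all-identical alignment every resolution is arbitrary, so
supports are pinned to zero. The pipeline default is 100 replicates —
enough to separate real clades from noise on the synthetic study at a
few seconds' cost; publication-scale figures conventionally use 1000,
available via `--bootstrap-n`.

Subfamily assignment looks for the smallest edge-induced clade
containing the query and at least one reference where all contained
references carry a single subfamily label; if none exists the nearest
reference by patristic distance decides, and the method used is
recorded in the output. Subgroups are resolved the same way within the
assigned subfamily's references.

## Transmembrane topology

The predictor is windowed Kyte–Doolittle hydropathy: window 19,
threshold 1.6 mean hydropathy, runs of above-threshold window centers
merged across gaps of at most 3 residues, minimum helix length 15 —
the classic literature settings for membrane-helix detection. Window
centers under-cover the helix ends by up to half a window, so each run
is grown outward over residues of positive hydropathy and then trimmed
so both span ends are hydrophobic. Unknown residues (X) score zero.
A sequence shorter than the window yields an empty annotation with a
warning.

Inter-helix loops are labeled A–E in order; loop B is defined only when
helices 2 and 3 exist, loop E only when helices 5 and 6 exist, so
truncated proteins naturally lose the corresponding NPA search windows.
A hydrophilic specificity residue planted near a helix terminus can
clip the predicted span by a few residues; span coordinates are
therefore treated as approximate (±3) everywhere downstream, while
helix *count* is the robust signal. This is a sliding-window
hydropathy method, not an HMM topology model: per-protein helix counts
from HMM-based predictors will occasionally differ, and only the modal
count (six for the MIP fold) is treated as meaningful.

## Specificity residues

NPA motifs are matched as X-P-Z with X ∈ {N,S} and Z ∈ {A,S,T,V,I,L} —
the alphabet spanning the degenerate variants observed across plant
NIP/SIP/XIP members — searching loop B and loop E padded by 5 residues;
the canonical NPA is preferred over variants, earlier positions win
ties, and an R,C at offsets +3,+4 is reported as the five-residue
NPARC extension typical of XIPs. Without usable topology the whole
sequence is scanned and the two best-separated sites reported.

ar/R filter (H2, H5, LE1, LE2) and Froger (P1–P5) residues are defined
structurally, not by local context, so they are located by *alignment
transfer*: the query is globally aligned to one annotated reference per
subfamily and the annotated coordinates are mapped through the
alignment; reference columns that land on query gaps yield nulls (the
truncated-protein case, rendered "-" in reports). Transfer is exact
under identity and terminal extension, which the suite verifies.

Substrate-specificity calls compare the filter's *aggregate* character
— the mean of the four residues' normalized (Kyte–Doolittle
hydropathy, Zamyatnin side-chain volume) embeddings — against the
water-channel exemplar F,H,T,R (the plant PIP configuration) and the
aquaglyceroporin exemplar T,G,F,R. The aggregate is used rather than a
per-position score because the discriminating physics is overall pore
size and polarity; position-matched distances would, for instance, call
the hydrophobic XIP filter I,T,A,R water-like merely because I and F
are similar residues. Distances to both exemplars are reported; a
margin below 5% of the exemplar separation, or any null residue, gives
`ambiguous`. Measuring the band relative to the exemplar separation
makes the call invariant to a common rescaling of the embedding axes.
Borderline filters (e.g. the NIP-type W,V,A,R) deliberately land in
the ambiguous band, matching their described mixed water/solute
capability.

Phosphorylation motifs are scanned in the C-terminal 15 residues:
PKC recognition defaults to S-x-R (the S-x-A variant is selectable in
config, since both appear in the literature); the CDPK recognition
site has no single published consensus at this granularity, so the
default is the basophilic [RK]-x-x-S pattern, also a config value.
The PIP1-vs-PIP2 diagnostic residues (Q vs L/V before helix 2, I vs V
after the second NPA) are reported as descriptive evidence only — the
tree, not these residues, assigns subgroups.

## Candidate scan and EST reconciliation

The scan aligns each proteome entry to one seed per subfamily after a
shared-4-mer prefilter (≥10 shared k-mers); acceptance uses score per
aligned column ≥ 1.0. The threshold was calibrated once on the
synthetic decoy battery: planted family members score ≥3 per column
against their subfamily seed while random decoys never survive the
prefilter, so the margin is wide in both directions. An optional
profile-HMM backend (pyhmmer, one HMM per subfamily built from the
panel) emits the same hit records and serves as a robustness
cross-check; it is off by default.

EST reconciliation globally aligns the chosen EST to the model CDS with
unit nucleotide scores (match +2, mismatch −3, gap open 5 / extend 2,
N neutral), enumerates indels, and flags a frameshift when the net
indel length is not divisible by three. A lone 1-bp insertion — the
classic cDNA cloning artifact, typically producing a premature stop —
is corrected by deletion whenever the repaired sequence translates
without internal stops; the premature stop position is reported when
present but is not a precondition, since an insertion near the 3' end
shifts the frame without creating one. EST-to-locus matching takes the
EST sharing the most 12-mers with the CDS (ties to the longest EST,
then lexicographic id), requiring at least 20% of the CDS k-mers so a
locus without real evidence stays unmatched rather than borrowing a
paralog's transcript.

Exon-structure summaries report the modal exon count per subfamily
(ties resolved to the smaller mode) with deviating loci listed.
Tandem clusters are maximal same-chromosome runs of accepted loci with
inter-locus gaps ≤ 100 kb — "adjacent" is not a sharp number in the
literature, and 100 kb comfortably covers local duplication arrays
while excluding unrelated neighbors at the gene densities involved.

## Synthetic data: what it emulates, and what it does not

The generator builds one scaffold per subfamily: six 21-residue
hydrophobic segments (alphabet LIVFAM) separated by hydrophilic loops
(alphabet DENQKRSTGH), with the NPA motifs, ar/R letters, Froger
letters and C-terminal kinase motifs planted at recorded coordinates.
The loop alphabet excludes P, C, W and Y, so an NPA-type motif cannot
arise in a loop by chance and planted motifs are the unique solutions.
Subgroup consensuses diverge from the subfamily scaffold at rate 0.15
and members from their subgroup consensus at rate 0.05 — within- and
between-group divergences that give clean subfamily clades while
keeping members distinguishable, comparable to real MIP families.
Substitutions are category-preserving (hydrophobic positions stay
hydrophobic) and planted positions are protected with probability 1 by
default; a stress mode lowers that to measure recovery degradation.
Defaults mirror the published tomato family: subfamily sizes
14/11/12/4/6 (PIP split 5+9 into PIP1/PIP2), exon plans PIP 4 / TIP 3 /
NIP 5 / SIP 3 / XIP 3, the XIP loci as a tandem array on one
chromosome, 200 decoys, EST coverage 0.75 with a 5% chance of a planted
1-bp insertion per EST. CDSs are back-translated with uniform
synonymous codon choice; GFF exons split each CDS per the plan.
Everything is bit-reproducible from the seed, and generation self-audits
(planted letters, translations and exon sums are re-checked against the
emitted files).

Deliberately *not* emulated: insertions/deletions along the tree (all
members of a subfamily share coordinates — real families need the
alignment transfer to absorb indels, which the terminal-extension and
truncation tests cover only in part), rate heterogeneity across sites,
codon usage bias, alternative splicing, and sequencing error beyond the
single planted insertions. Passing tests on this generator therefore
demonstrates the correctness of the machinery under the stated
statistical structure, not performance on diverged real proteomes.

The packaged reference panel and the AQP1/GlpF-style exemplar
scaffolds are synthetic stand-ins built by the same machinery, labeled
as such in their filenames and docstrings; the panel file formats
(FASTA + label TSV + position-annotation TSV) accept a curated panel of
real annotated MIPs without code changes.

## Problem sizes and determinism

The default acceptance computation regenerates the full synthetic study
(247 proteins), aligns 65 sequences progressively, runs a 100-replicate
bootstrap, evaluates 200 additive NJ instances (least-squares checked
on the 6-taxon ones), 50 brute-force alignment pairs, 100 frameshift
round trips, and a duplicate end-to-end pipeline run at 25 bootstrap
replicates for the byte-identity check. All randomness flows from a
single seed through `numpy.random.default_rng`; reports contain no
timestamps, and iteration orders are sorted, which together make rerun
outputs byte-identical.
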