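"""Specificity-determining residue extraction for MIP-family proteins.

Four kinds of sites are reported per protein: the two NPA motifs of
loops B and E (with the degenerate variants seen across plant NIP, SIP
and XIP members and the five-residue NPARC extension typical of XIPs),
the four-residue aromatic/arginine (ar/R) selectivity filter
(helix 2, helix 5, and two loop-E positions), the five Froger
discriminant positions P1..P5, and C-terminal kinase recognition motifs.
ar/R and Froger residues are located by alignment transfer from an
annotated reference protein rather than by motif search, because these
positions are defined structurally, not by local sequence context.

Substrate specificity is called by embedding the four ar/R residues in a
(hydropathy, side-chain volume) plane and comparing mean distance to a
water-channel exemplar filter (F,H,T,R - the plant PIP configuration)
and an aquaglyceroporin exemplar (T,G,F,R, as in GlpF-type channels).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .align import ScoringParams, global_align
from .seqio import ProteinRecord, ReferenceAnnotation
from .topology import KYTE_DOOLITTLE, TopologyAnnotation

#: Degenerate first/third NPA letters observed across plant MIP subfamilies.
NPA_X = "NS"
NPA_Z = "ASTVIL"
_NPA_RE = re.compile(f"[{NPA_X}]P[{NPA_Z}]")

#: Amino-acid side-chain volumes (A^3), Zamyatnin's consensus values.
SIDE_CHAIN_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0, "X": 140.0,
}

WATER_EXEMPLAR = ("F", "H", "T", "R")
SOLUTE_EXEMPLAR = ("T", "G", "F", "R")


@dataclass(frozen=True)
class NpaMotif:
    start: int  # 1-based position of the first motif letter
    motif: str
    loop: Literal["B", "E"]
    extended: str | None = None

    def __post_init__(self) -> None:
        if not _NPA_RE.fullmatch(self.motif):
            raise ValueError(f"{self.motif!r} is not an NPA-type motif")
        if self.extended is not None and not self.extended.startswith(self.motif):
            raise ValueError("extension must start with the 3-letter motif")

    @property
    def canonical(self) -> bool:
        return self.motif == "NPA"


@dataclass(frozen=True)
class ArRFilter:
    """ar/R filter letters and their 1-based query positions (nullable)."""

    residues: dict[str, str | None]
    positions: dict[str, int | None]

    LABELS = ("H2", "H5", "LE1", "LE2")

    def __post_init__(self) -> None:
        _check_labeled_group(self.residues, self.positions, self.LABELS)

    def letters(self) -> tuple[str | None, ...]:
        return tuple(self.residues[k] for k in self.LABELS)


@dataclass(frozen=True)
class FrogerPositions:
    residues: dict[str, str | None]
    positions: dict[str, int | None]

    LABELS = ("P1", "P2", "P3", "P4", "P5")

    def __post_init__(self) -> None:
        _check_labeled_group(self.residues, self.positions, self.LABELS)

    def letters(self) -> tuple[str | None, ...]:
        return tuple(self.residues[k] for k in self.LABELS)


def _check_labeled_group(residues, positions, labels) -> None:
    if set(residues) != set(labels) or set(positions) != set(labels):
        raise ValueError(f"labels must be exactly {labels}")
    filled = [positions[k] for k in labels if positions[k] is not None]
    if any(a >= b for a, b in zip(filled, filled[1:])):
        raise ValueError("non-null positions must be strictly increasing")


@dataclass(frozen=True)
class PhosphoSites:
    sites: tuple[tuple[int, str], ...]  # (1-based motif start, motif name)
    window: tuple[int, int]  # searched C-terminal interval


@dataclass(frozen=True)
class SpecificityCall:
    call: Literal["water", "solute", "ambiguous"]
    score_water: float | None
    score_solute: float | None
    margin: float | None


@dataclass(frozen=True)
class ResidueParams:
    loop_margin: int = 5
    pkc_motif: str = "S.R"  # the S-X-A variant is selectable here
    cdpk_motif: str = "[RK]..S"
    cterm_window: int = 15
    ambiguity_threshold: float = 0.05
    hydropathy_range: tuple[float, float] = (-4.5, 4.5)
    volume_range: tuple[float, float] = (60.1, 227.8)


# ---------------------------------------------------------------------------
# NPA motifs


def _sites_in(seq: str, lo: int, hi: int) -> list[tuple[int, str]]:
    """All X-P-Z sites starting within [lo, hi] (1-based, inclusive)."""
    out = []
    for m in _NPA_RE.finditer(seq):
        pos = m.start() + 1
        if lo <= pos <= hi:
            out.append((pos, m.group()))
    return out


def _best_site(sites: list[tuple[int, str]]) -> tuple[int, str] | None:
    """Prefer canonical NPA over variants, earliest position on ties."""
    if not sites:
        return None
    return min(sites, key=lambda s: (s[1] != "NPA", s[0]))


def _extend(seq: str, pos: int, motif: str) -> str | None:
    """Detect the XIP-style NPARC extension: +3,+4 are R,C."""
    tail = seq[pos + 2: pos + 4]
    if tail == "RC":
        return motif + "RC"
    return None


def find_npa_motifs(
    p: ProteinRecord,
    topo: TopologyAnnotation | None = None,
    params: ResidueParams | None = None,
) -> list[NpaMotif]:
    """Locate the loop-B and loop-E NPA-type motifs.

    With topology available, the best-matching site inside each loop
    (padded by ``loop_margin``) is reported.  Without usable loops the
    whole sequence is scanned and the two best-separated sites reported,
    the N-terminal one labeled B.  A single detected site is labeled by
    which half of the sequence it falls in.
    """
    params = params or ResidueParams()
    seq = p.sequence
    out: list[NpaMotif] = []
    loops_known = topo is not None and (topo.loop_B or topo.loop_E)
    if loops_known:
        for label in ("B", "E"):
            interval = topo.loops.get(label)
            if interval is None:
                continue
            lo = max(1, interval[0] - params.loop_margin)
            hi = min(len(seq), interval[1] + params.loop_margin)
            best = _best_site(_sites_in(seq, lo, hi))
            if best is not None:
                pos, motif = best
                out.append(NpaMotif(start=pos, motif=motif, loop=label,
                                    extended=_extend(seq, pos, motif)))
        return out
    sites = _sites_in(seq, 1, len(seq))
    if not sites:
        return []
    if len(sites) == 1:
        pos, motif = sites[0]
        loop = "B" if pos <= len(seq) // 2 else "E"
        return [NpaMotif(start=pos, motif=motif, loop=loop,
                         extended=_extend(seq, pos, motif))]
    # two best-separated sites: maximize canonical count, then separation
    best_pair = max(
        (
            ((a[1] == "NPA") + (b[1] == "NPA"), b[0] - a[0], -a[0], a, b)
            for i, a in enumerate(sites)
            for b in sites[i + 1:]
        ),
    )
    a, b = best_pair[3], best_pair[4]
    for site, loop in ((a, "B"), (b, "E")):
        out.append(NpaMotif(start=site[0], motif=site[1], loop=loop,
                            extended=_extend(seq, site[0], site[1])))
    return out


# ---------------------------------------------------------------------------
# Alignment transfer of ar/R and Froger positions


def transfer_positions(
    query: ProteinRecord,
    ref: ReferenceAnnotation,
    which: Literal["arR", "froger"],
    params: ScoringParams | None = None,
) -> ArRFilter | FrogerPositions:
    """Map annotated reference positions onto the query via global alignment.

    Reference columns that align to a query gap yield null residue and
    position (the truncated-protein case rendered '-' in reports).
    """
    ann = ref.arR_positions if which == "arR" else ref.froger_positions
    aln = global_align(ref.protein, query, params)
    ref_row, q_row = aln.rows
    pos_map: dict[int, int | None] = {}
    rp = qp = 0
    for rc, qc in zip(ref_row, q_row):
        if qc != "-":
            qp += 1
        if rc != "-":
            rp += 1
            pos_map[rp] = qp if qc != "-" else None
    residues: dict[str, str | None] = {}
    positions: dict[str, int | None] = {}
    for label, ref_pos in ann.items():
        q_pos = pos_map.get(ref_pos)
        positions[label] = q_pos
        residues[label] = query.sequence[q_pos - 1] if q_pos else None
    cls = ArRFilter if which == "arR" else FrogerPositions
    return cls(residues=residues, positions=positions)


# ---------------------------------------------------------------------------
# Phosphorylation motifs


def find_phospho_sites(p: ProteinRecord, params: ResidueParams | None = None) -> PhosphoSites:
    """Scan the C-terminal window for kinase recognition motifs.

    Defaults: PKC recognition S-x-R and a basophilic CDPK-style
    [RK]-x-x-S, both searched in the last ``cterm_window`` residues.
    Positions are 1-based full-sequence coordinates of the motif start.
    """
    params = params or ResidueParams()
    seq = p.sequence
    lo = max(1, len(seq) - params.cterm_window + 1)
    tail = seq[lo - 1:]
    sites: list[tuple[int, str]] = []
    for name, pattern in (("PKC", params.pkc_motif), ("CDPK", params.cdpk_motif)):
        for m in re.finditer(pattern, tail):
            sites.append((lo + m.start(), name))
    sites.sort()
    return PhosphoSites(sites=tuple(sites), window=(lo, len(seq)))


# ---------------------------------------------------------------------------
# Substrate-specificity call


def _embed(residue: str, params: ResidueParams) -> np.ndarray:
    h_lo, h_hi = params.hydropathy_range
    v_lo, v_hi = params.volume_range
    return np.array([
        (KYTE_DOOLITTLE[residue] - h_lo) / (h_hi - h_lo),
        (SIDE_CHAIN_VOLUME[residue] - v_lo) / (v_hi - v_lo),
    ])


def classify_specificity(f: ArRFilter, params: ResidueParams | None = None) -> SpecificityCall:
    """Call water vs solute transport from the ar/R filter composition.

    The discriminating signal is the *overall* character of the
    constriction - water-channel filters are larger and more
    hydrophilic, aquaglyceroporin filters smaller and more hydrophobic -
    so the four residues are summarized by their mean normalized
    (hydropathy, side-chain volume) point and scored by Euclidean
    distance to the water exemplar (F,H,T,R) and the aquaglyceroporin
    exemplar (T,G,F,R).  Aggregating before measuring keeps the call
    driven by filter chemistry rather than by which position carries
    which residue.  Any null residue, or a margin small relative to the
    exemplar separation, yields ``ambiguous``; the all-null filter has
    null scores too.
    """
    params = params or ResidueParams()
    letters = f.letters()
    if all(x is None for x in letters):
        return SpecificityCall(call="ambiguous", score_water=None,
                               score_solute=None, margin=None)
    present = [(x, w, s) for x, w, s in zip(letters, WATER_EXEMPLAR, SOLUTE_EXEMPLAR)
               if x is not None]

    def centroid(column: int) -> np.ndarray:
        return np.mean([_embed(t[column], params) for t in present], axis=0)

    q, w, s = centroid(0), centroid(1), centroid(2)
    dw = float(np.linalg.norm(q - w))
    ds = float(np.linalg.norm(q - s))
    margin = ds - dw  # positive: closer to the water exemplar
    # the ambiguity band scales with the exemplar separation, so the call
    # is invariant to a common rescaling of the embedding axes
    sep = float(np.linalg.norm(w - s))
    if any(x is None for x in letters) or abs(margin) < params.ambiguity_threshold * sep:
        call = "ambiguous"
    else:
        call = "water" if margin > 0 else "solute"
    return SpecificityCall(call=call, score_water=dw, score_solute=ds, margin=margin)


# ---------------------------------------------------------------------------
# PIP1-vs-PIP2 diagnostic residues (descriptive evidence, not a classifier)


def pip_subgroup_evidence(
    p: ProteinRecord,
    topo: TopologyAnnotation,
    npa_motifs: list[NpaMotif],
) -> dict[str, str | None]:
    """Report the residues at the classic PIP1/PIP2 diagnostic sites.

    PIP1 members carry Q just before helix 2 and I after the second NPA
    motif; PIP2 members carry L/V and V respectively (the latter linked
    to higher water transport activity in mutagenesis work).  The tree,
    not this table, assigns subgroups; this is supporting evidence.
    """
    out: dict[str, str | None] = {"pre_TMD2": None, "post_NPA2": None}
    if topo.n_tmd >= 2:
        pos = topo.tmd_spans[1][0] - 1
        if pos >= 1:
            out["pre_TMD2"] = p.sequence[pos - 1]
    npa2 = next((m for m in npa_motifs if m.loop == "E"), None)
    if npa2 is not None and npa2.start + 3 <= len(p.sequence):
        out["post_NPA2"] = p.sequence[npa2.start + 2]  # residue after the motif
    return out
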