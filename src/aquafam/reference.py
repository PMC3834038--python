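"""Synthetic annotated exemplar references for position transfer.

The two classic structural anchors for aquaporin specificity are the
water channel human AQP1, whose ar/R filter is written F58-H182-C191-R197,
and the aquaglyceroporin GlpF with the smaller, more hydrophobic filter
T48-G191-F200-R205.  The real proteins cannot be redistributed here, so
this module builds *synthetic* stand-ins: MIP-fold scaffolds (six
hydrophobic helices, NPA motifs in loops B and E) carrying exactly those
filter letters at exactly those literature coordinates.  Position
transfer, specificity calls and their tests all run against these
scaffolds; swapping in a curated FASTA + annotation table of the real
proteins requires no code change.
"""

from __future__ import annotations

import numpy as np

from .seqio import ProteinRecord, ReferenceAnnotation
from .synth import LOOP_ALPHABET, TM_ALPHABET


def _build(segments: list[tuple[str, int]], plants: dict[int, str],
           seed: int) -> tuple[str, dict[str, tuple[int, int]]]:
    rng = np.random.default_rng(seed)
    chars: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    for name, length in segments:
        start = len(chars) + 1
        alphabet = TM_ALPHABET if name.startswith("TM") else LOOP_ALPHABET
        chars.extend(rng.choice(list(alphabet), size=length))
        spans[name] = (start, len(chars))
    for pos, letters in plants.items():
        if not 1 <= pos <= len(chars) - len(letters) + 1:
            raise ValueError(f"planted position {pos} outside scaffold")
        for k, c in enumerate(letters):
            chars[pos - 1 + k] = c
    return "".join(chars), spans


def water_exemplar_annotation() -> ReferenceAnnotation:
    """Synthetic water-channel exemplar with the hAQP1 filter coordinates.

    The ar/R letters F, H, C, R sit at positions 58, 182, 191 and 197 of
    a 249-residue six-helix scaffold; NPA motifs occupy 76-78 (loop B)
    and 192-194 (loop E), matching the canonical AQP1 numbering.
    """
    segments = [
        ("nterm", 12), ("TM1", 21), ("loopA", 15), ("TM2", 21),
        ("loopB", 20), ("TM3", 21), ("loopC", 15), ("TM4", 21),
        ("loopD", 15), ("TM5", 21), ("loopE", 24), ("TM6", 21), ("cterm", 22),
    ]
    froger = {116: "M", 199: "S", 201: "A", 211: "F", 218: "W"}
    plants = {58: "F", 76: "NPA", 182: "H", 191: "C", 192: "NPA", 197: "R"}
    plants.update(froger)
    seq, spans = _build(segments, plants, seed=20131)
    protein = ProteinRecord(id="hAQP1_like_synthetic", sequence=seq)
    return ReferenceAnnotation(
        protein=protein, npa1_pos=76, npa2_pos=192,
        arR_positions={"H2": 58, "H5": 182, "LE1": 191, "LE2": 197},
        froger_positions={"P1": 116, "P2": 199, "P3": 201, "P4": 211, "P5": 218},
        tmd_spans=tuple(spans[f"TM{i}"] for i in range(1, 7)),
    )


def solute_exemplar_annotation() -> ReferenceAnnotation:
    """Synthetic aquaglyceroporin exemplar with the GlpF filter coordinates.

    Carries T, G, F, R at positions 48, 191, 200 and 205 of a 259-residue
    scaffold (G at 191 falls at the extracellular end of helix 5).
    """
    segments = [
        ("nterm", 2), ("TM1", 21), ("loopA", 15), ("TM2", 21),
        ("loopB", 24), ("TM3", 21), ("loopC", 24), ("TM4", 21),
        ("loopD", 24), ("TM5", 21), ("loopE", 24), ("TM6", 21), ("cterm", 20),
    ]
    froger = {110: "F", 208: "A", 210: "A", 220: "Y", 227: "L"}
    plants = {48: "T", 66: "NPA", 191: "G", 200: "F", 201: "NPA", 205: "R"}
    plants.update(froger)
    seq, spans = _build(segments, plants, seed=20132)
    protein = ProteinRecord(id="GlpF_like_synthetic", sequence=seq)
    return ReferenceAnnotation(
        protein=protein, npa1_pos=66, npa2_pos=201,
        arR_positions={"H2": 48, "H5": 191, "LE1": 200, "LE2": 205},
        froger_positions={"P1": 110, "P2": 208, "P3": 210, "P4": 220, "P5": 227},
        tmd_spans=tuple(spans[f"TM{i}"] for i in range(1, 7)),
    )
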