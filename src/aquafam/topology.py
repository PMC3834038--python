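"""Hydropathy-based transmembrane topology prediction and loop labeling.

A sliding Kyte-Doolittle window (default 19 residues, the classic
membrane-protein setting) marks candidate helix centers where the mean
hydropathy exceeds 1.6; maximal runs of such centers become helices,
nearby runs are merged, short runs dropped, and span ends trimmed back
to hydrophobic residues.  For the canonical six-helix MIP fold the
inter-helix loops are labeled A..E; loop B (between helices 2 and 3) and
loop E (between helices 5 and 6) host the two NPA motifs and the ar/R
loop-E residues, so they are exposed directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqio import ProteinRecord

#: Kyte-Doolittle hydropathy scale; unknown residue X is neutral.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}


@dataclass(frozen=True)
class HydropathyParams:
    window: int = 19
    threshold: float = 1.6
    merge_gap: int = 3
    min_helix_length: int = 15


@dataclass
class TopologyAnnotation:
    """Predicted transmembrane spans and inter-helix loops (1-based)."""

    protein_id: str
    tmd_spans: list[tuple[int, int]]
    loops: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.tmd_spans, self.tmd_spans[1:]):
            if s2 <= e1:
                raise ValueError("TMD spans must be sorted and non-overlapping")

    @property
    def n_tmd(self) -> int:
        return len(self.tmd_spans)

    @property
    def loop_B(self) -> tuple[int, int] | None:
        return self.loops.get("B")

    @property
    def loop_E(self) -> tuple[int, int] | None:
        return self.loops.get("E")


def hydropathy_profile(sequence: str, window: int = 19) -> np.ndarray:
    """Mean Kyte-Doolittle hydropathy per full window, indexed by center.

    Entry ``i`` (0-based) is the mean over the window centered at residue
    ``i``; positions whose window would overrun the ends hold NaN.
    """
    h = np.array([KYTE_DOOLITTLE[c] for c in sequence])
    n = len(h)
    out = np.full(n, np.nan)
    if n < window:
        return out
    kernel = np.ones(window) / window
    means = np.convolve(h, kernel, mode="valid")
    half = window // 2
    out[half: half + len(means)] = means
    return out


def predict_tmds(p: ProteinRecord, params: HydropathyParams | None = None) -> TopologyAnnotation:
    """Predict transmembrane helices from windowed hydropathy.

    Runs of above-threshold window centers become candidate helices;
    runs separated by at most ``merge_gap`` residues are merged, runs
    shorter than ``min_helix_length`` discarded, and each span is
    trimmed so its end residues have positive hydropathy.  A sequence
    shorter than the window yields an empty annotation with a warning.
    """
    params = params or HydropathyParams()
    seq = p.sequence
    if len(seq) < params.window:
        warnings.warn(
            f"sequence {p.id!r} shorter than hydropathy window; no prediction"
        )
        return TopologyAnnotation(protein_id=p.id, tmd_spans=[])
    prof = hydropathy_profile(seq, params.window)
    above = np.where(np.nan_to_num(prof, nan=-np.inf) > params.threshold)[0]
    runs: list[list[int]] = []
    for i in above:
        if runs and i - runs[-1][1] <= params.merge_gap + 1:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    h = np.array([KYTE_DOOLITTLE[c] for c in seq])
    # window centers under-cover the helix ends by up to half a window:
    # grow each run outward over hydrophobic residues, then trim back so
    # both span ends are themselves hydrophobic
    expanded: list[list[int]] = []
    for s, e in runs:
        while s > 0 and h[s - 1] > 0:
            s -= 1
        while e < len(seq) - 1 and h[e + 1] > 0:
            e += 1
        while s < e and h[s] <= 0:
            s += 1
        while e > s and h[e] <= 0:
            e -= 1
        if expanded and s - expanded[-1][1] <= params.merge_gap + 1:
            expanded[-1][1] = max(expanded[-1][1], e)
        else:
            expanded.append([s, e])
    final = [(s + 1, e + 1) for s, e in expanded
             if e - s + 1 >= params.min_helix_length]
    return label_loops(TopologyAnnotation(protein_id=p.id, tmd_spans=final), len(seq))


def label_loops(t: TopologyAnnotation, protein_length: int) -> TopologyAnnotation:
    """Label inter-helix intervals A..E (and beyond) for the MIP fold.

    Loop ``k`` lies between helices ``k`` and ``k+1``; loop B therefore
    needs helices 2 and 3 present, loop E helices 5 and 6.  For proteins
    with fewer detected helices only the defined loops are labeled.
    """
    labels = "ABCDEFG"
    loops: dict[str, tuple[int, int]] = {}
    for k in range(len(t.tmd_spans) - 1):
        start = t.tmd_spans[k][1] + 1
        end = t.tmd_spans[k + 1][0] - 1
        if start <= end and k < len(labels):
            loops[labels[k]] = (start, end)
    t.loops = loops
    return t
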