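"""Optional profile-HMM candidate scan (robustness check, off by default).

Builds one profile HMM per subfamily from the reference-panel sequences
with pyhmmer and searches the proteome, emitting the same
:class:`~aquafam.pipeline.CandidateHit` records as the default
seed-alignment scan so the two backends are interchangeable behind the
pipeline interface.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .pipeline import CandidateHit
from .seqio import ProteinRecord


def profile_scan_proteome(
    proteome: Sequence[ProteinRecord],
    panel_by_subfamily: Mapping[str, Sequence[ProteinRecord]],
    bitscore_threshold: float = 50.0,
) -> list[CandidateHit]:
    """Search the proteome with per-subfamily profile HMMs.

    Each subfamily's references are aligned (progressively) and turned
    into an HMM; every proteome entry keeps its best-scoring subfamily.
    ``normalized_score`` is bit score per model position so thresholds
    stay roughly length-independent.
    """
    import pyhmmer

    from .align import progressive_msa

    alphabet = pyhmmer.easel.Alphabet.amino()
    background = pyhmmer.plan7.Background(alphabet)
    builder = pyhmmer.plan7.Builder(alphabet)
    hmms = {}
    for fam, refs in sorted(panel_by_subfamily.items()):
        if len(refs) == 1:
            rows = [(refs[0].id, refs[0].sequence)]
        else:
            aln = progressive_msa(list(refs))
            rows = list(zip(aln.ids, aln.rows))
        msa = pyhmmer.easel.TextMSA(
            name=fam.encode(),
            sequences=[
                pyhmmer.easel.TextSequence(name=rid.encode(), sequence=row)
                for rid, row in rows
            ],
        )
        hmm, _, _ = builder.build_msa(msa.digitize(alphabet), background)
        hmms[fam] = hmm

    seqs = pyhmmer.easel.DigitalSequenceBlock(
        alphabet,
        [
            pyhmmer.easel.TextSequence(name=p.id.encode(),
                                       sequence=p.sequence).digitize(alphabet)
            for p in proteome
        ],
    )
    best: dict[str, tuple[float, str]] = {}
    for fam, hmm in hmms.items():
        pipeline = pyhmmer.plan7.Pipeline(alphabet, background=background)
        for hit in pipeline.search_hmm(hmm, seqs):
            name = hit.name if isinstance(hit.name, str) else hit.name.decode()
            norm = hit.score / hmm.M
            if name not in best or hit.score > best[name][0]:
                best[name] = (float(hit.score), fam)
    out: list[CandidateHit] = []
    for p in proteome:
        if p.id in best:
            score, fam = best[p.id]
            out.append(CandidateHit(
                locus=p.id, best_seed=f"HMM:{fam}", best_subfamily=fam,
                score=score, normalized_score=score / hmms[fam].M,
                accepted=score >= bitscore_threshold,
            ))
        else:
            out.append(CandidateHit(locus=p.id, best_seed=None,
                                    best_subfamily=None, score=0.0,
                                    normalized_score=0.0, accepted=False))
    return out
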