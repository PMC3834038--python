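from __future__ import annotations

import re

import numpy as np
import pytest

from aquafam.reference import solute_exemplar_annotation, water_exemplar_annotation
from aquafam.residues import (
    ArRFilter,
    NpaMotif,
    ResidueParams,
    classify_specificity,
    find_npa_motifs,
    find_phospho_sites,
    transfer_positions,
)
from aquafam.seqio import ProteinRecord
from aquafam.topology import predict_tmds


def _arr(letters) -> ArRFilter:
    labels = ("H2", "H5", "LE1", "LE2")
    return ArRFilter(
        residues=dict(zip(labels, letters)),
        positions=dict(zip(labels, (10, 20, 30, 40))),
    )


class TestNpaMotifs:
    def test_canonical_motif_in_loop_b(self, family, family_members):
        truth = family.truth
        pip = next(p for p in family_members if truth[p.id].subfamily == "PIP")
        motifs = {m.loop: m for m in find_npa_motifs(pip, predict_tmds(pip))}
        assert motifs["B"].motif == "NPA" and motifs["B"].canonical

    def test_xip_nparc_extension_detected(self, family, family_members):
        truth = family.truth
        for p in family_members:
            if truth[p.id].subfamily != "XIP":
                continue
            motifs = {m.loop: m for m in find_npa_motifs(p, predict_tmds(p))}
            assert motifs["E"].extended is not None
            assert motifs["E"].extended.endswith("RC")

    def test_nip_variant_motifs_recovered_exactly(self, family, family_members):
        """The NIP plan plants NPS (loop B) and NPV (loop E)."""
        truth = family.truth
        for p in family_members:
            entry = truth[p.id]
            if entry.subfamily != "NIP":
                continue
            motifs = {m.loop: m for m in find_npa_motifs(p, predict_tmds(p))}
            assert motifs["B"].motif == "NPS"
            assert motifs["E"].motif == "NPV"

    def test_whole_sequence_fallback_without_topology(self):
        seq = "S" * 40 + "NPA" + "S" * 60 + "NPT" + "S" * 40
        motifs = find_npa_motifs(ProteinRecord(id="q", sequence=seq), topo=None)
        assert [(m.loop, m.start, m.motif) for m in motifs] == [
            ("B", 41, "NPA"), ("E", 104, "NPT")]

    def test_every_reported_motif_matches_pattern(self, family, family_members):
        pat = re.compile("[NS]P[ASTVIL]")
        for p in family_members:
            for m in find_npa_motifs(p, predict_tmds(p)):
                assert pat.fullmatch(m.motif)

    def test_invalid_motif_rejected_by_type(self):
        with pytest.raises(ValueError):
            NpaMotif(start=1, motif="QPA", loop="B")


class TestTransferPositions:
    def test_identity_on_water_exemplar(self):
        """Self-transfer returns the annotated filter letters at the
        literature coordinates F58-H182-C191-R197."""
        ref = water_exemplar_annotation()
        arr = transfer_positions(ref.protein, ref, "arR")
        assert arr.letters() == ("F", "H", "C", "R")
        assert [arr.positions[k] for k in ("H2", "H5", "LE1", "LE2")] == \
            [58, 182, 191, 197]

    def test_identity_on_solute_exemplar(self):
        ref = solute_exemplar_annotation()
        arr = transfer_positions(ref.protein, ref, "arR")
        assert arr.letters() == ("T", "G", "F", "R")
        assert [arr.positions[k] for k in ("H2", "H5", "LE1", "LE2")] == \
            [48, 191, 200, 205]

    def test_terminal_extension_shifts_coordinates(self):
        ref = water_exemplar_annotation()
        extended = ProteinRecord(id="ext", sequence="DSESDKESQD" + ref.protein.sequence)
        arr = transfer_positions(extended, ref, "arR")
        assert arr.letters() == ("F", "H", "C", "R")
        assert [arr.positions[k] for k in ("H2", "H5", "LE1", "LE2")] == \
            [68, 192, 201, 207]

    def test_truncated_query_yields_nulls(self):
        ref = water_exemplar_annotation()
        stub = ProteinRecord(id="stub", sequence=ref.protein.sequence[:120])
        arr = transfer_positions(stub, ref, "arR")
        assert arr.residues["H2"] == "F"
        assert arr.residues["H5"] is None and arr.positions["H5"] is None

    def test_planted_letters_recovered_on_family(self, family, family_members):
        truth = family.truth
        ok = tot = 0
        for p in family_members:
            entry = truth[p.id]
            ann = family.panel.annotations[entry.subfamily]
            arr = transfer_positions(p, ann, "arR")
            fro = transfer_positions(p, ann, "froger")
            for lab, letter in zip(("H2", "H5", "LE1", "LE2"), entry.arr_letters):
                tot += 1
                ok += arr.residues[lab] == letter
            for lab, letter in zip(("P1", "P2", "P3", "P4", "P5"),
                                   entry.froger_letters):
                tot += 1
                ok += fro.residues[lab] == letter
        assert ok / tot >= 0.95

    def test_recovery_degrades_with_substitution_rate(self):
        """Accuracy is monotone non-increasing as the planted positions
        are allowed to mutate."""
        from aquafam.synth import FamilyConfig, generate_family

        accs = []
        for conservation in (1.0, 0.7, 0.3):
            fam = generate_family(FamilyConfig(
                seed=33, conservation_prob=conservation, n_decoys=0,
                est_coverage=0.0, within_rate=0.15))
            ok = tot = 0
            for p in fam.proteome:
                entry = fam.truth[p.id]
                ann = fam.panel.annotations[entry.subfamily]
                arr = transfer_positions(p, ann, "arR")
                for lab, letter in zip(("H2", "H5", "LE1", "LE2"),
                                       entry.arr_letters):
                    tot += 1
                    ok += arr.residues[lab] == letter
            accs.append(ok / tot)
        assert accs[0] >= accs[1] >= accs[2]
        assert accs[0] > accs[2]


class TestPhosphoSites:
    def test_pkc_motif_at_extreme_cterm(self):
        p = ProteinRecord(id="p", sequence="M" * 40 + "ASLR")
        sites = find_phospho_sites(p)
        assert (42, "PKC") in sites.sites

    def test_no_serine_no_pkc_hit(self):
        p = ProteinRecord(id="p", sequence="M" * 40 + "AKLRDEGH")
        assert find_phospho_sites(p).sites == ()

    def test_planted_sites_recovered(self, family, family_members):
        truth = family.truth
        for p in family_members:
            entry = truth[p.id]
            found = find_phospho_sites(p).sites
            for pos, name in entry.phospho_positions:
                assert (pos, name) in found, (p.id, pos, name)

    def test_sxa_variant_configurable(self):
        p = ProteinRecord(id="p", sequence="M" * 40 + "ASLA")
        default = find_phospho_sites(p)
        alt = find_phospho_sites(p, ResidueParams(pkc_motif="S.A"))
        assert all(name != "PKC" for _, name in default.sites)
        assert (42, "PKC") in alt.sites


class TestClassifySpecificity:
    def test_water_exemplar_identity(self):
        call = classify_specificity(_arr(("F", "H", "T", "R")))
        assert call.call == "water"
        assert call.score_water == 0.0

    def test_solute_exemplar_identity(self):
        call = classify_specificity(_arr(("T", "G", "F", "R")))
        assert call.call == "solute"
        assert call.score_solute == 0.0

    def test_xip_filter_calls_solute(self):
        call = classify_specificity(_arr(("I", "T", "A", "R")))
        assert call.call == "solute"

    def test_null_positions_force_ambiguous(self):
        call = classify_specificity(_arr(("F", None, "T", "R")))
        assert call.call == "ambiguous"
        all_null = classify_specificity(_arr((None, None, None, None)))
        assert all_null.call == "ambiguous"
        assert all_null.score_water is None

    def test_call_invariant_to_normalization_scale(self):
        # both axes rescaled by the same factor of 3
        params = ResidueParams(hydropathy_range=(-13.5, 13.5),
                               volume_range=(-107.6, 395.5))
        for letters in (("F", "H", "T", "R"), ("T", "G", "F", "R"),
                        ("I", "T", "A", "R"), ("W", "V", "A", "R")):
            base = classify_specificity(_arr(letters))
            scaled = classify_specificity(_arr(letters), params)
            assert base.call == scaled.call
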