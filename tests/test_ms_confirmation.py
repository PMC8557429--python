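"""Peptide mass arithmetic and MS identification-to-precursor matching."""

import random

import pytest
from pyteomics import mass as pyt_mass

from neuropep.ms_confirmation import (
    MOD_DELTA,
    WATER,
    MassError,
    MsIdentification,
    confirmation_summary,
    match_identifications,
    monoisotopic_mass,
    read_identifications,
    write_identifications,
)
from neuropep.precursor_annotation import annotate_precursor
from neuropep.sequence_io import ProteinRecord, SignalAnnotation

AA = "ACDEFGHIKLMNPQRSTVWY"

# monoisotopic atomic masses for the elemental-composition cross-checks
H, C_, N, O, S = 1.0078250319, 12.0, 14.0030740052, 15.9949146221, 31.97207069


def oracle_mass(seq, mods=(), carbamidomethyl=True):
    """Independent calculator: pyteomics composition + delta table."""
    m = pyt_mass.calculate_mass(sequence=seq, monoisotopic=True)
    if carbamidomethyl:
        m += seq.count("C") * (2 * C_ + 3 * H + N + O)  # +C2H3NO
    for name, _pos in mods:
        m += MOD_DELTA[name]
    return m


class TestMassArithmetic:
    def test_glycine(self):
        assert monoisotopic_mass("G", fixed_carbamidomethyl=False) == pytest.approx(
            75.03203, abs=1e-4
        )

    def test_amidation_delta_from_elements(self):
        # C-terminal -OH replaced by -NH2
        assert MOD_DELTA["amidation"] == pytest.approx((N + 2 * H) - (O + H), abs=1e-5)

    def test_pyroglu_delta_from_elements(self):
        # cyclization releases NH3
        assert MOD_DELTA["pyroglu_Q"] == pytest.approx(-(N + 3 * H), abs=1e-5)

    def test_carbamidomethyl_delta_from_elements(self):
        assert MOD_DELTA["carbamidomethyl_C"] == pytest.approx(
            2 * C_ + 3 * H + N + O, abs=1e-4
        )

    def test_additivity_identity(self):
        rng = random.Random(3)
        for _ in range(50):
            a, b = rng.choice(AA), rng.choice(AA)
            lhs = monoisotopic_mass(a + b, fixed_carbamidomethyl=False)
            rhs = (
                monoisotopic_mass(a, fixed_carbamidomethyl=False)
                + monoisotopic_mass(b, fixed_carbamidomethyl=False)
                - WATER
            )
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_100_random_modified_peptides_vs_pyteomics(self):
        rng = random.Random(29)
        for _ in range(100):
            seq = "".join(rng.choices(AA, k=rng.randint(4, 30)))
            mods = []
            if seq[0] == "Q" and rng.random() < 0.5:
                mods.append(("pyroglu_Q", 1))
            elif rng.random() < 0.3:
                mods.append(("acetyl_Nterm", 1))
            if rng.random() < 0.5:
                mods.append(("amidation", len(seq)))
            for i, c in enumerate(seq, 1):
                if c == "M" and rng.random() < 0.3:
                    mods.append(("oxidation_M", i))
                if c == "Y" and rng.random() < 0.3:
                    mods.append(("sulfo_Y", i))
            got = monoisotopic_mass(seq, mods)
            assert abs(got - oracle_mass(seq, mods)) < 1e-4

    def test_unknown_residue_rejected(self):
        with pytest.raises(MassError, match="position 2"):
            monoisotopic_mass("ABCD")

    def test_double_amidation_rejected(self):
        with pytest.raises(MassError):
            monoisotopic_mass("PEPTIDEK", [("amidation", 8), ("amidation", 8)])

    def test_misplaced_modifications_rejected(self):
        with pytest.raises(MassError):
            monoisotopic_mass("PEPTIDEK", [("amidation", 3)])
        with pytest.raises(MassError):
            monoisotopic_mass("PEPTIDEK", [("pyroglu_Q", 1)])
        with pytest.raises(MassError):
            monoisotopic_mass("PEPTIDEK", [("oxidation_M", 2)])


class TestMsIdentification:
    def test_minimum_length_four(self):
        with pytest.raises(ValueError, match="4"):
            MsIdentification("GWK", [], 400.0, "x")

    def test_tsv_round_trip(self, tmp_path):
        idents = [
            MsIdentification("AFMRF", [("amidation", 5)], 700.1, "a"),
            MsIdentification("QSGAK", [], 600.2, "b"),
        ]
        p = tmp_path / "ids.tsv"
        write_identifications(idents, p)
        back = read_identifications(p)
        assert [(i.peptide_sequence, i.modifications) for i in back] == [
            ("AFMRF", [("amidation", 5)]),
            ("QSGAK", []),
        ]


def _annotated(seq, pid="prec", sig_end=4):
    rec = ProteinRecord(pid, seq)
    return annotate_precursor(rec, SignalAnnotation(pid, True, sig_end, 0.9))


def _ident(seq, mods=()):
    return MsIdentification(seq, list(mods),
                            monoisotopic_mass(seq, mods), f"id_{seq}")


class TestMatching:
    def setup_method(self):
        # signal(4) | AFMRLFG | KR | AYLPSRFG | KR | tail
        self.ann = _annotated("MKLA" + "AFMRLFG" + "KR" + "AYLPSRFG" + "KR" + "ASTN")

    def test_full_dibasic_exact(self):
        (m,) = [
            x
            for x in match_identifications([_ident("AFMRLF", [("amidation", 6)])], [self.ann])
            if x.is_primary
        ]
        assert m.category == "full_dibasic"
        assert m.mass_error == pytest.approx(0, abs=1e-9)
        core = next(p for p in self.ann.peptides if p.sequence == "AFMRLF")
        assert (m.start, m.end) == (core.start, core.end)

    def test_truncations(self):
        results = {
            x.identification.peptide_sequence: x.category
            for x in match_identifications(
                [_ident("AFMRL"), _ident("YLPSRF"), _ident("FMRL")], [self.ann]
            )
            if x.is_primary
        }
        assert results["AFMRL"] == "truncated_C"
        assert results["YLPSRF"] == "truncated_N"
        assert results["FMRL"] == "truncated_both"

    def test_monobasic_product(self):
        # precursor with K supporting a lone downstream Arg inside the copy:
        # K at distance 4 from the cleavage point before R
        ann = _annotated("MKLA" + "KAAARWST" + "KR" + "AFMRLFG" + "KR")
        (m,) = [
            x
            for x in match_identifications([_ident("KAAA")], [ann])
            if x.is_primary
        ]
        assert m.category == "monobasic_product"

    def test_novel_precursor_via_background(self):
        background = [ProteinRecord("hidden", "MSTA" + "WWSTPLEN" + "KR" + "AST")]
        (m,) = [
            x
            for x in match_identifications(
                [_ident("WWSTPLEN")], [self.ann], background=background
            )
            if x.is_primary
        ]
        assert m.category == "novel_precursor" and m.precursor_id == "hidden"

    def test_unmatched(self):
        (m,) = match_identifications([_ident("WWWWHHHH")], [self.ann])
        assert m.category == "unmatched" and m.precursor_id is None

    def test_full_boundaries_coincide_with_sites(self):
        idents = [_ident("AFMRLF", [("amidation", 6)]),
                  _ident("AYLPSRF", [("amidation", 7)])]
        cores = {(p.start, p.end) for p in self.ann.peptides}
        for m in match_identifications(idents, [self.ann]):
            if m.category == "full_dibasic":
                assert (m.start, m.end) in cores

    def test_ambiguous_occurrence_reports_all(self):
        twin = _annotated("MKLA" + "AFMRLFG" + "KR" + "TTTT", pid="twin")
        ms = match_identifications([_ident("AFMRLF", [("amidation", 6)])],
                                   [self.ann, twin])
        assert len(ms) == 2 and sum(m.is_primary for m in ms) == 1
        # primary prefers the longer host at equal category
        assert next(m for m in ms if m.is_primary).precursor_id == "prec"

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_identifications([], [self.ann], tol=0)

    def test_inconsistent_observed_mass_raises(self):
        bad = MsIdentification("AFMRLF", [], 1.0, "bad")
        with pytest.raises(MassError):
            match_identifications([bad], [self.ann])


class TestSummary:
    def test_counts(self):
        ann2 = _annotated("MKLA" + "QSGALFG" + "KR" + "AAAA", pid="p2")
        ann = _annotated("MKLA" + "AFMRLFG" + "KR" + "AYLPSRFG" + "KR" + "ASTN")
        idents = [
            _ident("AFMRLF", [("amidation", 6)]),
            _ident("AYLPSRF", [("amidation", 7)]),
            _ident("AFMRL"),
            _ident("QSGALF", [("amidation", 6)]),
        ]
        matches = match_identifications(idents, [ann, ann2])
        per_precursor, totals = confirmation_summary(matches)
        assert totals["confirmed_full_peptides"] == 3
        assert totals["confirmed_full_precursors"] == 2
        assert totals["truncated_peptides"] == 1
        assert per_precursor.loc["prec", "full_dibasic"] == 2

    def test_empty(self):
        per_precursor, totals = confirmation_summary([])
        assert totals["confirmed_full_peptides"] == 0
        assert totals["novel_support"] == {}
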