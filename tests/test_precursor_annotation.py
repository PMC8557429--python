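"""Cleavage-site prediction, peptide derivation, and architecture calls."""

import random

import pytest

from neuropep.precursor_annotation import (
    annotate_precursor,
    classify_architecture,
    derive_peptides,
    detect_consecutive_copies,
    find_cleavage_sites,
    reconstruct,
    render_precursor,
)
from neuropep.sequence_io import ProteinRecord, SignalAnnotation

BASIC = set("KR")
DIMERS = {"KR", "RR", "KK", "RK"}


def oracle_sites(seq, include_monobasic=False):
    """Exhaustive position-by-position re-derivation of the site rules.

    Dibasic: left-to-right non-overlapping dimers.  Monobasic: any unpaired,
    non-adjacent-to-basic Arg with a K/R 3-6 positions N-terminal of the
    cleavage point.
    """
    seq = seq.rstrip("*")
    dibasic = []
    used = set()
    i = 0
    while i < len(seq) - 1:
        if seq[i : i + 2] in DIMERS:
            dibasic.append(i + 2)
            used.update((i, i + 1))
            i += 2
        else:
            i += 1
    mono = []
    if include_monobasic:
        for p in range(1, len(seq) + 1):  # 1-based Arg position
            if seq[p - 1] != "R" or (p - 1) in used:
                continue
            if p >= 2 and seq[p - 2] in BASIC:
                continue
            if p < len(seq) and seq[p] in BASIC:
                continue
            if any(p - d >= 1 and seq[p - d - 1] in BASIC for d in (3, 4, 5, 6)):
                if p - 1 >= 1 and (p - 1) not in dibasic:
                    mono.append(p - 1)
    return sorted(dibasic), sorted(mono)


class TestCleavageSites:
    def test_single_dibasic(self):
        (site,) = find_cleavage_sites("AAKRAA")
        assert (site.position, site.site_type, site.motif) == (4, "dibasic", "KR")

    def test_no_basic_no_sites(self):
        assert find_cleavage_sites("AAAAAA") == []

    def test_overlapping_run_krkr(self):
        sites = find_cleavage_sites("AKRKRA")
        assert [s.position for s in sites] == [3, 5]

    def test_monobasic_with_supporting_lysine(self):
        sites = find_cleavage_sites("KAAARA", include_monobasic=True)
        mono = [s for s in sites if s.site_type == "monobasic"]
        assert len(mono) == 1
        assert mono[0].position == 4  # cleavage N-terminal to the Arg at 5
        assert mono[0].confidence == "alternative"

    def test_monobasic_requires_support(self):
        sites = find_cleavage_sites("AAAARA", include_monobasic=True)
        assert [s for s in sites if s.site_type == "monobasic"] == []

    @pytest.mark.parametrize("include_monobasic", [False, True])
    def test_matches_exhaustive_oracle(self, include_monobasic):
        rng = random.Random(13)
        for _ in range(400):
            seq = "".join(rng.choices("AKRGSQPLE", k=rng.randint(5, 120)))
            sites = find_cleavage_sites(seq, include_monobasic=include_monobasic)
            got_d = sorted(s.position for s in sites if s.site_type == "dibasic")
            got_m = sorted(s.position for s in sites if s.site_type == "monobasic")
            exp_d, exp_m = oracle_sites(seq, include_monobasic)
            assert (got_d, got_m) == (exp_d, exp_m), seq


def _signal(pid, n):
    return SignalAnnotation(pid, True, n, 0.9)


class TestDerivePeptides:
    def test_fmrfamide_style_hand_oracle(self):
        # signal(4) | AFMRFG | KR | AYLRFG | KR  -- processed by hand:
        # both segments lose the trailing Gly to amidation
        seq = "MKLA" + "AFMRFG" + "KR" + "AYLRFG" + "KR"
        rec = ProteinRecord("p", seq)
        sites = find_cleavage_sites(seq)
        peps = derive_peptides(rec, sites, _signal("p", 4))
        assert [(p.sequence, p.amidated) for p in peps] == [
            ("AFMRF", True),
            ("AYLRF", True),
        ]
        assert peps[0].flanking == "signal-dibasic"
        assert (peps[0].start, peps[0].end) == (5, 9)

    def test_pyroglutamate_flag(self):
        seq = "MKLA" + "QSGAKG" + "KR" + "AAAA"
        rec = ProteinRecord("p", seq)
        peps = derive_peptides(rec, find_cleavage_sites(seq), _signal("p", 4))
        assert peps[0].sequence == "QSGAK" and peps[0].amidated and peps[0].pyroglu
        assert peps[1].flanking == "dibasic-end" and not peps[1].pyroglu

    def test_no_sites_no_signal_single_peptide(self):
        rec = ProteinRecord("p", "MASTNDEPQST")
        peps = derive_peptides(rec, [], None)
        assert len(peps) == 1
        assert peps[0].sequence == rec.sequence
        assert not peps[0].amidated and not peps[0].pyroglu

    def test_zero_length_segment_dropped(self):
        seq = "MKLA" + "AFMRF" + "KRKR" + "AAAA"
        rec = ProteinRecord("p", seq)
        peps = derive_peptides(rec, find_cleavage_sites(seq), _signal("p", 4))
        assert [p.sequence for p in peps] == ["AFMRF", "AAAA"]

    def test_terminal_stop_amidation(self):
        # trailing Gly before a retained stop is an amidation donor
        seq = "MKLA" + "AFMRFG" + "KR" + "AYLRFG*"
        rec = ProteinRecord("p", seq)
        peps = derive_peptides(rec, find_cleavage_sites(seq), _signal("p", 4))
        assert peps[-1].sequence == "AYLRF" and peps[-1].amidated

    def test_tiling_on_random_sequences(self):
        rng = random.Random(17)
        for _ in range(200):
            seq = "".join(rng.choices("AKRGSQPLEFMNDY", k=rng.randint(10, 300)))
            rec = ProteinRecord("p", seq)
            sig = _signal("p", rng.randint(1, 5)) if rng.random() < 0.7 else None
            sites = find_cleavage_sites(seq)
            peps = derive_peptides(rec, sites, sig)
            assert reconstruct(rec, sig, sites, peps) == seq

    def test_amidation_flag_iff_gly_before_boundary(self):
        rng = random.Random(19)
        for _ in range(100):
            seq = "".join(rng.choices("AKRGSQPLE", k=rng.randint(20, 200)))
            rec = ProteinRecord("p", seq)
            sites = find_cleavage_sites(seq)
            for p in derive_peptides(rec, sites, None):
                following = seq[p.end] if p.end < len(seq) else ""
                assert p.amidated == (following == "G")


class TestConsecutiveCopies:
    def build(self, n_copies, spacered=False):
        parts = ["MKLA"]
        for i in range(n_copies):
            if spacered and i:
                parts.append("ASTN")
            parts.append("ARGWG")
            parts.append("KR")
        seq = "".join(parts) + "AA"
        rec = ProteinRecord("p", seq)
        sites = find_cleavage_sites(seq)
        return rec, derive_peptides(rec, sites, _signal("p", 4))

    def test_abutting_copies_flagged_with_gw_alternative(self):
        rec, peps = self.build(2)
        flagged, alts = detect_consecutive_copies(peps, r"A.GW")
        copies = [p for p in flagged if p.sequence == "ARGW"]
        assert all(p.consecutive_copy for p in copies)
        assert {a.sequence for a in alts} == {"GW"}
        assert all(a.amidated for a in alts)

    def test_spacer_breaks_adjacency(self):
        rec, peps = self.build(2, spacered=True)
        flagged, alts = detect_consecutive_copies(peps, r"A.GW")
        assert not any(p.consecutive_copy for p in flagged)
        assert alts == []

    def test_empty_input(self):
        assert detect_consecutive_copies([], r"A.GW") == ([], [])


class TestArchitecture:
    def test_multicopy(self):
        seq = "MKLA" + ("AFMRFG" + "KR") * 3 + "AA"
        rec = ProteinRecord("p", seq)
        ann = annotate_precursor(rec, _signal("p", 4))
        assert ann.architecture.class_name == "multicopy"
        assert ann.architecture.copy_count == 3

    def test_single_copy_plus_cys_domain(self):
        domain = "ASTC" * 7  # 7 Cys
        seq = "MKLA" + "CYIQNCPRG"[:8] + "G" + "KR" + domain
        # first peptide has 2 Cys though -- use a Cys-poor active peptide
        seq = "MKLA" + "AYIQNPRG" + "KR" + domain
        rec = ProteinRecord("p", seq)
        ann = annotate_precursor(rec, _signal("p", 4))
        assert ann.architecture.class_name == "single_copy_plus_cys_domain"

    def test_cys8_terminal_peptide(self):
        peptide = "C" + "AST" + "C" + "AS" + "C" + "ASTA" + "C" + "AST" + "C" + "ASTAS" + "C" + "W" + "AST" + "C" + "AS" + "C" + "W"
        assert peptide.count("C") == 8
        seq = "MKLA" + "ASTNQ" + "KR" + peptide + "G"
        rec = ProteinRecord("p", seq)
        ann = annotate_precursor(rec, _signal("p", 4))
        assert ann.architecture.class_name == "cys8_peptide"
        assert ann.peptides[-1].amidated

    def test_single_copy(self):
        seq = "MKLA" + "ASTNQPLDE"
        ann = annotate_precursor(ProteinRecord("p", seq), _signal("p", 4))
        assert ann.architecture.class_name == "single_copy"

    def test_cys_positions_recorded(self):
        seq = "MCLA" + "ACTNQ"
        ann = annotate_precursor(ProteinRecord("p", seq), _signal("p", 4))
        assert ann.architecture.cys_positions == [2, 6]

    def test_deterministic_under_equal_position_permutation(self):
        seq = "MKLA" + ("AFMRFG" + "KR") * 4 + "AA"
        rec = ProteinRecord("p", seq)
        sites = find_cleavage_sites(seq)
        peps = derive_peptides(rec, sites, _signal("p", 4))
        a = classify_architecture(rec, peps)
        b = classify_architecture(rec, list(reversed(peps)))
        assert (a.class_name, a.copy_count) == (b.class_name, b.copy_count)


def test_render_precursor_shows_marks():
    seq = "MKLA" + "AFMRFG" + "KR" + "AA"
    ann = annotate_precursor(ProteinRecord("p1", seq), _signal("p1", 4))
    text = render_precursor(ann)
    assert "mkla" in text  # signal lower-cased
    assert "[K][R]" in text
    assert "AFMRF-NH2" in text
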