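"""Matching observed MS peptide identifications to predicted precursor products.

The spectral search itself (spectra -> peptide sequences) is consumed as a
table; what this module reproduces is the peptide-to-precursor confirmation
logic: locating each identified peptide on the precursor set, deciding whether
it confirms a predicted dibasic-site product, a truncation, a monobasic
cleavage (single Arg with a supporting basic residue 3-6 positions N-terminal
of the cut), or reveals a precursor the discovery arm missed entirely.

Masses are monoisotopic; carbamidomethylation of Cys is a fixed modification
(matching the search settings the identifications come from), the variable
set is N-terminal pyroglutamate from Gln, Met oxidation, N-terminal
acetylation, C-terminal amidation, and Tyr sulfation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .precursor_annotation import AnnotatedPrecursor, find_cleavage_sites
from .sequence_io import ProteinRecord

WATER = 18.010565
PROTON = 1.00727646

#: Standard monoisotopic residue (amino-acid minus water) masses, Da.
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: Modification mass deltas, monoisotopic Da.
MOD_DELTA = {
    "amidation": -0.98402,
    "pyroglu_Q": -17.02655,
    "oxidation_M": +15.99491,
    "acetyl_Nterm": +42.01057,
    "sulfo_Y": +79.95682,
    "carbamidomethyl_C": +57.02146,
}

MIN_PEPTIDE_LEN = 4

CATEGORY_RANK = {
    "full_dibasic": 0,
    "monobasic_product": 1,
    "truncated_N": 2,
    "truncated_C": 2,
    "truncated_both": 2,
    "internal": 3,
    "novel_precursor": 4,
    "unmatched": 5,
}

#: Largest single-end truncation treated as degradation of a predicted core.
TRUNCATION_WINDOW = 3


class MassError(ValueError):
    pass


def monoisotopic_mass(
    sequence: str,
    modifications: Sequence[tuple[str, int]] = (),
    fixed_carbamidomethyl: bool = True,
) -> float:
    """Monoisotopic peptide mass: residue masses + water + modification deltas.

    ``modifications`` is a list of (name, 1-based position); carbamidomethyl
    is applied to every Cys automatically when ``fixed_carbamidomethyl`` and
    must not be listed.  Additivity: mass(AB) = mass(A) + mass(B) - water.
    """
    total = WATER
    for i, res in enumerate(sequence, 1):
        if res not in RESIDUE_MASS:
            raise MassError(f"unknown residue {res!r} at position {i}")
        total += RESIDUE_MASS[res]
        if fixed_carbamidomethyl and res == "C":
            total += MOD_DELTA["carbamidomethyl_C"]
    n_amid = 0
    for name, pos in modifications:
        if name not in MOD_DELTA:
            raise MassError(f"unknown modification {name!r}")
        if not 1 <= pos <= len(sequence):
            raise MassError(f"modification {name} at {pos} outside peptide")
        if name == "amidation":
            n_amid += 1
            if pos != len(sequence):
                raise MassError("amidation must sit on the C-terminal residue")
        if name == "pyroglu_Q" and (pos != 1 or sequence[0] != "Q"):
            raise MassError("pyroglu_Q requires an N-terminal Gln")
        if name == "oxidation_M" and sequence[pos - 1] != "M":
            raise MassError("oxidation_M requires Met")
        if name == "sulfo_Y" and sequence[pos - 1] != "Y":
            raise MassError("sulfo_Y requires Tyr")
        if name == "acetyl_Nterm" and pos != 1:
            raise MassError("acetyl_Nterm must sit on position 1")
        if name == "carbamidomethyl_C" and fixed_carbamidomethyl:
            raise MassError("carbamidomethyl is already applied as fixed")
        total += MOD_DELTA[name]
    if n_amid > 1:
        raise MassError("a peptide cannot be amidated twice (amide vs free acid)")
    return total


@dataclass
class MsIdentification:
    peptide_sequence: str
    modifications: list[tuple[str, int]] = field(default_factory=list)
    observed_mass: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.peptide_sequence) < MIN_PEPTIDE_LEN:
            raise ValueError(
                f"identification {self.source_id!r}: peptides shorter than "
                f"{MIN_PEPTIDE_LEN} residues are not accepted"
            )
        for name, pos in self.modifications:
            if not 1 <= pos <= len(self.peptide_sequence):
                raise ValueError(
                    f"identification {self.source_id!r}: modification position "
                    f"{pos} outside the peptide"
                )


@dataclass
class MsMatch:
    identification: MsIdentification
    precursor_id: Optional[str]
    start: Optional[int]  # 1-based on the precursor
    end: Optional[int]
    category: str
    mass_error: float
    is_primary: bool = False


def _classify_occurrence(
    s: int, e: int, ann: AnnotatedPrecursor, mono_positions: set[int]
) -> str:
    """Category of a located span (1-based inclusive) on one precursor."""
    cores = [(p.start, p.end) for p in ann.peptides]
    if (s, e) in cores:
        return "full_dibasic"
    if e in mono_positions:
        return "monobasic_product"
    for cs, ce in cores:
        if cs <= s and e <= ce:
            if s == cs:
                return "truncated_C"
            if e == ce:
                return "truncated_N"
            if s - cs <= TRUNCATION_WINDOW and ce - e <= TRUNCATION_WINDOW:
                return "truncated_both"
            return "internal"
    return "internal"


def match_identifications(
    identifications: Sequence[MsIdentification],
    precursors: Sequence[AnnotatedPrecursor],
    tol: float = 0.01,
    background: Sequence[ProteinRecord] = (),
) -> list[MsMatch]:
    """Locate each identification on the precursor set and classify it.

    All substring occurrences are reported; the primary match is chosen by
    category rank, then longest host precursor, then lexicographic id.
    Peptides found only in ``background`` proteins (records outside the
    discovered precursor set) are flagged novel_precursor.  The theoretical
    mass is recomputed from sequence + modifications and the difference to
    the observed mass recorded; a non-unmatched match with |mass_error| > tol
    raises, since identifications carry their own sequences and a larger gap
    indicates an inconsistent table.
    """
    if tol <= 0:
        raise ValueError("mass tolerance must be positive")
    mono_cache: dict[str, set[int]] = {}
    for ann in precursors:
        sites = find_cleavage_sites(ann.record.sequence, include_monobasic=True)
        mono_cache[ann.record.id] = {
            s.position for s in sites if s.site_type == "monobasic"
        }
    matches: list[MsMatch] = []
    for ident in identifications:
        theo = monoisotopic_mass(ident.peptide_sequence, ident.modifications)
        err = ident.observed_mass - theo
        found: list[MsMatch] = []
        for ann in precursors:
            seq = ann.record.residues
            start = seq.find(ident.peptide_sequence)
            while start != -1:
                s, e = start + 1, start + len(ident.peptide_sequence)
                cat = _classify_occurrence(s, e, ann, mono_cache[ann.record.id])
                found.append(MsMatch(ident, ann.record.id, s, e, cat, err))
                start = seq.find(ident.peptide_sequence, start + 1)
        if not found:
            for rec in background:
                start = rec.residues.find(ident.peptide_sequence)
                while start != -1:
                    s, e = start + 1, start + len(ident.peptide_sequence)
                    found.append(
                        MsMatch(ident, rec.id, s, e, "novel_precursor", err)
                    )
                    start = rec.residues.find(ident.peptide_sequence, start + 1)
        if not found:
            matches.append(MsMatch(ident, None, None, None, "unmatched", err))
            continue
        if abs(err) > tol:
            raise MassError(
                f"identification {ident.source_id!r}: observed mass deviates "
                f"from theoretical by {err:+.5f} Da (tolerance {tol})"
            )
        lengths = {m.precursor_id: 0 for m in found}
        for ann in precursors:
            if ann.record.id in lengths:
                lengths[ann.record.id] = len(ann.record.residues)
        for rec in background:
            if rec.id in lengths:
                lengths[rec.id] = len(rec.residues)
        found.sort(
            key=lambda m: (
                CATEGORY_RANK[m.category],
                -lengths[m.precursor_id],
                m.precursor_id,
            )
        )
        found[0].is_primary = True
        matches.extend(found)
    return matches


def confirmation_summary(matches: Sequence[MsMatch]) -> tuple[pd.DataFrame, dict]:
    """Per-precursor category counts plus pipeline totals.

    Totals mirror the bookkeeping of a confirmation run: how many distinct
    peptides confirm predicted dibasic products, on how many precursors, how
    many truncations/monobasic/internal products were seen, and which novel
    precursors are supported by how many peptides.
    """
    primary = [m for m in matches if m.is_primary or m.category == "unmatched"]
    rows = []
    for m in primary:
        rows.append(
            {
                "precursor_id": m.precursor_id or "-",
                "category": m.category,
                "peptide": m.identification.peptide_sequence,
            }
        )
    frame = pd.DataFrame(rows, columns=["precursor_id", "category", "peptide"])
    if len(frame):
        per_precursor = (
            frame[frame.precursor_id != "-"]
            .pivot_table(
                index="precursor_id",
                columns="category",
                values="peptide",
                aggfunc="count",
                fill_value=0,
            )
            .astype(int)
        )
    else:
        per_precursor = pd.DataFrame()

    def _count(cat: str) -> int:
        return int((frame.category == cat).sum()) if len(frame) else 0

    full = frame[frame.category == "full_dibasic"] if len(frame) else frame
    novel = frame[frame.category == "novel_precursor"] if len(frame) else frame
    totals = {
        "confirmed_full_peptides": _count("full_dibasic"),
        "confirmed_full_precursors": int(full.precursor_id.nunique()) if len(full) else 0,
        "truncated_peptides": _count("truncated_N")
        + _count("truncated_C")
        + _count("truncated_both"),
        "monobasic_peptides": _count("monobasic_product"),
        "internal_peptides": _count("internal"),
        "novel_peptides": _count("novel_precursor"),
        "novel_precursors": int(novel.precursor_id.nunique()) if len(novel) else 0,
        "unmatched": _count("unmatched"),
        "novel_support": (
            novel.groupby("precursor_id").size().to_dict() if len(novel) else {}
        ),
    }
    return per_precursor, totals


# --- identification table I/O -------------------------------------------------

def _format_mods(mods: Sequence[tuple[str, int]]) -> str:
    return ";".join(f"{name}@{pos}" for name, pos in mods) if mods else "-"


def _parse_mods(text: str) -> list[tuple[str, int]]:
    if not text or text == "-":
        return []
    out = []
    for item in text.split(";"):
        name, _, pos = item.partition("@")
        out.append((name, int(pos)))
    return out


def read_identifications(path) -> list[MsIdentification]:
    """Read the identification TSV (peptide_sequence, modifications, observed_mass, source_id).

    The modification column uses "name@pos;name@pos" syntax ('-' for none) —
    a documented subset of a MaxQuant peptides-table export.
    """
    idents = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            idents.append(
                MsIdentification(
                    peptide_sequence=row["peptide_sequence"],
                    modifications=_parse_mods(row["modifications"]),
                    observed_mass=float(row["observed_mass"]),
                    source_id=row.get("source_id", ""),
                )
            )
    return idents


def write_identifications(idents: Iterable[MsIdentification], path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide_sequence\tmodifications\tobserved_mass\tsource_id\n")
        for i in idents:
            fh.write(
                f"{i.peptide_sequence}\t{_format_mods(i.modifications)}\t"
                f"{i.observed_mass:.5f}\t{i.source_id}\n"
            )


def write_matches(matches: Iterable[MsMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "peptide_sequence\tprecursor_id\tstart\tend\tcategory\t"
            "mass_error\tis_primary\tsource_id\n"
        )
        for m in matches:
            fh.write(
                f"{m.identification.peptide_sequence}\t{m.precursor_id or '-'}\t"
                f"{m.start or 0}\t{m.end or 0}\t{m.category}\t"
                f"{m.mass_error:.5f}\t{int(m.is_primary)}\t"
                f"{m.identification.source_id}\n"
            )
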