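"""Readers/writers for the pipeline's file formats and a six-frame ORF translator.

The translator stands in for a full coding-potential predictor: downstream
motif screens only need candidate protein stretches, so every maximal
stop-free stretch of at least ``min_len`` residues (in all six frames) is
emitted, whether or not it starts at an ATG.  Transcriptome fragments
frequently truncate secreted precursors, so incomplete stretches are kept.

Coordinates are 0-based half-open internally; file formats and reports use
1-based inclusive positions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDES = set("ACGTN")


class FormatError(ValueError):
    """Raised for malformed input files or records."""


@dataclass
class ProteinRecord:
    """A translated transcript or protein sequence with provenance.

    ``sequence`` is upper-case over the 20 standard residues plus 'X'
    (ambiguous) and '*', where '*' may occur only as the final character
    (a retained stop codon, as translator output conventionally carries).
    """

    id: str
    sequence: str
    species: str = ""
    source_transcript: Optional[str] = None
    frame_start: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty id")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"protein record {self.id!r} has empty sequence")
        if "*" in self.sequence[:-1]:
            raise FormatError(
                f"protein record {self.id!r} contains an internal stop '*'"
            )
        bad = set(self.sequence) - AMINO_ACIDS - {"*", "X"}
        if bad:
            raise FormatError(
                f"protein record {self.id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def residues(self) -> str:
        """Sequence without a trailing stop symbol."""
        return self.sequence.rstrip("*")


@dataclass
class TranscriptRecord:
    """A nucleotide sequence over the ACGTN alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("transcript record with empty id")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"transcript {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SignalAnnotation:
    """Signal-peptide call for one protein (SignalP-short style).

    ``cleavage_after`` is the 1-based index of the last signal-peptide
    residue; the mature chain starts at ``cleavage_after + 1``.
    """

    protein_id: str
    has_signal: bool
    cleavage_after: Optional[int] = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.has_signal:
            if self.cleavage_after is None or self.cleavage_after < 1:
                raise FormatError(
                    f"signal annotation for {self.protein_id!r}: cleavage_after "
                    f"must be a positive integer when has_signal=Y"
                )


def _check_fasta_header(path: Path) -> None:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}: first non-blank line is not a FASTA header")
            return


def read_fasta(path, kind: str = "protein"):
    """Read a FASTA file into ProteinRecord or TranscriptRecord objects.

    Order is preserved; sequences are upper-cased with whitespace stripped.
    Duplicate ids and empty sequences are errors.
    """
    path = Path(path)
    _check_fasta_header(path)
    cls = ProteinRecord if kind == "protein" else TranscriptRecord
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).strip().upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(cls(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable, path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns.

    Round-trip property: ``read_fasta(write_fasta(x))`` reproduces ids and
    sequences exactly.
    """
    if wrap < 1:
        raise ValueError("wrap must be a positive integer")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


_FRAME_LABELS = ("+1", "+2", "+3", "-1", "-2", "-3")


def translate_orfs(
    transcripts: Iterable[TranscriptRecord],
    min_len: int = 60,
    species: str = "",
) -> list[ProteinRecord]:
    """Six-frame translation into maximal stop-free stretches.

    Every stop-free translated stretch of length >= ``min_len`` residues is
    emitted, in deterministic order (transcript, then frame +1..+3,-1..-3,
    then position).  Stretches ending at a stop codon keep a trailing '*';
    ``min_len`` counts residues excluding it.  Codons containing N translate
    to 'X' unless the amino acid is unambiguous.

    ``frame_start`` and the id's offset are the 0-based nucleotide offset of
    the stretch on the frame's own strand.
    """
    out: list[ProteinRecord] = []
    for tr in transcripts:
        bad = [i for i, c in enumerate(tr.sequence) if c not in NUCLEOTIDES]
        if bad:
            raise FormatError(
                f"transcript {tr.id!r}: invalid character "
                f"{tr.sequence[bad[0]]!r} at position {bad[0] + 1}"
            )
        fwd = tr.sequence
        rev = str(Seq(fwd).reverse_complement())
        for fi, label in enumerate(_FRAME_LABELS):
            strand_seq = fwd if fi < 3 else rev
            offset = fi % 3
            usable = len(strand_seq) - offset
            if usable < 3:
                continue
            coding = strand_seq[offset : offset + usable - usable % 3]
            aa = str(Seq(coding).translate())
            # split into maximal stop-free stretches, tracking positions
            start = 0
            for chunk in aa.split("*"):
                if len(chunk) >= min_len:
                    end = start + len(chunk)
                    stop_terminated = end < len(aa)  # a '*' followed
                    nt_start = offset + 3 * start
                    seq = chunk + ("*" if stop_terminated else "")
                    out.append(
                        ProteinRecord(
                            id=f"{tr.id}|{label}|{nt_start}",
                            sequence=seq,
                            species=species,
                            source_transcript=tr.id,
                            frame_start=nt_start,
                        )
                    )
                start += len(chunk) + 1
    return out


def read_signal_annotations(path) -> list[SignalAnnotation]:
    """Parse a tab-separated signal-annotation file.

    Columns: protein_id, has_signal (Y/N), cleavage_after, score.  Lines
    starting with '#' are comments.  Unknown protein ids are tolerated here
    and validated at use time.
    """
    path = Path(path)
    annotations = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 tab-separated columns")
            pid, flag, cleave, score = parts[:4]
            if flag not in ("Y", "N"):
                raise FormatError(f"{path}:{ln}: has_signal must be Y or N")
            has_signal = flag == "Y"
            cleavage_after = None
            if has_signal:
                try:
                    cleavage_after = int(cleave)
                except ValueError:
                    raise FormatError(
                        f"{path}:{ln}: cleavage_after {cleave!r} is not an integer"
                    ) from None
                if cleavage_after < 1:
                    raise FormatError(
                        f"{path}:{ln}: cleavage_after must be positive, got {cleave}"
                    )
            annotations.append(
                SignalAnnotation(
                    protein_id=pid,
                    has_signal=has_signal,
                    cleavage_after=cleavage_after,
                    score=float(score),
                )
            )
    return annotations


def write_signal_annotations(annotations: Iterable[SignalAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_id\thas_signal\tcleavage_after\tscore\n")
        for a in annotations:
            cleave = str(a.cleavage_after) if a.has_signal else "-"
            fh.write(f"{a.protein_id}\t{'Y' if a.has_signal else 'N'}\t{cleave}\t{a.score:.3f}\n")


# Kyte-Doolittle hydropathy, used by the optional built-in signal heuristic.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0, "*": 0.0,
}


def heuristic_signal(
    record: ProteinRecord, threshold: float = 1.6, window: int = 9, search_len: int = 30
) -> SignalAnnotation:
    """Crude hydrophobic-core signal-peptide heuristic.

    Calls a signal peptide when some ``window``-residue mean Kyte-Doolittle
    hydropathy within the first ``search_len`` residues exceeds ``threshold``.
    A rough cleavage position (end of the best window + 5, clipped) is
    reported.  This is a deliberately simple stand-in so the pipeline can run
    without an external predictor; real analyses should supply a proper
    signal-annotation file.
    """
    seq = record.residues[:search_len]
    best, best_end = float("-inf"), None
    for i in range(0, max(0, len(seq) - window + 1)):
        mean = sum(_KD[c] for c in seq[i : i + window]) / window
        if mean > best:
            best, best_end = mean, i + window
    if best_end is not None and best > threshold:
        cleave = min(best_end + 5, len(record.residues) - 1)
        if cleave >= 1:
            return SignalAnnotation(record.id, True, cleave, min(1.0, best / 4.5))
    return SignalAnnotation(record.id, False, None, 0.0)
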