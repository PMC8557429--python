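"""Exon-intron structure as homology evidence.

Intron positions are expressed in protein coordinates together with their
phase: phase 0 introns fall between codons (after residue ``protein_pos``),
phase 1/2 introns interrupt the codon of residue ``protein_pos`` after its
first/second nucleotide.  Orthologous precursors sharing an intron at the
same aligned position with the same phase — e.g. a phase-0 intron between
the codons of two C-terminal Cys residues, or a phase-2 intron inside a
cleavage-site codon — is strong evidence of common descent even when the
peptide sequences themselves have diverged.

Gene models are consumed as GFF3 (+ genomic FASTA); spliced alignment is out
of scope.  Ortholog alignments are consumed as aligned FASTA.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio.Seq import Seq

from .sequence_io import ProteinRecord


class GeneModelError(ValueError):
    pass


@dataclass
class GeneModel:
    """Coding exon structure of one gene (GFF3 conventions, 1-based inclusive).

    ``exons`` are the CDS segments in transcription order: ascending genomic
    coordinates on '+', descending on '-'.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_phase_start: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: strand must be '+' or '-'")
        ordered = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise GeneModelError(f"{self.gene_id}: overlapping exons")
        expected = ordered if self.strand == "+" else ordered[::-1]
        if list(self.exons) != expected:
            raise GeneModelError(
                f"{self.gene_id}: exons not in transcription order for strand "
                f"{self.strand}"
            )


@dataclass
class IntronAnnotation:
    intron_index: int  # 0-based, in transcription order
    protein_pos: int  # 1-based residue containing or preceding the intron
    phase: int  # 0, 1 or 2


def _cds_sequence(model: GeneModel, genome: Mapping[str, str]) -> str:
    if model.chrom not in genome:
        raise GeneModelError(f"{model.gene_id}: chromosome {model.chrom!r} not in genome")
    chrom = genome[model.chrom]
    parts = []
    for s, e in model.exons:
        if not 1 <= s <= e <= len(chrom):
            raise GeneModelError(f"{model.gene_id}: exon ({s},{e}) outside chromosome")
        seg = chrom[s - 1 : e]
        parts.append(str(Seq(seg).reverse_complement()) if model.strand == "-" else seg)
    return "".join(parts)


def protein_introns(
    model: GeneModel, protein: ProteinRecord, genome: Mapping[str, str]
) -> list[IntronAnnotation]:
    """Protein-coordinate intron positions and phases for one gene model.

    The translated CDS must equal the protein (a trailing stop on either side
    is ignored); any mismatch is an error naming the first differing residue.
    Phase = cumulative CDS nucleotides before the junction mod 3;
    protein_pos = cumulative // 3 for phase 0 (the intron follows that
    residue) and cumulative // 3 + 1 otherwise (the interrupted residue).
    Strand-symmetric: a reverse-complemented mirror model yields identical
    annotations.
    """
    cds = _cds_sequence(model, genome)
    if len(cds) % 3:
        raise GeneModelError(f"{model.gene_id}: CDS length {len(cds)} not a multiple of 3")
    translated = str(Seq(cds).translate()).rstrip("*")
    expected = protein.residues
    if translated != expected:
        n = min(len(translated), len(expected))
        diff = next(
            (i for i in range(n) if translated[i] != expected[i]), n
        )
        raise GeneModelError(
            f"{model.gene_id}: CDS translation differs from protein "
            f"{protein.id!r} at residue {diff + 1}"
        )
    annotations = []
    cumulative = 0
    for idx, (s, e) in enumerate(model.exons[:-1]):
        cumulative += e - s + 1
        phase = cumulative % 3
        protein_pos = cumulative // 3 if phase == 0 else cumulative // 3 + 1
        annotations.append(IntronAnnotation(idx, protein_pos, phase))
    return annotations


def read_gene_models(gff_path, genome: Optional[Mapping[str, str]] = None) -> dict[str, GeneModel]:
    """Read GFF3 gene models (gene/mRNA/CDS features).

    When a gene has multiple mRNAs the longest complete CDS is used
    (ties broken by transcript id).
    """
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        best = None
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = sorted(
                (f.start, f.end) for f in db.children(mrna, featuretype="CDS")
            )
            if not cds:
                continue
            total = sum(e - s + 1 for s, e in cds)
            key = (-total, mrna.id)
            if best is None or key < best[0]:
                best = (key, cds, gene.strand)
        if best is None:
            continue
        _, cds, strand = best
        exons = cds if strand == "+" else cds[::-1]
        models[gene.id] = GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=strand, exons=exons
        )
    return models


def _column_of_residue(aligned: str, residue_pos: int) -> int:
    """1-based alignment column of the ``residue_pos``-th non-gap character."""
    count = 0
    for col, c in enumerate(aligned, 1):
        if c != "-":
            count += 1
            if count == residue_pos:
                return col
    raise ValueError(f"residue {residue_pos} beyond aligned sequence")


def conserved_introns(
    annotated: Sequence[tuple[ProteinRecord, Sequence[IntronAnnotation]]],
    alignment: Mapping[str, str],
    col_tol: int = 2,
) -> pd.DataFrame:
    """Group introns conserved across orthologs.

    Each intron is projected to the alignment column of its ``protein_pos``;
    introns with identical phase whose columns agree within ``col_tol`` are
    called conserved (single-linkage grouping within phase).  Only groups
    with >= 2 members are reported: columns is per-member, size the group
    size.
    """
    rows = []
    for protein, introns in annotated:
        if protein.id not in alignment:
            raise ValueError(f"protein {protein.id!r} absent from the alignment")
        aligned = alignment[protein.id]
        for intron in introns:
            rows.append(
                {
                    "protein_id": protein.id,
                    "intron_index": intron.intron_index,
                    "protein_pos": intron.protein_pos,
                    "phase": intron.phase,
                    "column": _column_of_residue(aligned, intron.protein_pos),
                }
            )
    groups = []
    group_id = 0
    by_phase: dict[int, list[dict]] = {}
    for row in rows:
        by_phase.setdefault(row["phase"], []).append(row)
    for phase in sorted(by_phase):
        items = sorted(by_phase[phase], key=lambda r: (r["column"], r["protein_id"]))
        current: list[dict] = []
        for item in items:
            if current and item["column"] - current[-1]["column"] > col_tol:
                if len(current) >= 2:
                    groups.append((group_id, phase, current))
                    group_id += 1
                current = []
            current.append(item)
        if len(current) >= 2:
            groups.append((group_id, phase, current))
            group_id += 1
    out_rows = []
    for gid, phase, members in groups:
        for m in members:
            out_rows.append(
                {
                    "group": gid,
                    "phase": phase,
                    "size": len(members),
                    "protein_id": m["protein_id"],
                    "intron_index": m["intron_index"],
                    "protein_pos": m["protein_pos"],
                    "column": m["column"],
                }
            )
    return pd.DataFrame(
        out_rows,
        columns=["group", "phase", "size", "protein_id", "intron_index",
                 "protein_pos", "column"],
    )


def read_alignment_fasta(path) -> dict[str, str]:
    """Read an aligned FASTA into {id: aligned sequence} (gaps '-')."""
    from Bio import SeqIO

    alignment = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        alignment[rec.id] = str(rec.seq).upper()
    return alignment
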