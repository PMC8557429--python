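"""Deterministic sequence-similarity engine and the precursor similarity graph.

Local alignment is exact Smith-Waterman with affine gaps under BLOSUM62
(a gap of length L costs gap_open + gap_extend * L, the BLAST convention);
significance uses a Karlin-Altschul-style E-value

    E = K * m * n * exp(-lambda * S)

with the published gapped-BLOSUM62 constants lambda = 0.267, K = 0.041.
This replaces a heuristic search engine at desk scale; an adapter reads/writes
BLAST outfmt-6 tables so external search output can be swapped in for large
data.

The two-pass strategy mirrors the published protocol: a relaxed first pass
against reference queries, union with motif-screen candidates (after an
optional curation hook), then a stringent second pass using that union as the
new query set to recover hidden orthologs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import ProteinRecord

_MIN_SCORE_RESIDUES = ("X", "*", "B", "Z")


@dataclass
class SearchParams:
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    relaxed_evalue: float = 1e-1
    stringent_evalue: float = 1e-5
    cluster_evalue: float = 1e-5
    display_evalue: float = 1e-10

    def __post_init__(self) -> None:
        for t in (self.relaxed_evalue, self.stringent_evalue,
                  self.cluster_evalue, self.display_evalue):
            if t <= 0:
                raise ValueError("E-value thresholds must be positive")
        if self.relaxed_evalue < self.stringent_evalue:
            raise ValueError("relaxed threshold must be >= stringent threshold")


@dataclass
class AlignScore:
    query_id: str
    subject_id: str
    raw_score: int
    evalue: float


def _build_aligner(params: SearchParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(params.matrix)
    arr = matrix.copy()
    floor = matrix.min()
    alphabet = matrix.alphabet
    for r in _MIN_SCORE_RESIDUES:
        if r in alphabet:
            for c in alphabet:
                arr[r, c] = floor
                arr[c, r] = floor
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = arr
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


_aligner_cache: dict[tuple, Align.PairwiseAligner] = {}


def _aligner(params: SearchParams) -> Align.PairwiseAligner:
    key = (params.matrix, params.gap_open, params.gap_extend)
    if key not in _aligner_cache:
        _aligner_cache[key] = _build_aligner(params)
    return _aligner_cache[key]


def evalue(raw_score: float, m: int, n: int, params: Optional[SearchParams] = None) -> float:
    params = params or SearchParams()
    return params.K * m * n * math.exp(-params.lam * raw_score)


def local_align(
    a: ProteinRecord, b: ProteinRecord, params: Optional[SearchParams] = None
) -> AlignScore:
    """Optimal local alignment score and E-value for a sequence pair.

    'X' and '*' score the matrix minimum everywhere.
    """
    params = params or SearchParams()
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    score = _aligner(params).score(a.sequence, b.sequence)
    return AlignScore(
        query_id=a.id,
        subject_id=b.id,
        raw_score=int(score),
        evalue=evalue(score, len(a.sequence), len(b.sequence), params),
    )


def two_pass_search(
    proteome: Sequence[ProteinRecord],
    seed_queries: Sequence[ProteinRecord],
    params: Optional[SearchParams] = None,
    pattern_candidates: Sequence[ProteinRecord] = (),
    curation_hook: Optional[Callable[[Sequence[ProteinRecord]], Sequence[ProteinRecord]]] = None,
) -> dict[str, set[str]]:
    """Relaxed-then-stringent homology search with provenance tags.

    Pass 1 keeps proteome entries with E <= relaxed_evalue against any seed.
    The union of pass-1 hits and motif-screen candidates (optionally filtered
    by ``curation_hook``, which models the manual-curation step) becomes the
    query set of pass 2 at stringent_evalue.  Returns {protein_id: tags}
    where tags is a subset of {"pass1", "pass2", "pattern"}; the result is a
    superset of a single stringent pass with the original seeds.
    """
    params = params or SearchParams()
    if not seed_queries:
        raise ValueError("seed_queries must be non-empty")
    tags: dict[str, set[str]] = {}
    by_id = {r.id: r for r in proteome}

    def hits(queries: Sequence[ProteinRecord], threshold: float) -> list[str]:
        found = []
        for rec in proteome:
            for q in queries:
                if q.id == rec.id:
                    continue
                if local_align(q, rec, params).evalue <= threshold:
                    found.append(rec.id)
                    break
        return found

    for rid in hits(seed_queries, params.relaxed_evalue):
        tags.setdefault(rid, set()).add("pass1")
    for rec in pattern_candidates:
        tags.setdefault(rec.id, set()).add("pattern")

    second_queries = [by_id[rid] for rid in tags if rid in by_id]
    second_queries += [r for r in pattern_candidates if r.id not in by_id]
    if curation_hook is not None:
        second_queries = list(curation_hook(second_queries))
    if second_queries:
        for rid in hits(second_queries, params.stringent_evalue):
            tags.setdefault(rid, set()).add("pass2")
    return tags


def build_graph(
    records: Sequence[ProteinRecord],
    params: Optional[SearchParams] = None,
    threshold: float = 1e-5,
) -> nx.Graph:
    """All-vs-all similarity graph with edges at E-value < ``threshold``.

    Scores are symmetric (identical matrix both directions), so each
    unordered pair is aligned once; no self-edges.  Edge sets at a lower
    threshold are always a subset of those at a higher one.
    """
    if not records:
        raise ValueError("build_graph requires at least one record")
    params = params or SearchParams()
    g = nx.Graph()
    g.add_nodes_from(r.id for r in records)
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            s = local_align(a, b, params)
            if s.evalue < threshold:
                g.add_edge(a.id, b.id, evalue=s.evalue, raw_score=s.raw_score)
    return g


def components(graph: nx.Graph) -> list[list[str]]:
    """Connected components as clusters, largest first, ties by smallest member."""
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


# --- BLAST outfmt-6 adapter --------------------------------------------------

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_outfmt6(path) -> list[AlignScore]:
    """Read a BLAST tabular (outfmt 6) file into AlignScore records."""
    scores = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            scores.append(
                AlignScore(
                    query_id=parts[0],
                    subject_id=parts[1],
                    raw_score=int(round(float(parts[11]))),
                    evalue=float(parts[10]),
                )
            )
    return scores


def write_outfmt6(scores: Iterable[AlignScore], path) -> None:
    """Write AlignScore records as a minimal outfmt-6-style table.

    Alignment-coordinate columns not tracked here are written as 0.
    """
    with open(path, "w") as fh:
        for s in scores:
            fh.write(
                f"{s.query_id}\t{s.subject_id}\t0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{s.evalue:.3g}\t{s.raw_score}\n"
            )


def graph_from_scores(
    records: Sequence[ProteinRecord], scores: Iterable[AlignScore], threshold: float
) -> nx.Graph:
    """Build the similarity graph from externally computed scores.

    The minimum E-value of the two directions is used per unordered pair.
    """
    g = nx.Graph()
    g.add_nodes_from(r.id for r in records)
    best: dict[tuple[str, str], AlignScore] = {}
    for s in scores:
        if s.query_id == s.subject_id:
            continue
        key = tuple(sorted((s.query_id, s.subject_id)))
        if key not in best or s.evalue < best[key].evalue:
            best[key] = s
    for (a, b), s in best.items():
        if s.evalue < threshold:
            g.add_edge(a, b, evalue=s.evalue, raw_score=s.raw_score)
    return g
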