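"""Motif-based screen for multicopy neuropeptide precursors.

Secreted multicopy precursors betray themselves by repeated prohormone
convertase sites: runs of amidation units (Gly followed by a dibasic pair, or
a basic residue 2/4/6 positions before the Gly) or plain dibasic-pair runs.
The screen is defined by two published POSIX-ERE patterns::

    ((.{2,25}G[KR][KR])|(.{2,25}[KR](.{1}|.{3}|.{5})G[KR*])){3,}
    (.{5,25}[KR][KR]){5,}

With default parameters the generated patterns reproduce those strings
byte-for-byte (including the literal '*' in ``[KR*]`` — translated records
may retain a terminal stop, which can close an amidated C-terminal peptide).
Matching is unanchored and greedy, exactly as a regex engine evaluates the
published command; there is no bespoke repeat-counting heuristic, so the
accept/reject decision is engine-independent language membership.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align

from .sequence_io import ProteinRecord, SignalAnnotation

log = logging.getLogger(__name__)

#: The published patterns, verbatim.
PRINTED_AMIDATION_PATTERN = r"((.{2,25}G[KR][KR])|(.{2,25}[KR](.{1}|.{3}|.{5})G[KR*])){3,}"
PRINTED_DIBASIC_PATTERN = r"(.{5,25}[KR][KR]){5,}"


@dataclass
class PatternParams:
    """Tunable thresholds of the multicopy screen (defaults = published)."""

    amid_min_repeats: int = 3
    amid_spacer: tuple[int, int] = (2, 25)
    dibasic_min_repeats: int = 5
    dibasic_spacer: tuple[int, int] = (5, 25)
    max_precursor_len: int = 650
    dedup_identity: float = 0.95

    def __post_init__(self) -> None:
        if self.amid_min_repeats < 1 or self.dibasic_min_repeats < 1:
            raise ValueError("repeat minima must be >= 1")
        for lo, hi in (self.amid_spacer, self.dibasic_spacer):
            if lo < 0 or hi < lo:
                raise ValueError("spacer ranges must be non-empty")
        if not 0 < self.dedup_identity <= 1:
            raise ValueError("dedup_identity must be in (0, 1]")

    def amidation_pattern(self) -> str:
        lo, hi = self.amid_spacer
        return (
            f"((.{{{lo},{hi}}}G[KR][KR])|"
            f"(.{{{lo},{hi}}}[KR](.{{1}}|.{{3}}|.{{5}})G[KR*]))"
            f"{{{self.amid_min_repeats},}}"
        )

    def dibasic_pattern(self) -> str:
        lo, hi = self.dibasic_spacer
        return f"(.{{{lo},{hi}}}[KR][KR]){{{self.dibasic_min_repeats},}}"


assert PatternParams().amidation_pattern() == PRINTED_AMIDATION_PATTERN
assert PatternParams().dibasic_pattern() == PRINTED_DIBASIC_PATTERN


@dataclass
class PatternHit:
    protein_id: str
    matched_branch: str  # amidation | dibasic | both
    match_spans: list[tuple[int, int]]  # 1-based inclusive


def scan_multicopy(
    protein: ProteinRecord, params: Optional[PatternParams] = None
) -> Optional[PatternHit]:
    """Scan one protein with both multicopy patterns.

    Returns a hit iff either pattern matches anywhere in the sequence; the
    reported span per matching branch is the engine's leftmost greedy match
    (1-based inclusive).
    """
    params = params or PatternParams()
    seq = protein.sequence
    spans = []
    branches = []
    for name, pat in (
        ("amidation", params.amidation_pattern()),
        ("dibasic", params.dibasic_pattern()),
    ):
        m = re.search(pat, seq)
        if m:
            branches.append(name)
            spans.append((m.start() + 1, m.end()))
    if not branches:
        return None
    branch = branches[0] if len(branches) == 1 else "both"
    return PatternHit(protein_id=protein.id, matched_branch=branch, match_spans=spans)


def select_secretome(
    records: Iterable[ProteinRecord],
    annotations: Iterable[SignalAnnotation],
    missing: str = "drop",
) -> list[ProteinRecord]:
    """Restrict records to those with a predicted signal peptide.

    Applied BEFORE pattern scanning in the pipeline, mirroring the published
    order (the motif screen runs on the secretome to curb false positives).
    ``missing`` controls unannotated records: "drop" (default, logged) or
    "keep".
    """
    by_id = {a.protein_id: a for a in annotations}
    kept = []
    n_missing = 0
    for rec in records:
        ann = by_id.get(rec.id)
        if ann is None:
            n_missing += 1
            if missing == "keep":
                kept.append(rec)
            continue
        if ann.has_signal:
            kept.append(rec)
    if n_missing:
        log.warning("select_secretome: %d records without signal annotation (%s)",
                    n_missing, missing)
    return kept


def gate_by_signal(
    hits: Iterable[PatternHit],
    annotations: Iterable[SignalAnnotation],
    missing: str = "drop",
) -> list[PatternHit]:
    """Keep only hits whose protein carries a signal peptide."""
    by_id = {a.protein_id: a for a in annotations}
    kept = []
    for hit in hits:
        ann = by_id.get(hit.protein_id)
        if ann is None:
            log.warning("gate_by_signal: %s unannotated (%s)", hit.protein_id, missing)
            if missing == "keep":
                kept.append(hit)
            continue
        if ann.has_signal:
            kept.append(hit)
    return kept


def filter_length(records: Sequence[ProteinRecord], max_len: int = 650) -> list[ProteinRecord]:
    """Remove candidates longer than ``max_len`` residues.

    A record of exactly ``max_len`` residues is kept (only strictly longer
    candidates are deleted).  Length excludes a trailing stop symbol.
    """
    kept = [r for r in records if len(r.residues) <= max_len]
    removed = len(records) - len(kept)
    if removed:
        log.info("filter_length: removed %d records longer than %d aa", removed, max_len)
    return kept


# --- greedy redundancy reduction (CD-hit style) -----------------------------

_lcs_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1_000_000,
    open_gap_score=0,
    extend_gap_score=0,
)


def identity_over_shorter(a: str, b: str) -> float:
    """Maximum fraction of identically aligned residues over the shorter sequence.

    The maximum number of identities over all global alignments equals the
    longest common subsequence, computed here with a scoring scheme in which
    only matches pay.
    """
    if not a or not b:
        return 0.0
    matches = _lcs_aligner.score(a, b)
    return matches / min(len(a), len(b))


def _kmers(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def dedup_greedy(
    records: Sequence[ProteinRecord], identity: float = 0.95
) -> tuple[list[ProteinRecord], dict[str, list[str]]]:
    """Greedy longest-first redundancy reduction at an identity threshold.

    Records are visited in order of decreasing length (ties broken by id); a
    record joins the first representative with global-alignment identity over
    the shorter sequence >= ``identity``, else becomes a new representative.
    Idempotent: re-running on the representatives changes nothing.

    A conservative shared-4-mer prefilter skips hopeless alignments: identity
    >= t over the shorter sequence of length L forces >= (1 - 4(1 - t))L - 3
    shared 4-mers, so at thresholds >= 0.8 pairs sharing < 20% are rejected
    without aligning.  Decisions are unchanged.
    """
    order = sorted(records, key=lambda r: (-len(r.residues), r.id))
    reps: list[ProteinRecord] = []
    rep_kmers: list[set[str]] = []
    members: dict[str, list[str]] = {}
    use_prefilter = identity >= 0.8
    for rec in order:
        seq = rec.residues
        km = _kmers(seq) if use_prefilter else set()
        home = None
        for rep, rkm in zip(reps, rep_kmers):
            if use_prefilter and km:
                shared = len(km & rkm) / len(km)
                if shared < 0.2:
                    continue
            if identity_over_shorter(seq, rep.residues) >= identity:
                home = rep
                break
        if home is None:
            reps.append(rec)
            rep_kmers.append(km)
            members[rec.id] = [rec.id]
        else:
            members[home.id].append(rec.id)
    return reps, members
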