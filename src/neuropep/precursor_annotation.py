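"""Prohormone processing model: cleavage sites, mature peptides, architecture.

Secreted precursors are processed by prohormone convertases at basic sites.
The model here:

* every dibasic pair (KR/RR/KK/RK, scanned left-to-right without overlap)
  cleaves C-terminal to the pair, and carboxypeptidase trimming removes both
  basic residues from the mature products;
* a single Arg can act as an alternative (monobasic) cleavage point when a
  second basic residue lies 3-6 positions N-terminal of the cleavage site —
  off by default for peptide derivation, on for MS-match interpretation;
* a Gly left at a peptide's C-terminus (immediately before the downstream
  site, a retained stop, or the precursor end) is converted to a C-terminal
  amide and removed from the mature sequence;
* an N-terminal Gln marks potential pyroglutamate formation.

Tiling invariant: signal peptide + mature cores + removed amidation glycines
+ cleavage-site residues reconstructs the precursor exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .pattern_discovery import identity_over_shorter
from .sequence_io import ProteinRecord, SignalAnnotation

DIBASIC_MOTIFS = ("KR", "RR", "KK", "RK")
BASIC = set("KR")


@dataclass
class CleavageSite:
    """A predicted cleavage point.

    ``position`` is the 1-based index of the residue AFTER which cleavage
    occurs: for a dibasic site that is the second basic residue; for a
    monobasic site the residue preceding the Arg (cleavage is N-terminal to
    the Arg).
    """

    position: int
    site_type: str  # dibasic | monobasic | signal
    motif: str
    confidence: str = "standard"  # standard | alternative


@dataclass
class MaturePeptide:
    precursor_id: str
    start: int  # 1-based inclusive, unmodified core
    end: int
    sequence: str
    amidated: bool = False
    pyroglu: bool = False
    flanking: str = "dibasic-dibasic"
    consecutive_copy: bool = False


@dataclass
class ArchitectureClass:
    class_name: str  # multicopy | single_copy_plus_cys_domain | single_copy | cys8_peptide | other
    cys_positions: list[int] = field(default_factory=list)
    copy_count: int = 0


@dataclass
class AnnotatedPrecursor:
    record: ProteinRecord
    signal: SignalAnnotation
    sites: list[CleavageSite]
    peptides: list[MaturePeptide]
    architecture: ArchitectureClass


def find_cleavage_sites(seq: str, include_monobasic: bool = False) -> list[CleavageSite]:
    """Locate dibasic (and optionally monobasic) convertase sites.

    Dibasic pairs are consumed left-to-right without overlap, so ``KRKR``
    yields sites after positions 2 and 4 (the zero-length peptide between is
    dropped downstream — the consecutive-copy situation).  Monobasic sites
    require an unpaired Arg with a supporting K/R 3-6 positions N-terminal of
    the cleavage point and carry 'alternative' confidence.
    """
    seq = seq.rstrip("*")
    sites: list[CleavageSite] = []
    paired = set()  # 0-based indices consumed by dibasic pairs
    i = 0
    while i < len(seq) - 1:
        dimer = seq[i : i + 2]
        if dimer in DIBASIC_MOTIFS:
            sites.append(CleavageSite(position=i + 2, site_type="dibasic", motif=dimer))
            paired.update((i, i + 1))
            i += 2
        else:
            i += 1
    if include_monobasic:
        dibasic_positions = {s.position for s in sites}
        for p0, res in enumerate(seq):  # p0 is 0-based, Arg at 1-based p0+1
            if res != "R" or p0 in paired:
                continue
            # an Arg adjacent to another basic residue is part of a basic run,
            # not a lone monobasic site
            if (p0 > 0 and seq[p0 - 1] in BASIC) or (
                p0 + 1 < len(seq) and seq[p0 + 1] in BASIC
            ):
                continue
            p = p0 + 1
            # supporting basic residue at distance 3-6 N-terminal of the
            # cleavage point (which sits just before the Arg)
            support = any(
                1 <= p - d <= len(seq) and seq[p - d - 1] in BASIC for d in range(3, 7)
            )
            if support and p - 1 >= 1 and (p - 1) not in dibasic_positions:
                sites.append(
                    CleavageSite(
                        position=p - 1,
                        site_type="monobasic",
                        motif="R",
                        confidence="alternative",
                    )
                )
    sites.sort(key=lambda s: (s.position, s.site_type))
    return sites


def derive_peptides(
    precursor: ProteinRecord,
    sites: Sequence[CleavageSite],
    signal: Optional[SignalAnnotation] = None,
) -> list[MaturePeptide]:
    """Segment the post-signal region at dibasic sites into mature peptides.

    Only dibasic sites segment in standard mode (monobasic sites are an MS
    interpretation aid).  Within a segment a trailing Gly marks amidation and
    is removed; a leading Gln flags potential pyroglutamate.  Site residues
    belong to no peptide; empty segments are dropped.  A precursor without
    any internal site yields one peptide spanning signal end to the terminus.
    """
    seq = precursor.sequence
    core_seq = seq.rstrip("*")
    sig_end = (
        signal.cleavage_after if signal is not None and signal.has_signal else 0
    )
    dibasic = [
        s for s in sites if s.site_type == "dibasic" and s.position - 2 >= sig_end
    ]
    peptides: list[MaturePeptide] = []
    cursor = sig_end  # 0-based start of the next segment
    boundaries = [(s.position - 2, s.position) for s in dibasic]  # 0-based [pair)
    segments = []
    for pair_start, pair_end in boundaries:
        segments.append((cursor, pair_start, False))
        cursor = pair_end
    segments.append((cursor, len(core_seq), True))  # terminal segment
    n_dib = len(boundaries)
    for idx, (s0, s1, terminal) in enumerate(segments):
        if s1 <= s0:
            continue
        segment = core_seq[s0:s1]
        # a lone Gly segment has no peptide to amidate; keep it as a core
        amidated = segment.endswith("G") and len(segment) > 1
        core = segment[:-1] if amidated else segment
        if not core:
            continue
        if terminal and idx == 0:
            flanking = "dibasic-end"  # site-less precursor
        elif terminal:
            flanking = "dibasic-end"
        elif idx == 0 and sig_end > 0:
            flanking = "signal-dibasic"
        else:
            flanking = "dibasic-dibasic"
        peptides.append(
            MaturePeptide(
                precursor_id=precursor.id,
                start=s0 + 1,
                end=s0 + len(core),
                sequence=core,
                amidated=amidated,
                pyroglu=core.startswith("Q"),
                flanking=flanking,
            )
        )
    return peptides


def reconstruct(precursor: ProteinRecord, signal, sites, peptides) -> str:
    """Re-tile signal + peptides + removed glycines + site residues.

    Used to check the tiling invariant: the result must equal the precursor
    sequence exactly.
    """
    seq = precursor.sequence
    core_seq = seq.rstrip("*")
    sig_end = signal.cleavage_after if signal is not None and signal.has_signal else 0
    pieces = [core_seq[:sig_end]]
    events = []  # (start0, text)
    for p in peptides:
        text = p.sequence + ("G" if p.amidated else "")
        events.append((p.start - 1, text))
    for s in sites:
        if s.site_type == "dibasic" and s.position - 2 >= sig_end:
            events.append((s.position - 2, s.motif))
    events.sort()
    for _, text in events:
        pieces.append(text)
    pieces.append(seq[len(core_seq):])  # retained stop, if any
    return "".join(pieces)


def detect_consecutive_copies(
    peptides: Sequence[MaturePeptide], motif: str
) -> tuple[list[MaturePeptide], list[MaturePeptide]]:
    """Flag abutting peptide copies and derive their alternative products.

    When two or more peptides whose cores fully match ``motif`` (a regular
    expression) abut with no intersequence — separated only by the cleavage
    pair (and an amidation Gly) — processing can instead cleave after the
    last internal basic residue, yielding a shorter product (the GWamide-
    dipeptide situation for consecutive RGWamide copies).  Returns the
    peptides (flagged copies have ``consecutive_copy=True`` and flanking
    ``consecutive-copy``) and the alternative products.
    """
    pat = re.compile(motif)
    peps = [
        MaturePeptide(**{**p.__dict__}) for p in peptides
    ]
    n = len(peps)
    adjacent = [False] * n
    for i in range(n - 1):
        a, b = peps[i], peps[i + 1]
        if not (pat.fullmatch(a.sequence) and pat.fullmatch(b.sequence)):
            continue
        gap_start = a.end + (1 if a.amidated else 0) + 1  # first residue after copy+G
        # two site residues then the next peptide must start immediately
        if b.start == gap_start + 2:
            adjacent[i] = adjacent[i + 1] = True
    alternatives: list[MaturePeptide] = []
    for i, flag in enumerate(adjacent):
        if not flag:
            continue
        p = peps[i]
        p.consecutive_copy = True
        p.flanking = "consecutive-copy"
        last_basic = max(
            (j for j, c in enumerate(p.sequence) if c in BASIC), default=None
        )
        if last_basic is not None and last_basic < len(p.sequence) - 1:
            alt_seq = p.sequence[last_basic + 1 :]
            alternatives.append(
                MaturePeptide(
                    precursor_id=p.precursor_id,
                    start=p.start + last_basic + 1,
                    end=p.end,
                    sequence=alt_seq,
                    amidated=p.amidated,
                    pyroglu=alt_seq.startswith("Q"),
                    flanking="monobasic-involved",
                    consecutive_copy=True,
                )
            )
    return peps, alternatives


def classify_architecture(
    precursor: ProteinRecord,
    peptides: Sequence[MaturePeptide],
    copy_identity: float = 0.5,
) -> ArchitectureClass:
    """Classify the precursor layout.

    Precedence: cys8_peptide (terminal peptide with exactly 8 Cys) >
    single_copy_plus_cys_domain (one Cys-poor peptide followed by a region
    with >= 4 Cys, the neurophysin-style layout) > multicopy (>= 3 copies at
    pairwise identity >= ``copy_identity`` over the shorter copy) >
    single_copy > other.  Deterministic under permutations of equal-position
    peptides (peptides are ordered by start).
    """
    seq = precursor.residues
    cys_positions = [i + 1 for i, c in enumerate(seq) if c == "C"]
    peps = sorted(peptides, key=lambda p: (p.start, p.end))
    if not peps:
        return ArchitectureClass("other", cys_positions, 0)
    # copy grouping by greedy seed clustering; the length-ratio guard keeps
    # short tails/spacers from degenerately matching a copy over their own
    # couple of residues
    def _same_copy(a: str, b: str) -> bool:
        if min(len(a), len(b)) / max(len(a), len(b)) < 0.5:
            return False
        return identity_over_shorter(a, b) >= copy_identity

    clusters: list[list[MaturePeptide]] = []
    for p in peps:
        for cl in clusters:
            if _same_copy(p.sequence, cl[0].sequence):
                cl.append(p)
                break
        else:
            clusters.append([p])
    copy_count = max(len(cl) for cl in clusters)

    terminal = peps[-1]
    if terminal.sequence.count("C") == 8:
        return ArchitectureClass("cys8_peptide", cys_positions, copy_count)
    non_cys = [p for p in peps if p.sequence.count("C") < 2]
    if len(non_cys) == 1 and non_cys[0] is peps[0]:
        after = seq[peps[0].end :]
        if after.count("C") >= 4:
            return ArchitectureClass(
                "single_copy_plus_cys_domain", cys_positions, copy_count
            )
    if copy_count >= 3:
        return ArchitectureClass("multicopy", cys_positions, copy_count)
    if len(peps) == 1:
        return ArchitectureClass("single_copy", cys_positions, copy_count)
    return ArchitectureClass("other", cys_positions, copy_count)


def annotate_precursor(
    record: ProteinRecord,
    signal: Optional[SignalAnnotation] = None,
    include_monobasic: bool = False,
) -> AnnotatedPrecursor:
    """Full annotation: sites, mature peptides, architecture."""
    if signal is None:
        signal = SignalAnnotation(record.id, False, None, 0.0)
    sites = find_cleavage_sites(record.sequence, include_monobasic=include_monobasic)
    peptides = derive_peptides(record, sites, signal)
    architecture = classify_architecture(record, peptides)
    return AnnotatedPrecursor(record, signal, sites, peptides, architecture)


def render_precursor(ann: AnnotatedPrecursor) -> str:
    """Human-readable rendering in supplementary-list style.

    Signal peptide in lower case, cleavage-site residues bracketed, amidation
    glycines marked 'g', mature peptides upper case.
    """
    seq = ann.record.sequence
    core = seq.rstrip("*")
    sig_end = ann.signal.cleavage_after if ann.signal.has_signal else 0
    marks = ["."] * len(core)
    for i in range(sig_end):
        marks[i] = "s"
    for s in ann.sites:
        if s.site_type == "dibasic":
            marks[s.position - 2] = marks[s.position - 1] = "b"
    out = []
    for p in ann.peptides:
        for i in range(p.start - 1, p.end):
            marks[i] = "P"
        if p.amidated:
            marks[p.end] = "g"
    rendered = []
    for c, m in zip(core, marks):
        if m == "s":
            rendered.append(c.lower())
        elif m == "b":
            rendered.append(f"[{c}]")
        elif m == "g":
            rendered.append("g")
        else:
            rendered.append(c)
    pep_lines = [
        f"  {p.start:>4}-{p.end:<4} {p.sequence}"
        f"{'-NH2' if p.amidated else ''}{' (pyroGlu?)' if p.pyroglu else ''}"
        for p in ann.peptides
    ]
    return "\n".join(
        [f">{ann.record.id} [{ann.architecture.class_name}]", "".join(rendered)]
        + pep_lines
    )
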