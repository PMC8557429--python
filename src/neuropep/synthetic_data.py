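"""Ground-truth generators for every pipeline stage.

The generators emulate the statistical structure the discovery procedure
assumes: secreted precursors with a signal peptide followed by repeated
peptide copies flanked by basic cleavage sites and amidation glycines;
single-copy precursors trailed by a Cys-rich carrier domain; short 8-Cys
amidated terminal peptides; and a decoy background of globular proteins,
secreted non-precursors and glycine-rich traps (the class of sequence known
to cluster spuriously with glycine-rich precursors).  Gene-model and MS
generators plant intron positions/phases and identification categories whose
exact recovery downstream is the test.

Every generator is fully deterministic for a fixed seed.  Discoverable
planted precursors are verified against the published regex patterns (and
the signal gate and length cutoff) at generation time, so a discovery recall
below 1.0 is always an implementation defect, never generator noise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .ms_confirmation import (
    MIN_PEPTIDE_LEN,
    MsIdentification,
    monoisotopic_mass,
)
from .pattern_discovery import (
    PRINTED_AMIDATION_PATTERN,
    PRINTED_DIBASIC_PATTERN,
)
from .precursor_annotation import AnnotatedPrecursor, find_cleavage_sites
from .sequence_io import ProteinRecord, SignalAnnotation, TranscriptRecord

_ORACLE_AMID = re.compile(PRINTED_AMIDATION_PATTERN)
_ORACLE_DIBASIC = re.compile(PRINTED_DIBASIC_PATTERN)

# spacer alphabet avoids K/R/G so planted copies, not intersequences, carry
# the motif signal; decoys cover the enriched side
_SPACER_AA = "ASTNQDEPVHLI"
_GLOBULAR_AA = "ACDEFGHIKLMNPQRSTVWY"
_HYDROPHOBIC = "LIVFM"
_DIBASIC = ("KR", "RR", "KK", "RK")


class GenerationError(ValueError):
    pass


@dataclass
class FamilySpec:
    """Recipe for one synthetic precursor family.

    ``copy_motif`` uses 'x' for wildcard positions filled once per family
    (conserved across members); the trailing residue list stays protected
    from ortholog divergence so copies remain recognizable.
    """

    family_id: str
    architecture: str = "multicopy"  # multicopy | single_copy_plus_cys_domain | cys8_peptide
    copy_motif: str = "AFLRF"
    copy_count_range: tuple[int, int] = (4, 7)
    spacer_len_range: tuple[int, int] = (4, 16)
    amidated: bool = True
    cys_domain_len: int = 0
    cys_count: int = 0
    n_members: int = 8
    substitution_rate: float = 0.08
    discoverable: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.spacer_len_range
        if lo < 0 or hi < lo:
            raise GenerationError(f"{self.family_id}: empty spacer range")
        if self.discoverable and self.architecture == "multicopy":
            # the published patterns bound (spacer + copy) length at 25
            limit = 25 - len(self.copy_motif) - (1 if self.amidated else 0)
            if hi > limit:
                raise GenerationError(
                    f"{self.family_id}: spacer up to {hi} cannot satisfy the "
                    f"published repeat pattern (max {limit} for this motif)"
                )
            min_repeats = 3 if self.amidated else 5
            if self.copy_count_range[0] < min_repeats:
                raise GenerationError(
                    f"{self.family_id}: discoverable families need >= "
                    f"{min_repeats} copies, got {self.copy_count_range[0]}"
                )


@dataclass
class TruthTable:
    """Ground-truth labels consumed by the acceptance tests."""

    record_label: dict[str, str] = field(default_factory=dict)  # id -> label
    record_family: dict[str, str] = field(default_factory=dict)
    discoverable: dict[str, bool] = field(default_factory=dict)
    ms_category: dict[str, str] = field(default_factory=dict)  # source_id -> category
    ms_precursor: dict[str, str] = field(default_factory=dict)
    intron_truth: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def planted_ids(self, discoverable_only: bool = False) -> list[str]:
        out = []
        for rid, label in self.record_label.items():
            if label != "planted_precursor":
                continue
            if discoverable_only and not self.discoverable.get(rid, False):
                continue
            out.append(rid)
        return out


def _signal_peptide(rng: np.random.Generator) -> str:
    """Canonical signal peptide: charged n-region, hydrophobic core, AXA end."""
    n_region = "M" + str(rng.choice(list("KR")))
    h_region = "".join(rng.choice(list(_HYDROPHOBIC), size=12))
    c_region = "S" + "A" + str(rng.choice(list("QSG"))) + "A"
    return n_region + h_region + c_region


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = _SPACER_AA) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _fill_motif(motif: str, rng: np.random.Generator) -> str:
    return "".join(
        str(rng.choice(list(_SPACER_AA))) if c == "x" else c for c in motif
    )


def _mutate(seq: str, protected: set[int], rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            out[i] = str(rng.choice(list(_SPACER_AA)))
    return "".join(out)


def _build_multicopy(spec: FamilySpec, copy_seq: str, rng: np.random.Generator) -> tuple[str, set[int]]:
    """Post-signal body of a multicopy precursor; returns (body, protected positions)."""
    lo, hi = spec.copy_count_range
    n_copies = int(rng.integers(lo, hi + 1))
    slo, shi = spec.spacer_len_range
    parts: list[str] = []
    protected: set[int] = set()
    pos = 0
    for _ in range(n_copies):
        spacer = _random_seq(rng, int(rng.integers(slo, shi + 1)))
        parts.append(spacer)
        pos += len(spacer)
        unit = copy_seq + ("G" if spec.amidated else "")
        parts.append(unit)
        protected.update(range(pos, pos + len(unit)))
        pos += len(unit)
        dimer = str(rng.choice(_DIBASIC))
        parts.append(dimer)
        protected.update(range(pos, pos + 2))
        pos += 2
    tail = _random_seq(rng, int(rng.integers(3, 10)))
    parts.append(tail)
    return "".join(parts), protected


def _build_cys8(spec: FamilySpec, rng: np.random.Generator) -> tuple[str, set[int]]:
    """Non-conserved peptide + dibasic site + amidated 8-Cys terminal peptide."""
    lead = _random_seq(rng, int(rng.integers(10, 20)))
    # 8 Cys at conserved offsets, aromatic between C6 and C7, amidated Trp end
    inter = [3, 2, 4, 3, 5, 2, 3]
    body = ["C"]
    for k, gap in enumerate(inter):
        body.append(_random_seq(rng, gap))
        if k == 5:
            body.append("W")  # aromatic between the sixth and seventh Cys
        body.append("C")
    peptide = "".join(body) + "W"
    parts = lead + "KR" + peptide + "G"
    protected = set(range(len(lead), len(parts)))
    return parts, protected


def _build_cys_domain(spec: FamilySpec, copy_seq: str, rng: np.random.Generator) -> tuple[str, set[int]]:
    """Single amidated peptide + dibasic site + Cys-rich carrier domain."""
    peptide = copy_seq + "G"
    domain_len = spec.cys_domain_len or 80
    n_cys = spec.cys_count or 10
    domain = list(_random_seq(rng, domain_len))
    cys_at = rng.choice(domain_len, size=n_cys, replace=False)
    for i in cys_at:
        domain[int(i)] = "C"
    body = peptide + "KR" + "".join(domain)
    protected = set(range(0, len(peptide) + 2)) | {
        len(peptide) + 2 + int(i) for i in cys_at
    }
    return body, protected


def oracle_accepts(sequence: str) -> bool:
    """Direct evaluation of the two published patterns (generator-side oracle)."""
    return bool(_ORACLE_AMID.search(sequence) or _ORACLE_DIBASIC.search(sequence))


def default_family_specs() -> list[FamilySpec]:
    """The default study conditions: five discoverable multicopy families of
    eight members each plus two non-multicopy architectures recoverable only
    by similarity (mirroring single-copy precursor classes)."""
    return [
        FamilySpec("FMRFa-like", copy_motif="xFMRF", amidated=True,
                   copy_count_range=(4, 7), spacer_len_range=(4, 14)),
        FamilySpec("Wamide-like", copy_motif="AxRGW", amidated=True,
                   copy_count_range=(3, 6), spacer_len_range=(2, 12)),
        # the internal Arg with a Lys five positions N-terminal guarantees a
        # supported monobasic cleavage point inside every copy, mirroring the
        # peptides that suggested alternative processing in real data
        FamilySpec("pedal-like", copy_motif="PKDFSxRLG", amidated=False,
                   copy_count_range=(6, 9), spacer_len_range=(5, 14)),
        FamilySpec("allatostatin-like", copy_motif="xSxYNFGL", amidated=True,
                   copy_count_range=(4, 6), spacer_len_range=(3, 14)),
        FamilySpec("luqin-like", copy_motif="xxPSLRL", amidated=True,
                   copy_count_range=(3, 5), spacer_len_range=(2, 15)),
        FamilySpec("vasotocin-like", architecture="single_copy_plus_cys_domain",
                   copy_motif="CYIQNCPRG"[:8], amidated=True,
                   cys_domain_len=80, cys_count=12, discoverable=False),
        FamilySpec("CCWamide-like", architecture="cys8_peptide",
                   copy_motif="", amidated=True, discoverable=False),
    ]


def generate_proteome(
    specs: Optional[Sequence[FamilySpec]] = None,
    n_decoys: int = 1000,
    seed: int = 0,
    species_prefix: str = "syn",
) -> tuple[list[ProteinRecord], list[SignalAnnotation], TruthTable]:
    """Synthetic proteome: planted families + signal TSV rows + truth labels.

    Planted members carry the canonical signal peptide (annotated in the
    signal list); decoys alternate between globular sequences without a
    signal, signal-bearing non-precursors, and glycine-rich traps.  Every
    record labeled discoverable is re-checked against the published patterns
    (plus signal and 650-aa gate) before emission.
    """
    specs = list(specs) if specs is not None else default_family_specs()
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    annotations: list[SignalAnnotation] = []
    truth = TruthTable()

    for spec in specs:
        copy_seq = _fill_motif(spec.copy_motif, rng)
        # family consensus body, then per-member divergence
        if spec.architecture == "multicopy":
            body, protected = _build_multicopy(spec, copy_seq, rng)
        elif spec.architecture == "cys8_peptide":
            body, protected = _build_cys8(spec, rng)
        elif spec.architecture == "single_copy_plus_cys_domain":
            body, protected = _build_cys_domain(spec, copy_seq, rng)
        else:
            raise GenerationError(f"unknown architecture {spec.architecture!r}")
        for m in range(spec.n_members):
            signal = _signal_peptide(rng)
            member_body = _mutate(body, protected, spec.substitution_rate, rng)
            seq = signal + member_body
            rid = f"{species_prefix}{m}|{spec.family_id}"
            if spec.discoverable:
                for _ in range(20):
                    if oracle_accepts(seq) and len(seq) <= 650:
                        break
                    member_body = _mutate(body, protected, spec.substitution_rate, rng)
                    seq = signal + member_body
                else:
                    raise GenerationError(
                        f"{spec.family_id}: could not build a member satisfying "
                        f"the published discovery thresholds"
                    )
            records.append(ProteinRecord(id=rid, sequence=seq, species=f"{species_prefix}{m}"))
            annotations.append(SignalAnnotation(rid, True, len(signal), 0.9))
            truth.record_label[rid] = "planted_precursor"
            truth.record_family[rid] = spec.family_id
            truth.discoverable[rid] = spec.discoverable

    kinds = ("globular", "secreted_nonprecursor", "glycine_rich_trap")
    for d in range(n_decoys):
        kind = kinds[d % 3]
        length = int(rng.integers(80, 620))
        if kind == "globular":
            seq = "M" + _random_seq(rng, length, _GLOBULAR_AA)
            has_signal = False
        elif kind == "secreted_nonprecursor":
            signal = _signal_peptide(rng)
            seq = signal + _random_seq(rng, length, _GLOBULAR_AA)
            has_signal = True
        else:  # glycine-rich trap: collagen-like composition with occasional
            # basic residues, the kind of sequence that clusters spuriously
            # with glycine-rich precursors and sometimes slips past the motifs
            signal = _signal_peptide(rng)
            trap_aa = list("GSAPTNQKR")
            trap_p = np.array([0.35, 0.14, 0.14, 0.09, 0.08, 0.06, 0.06, 0.04, 0.04])
            body = "".join(rng.choice(trap_aa, size=length, p=trap_p))
            seq = signal + body
            has_signal = True
        rid = f"decoy{d}|{kind}"
        records.append(ProteinRecord(id=rid, sequence=seq))
        annotations.append(
            SignalAnnotation(rid, has_signal, 19 if has_signal else None,
                             0.8 if has_signal else 0.05)
        )
        truth.record_label[rid] = (
            "decoy_trap" if kind == "glycine_rich_trap" else "decoy"
        )
        truth.discoverable[rid] = False
    return records, annotations, truth


# --- gene models ---------------------------------------------------------------

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["CTT", "CTC", "CTA", "CTG", "TTA", "TTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA"],
    "S": ["TCT", "TCC", "TCA", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for res in protein:
        if res not in _CODONS:
            raise GenerationError(f"cannot back-translate residue {res!r}")
        codons.append(str(rng.choice(_CODONS[res])))
    return "".join(codons) + "TAA"


def _intron_seq(rng: np.random.Generator) -> str:
    inner = _random_seq(rng, int(rng.integers(56, 496)), "ACGT")
    return "GT" + inner + "AG"


def generate_gene_models(
    proteins: Sequence[ProteinRecord],
    intron_plan: Mapping[str, Sequence[tuple[int, int]]],
    seed: int = 0,
    strands: Optional[Mapping[str, str]] = None,
) -> tuple[dict[str, str], str, dict[str, list[tuple[int, int]]]]:
    """Emit a genome FASTA dict + GFF3 text with planted introns.

    ``intron_plan`` maps protein id -> [(protein_pos, phase), ...]; an intron
    with phase 0 is placed after that residue's codon, phases 1/2 inside it.
    Returns (genome, gff3_text, truth) where truth records the plan actually
    planted; ``protein_introns`` on the output recovers it exactly.
    """
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    gff_lines = ["##gff-version 3"]
    truth: dict[str, list[tuple[int, int]]] = {}
    for prot in proteins:
        plan = sorted(intron_plan.get(prot.id, ()))
        seq = prot.residues
        cds = _back_translate(seq, rng)
        cuts = []
        for pos, phase in plan:
            if not 1 <= pos <= len(seq):
                raise GenerationError(
                    f"{prot.id}: planned intron position {pos} beyond protein"
                )
            cut = pos * 3 if phase == 0 else (pos - 1) * 3 + phase
            if not 0 < cut < len(cds):
                raise GenerationError(f"{prot.id}: intron cut {cut} outside CDS")
            cuts.append(cut)
        if sorted(set(cuts)) != cuts:
            raise GenerationError(f"{prot.id}: intron plan positions collide")
        segments = []
        prev = 0
        for cut in cuts:
            segments.append(cds[prev:cut])
            prev = cut
        segments.append(cds[prev:])
        strand = (strands or {}).get(prot.id, "+")
        gene_id = prot.id.replace("|", "_")
        chrom = f"chr_{gene_id}"
        flank5 = _random_seq(rng, int(rng.integers(50, 200)), "ACGT")
        flank3 = _random_seq(rng, int(rng.integers(50, 200)), "ACGT")
        pieces = [flank5]
        exon_coords = []  # 1-based inclusive on the forward genome
        pos = len(flank5)
        for k, seg in enumerate(segments):
            exon_coords.append((pos + 1, pos + len(seg)))
            pieces.append(seg)
            pos += len(seg)
            if k < len(segments) - 1:
                intron = _intron_seq(rng)
                pieces.append(intron)
                pos += len(intron)
        pieces.append(flank3)
        fwd = "".join(pieces)
        if strand == "-":
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            fwd_rc = "".join(comp[c] for c in reversed(fwd))
            L = len(fwd)
            exon_coords = [(L - e + 1, L - s + 1) for s, e in exon_coords][::-1]
            fwd = fwd_rc
        genome[chrom] = fwd
        gene_start = min(s for s, _ in exon_coords)
        gene_end = max(e for _, e in exon_coords)
        gff_lines.append(
            f"{chrom}\tsynthetic\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t"
            f"ID={gene_id}"
        )
        gff_lines.append(
            f"{chrom}\tsynthetic\tmRNA\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t"
            f"ID={gene_id}.t1;Parent={gene_id}"
        )
        ordered = exon_coords if strand == "+" else exon_coords[::-1]
        cumulative = 0
        for s, e in ordered:
            gff_phase = (3 - cumulative % 3) % 3
            gff_lines.append(
                f"{chrom}\tsynthetic\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                f"Parent={gene_id}.t1"
            )
            gff_lines.append(
                f"{chrom}\tsynthetic\tCDS\t{s}\t{e}\t.\t{strand}\t{gff_phase}\t"
                f"ID=cds_{gene_id};Parent={gene_id}.t1"
            )
            cumulative += e - s + 1
        truth[gene_id] = list(plan)
    return genome, "\n".join(gff_lines) + "\n", truth


# --- MS identifications --------------------------------------------------------

MS_CATEGORIES = (
    "full_dibasic", "truncated_N", "truncated_C", "truncated_both",
    "internal", "monobasic_product", "novel_precursor",
)


def _standard_mods(peptide, core_required: bool = True) -> list[tuple[str, int]]:
    mods = []
    if peptide.amidated:
        mods.append(("amidation", len(peptide.sequence)))
    return mods


def generate_ms_identifications(
    precursors: Sequence[AnnotatedPrecursor],
    category_mix: Mapping[str, float],
    n: int = 200,
    seed: int = 0,
    novel_precursors: Sequence[AnnotatedPrecursor] = (),
    mass_sigma: float = 0.0,
) -> tuple[list[MsIdentification], TruthTable]:
    """Sample identifications per category with exact ground-truth labels.

    Categories follow the matcher's taxonomy.  Truncations remove 1-3
    residues from the stated end (1 each side for truncated_both); internal
    windows sit >= 4 residues from every predicted boundary; monobasic
    products end at a predicted monobasic cleavage point; novel peptides are
    full cores of held-out precursors absent from the discovery set.
    Truncation cut points that coincide with a monobasic site are resampled,
    so generator truth and matcher taxonomy agree by construction.  Observed
    mass is the theoretical mass plus optional Gaussian error (default 0).
    """
    mix = dict(category_mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise GenerationError("category_mix proportions must sum to 1")
    unknown = set(mix) - set(MS_CATEGORIES)
    if unknown:
        raise GenerationError(f"unknown MS categories {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    truth = TruthTable()
    out: list[MsIdentification] = []

    mono_sites: dict[str, list[int]] = {}
    for ann in precursors:
        sites = find_cleavage_sites(ann.record.sequence, include_monobasic=True)
        mono_sites[ann.record.id] = [
            s.position for s in sites if s.site_type == "monobasic"
        ]

    def eligible_cores(min_len: int):
        cores = []
        for ann in precursors:
            for p in ann.peptides:
                if len(p.sequence) >= min_len:
                    cores.append((ann, p))
        return cores

    def pick(pool):
        if not pool:
            return None
        return pool[int(rng.integers(len(pool)))]

    counts = {cat: int(round(mix.get(cat, 0.0) * n)) for cat in MS_CATEGORIES}
    # distribute rounding remainder deterministically
    short = n - sum(counts.values())
    for cat in sorted(mix, key=lambda c: -mix[c]):
        if short == 0:
            break
        counts[cat] += 1
        short -= 1

    def emit(seq, mods, category, precursor_id, tag):
        theo = monoisotopic_mass(seq, mods)
        obs = theo + (rng.normal(0.0, mass_sigma) if mass_sigma > 0 else 0.0)
        sid = f"ms{len(out)}|{tag}"
        out.append(MsIdentification(seq, mods, obs, sid))
        truth.ms_category[sid] = category
        truth.ms_precursor[sid] = precursor_id

    for cat, count in counts.items():
        made = 0
        attempts = 0
        while made < count:
            attempts += 1
            if attempts > 200 * max(count, 1):
                raise GenerationError(
                    f"no eligible peptide for category {cat!r} "
                    f"(made {made} of {count})"
                )
            if cat == "full_dibasic":
                chosen = pick(eligible_cores(MIN_PEPTIDE_LEN))
                if chosen is None:
                    raise GenerationError("no predicted peptide long enough for full_dibasic")
                ann, p = chosen
                emit(p.sequence, _standard_mods(p), cat, ann.record.id, cat)
            elif cat in ("truncated_N", "truncated_C", "truncated_both"):
                chosen = pick(eligible_cores(MIN_PEPTIDE_LEN + 4))
                if chosen is None:
                    raise GenerationError(f"no core long enough to truncate for {cat}")
                ann, p = chosen
                if cat == "truncated_N":
                    cut = int(rng.integers(1, 4))
                    seq = p.sequence[cut:]
                    end = p.end
                elif cat == "truncated_C":
                    cut = int(rng.integers(1, 4))
                    seq = p.sequence[:-cut]
                    end = p.end - cut
                else:
                    seq = p.sequence[1:-1]
                    end = p.end - 1
                if len(seq) < MIN_PEPTIDE_LEN:
                    continue
                # a truncation ending at a monobasic cleavage point would be
                # (correctly) read as monobasic evidence; resample
                if cat != "truncated_N" and end in mono_sites[ann.record.id]:
                    continue
                mods = []
                if cat == "truncated_N" and p.amidated:
                    mods = [("amidation", len(seq))]
                emit(seq, mods, cat, ann.record.id, cat)
            elif cat == "internal":
                chosen = pick(eligible_cores(MIN_PEPTIDE_LEN + 8))
                if chosen is None:
                    raise GenerationError("no core long enough for internal windows")
                ann, p = chosen
                lo = p.start + 4
                hi = p.end - 4
                if hi - lo + 1 < MIN_PEPTIDE_LEN:
                    continue
                w = int(rng.integers(MIN_PEPTIDE_LEN, hi - lo + 2))
                s = int(rng.integers(lo, hi - w + 2))
                e = s + w - 1
                if e in mono_sites[ann.record.id]:
                    continue
                seq = ann.record.residues[s - 1 : e]
                emit(seq, [], cat, ann.record.id, cat)
            elif cat == "monobasic_product":
                candidates = []
                for ann in precursors:
                    for p in ann.peptides:
                        for mpos in mono_sites[ann.record.id]:
                            if p.start <= mpos < p.end:
                                seq = ann.record.residues[p.start - 1 : mpos]
                                if len(seq) >= MIN_PEPTIDE_LEN:
                                    candidates.append((ann, p.start, mpos, seq))
                chosen = pick(candidates)
                if chosen is None:
                    raise GenerationError(
                        "no precursor offers a monobasic product >= 4 residues; "
                        "add a family whose copies contain a supported internal Arg"
                    )
                ann, s, mpos, seq = chosen
                emit(seq, [], cat, ann.record.id, cat)
            elif cat == "novel_precursor":
                pool = []
                for ann in novel_precursors:
                    for p in ann.peptides:
                        if len(p.sequence) >= MIN_PEPTIDE_LEN:
                            pool.append((ann, p))
                chosen = pick(pool)
                if chosen is None:
                    raise GenerationError(
                        "novel_precursor requested but no held-out precursors given"
                    )
                ann, p = chosen
                emit(p.sequence, _standard_mods(p), cat, ann.record.id, cat)
            made += 1
    return out, truth


# --- transcript wrapping --------------------------------------------------------

def proteins_to_transcripts(
    proteins: Sequence[ProteinRecord], seed: int = 0
) -> list[TranscriptRecord]:
    """Back-translate proteins into single-ORF transcripts with UTR flanks.

    Lets pipeline tests exercise the six-frame translator end to end.
    """
    rng = np.random.default_rng(seed)
    out = []
    for prot in proteins:
        cds = _back_translate(prot.residues, rng)
        utr5 = _random_seq(rng, int(rng.integers(10, 60)), "ACT")  # no ATG/stop risk control
        utr3 = _random_seq(rng, int(rng.integers(10, 60)), "ACGT")
        out.append(TranscriptRecord(id=prot.id.replace("|", "_"), sequence=utr5 + cds + utr3))
    return out
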