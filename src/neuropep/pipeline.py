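"""End-to-end discovery pipeline driver.

Stage order mirrors the published protocol: translate (if transcripts) ->
signal gate -> motif scan on the secretome, in parallel a relaxed similarity
pass of reference queries against the full proteome -> union of candidates ->
greedy redundancy reduction -> 650-aa length filter -> stringent second
similarity pass using the candidate union as queries -> prohormone annotation
-> similarity-graph clustering.  Every run writes a manifest (parameters,
seed, per-stage counts) sufficient to reproduce it; stage outputs are pure
functions of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import similarity_search as sim
from .ms_confirmation import (
    confirmation_summary,
    match_identifications,
    read_identifications,
    write_matches,
)
from .pattern_discovery import (
    PatternParams,
    dedup_greedy,
    filter_length,
    scan_multicopy,
    select_secretome,
)
from .precursor_annotation import (
    AnnotatedPrecursor,
    annotate_precursor,
    render_precursor,
)
from .sequence_io import (
    ProteinRecord,
    SignalAnnotation,
    heuristic_signal,
    read_fasta,
    read_signal_annotations,
    translate_orfs,
    write_fasta,
)

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Bad configuration or inconsistent inputs (CLI exit code 2)."""


@dataclass
class DiscoveryResult:
    candidates: list[ProteinRecord]
    hits: dict[str, object]  # protein_id -> PatternHit
    provenance: dict[str, set[str]]  # protein_id -> {pattern, pass1, pass2}
    membership: dict[str, list[str]]  # representative -> redundant members
    annotated: list[AnnotatedPrecursor]
    clusters: list[list[str]]
    manifest: dict

    def recovered_ids(self) -> set[str]:
        """All ids the pipeline accounts for: representatives plus the
        redundant members they absorbed during dedup."""
        out = set()
        for rep, members in self.membership.items():
            out.add(rep)
            out.update(members)
        kept = {r.id for r in self.candidates}
        # drop members of representatives later removed by the length filter
        return {i for i in out if i in kept} | {
            m for rep, ms in self.membership.items() if rep in kept for m in ms
        }


def run_discover(
    proteins: Optional[Sequence[ProteinRecord]] = None,
    transcripts=None,
    signal_annotations: Optional[Sequence[SignalAnnotation]] = None,
    seed_queries: Sequence[ProteinRecord] = (),
    pattern_params: Optional[PatternParams] = None,
    search_params: Optional[sim.SearchParams] = None,
    use_signal_heuristic: bool = False,
    min_orf_len: int = 60,
    outdir=None,
    seed: int = 0,
) -> DiscoveryResult:
    """Run the full discovery arm on an in-memory proteome.

    Either ``proteins`` or ``transcripts`` must be given (transcripts are
    six-frame translated first).  ``signal_annotations`` is required unless
    ``use_signal_heuristic`` is set.
    """
    pattern_params = pattern_params or PatternParams()
    search_params = search_params or sim.SearchParams()
    manifest: dict = {
        "seed": seed,
        "pattern_params": vars(pattern_params).copy(),
        "search_params": vars(search_params).copy(),
        "counts": {},
    }
    counts = manifest["counts"]

    if proteins is None and transcripts is None:
        raise ValidationError("run_discover needs proteins or transcripts")
    if proteins is None:
        proteins = translate_orfs(transcripts, min_len=min_orf_len)
        counts["translated_orfs"] = len(proteins)
    proteins = list(proteins)
    counts["proteins"] = len(proteins)

    if signal_annotations is None:
        if not use_signal_heuristic:
            raise ValidationError(
                "signal annotations missing and the built-in heuristic is disabled"
            )
        signal_annotations = [heuristic_signal(r) for r in proteins]
    signal_by_id = {a.protein_id: a for a in signal_annotations}

    secretome = select_secretome(proteins, signal_annotations)
    counts["secretome"] = len(secretome)

    hits = {}
    for rec in secretome:
        hit = scan_multicopy(rec, pattern_params)
        if hit is not None:
            hits[rec.id] = hit
    counts["pattern_hits"] = len(hits)

    by_id = {r.id: r for r in proteins}
    provenance: dict[str, set[str]] = {rid: {"pattern"} for rid in hits}

    if seed_queries:
        tags = sim.two_pass_search(
            proteins,
            seed_queries,
            params=search_params,
            pattern_candidates=[by_id[rid] for rid in hits],
        )
        for rid, t in tags.items():
            provenance.setdefault(rid, set()).update(t)
    counts["candidates_union"] = len(provenance)

    candidates = [by_id[rid] for rid in sorted(provenance)]
    reps, membership = dedup_greedy(candidates, pattern_params.dedup_identity)
    counts["after_dedup"] = len(reps)
    reps = filter_length(reps, pattern_params.max_precursor_len)
    counts["after_length_filter"] = len(reps)

    annotated = [
        annotate_precursor(rec, signal_by_id.get(rec.id)) for rec in reps
    ]
    counts["annotated"] = len(annotated)

    if len(reps) >= 1:
        graph = sim.build_graph(reps, search_params, search_params.cluster_evalue)
        clusters = sim.components(graph)
    else:
        clusters = []
    counts["clusters"] = len(clusters)
    counts["multi_member_clusters"] = sum(1 for c in clusters if len(c) > 1)

    result = DiscoveryResult(
        candidates=reps,
        hits=hits,
        provenance=provenance,
        membership=membership,
        annotated=annotated,
        clusters=clusters,
        manifest=manifest,
    )
    if outdir is not None:
        _write_discovery(result, Path(outdir))
    return result


def _write_discovery(result: DiscoveryResult, outdir: Path) -> None:
    membership = result.membership
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.candidates, outdir / "candidates.fasta")
    with open(outdir / "hits.tsv", "w") as fh:
        fh.write("protein_id\tbranch\tspans\tprovenance\n")
        for rid in sorted(result.provenance):
            hit = result.hits.get(rid)
            branch = hit.matched_branch if hit else "-"
            spans = (
                ";".join(f"{s}-{e}" for s, e in hit.match_spans) if hit else "-"
            )
            prov = ",".join(sorted(result.provenance[rid]))
            fh.write(f"{rid}\t{branch}\t{spans}\t{prov}\n")
    with open(outdir / "annotations.txt", "w") as fh:
        for ann in result.annotated:
            fh.write(render_precursor(ann) + "\n\n")
    with open(outdir / "peptides.fasta", "w") as fh:
        for ann in result.annotated:
            for i, p in enumerate(ann.peptides):
                tags = []
                if p.amidated:
                    tags.append("amidated")
                if p.pyroglu:
                    tags.append("pyroglu")
                tag = (" " + ",".join(tags)) if tags else ""
                fh.write(f">{ann.record.id}|pep{i}|{p.start}-{p.end}{tag}\n")
                fh.write(p.sequence + "\n")
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("cluster\tmember\n")
        for ci, cluster in enumerate(result.clusters):
            for member in cluster:
                fh.write(f"{ci}\t{member}\n")
    with open(outdir / "dedup_members.tsv", "w") as fh:
        fh.write("representative\tmember\n")
        for rep, members in membership.items():
            for m in members:
                fh.write(f"{rep}\t{m}\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def run_ms(
    annotated: Sequence[AnnotatedPrecursor],
    identifications_path,
    tol: float = 0.01,
    background: Sequence[ProteinRecord] = (),
    outdir=None,
):
    """MS confirmation stage: match an identification table to precursors."""
    idents = read_identifications(identifications_path)
    matches = match_identifications(idents, annotated, tol=tol, background=background)
    per_precursor, totals = confirmation_summary(matches)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_matches(matches, outdir / "ms_matches.tsv")
        per_precursor.to_csv(outdir / "ms_per_precursor.tsv", sep="\t")
        with open(outdir / "ms_totals.json", "w") as fh:
            json.dump(totals, fh, indent=2, default=str)
    return matches, per_precursor, totals
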