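# Methods

## The problem

Proneuropeptides (pNPs) are secreted precursor proteins: an N-terminal signal
peptide followed by one or more short bioactive peptides flanked by basic
cleavage sites, often with a C-terminal amidation signal (a Gly preceding the
site) and sometimes an N-terminal pyroglutamate (from Gln).  Because the
bioactive peptides are short and the spacers between them evolve quickly,
standard homology search misses many precursors; multicopy precursors,
however, betray themselves by their *repeat structure*.  `neuropep`
implements a complete desk-scale discovery-and-validation pipeline around
that observation: motif-based mining of translated transcriptomes, prohormone
processing prediction, similarity clustering, confirmation against MS peptide
identifications, and exon–intron comparison as independent homology evidence.

## The motif screen

Two extended regular expressions define the multicopy screen:

```
((.{2,25}G[KR][KR])|(.{2,25}[KR](.{1}|.{3}|.{5})G[KR*])){3,}
(.{5,25}[KR][KR]){5,}
```

The first demands at least three amidation units — a Gly followed by a
dibasic pair, or a basic residue 2/4/6 positions before the Gly — each
preceded by a 2–25 residue stretch; the second demands at least five dibasic
pairs separated by 5–25 residues.  The literal `*` inside `[KR*]` is
deliberate: six-frame translator output retains terminal stop symbols, and a
stop can close an amidated C-terminal peptide.  `PatternParams` generalizes
the repeat counts and spacer bounds; with defaults the generated strings are
byte-identical to the two patterns above (asserted at import time).

Matching is unanchored, greedy, engine-agnostic language membership: the
implementation evaluates the patterns with Python's `re`, and the test suite
certifies decision-equivalence against an independent POSIX ERE engine
(system `grep -E`, run under `LC_ALL=C` for byte semantics) on 10,000
seeded random sequences with a K/R/G-enriched alphabet.  Reported match
spans are the leftmost greedy match; only the accept/reject decision is
engine-independent, and only that decision defines the candidate set.

The screen runs on the *secretome*: records gated by signal-peptide
annotations (SignalP-style TSV) before scanning, which is what keeps the
false-positive load manageable.  Candidates are then redundancy-reduced by
greedy longest-first clustering at 0.95 identity and candidates longer than
650 residues are deleted (650 itself is kept — the filter removes only
strictly longer sequences).

### Redundancy reduction

CD-hit's convention is reproduced without its word-filter heuristics:
records are visited longest-first (ties by id); a record joins the first
representative whose global-alignment identity over the shorter sequence
reaches the threshold.  Identity is computed as the maximum number of
identically aligned residues over all global alignments (equivalently the
longest common subsequence) divided by the shorter length — the most
generous defensible reading, so near-fragments reliably merge.  A
conservative shared-4-mer prefilter (identity ≥ t over length L forces at
least (1 − 4(1 − t))L − 3 shared 4-mers, so a 20% overlap floor is safe for
t ≥ 0.8) skips hopeless alignments without changing any decision.

## Prohormone processing model

* Dibasic sites (KR/RR/KK/RK) are consumed left-to-right without overlap, so
  `KRKR` yields sites after positions 2 and 4 with a zero-length (dropped)
  peptide between — the consecutive-copy situation.  Cleavage is modeled
  C-terminal to the pair and carboxypeptidase trimming removes both basic
  residues from mature products.
* Monobasic sites: a lone Arg (not adjacent to another basic residue)
  with a second basic residue 3–6 positions N-terminal of the cleavage
  point, cleaving N-terminal to the Arg.  They carry `alternative`
  confidence and are OFF for peptide derivation, ON for MS-match
  interpretation, reflecting their status as a-posteriori evidence.
* A Gly left at a segment's C-terminus — immediately before the downstream
  site, a retained stop, or the precursor end — marks amidation and is
  removed from the mature core.  A lone-Gly segment has no peptide to
  amidate and is kept as a one-residue core instead.  Treating a
  sequence-terminal Gly as an amidation donor is a modeling choice (the
  evidence either way is thin); it follows from requiring a single uniform
  rule "amidated iff the residue after the core is Gly followed by a
  boundary".
* An N-terminal Gln flags *potential* pyroglutamate (Glu is not flagged,
  matching the modification set used in the MS search).

**Tiling invariant.** For every annotated precursor, signal peptide +
mature cores + removed amidation glycines + cleavage-site residues must
reconstruct the input string exactly.  This is checked for 100% of generated
and hand-written precursors; it is the property that catches every off-by-one
in the segmentation.

**Architecture classes.** Precedence: `cys8_peptide` (terminal peptide with
exactly 8 Cys — the CCWamide/agatoxin-like layout) > 
`single_copy_plus_cys_domain` (one Cys-poor peptide followed by a region
with ≥ 4 Cys — the vasotocin/neurophysin layout) > `multicopy` (≥ 3 copies
at ≥ 0.5 identity over the shorter copy, with a 0.5 length-ratio guard so a
two-residue tail cannot "match" a copy over its own two residues) >
`single_copy` > `other`.  The 0.5 copy-identity threshold is a config knob;
no published value exists, and 0.5 cleanly separates planted copies from
spacers.

**Consecutive copies.** When two or more motif-matching peptides abut with
no intersequence, each is flagged and the alternative shorter product —
the sequence after the last internal basic residue — is reported (the
GWamide-dipeptide situation for abutting RGWamide copies).

## Similarity engine

BLAST is replaced at desk scale by exact Smith–Waterman under BLOSUM62 with
affine gaps (a gap of length L costs 11 + L, the BLAST default convention)
and a Karlin–Altschul-style E-value `E = K·m·n·exp(−λS)` with the published
gapped-BLOSUM62 constants λ = 0.267, K = 0.041.  `X` and `*` score the
matrix minimum everywhere so translator artifacts never create similarity.
An outfmt-6 adapter lets external BLAST output stand in for large data.

The two-pass search keeps proteome entries at E ≤ 1e-1 against any
reference query (pass 1), unions them with the motif-screen candidates
(an optional curation hook models the manual-inspection step), and re-uses
that union as the query set at E ≤ 1e-5 (pass 2) — the mechanism that
recovers *hidden orthologs* similar to a first-pass hit but not to any
original query.  The two-pass output is provably a superset of the
single stringent pass.

Clustering is the thresholded similarity graph (all-vs-all, E < 1e-5) and
its connected components; the force-directed layout of interactive cluster
tools is cosmetic and not reproduced.  Edge sets at a lower threshold are a
subset of those at a higher one, so components at 1e-10 always refine
components at 1e-5.

## MS confirmation

Identifications arrive as a table (peptide sequence, modifications,
observed monoisotopic mass) — a documented subset of a MaxQuant peptides
export; the spectral search itself is out of scope.  Masses use a standard
monoisotopic residue table + water (18.010565 Da) with deltas: amidation
−0.98402, pyroglutamate (Gln) −17.02655, Met oxidation +15.99491, N-terminal
acetylation +42.01057, Tyr sulfation +79.95682; Cys carbamidomethylation
(+57.02146) is fixed, matching the originating search settings.  The suite
cross-checks 100 random modified peptides against an independent calculator
(pyteomics) at 1e-4 Da and re-derives the amidation/pyroglutamate deltas
from monoisotopic atomic masses.

Each identification is located as an exact substring of the precursor set
(all occurrences reported; the primary match is chosen by category rank,
then longest host, then id) and classified:

* `full_dibasic` — span equals a predicted mature core exactly;
* `monobasic_product` — span ends at a supported monobasic cleavage point;
* `truncated_N` / `truncated_C` — proper sub-span sharing the C (N) boundary;
* `truncated_both` — sub-span with both end offsets ≤ 3 (the degradation
  window) from the host core's boundaries;
* `internal` — inside a core but away from its boundaries;
* `novel_precursor` — found only in proteins outside the discovered set;
* `unmatched` — found nowhere.

`monobasic_product` outranks the truncation categories: a peptide ending
exactly before a supported lone Arg is read as evidence *for* monobasic
processing, not as degradation.  Leu/Ile are distinct (matching is
sequence-level, not spectral).  The default 0.01 Da tolerance is an internal
consistency check — identifications carry sequences, so a larger gap means a
corrupt table, which raises rather than silently down-classifying.

## Gene structure

Gene models are consumed as GFF3 (+ genomic FASTA); the translated CDS must
equal the protein or the call errors with the first differing residue.
For each intron, phase = cumulative CDS nucleotides mod 3 at the junction;
the protein position is cumulative/3 for phase 0 (the intron follows that
residue) and cumulative/3 + 1 otherwise (the interrupted residue).  The
computation is strand-symmetric.  For conservation calls each intron is
projected to the alignment column of its residue; introns with identical
phase whose columns agree within ±2 (single linkage; the tolerance is a
config knob — published comparisons say "similar position" without a number)
form a conserved group.  Both phase identity and column agreement are
required; groups of one are not reported.

## Synthetic data: what it emulates and what it does not

The generator plants, per family, a canonical signal peptide (charged
n-region, 12-residue hydrophobic core, A-X-A cleavage motif), repeated
peptide copies flanked by random dibasic pairs with amidation glycines,
spacers drawn from a K/R/G-free alphabet, and per-member substitution
divergence (default 8%/site) with copy and Cys positions protected.  Default
study conditions: five discoverable multicopy families × 8 members, plus a
vasotocin-like (single copy + Cys domain) and a CCWamide-like (8-Cys
terminal peptide) family recoverable only by similarity, and 1,000 decoys
(globular, secreted non-precursor, glycine-rich trap — the composition
class known to cluster spuriously with glycine-rich precursors).  The
pedal-peptide-like family's copies carry an internal Arg with a Lys five
positions N-terminal, so a supported monobasic cleavage point exists inside
every copy and the monobasic MS category is generatable for any seed.
Discoverable members are verified against the *published* patterns (plus
signal gate and length cutoff) at generation time, so discovery recall
below 1.0 always indicts the implementation, not the data.

Gene models are emitted by back-translation with random synonymous codons,
GT..AG introns of 60–500 nt at planned (position, phase) points, on either
strand.  MS identifications are sampled per category with exact truth
labels; truncation cut points that coincide with a monobasic site are
resampled so generator truth and matcher taxonomy agree by construction.
Observed masses equal theoretical masses by default (σ = 0); Gaussian error
is available but unused in tests.

What the generator does **not** emulate: codon-usage and phylogenetic
realism, indel divergence (orthologs are substitution-only, hence
pre-aligned — deliberate, because alignment fidelity is orthogonal to the
intron logic), spectral noise, chimeric transcripts, and the long tail of
real decoy compositions.  Passing tests therefore certify the *logic* of
every stage under the stated statistical structure; they say nothing about
SignalP's accuracy, assembly quality, or search-engine FDR on real data.

## Numerical and procedural choices

* Internal coordinates 0-based half-open; all reports 1-based inclusive.
* Dedup before the length filter, mirroring the published order of
  operations; representatives removed by the length filter drop their
  members from the recovered set.
* Six-frame translation emits every maximal stop-free stretch ≥ 60 residues
  (complete ORFs are a special case); N-containing codons translate to X
  unless the residue is unambiguous; X never matches any motif class.
* The built-in signal heuristic (any 9-residue Kyte–Doolittle window mean
  > 1.6 within the first 30 residues) is a deliberately crude fallback so
  the pipeline can run without an external predictor; real analyses should
  supply an annotation file.
* Problem sizes in tests and in `scripts/acceptance.py` — 10,000 sequences
  for the pattern-engine equivalence, 1,000 decoys, 200 identifications, 50
  alignment-oracle pairs, 4-member ortholog families — are the package's
  chosen desk-scale study conditions; they run in a few minutes on one CPU.

## Known limitations

* The E-value calibration uses fixed gapped-BLOSUM62 constants; scores for
  short sequences (< ~40 aa) are conservative and edge-length corrections
  are not applied.
* Greedy dedup is order-dependent by design (longest first); CD-hit's exact
  output can differ on borderline pairs near the identity threshold.
* `single_copy_plus_cys_domain` classification assumes the Cys domain
  segments into Cys-bearing fragments; a Cys-poor spacer peptide inside the
  domain can demote the call to `other`.
* The matcher classifies against *predicted* peptides; if derivation itself
  is wrong (e.g., an unusual convertase), a correct identification will be
  reported as internal/truncated rather than flagged as a model violation.
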