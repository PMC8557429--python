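# neuropep

Discovery and annotation of neuropeptide precursors (proneuropeptides, pNPs)
from translated transcriptomes — for comparative neuropeptidomics at desk
scale.

Proneuropeptides are secreted precursors: a signal peptide followed by one or
more short bioactive peptides flanked by basic prohormone-convertase sites
(KR/RR/KK/RK), frequently with a C-terminal amidation glycine and an
N-terminal pyroglutamate-forming glutamine.  The peptides are short and the
spacers between them diverge fast, so plain homology search misses whole
families.  Multicopy precursors, however, carry a conspicuous repeat
signature that two extended regular expressions capture directly on the
translated sequence:

```
((.{2,25}G[KR][KR])|(.{2,25}[KR](.{1}|.{3}|.{5})G[KR*])){3,}   # ≥3 amidation units
(.{5,25}[KR][KR]){5,}                                          # ≥5 dibasic pairs
```

`neuropep` wires that screen into a complete, tested pipeline:

* **sequence_io** — FASTA I/O, SignalP-style annotation TSV, six-frame ORF
  translation (≥ 60 aa stretches, stops retained as `*`);
* **pattern_discovery** — the signal-gated motif screen, greedy 0.95-identity
  redundancy reduction, 650-aa length filter;
* **precursor_annotation** — dibasic/monobasic cleavage prediction, mature
  peptides with amidation/pyroglutamate flags, architecture classification
  (multicopy, single copy + Cys domain, 8-Cys terminal peptide);
* **similarity_search** — exact Smith–Waterman + Karlin–Altschul E-values
  (λ = 0.267, K = 0.041), the relaxed→stringent two-pass search that recovers
  hidden orthologs, and similarity-graph clustering (components at E < 1e-5);
* **ms_confirmation** — matching MS peptide identifications to predicted
  products: full dibasic products, truncations, monobasic (single-Arg)
  products, and novel precursors missed by discovery;
* **gene_structure** — intron positions in protein coordinates with phases,
  and cross-ortholog conserved-intron calls from GFF3 + genome FASTA;
* **synthetic_data** — a deterministic generator of ground-truthed proteomes,
  gene models, and MS identification tables so every stage is testable
  without downloads;
* **cli / pipeline** — `neuropep simulate | discover | ms-match |
  gene-structure | all`.

See `docs/methods.md` for the processing model, parameter defaults, and what
the synthetic benchmark does and does not demonstrate.

## Worked example

Generate a synthetic proteome (5 discoverable multicopy families × 8
members, two single-copy architectures, 1,000 decoys including glycine-rich
traps) and run discovery on it:

```
$ neuropep simulate --seed 1 --n-decoys 1000 --outdir demo
wrote 1056 records to demo
$ neuropep discover --proteins demo/proteome.fasta --signals demo/signals.tsv \
      --outdir demo/discovery
{"proteins": 1056, "secretome": 722, "pattern_hits": 66,
 "candidates_union": 66, "after_dedup": 66, "after_length_filter": 66,
 "annotated": 66, "clusters": 4, "multi_member_clusters": 2}
```

Of 1,056 records, 722 carry a signal peptide; the motif screen flags 66
candidates — all 40 discoverable planted precursors plus 26 glycine-rich
decoys that genuinely match the patterns (inspect `hits.tsv`; every flagged
decoy is accepted by the raw regular expressions too, which is why the
published workflow ends in manual curation).  `annotations.txt` renders each
candidate in supplementary-list style — signal peptide in lower case,
cleavage sites bracketed, amidation glycines as `g`:

```
>syn0|FMRFa-like [multicopy]
mkvmiimvvfvmflsaqaIASHITNLDNHNDFMRFg[R][R]LSALHLEHNDHDFMRFg[K][R]SDPSQQLDFMRFg[K][R]...
    19-35   IASHITNLDNHNDFMRF-NH2
    39-54   LSALHLEHNDHDFMRF-NH2
    58-69   SDPSQQLDFMRF-NH2
    ...
   130-135  QADPHL (pyroGlu?)
```

Six near-identical FMRFamide-type copies, each ending in an amidated Phe
(`-NH2`: the trailing Gly is converted to the amide), plus a C-terminal
leftover whose initial Gln flags potential pyroglutamate.  The peptide FASTA
(`peptides.fasta`) and cluster membership (`clusters.tsv`) feed the MS and
comparative stages; `neuropep all` chains simulate → discover → ms-match.

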