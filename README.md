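# qsalvage

Comparative-genomics discovery of missing **queuosine-precursor transporters**
in bacterial pangenomes.

Queuosine (Q) is a hypermodified 7-deazaguanosine at the wobble position 34 of
GUN-anticodon tRNAs. Only bacteria synthesize it de novo (QueD/E/C/F build the
preQ₁ base; bTGT inserts it into tRNA; QueA and QueG/QueH finish the
modification), but many bacteria instead salvage intermediates — the preQ₀ and
preQ₁ bases, or the free queuine (q) base directly or indirectly via the
queuine lyase QueL, with the hydrolases Qng1/QueK releasing q from Q
nucleosides. Salvage requires import, yet only two transporter families are
known (QPTR and the ECF-type QueT/QrtT). Many genomes predicted to salvage
encode neither — a **transporter gap** that implies undiscovered transporter
families. `qsalvage` implements the in-silico pipeline for finding candidates:

1. **Profile** — call marker presence per genome from homology hits
   (identity ≥ 20%, E-value ≤ 10⁻¹⁰) and classify each genome's Q-pathway
   profile (non-user, de novo, preQ salvager, direct/indirect q salvager) with
   a total rule table over the capability flags.
2. **Associate** — mine gene neighborhoods (±10 gene ranks) of the salvage
   signature genes bTGT, Qng1, and QueK; keep families with median gene
   distance ≤ 2 and clustering ratio > 0.2% of family members.
3. **Fuse** — detect Rosetta-stone proteins (500–2000 aa) fusing a bTGT
   domain with a transporter domain.
4. **SSN** — build sequence similarity networks at an alignment-score cutoff
   (AS = −log₁₀ E-value) chosen so edges mean > 40% identity, collapse
   > 90%-identical proteins into representative nodes, and raise the cutoff in
   5-AS steps until clusters are homogeneous in profile category.
5. **Score** — weight each candidate family's neighbor occurrences by the
   encoding genome's profile (transporter-gap salvagers count most), take
   z-scores across families, and select candidates with
   z ≥ 1 that pass the clustering filters; report per-SSN-cluster enrichment
   percentages.

A first-class **synthetic pangenome generator** plants a true transporter
family next to signature genes in salvage-requiring genomes (plus uniform
decoys, fusions, and two-component pair scores) with a machine-readable truth
file, so every stage is testable end to end without any downloads.

## Worked example

```bash
python examples/05_end_to_end_discovery.py
```

generates 200 genomes (40% salvage-requiring; a planted family next to the
signature genes in 80% of those; 20 uniform decoys) and runs all stages:

```
profile categories:
de_novo_Q                 71
preQ_salvager             33
non_user                  29
q_salvager_direct         28
de_novo_preQ1_terminal    22
q_salvager_indirect       17

selected candidate families:
 rank     family_accession  z_score  median_distance  clustering_ratio dominates  fused
    1 PF_planted_synthetic 4.997894              2.0          0.697917       5/5      1
```

The planted family is the only selected candidate: rank 1 with z ≈ 5.0, median
gene distance 2 to the signature genes (within the ≤ 2 filter), dominant in
all 5 SSN clusters, and independently flagged by a planted fusion. The 20
decoy families, placed uniformly, never pass the selection rule. The other
examples (`examples/01…04`) demonstrate each stage in isolation with small
hand-built inputs and print what the numbers mean.

The same run is available from the shell:

```bash
qsalvage all --out run_dir --seed 1          # all stages, default config
qsalvage validate --config cfg.yaml          # check a config file
```

Each stage writes plain headered TSV/JSON artifacts (gene table, presence
matrix, profiles, neighborhoods, family stats, fusions, SSN as GraphML and a
round-trip-safe edge-list TSV, candidate scores, report) plus the exact config
that produced them; identical config and seed give byte-identical directories.

## Layout

- `src/qsalvage/` — library: `records`/`io` (domain types, GFF3/TSV/BLAST
  tabular/GraphML), `profiler`, `association`, `ssn`, `scoring`,
  `synthetic`, `pipeline`, `cli`
- `examples/` — one narrative script per capability
- `docs/methods.md` — model, parameters, numerical choices, limitations
- `tests/` — unit, property (hypothesis), and acceptance suites
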