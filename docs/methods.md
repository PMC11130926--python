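# Methods

## The problem and the approach

Queuosine (Q) salvage in bacteria depends on importing one of the precursors
preQ₀, preQ₁, queuine (q), or Q itself, but only two transporter families are
experimentally known (QPTR; the ECF-type QueT/QrtT substrate components). A
genome whose marker content predicts salvage but encodes no known transporter
has a *transporter gap* and must use an unidentified importer. `qsalvage`
operationalizes the classic guilt-by-association toolkit for this gap:
metabolic reconstruction from marker presence/absence, gene-neighborhood
(genomic context) mining, Rosetta-stone fusion detection, sequence similarity
networks (SSNs), and an enrichment score that privileges evidence from the
genomes that actually need a transporter.

## Profile classification

Presence of a marker in a genome is called when some homology hit reaches
**identity ≥ 20% and E-value ≤ 10⁻¹⁰**; both boundaries are inclusive, the
common convention for homology-filter thresholds. Relaxing either threshold
can only add presences (monotonicity, property-tested).

Classification is a total function of five derived flags — `has_tgt`,
`makes_preQ1` (QueD ∧ QueE ∧ QueC ∧ QueF), `finishes_Q` (QueA ∧ (QueG ∨
QueH)), `has_queL`, `has_hydrolase` (Qng1 ∨ QueK) — evaluated in a fixed
order: no bTGT → `non_user`; full synthesis and finishing → `de_novo_Q`;
synthesis without finishing → `de_novo_preQ1_terminal` (organisms whose tRNA
carries preQ₁ as the terminal modification); no synthesis but finishing →
`q_salvager_indirect` when QueL is present, else `preQ_salvager`; neither →
`q_salvager_direct`. Salvage substrates follow the flags (QueF adds preQ₀;
a hydrolase adds Q to direct q salvage). Design choices worth noting:

- **Synthesis dominates salvage.** Genomes that both synthesize and carry
  salvage markers are labeled `de_novo_Q`; their salvage capacity stays
  visible through `has_known_transporter`. This matches organisms such as
  *E. coli* that synthesize de novo yet encode precursor transporters.
- **Partial synthesis sets are conservative.** `makes_preQ1` requires all
  four of QueD/E/C/F; a genome with, say, only QueF is routed through the
  salvage rules and flagged `partial_synthesis` rather than guessed at.
- **The profile is a prediction.** Every profile carries a caveat field;
  reconstructions of this kind are known to miss real transport phenotypes.
- QueG and QueH are interchangeable everywhere (they only enter via
  `finishes_Q`); the rule table is verified exhaustively (2¹⁰ rows) against
  an independently coded oracle.

Marker accessions default to the marker name itself plus the database
aliases in common use for the anchors (bTGT = IPR004803, Qng1 = IPR019438,
QueK = IPR023186, QPTR = PF02592/IPR003744, QrtT = PF12822); all lists are
configurable.

## Gene-neighborhood association

Distances are **gene ranks** (adjacent gene = 1), never base pairs, matching
genome-neighborhood-network practice; strand is ignored. Signature genes are
bTGT, Qng1, and QueK; the window defaults to ±10 genes, truncated at contig
ends (circular contigs, off by default, use min(|i−j|, L−|i−j|)). Per
candidate family: the **median** gene distance over all neighbor occurrences
(even counts average the central pair), and the **clustering ratio** =
distinct neighbor proteins / family size in the analyzed dataset (a protein
seen from two signature genes counts once). A family passes with median ≤ 2
(inclusive) and ratio > 0.002 (strict). The ratio denominator is the family's
size in the dataset; callers can substitute any denominator through the
`family_sizes` argument.

## Fusion detection

A fusion call requires ≥ 1 signature (bTGT) domain and ≥ 1 transporter-family
domain on one protein of 500–2000 aa. A partner domain overlapping a
signature domain by more than half the shorter domain is treated as a
double-annotation artifact, not a fusion — database fusion queries implicitly
assume non-overlapping architectures.

## Sequence similarity networks

The edge unit is the alignment score **AS = −log₁₀(pairwise E-value)**
(tables may carry AS directly or an `evalue` column; E-values of 0 clip at
10⁻³⁰⁰). Proteins sharing **> 90% identity** (strict) are collapsed by
single linkage into representative nodes (longest member represents, ties to
the smallest id); node-level edge AS is the maximum over member pairs (the
most permissive lift, keeping rep-node clusters as connected as the
underlying proteins). The initial cutoff is the median AS among pairs within
±1 identity point of the 40% target (±2 if that band is empty; otherwise the
minimum observed AS — then every edge already exceeds the target). Edges are
kept at AS ≥ threshold (inclusive), components come from union-find
(networkx), and cluster numbering is deterministic (size descending, then
smallest member id).

"Homogeneous in color" needs a number: refinement raises the threshold in
5-AS steps until every cluster of **size ≥ 3** has a modal profile-category
fraction **≥ 0.9** (both configurable), or the threshold passes one step
beyond the maximum edge AS, at which point all nodes are singletons —
guaranteeing termination. Overlay marks a node *filled* when a member has a
filter-passing candidate family within gene distance ≤ 3 or is itself a
fusion protein; genomes without bTGT get a gray border.

## Candidate scoring

raw_score(family) = Σ over the family's distinct neighbor proteins of a
weight set by the encoding genome's profile:

| genome profile                         | weight |
|----------------------------------------|--------|
| salvage-requiring with transporter gap | 2.0    |
| salvage-requiring, known transporter   | 1.0    |
| de novo (either variant)               | 0.25   |
| non-user                               | 0.0    |

The weights encode the motivating logic — evidence from genomes that *need*
an importer and have none known counts most — and are config-exposed;
z-scores are invariant to positive rescaling (property-tested). z-scores
standardize raw scores across **all families with ≥ 1 neighborhood
occurrence** using the sample (n−1) standard deviation; with < 2 families or
zero variance, all z = 0 and selection is disabled rather than dividing by
zero. A candidate is **selected** when z ≥ 1 *and* it passes the
physical-clustering filters; known transporter families are kept and flagged
as positive controls. Scoring over all occurring families rather than the
filtered subset keeps the z reference distribution non-degenerate — on data
where only one family survives the filters, a filtered-set z would be
undefined — while the filters still gate selection, so the compound rule is
the same one applied when the method meets real data. Per-cluster enrichment
counts (member neighbor protein, family) pairs once; percentages per cluster
sum to 100 when any candidate occurs.

## Synthetic pangenome generator

The generator emulates the statistical structure of a screened pangenome,
not its sequences. Defaults define the study conditions used throughout the
tests: **200 genomes × 60 genes**, profile mixture (de novo 0.35, non-user
0.15, preQ₁-terminal 0.10, preQ salvager 0.15, direct q salvager 0.15,
indirect 0.10 — i.e. 40% salvage-requiring), planted family placed at gene
distance Uniform{1..2} from the bTGT gene with probability **p_plant = 0.8**
in salvage-requiring genomes, **20 decoy families** placed uniformly at a
0.3 per-genome rate (decoys *can* land near signatures — required for honest
null behavior; under p_plant = 0 the planted family is placed exactly like a
decoy), known transporters present in 30% of non-non-users, hydrolases in
70% of direct q salvagers, fusions (bTGT + partner domains on a 500–2000 aa
protein) at rate 0.05, and failing hits emitted for 30% of absent markers so
threshold logic is actually exercised. Marker presence vectors satisfy the
assigned category's rule definition exactly, and `verify_truth` closes the
loop by re-deriving every category from the emitted hit table. Pair scores
are two truncated normal components — within-category identity N(75, 12) /
AS N(120, 15), between-category identity N(32, 6) / AS N(25, 10) — the
simplest model that puts a usable 40%-identity band in the data and lets
refinement separate categories. All draws come from one seeded numpy
generator in a fixed order, so identical configs give byte-identical files.

What the generator does **not** model — and what passing tests therefore do
not show about real data: sequence evolution, phylogenetic correlation
between genomes (neighborhood evidence in related genomes is not
independent), uneven family sizes, multi-contig fragmentation, and
annotation noise in domain assignments.

## Problem sizes and numerical choices

The test and acceptance workloads use the study conditions above: recovery
and null experiments run 100 seeds per arm in the suite (40 per arm in the
acceptance script), the neighborhood oracle uses 50 genomes, the SSN oracle
200 random graphs of ≤ 100 nodes, and fusion recall 120 genomes at fusion
rate 0.3. Ties break lexicographically everywhere (representatives, cluster
numbering, report ordering) so outputs are identical across runs and
platforms. Degenerate inputs have defined behavior: empty hit/pair files
parse to empty lists, an empty SSN writes a valid file, zero-variance scores
disable selection, and an all-singleton partition is homogeneous by
definition.

## Known limitations

- The classifier cannot see phenotypes the markers do not encode (e.g.
  preQ₁ transport in genomes lacking finishing enzymes was missed by exactly
  this kind of reconstruction); profiles are predictions with a caveat field.
- The clustering-ratio denominator is the dataset family size; with very
  incomplete datasets the ratio is inflated relative to a database-wide
  denominator.
- Neighborhood evidence treats genomes as independent; strongly related
  genomes multiply-count the same ancestral gene arrangement.
- The refinement stop rule is a quantitative stand-in for a visual
  judgment; different majority/size settings can split or keep clusters
  near the boundary.
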