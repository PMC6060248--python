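# Methods

t4apscan reconstructs, as a reusable pipeline, the comparative-genomics
workflow used to contrast the two organizations of type IVa pilus (T4aP)
gene systems in bacteria: *clustered* lineages, in which a single large
locus carries most structural and regulatory components, and *dispersed*
lineages, in which only the pilMNOPQ envelope sub-complex stays contiguous
while the remaining genes scatter over the chromosome. This note records the
models, parameters and numerical choices behind each stage, what the
synthetic genomes do and do not emulate, and the known limits of the
approach.

## Homology scan

Family assignment uses exact local alignment rather than a heuristic search:
reference panels here hold a handful of sequences per family, so full
Smith–Waterman (BLOSUM62, affine gaps, open 11 / extend 1 — a gap of length
k costs 11 + k) is affordable and removes an external-binary dependency.
Alignment itself is delegated to Biopython's `PairwiseAligner`; the module
adds the hit statistics and the decision rule.

Three filters are applied conjunctively to every reference-vs-gene hit:

* **E-value ≤ 1e-5.** A simplified desk-scale statistic `E = m·n·2^(−bits)`
  with `bits = (λ·S − ln K)/ln 2`, λ = 0.267 and K = 0.041 (the standard
  gapped-BLOSUM62 constants). Only the relative cutoff behaviour matters at
  this scale; the constants are module-level and configurable. `m` is the
  reference length and `n` the gene length — per-pair, not whole-database,
  search space.
* **Reference coverage ≥ 35 %**, measured on the reference (family) side of
  the alignment, since the panel sequences play the "query" role of the
  original protocol.
* **Similarity ≥ 35 %**, defined as the percentage of aligned columns
  (gap columns included) whose residue pair has a positive BLOSUM62 score —
  the BLAST "positives" reading of an otherwise loosely used term. Identity
  is computed the same way with exact matches.

The winning family per gene is the highest bit score (ties: lower E-value,
then alphabetical family). Type II secretion system (T2SS) paralogs are
handled competitively: decoy families sit in the panel, can win, and a decoy
winner leaves the gene unassigned with an `excluded_as_decoy` flag. This
replaces manual curation with a reproducible rule. Profile-HMM corroboration
is out of scope; the reference-panel search stands in for it.

pilR/pilS are detected as one combined `pilRS` family because two-component
regulators are too numerous and too self-similar for sequence homology alone
to tell pilus-specific pairs from the rest; the positional context inside a
main cluster is what licenses the pilR1S1/pilR2S2 labels, and that
resolution therefore lives in the cluster stage.

## Cluster detection and organization calls

All neighbourhood logic runs on `locus_index` — the rank of a gene on its
contig — never on nucleotide distance: the quantity of interest is the
number of intervening genes. Scanning each contig left to right, two
assigned genes join the same cluster when at most `max_gap` non-member genes
lie between them. Strand is recorded but never affects membership.

* `max_gap = 5` (default). Observed intervening runs inside real T4aP loci
  are small (0–2); 5 keeps loci together under moderate annotation noise
  while staying far below the inter-locus spacing. It is the single most
  consequential knob and is exposed first in the config.
* `main` label: ≥ 10 members covering ≥ 5 of the ten core families
  (pilA, pilB, pilC, pilD, pilM–pilQ, pilT). Real main loci carry 15+ genes
  and dispersed genomes' largest locus (pilMNOPQ) has 5, so the thresholds
  sit in the gap between the two regimes.
* `minor_pilin` label: ≥ 2 members, all from {fimU, pilV, pilW, pilX, pilE,
  pilY1}. The size floor keeps scattered singleton minor pilins from being
  called "clusters".
* `mnopq` label: family set within {pilM..pilQ}, ≥ 4 distinct members.
* The riboflavin kinase anchor ribF is never a cluster member (role
  `anchor`); it is evidence for the synteny stage only.

Organization call: *clustered* if any main cluster exists; *dispersed* if
none does but an mnopq cluster does; *ambiguous* otherwise (including the
degenerate zero-T4aP-gene case).

Draft assemblies can split a main locus across contigs. Two clusters are
flagged as split candidates when they lie on different contigs, each has ≥ 3
members within `edge_window = 5` genes of a contig end, their family sets
are disjoint, and their union would qualify as main; a flagged pair upgrades
the call to clustered. The disjointness requirement is deliberately strict —
a cut through the block of four pilRS genes defeats it — trading a small
miss rate for near-zero false merging.

Architecture strings render members joined by `-` with intervening runs as
`x` (one gene) or `[k]` (k genes); `parse_architecture` inverts the encoding
losslessly, so the string is an interchange format, not just a display.

## Synteny anchors

`flanking_context` takes the k = 5 genes on each side of a cluster,
truncated at contig ends. `anchor_adjacent(pilB, ribF)` is true when a ribF
gene lies downstream of a pilB gene *in pilB's transcription direction* on
the same contig with ≤ 1 intervening gene (`max_intervening = 1`,
configurable; the biological claim is strict adjacency, the slack absorbs
one mis-annotated ORF). The verdict is invariant under reversing a contig's
coordinates and strands. Flanking-conservation tables compare family
assignments where available and otherwise the first token of the free-text
product, with no cross-genome orthology inference.

## Pilin diagnostics

Major pilins are synthesized as prepilins; the peptidase PilD cleaves after
an invariant Gly of a class III signal motif. The default motif
`G[FY][ST]L[ILMV]E` within the first 50 residues is the canonical consensus;
`cleavage_pos` is the 0-based index of that Gly and the mature sequence
starts right after it. The disulfide-bonded loop (DSL) classifier considers
cysteines in the C-terminal half of the mature sequence, takes the last pair
separated by 6–60 residues, and calls `terminal_dsl` if the downstream Cys
is within 15 residues of the C-terminus, `mid_cterm_pair` otherwise
(`cterm_fraction = 0.5`, `min_loop = 6`, `max_loop = 60`,
`terminal_window = 15` — chosen to separate the two arrangements seen in
cluster-resident versus cluster-distal pilins; all configurable, since real
Cys positions vary by lineage). DSL classification operates on the mature
sequence and is therefore invariant to prepending leader residues.

N-terminal conservation is summarized as the per-column modal-residue
fraction of a multiple alignment of mature pilins, with `window_mean` over
the first 60 columns (the conserved α-helical stalk). Paralog identity and
similarity matrices come from pairwise global alignments under the same
scoring scheme as the scan.

## Alignment and phylogenetics

The multiple aligner is deterministic progressive alignment: pairwise global
p-distances feed a UPGMA guide tree; profiles are merged leaf-to-root by
profile–profile Needleman–Wunsch with expected BLOSUM62 column scores and
the same affine gap costs. For two sequences this is exactly the optimal
pairwise global alignment. It is a deliberate stand-in for structure-guided
or iterative aligners — adequate here because the analyses that depend on it
(distance trees, conservation windows) operate on families whose members are
substitution-diverged rather than indel-rich.

Distances are computed over ungapped shared columns with Poisson correction
`d = −ln(1 − p)` for proteins (JC69 for nucleotide input); saturated pairs
raise an error naming the pair, except inside the bootstrap where they are
capped at 10 substitutions/site (resampling can transiently saturate a pair
that the full alignment supports). Trees come from a hand-written Saitou–Nei
neighbor joining with a fixed tie rule (smallest index pair in the current
Q-matrix), so output is deterministic; for additive inputs the tree
reproduces the input distances exactly, which the tests exploit. Full
likelihood inference is deliberately out of scope: the questions asked of
the trees — does the cluster-resident subfamily form one clade, with what
support — are answered by distance methods at a fraction of the cost, and
this fidelity trade-off is the package's main methodological substitution.

Bootstrap supports resample alignment columns with replacement; the support
of an internal edge is the percentage of replicate NJ trees containing its
bipartition (default 100 replicates). All replicate draws come from one
seeded stream laid out so replicate r consumes draws r·L..r·L+L−1,
independent of evaluation order. Monophyly of a taxon subset is decided by
exact bipartition match, with the matching edge's support attached;
singletons, the full leaf set, and (n−1)-subsets are trivially monophyletic
on an unrooted tree. Pilin phylogenies use only the first 60 mature
alignment columns (`nterm_window`), because pilin C-termini are too
divergent to align reliably.

## Synthetic genomes

The generator provides planted ground truth for every stage. Design points:

* **Panel.** One random ancestor per family (pilins 140–230 aa, pilQ
  600–900, others 200–500; pilRS contributes separate pilR-like and
  pilS-like ancestors). Decoys are derived from the pilB/pilC/pilD ancestors
  at 0.45–0.55 substitutions/site, redrawn until global identity lands in
  (35 %, 65 %) — similar enough to attract assignments, distinct enough that
  the true family always outscores them.
* **Mutation model.** Per-site substitution with probability 1 − e^(−d);
  replacements are BLOSUM62-biased (weight 2^(s/2) toward residue exchanges
  with positive scores), so percent similarity decays more slowly than
  identity — which is precisely what makes a 35 % similarity filter
  different from a 35 % identity filter. No indels are simulated.
* **pilA structure.** Leader (5 aa) + cleavage motif + 55 conserved residues
  (the mature N-terminal 60) + a divergent C-terminal head ending in a
  planted Cys pair (separation 10–14, second Cys 2 residues from the end).
  The stalk evolves at 0.2× the head rate; the motif and the Cys pair are
  protected from mutation, modelling purifying selection on the diagnostic
  sites. Scattered extra pilA paralogs are emitted with the Cys pair
  replaced, mirroring the second-pilin arrangement of clustered lineages.
* **Layouts.** Clustered genomes place the 17-slot main locus (order read
  from the editable packaged layout file) with pilB at the ribF-proximal
  end so ribF sits directly downstream of pilB in transcription direction,
  plus two fimU-pilW-pilV-pilY1-pilX loci, one pilW-x-pilY1 locus, and
  scattered singletons. Dispersed genomes keep only pilMNOPQ contiguous and
  scatter everything else, ribF included, with at least 6 background genes
  between planted elements (strictly more than `max_gap`, so planted
  singletons never coalesce). Background genes are uniform-random proteins
  of 150–350 aa with products drawn from a neutral vocabulary.
* **Fragmentation.** Contig breaks are Poisson-distributed over random
  intergenic points; the truth table records whether a break fell inside
  the main locus.
* **Determinism.** Every stream is seeded and domain-tagged
  (`default_rng([domain, seed])`), so a panel and a genome given the same
  integer seed still draw independent streams, and equal master seeds give
  identical cohorts.

What the generator does **not** emulate: indels and alignment ambiguity,
composition bias, overlapping genes and operon structure, annotation error
other than missing translations, real inter-family sequence relationships
(decoy divergence is calibrated only to exercise the exclusion rule), and
nucleotide-level evolution. Passing the planted-recovery suites therefore
demonstrates that the decision rules are implemented correctly and are
robust to substitution divergence up to ~0.35 subs/site — not that the
thresholds would reproduce a curated annotation of real genomes.

## Problem sizes and verification

The validation cohort is 100 genomes (seeds 1..100, half clustered, half
dispersed, per-genome divergence drawn from [0.05, 0.35], pilA copy number
1..7, expected 0.3 contig breaks each) — large enough that organization
accuracy, anchor linkage and copy-number recovery are measured over a few
thousand planted genes, small enough to scan in minutes on one CPU. Oracle
suites compare Smith–Waterman scores against an independent DP (200 random
peptide pairs, plus exhaustive substring enumeration at tiny lengths),
cluster detection against a graph-component oracle (500 random contigs),
NJ against random additive trees, and monophyly against edge-removal
enumeration (100 random 10-leaf trees). `scripts/acceptance.py` rebuilds
the two architecture fixtures from scratch and reports the main-cluster
size, minor-locus count, tandem-pilA count and pilRS pair count.

## Known limitations

* The E-value is not a calibrated Karlin–Altschul statistic; absolute
  values are meaningful only relative to the configured cutoff.
* The progressive aligner has no iterative refinement; with indel-rich real
  pilins the conservation window and N-terminal tree would inherit its
  alignment errors — supply an external alignment via
  `MultipleAlignment.from_fasta` in that case.
* The split-cluster heuristic requires disjoint family sets and so misses
  splits through a duplicated-family block (e.g. the pilRS pairs).
* Organization calls trust the annotation given; unannotated or
  frame-shifted genes simply count as intervening occupants.
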