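# t4apscan

Comparative analysis of **type IVa pilus (T4aP) gene systems** in bacterial
genomes. The T4aP machine — major pilin PilA, assembly/retraction ATPases
PilB/PilT, platform PilC, peptidase PilD, the envelope-spanning
PilM-PilN-PilO-PilP-PilQ sub-complex, minor pilins and regulators — is
encoded in two very different chromosomal arrangements: some lineages carry
one large multi-family cluster (plus satellite minor-pilin loci), others
disperse the genes and keep only *pilMNOPQ* contiguous. t4apscan annotates
annotated genomes (GFF3 + protein FASTA), decides which arrangement each
genome has, and tests the diagnostic signals that travel with the clustered
form: the riboflavin kinase gene *ribF* directly downstream of *pilB*, the
pilR1S1/pilR2S2 two-component pairs inside the main cluster, terminal
disulfide-bonded-loop (DSL) cysteines in cluster-resident pilins, and the
phylogenetic coherence of cluster-resident PilT/PilA copies.

It is aimed at comparative genomicists who want these calls reproducible
and parameterized instead of curated by hand.

## What it computes

1. **Homology scan** — exact Smith–Waterman (BLOSUM62, affine gaps 11/1)
   of every protein against a reference panel; hits pass only with
   E ≤ 1e-5, reference coverage ≥ 35 % and similarity ≥ 35 % (positives
   fraction); best bit score wins, and type II secretion system decoy
   families competitively exclude look-alikes.
2. **Cluster detection** — genes join a cluster when ≤ `max_gap` (default
   5) non-member genes intervene; clusters are labelled `main`,
   `minor_pilin`, `mnopq` or `other`, rendered as architecture strings
   like `fimU-pilW-pilV-pilY1-pilX` or `pilW-x-pilY1` (`x` = one
   intervening gene), and each genome is called
   clustered / dispersed / ambiguous. Main loci split across contig ends of
   draft assemblies are recognised and rescued.
3. **Synteny** — flanking context (5 genes each side) and anchor tests,
   chiefly *ribF* downstream of *pilB* in transcription direction.
4. **Pilin diagnostics** — prepilin cleavage site (`G[FY][ST]L[ILMV]E`
   motif), N-terminal 60-residue conservation, DSL cysteine-pair
   classification, paralog identity/similarity matrices.
5. **Phylogenetics** — deterministic progressive alignment, Poisson-corrected
   distances, Saitou–Nei neighbor joining with column-bootstrap supports
   (default 100 replicates), and exact monophyly tests of cluster-resident
   sequence sets.
6. **Synthetic genomes** — a generator that plants either organization,
   pilin sequence structure, decoys and draft fragmentation, with a full
   truth table, so every stage is testable against planted ground truth.

See `docs/methods.md` for models, defaults and limitations. The packaged
reference panel (`src/t4apscan/data/panel_synthetic.fasta`) is synthetic,
produced by the generator; supply your own panel FASTA (headers
`family|role`) for real analyses.

## Worked example

Simulate a four-genome cohort (two clustered, two dispersed) and run the
whole pipeline:

```bash
t4apscan simulate --out-dir demo --seed 4 --n 4 --mix 0.5
t4apscan all --out-dir demo/results --genomes-dir demo/genomes \
             --panel demo/panel.fasta --seed 4
cat demo/results/summary.tsv
```

```
genome	organization	main_cluster_size	split_candidate	n_pilA	pilB_ribF_linked
sim000	clustered	17	False	6	True
sim001	clustered	17	False	1	True
sim002	dispersed	0	False	1	False
sim003	dispersed	0	False	2	False
```

Both clustered genomes show the 17-gene main locus and *ribF* linked to
*pilB* with zero intervening genes (`demo/results/anchors.tsv`); the
dispersed genomes have no main cluster and an unlinked *ribF* — the planted
contrast, recovered from sequence alone. `n_pilA` is the pilA copy number
(1–7 in the simulation, matching the observed range in real genomes).
The bundle also contains per-cluster architectures (`clusters.tsv`), pilin
features, synteny frequency tables, Newick trees with bootstrap supports
(`pilT_nj.nwk`, `pilA_nj.nwk`), monophyly verdicts and an iTOL
DATASET_BINARY presence/absence annotation. Reruns with the same seed and
config are byte-identical.

The same machinery is available as a library:

```python
from t4apscan import (generate_panel, dk1622_fixture, assign_families,
                      detect_clusters, classify_all, call_organization)

panel, ancestors = generate_panel(20)
genome, truth = dk1622_fixture(ancestors, seed=1)   # 17-gene main locus
assignments = assign_families(genome, panel)
clusters = classify_all(detect_clusters(genome, assignments, 5, panel), panel)
main = next(c for c in clusters if c.label == "main")
print(main.size, main.pilrs_pairs)                  # 17 ['pilR1S1', 'pilR2S2']
```

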