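# strucphylo

Structure-based phylogenetics for protein structure models.

When homologs are too divergent for reliable sequence alignment — viral
RNA-dependent RNA polymerases (RdRPs) are the canonical case, with pairwise
identities deep in the twilight zone and some families carrying circularly
permuted domains — their three-dimensional folds still retain phylogenetic
signal. `strucphylo` turns a directory of predicted structure models
(PDB/mmCIF with per-residue pLDDT in the B-factor column, the AlphaFold
convention) into a supported phylogenetic tree:

1. **Quality control** — pLDDT-driven terminal trimming (15-residue window,
   threshold 70), rejection of unreliable models (> 5% of residues below
   pLDDT 50 or > 10% below 70), and removal of residues below pLDDT 50.
2. **Common structural core** — sequence-order-independent pairwise
   superposition (Kabsch) with progressive merging identifies the columns of
   structurally equivalent residues shared by *all* models.
3. **Distances and tree** — pairwise similarity scores *S* over the core
   become distances via

   D(A,B) = min[S(A,A), S(B,B)] − S(A,B)

   and a neighbor-joining tree is inferred (Saitou–Nei, exact on additive
   matrices), optionally rooted on an outgroup.
4. **Jackknife support** — core columns are resampled (random sites, or
   contiguous blocks of ≥ 10 columns; default 50% of columns, 100
   replicates, block mode), trees are rebuilt per replicate, and each branch
   of the reference tree is annotated with the percentage of replicates that
   contain it. A sampling-fraction sweep (10–90%) reports how the mean
   normalized Robinson–Foulds distance to the reference tree decays with
   sampling fraction.

A synthetic-data generator (`strucphylo.synthfix`) produces structure sets
evolved along a known tree — with spatially correlated coordinate noise,
programmable pLDDT profiles, indels and low-confidence tails — so the entire
pipeline is testable without any external dataset.

## Worked example

Simulate six structures related by a known tree, run the full pipeline, and
compare the inferred tree with the truth:

```sh
$ strucphylo simulate --n-leaves 6 --seed 7 --out data
wrote dataset to data

$ strucphylo run --in data --out results --seed 7
qc_report: results/qc_report.tsv
core: results/core.json
scores: results/scores.tsv
tree: results/tree.nwk
tree_support: results/tree_support.nwk
sweep: results/sweep.tsv
log: results/run_log.yaml

$ cat results/tree_support.nwk
[strucphylo v0.1.0 seed=7 fraction=0.5 mode=block reps=100]
(t4:1.18,(t6:1.19,(t1:6.97,t3:3.85)100:7.97)100:9.88,(t2:2.61,t5:5.51)100:3.04);

$ strucphylo compare --t1 results/tree.nwk --t2 data/truth.nwk --normalized
0
```

Reading the output: the Newick labels `100` after each internal group are
jackknife support percentages — here every internal branch appears in all
100 block-jackknife replicates, and the inferred topology is identical to
the generating tree (normalized Robinson–Foulds distance 0). The sweep table
shows the topology stabilizing as more of the core is sampled:

```
fraction  mean_rf  sd_rf  replicates
0.1       0.240    0.322  100
0.2       0.117    0.203  100
0.3       0.053    0.140  100
0.4       0.010    0.057  100
0.5       0.003    0.033  100
0.6-0.9   0.000    0.000  100
```

(mean_rf = mean normalized Robinson–Foulds distance of replicate trees to
the reference; branch lengths in the example tree above are shown rounded.)

The same steps are available as library calls (`qc_batch`, `build_core`,
`score_to_distance`, `neighbor_joining`, `jackknife_support`,
`fraction_sweep`, `compare_modes`) on `StructureModel` objects from
`read_structure`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline from scratch at the given seed: it simulates an
8-leaf dataset with spatially correlated structural noise and low-confidence
tails, runs QC, core alignment, neighbor joining, the 100-replicate block
jackknife at 50% sampling and the 10–90% fraction sweep, and writes the
result JSON to `--out`.
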