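# Methods

`strucphylo` infers phylogenies from protein structure models alone: no
multiple sequence alignment is computed, and sequence order is never used to
decide which residues are equivalent. The intended inputs are AlphaFold-style
predicted models of a protein family too divergent for reliable sequence
alignment (the motivating case is viral RNA-dependent RNA polymerases, where
pairwise identities fall below the twilight zone and some families carry
circularly permuted domains).

## Pipeline

1. **Quality control** (`qc`). Per-residue confidence (pLDDT, read from the
   B-factor column) drives three rules, applied in this order:
   - *Terminal trimming*: a 15-residue window slides in from each terminus;
     everything outside the first/last window whose residues are all
     strictly above pLDDT 70 is deleted.
   - *Rejection*: a trimmed model is discarded if strictly more than 5% of
     its residues are below pLDDT 50, or strictly more than 10% are below
     70. Boundary models (exactly 5%/10%) are kept.
   - *Removal*: residues strictly below pLDDT 50 are dropped from models
     that pass. The downstream aligner consumes the gapped C-alpha trace.
   All thresholds are read literally as strict inequalities; the boundary
   semantics are pinned by unit tests. Files whose B-factors are all zero
   are treated as experimental structures (pLDDT set to 100; QC becomes a
   no-op), since confidence screening only makes sense for predictions.
   An optional region trim keeps an annotated domain ±200 residues.

2. **Common-core alignment** (`corealign`). Structural equivalence is
   decided geometrically:
   - *Pairwise*: candidate superpositions are seeded from all pairs of
     gapless 12-residue fragments (stride 6, batched Kabsch/SVD); seeds with
     fragment RMSD < 2 Å are kept if their whole transform (rotation *and*
     translation) differs from seeds already taken — rotation alone is not
     sufficient because register shifts along repetitive backbone share the
     rotation. Each seed is extended by alternating (a) Kabsch superposition
     on the current pairs and (b) one-to-one residue assignment among pairs
     with transformed C-alpha distance < 4.5 Å, to a fixed point (≤ 50
     rounds). Assignment is minimum-cost (Hungarian) rather than greedy
     nearest-neighbour: at divergences where the nearest neighbour is not
     the true equivalent, the global optimum makes measurably fewer
     mismatches (on synthetic ground truth, greedy left 15–25% wrong core
     columns at 8 leaves). The extension with the highest score wins.
     Because nothing in this procedure consults residue order, circular
     permutations align correctly.
   - *Column score*: each matched column contributes
     `w_geo * exp(-d^2 / (2 sigma^2)) + w_aa * aa_sim`, with `d` the
     inter-C-alpha distance after superposition (`sigma` = 3 Å, `w_geo` = 1,
     `w_aa` = 0.5) and `aa_sim` a BLOSUM62 value rescaled to [0, 1]
     (pairs involving X score 0). This is a deliberately simplified,
     geometry-dominant surrogate for the multi-property scoring of the
     original progressive aligner, whose parameterization is not public.
     `sigma` = 3 Å rather than a narrower kernel: the downstream distance
     formula needs scores near-additive in divergence, and a narrower
     kernel's concavity compresses distances between divergent structures
     (long-branch attraction in NJ). Self-scores use the identity
     correspondence (d = 0 per residue), which makes
     `S(A,B) <= min(S(A,A), S(B,B))` hold column by column.
   - *Progressive merge*: all pairwise scores are computed first; groups are
     merged highest-score-first (group score = mean of member pairwise
     scores, ties broken lexicographically). A merge intersects the two
     groups' column sets via the correspondence of the most similar cross
     pair — the most reliable available bridge. The final core contains only
     columns present in every model. Per-column score contributions are
     stored, so any column subset's score matrix is an exact partial sum.

3. **Tree inference** (`phylo`). Scores become distances via
   `D(A,B) = min(S(A,A), S(B,B)) - S(A,B)` (non-negative by the dominance
   property; violations raise). Trees come from canonical neighbor joining
   (Saitou–Nei agglomeration, Studier–Keppler Q-criterion), which is exact
   on additive matrices; negative branch-length estimates are clamped to
   zero and the deficit logged. Optional outgroup rooting places the root
   mid-edge on the branch separating the outgroup. Robinson–Foulds distances
   count bipartitions present in exactly one tree; the normalized variant
   divides by the total number of non-trivial bipartitions in both trees.

4. **Jackknife support** (`jackknife`). Core columns are resampled without
   replacement — independent sites, or contiguous blocks of ≥ 10 columns
   (block lengths uniform in [10, remaining quota]; one final remainder
   block may be shorter so the sampled count is exactly
   `round(fraction × core length)`; block starts uniform over legal
   non-overlapping positions, with bounded whole-attempt restarts). Scores
   are restricted to the sampled columns (exact, by column additivity),
   distances and NJ trees recomputed per replicate, and each internal edge
   of the reference tree is annotated with the percentage of replicates
   containing its bipartition. Replicates draw from per-replicate substreams
   of one seeded generator, so runs are reproducible byte for byte.
   Defaults: fraction 0.5, 100 replicates, block mode — fraction 0.5 sits in
   the stabilization region of the sampling-fraction sweep (mean RF to the
   reference drops steeply at low fractions and flattens around 40%), and
   block deletion is the stricter perturbation when structural noise is
   spatially correlated.

## Synthetic data (`synthfix`)

The generator emulates exactly what the pipeline consumes, so every stage is
testable without external data:

- **Template**: a self-avoiding C-alpha trace built from idealized helix
  rows (rise 1.5 Å, radius 2.3 Å, 100°/residue) and strand rows (rise
  3.3 Å, z-zigzag) in a serpentine layout connected by semicircular turns.
  Consecutive C-alpha spacing stays in [3.5, 4.1] Å and non-consecutive
  residues stay ≥ 3 Å apart (both property-tested).
- **Divergence**: along each branch of a known tree (Yule-like, balanced or
  caterpillar topology; branch lengths U(0.5, 1.5)), every residue receives
  Gaussian displacement with per-residue sd = `noise_per_unit_branch` ×
  branch length, smoothed along the chain with a moving-average window of
  `spatial_correlation_length` residues (and rescaled to keep the
  per-residue sd). Smoothing is what makes contiguous structural segments
  carry redundant signal — the feature the block jackknife is designed to
  respect. Displacements accumulate down the tree, so pairwise divergence
  tracks path length (rank correlation property-tested).
- **Leaf decorations**: optional indels (terminal branches only), terminal
  tails of programmable length and pLDDT (default pLDDT 55, i.e. removed by
  terminal trimming), a random rigid motion per leaf, and a
  ground-truth residue map to the template in `meta["template_map"]`.
- **Defaults** (chosen once): template 120 residues, noise 0.5 Å per unit
  branch, correlation length 15 residues, body pLDDT 92, tails 30 × pLDDT
  55. A 120-residue template keeps the full pipeline fast enough for
  simulation-heavy tests; 0.5 Å/unit with U(0.5, 1.5) branches produces
  pairwise core RMSDs of roughly 1–3 Å, i.e. divergent but alignable.

### What a green test does and does not establish

The generator produces single-chain, gap-free, equal-length C-alpha traces
with idealized geometry and *no sequence evolution* (amino acids are
inherited unchanged from the template, so the score's sequence term is
uninformative between true equivalents and only penalizes mismatches). Real
predicted structures differ in length, contain genuine insertions/deletions
and low-confidence interiors, and their structural noise is neither Gaussian
nor stationary. Green tests therefore establish the *correctness of the
algorithms under their stated model* — exact QC semantics, exact NJ/RF
behaviour, unbiased resampling, directionally correct jackknife behaviour —
not the accuracy of the pipeline on any particular empirical dataset.

An information-theoretic caveat worth knowing: with spatial correlation
length 15 on a 120-column core there are only ~8 effectively independent
structural observations, and *no* distance estimator reliably recovers a
6-taxon topology from that (verified with ground-truth correspondences).
Topology-recovery benchmarks therefore use weakly correlated noise
(correlation length 2); the strongly correlated default world is used where
spatial correlation is the point (block-vs-site jackknife contrast).

## Numerical choices and degenerate inputs

- Kabsch superposition uses SVD with a determinant sign correction; fits
  with a vanishing second singular value (collinear points) are flagged
  `degenerate` and logged, not rejected.
- Ties in assignment are resolved by `scipy.optimize.linear_sum_assignment`
  deterministically; ties in merge order lexicographically by model id.
- All randomness flows through `numpy.random.Generator` instances seeded
  from the run seed; jackknife replicate r uses the r-th spawned substream.
- Models shorter than the QC window are rejected (no qualifying window can
  exist). An all-zero B-factor file is treated as experimental (see above).
  Models sharing fewer than `min_core_len` (default 30) aligned residues
  with every other model are excluded from the core with a warning, or
  raise under `--strict`.
- `fraction_sweep` reports an advisory stabilization fraction: the smallest
  fraction whose mean RF changes by < 0.02 to the next fraction.

## Known limitations

- The pairwise aligner is rigid: hinged or domain-swapped conformations are
  aligned by their dominant rigid component only.
- The column score is a two-term surrogate; scores (and therefore absolute
  distances) are not comparable to those of the original multi-property
  aligner, though the derived topologies behave the same way under the
  published distance formula.
- Progressive merging intersects correspondences; a single poorly aligned
  bridge pair can shrink the core (mitigated, not eliminated, by using the
  most similar cross pair as the bridge).
- NJ with clamped negative branches is not a likelihood method; no model of
  structural evolution is fitted.
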