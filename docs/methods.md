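# Methods

## Model overview

`phyloshot` assigns species labels to short marker amplicons in three
stages.  First, species embeddings are learned from a phylogeny alone:
one vector per species, adjusted by stochastic gradient steps so that
pairwise cosine distances reproduce normalized patristic distances.
Second, a convolutional encoder is trained to map raw sequences onto the
frozen embeddings of their species; an exponential kernel over cosine
distance then turns any embedded query into a probability vector over all
species (a soft nearest-neighbour classifier).  Third, a low-rank bilinear
layer modulates the probability vectors of all sequences detected at one
site jointly, exploiting the fact that close relatives tend not to
co-occur.  Species never seen by the encoder remain predictable because
they still own an embedding, and the co-occurrence layer can shift mass
from a confusable relative to the species that fits the observed
community.

All three stages are trained with AdamW in double-precision NumPy with
analytically derived gradients (the convolution/MLP backward pass is
verified against finite differences in the test suite).  Every source of
randomness flows from explicit integer seeds through
`numpy.random.Generator`, so training traces and model parameters are
bit-reproducible on one machine.

## Stage 1 — species embeddings

* Loss: squared gap between the target distance and the cosine distance,
  summed over a contrast set sampled fresh at every visit of a focal
  species: one random leaf from the sibling subtree at each branching of
  the root-to-focal path.  At a polytomy the union of the non-focal child
  subtrees acts as the sibling set.  The contrast set therefore mixes
  close and distant relatives in proportion to tree depth.
* Defaults: dimension 64, learning rate 0.01 (constant), batch = 64 focal
  species per optimizer step, 100 epochs (a randomized full pass over all
  species).  Desk-scale runs in this package use dimension 16 for worlds
  of a few hundred species.
* Distance normalization: patristic distances are divided by the maximum
  pairwise distance, mapping targets into [0, 1] (the non-antipodal
  half-space of the cosine distance).  A `tree_diameter_x2` mode scaling
  the maximum to 2 is available; [0, 1] is the default because embeddings
  confined to a half-space stay well away from the antipodal regime where
  the cosine gradient degenerates.
* Initialization: i.i.d. Gaussian rows scaled to unit norm.  Embeddings
  are not renormalized during training (cosine distance is
  scale-invariant).

### Fidelity and its limits

On a 128-leaf Yule tree with dimension 16 the final loss corresponds to a
root-mean-square pairwise distance error of ~0.07 and a Pearson
correlation of ~0.96 between realized and target distances.  Rank
(Spearman) correlation over all pairs is substantially lower (typically
0.7–0.9 depending on tree shape): an ultrametric tree has only n−1
distinct pairwise distances, and all cross-root pairs are exactly tied at
the diameter, so any fit error scrambles ranks within these large tied
groups.  The squared-error objective is indifferent to within-tie order,
which caps all-pairs rank correlation well below 1 even when the fit is
numerically excellent.  This does not affect classification, which relies
on local neighbourhood structure (sister species and congeners at small,
well-separated distances); trees whose root split is very balanced simply
carry a larger tied mass.  A truncated eigendecomposition of the
similarity matrix preserves ties better (rank correlation ~0.94 at
dimension 16) but degrades as soon as the pairwise loss is optimized, so
it is not used.

## Stage 2 — DNA encoder

* Tokenization: A/C/G/T map to four tokens, every other character (IUPAC
  ambiguity codes, sequencing artefacts) to a single ambiguity token;
  sequences are right-padded to `max_len` with a pad token whose base
  embedding is pinned at zero (so padding behaves like the convolutions'
  zero padding), and longer sequences are truncated with a warning.
* Architecture: learnable base-embedding table → conv1d (kernel 5,
  dilation 1, symmetric zero padding 2) → ReLU → conv1d (kernel 5,
  dilation 5, padding 10) → ReLU → flatten → linear (hidden 2048) → ReLU
  → linear (output = embedding dimension).  Both convolutions preserve
  sequence length for any `max_len` ≥ 21 (so the dilated kernel fits).
  Flattening rather than pooling before the MLP retains positional
  information, which matters for 29–96 bp amplicons; mean pooling is
  available as a config option.  Channel width defaults to 64
  (32 at desk scale, with hidden width 256 and `max_len` 96).
* Training: cosine distance to the frozen species embedding, AdamW at
  1e-3, batch 16, a fixed 30 epochs, no validation set and no early
  stopping.  Records of holdout species are excluded from every batch.
  Multiple reference sequences of one species each form their own
  training example, including sequences shared verbatim across species.

## Stage 3 — co-occurrence modulation

* For the M members of a site, item i's logits are
  `log p_i + U V^T q_i` with `q_i` the leave-one-out mean of the other
  members' probability vectors, followed by a softmax.  U, V have shape
  (n_species × m), m = 256 by default.
* Initialization: U = 0, V ~ N(0, 0.01²).  Zero U makes the first
  optimizer step see exactly the unmodulated likelihood and guarantees a
  smooth departure from the identity map.
* Training: per-site batches (one AdamW step at 1e-3 per site visit, no
  batching across sites), sites visited in seeded random order, 10 passes
  by default.  Sites with fewer than two usable members are skipped — the
  leave-one-out mean is undefined — and such items pass through unchanged
  at inference.  Probabilities are floored at 1e-30 before the log; the
  exponential kernel cannot produce exact zeros analytically, but
  double-precision underflow can.
* Site vectors during training: species with at least one usable
  reference sequence contribute the encoder's mapping of one seeded-chosen
  sequence; species without sequences contribute their embedding plus
  isotropic Gaussian noise.  The noise standard deviation is calibrated by
  bisection so that the median cosine perturbation matches the encoder's
  median mapping error on held-out species (~0.15–0.18 in the desk
  worlds), i.e. the stand-ins are exactly as wrong as the encoder would
  be.  Discarding sequence-less species instead is available as a flag.
* Inference applies a single modulation pass with unmodulated context
  vectors (no fixed-point iteration), identically for assemblage-trained
  and grid-trained models.

## Evaluation protocol

A random subset of referenced species (10% at desk scale, mirroring the
full-scale 431-species holdout) is excluded from encoder training and
treated as sequence-less during co-occurrence training.  Accuracies are
two-stage averages: per species over all of its sequences, then unweighted
over species, reported independently at species/genus/family/order (a
prediction is rank-correct when the predicted species shares that rank's
value with the truth).  Modulated evaluation visits every site containing
an evaluation species, using the other members' vectors (encoder mappings
or noisy embeddings) as context.  Calibration bins top-1 probabilities
into twenty 5%-wide bins; empty bins report an undefined proportion
rather than zero.  Agreement with an external annotation table is scored
at the shallower of the two assignment depths, taking the deepest rank at
which the two assignments name the same taxon.

## Sample pipeline

Reads are dereplicated, then clustered by iterative single linkage at
edit distance d = 1 (seeds in order of decreasing abundance; a cluster
absorbs every unassigned sequence within d of any member, i.e. the
connected component), and clusters with fewer than 3 total copies are
discarded.  Candidate neighbour pairs come from a symmetric-deletion
index (exact for d = 1) and are verified with edlib.  This is a
deliberate simplification of SWARM — no fastidious phase, no
abundance-gradient cluster breaking — and pre-clustered input is accepted
as an alternative.  The cluster representative is the most abundant
member (ties: lexicographically smallest sequence).  A 10⁴–10⁵-read
sample annotates in a few seconds on one CPU.

## Synthetic worlds

The generator produces the data structure the method assumes, at desk
scale:

* **Tree:** Yule (pure-birth) with exactly n extant tips, ultrametric,
  birth rate 1.0, via dendropy.
* **Sequences:** Jukes–Cantor evolution from a uniform root sequence,
  exact per-branch transition probabilities, rate 0.05 per unit time —
  sister species differ at a few percent of sites while deep clades
  approach (but do not reach) saturation.  Per-species amplicon lengths
  are uniform on 29–96 bp (prefix truncation), matching the teleo
  marker's length range; ~30% of referenced species carry a second,
  lightly diverged sequence so the reference database has more sequences
  than species.
* **Taxonomy:** genus/family/order are connected components of the tree
  cut at 25% / 50% / 75% of its height (from the tips); nesting is
  guaranteed by construction.  On 600-species worlds this yields roughly
  125 genera, 22 families, 7 orders — about 5 species per genus, similar
  in spirit to the fish data's ratios.
* **Assemblages:** species are assigned to 8 regions; with probability
  0.9 (the segregation strength) a sister-pair member avoids its
  already-placed sister's region.  Each region contributes 40 sites of
  exactly 25 species drawn from the regional pool.  The occurrence grid
  places each species in all 4 cells of its region's block, so
  grid-derived co-occurrence is a coarsened (pool-level) version of the
  site-level community data — mirroring the contrast between range-map
  and observed-community co-occurrence.
* **Reads:** per-species copy numbers log-uniform on [1, max]; per-base
  substitution errors at 1% by default.  No indels or chimeras.
* The default world is 600 species with a 20% reference gap.  One master
  seed fans out to all components; two builds from the same seed are
  identical field by field.

### What the synthetic worlds do not emulate

Real 12S reference databases contain identical sequences shared across
species, PCR/sequencing indels and chimeras, ragged taxon sampling, and
assemblages shaped by environmental filtering rather than a block-regional
pool.  Passing the desk-scale tests demonstrates that the mechanism —
zero-shot placement near relatives plus co-occurrence disambiguation — is
implemented correctly and recoverable when its assumptions hold; it does
not predict absolute accuracies on real data, which depend on reference
coverage, marker resolution and co-occurrence data quality.  Desk-scale
zero-shot accuracies are much higher than full-scale ones simply because
600 candidate species with clean phylogenetic signal are far easier than
31,516.

## Numerical choices

* Kernel probabilities are computed in log space with max subtraction: at
  τ = 0.05 the raw kernel underflows for cosine distances ≳ 1.7.
* Top-1 ties (exact float equality) break to the lexicographically
  smallest species id.
* Patristic distances are computed by an O(n²) LCA sweep (depth(i) +
  depth(j) − 2·depth(lca)); branch lengths must be present and
  non-negative, and malformed trees fail loudly with the offending edge
  named.
* Non-finite losses abort training immediately with a diagnostic rather
  than continuing with NaNs.

## Known limitations

* Training is CPU NumPy: adequate for 10²–10³ species worlds, not for a
  31k-species phylogeny; the n×n distance matrix is held in memory.
* The all-pairs rank-fidelity ceiling on ultrametric trees (see Stage 1)
  is inherent to the squared-distance objective.
* The clustering is not SWARM-exact (no fastidious phase or breaking);
  for production use on real samples, run SWARM and pass `--pre-clustered`.
* Synonymy, taxonomic name reconciliation and reference curation are out
  of scope; species identifiers are exact strings.
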