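# phyloshot

Zero-shot taxonomic annotation of eDNA metabarcoding sequences using
phylogenetic embeddings and species co-occurrence.

## The problem

Environmental DNA (eDNA) metabarcoding detects species from short marker
amplicons (e.g. the ~29–96 bp teleo fragment of the mitochondrial 12S gene
in fish surveys), but reference databases cover only a fraction of the
species pool.  A sequence from an unreferenced species cannot be assigned
by similarity search — yet its correct label is often recoverable, because
(i) a phylogeny relates every species, referenced or not, and (ii) local
assemblages rarely contain more than one member of a clade of close
relatives (allopatric speciation geographically dissociates sister
species), so the other species detected in the same sample constrain which
relative is actually present.

`phyloshot` implements this idea as a three-stage model plus an end-to-end
sample pipeline:

1. **Phylogenetic embedding.**  Each species *i* in the tree gets a learned
   vector **e**ᵢ ∈ ℝᵈ, optimized directly (no network) so that the cosine
   distance matches the normalized patristic distance:

       L_tree(i, Sᵢ) = Σ_{j∈Sᵢ} ( d_tree(i,j) − d_cos(eᵢ, eⱼ) )²

   where the contrast set Sᵢ holds one randomly sampled species from the
   sibling subtree at every branching on the root-to-*i* path, so each
   focal species is contrasted against relatives at every depth.

2. **DNA encoder.**  A small convolutional network f_θ (learnable base
   embedding; two length-preserving 1-D convolutions, kernel 5 with
   dilations 1 and 5; a 2-layer MLP head) maps a raw sequence **s**ᵢ into
   the same space by minimizing L_DNA = d_cos(f_θ(**s**ᵢ), **e**ᵢ) against
   the frozen species embeddings.  A query sequence **s**\* becomes a
   probability vector over all species through a temperature kernel
   (soft nearest neighbour, τ = 0.05):

       P(i|s*) = k(f_θ(s*), eᵢ; τ) / Σⱼ k(f_θ(s*), eⱼ; τ),
       k(x, y; τ) = exp(−d_cos(x, y)/τ)

3. **Co-occurrence modulation.**  For the M sequences/species detected at
   one site, each initial vector p̂ᵢ is jointly reshaped by the others:

       p̂ᵢᶜᵒ = σ( log p̂ᵢ + U Vᵀ · (1/(M−1)) Σ_{l≠i} p̂ₗ )

   with learnable low-rank matrices U, V ∈ ℝⁿˣᵐ (m = 256) trained by the
   negative log-likelihood of the true species over assemblage data — from
   observed communities or from range-map grids (two species co-occur if
   their ranges share a 1° cell).

The sample pipeline dereplicates and clusters demultiplexed reads with a
SWARM-style single-linkage rule (d = 1, clusters of size ≥ 3), annotates
cluster representatives, and optionally modulates each cluster by the other
clusters detected in the same sample.

A synthetic-data module generates complete desk-scale worlds (Yule tree,
Jukes–Cantor marker sequences, tree-cut taxonomy, geographically segregated
assemblages, occurrence grids, eDNA read sets) so the whole mechanism is
testable without any downloads.

All training is plain NumPy with hand-written gradients and an AdamW
optimizer; everything is deterministic under explicit seeds.

## Worked example

Build the default synthetic world (600 species, 20% of species missing
from the reference database, sister-species segregation 0.9), train all
three stages, and evaluate zero-shot classification of held-out species:

```python
import phyloshot as ps
from phyloshot.evaluation import ProtocolConfig, run_zero_shot_protocol

world = ps.make_world(seed=11)
res = run_zero_shot_protocol(world, ProtocolConfig.desk(), seed=1)
for (split, model), rep in sorted(res.reports.items()):
    print(f"{split:8s} {model:10s} species {rep.accuracy['species']:.3f}"
          f"  genus {rep.accuracy['genus']:.3f}")
```

prints (about a minute on one CPU):

```
holdout  community  species 0.632  genus 0.833
holdout  grid       species 0.608  genus 0.812
holdout  single     species 0.104  genus 0.771
train    community  species 0.997  genus 1.000
train    grid       species 1.000  genus 1.000
train    single     species 0.995  genus 1.000
```

Reading this: for the held-out species (simulating reference-database
gaps), the DNA model alone rarely lands on the exact species (10%) but
almost always on the right genus (77%) — the sequence is placed next to a
close relative.  Adding the community-trained co-occurrence model lifts
exact-species recovery to 63%, and the model trained on coarser range-map
grids sits in between.  Training-set species are classified at ~99.5%
either way.  This is the qualitative signature of the full-scale study,
reproduced at desk scale.

Annotating a simulated eDNA sample end to end:

```python
from phyloshot.synthetic_data import simulate_edna_reads
from phyloshot.sample_pipeline import annotate_sample

site = world.sites[0]
reads, truth = simulate_edna_reads(site.species_ids, world.sequences,
                                   reads_per_species=500, error_rate=0.01,
                                   seed=3)
table = annotate_sample(reads, res.dna_model, res.embeddings,
                        res.cooc_models["community"])
print(table.head(3))
```

```
cluster_id  abundance predicted_species  top1_probability
 cluster_1        300            sp0233          0.554680
 cluster_2        331            sp0334          0.478023
 cluster_3        264            sp0334          0.932412
```

The same steps are available from the shell via the `phyloshot` CLI
(`simulate`, `embed-tree`, `train-dna`, `train-cooc`, `annotate`,
`evaluate`); run `phyloshot --help`.

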