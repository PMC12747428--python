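"""Synthetic worlds: tree, marker sequences, taxonomy, assemblages,
occurrence grids and eDNA read sets with the statistical structure the
annotation method relies on.

The generator emulates, at desk scale, the data a marine 12S metabarcoding
study would assemble: a Yule (pure-birth) species tree standing in for a
large fish phylogeny; short Jukes-Cantor-evolved marker sequences with
teleo-like lengths (29-96 bp); taxonomy ranks cut from the tree at fixed
depths; and local assemblages in which sister species are geographically
segregated — the pattern produced by allopatric speciation that the
co-occurrence model exploits.  A configurable fraction of species is absent
from the reference database, mimicking real reference gaps.
"""

from __future__ import annotations

import math
import random as _pyrandom
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
from dendropy.model import birthdeath

from .data_io import (OccurrenceGrid, PhyloTree, ReferenceRecord, RANKS,
                      SiteAssemblage, TaxonomyTable, write_reference_fasta,
                      write_assemblages, write_reads)

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def simulate_yule_tree(n_leaves: int, birth_rate: float = 1.0,
                       seed: int = 0) -> PhyloTree:
    """Pure-birth tree with exactly ``n_leaves`` extant tips, ultrametric in
    time units; leaves are relabelled sp0001, sp0002, ..."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    dtree = birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_leaves, rng=_pyrandom.Random(seed))
    width = max(4, len(str(n_leaves)))
    for k, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{k:0{width}d}"
    return PhyloTree(dtree)


# ---------------------------------------------------------------------------
# Sequences (Jukes-Cantor)
# ---------------------------------------------------------------------------

def _jc_mutate(parent: np.ndarray, branch: float, rate: float,
               rng: np.random.Generator) -> np.ndarray:
    """Exact JC69 transition along one branch: each site changes with
    probability 3/4 (1 - e^(-4 r t / 3)), uniformly to one of the other bases."""
    p_change = 0.75 * (1.0 - math.exp(-4.0 * rate * branch / 3.0))
    child = parent.copy()
    hit = rng.random(parent.shape[0]) < p_change
    if hit.any():
        child[hit] = (parent[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return child


def evolve_sequences_jc(
    tree: PhyloTree,
    seq_length: int | tuple[int, int],
    subst_rate: float,
    seed: int = 0,
) -> dict[str, str]:
    """Evolve one marker sequence per species down the tree under JC69.

    The root sequence is uniform over A/C/G/T.  ``seq_length`` may be a
    single length or a (lo, hi) range, in which case the full-length sequence
    evolves and each species keeps a prefix of a length drawn uniformly from
    the range (mimicking amplicon length variation).
    """
    if subst_rate < 0:
        raise ValueError("substitution rate must be >= 0")
    if isinstance(seq_length, tuple):
        lo, hi = seq_length
        full_len = hi
    else:
        lo = hi = full_len = int(seq_length)
    if lo < 1:
        raise ValueError("sequence length must be >= 1")
    rng = np.random.default_rng(seed)
    n = tree.n_nodes
    seqs: list[Optional[np.ndarray]] = [None] * n
    seqs[0] = rng.integers(0, 4, size=full_len)
    for i in range(1, n):  # preorder: parent before child
        seqs[i] = _jc_mutate(seqs[tree.parent[i]], tree.blen[i], subst_rate, rng)
    out: dict[str, str] = {}
    for label in tree.taxa:
        node = tree._leaf_node[label]
        L = int(rng.integers(lo, hi + 1)) if lo != hi else full_len
        out[label] = "".join(BASES[seqs[node][:L]])
    return out


# ---------------------------------------------------------------------------
# Taxonomy from tree cuts
# ---------------------------------------------------------------------------

def derive_taxonomy_from_tree(
    tree: PhyloTree, cut_depths: tuple[float, float, float] = (0.25, 0.5, 0.75)
) -> TaxonomyTable:
    """Assign genus/family/order by cutting the tree at increasing heights.

    ``cut_depths`` are fractions of tree height measured from the tips;
    each rank groups leaves by the connected component they fall into when
    all edges crossing that height are cut.  Deeper cuts give coarser,
    strictly nested ranks.
    """
    g, f, o = cut_depths
    if not (0 < g < f < o):
        raise ValueError("cut depths must satisfy 0 < genus < family < order")
    ages = tree.node_ages()
    height = ages.max()
    import pandas as pd

    data: dict[str, list[str]] = {r: [] for r in RANKS}
    prefixes = {"genus": "g", "family": "f", "order": "o"}
    for rank, frac in zip(RANKS, (g, f, o)):
        h = frac * height
        group_of: dict[str, int] = {}
        seen: dict[int, int] = {}
        for label in tree.taxa:
            node = tree._leaf_node[label]
            grp = node
            while tree.parent[grp] != -1 and ages[tree.parent[grp]] <= h:
                grp = tree.parent[grp]
            if grp not in seen:
                seen[grp] = len(seen) + 1
            group_of[label] = seen[grp]
        width = max(3, len(str(len(seen))))
        data[rank] = [f"{prefixes[rank]}{group_of[t]:0{width}d}" for t in tree.taxa]
    df = pd.DataFrame(data, index=pd.Index(tree.taxa, name="species"))
    return TaxonomyTable(df)


# ---------------------------------------------------------------------------
# Assemblages with sister-species segregation
# ---------------------------------------------------------------------------

def _cherry_pairs(tree: PhyloTree) -> dict[int, int]:
    """taxa position -> taxa position of its sister for every cherry leaf."""
    out: dict[int, int] = {}
    node_pos = {tree._leaf_node[t]: k for k, t in enumerate(tree.taxa)}
    for u in range(tree.n_nodes):
        ch = tree.children[u]
        leaves = [c for c in ch if not tree.children[c]]
        if len(ch) == 2 and len(leaves) == 2:
            a, b = node_pos[leaves[0]], node_pos[leaves[1]]
            out[a] = b
            out[b] = a
    return out


def simulate_assemblages(
    tree: PhyloTree,
    n_regions: int = 8,
    sites_per_region: int = 40,
    richness: int = 25,
    segregation_strength: float = 0.9,
    seed: int = 0,
    cells_per_region: int = 4,
) -> tuple[list[SiteAssemblage], OccurrenceGrid]:
    """Assign species to regions, then sample fixed-richness sites per region.

    With probability ``segregation_strength`` a cherry (sister-pair) member
    is forced into a region different from its already-placed sister;
    otherwise regions are uniform.  The occurrence grid lays each region out
    as a block of ``cells_per_region`` one-degree cells (row = region), with
    every species present throughout its region, so grid-derived
    co-occurrence is a coarsened version of the assemblage co-occurrence.
    """
    if not 0 <= segregation_strength <= 1:
        raise ValueError("segregation_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = tree.n_leaves
    sisters = _cherry_pairs(tree)
    region_of = np.full(n, -1, dtype=np.int64)
    for i in rng.permutation(n):
        sis = sisters.get(int(i))
        if sis is not None and region_of[sis] >= 0 and rng.random() < segregation_strength:
            choices = [r for r in range(n_regions) if r != region_of[sis]]
            region_of[i] = choices[int(rng.integers(len(choices)))]
        else:
            region_of[i] = int(rng.integers(n_regions))

    sites: list[SiteAssemblage] = []
    for r in range(n_regions):
        pool = np.flatnonzero(region_of == r)
        if len(pool) < richness:
            raise ValueError(
                f"region {r} holds {len(pool)} species < richness {richness}; "
                "reduce richness or n_regions")
        for k in range(sites_per_region):
            members = rng.choice(pool, size=richness, replace=False)
            sp = tuple(sorted(tree.taxa[i] for i in members))
            sites.append(SiteAssemblage(f"r{r}_s{k:03d}", sp))

    grid = OccurrenceGrid()
    for i in range(n):
        for c in range(cells_per_region):
            grid.add(tree.taxa[i], int(region_of[i]), c)
    return sites, grid


# ---------------------------------------------------------------------------
# eDNA reads
# ---------------------------------------------------------------------------

def simulate_edna_reads(
    site_species: Sequence[str],
    sequences: dict[str, str],
    reads_per_species: int = 100,
    error_rate: float = 0.01,
    seed: int = 0,
) -> tuple[list[tuple[str, str, int]], dict[str, str]]:
    """Simulate a demultiplexed, primer-trimmed read set for one site.

    Per-species copy numbers are log-uniform on [1, reads_per_species]; each
    read is its species' marker sequence with independent per-base
    substitution errors at ``error_rate``.  Returns (read rows, truth map
    read_id -> species).
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    missing = [s for s in site_species if s not in sequences]
    if missing:
        raise ValueError(f"species without sequences: {missing}")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str, int]] = []
    truth: dict[str, str] = {}
    rid = 0
    for sp in site_species:
        seq = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in sequences[sp]])
        count = max(1, int(round(math.exp(rng.uniform(0, math.log(max(reads_per_species, 1)))))))
        for _ in range(count):
            read = seq.copy()
            hit = rng.random(len(seq)) < error_rate
            if hit.any():
                read[hit] = (read[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
            rid += 1
            name = f"read_{rid:06d}"
            reads.append((name, "".join(BASES[read]), 1))
            truth[name] = sp
    return reads, truth


# ---------------------------------------------------------------------------
# Whole worlds
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorld:
    """Everything the pipeline needs, generated from one master seed."""

    tree: PhyloTree
    sequences: dict[str, str]            # ground truth, every species
    records: list[ReferenceRecord]       # reference DB (gap species absent)
    taxonomy: TaxonomyTable
    sites: list[SiteAssemblage]
    grid: OccurrenceGrid
    gap_species: list[str]
    seed: int

    @property
    def referenced_species(self) -> list[str]:
        return sorted({r.species_id for r in self.records})

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.tree.write(out / "tree.nwk")
        write_reference_fasta(self.records, out / "ref.fasta")
        self.taxonomy.to_tsv(out / "tax.tsv")
        write_assemblages(self.sites, out / "sites.tsv")
        self.grid.to_tsv(out / "grid.tsv")


def make_world(
    n_species: int = 600,
    gap_fraction: float = 0.2,
    segregation: float = 0.9,
    seed: int = 0,
    birth_rate: float = 1.0,
    subst_rate: float = 0.05,
    seq_length: tuple[int, int] = (29, 96),
    second_seq_fraction: float = 0.3,
    n_regions: int = 8,
    sites_per_region: int = 40,
    richness: int = 25,
    cut_depths: tuple[float, float, float] = (0.25, 0.5, 0.75),
) -> SyntheticWorld:
    """Build the default study world: 600 species, 20% reference gap,
    sister-species segregation 0.9.

    A fraction of referenced species carries a second, slightly diverged
    reference sequence (intraspecific variation), matching the
    more-sequences-than-species shape of real reference databases.
    """
    ss = np.random.SeedSequence(seed)
    s_tree, s_seq, s_asm, s_misc = [int(c.generate_state(1, np.uint64)[0] >> 33) for c in ss.spawn(4)]
    tree = simulate_yule_tree(n_species, birth_rate, seed=s_tree)
    sequences = evolve_sequences_jc(tree, seq_length, subst_rate, seed=s_seq)
    taxonomy = derive_taxonomy_from_tree(tree, cut_depths)
    sites, grid = simulate_assemblages(
        tree, n_regions, sites_per_region, richness, segregation, seed=s_asm)

    rng = np.random.default_rng(s_misc)
    n_gap = int(round(gap_fraction * n_species))
    gap = sorted(str(s) for s in rng.choice(tree.taxa, size=n_gap, replace=False))
    gap_set = set(gap)
    records: list[ReferenceRecord] = []
    for sp in tree.taxa:
        if sp in gap_set:
            continue
        records.append(ReferenceRecord(f"{sp}-1|{sp}", sp, sequences[sp]))
        if rng.random() < second_seq_fraction:
            seq = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in sequences[sp]])
            hit = rng.random(len(seq)) < 0.005   # light intraspecific divergence
            if hit.any():
                seq[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
            records.append(ReferenceRecord(f"{sp}-2|{sp}", sp, "".join(BASES[seq])))
    return SyntheticWorld(tree, sequences, records, taxonomy, sites, grid,
                          list(gap), seed)
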