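import math

import numpy as np
import pytest

import phyloshot as ps
from phyloshot.data_io import RANKS
from phyloshot.synthetic_data import (derive_taxonomy_from_tree, evolve_sequences_jc,
                                      make_world, simulate_assemblages,
                                      simulate_edna_reads, simulate_yule_tree)


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestYuleTree:
    def test_two_leaves_form_equal_depth_cherry(self):
        tree = simulate_yule_tree(2, seed=1)
        depths = tree.node_depths()
        leaf_depths = [depths[tree._leaf_node[t]] for t in tree.taxa]
        assert leaf_depths[0] == pytest.approx(leaf_depths[1])

    def test_eight_leaves_bifurcating_node_count(self):
        tree = simulate_yule_tree(8, seed=1)
        internal = sum(1 for i in range(tree.n_nodes) if tree.children[i])
        assert internal == 7
        assert tree.n_nodes == 15

    def test_ultrametric(self):
        tree = simulate_yule_tree(20, seed=3)
        depths = tree.node_depths()
        leaf_depths = [depths[tree._leaf_node[t]] for t in tree.taxa]
        assert np.ptp(leaf_depths) < 1e-9

    def test_deterministic_and_labelled(self):
        t1 = simulate_yule_tree(10, seed=5)
        t2 = simulate_yule_tree(10, seed=5)
        assert t1.to_newick() == t2.to_newick()
        assert t1.taxa == [f"sp{k:04d}" for k in range(1, 11)]

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1)

    def test_lineage_growth_matches_pure_birth_expectation(self):
        # starting from the root split (2 lineages), E[N(t)] = 2 e^(lambda t)
        t_probe, lam, n_rep = 1.0, 1.0, 200
        counts = []
        for s in range(n_rep):
            tree = simulate_yule_tree(32, birth_rate=lam, seed=s)
            d = tree.node_depths()
            counts.append(sum(1 for i in range(1, tree.n_nodes)
                              if d[tree.parent[i]] <= t_probe < d[i]))
        mean = np.mean(counts)
        se = np.std(counts) / math.sqrt(n_rep)
        assert abs(mean - 2 * math.exp(lam * t_probe)) < 4 * se + 0.3


class TestJukesCantor:
    def test_zero_rate_keeps_root_sequence(self):
        tree = simulate_yule_tree(6, seed=2)
        seqs = evolve_sequences_jc(tree, 40, subst_rate=0.0, seed=1)
        assert len(set(seqs.values())) == 1

    def test_branch_divergence_matches_closed_form(self):
        # two leaves separated by path t: P(diff) = 3/4 (1 - e^(-4 r t / 3))
        tree = ps.PhyloTree.from_newick("(A:0.5,B:0.5);")
        L, rate = 10_000, 0.3
        seqs = evolve_sequences_jc(tree, L, subst_rate=rate, seed=7)
        p_obs = hamming(seqs["A"], seqs["B"]) / L
        t = 1.0  # path length A-B
        p_exp = 0.75 * (1 - math.exp(-4 * rate * t / 3))
        se = math.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) < 3 * se

    def test_seeded_determinism_and_length_range(self):
        tree = simulate_yule_tree(12, seed=4)
        s1 = evolve_sequences_jc(tree, (29, 96), 0.05, seed=9)
        s2 = evolve_sequences_jc(tree, (29, 96), 0.05, seed=9)
        assert s1 == s2
        assert all(29 <= len(v) <= 96 for v in s1.values())

    def test_negative_rate_rejected(self):
        tree = simulate_yule_tree(4, seed=0)
        with pytest.raises(ValueError):
            evolve_sequences_jc(tree, 10, subst_rate=-0.1)


class TestDerivedTaxonomy:
    def test_cherry_shares_genus(self):
        tree = ps.PhyloTree.from_newick("((A:0.1,B:0.1):0.9,C:1.0);")
        tax = derive_taxonomy_from_tree(tree, (0.25, 0.5, 0.75))
        assert tax.rank_of("A", "genus") == tax.rank_of("B", "genus")
        assert tax.rank_of("A", "genus") != tax.rank_of("C", "genus")

    def test_cuts_above_root_collapse_to_single_groups(self):
        tree = simulate_yule_tree(10, seed=1)
        tax = derive_taxonomy_from_tree(tree, (1.1, 1.2, 1.3))
        for rank in RANKS:
            assert len({tax.rank_of(t, rank) for t in tree.taxa}) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_ranks_are_nested(self, seed):
        tree = simulate_yule_tree(40, seed=seed)
        tax = derive_taxonomy_from_tree(tree)
        genus_of = {}
        family_of = {}
        for t in tree.taxa:
            g, f, o = (tax.rank_of(t, r) for r in RANKS)
            assert genus_of.setdefault(g, f) == f   # same genus -> same family
            assert family_of.setdefault(f, o) == o  # same family -> same order

    def test_non_monotone_cuts_rejected(self):
        tree = simulate_yule_tree(5, seed=0)
        with pytest.raises(ValueError):
            derive_taxonomy_from_tree(tree, (0.5, 0.25, 0.75))


class TestAssemblages:
    def test_full_segregation_separates_all_cherries(self):
        tree = simulate_yule_tree(60, seed=2)
        sites, _ = simulate_assemblages(tree, n_regions=2, sites_per_region=20,
                                        richness=10, segregation_strength=1.0,
                                        seed=3)
        from phyloshot.synthetic_data import _cherry_pairs
        cherries = _cherry_pairs(tree)
        for site in sites:
            members = {tree.taxon_index[s] for s in site.species_ids}
            for a in members:
                assert cherries.get(a) not in members

    def test_no_segregation_matches_random_null(self):
        # sister co-region frequency ~ 1/n_regions when segregation is off
        from phyloshot.synthetic_data import _cherry_pairs
        n_regions = 4
        together, total = 0, 0
        for seed in range(30):
            tree = simulate_yule_tree(60, seed=seed)
            _, grid = simulate_assemblages(tree, n_regions=n_regions,
                                           sites_per_region=1, richness=5,
                                           segregation_strength=0.0, seed=seed)
            region = {sp: next(iter(cells))[0] for sp, cells in grid.cells.items()}
            seen = set()
            for a, b in _cherry_pairs(tree).items():
                if (b, a) in seen:
                    continue
                seen.add((a, b))
                together += region[tree.taxa[a]] == region[tree.taxa[b]]
                total += 1
        freq = together / total
        se = math.sqrt((1 / n_regions) * (1 - 1 / n_regions) / total)
        assert abs(freq - 1 / n_regions) < 4 * se

    def test_site_sizes_and_uniqueness(self):
        tree = simulate_yule_tree(50, seed=5)
        sites, grid = simulate_assemblages(tree, n_regions=2, sites_per_region=5,
                                           richness=8, seed=1)
        assert len(sites) == 10
        for site in sites:
            assert site.size == 8
            assert len(set(site.species_ids)) == 8
        assert set(grid.cells) == set(tree.taxa)

    def test_infeasible_richness_rejected(self):
        tree = simulate_yule_tree(10, seed=0)
        with pytest.raises(ValueError, match="richness"):
            simulate_assemblages(tree, n_regions=2, sites_per_region=1,
                                 richness=9, seed=0)


class TestEdnaReads:
    def test_error_free_reads_equal_source(self):
        seqs = {"spX": "ACGTACGTAC"}
        reads, truth = simulate_edna_reads(["spX"], seqs, reads_per_species=10,
                                           error_rate=0.0, seed=1)
        assert all(seq == "ACGTACGTAC" for _, seq, _ in reads)
        assert set(truth.values()) == {"spX"}

    def test_read_count_conservation(self):
        seqs = {f"s{i}": "ACGT" * 10 for i in range(5)}
        reads, truth = simulate_edna_reads(list(seqs), seqs, 50, 0.02, seed=2)
        assert len(reads) == len(truth)
        assert all(n == 1 for _, _, n in reads)

    def test_error_rate_matches_binomial_expectation(self):
        L = 80
        seqs = {"spX": "A" * L}
        reads, _ = simulate_edna_reads(["spX"], seqs, reads_per_species=10_000,
                                       error_rate=0.01, seed=3)
        dists = [hamming(seq, "A" * L) for _, seq, _ in reads]
        mean = np.mean(dists)
        se = np.std(dists) / math.sqrt(len(dists))
        assert abs(mean - 0.01 * L) < 4 * se + 0.05

    def test_invalid_error_rate(self):
        with pytest.raises(ValueError):
            simulate_edna_reads(["s"], {"s": "ACGT"}, 5, error_rate=1.0)

    def test_missing_sequence_rejected(self):
        with pytest.raises(ValueError, match="without sequences"):
            simulate_edna_reads(["sZ"], {"s": "ACGT"}, 5, 0.0)


class TestWorld:
    def test_world_is_deterministic_from_master_seed(self):
        kw = dict(n_species=40, gap_fraction=0.25, segregation=0.8, seed=13,
                  n_regions=2, sites_per_region=4, richness=6)
        w1, w2 = make_world(**kw), make_world(**kw)
        assert w1.tree.to_newick() == w2.tree.to_newick()
        assert w1.sequences == w2.sequences
        assert w1.records == w2.records
        assert w1.sites == w2.sites
        assert w1.gap_species == w2.gap_species
        assert w1.grid.cells == w2.grid.cells

    def test_gap_fraction_respected(self):
        world = make_world(n_species=40, gap_fraction=0.25, seed=3,
                           n_regions=2, sites_per_region=2, richness=6)
        assert len(world.gap_species) == 10
        assert not set(world.gap_species) & set(world.referenced_species)
        assert len(world.referenced_species) == 30

    def test_world_files_roundtrip(self, tmp_path):
        world = make_world(n_species=30, gap_fraction=0.2, seed=4,
                           n_regions=2, sites_per_region=2, richness=5)
        world.write(tmp_path)
        tree = ps.load_tree(tmp_path / "tree.nwk")
        assert tree.taxa == world.tree.taxa
        records, tax = ps.load_reference(tmp_path / "ref.fasta",
                                         tmp_path / "tax.tsv")
        assert len(records) == len(world.records)
        sites = ps.load_assemblages(tmp_path / "sites.tsv")
        assert len(sites) == len(world.sites)
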