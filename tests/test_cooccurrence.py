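import math

import numpy as np
import pytest

import phyloshot as ps
from phyloshot.cooccurrence import (CooccurrenceModel, CoocTrainConfig, NoiseConfig,
                                    calibrate_noise_sigma, grid_to_cooccurrence,
                                    modulate, modulate_matrix, site_initial_probs,
                                    site_nll, train_cooccurrence)
from phyloshot.data_io import OccurrenceGrid, SiteAssemblage, reference_index
from phyloshot.kernel_classifier import ProbabilityVector


def scalar_modulate(p_i, others, U, V):
    """Independent loop-based oracle for the modulation arithmetic."""
    n, m = len(U), len(U[0])
    q = [sum(o[k] for o in others) / len(others) for k in range(n)]
    z = []
    for k in range(n):
        acc = math.log(max(p_i[k], 1e-30))
        for j in range(m):
            vq = sum(V[l][j] * q[l] for l in range(n))
            acc += U[k][j] * vq
        z.append(acc)
    zmax = max(z)
    e = [math.exp(v - zmax) for v in z]
    s = sum(e)
    return [v / s for v in e]


class TestModulate:
    def test_zero_coupling_is_identity(self, rng):
        n = 8
        p = rng.random(n)
        p /= p.sum()
        model = CooccurrenceModel([f"s{i}" for i in range(n)],
                                  np.zeros((n, 4)), rng.standard_normal((n, 4)))
        pv = ProbabilityVector(model.species_ids, p)
        others = [ProbabilityVector(model.species_ids, np.full(n, 1 / n))]
        out = modulate(pv, others, model)
        np.testing.assert_allclose(out.probabilities, p, atol=1e-12)

    def test_no_others_passes_through(self, rng):
        n = 5
        p = rng.random(n)
        p /= p.sum()
        model = CooccurrenceModel([f"s{i}" for i in range(n)],
                                  rng.standard_normal((n, 3)),
                                  rng.standard_normal((n, 3)))
        pv = ProbabilityVector(model.species_ids, p)
        assert modulate(pv, [], model) is pv

    def test_matches_scalar_oracle(self, rng):
        n, m = 3, 2
        U = rng.standard_normal((n, m))
        V = rng.standard_normal((n, m))
        model = CooccurrenceModel(["a", "b", "c"], U, V)
        p = np.array([0.6, 0.3, 0.1])
        o1 = np.array([0.0 + 1e-12, 1.0 - 2e-12, 1e-12])
        o1 /= o1.sum()
        out = modulate(ProbabilityVector(model.species_ids, p),
                       [ProbabilityVector(model.species_ids, o1)], model)
        expected = scalar_modulate(p, [o1], U.tolist(), V.tolist())
        np.testing.assert_allclose(out.probabilities, expected, atol=1e-10)

    def test_matrix_variant_preserves_normalization(self, rng):
        n = 20
        P = rng.random((6, n))
        P /= P.sum(axis=1, keepdims=True)
        model = CooccurrenceModel([f"s{i}" for i in range(n)],
                                  rng.standard_normal((n, 5)),
                                  rng.standard_normal((n, 5)))
        out = modulate_matrix(P, model)
        np.testing.assert_allclose(out.sum(axis=1), np.ones(6), atol=1e-9)
        assert np.all(out >= 0)

    def test_vector_length_mismatch_rejected(self, rng):
        model = CooccurrenceModel(["a", "b"], np.zeros((2, 2)), np.zeros((2, 2)))
        p3 = ProbabilityVector(["a", "b", "c"], np.full(3, 1 / 3))
        with pytest.raises(ValueError):
            modulate(p3, [p3], model)


class TestSiteNll:
    def test_one_hot_correct_gives_zero(self):
        P = np.eye(4)
        assert site_nll(P, [0, 1, 2, 3]) == pytest.approx(0.0)

    def test_uniform_over_100_species_gives_log_100(self):
        P = np.full((3, 100), 0.01)
        assert site_nll(P, [5, 50, 99]) == pytest.approx(math.log(100))

    def test_two_member_arithmetic(self):
        P = np.array([[0.5, 0.5], [0.75, 0.25]])
        expected = -(math.log(0.5) + math.log(0.25)) / 2
        assert site_nll(P, [0, 1]) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(1.0397, abs=1e-4)

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            site_nll(np.full((1, 4), 0.25), [4])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            site_nll(np.full((2, 4), 0.25), [0])


class TestGridToCooccurrence:
    def test_shared_cell_means_cooccurrence(self):
        grid = OccurrenceGrid({"A": {(0, 0)}, "B": {(0, 0)}})
        sites = grid_to_cooccurrence(grid)
        assert len(sites) == 1
        assert sites[0].species_ids == ("A", "B")

    def test_disjoint_cells_give_singletons(self):
        grid = OccurrenceGrid({"A": {(0, 0)}, "B": {(5, 5)}})
        sites = grid_to_cooccurrence(grid)
        assert sorted(s.species_ids for s in sites) == [("A",), ("B",)]

    def test_multi_cell_enumeration(self):
        grid = OccurrenceGrid({"A": {(0, 0), (0, 1)}, "B": {(0, 1)}, "C": {(0, 1)}})
        sites = grid_to_cooccurrence(grid)
        assert [s.species_ids for s in sites] == [("A",), ("A", "B", "C")]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_to_cooccurrence(OccurrenceGrid())


class TestSiteInitialProbs:
    def test_own_embedding_argmax_without_noise(self, small_world, small_models):
        emb = small_models["embeddings"]
        site = SiteAssemblage("s", tuple(small_world.tree.taxa[:3]))
        # no reference sequences available -> pure embeddings, sigma 0
        probs = site_initial_probs(site, emb, None, {},
                                   NoiseConfig(sigma=0.0, seed=0))
        for sp, p in zip(site.species_ids, probs):
            assert p.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
            assert p.species_ids[int(np.argmax(p.probabilities))] == sp

    def test_species_without_embedding_rejected(self, small_models):
        emb = small_models["embeddings"]
        site = SiteAssemblage("s", ("nonexistent_sp",))
        with pytest.raises(ValueError, match="without embeddings"):
            site_initial_probs(site, emb, None, {})

    def test_noisy_embeddings_often_hit_near_relatives(self, small_world, small_models):
        # with noise near the holdout mapping error, the argmax is frequently
        # a relative (same genus) rather than the species itself
        emb = small_models["embeddings"]
        world = small_world
        site = SiteAssemblage("s", tuple(world.tree.taxa))
        probs = site_initial_probs(site, emb, None, {},
                                   NoiseConfig(sigma=0.25, seed=1))
        wrong_but_same_genus = 0
        wrong = 0
        for sp, p in zip(site.species_ids, probs):
            pred = p.species_ids[int(np.argmax(p.probabilities))]
            if pred != sp:
                wrong += 1
                if (world.taxonomy.rank_of(pred, "genus")
                        == world.taxonomy.rank_of(sp, "genus")):
                    wrong_but_same_genus += 1
        assert wrong > 0
        assert wrong_but_same_genus / wrong > 0.5


class TestTrainCooccurrence:
    def test_zero_init_first_epoch_matches_unmodulated_nll(self, small_world, small_models):
        world, emb, dna = small_world, small_models["embeddings"], small_models["dna"]
        ref = reference_index(world.records)
        noise = NoiseConfig(sigma=0.1, seed=3)
        # lr = 0 freezes U at its zero init: every visit sees the raw NLL
        model, trace = train_cooccurrence(
            world.sites, emb, dna, ref,
            CoocTrainConfig(rank=8, learning_rate=0.0, epochs=2, seed=3), noise)
        assert trace[0] == pytest.approx(trace[1], abs=1e-12)
        assert np.all(model.U == 0)

    def test_training_reduces_nll_and_is_reproducible(self, small_world, small_models):
        world, emb, dna = small_world, small_models["embeddings"], small_models["dna"]
        ref = reference_index(world.records)
        cfg = CoocTrainConfig(rank=16, epochs=4, seed=5)
        m1, tr1 = train_cooccurrence(world.sites, emb, dna, ref, cfg,
                                     NoiseConfig(sigma=0.1, seed=5))
        m2, tr2 = train_cooccurrence(world.sites, emb, dna, ref, cfg,
                                     NoiseConfig(sigma=0.1, seed=5))
        assert tr1[-1] < tr1[0]
        assert tr1 == tr2
        np.testing.assert_array_equal(m1.U, m2.U)

    def test_degenerate_sites_skipped_then_error(self, small_models, caplog):
        emb = small_models["embeddings"]
        taxa = emb.species_ids
        singles = [SiteAssemblage(f"s{i}", (taxa[i],)) for i in range(3)]
        with pytest.raises(ValueError, match="degenerate"):
            train_cooccurrence(singles, emb, None, {},
                               CoocTrainConfig(rank=4, epochs=1))
        mixed = singles + [SiteAssemblage("ok", tuple(taxa[:3]))]
        with caplog.at_level("WARNING"):
            train_cooccurrence(mixed, emb, None, {},
                               CoocTrainConfig(rank=4, epochs=1),
                               NoiseConfig(sigma=0.1, seed=0))
        assert any("degenerate" in m for m in caplog.messages)


def test_calibrate_noise_sigma_hits_target(small_models):
    emb = small_models["embeddings"]
    target = 0.15
    sigma = calibrate_noise_sigma(emb, target, seed=2)
    rng = np.random.default_rng(9)
    noisy = emb.vectors + sigma * rng.standard_normal(emb.vectors.shape)
    num = np.einsum("ij,ij->i", emb.vectors, noisy)
    den = (np.linalg.norm(emb.vectors, axis=1) * np.linalg.norm(noisy, axis=1))
    med = np.median(1 - num / den)
    assert med == pytest.approx(target, abs=0.05)


def test_cooc_model_save_load_roundtrip(tmp_path, rng):
    model = CooccurrenceModel(["a", "b"], rng.standard_normal((2, 3)),
                              rng.standard_normal((2, 3)))
    p = tmp_path / "cooc.npz"
    model.save(p)
    back = CooccurrenceModel.load(p)
    assert back.species_ids == model.species_ids
    np.testing.assert_array_equal(back.U, model.U)
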