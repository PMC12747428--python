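"""Species embeddings learned from a phylogeny.

Each species in the tree receives a fixed-dimensional vector, optimized
directly (no network) so that the cosine distance between any two vectors
matches the normalized patristic distance between the species.  Training
pairs are drawn by a branching-point contrast scheme: for a focal species,
one species is sampled at random from the sibling subtree at every branching
on the root-to-leaf path, so the contrast set spans all levels of
relatedness.

The per-focal loss is

    L(i, S_i) = sum_{j in S_i} (d_tree(i, j) - d_cos(e_i, e_j))^2

with d_cos(x, y) = 1 - x.y / (|x||y|).  Optimization uses AdamW with a
constant learning rate; a batch is ``batch_size`` focal species, each with a
freshly sampled contrast set, and one optimizer step is taken per batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._optim import AdamW
from .data_io import PhyloTree

logger = logging.getLogger(__name__)


@dataclass
class EmbedConfig:
    """Hyperparameters of the tree-embedding optimization.

    ``distance_normalization`` selects how patristic distances are mapped
    into the range of the cosine distance: ``max_pairwise`` divides by the
    maximum pairwise distance (targets in [0, 1], the non-antipodal
    half-space); ``tree_diameter_x2`` scales the maximum to 2 instead.
    """

    embed_dim: int = 64
    epochs: int = 100
    learning_rate: float = 0.01
    batch_size: int = 64
    seed: int = 0
    distance_normalization: str = "max_pairwise"

    def __post_init__(self):
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.distance_normalization not in ("max_pairwise", "tree_diameter_x2"):
            raise ValueError(f"unknown normalization {self.distance_normalization!r}")


@dataclass
class EmbeddingTable:
    """One vector per species, rows aligned with ``species_ids``."""

    species_ids: list[str]
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.species_ids):
            raise ValueError("vectors must be (n_species, embed_dim)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding vectors")
        self.index = {s: i for i, s in enumerate(self.species_ids)}
        if len(self.index) != len(self.species_ids):
            raise ValueError("duplicate species ids in embedding table")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, species_id: str) -> np.ndarray:
        return self.vectors[self.index[species_id]]

    def to_tsv(self, path: str | Path, config: EmbedConfig | None = None,
               final_loss: float | None = None) -> None:
        cols = [f"v{k + 1}" for k in range(self.dim)]
        df = pd.DataFrame(self.vectors, columns=cols)
        df.insert(0, "species_id", self.species_ids)
        df.to_csv(path, sep="\t", index=False)
        if config is not None:
            sidecar = Path(str(path) + ".json")
            sidecar.write_text(json.dumps(
                {"config": asdict(config), "final_loss": final_loss}, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EmbeddingTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df["species_id"].tolist(),
                   df.drop(columns="species_id").to_numpy(float))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def patristic_distances(tree: PhyloTree) -> np.ndarray:
    """Symmetric matrix of branch-length path sums, in ``tree.taxa`` order."""
    return tree.patristic_matrix()


def normalize_distances(D: np.ndarray, mode: str = "max_pairwise") -> np.ndarray:
    """Scale a patristic distance matrix onto the cosine-distance range.

    Order of entries is preserved (the map is a positive rescaling).
    """
    D = np.asarray(D, dtype=np.float64)
    dmax = D.max() if D.size else 0.0
    if dmax <= 0:
        raise ValueError("cannot normalize an all-zero distance matrix "
                         "(single species, or identical leaves only)")
    if mode == "max_pairwise":
        return D / dmax
    if mode == "tree_diameter_x2":
        return 2.0 * D / dmax
    raise ValueError(f"unknown normalization mode {mode!r}")


def cosine_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 minus cosine similarity; range [0, 2]."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - float(x @ y) / (nx * ny))


def tree_embedding_loss(focal_vec: np.ndarray,
                        contrast_vecs: Sequence[np.ndarray],
                        normalized_dists: Sequence[float]) -> float:
    """Sum of squared gaps between target and realized cosine distances."""
    if len(contrast_vecs) != len(normalized_dists):
        raise ValueError("contrast_vecs and normalized_dists length mismatch")
    if len(contrast_vecs) < 1:
        raise ValueError("need at least one contrast species")
    return float(sum(
        (t - cosine_distance(focal_vec, v)) ** 2
        for v, t in zip(contrast_vecs, normalized_dists)))


# ---------------------------------------------------------------------------
# Contrast sampling
# ---------------------------------------------------------------------------

def sample_contrast_set(tree: PhyloTree, focal: str,
                        rng: np.random.Generator) -> list[str]:
    """Sample one species from the sibling subtree at every branching on the
    root-to-``focal`` path.

    Size equals the number of branchings on that path; a single-leaf tree
    yields the empty set.  At a polytomy the sample is drawn from the union
    of all non-focal child subtrees.
    """
    out: list[str] = []
    for sibs in tree.sibling_leaf_sets(focal):
        out.append(tree.taxa[sibs[rng.integers(len(sibs))]])
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _pair_loss_and_grad(E: np.ndarray, I: np.ndarray, J: np.ndarray,
                        T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair squared losses and dense gradient of their sum w.r.t. E."""
    X = E[I]
    Y = E[J]
    nx = np.linalg.norm(X, axis=1)
    ny = np.linalg.norm(Y, axis=1)
    dot = np.einsum("ij,ij->i", X, Y)
    s = dot / (nx * ny)
    d = 1.0 - s
    r = d - T
    losses = r ** 2
    # d d_cos/dx = s x / |x|^2 - y / (|x||y|); chain with dL/dd = 2 r
    coef = 2.0 * r
    gX = coef[:, None] * (s / nx ** 2)[:, None] * X - coef[:, None] * Y / (nx * ny)[:, None]
    gY = coef[:, None] * (s / ny ** 2)[:, None] * Y - coef[:, None] * X / (nx * ny)[:, None]
    grad = np.zeros_like(E)
    np.add.at(grad, I, gX)
    np.add.at(grad, J, gY)
    return losses, grad


def train_species_embeddings(
    tree: PhyloTree, config: EmbedConfig
) -> tuple[EmbeddingTable, list[float]]:
    """Directly optimize one vector per leaf against normalized tree distances.

    Returns the table plus the per-epoch mean of the per-focal losses.  An
    epoch is a full randomized pass over all species; each focal contributes
    a freshly sampled contrast set, and one AdamW step is taken per batch of
    ``batch_size`` focal species.
    """
    n = tree.n_leaves
    if n < 2:
        raise ValueError("need at least 2 leaves to train embeddings")
    rng = np.random.default_rng(config.seed)
    Dn = normalize_distances(patristic_distances(tree), config.distance_normalization)

    # init: unit-norm Gaussian rows
    E = rng.standard_normal((n, config.embed_dim))
    E /= np.linalg.norm(E, axis=1, keepdims=True)

    # precompute sibling leaf sets once per focal
    contrasts = [tree.sibling_leaf_sets(t) for t in tree.taxa]

    opt = AdamW({"E": E}, lr=config.learning_rate)
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        focal_losses = np.zeros(n)
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            I_list, J_list = [], []
            for i in batch:
                for sibs in contrasts[i]:
                    I_list.append(i)
                    J_list.append(sibs[rng.integers(len(sibs))])
            if not I_list:
                continue
            I = np.asarray(I_list)
            J = np.asarray(J_list)
            T = Dn[I, J]
            losses, grad = _pair_loss_and_grad(E, I, J, T)
            if not np.all(np.isfinite(losses)):
                raise FloatingPointError("non-finite embedding loss; "
                                         "lower the learning rate")
            np.add.at(focal_losses, I, losses)
            opt.step({"E": grad})
        trace.append(float(focal_losses.mean()))
    return EmbeddingTable(list(tree.taxa), E.copy()), trace
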