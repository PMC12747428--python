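"""Temperature-kernel conversion of embedded sequences into species
probabilities.

The kernel k(x, y; tau) = exp(-d_cos(x, y) / tau) with tau = 0.05 turns the
cosine distance from a query vector to every species embedding into an
unnormalized similarity; normalizing over all species yields a probability
vector (soft nearest-neighbour aggregation).  All computation happens in
log space with max-subtraction: at tau = 0.05 the raw kernel underflows for
cosine distances beyond about 1.7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo_embedding import EmbeddingTable, cosine_distance


@dataclass(frozen=True)
class KernelConfig:
    temperature: float = 0.05

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass
class ProbabilityVector:
    """Probabilities over species, aligned with an embedding table's order."""

    species_ids: list[str]
    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.ndim != 1 or p.shape[0] != len(self.species_ids):
            raise ValueError("probabilities must be 1-D, one entry per species")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        self.probabilities = p

    def __len__(self) -> int:
        return len(self.species_ids)


def kernel_similarity(x: np.ndarray, y: np.ndarray, tau: float) -> float:
    """exp(-d_cos(x, y) / tau); 1 iff the vectors are parallel."""
    if tau <= 0:
        raise ValueError("temperature must be > 0")
    return float(np.exp(-cosine_distance(x, y) / tau))


def _cosine_distances_to_table(query: np.ndarray, table: EmbeddingTable) -> np.ndarray:
    q = np.asarray(query, float)
    nq = np.linalg.norm(q)
    if nq == 0:
        raise ValueError("zero query vector")
    norms = np.linalg.norm(table.vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("embedding table contains a zero vector")
    return 1.0 - (table.vectors @ q) / (norms * nq)


def species_probabilities(
    query_vec: np.ndarray, embeddings: EmbeddingTable,
    config: KernelConfig = KernelConfig(),
) -> ProbabilityVector:
    """Normalized kernel similarities from a query to every species."""
    if len(embeddings.species_ids) == 0:
        raise ValueError("empty embedding table")
    logk = -_cosine_distances_to_table(query_vec, embeddings) / config.temperature
    logk -= logk.max()
    p = np.exp(logk)
    p /= p.sum()
    return ProbabilityVector(embeddings.species_ids, p)


def probability_matrix(
    queries: np.ndarray, embeddings: EmbeddingTable,
    config: KernelConfig = KernelConfig(),
) -> np.ndarray:
    """Row-wise :func:`species_probabilities` for a (B, dim) query stack."""
    Q = np.asarray(queries, float)
    nq = np.linalg.norm(Q, axis=1, keepdims=True)
    if np.any(nq == 0):
        raise ValueError("zero query vector")
    norms = np.linalg.norm(embeddings.vectors, axis=1)
    D = 1.0 - (Q / nq) @ (embeddings.vectors / norms[:, None]).T
    logk = -D / config.temperature
    logk -= logk.max(axis=1, keepdims=True)
    P = np.exp(logk)
    P /= P.sum(axis=1, keepdims=True)
    return P


def top1_prediction(p: ProbabilityVector) -> str:
    """Highest-probability species; exact ties break to the lexicographically
    smallest species id."""
    best = p.probabilities.max()
    ties = [p.species_ids[i] for i in np.flatnonzero(p.probabilities == best)]
    return min(ties)
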