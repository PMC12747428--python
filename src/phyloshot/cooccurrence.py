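"""Low-rank co-occurrence modulation of species probability vectors.

Ecological rationale: because speciation is mostly geographic, close
relatives tend not to co-occur, so a local assemblage usually contains one
representative per lineage.  A sequence whose DNA-based probabilities are
split between a few near-indistinguishable relatives can therefore be
disambiguated by the other species detected at the same site.

For an item i at a site with M members, the modulated vector is

    p_co_i = softmax( log p_i + U V^T * mean_{l != i} p_l )

with U, V in R^(n_species x m) learned by minimizing the mean negative
log-likelihood of the true species over the items of a site; one optimizer
step is taken per site visit (batches are sites, of naturally varying size).

During training the site members' initial probability vectors come from the
DNA encoder when the species has a usable reference sequence, and otherwise
from its species embedding perturbed with isotropic Gaussian noise sized to
mimic the encoder's zero-shot mapping error.  Sites with a single member are
skipped: the leave-one-out mean is undefined there, and at inference such
items pass through unmodulated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._optim import AdamW
from .data_io import OccurrenceGrid, ReferenceRecord, SiteAssemblage
from .dna_encoder import DnaEncoderModel, encode_batch
from .kernel_classifier import KernelConfig, ProbabilityVector, probability_matrix
from .phylo_embedding import EmbeddingTable, cosine_distance

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-30


@dataclass
class CooccurrenceModel:
    """Learnable low-rank modulation matrices, rows aligned with species."""

    species_ids: list[str]
    U: np.ndarray
    V: np.ndarray

    def __post_init__(self):
        self.U = np.asarray(self.U, float)
        self.V = np.asarray(self.V, float)
        n = len(self.species_ids)
        if self.U.shape != self.V.shape or self.U.shape[0] != n:
            raise ValueError("U and V must both be (n_species, m)")
        if not (np.all(np.isfinite(self.U)) and np.all(np.isfinite(self.V))):
            raise ValueError("non-finite co-occurrence parameters")

    @property
    def rank(self) -> int:
        return self.U.shape[1]

    def save(self, path: str | Path) -> None:
        np.savez(path, U=self.U, V=self.V,
                 species=np.array(self.species_ids, dtype=object).astype(str))

    @classmethod
    def load(cls, path: str | Path) -> "CooccurrenceModel":
        with np.load(path, allow_pickle=False) as z:
            return cls(list(z["species"]), z["U"], z["V"])


@dataclass
class NoiseConfig:
    """Isotropic Gaussian noise applied to embeddings of sequence-less species.

    ``sigma`` is the per-coordinate standard deviation; ``discard_unsequenced``
    drops such species from site contexts entirely instead.
    """

    sigma: float = 0.1
    seed: int = 0
    discard_unsequenced: bool = False

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class CoocTrainConfig:
    rank: int = 256
    learning_rate: float = 0.001
    epochs: int = 10
    seed: int = 0


def calibrate_noise_sigma(
    embeddings: EmbeddingTable, target_median_dcos: float,
    seed: int = 0, n_draws: int = 200,
) -> float:
    """Bisect sigma so the median cosine perturbation of noisy embeddings
    matches a target (typically the encoder's median zero-shot mapping error)."""
    if target_median_dcos <= 0:
        return 0.0
    rng = np.random.default_rng(seed)
    n = len(embeddings.species_ids)
    take = rng.choice(n, size=min(n, n_draws), replace=False)
    base = embeddings.vectors[take]

    def median_dcos(sigma: float) -> float:
        noisy = base + sigma * rng.standard_normal(base.shape)
        num = np.einsum("ij,ij->i", base, noisy)
        den = np.linalg.norm(base, axis=1) * np.linalg.norm(noisy, axis=1)
        return float(np.median(1.0 - num / den))

    lo, hi = 0.0, 1.0
    while median_dcos(hi) < target_median_dcos and hi < 64:
        hi *= 2
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if median_dcos(mid) < target_median_dcos:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Site probability vectors
# ---------------------------------------------------------------------------

def _site_prob_matrix(
    site: SiteAssemblage,
    embeddings: EmbeddingTable,
    dna_model: Optional[DnaEncoderModel],
    reference_index: dict[str, list[ReferenceRecord]],
    noise_cfg: NoiseConfig,
    kernel_cfg: KernelConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Initial probability vectors for every site member; returns (P, y).

    P is (M, n_species); y holds each member's own index in species order.
    """
    missing = [s for s in site.species_ids if s not in embeddings.index]
    if missing:
        raise ValueError(f"site {site.site_id}: species without embeddings: {missing}")
    queries = []
    kept = []
    for sp in site.species_ids:
        recs = reference_index.get(sp)
        if recs and dna_model is not None:
            rec = recs[int(rng.integers(len(recs)))]
            queries.append(("seq", rec.sequence))
            kept.append(sp)
        elif noise_cfg.discard_unsequenced:
            continue
        else:
            vec = embeddings.vector(sp) + noise_cfg.sigma * rng.standard_normal(embeddings.dim)
            queries.append(("vec", vec))
            kept.append(sp)
    seqs = [q for kind, q in queries if kind == "seq"]
    if seqs and dna_model is not None:
        mapped = encode_batch(dna_model, seqs)
    vecs = np.empty((len(queries), embeddings.dim))
    si = 0
    for row, (kind, q) in enumerate(queries):
        if kind == "seq":
            vecs[row] = mapped[si]
            si += 1
        else:
            vecs[row] = q
    P = probability_matrix(vecs, embeddings, kernel_cfg)
    y = np.array([embeddings.index[sp] for sp in kept], dtype=np.int64)
    return P, y


def site_initial_probs(
    site: SiteAssemblage,
    embeddings: EmbeddingTable,
    dna_model: Optional[DnaEncoderModel],
    reference_index: dict[str, list[ReferenceRecord]],
    noise_cfg: NoiseConfig = NoiseConfig(),
    kernel_cfg: KernelConfig = KernelConfig(),
    rng: Optional[np.random.Generator] = None,
) -> list[ProbabilityVector]:
    """Per-member initial probability vectors for one site.

    Species with at least one reference sequence are represented by the DNA
    model's mapping of one sequence (seeded uniform choice among its
    records); species without sequences by their embedding plus Gaussian
    noise (or dropped, if so configured).
    """
    if rng is None:
        rng = np.random.default_rng(noise_cfg.seed)
    P, _ = _site_prob_matrix(site, embeddings, dna_model, reference_index,
                             noise_cfg, kernel_cfg, rng)
    return [ProbabilityVector(embeddings.species_ids, row) for row in P]


# ---------------------------------------------------------------------------
# Modulation
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def modulate_matrix(P: np.ndarray, model: CooccurrenceModel) -> np.ndarray:
    """Jointly modulate every row of a site's (M, n) probability matrix using
    the leave-one-out mean of the other rows; M == 1 passes through."""
    M = P.shape[0]
    if M == 1:
        return P.copy()
    total = P.sum(axis=0)
    Q = (total[None, :] - P) / (M - 1)        # leave-one-out means
    Z = np.log(np.maximum(P, PROB_FLOOR)) + (Q @ model.V) @ model.U.T
    return _softmax(Z)


def modulate(p_i: ProbabilityVector, others: Sequence[ProbabilityVector],
             model: CooccurrenceModel) -> ProbabilityVector:
    """Reshape one item's probabilities using the other items at its site.

    With no co-detected items the input is returned unchanged (the
    leave-one-out mean is undefined for a singleton site).
    """
    if len(others) == 0:
        return p_i
    n = len(model.species_ids)
    if len(p_i) != n or any(len(o) != n for o in others):
        raise ValueError("probability vectors do not match model species count")
    q = np.mean([o.probabilities for o in others], axis=0)
    z = np.log(np.maximum(p_i.probabilities, PROB_FLOOR)) + model.U @ (model.V.T @ q)
    return ProbabilityVector(p_i.species_ids, _softmax(z))


def site_nll(modulated: Sequence[ProbabilityVector] | np.ndarray,
             truth_indices: Sequence[int]) -> float:
    """Mean negative log-likelihood of the true species across a site."""
    if isinstance(modulated, np.ndarray):
        P = modulated
    else:
        P = np.stack([m.probabilities for m in modulated])
    y = np.asarray(truth_indices, dtype=np.int64)
    if P.shape[0] != y.shape[0]:
        raise ValueError("one truth index per modulated vector required")
    if np.any(y < 0) or np.any(y >= P.shape[1]):
        raise IndexError("truth index out of range")
    return float(-np.mean(np.log(np.maximum(P[np.arange(len(y)), y], PROB_FLOOR))))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_cooccurrence(
    sites: Sequence[SiteAssemblage],
    embeddings: EmbeddingTable,
    dna_model: Optional[DnaEncoderModel],
    reference_index: dict[str, list[ReferenceRecord]],
    cfg: CoocTrainConfig = CoocTrainConfig(),
    noise_cfg: NoiseConfig = NoiseConfig(),
    kernel_cfg: KernelConfig = KernelConfig(),
) -> tuple[CooccurrenceModel, list[float]]:
    """Fit U and V over seeded random passes through the sites.

    U starts at zero (so the first step sees exactly the unmodulated NLL)
    and V at small Gaussian values.  Sites with fewer than two usable
    members are skipped with a warning.
    """
    if not sites:
        raise ValueError("no sites provided")
    rng = np.random.default_rng(cfg.seed)
    prepared: list[tuple[np.ndarray, np.ndarray]] = []
    skipped = 0
    for site in sites:
        P, y = _site_prob_matrix(site, embeddings, dna_model, reference_index,
                                 noise_cfg, kernel_cfg, rng)
        if len(y) < 2:
            skipped += 1
            continue
        prepared.append((P, y))
    if skipped:
        logger.warning("skipped %d degenerate sites (M < 2)", skipped)
    if not prepared:
        raise ValueError("all sites degenerate (M < 2); nothing to train on")

    n = len(embeddings.species_ids)
    U = np.zeros((n, cfg.rank))
    V = 0.01 * rng.standard_normal((n, cfg.rank))
    opt = AdamW({"U": U, "V": V}, lr=cfg.learning_rate)
    trace: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(len(prepared))
        epoch_loss = 0.0
        for si in order:
            P, y = prepared[si]
            M = P.shape[0]
            total = P.sum(axis=0)
            Q = (total[None, :] - P) / (M - 1)
            A = Q @ V                                   # (M, m)
            Z = np.log(np.maximum(P, PROB_FLOOR)) + A @ U.T
            S = _softmax(Z)
            epoch_loss += site_nll(S, y)
            G = S.copy()
            G[np.arange(M), y] -= 1.0
            G /= M                                      # dNLL/dZ
            gU = G.T @ A
            gV = Q.T @ (G @ U)
            opt.step({"U": gU, "V": gV})
        trace.append(epoch_loss / len(prepared))
    return CooccurrenceModel(list(embeddings.species_ids), U.copy(), V.copy()), trace


# ---------------------------------------------------------------------------
# Range-grid co-occurrence
# ---------------------------------------------------------------------------

def grid_to_cooccurrence(grid: OccurrenceGrid) -> list[SiteAssemblage]:
    """Treat every occupied 1-degree cell as a site whose members are all
    species present in that cell; singleton cells are retained here and
    filtered at training time."""
    if not grid.cells:
        raise ValueError("empty occurrence grid")
    by_cell: dict[tuple[int, int], list[str]] = {}
    for sp, cells in grid.cells.items():
        for cell in cells:
            by_cell.setdefault(cell, []).append(sp)
    sites = []
    for (r, c) in sorted(by_cell):
        sites.append(SiteAssemblage(f"cell_{r}_{c}", tuple(sorted(by_cell[(r, c)]))))
    return sites
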