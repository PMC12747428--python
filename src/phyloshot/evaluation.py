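"""Validation protocol: zero-shot holdout splits, per-species macro-averaged
rank accuracies, probability calibration, and agreement against an external
annotation pipeline.

Accuracy bookkeeping follows a two-stage average: predictions are first
averaged per species (over all known sequences of that species), then those
per-species scores are averaged, unweighted, over species.  A prediction is
correct at a rank if the predicted species carries the same value of that
rank as the true species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cooccurrence import (CooccurrenceModel, CoocTrainConfig, NoiseConfig,
                           PROB_FLOOR, calibrate_noise_sigma, grid_to_cooccurrence,
                           train_cooccurrence)
from .data_io import RANKS, TaxonomyTable, reference_index
from .dna_encoder import DnaEncoderModel, DnaTrainConfig, encode_batch, train_dna_encoder
from .kernel_classifier import KernelConfig, probability_matrix
from .phylo_embedding import (EmbedConfig, EmbeddingTable, normalize_distances,
                              patristic_distances, train_species_embeddings)

logger = logging.getLogger(__name__)

RANK_ORDER = ("species",) + RANKS  # species, genus, family, order


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def zero_shot_split(species: Sequence[str], n_holdout: int,
                    seed: int = 0) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive, seeded train/holdout split of a species list."""
    if n_holdout >= len(species):
        raise ValueError("n_holdout must be smaller than the species list")
    rng = np.random.default_rng(seed)
    held = set(rng.choice(len(species), size=n_holdout, replace=False).tolist())
    train = [s for i, s in enumerate(species) if i not in held]
    holdout = [s for i, s in enumerate(species) if i in held]
    return train, holdout


# ---------------------------------------------------------------------------
# Rank accuracies
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Macro-averaged accuracies at each rank plus the per-species table."""

    accuracy: dict[str, float]
    per_species: pd.DataFrame
    n_species_evaluated: int


def rank_accuracy(
    predictions: Iterable[tuple[str, str, str]],
    taxonomy: TaxonomyTable,
) -> EvalReport:
    """Two-stage (per-species, then macro) accuracy at every taxonomic rank.

    ``predictions`` rows are (sequence_id, true_species, predicted_species).
    """
    rows = []
    for seq_id, true_sp, pred_sp in predictions:
        for sp in (true_sp, pred_sp):
            if sp not in taxonomy:
                raise ValueError(f"species {sp!r} missing from taxonomy")
        row = {"sequence_id": seq_id, "true": true_sp, "pred": pred_sp,
               "species": float(true_sp == pred_sp)}
        for rank in RANKS:
            row[rank] = float(taxonomy.rank_of(true_sp, rank)
                              == taxonomy.rank_of(pred_sp, rank))
        rows.append(row)
    if not rows:
        raise ValueError("no predictions to evaluate")
    df = pd.DataFrame(rows)
    per_species = df.groupby("true")[list(RANK_ORDER)].mean()
    acc = {rank: float(per_species[rank].mean()) for rank in RANK_ORDER}
    return EvalReport(acc, per_species, len(per_species))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationTable:
    """20 probability bins of width 0.05 partitioning (0, 1]."""

    bin_edges: np.ndarray          # 21 edges, 0.0 .. 1.0
    counts: np.ndarray             # (20,)
    proportions: np.ndarray        # (20,), NaN where a bin is empty

    def nonempty(self, min_count: int = 1) -> pd.DataFrame:
        keep = self.counts >= min_count
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame({"bin_center": centers[keep],
                             "count": self.counts[keep],
                             "proportion": self.proportions[keep]})


def calibration_curve(probabilities: Sequence[float],
                      correct: Sequence[bool]) -> CalibrationTable:
    """Bin top-1 probabilities into 5% bins and tally correctness per bin.

    Empty bins report count 0 and an undefined (NaN) proportion rather than
    a fabricated 0.
    """
    p = np.asarray(probabilities, float)
    c = np.asarray(correct, float)
    if p.shape != c.shape:
        raise ValueError("probabilities and correctness flags length mismatch")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in (0, 1]")
    edges = np.linspace(0.0, 1.0, 21)
    idx = np.minimum(np.ceil(p / 0.05).astype(int) - 1, 19)  # bins are (lo, hi]
    counts = np.bincount(idx, minlength=20)
    hits = np.bincount(idx, weights=c, minlength=20)
    with np.errstate(invalid="ignore"):
        props = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    return CalibrationTable(edges, counts, props)


# ---------------------------------------------------------------------------
# Agreement with an external pipeline
# ---------------------------------------------------------------------------

def agreement_table(
    ours: pd.DataFrame | Mapping[str, str],
    external: pd.DataFrame,
    taxonomy: TaxonomyTable,
) -> dict[str, int]:
    """Classify each shared cluster into its deepest agreement category.

    ``ours`` maps cluster_id -> predicted species (always species level);
    ``external`` has columns (cluster_id, assigned_rank, assigned_name) — the
    consumable subset of an LCA-style output.  Agreement is evaluated at the
    shallower of the two assignment depths: if the external pipeline only
    assigned a genus, matching that genus counts as genus-level agreement.
    Records present on only one side are excluded.
    """
    if isinstance(ours, pd.DataFrame):
        if ours["cluster_id"].duplicated().any():
            raise ValueError("duplicate cluster ids in our annotation")
        ours_map = dict(zip(ours["cluster_id"], ours["predicted_species"]))
    else:
        ours_map = dict(ours)
    if external["cluster_id"].duplicated().any():
        raise ValueError("duplicate cluster ids in external annotation")

    # rank value -> values at coarser ranks, derived from the taxonomy table
    parents: dict[str, dict[str, dict[str, str]]] = {r: {} for r in RANK_ORDER}
    for sp in taxonomy.species:
        vals = {"species": sp, **{r: taxonomy.rank_of(sp, r) for r in RANKS}}
        for r in RANK_ORDER:
            parents[r].setdefault(vals[r], vals)

    counts = {r: 0 for r in RANK_ORDER}
    counts["mismatch"] = 0
    for cid, ext_rank, ext_name in external[
            ["cluster_id", "assigned_rank", "assigned_name"]].itertuples(index=False):
        if cid not in ours_map:
            continue
        if ext_rank not in RANK_ORDER:
            raise ValueError(f"unknown external rank {ext_rank!r}")
        our_sp = ours_map[cid]
        our_vals = {"species": our_sp,
                    **{r: taxonomy.rank_of(our_sp, r) for r in RANKS}}
        ext_vals = parents[ext_rank].get(ext_name, {ext_rank: ext_name})
        start = RANK_ORDER.index(ext_rank)  # shallower of the two depths
        category = "mismatch"
        for rank in RANK_ORDER[start:]:
            if rank in ext_vals and our_vals[rank] == ext_vals[rank]:
                category = rank
                break
        counts[category] += 1
    return counts


# ---------------------------------------------------------------------------
# Full zero-shot protocol
# ---------------------------------------------------------------------------

@dataclass
class ProtocolConfig:
    """Bundled training/evaluation setup for one world."""

    embed: EmbedConfig = field(default_factory=EmbedConfig)
    dna: DnaTrainConfig = field(default_factory=DnaTrainConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    cooc: CoocTrainConfig = field(default_factory=CoocTrainConfig)
    noise_sigma: Optional[float] = None   # None: calibrate to holdout mapping error
    holdout_fraction: float = 0.1
    discard_unsequenced: bool = False

    @classmethod
    def desk(cls) -> "ProtocolConfig":
        """Desk-scale settings: a 16-dim embedding space and a narrow encoder,
        matched to worlds of a few hundred species."""
        return cls(
            embed=EmbedConfig(embed_dim=16, epochs=100),
            dna=DnaTrainConfig(channels=32, hidden_dim=256, max_len=96, epochs=30),
            cooc=CoocTrainConfig(rank=256, epochs=10),
        )


@dataclass
class ProtocolResult:
    embeddings: EmbeddingTable
    dna_model: DnaEncoderModel
    cooc_models: dict[str, CooccurrenceModel]
    reports: dict[tuple[str, str], EvalReport]       # (split, model) -> report
    predictions: pd.DataFrame
    holdout_species: list[str]
    noise_sigma: float
    embedding_spearman: float
    traces: dict[str, list[float]]


def embedding_fidelity(tree, embeddings: EmbeddingTable,
                       normalization: str = "max_pairwise") -> float:
    """Spearman correlation between all-pairs cosine distances of the learned
    vectors and the normalized patristic distances."""
    Dn = normalize_distances(patristic_distances(tree), normalization)
    V = embeddings.vectors / np.linalg.norm(embeddings.vectors, axis=1, keepdims=True)
    order = [embeddings.index[t] for t in tree.taxa]
    V = V[order]
    C = 1.0 - V @ V.T
    iu = np.triu_indices(len(order), k=1)
    rho = stats.spearmanr(Dn[iu], C[iu]).statistic
    return float(rho)


def _argmax_top1(P: np.ndarray) -> np.ndarray:
    # species ids are kept sorted, so the first argmax is also the
    # lexicographic tie-break winner
    return P.argmax(axis=1)


def run_zero_shot_protocol(world, cfg: ProtocolConfig, seed: int = 0) -> ProtocolResult:
    """Train all three model stages on a synthetic world and evaluate the
    single-sequence, community-modulated and grid-modulated classifiers on
    both the training species and the held-out (zero-shot) species.

    Mirrors the full-scale study design: embeddings on the whole tree, the
    encoder on reference records minus a random holdout, the co-occurrence
    models on assemblage sites and on grid-derived sites, with holdout and
    gap species represented at sites by noisy embeddings.
    """
    ss = np.random.SeedSequence(seed)
    sub = [int(c.generate_state(1, np.uint64)[0] >> 33) for c in ss.spawn(6)]
    s_embed, s_dna, s_cooc, s_grid, s_noise, s_eval = sub

    embeddings, embed_trace = train_species_embeddings(
        world.tree, replace(cfg.embed, seed=s_embed))
    rho = embedding_fidelity(world.tree, embeddings,
                             cfg.embed.distance_normalization)

    referenced = world.referenced_species
    n_holdout = max(1, int(round(cfg.holdout_fraction * len(referenced))))
    train_species, holdout = zero_shot_split(referenced, n_holdout, seed=s_eval)
    dna_model, dna_trace = train_dna_encoder(
        world.records, embeddings,
        replace(cfg.dna, seed=s_dna, holdout_species=tuple(holdout)))

    # map every reference record once
    rec_ids = [r.sequence_id for r in world.records]
    rec_species = [r.species_id for r in world.records]
    rec_vecs = encode_batch(dna_model, [r.sequence for r in world.records])
    vec_of_record = dict(zip(rec_ids, rec_vecs))

    holdout_set = set(holdout)
    holdout_err = [1.0 - float(v @ embeddings.vector(sp))
                   / (np.linalg.norm(v) * np.linalg.norm(embeddings.vector(sp)))
                   for rid, sp, v in zip(rec_ids, rec_species, rec_vecs)
                   if sp in holdout_set]
    median_err = float(np.median(holdout_err))
    sigma = cfg.noise_sigma if cfg.noise_sigma is not None else \
        calibrate_noise_sigma(embeddings, median_err, seed=s_noise)
    noise_cfg = NoiseConfig(sigma=sigma, seed=s_noise,
                            discard_unsequenced=cfg.discard_unsequenced)

    # species the pipeline treats as 'sequenced': in the reference DB and not
    # held out (holdout species simulate absence from the DB)
    ref_idx = {sp: recs for sp, recs in reference_index(world.records).items()
               if sp not in holdout_set}

    cooc_models: dict[str, CooccurrenceModel] = {}
    traces: dict[str, list[float]] = {"embedding": embed_trace, "dna": dna_trace}
    for name, sites, s in (("community", world.sites, s_cooc),
                           ("grid", grid_to_cooccurrence(world.grid), s_grid)):
        model, tr = train_cooccurrence(
            sites, embeddings, dna_model, ref_idx,
            replace(cfg.cooc, seed=s), noise_cfg, cfg.kernel)
        cooc_models[name] = model
        traces[f"cooc_{name}"] = tr

    # ---- evaluation -------------------------------------------------------
    rng = np.random.default_rng(s_eval)
    species_arr = np.array(embeddings.species_ids)
    pred_rows: list[dict] = []

    # single-sequence: every reference record on its own
    P_all = probability_matrix(rec_vecs, embeddings, cfg.kernel)
    top = _argmax_top1(P_all)
    for k, (rid, sp) in enumerate(zip(rec_ids, rec_species)):
        split = "holdout" if sp in holdout_set else "train"
        pred_rows.append(dict(model="single", split=split, site_id="",
                              sequence_id=rid, true=sp,
                              pred=str(species_arr[top[k]]),
                              prob=float(P_all[k, top[k]])))

    # context representative record per sequenced species (seeded choice)
    ctx_choice = {sp: recs[int(rng.integers(len(recs)))].sequence_id
                  for sp, recs in sorted(ref_idx.items())}
    all_ref_idx = reference_index(world.records)

    # modulated: every site, every member with reference records
    for site in world.sites:
        members = list(site.species_ids)
        M = len(members)
        if M < 2:
            continue
        ctx = np.empty((M, embeddings.dim))
        for i, sp in enumerate(members):
            if sp in ctx_choice:
                ctx[i] = vec_of_record[ctx_choice[sp]]
            else:
                ctx[i] = embeddings.vector(sp) + sigma * rng.standard_normal(embeddings.dim)
        P_ctx = probability_matrix(ctx, embeddings, cfg.kernel)
        total = P_ctx.sum(axis=0)
        evals = [(i, rec) for i, sp in enumerate(members) if sp in all_ref_idx
                 for rec in all_ref_idx[sp]]
        if not evals:
            continue
        Q = np.stack([(total - P_ctx[i]) / (M - 1) for i, _ in evals])
        Pq = probability_matrix(
            np.stack([vec_of_record[rec.sequence_id] for _, rec in evals]),
            embeddings, cfg.kernel)
        logPq = np.log(np.maximum(Pq, PROB_FLOOR))
        for name, model in cooc_models.items():
            Z = logPq + (Q @ model.V) @ model.U.T
            Z -= Z.max(axis=1, keepdims=True)
            S = np.exp(Z)
            S /= S.sum(axis=1, keepdims=True)
            top = _argmax_top1(S)
            for row, (i, rec) in enumerate(evals):
                sp = rec.species_id
                split = "holdout" if sp in holdout_set else "train"
                pred_rows.append(dict(
                    model=name, split=split, site_id=site.site_id,
                    sequence_id=f"{rec.sequence_id}@{site.site_id}",
                    true=sp, pred=str(species_arr[top[row]]),
                    prob=float(S[row, top[row]])))

    predictions = pd.DataFrame(pred_rows)
    reports: dict[tuple[str, str], EvalReport] = {}
    for (split, model), grp in predictions.groupby(["split", "model"]):
        reports[(split, model)] = rank_accuracy(
            grp[["sequence_id", "true", "pred"]].itertuples(index=False),
            world.taxonomy)
    return ProtocolResult(embeddings, dna_model, cooc_models, reports,
                          predictions, holdout, sigma, rho, traces)
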