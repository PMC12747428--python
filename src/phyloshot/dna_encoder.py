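"""Convolutional encoder mapping raw marker sequences into the species
embedding space.

Architecture: a learnable per-base embedding over the tokens
{A, C, G, T, ambiguity, pad}; two 1-D convolutions with ReLU, the first with
kernel 5 / dilation 1 / symmetric zero padding 2, the second with kernel 5 /
dilation 5 / symmetric zero padding 10 (both preserve sequence length); then
a two-layer MLP head (hidden width ``hidden_dim``, ReLU in between) emitting
a vector of the embedding dimension.  The pad token's base embedding is
pinned at zero so right-padding behaves like the convs' zero padding.

Training minimizes the cosine distance between the encoder output and the
frozen species embedding of the sequence's species, for a fixed number of
epochs with AdamW and no early stopping.  All forward/backward passes are
plain NumPy; everything is deterministic under the configured seed.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from ._optim import AdamW
from .data_io import ReferenceRecord
from .phylo_embedding import EmbeddingTable, cosine_distance

logger = logging.getLogger(__name__)

TOKENS = {"A": 0, "C": 1, "G": 2, "T": 3}
AMBIG = 4
PAD = 5
N_TOKENS = 6
KERNEL = 5


@dataclass(frozen=True)
class EncodedSequence:
    """Token indices right-padded to a fixed length."""

    tokens: np.ndarray
    original_length: int
    padded_length: int


def encode_sequence(seq: str, max_len: int) -> EncodedSequence:
    """Tokenize a nucleotide string and right-pad to ``max_len``.

    A/C/G/T map to dedicated tokens; any other character (IUPAC ambiguity,
    read errors) maps to a single ambiguity token.  Longer sequences are
    truncated with a warning.
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    if len(seq) > max_len:
        logger.warning("sequence of length %d truncated to max_len=%d",
                       len(seq), max_len)
        seq = seq[:max_len]
    toks = np.full(max_len, PAD, dtype=np.int64)
    for i, ch in enumerate(seq.upper()):
        toks[i] = TOKENS.get(ch, AMBIG)
    return EncodedSequence(toks, len(seq), max_len)


@dataclass
class DnaEncoderModel:
    """Parameters and shape configuration of the sequence encoder f_theta."""

    params: dict[str, np.ndarray]
    channels: int
    max_len: int
    hidden_dim: int
    embed_dim: int
    aggregation: str = "flatten"  # or "mean" over positions

    @classmethod
    def init(cls, embed_dim: int, channels: int = 64, max_len: int = 128,
             hidden_dim: int = 2048, aggregation: str = "flatten",
             seed: int = 0) -> "DnaEncoderModel":
        if max_len < 21:
            raise ValueError("max_len must be >= 21 so the dilated kernel fits")
        rng = np.random.default_rng(seed)

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        emb = rng.standard_normal((N_TOKENS, channels)) * 0.5
        emb[PAD] = 0.0  # pinned; never updated
        flat_in = channels * max_len if aggregation == "flatten" else channels
        params = {
            "emb": emb,
            "W1": he((channels, KERNEL, channels), KERNEL * channels),
            "b1": np.zeros(channels),
            "W2": he((channels, KERNEL, channels), KERNEL * channels),
            "b2": np.zeros(channels),
            "Wm1": he((flat_in, hidden_dim), flat_in),
            "bm1": np.zeros(hidden_dim),
            "Wm2": he((hidden_dim, embed_dim), hidden_dim),
            "bm2": np.zeros(embed_dim),
        }
        return cls(params, channels, max_len, hidden_dim, embed_dim, aggregation)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = dict(channels=self.channels, max_len=self.max_len,
                    hidden_dim=self.hidden_dim, embed_dim=self.embed_dim,
                    aggregation=self.aggregation)
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "DnaEncoderModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            params = {k: z[k] for k in z.files if k != "__meta__"}
        return cls(params, **meta)


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------

def _conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray,
                    dilation: int) -> np.ndarray:
    """Length-preserving 1-D convolution; x is (B, L, C_in)."""
    B, L, _ = x.shape
    pad = 2 * dilation  # (KERNEL - 1) // 2 * dilation
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    y = np.broadcast_to(b, (B, L, W.shape[0])).copy()
    for k in range(KERNEL):
        y += xp[:, k * dilation:k * dilation + L, :] @ W[:, k, :].T
    return y


def _conv1d_backward(x: np.ndarray, W: np.ndarray, g: np.ndarray,
                     dilation: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    B, L, C_in = x.shape
    pad = 2 * dilation
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    gf = g.reshape(B * L, -1)
    for k in range(KERNEL):
        sl = xp[:, k * dilation:k * dilation + L, :]
        dW[:, k, :] = gf.T @ sl.reshape(B * L, C_in)
        dxp[:, k * dilation:k * dilation + L, :] += g @ W[:, k, :]
    db = gf.sum(axis=0)
    dx = dxp[:, pad:pad + L, :]
    return dW, db, dx


def _forward(model: DnaEncoderModel, tokens: np.ndarray,
             want_cache: bool = False):
    """Batched forward pass; tokens is (B, max_len) int."""
    p = model.params
    x0 = p["emb"][tokens]                         # (B, L, C)
    a1 = _conv1d_forward(x0, p["W1"], p["b1"], dilation=1)
    r1 = np.maximum(a1, 0.0)
    a2 = _conv1d_forward(r1, p["W2"], p["b2"], dilation=5)
    r2 = np.maximum(a2, 0.0)
    if model.aggregation == "flatten":
        h0 = r2.reshape(tokens.shape[0], -1)
    else:
        h0 = r2.mean(axis=1)
    a3 = h0 @ p["Wm1"] + p["bm1"]
    r3 = np.maximum(a3, 0.0)
    out = r3 @ p["Wm2"] + p["bm2"]
    if not want_cache:
        return out, None
    return out, (tokens, x0, a1, r1, a2, r2, h0, a3, r3)


def _backward(model: DnaEncoderModel, cache, g_out: np.ndarray) -> dict[str, np.ndarray]:
    p = model.params
    tokens, x0, a1, r1, a2, r2, h0, a3, r3 = cache
    B = tokens.shape[0]
    grads: dict[str, np.ndarray] = {}
    grads["Wm2"] = r3.T @ g_out
    grads["bm2"] = g_out.sum(axis=0)
    g_r3 = g_out @ p["Wm2"].T
    g_a3 = g_r3 * (a3 > 0)
    grads["Wm1"] = h0.T @ g_a3
    grads["bm1"] = g_a3.sum(axis=0)
    g_h0 = g_a3 @ p["Wm1"].T
    if model.aggregation == "flatten":
        g_r2 = g_h0.reshape(r2.shape)
    else:
        g_r2 = np.repeat(g_h0[:, None, :] / r2.shape[1], r2.shape[1], axis=1)
    g_a2 = g_r2 * (a2 > 0)
    dW2, db2, g_r1 = _conv1d_backward(r1, p["W2"], g_a2, dilation=5)
    grads["W2"], grads["b2"] = dW2, db2
    g_a1 = g_r1 * (a1 > 0)
    dW1, db1, g_x0 = _conv1d_backward(x0, p["W1"], g_a1, dilation=1)
    grads["W1"], grads["b1"] = dW1, db1
    g_emb = np.zeros_like(p["emb"])
    np.add.at(g_emb, tokens.ravel(), g_x0.reshape(-1, g_x0.shape[-1]))
    g_emb[PAD] = 0.0  # pad embedding stays pinned at zero
    grads["emb"] = g_emb
    return grads


def encoder_forward(model: DnaEncoderModel, encoded: EncodedSequence) -> np.ndarray:
    """Embed a single encoded sequence."""
    if encoded.padded_length != model.max_len:
        raise ValueError(
            f"encoded length {encoded.padded_length} != model max_len {model.max_len}")
    out, _ = _forward(model, encoded.tokens[None, :])
    return out[0]


def encode_batch(model: DnaEncoderModel, sequences: Sequence[str]) -> np.ndarray:
    """Embed raw sequences in one batched pass; returns (B, embed_dim)."""
    toks = np.stack([encode_sequence(s, model.max_len).tokens for s in sequences])
    out, _ = _forward(model, toks)
    return out


def dna_mapping_loss(model_output: np.ndarray, species_vec: np.ndarray) -> float:
    """Cosine distance between the encoder output and the frozen species vector."""
    return cosine_distance(model_output, species_vec)


def _cosine_loss_and_grad(V: np.ndarray, E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row cosine distances d(V_i, E_i) and gradient w.r.t. V of their mean."""
    nv = np.linalg.norm(V, axis=1)
    ne = np.linalg.norm(E, axis=1)
    s = np.einsum("ij,ij->i", V, E) / (nv * ne)
    d = 1.0 - s
    # dd/dv = s v/|v|^2 - e/(|v||e|); mean over batch
    B = V.shape[0]
    gV = ((s / nv ** 2)[:, None] * V - E / (nv * ne)[:, None]) / B
    return d, gV


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class DnaTrainConfig:
    """Fixed-epoch training setup; no validation set, no early stopping."""

    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 30
    seed: int = 0
    holdout_species: tuple[str, ...] = ()
    channels: int = 64
    max_len: int = 128
    hidden_dim: int = 2048
    aggregation: str = "flatten"


def train_dna_encoder(
    records: Sequence[ReferenceRecord],
    embeddings: EmbeddingTable,
    config: DnaTrainConfig,
) -> tuple[DnaEncoderModel, list[float]]:
    """Fit the encoder against frozen species embeddings.

    Records of holdout species are excluded from every batch (that is the
    zero-shot evaluation set).  Returns the model and the per-epoch mean
    cosine-distance loss over the training records.
    """
    holdout = set(config.holdout_species)
    train = [r for r in records if r.species_id not in holdout]
    if not train:
        raise ValueError("no training records left after holdout exclusion")
    missing = sorted({r.species_id for r in train} - set(embeddings.index))
    if missing:
        raise ValueError(f"training species without embeddings: {missing}")

    model = DnaEncoderModel.init(
        embed_dim=embeddings.dim, channels=config.channels,
        max_len=config.max_len, hidden_dim=config.hidden_dim,
        aggregation=config.aggregation, seed=config.seed)
    tokens = np.stack([encode_sequence(r.sequence, config.max_len).tokens
                       for r in train])
    targets = np.stack([embeddings.vector(r.species_id) for r in train])

    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.params, lr=config.learning_rate)
    trace: list[float] = []
    n = len(train)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            out, cache = _forward(model, tokens[idx], want_cache=True)
            d, gV = _cosine_loss_and_grad(out, targets[idx])
            if not np.all(np.isfinite(d)):
                raise FloatingPointError("non-finite encoder loss")
            epoch_loss += float(d.sum())
            grads = _backward(model, cache, gV)
            opt.step(grads)
        trace.append(epoch_loss / n)
    return model, trace
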