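"""Masked-language model over expression+metadata token sequences.

Wraps the NumPy transformer encoder with the training scheme (masked-token
prediction with exact 85% gene masking per sequence and independent 15%
metadata masking), a held-out split for monitoring, and the embedding /
prediction contracts the downstream analyses rely on:

* ``contextual_embeddings`` — encoder hidden state at every position of
  the unmasked sequence (one d-vector per token; depth selectable);
* ``predict_masked`` — per-masked-position probability distribution over
  the full vocabulary (softmax of the untied output head);
* ``token_embedding`` — a row of the static token-embedding table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import Adam, Transformer, softmax
from .tokenizer import N_META_POSITIONS, Vocabulary, mask_batch

__all__ = [
    "ModelConfig",
    "TrainedMLM",
    "init_model",
    "train",
    "contextual_embeddings",
    "predict_masked",
    "token_embedding",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Desk-scale transformer hyperparameters (d=64, 2 layers, 4 heads by default)."""

    d: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 256
    dropout: float = 0.0
    lr: float = 1e-3
    warmup_steps: int = 200
    batch_size: int = 64
    epochs: int = 6
    gene_mask_rate: float = 0.85
    meta_mask_rate: float = 0.15
    meta_loss_weight: float = 50.0
    light_mask_fraction: float = 0.3
    light_gene_mask_rate: float = 0.15
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d % self.n_heads != 0:
            raise ValueError(f"d={self.d} must be divisible by n_heads={self.n_heads}")
        if min(self.d, self.n_layers, self.n_heads, self.d_ff, self.batch_size) < 1:
            raise ValueError("all model dimensions must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class TrainedMLM:
    """A (possibly trained) model plus its vocabulary and config."""

    net: Transformer
    vocab: Vocabulary
    config: ModelConfig

    @property
    def seq_len(self) -> int:
        return self.net.seq_len

    @property
    def d(self) -> int:
        return self.net.d


def init_model(vocab: Vocabulary, seq_len: int, config: ModelConfig) -> TrainedMLM:
    """Seeded initialization; identical config + vocab gives identical parameters."""
    net = Transformer(
        k=vocab.k, seq_len=seq_len, d=config.d, n_layers=config.n_layers,
        n_heads=config.n_heads, d_ff=config.d_ff, dropout=config.dropout,
        seed=config.seed,
    )
    return TrainedMLM(net=net, vocab=vocab, config=config)


def train(model: TrainedMLM, sequences: np.ndarray, config: ModelConfig | None = None
          ) -> tuple[TrainedMLM, pd.DataFrame]:
    """Train by masked-token prediction; returns the model and a per-epoch loss trace.

    A deterministic ``val_fraction`` split is held out and scored with a
    fixed mask each epoch.  Raises ``RuntimeError`` on divergence
    (non-finite loss).  With ``epochs=0`` the model is returned unchanged.
    """
    cfg = config or model.config
    sequences = np.asarray(sequences)
    if sequences.ndim != 2 or sequences.shape[0] < 1:
        raise ValueError("need at least one training sequence")
    rng = np.random.default_rng(cfg.seed + 1)
    n = sequences.shape[0]
    n_val = int(round(cfg.val_fraction * n)) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    val_seqs = sequences[val_idx]
    val_mask = None
    if n_val:
        val_rng = np.random.default_rng(cfg.seed + 2)
        val_mask = mask_batch(val_seqs, model.vocab, val_rng,
                              cfg.gene_mask_rate, cfg.meta_mask_rate)
    opt = Adam(model.net.params, lr=cfg.lr)
    trace = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_idx))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            step += 1
            # linear warmup stabilizes the early post-LN optimization, which
            # otherwise lands in a visibly worse plateau for some seeds
            opt.lr = cfg.lr * min(1.0, step / max(cfg.warmup_steps, 1))
            batch = sequences[train_idx[order[start:start + cfg.batch_size]]]
            mb = _curriculum_mask(batch, model.vocab, rng, cfg)
            loss, grads = model.net.loss_and_grads(
                mb.tokens, mb.targets, mb.mask, train=True, rng=rng,
                weights=_position_weights(mb.tokens.shape, cfg.meta_loss_weight),
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss {loss!r}"
                )
            opt.step(model.net.params, grads)
            losses.append(loss)
        val_loss = _eval_loss(model, val_mask) if val_mask is not None else np.nan
        trace.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                      "val_loss": val_loss})
    return model, pd.DataFrame(trace, columns=["epoch", "train_loss", "val_loss"])


def _curriculum_mask(batch: np.ndarray, vocab: Vocabulary, rng: np.random.Generator,
                     cfg: ModelConfig):
    """Per-sequence masking curriculum.

    Most sequences get the heavy reconstruction masking
    (``gene_mask_rate``, default 85% of gene positions).  A
    ``light_mask_fraction`` of sequences instead get a lightly masked
    context (``light_gene_mask_rate``) with the age token always masked:
    the analyses score predictions in nearly full contexts (age clock,
    one-token-at-a-time entropy), and without such examples the model's
    predictive distributions are never calibrated for them.
    """
    from .tokenizer import AGE_POS  # local import to avoid a cycle at module load

    mb = mask_batch(batch, vocab, rng, cfg.gene_mask_rate, cfg.meta_mask_rate)
    if cfg.light_mask_fraction <= 0.0:
        return mb
    light = rng.random(len(batch)) < cfg.light_mask_fraction
    if light.any():
        lb = mask_batch(batch[light], vocab, rng, cfg.light_gene_mask_rate,
                        cfg.meta_mask_rate)
        lb.mask[:, AGE_POS] = True
        lb.tokens[:, AGE_POS] = vocab.mask_id
        mb.tokens[light] = lb.tokens
        mb.mask[light] = lb.mask
    return mb


def _position_weights(shape: tuple[int, int], meta_loss_weight: float) -> np.ndarray:
    """Loss weights: metadata positions up-weighted against the ~n_genes gene positions.

    Without rebalancing, the four metadata positions contribute a negligible
    share of the masked-token gradient and the model never learns to predict
    the age token, which the clock and the age-conditioned entropy require.
    """
    w = np.ones(shape)
    w[:, :N_META_POSITIONS] = meta_loss_weight
    return w


def _eval_loss(model: TrainedMLM, mb, batch_size: int = 128) -> float:
    """Cross entropy of a fixed masked batch in eval mode."""
    total, n_masked = 0.0, 0
    for start in range(0, len(mb.tokens), batch_size):
        sl = slice(start, start + batch_size)
        hidden, _ = model.net.forward(mb.tokens[sl], train=False)
        logits = model.net.logits(hidden)
        probs = softmax(logits.astype(np.float64), axis=-1)
        b, s = np.nonzero(mb.mask[sl])
        t = mb.targets[sl][b, s]
        total += -np.sum(np.log(probs[b, s, t] + 1e-300))
        n_masked += len(b)
    return float(total / max(n_masked, 1))


def contextual_embeddings(model: TrainedMLM, sequences: np.ndarray,
                          layer: int | None = None) -> np.ndarray:
    """Hidden states of full (unmasked) sequences at a chosen encoder depth.

    ``layer`` counts applied encoder layers (0 = static token+position sum;
    ``None`` = final layer).  Accepts one sequence (S,) or a batch (n, S);
    returns (S, d) or (n, S, d).
    """
    seqs = np.asarray(sequences)
    single = seqs.ndim == 1
    if single:
        seqs = seqs[None, :]
    hidden, _ = model.net.forward(seqs, train=False, n_layers_applied=layer)
    return hidden[0] if single else hidden


def predict_masked(model: TrainedMLM, tokens: np.ndarray, mask: np.ndarray
                   ) -> list[tuple[int, np.ndarray]]:
    """Probability distributions over the vocabulary at each masked position.

    Returns a list of (position, probability vector of length k), one per
    masked position, in position order; empty if nothing is masked.
    """
    tokens = np.asarray(tokens)
    if tokens.ndim != 1:
        raise ValueError("predict_masked scores one sequence; use predict_masked_batch")
    positions = np.flatnonzero(mask)
    if len(positions) == 0:
        return []
    hidden, _ = model.net.forward(tokens[None, :], train=False)
    logits = model.net.logits(hidden)[0]
    probs = softmax(logits[positions].astype(np.float64), axis=-1)
    return [(int(p), probs[j]) for j, p in enumerate(positions)]


def predict_position_batch(model: TrainedMLM, tokens: np.ndarray, position: int,
                           batch_size: int = 128) -> np.ndarray:
    """Distributions (n, k) at one masked position for a batch of sequences.

    The caller is responsible for having placed MASK at ``position``.
    """
    out = np.empty((len(tokens), model.vocab.k))
    for start in range(0, len(tokens), batch_size):
        sl = slice(start, start + batch_size)
        hidden, _ = model.net.forward(tokens[sl], train=False)
        logits = model.net.logits(hidden[:, position, :])
        out[sl] = softmax(logits.astype(np.float64), axis=-1)
    return out


def predict_rowwise_positions(model: TrainedMLM, tokens: np.ndarray,
                              positions: np.ndarray, batch_size: int = 128
                              ) -> np.ndarray:
    """Distributions (n, k) where row i is scored at its own position ``positions[i]``.

    The caller is responsible for having placed MASK at each row's position.
    """
    tokens = np.asarray(tokens)
    positions = np.asarray(positions)
    out = np.empty((len(tokens), model.vocab.k))
    for start in range(0, len(tokens), batch_size):
        sl = slice(start, start + batch_size)
        hidden, _ = model.net.forward(tokens[sl], train=False)
        rows = np.arange(hidden.shape[0])
        logits = model.net.logits(hidden[rows, positions[sl], :])
        out[sl] = softmax(logits.astype(np.float64), axis=-1)
    return out


def token_embedding(model: TrainedMLM, token_id: int) -> np.ndarray:
    """Static embedding-table row of a token."""
    if not 0 <= token_id < model.vocab.k:
        raise ValueError(f"token id {token_id} out of range [0, {model.vocab.k})")
    return model.net.params.data["tok_emb"][token_id].astype(np.float64)


# ------------------------------------------------------------------ persistence

def save_model(model: TrainedMLM, path: str | Path) -> None:
    """Checkpoint as NPZ (parameters) + JSON sidecar (config and vocabulary)."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), **model.net.params.data)
    sidecar = {
        "model_config": dataclasses.asdict(model.config),
        "vocab": dataclasses.asdict(model.vocab),
        "seq_len": model.seq_len,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_model(path: str | Path) -> TrainedMLM:
    path = Path(path)
    json_path = path.with_suffix(".json")
    npz_path = path.with_suffix(".npz")
    for p in (json_path, npz_path):
        if not p.exists():
            raise FileNotFoundError(f"missing checkpoint file: {p}")
    with open(json_path) as fh:
        sidecar = json.load(fh)
    sidecar["vocab"]["age_midpoints"] = tuple(sidecar["vocab"]["age_midpoints"])
    vocab = Vocabulary(**sidecar["vocab"])
    cfg = ModelConfig(**sidecar["model_config"])
    model = init_model(vocab, sidecar["seq_len"], cfg)
    try:
        with np.load(npz_path) as data:
            for key in model.net.params.data:
                model.net.params.data[key] = data[key]
    except Exception as exc:
        raise ValueError(f"corrupted checkpoint {npz_path}: {exc}") from exc
    return model
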