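"""Per-gene, per-age embedding trajectories and similarity analyses.

A gene's embedding at age ``t`` is the mean of its contextual vectors
(first-encoder-layer hidden states by default; depth selectable) over all
cells in age bin ``t`` within a stratum; bins with fewer
than ``min_cells`` supporting cells are dropped rather than zero-filled.
The age token gets the analogous per-bin trajectory from position 0.  Two
similarity analyses are built on top:

* ranking tissues / cell types by cosine similarity of their static token
  embeddings to the age-token centroid (mean of all age-token embeddings);
* per-gene cosine-similarity trajectories against the age-token trajectory
  across the lifespan, comparable between healthy and diseased strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mlm import TrainedMLM, token_embedding
from .tokenizer import AGE_POS, N_META_POSITIONS

__all__ = [
    "GeneTrajectory",
    "select_stratum",
    "binned_position_means",
    "gene_age_embeddings",
    "age_token_trajectory",
    "cosine_similarity",
    "token_similarity_ranking",
    "gene_age_similarity_trajectory",
]

DEFAULT_MIN_CELLS = 20

#: encoder depth used for trajectory analyses: the first encoder layer output
#: is contextual yet retains the gene's own token, which deeper layers of a
#: small model progressively wash out (see docs/methods.md)
DEFAULT_TRAJECTORY_LAYER = 1


@dataclass
class GeneTrajectory:
    """Mean contextual embedding of one gene per supported age bin.

    ``bins`` are the supported age-bin indices in increasing order; ``vectors``
    is the matching (N, d) array.  The baseline bin ``t0`` is the earliest
    supported bin.
    """

    gene: str
    stratum: str
    bins: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins)
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if len(self.bins) != len(self.vectors):
            raise ValueError("bins and vectors must have equal length")
        if len(self.bins) and np.any(np.diff(self.bins) <= 0):
            raise ValueError("bins must be strictly increasing")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("trajectory vectors must be finite")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def t0(self) -> int:
        return int(self.bins[0])

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


def select_stratum(meta: pd.DataFrame, tissue: int | None = None,
                   cell_type: int | None = None, disease: int | None = None
                   ) -> np.ndarray:
    """Boolean cell selector for a (tissue, cell type, disease) stratum; None = all."""
    sel = np.ones(len(meta), dtype=bool)
    if tissue is not None:
        sel &= meta["tissue"].to_numpy() == tissue
    if cell_type is not None:
        sel &= meta["cell_type"].to_numpy() == cell_type
    if disease is not None:
        sel &= meta["disease"].to_numpy() == disease
    return sel


def binned_position_means(model: TrainedMLM, tokens: np.ndarray, age_bins: np.ndarray,
                          batch_size: int = 128,
                          layer: int | None = DEFAULT_TRAJECTORY_LAYER):
    """Per-age-bin mean contextual embedding at every sequence position.

    Single forward pass over the cells; returns ``(bin_ids, means, counts)``
    where ``means`` has shape (n_bins_present, S, d) and ``counts`` the number
    of supporting cells per present bin.  ``layer`` selects the encoder
    depth (clipped to the model's layer count; ``None`` = final layer).
    """
    tokens = np.asarray(tokens)
    age_bins = np.asarray(age_bins)
    if len(tokens) == 0:
        raise ValueError("stratum contains no cells")
    if layer is not None:
        layer = min(layer, model.net.n_layers)
    bin_ids = np.unique(age_bins)
    S, d = model.seq_len, model.d
    sums = np.zeros((len(bin_ids), S, d))
    counts = np.zeros(len(bin_ids), dtype=np.int64)
    bin_index = {int(b): i for i, b in enumerate(bin_ids)}
    for start in range(0, len(tokens), batch_size):
        sl = slice(start, start + batch_size)
        hidden, _ = model.net.forward(tokens[sl], train=False,
                                      n_layers_applied=layer)
        for b in np.unique(age_bins[sl]):
            rows = age_bins[sl] == b
            sums[bin_index[int(b)]] += hidden[rows].sum(axis=0)
            counts[bin_index[int(b)]] += int(rows.sum())
    means = sums / counts[:, None, None]
    return bin_ids, means, counts


def gene_age_embeddings(model: TrainedMLM, tokens: np.ndarray, age_bins: np.ndarray,
                        gene_ids: list[str], stratum: str = "all",
                        min_cells: int = DEFAULT_MIN_CELLS,
                        _precomputed=None) -> dict[str, GeneTrajectory]:
    """One trajectory per gene, restricted to bins with >= min_cells support.

    Raises ``ValueError`` (listing the per-bin supports) if no bin reaches
    ``min_cells``.
    """
    bin_ids, means, counts = (
        _precomputed if _precomputed is not None
        else binned_position_means(model, tokens, age_bins)
    )
    keep = counts >= min_cells
    if not keep.any():
        support = {int(b): int(c) for b, c in zip(bin_ids, counts)}
        raise ValueError(
            f"no age bin reaches min_cells={min_cells}; per-bin support: {support}"
        )
    kept_bins = bin_ids[keep]
    out: dict[str, GeneTrajectory] = {}
    for g, gene in enumerate(gene_ids):
        out[gene] = GeneTrajectory(
            gene=gene, stratum=stratum, bins=kept_bins,
            vectors=means[keep, N_META_POSITIONS + g, :],
        )
    return out


def age_token_trajectory(model: TrainedMLM, tokens: np.ndarray, age_bins: np.ndarray,
                         stratum: str = "all", min_cells: int = DEFAULT_MIN_CELLS,
                         _precomputed=None) -> GeneTrajectory:
    """Per-bin mean contextual embedding at the age position (position 0)."""
    bin_ids, means, counts = (
        _precomputed if _precomputed is not None
        else binned_position_means(model, tokens, age_bins)
    )
    keep = counts >= min_cells
    if not keep.any():
        support = {int(b): int(c) for b, c in zip(bin_ids, counts)}
        raise ValueError(
            f"no age bin reaches min_cells={min_cells}; per-bin support: {support}"
        )
    return GeneTrajectory(
        gene="<age>", stratum=stratum, bins=bin_ids[keep], vectors=means[keep, AGE_POS, :]
    )


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); requires both norms positive."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(np.dot(u, v) / (nu * nv))


def token_similarity_ranking(model: TrainedMLM, category: str) -> pd.DataFrame:
    """Rank tissue or cell-type tokens by cosine similarity to the age-token centroid.

    Uses static token-table embeddings; the age centroid is the mean of all
    age-token embeddings.  Ties sort stably by token id.
    """
    vocab = model.vocab
    if category == "tissue":
        ids = vocab.tissue_token_ids
    elif category == "cell_type":
        ids = vocab.cell_type_token_ids
    else:
        raise ValueError(f"category must be 'tissue' or 'cell_type', got {category!r}")
    centroid = np.mean([token_embedding(model, int(t)) for t in vocab.age_token_ids], axis=0)
    records = [
        {"token_id": int(t), "label": vocab.label(int(t)),
         "score": cosine_similarity(token_embedding(model, int(t)), centroid)}
        for t in ids
    ]
    df = pd.DataFrame(records)
    df = df.sort_values(["score", "token_id"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def gene_age_similarity_trajectory(traj: GeneTrajectory, ages: GeneTrajectory
                                   ) -> pd.DataFrame:
    """Cosine similarity of a gene's trajectory to the age-token trajectory, per bin.

    Defined on the bins supported by both inputs.
    """
    common = np.intersect1d(traj.bins, ages.bins)
    gi = {int(b): i for i, b in enumerate(traj.bins)}
    ai = {int(b): i for i, b in enumerate(ages.bins)}
    rows = [
        {"age_bin": int(b),
         "cosine": cosine_similarity(traj.vectors[gi[int(b)]], ages.vectors[ai[int(b)]])}
        for b in common
    ]
    return pd.DataFrame(rows, columns=["age_bin", "cosine"])


def trajectories_to_frame(trajs: dict[str, GeneTrajectory]) -> pd.DataFrame:
    """Long-format table (gene, stratum, age_bin, dim_0..dim_{d-1})."""
    frames = []
    for gene, tr in trajs.items():
        df = pd.DataFrame(tr.vectors, columns=[f"dim_{i}" for i in range(tr.d)])
        df.insert(0, "age_bin", tr.bins)
        df.insert(0, "stratum", tr.stratum)
        df.insert(0, "gene", gene)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
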