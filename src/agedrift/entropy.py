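"""Shannon entropy of masked-token predictions as a disorder metric.

For a masked token the model emits a probability distribution over the full
vocabulary; its Shannon entropy ``H = -sum_i p_i log p_i`` (natural log,
``0 log 0 := 0``) measures the model's uncertainty, bounded by ``ln k``.
Tokens are scored one at a time — every other position stays visible, and
the age token is visible iff the scoring is conditioned on age — so each
distribution is conditioned on a maximally informative context.  Aggregated
over age bins and the disease flag, rising entropy with age quantifies the
loss of molecular specificity that dissipation predicts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .mlm import TrainedMLM, predict_rowwise_positions
from .tokenizer import AGE_POS, N_META_POSITIONS

__all__ = ["token_entropy", "masked_entropy_profile",
           "reconstruction_entropy_profile", "entropy_by_age"]

NORMALIZATION_TOL = 1e-6


def token_entropy(dist: np.ndarray, base: str = "nats") -> float:
    """Shannon entropy of a probability vector (natural log by default)."""
    p = np.asarray(dist, dtype=np.float64)
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > NORMALIZATION_TOL:
        raise ValueError(f"distribution sums to {p.sum():.8f}, not 1 within {NORMALIZATION_TOL}")
    nz = p[p > 0]
    h = float(-np.sum(nz * np.log(nz)))
    return h / np.log(2.0) if base == "bits" else h


def masked_entropy_profile(model: TrainedMLM, tokens: np.ndarray, meta: pd.DataFrame,
                           rng: np.random.Generator, target: str = "genes",
                           condition_on_age: bool = True, genes_per_cell: int = 32,
                           restrict_to_category: bool = False,
                           fixed_panel: bool = False) -> pd.DataFrame:
    """Per-(cell, masked position) entropy records, one token masked at a time.

    For every cell, ``genes_per_cell`` gene positions (or the single
    metadata position for ``target='tissue'|'cell_type'``) are masked one at
    a time — every other position visible — and the entropy of each
    predicted distribution is recorded.  ``fixed_panel`` draws one random
    gene panel scored for every cell instead of a fresh panel per cell
    (removes gene-sampling variance between strata).  With
    ``condition_on_age=False`` the age token is masked as well, so the
    prediction is not informed by age.  ``restrict_to_category``
    renormalizes the distribution to the masked token's own category before
    scoring (default scores the full-vocabulary distribution).

    See :func:`reconstruction_entropy_profile` for the variant that scores
    predictions inside the training masking scheme, which is the better
    calibrated default for entropy-vs-age trends.
    """
    vocab = model.vocab
    tokens = np.asarray(tokens)
    n_cells, S = tokens.shape
    n_genes = S - N_META_POSITIONS
    if target == "genes":
        m = genes_per_cell
        if m > n_genes:
            raise ValueError(f"genes_per_cell={m} exceeds {n_genes} gene positions")
        if m == 0:
            return _empty_records()
        if fixed_panel:
            panel = rng.choice(n_genes, size=m, replace=False) + N_META_POSITIONS
            chosen = np.tile(panel, (n_cells, 1))
        else:
            chosen = np.stack([
                rng.choice(n_genes, size=m, replace=False) + N_META_POSITIONS
                for _ in range(n_cells)
            ])
    elif target in ("tissue", "cell_type"):
        pos = {"tissue": 1, "cell_type": 2}[target]
        chosen = np.full((n_cells, 1), pos)
        m = 1
    else:
        raise ValueError(f"target must be genes|tissue|cell_type, got {target!r}")

    cat_ids = None
    if restrict_to_category:
        cat_ids = {
            "genes": np.arange(0, vocab.n_value_bins + 1),
            "tissue": vocab.tissue_token_ids,
            "cell_type": vocab.cell_type_token_ids,
        }[target]

    records = []
    for j in range(m):
        masked = tokens.copy()
        positions = chosen[:, j]
        masked[np.arange(n_cells), positions] = vocab.mask_id
        if not condition_on_age:
            masked[:, AGE_POS] = vocab.mask_id
        dists = predict_rowwise_positions(model, masked, positions)
        if cat_ids is not None:
            sub = dists[:, cat_ids]
            dists = sub / sub.sum(axis=1, keepdims=True)
        for r in range(n_cells):
            records.append(
                {
                    "cell_id": meta["cell_id"].iat[r],
                    "position": int(positions[r]),
                    "target_category": target,
                    "H_nats": token_entropy(dists[r]),
                    "age_bin": int(meta["age_bin"].iat[r]),
                    "tissue": int(meta["tissue"].iat[r]),
                    "disease": int(meta["disease"].iat[r]),
                    "conditioned_on_age": condition_on_age,
                }
            )
    return pd.DataFrame(records, columns=_RECORD_COLUMNS)


def reconstruction_entropy_profile(model: TrainedMLM, tokens: np.ndarray,
                                   meta: pd.DataFrame, rng: np.random.Generator,
                                   gene_mask_rate: float = 0.85,
                                   condition_on_age: bool = True,
                                   n_draws: int = 2,
                                   batch_size: int = 128) -> pd.DataFrame:
    """Entropy of every masked gene position under the training masking scheme.

    Each draw applies the reconstruction mask (``gene_mask_rate`` of gene
    positions, metadata visible; the age token additionally masked when not
    conditioning on age) and records the Shannon entropy of the prediction
    at every masked gene position.  Scoring inside the mask distribution the
    model was trained on yields better-calibrated uncertainty than the
    one-token-at-a-time profile, and one forward pass scores ~all masked
    positions at once.
    """
    from .nn import softmax
    from .tokenizer import mask_batch

    vocab = model.vocab
    tokens = np.asarray(tokens)
    gene_pos = (np.arange(tokens.shape[1]) >= N_META_POSITIONS)[None, :]
    cells, positions, entropies = [], [], []
    for _ in range(n_draws):
        mb = mask_batch(tokens, vocab, rng, gene_mask_rate=gene_mask_rate,
                        meta_mask_rate=0.0)
        if not condition_on_age:
            mb.mask[:, AGE_POS] = True
            mb.tokens[:, AGE_POS] = vocab.mask_id
        for start in range(0, len(tokens), batch_size):
            sl = slice(start, start + batch_size)
            hidden, _ = model.net.forward(mb.tokens[sl], train=False)
            logits = model.net.logits(hidden)
            probs = softmax(logits.astype(np.float64), axis=-1)
            b, s = np.nonzero(mb.mask[sl] & gene_pos)
            p = probs[b, s]
            entropies.append(-(p * np.log(p + 1e-300)).sum(axis=1))
            cells.append(start + b)
            positions.append(s)
    cells = np.concatenate(cells)
    positions = np.concatenate(positions)
    return pd.DataFrame(
        {
            "cell_id": meta["cell_id"].to_numpy()[cells],
            "position": positions,
            "target_category": "genes",
            "H_nats": np.concatenate(entropies),
            "age_bin": meta["age_bin"].to_numpy()[cells],
            "tissue": meta["tissue"].to_numpy()[cells],
            "disease": meta["disease"].to_numpy()[cells],
            "conditioned_on_age": condition_on_age,
        },
        columns=_RECORD_COLUMNS,
    )


_RECORD_COLUMNS = [
    "cell_id", "position", "target_category", "H_nats", "age_bin", "tissue",
    "disease", "conditioned_on_age",
]


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=_RECORD_COLUMNS)


def entropy_by_age(records: pd.DataFrame) -> pd.DataFrame:
    """Entropy summaries keyed by (age bin, disease flag).

    Returns mean/sd/quantiles per key; ``attrs['spearman']`` maps each
    disease level to the Spearman rank correlation of per-bin mean entropy
    versus bin index (``None`` where undefined, e.g. constant records), and
    ``attrs['spearman_pooled']`` is the same correlation over all records
    regardless of disease status.
    """
    if len(records) == 0:
        raise ValueError("no entropy records")
    table = records.groupby(["age_bin", "disease"])["H_nats"].agg(
        n="size", mean="mean", sd=lambda h: h.std(ddof=0),
        q25=lambda h: h.quantile(0.25), median="median",
        q75=lambda h: h.quantile(0.75),
    ).reset_index()
    spearman: dict[int, float | None] = {}
    for dz, sub in table.groupby("disease"):
        if len(sub) < 2 or sub["mean"].nunique() == 1:
            spearman[int(dz)] = None
            continue
        rho = stats.spearmanr(sub["age_bin"], sub["mean"]).statistic
        spearman[int(dz)] = None if np.isnan(rho) else float(rho)
    table.attrs["spearman"] = spearman
    pooled = records.groupby("age_bin")["H_nats"].mean()
    if len(pooled) >= 2 and pooled.nunique() > 1:
        rho = stats.spearmanr(pooled.index.to_numpy(), pooled.to_numpy()).statistic
        table.attrs["spearman_pooled"] = None if np.isnan(rho) else float(rho)
    else:
        table.attrs["spearman_pooled"] = None
    return table
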