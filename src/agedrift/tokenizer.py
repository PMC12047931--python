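"""Token vocabulary, expression binning, cell encoding and masking.

Each cell becomes a fixed-length token sequence: positions 0..3 carry the
metadata tokens (age bin, tissue, cell type, disease flag) and position
``4 + g`` carries the expression-bin token of gene ``g``.  Genes are
identified purely by position (the model's positional embedding), so the
gene -> position map is a bijection fixed when the vocabulary is built.

Expression values are encoded per cell by rank: zero counts map to a
dedicated zero bin, and nonzero counts are rank-transformed within the cell
and cut into ``B`` equal-frequency bins (ties broken by gene position,
ascending).  The encoding is therefore invariant to sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Vocabulary",
    "TokenSequence",
    "N_META_POSITIONS",
    "build_vocabulary",
    "bin_expression",
    "encode_cell",
    "encode_study",
    "decode_cell",
    "mask_sequence",
    "mask_batch",
]

#: reserved metadata positions: age, tissue, cell type, disease
N_META_POSITIONS = 4
AGE_POS, TISSUE_POS, CELL_TYPE_POS, DISEASE_POS = 0, 1, 2, 3


@dataclass(frozen=True)
class Vocabulary:
    """Contiguous token-id space over value bins, metadata categories and specials.

    Id layout (contiguous from 0): value bins ``BIN_0..BIN_B`` (``BIN_0`` is
    the zero-count bin), then age tokens, tissue tokens, cell-type tokens,
    the two disease tokens, then ``MASK`` and ``PAD``.  ``k`` is the total
    dictionary size, the ``k`` of the masked-token entropy bound ``ln k``.
    """

    n_value_bins: int  # B; value tokens are BIN_0..BIN_B (B+1 tokens)
    n_age_bins: int
    n_tissues: int
    n_cell_types: int
    age_midpoints: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_value_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_value_bins}")

    # --- id arithmetic -----------------------------------------------------
    @property
    def value_offset(self) -> int:
        return 0

    @property
    def age_offset(self) -> int:
        return self.n_value_bins + 1

    @property
    def tissue_offset(self) -> int:
        return self.age_offset + self.n_age_bins

    @property
    def cell_type_offset(self) -> int:
        return self.tissue_offset + self.n_tissues

    @property
    def disease_offset(self) -> int:
        return self.cell_type_offset + self.n_cell_types

    @property
    def mask_id(self) -> int:
        return self.disease_offset + 2

    @property
    def pad_id(self) -> int:
        return self.mask_id + 1

    @property
    def k(self) -> int:
        """Total vocabulary size, including special tokens."""
        return self.pad_id + 1

    def value_token(self, b: int | np.ndarray) -> int | np.ndarray:
        return self.value_offset + b

    def age_token(self, age_bin: int | np.ndarray) -> int | np.ndarray:
        if np.any(np.asarray(age_bin) >= self.n_age_bins) or np.any(np.asarray(age_bin) < 0):
            raise ValueError(f"age_bin out of range [0, {self.n_age_bins})")
        return self.age_offset + age_bin

    def tissue_token(self, tissue: int | np.ndarray) -> int | np.ndarray:
        if np.any(np.asarray(tissue) >= self.n_tissues) or np.any(np.asarray(tissue) < 0):
            raise ValueError(f"tissue id out of range [0, {self.n_tissues})")
        return self.tissue_offset + tissue

    def cell_type_token(self, ct: int | np.ndarray) -> int | np.ndarray:
        if np.any(np.asarray(ct) >= self.n_cell_types) or np.any(np.asarray(ct) < 0):
            raise ValueError(f"cell_type id out of range [0, {self.n_cell_types})")
        return self.cell_type_offset + ct

    def disease_token(self, flag: int | np.ndarray) -> int | np.ndarray:
        if np.any(~np.isin(np.asarray(flag), (0, 1))):
            raise ValueError("disease flag must be 0 or 1")
        return self.disease_offset + flag

    @property
    def age_token_ids(self) -> np.ndarray:
        return np.arange(self.age_offset, self.age_offset + self.n_age_bins)

    @property
    def tissue_token_ids(self) -> np.ndarray:
        return np.arange(self.tissue_offset, self.tissue_offset + self.n_tissues)

    @property
    def cell_type_token_ids(self) -> np.ndarray:
        return np.arange(self.cell_type_offset, self.cell_type_offset + self.n_cell_types)

    def label(self, token_id: int) -> str:
        if 0 <= token_id <= self.n_value_bins:
            return f"BIN_{token_id}"
        if token_id < self.tissue_offset:
            return f"AGE_{token_id - self.age_offset}"
        if token_id < self.cell_type_offset:
            return f"TISSUE_{token_id - self.tissue_offset}"
        if token_id < self.disease_offset:
            return f"CT_{token_id - self.cell_type_offset}"
        if token_id == self.disease_offset:
            return "HEALTHY"
        if token_id == self.disease_offset + 1:
            return "DISEASED"
        if token_id == self.mask_id:
            return "MASK"
        if token_id == self.pad_id:
            return "PAD"
        raise ValueError(f"token id {token_id} out of range [0, {self.k})")

    def category(self, token_id: int) -> str:
        label = self.label(token_id)
        return label.split("_")[0].lower() if "_" in label else {
            "HEALTHY": "disease",
            "DISEASED": "disease",
            "MASK": "special",
            "PAD": "special",
        }[label]

    def to_tsv(self, path: str | Path) -> None:
        rows = [(i, self.category(i), self.label(i)) for i in range(self.k)]
        pd.DataFrame(rows, columns=["token_id", "category", "label"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class TokenSequence:
    """A cell's token vector with an optional mask and the original targets."""

    tokens: np.ndarray  # int, length N_META_POSITIONS + n_genes
    mask: np.ndarray  # bool, same length
    targets: np.ndarray  # original (pre-mask) tokens, same length

    def __post_init__(self) -> None:
        if not (len(self.tokens) == len(self.mask) == len(self.targets)):
            raise ValueError("tokens, mask and targets must have equal length")

    @property
    def masked_positions(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


def build_vocabulary(study, n_bins: int) -> Vocabulary:
    """Build the deterministic vocabulary of a study; gene order follows ``gene_ids``."""
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    meta = study.cell_meta
    n_age = int(meta["age_bin"].max()) + 1
    if study.config is not None:
        n_age = study.config.n_age_bins
        n_tissues = study.config.n_tissues
        n_ct = study.config.n_cell_types
    else:
        n_tissues = int(meta["tissue"].max()) + 1
        n_ct = int(meta["cell_type"].max()) + 1
    midpoints = study.age_midpoints() if hasattr(study, "age_midpoints") else np.array([])
    if study.config is not None:
        midpoints = study.config.age_midpoints()
    return Vocabulary(
        n_value_bins=n_bins,
        n_age_bins=n_age,
        n_tissues=n_tissues,
        n_cell_types=n_ct,
        age_midpoints=tuple(float(m) for m in midpoints),
    )


def bin_expression(count_row: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-frequency binning of one cell's counts into bins 0..B.

    Zero counts map to bin 0.  Nonzero counts are ranked ascending within the
    cell (ties broken by gene position, ascending) and cut into ``n_bins``
    equal-frequency bins 1..B.  Monotone: a higher count never gets a lower
    bin.  Scale-free: multiplying the row by a positive constant leaves the
    bins unchanged.
    """
    row = np.asarray(count_row)
    if (row < 0).any():
        raise ValueError("counts must be non-negative")
    bins = np.zeros(len(row), dtype=np.int64)
    nz = np.flatnonzero(row)
    if len(nz) == 0:
        return bins
    order = np.argsort(row[nz], kind="stable")  # stable sort = positional tie-break
    ranks = np.empty(len(order), dtype=np.int64)
    ranks[order] = np.arange(len(order))
    bins[nz] = 1 + (ranks * n_bins) // len(nz)
    # the top rank lands exactly on n_bins only via integer arithmetic guard
    np.clip(bins, 0, n_bins, out=bins)
    return bins


def encode_cell(count_row: np.ndarray, age_bin: int, tissue: int, cell_type: int,
                disease: int, vocab: Vocabulary) -> TokenSequence:
    """Encode one cell as [AGE, TISSUE, CT, DISEASE, BIN(g0), BIN(g1), ...]."""
    bins = bin_expression(count_row, vocab.n_value_bins)
    tokens = np.concatenate(
        [
            np.array(
                [
                    vocab.age_token(age_bin),
                    vocab.tissue_token(tissue),
                    vocab.cell_type_token(cell_type),
                    vocab.disease_token(disease),
                ]
            ),
            vocab.value_token(bins),
        ]
    ).astype(np.int64)
    return TokenSequence(tokens=tokens, mask=np.zeros(len(tokens), bool), targets=tokens.copy())


def decode_cell(seq: TokenSequence, vocab: Vocabulary) -> dict:
    """Recover metadata ids and the expression-bin vector from an unmasked sequence."""
    t = seq.targets
    return {
        "age_bin": int(t[AGE_POS] - vocab.age_offset),
        "tissue": int(t[TISSUE_POS] - vocab.tissue_offset),
        "cell_type": int(t[CELL_TYPE_POS] - vocab.cell_type_offset),
        "disease": int(t[DISEASE_POS] - vocab.disease_offset),
        "bins": (t[N_META_POSITIONS:] - vocab.value_offset).astype(np.int64),
    }


def encode_study(study, vocab: Vocabulary) -> np.ndarray:
    """Encode all cells of a study into an (n_cells, 4 + n_genes) int matrix."""
    counts = study.counts.toarray()
    meta = study.cell_meta
    n = study.n_cells
    tokens = np.empty((n, N_META_POSITIONS + study.n_genes), dtype=np.int64)
    tokens[:, AGE_POS] = vocab.age_token(meta["age_bin"].to_numpy())
    tokens[:, TISSUE_POS] = vocab.tissue_token(meta["tissue"].to_numpy())
    tokens[:, CELL_TYPE_POS] = vocab.cell_type_token(meta["cell_type"].to_numpy())
    tokens[:, DISEASE_POS] = vocab.disease_token(meta["disease"].to_numpy())
    for i in range(n):
        tokens[i, N_META_POSITIONS:] = vocab.value_token(
            bin_expression(counts[i], vocab.n_value_bins)
        )
    return tokens


def mask_sequence(
    seq: TokenSequence,
    vocab: Vocabulary,
    rng: np.random.Generator,
    gene_mask_rate: float = 0.85,
    meta_mask_rate: float = 0.15,
    keep_age_visible: bool = False,
) -> TokenSequence:
    """Apply the masking scheme to a single sequence.

    Exactly ``round(gene_mask_rate * n_genes)`` gene positions are masked,
    chosen uniformly without replacement; each metadata position is masked
    independently with ``meta_mask_rate``.  With ``keep_age_visible`` the age
    position is never masked (age-conditioned scoring).
    """
    masked = mask_batch(
        seq.targets[None, :], vocab, rng, gene_mask_rate, meta_mask_rate, keep_age_visible
    )
    return TokenSequence(tokens=masked.tokens[0], mask=masked.mask[0], targets=seq.targets.copy())


@dataclass
class MaskedBatch:
    tokens: np.ndarray  # (n, S) with MASK substituted
    mask: np.ndarray  # (n, S) bool
    targets: np.ndarray  # (n, S) originals


def mask_batch(
    targets: np.ndarray,
    vocab: Vocabulary,
    rng: np.random.Generator,
    gene_mask_rate: float = 0.85,
    meta_mask_rate: float = 0.15,
    keep_age_visible: bool = False,
) -> MaskedBatch:
    """Vectorized masking of a batch of sequences (same contract as mask_sequence)."""
    if not (0.0 <= gene_mask_rate <= 1.0 and 0.0 <= meta_mask_rate <= 1.0):
        raise ValueError("mask rates must be in [0, 1]")
    targets = np.asarray(targets)
    n, S = targets.shape
    n_genes = S - N_META_POSITIONS
    n_masked = int(round(gene_mask_rate * n_genes))
    mask = np.zeros((n, S), dtype=bool)
    if n_masked > 0:
        # exact count per row: argsort of uniforms = uniform permutation
        u = rng.random((n, n_genes))
        sel = np.argsort(u, axis=1)[:, :n_masked] + N_META_POSITIONS
        np.put_along_axis(mask, sel, True, axis=1)
    if meta_mask_rate > 0:
        mask[:, :N_META_POSITIONS] = rng.random((n, N_META_POSITIONS)) < meta_mask_rate
    if keep_age_visible:
        mask[:, AGE_POS] = False
    tokens = targets.copy()
    tokens[mask] = vocab.mask_id
    return MaskedBatch(tokens=tokens, mask=mask, targets=targets.copy())
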