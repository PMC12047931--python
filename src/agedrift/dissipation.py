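"""Embedding drift, conservative/dissipative gene classification and contrasts.

The drift of gene ``g`` at age ``t`` is the Euclidean distance between its
mean contextual embedding at ``t`` and at the baseline (earliest supported)
bin, ``D_g(t) = ||E_{g,t} - E_{g,t0}||``.  Genes whose maximum drift stays
at or below a percentile threshold ``delta`` of the max-drift distribution
are *conservative*; the rest are *dissipative* — the operational form of a
Hopf decomposition of the expression dynamics into recurrent and wandering
parts.  A per-condition contrast identifies genes whose stability flips
between health and disease, and an empirical Lipschitz estimate bounds the
sensitivity of embeddings to one-token input or age perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embeddings import GeneTrajectory
from .mlm import TrainedMLM, contextual_embeddings
from .tokenizer import AGE_POS, N_META_POSITIONS

__all__ = [
    "DriftProfile",
    "ClassificationResult",
    "LipschitzEstimate",
    "drift",
    "embedding_variance",
    "classify_genes",
    "condition_contrast",
    "estimate_lipschitz",
]

RATIO_EPS = 1e-9


@dataclass
class DriftProfile:
    """Per-gene drift curve and embedding variance within one stratum."""

    gene: str
    stratum: str
    bins: np.ndarray
    drifts: np.ndarray  # D_g(t) per supported bin; D_g(t0) = 0
    sigma2: float
    mean_embedding: np.ndarray

    @property
    def max_drift(self) -> float:
        return float(np.max(self.drifts))


def drift(traj: GeneTrajectory, n_baseline_bins: int = 1) -> np.ndarray:
    """Euclidean drift from the baseline embedding, per supported bin.

    The baseline is the earliest supported bin (or the mean of the first
    ``n_baseline_bins`` bins when early bins are pooled).  Requires at least
    two supported bins.
    """
    if traj.n_bins < 2:
        raise ValueError(
            f"gene {traj.gene}: need >= 2 supported bins including the baseline, "
            f"got {traj.n_bins}"
        )
    if not 1 <= n_baseline_bins <= traj.n_bins:
        raise ValueError("n_baseline_bins out of range")
    baseline = traj.vectors[:n_baseline_bins].mean(axis=0)
    return np.linalg.norm(traj.vectors - baseline[None, :], axis=1)


def embedding_variance(traj: GeneTrajectory) -> tuple[np.ndarray, float]:
    """Mean embedding and population variance over supported bins.

    ``mean = (1/N) sum_i E_{g,t_i}``;
    ``sigma2 = (1/N) sum_i ||E_{g,t_i} - mean||^2``.
    """
    mean = traj.vectors.mean(axis=0)
    sigma2 = float(np.mean(np.sum((traj.vectors - mean[None, :]) ** 2, axis=1)))
    return mean, sigma2


def drift_profile(traj: GeneTrajectory, n_baseline_bins: int = 1) -> DriftProfile:
    mean, sigma2 = embedding_variance(traj)
    return DriftProfile(
        gene=traj.gene, stratum=traj.stratum, bins=traj.bins,
        drifts=drift(traj, n_baseline_bins), sigma2=sigma2, mean_embedding=mean,
    )


@dataclass
class ClassificationResult:
    """Conservative/dissipative split at a max-drift percentile threshold."""

    delta: float
    q: float
    labels: pd.DataFrame  # gene, max_drift, sigma2, label

    @property
    def conservative(self) -> set[str]:
        return set(self.labels.loc[self.labels["label"] == "conservative", "gene"])

    @property
    def dissipative(self) -> set[str]:
        return set(self.labels.loc[self.labels["label"] == "dissipative", "gene"])


def classify_genes(profiles: list[DriftProfile], q: float = 80.0) -> ClassificationResult:
    """Split genes at ``delta`` = q-th percentile (linear interpolation) of max drift.

    Conservative: ``max_t D_g(t) <= delta``; dissipative: the rest.  At the
    q=100 boundary every gene is conservative.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 gene profiles to classify")
    if not 0.0 < q <= 100.0:
        raise ValueError(f"percentile q must be in (0, 100], got {q}")
    max_drifts = np.array([p.max_drift for p in profiles])
    delta = float(np.percentile(max_drifts, q))
    labels = pd.DataFrame(
        {
            "gene": [p.gene for p in profiles],
            "max_drift": max_drifts,
            "sigma2": [p.sigma2 for p in profiles],
            "label": np.where(max_drifts <= delta, "conservative", "dissipative"),
        }
    )
    return ClassificationResult(delta=delta, q=q, labels=labels)


def condition_contrast(profiles_healthy: list[DriftProfile],
                       profiles_diseased: list[DriftProfile],
                       q: float = 80.0) -> pd.DataFrame:
    """Per-gene drift ratio (diseased/healthy) and stability label changes.

    Both conditions are classified independently at the same percentile
    ``q`` (each with its own ``delta``; recorded in ``attrs``).  The ratio
    denominator is floored at 1e-9; floored genes carry ``degenerate=True``.
    Change categories: C->C, C->D, D->C, D->D.
    """
    ch = classify_genes(profiles_healthy, q)
    cd = classify_genes(profiles_diseased, q)
    h = ch.labels.set_index("gene")
    d = cd.labels.set_index("gene")
    genes = h.index.intersection(d.index)
    short = {"conservative": "C", "dissipative": "D"}
    rows = []
    for g in genes:
        dh, dd = float(h.loc[g, "max_drift"]), float(d.loc[g, "max_drift"])
        rows.append(
            {
                "gene": g,
                "max_drift_healthy": dh,
                "max_drift_diseased": dd,
                "ratio": dd / max(dh, RATIO_EPS),
                "degenerate": dh < RATIO_EPS,
                "label_healthy": h.loc[g, "label"],
                "label_diseased": d.loc[g, "label"],
                "change": f"{short[h.loc[g, 'label']]}->{short[d.loc[g, 'label']]}",
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["delta_healthy"] = ch.delta
    out.attrs["delta_diseased"] = cd.delta
    out.attrs["q"] = q
    return out


@dataclass
class LipschitzEstimate:
    """Extremes of ||dE|| / (||dx|| + |dt|) over sampled one-token perturbations."""

    l_max: float
    l_min: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.l_max) and np.isfinite(self.l_min)):
            raise ValueError("Lipschitz estimates must be finite")
        if not self.l_max >= self.l_min >= 0:
            raise ValueError("require l_max >= l_min >= 0")


def estimate_lipschitz(model: TrainedMLM, tokens: np.ndarray, n_pairs: int,
                       rng: np.random.Generator,
                       age_step_years: float | None = None) -> LipschitzEstimate:
    """Empirical Lipschitz ratio of contextual embeddings to one-token changes.

    For each sampled cell, either one gene's bin token is moved by one bin
    level (input displacement ``dx = 1``) or the age token by one bin
    (time displacement ``dt`` = bin width in years), or both; the embedding
    displacement is measured at the perturbed gene position (or the age
    position for pure age perturbations).  Perturbations that leave the
    token unchanged are excluded as zero-displacement pairs.
    """
    vocab = model.vocab
    tokens = np.asarray(tokens)
    if age_step_years is None:
        mids = np.asarray(vocab.age_midpoints)
        age_step_years = float(mids[1] - mids[0]) if len(mids) > 1 else 1.0
    n_genes = model.seq_len - N_META_POSITIONS
    originals, perturbed, denoms, positions = [], [], [], []
    attempts = 0
    while len(originals) < n_pairs and attempts < 20 * n_pairs:
        attempts += 1
        seq = tokens[rng.integers(len(tokens))].copy()
        mode = rng.integers(3)  # 0: gene token, 1: age token, 2: both
        new = seq.copy()
        dx, dt = 0.0, 0.0
        pos = AGE_POS
        if mode in (0, 2):
            pos = int(N_META_POSITIONS + rng.integers(n_genes))
            b = int(new[pos] - vocab.value_offset)
            step = 1 if (b == 0 or (b < vocab.n_value_bins and rng.random() < 0.5)) else -1
            nb = b + step
            if not 0 <= nb <= vocab.n_value_bins:
                continue
            new[pos] = vocab.value_token(nb)
            dx = 1.0
        if mode in (1, 2):
            a = int(new[AGE_POS] - vocab.age_offset)
            step = 1 if (a == 0 or (a < vocab.n_age_bins - 1 and rng.random() < 0.5)) else -1
            na = a + step
            if not 0 <= na < vocab.n_age_bins:
                continue
            new[AGE_POS] = vocab.age_token(na)
            dt = age_step_years
            if mode == 1:
                pos = AGE_POS
        if np.array_equal(new, seq):  # zero perturbation: ratio undefined
            continue
        originals.append(seq)
        perturbed.append(new)
        denoms.append(dx + dt)
        positions.append(pos)
    if not originals:
        raise ValueError("no valid perturbation pairs sampled")
    e0 = contextual_embeddings(model, np.asarray(originals))
    e1 = contextual_embeddings(model, np.asarray(perturbed))
    idx = np.arange(len(originals))
    disp = np.linalg.norm(
        e1[idx, np.asarray(positions), :] - e0[idx, np.asarray(positions), :], axis=1
    )
    ratios = disp / np.asarray(denoms)
    return LipschitzEstimate(
        l_max=float(ratios.max()), l_min=float(ratios.min()), n_pairs=len(ratios)
    )
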