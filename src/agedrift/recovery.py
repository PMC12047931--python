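"""Parameter-recovery evaluation on synthetic corpora with planted ground truth.

Runs the full chain — simulate, tokenize, train, analyze — for one seed and
scores how well each analysis recovers what was planted: the
conservative/dissipative labels (balanced accuracy of the drift
classification), chronological age (Pearson r of the masked-age-token clock
on held-out cells, with a permuted-label control), the age-increasing
transcriptional noise (Spearman rank correlation of per-bin mean entropy in
the noise-ramp tissue), and the disease-induced stability flips (log odds
of planted flipped genes among conservative-to-dissipative label changes).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import dissipation as dis_mod
from .clock import build_age_gap_table, predict_age
from .embeddings import gene_age_embeddings, select_stratum
from .entropy import entropy_by_age, reconstruction_entropy_profile
from .mlm import ModelConfig, TrainedMLM, init_model, train
from .synthetic_corpus import ExpressionStudy, SimulationConfig, simulate_corpus
from .tokenizer import build_vocabulary, encode_study

__all__ = ["RecoveryResult", "recovery_run", "balanced_accuracy", "flip_enrichment"]

DEFAULT_BINS = 8


def balanced_accuracy(predicted: set, planted: set, universe: set) -> float:
    """Mean of sensitivity and specificity of a predicted label set."""
    negatives = universe - planted
    tp = len(predicted & planted)
    tn = len(negatives - predicted)
    sens = tp / len(planted) if planted else np.nan
    spec = tn / len(negatives) if negatives else np.nan
    return 0.5 * (sens + spec)


def flip_enrichment(cd_genes: set, flipped: set, universe: set) -> dict:
    """2x2 association of C->D label changes with planted disease flips.

    Returns the contingency counts and the (Haldane-corrected) log odds
    ratio; a positive log odds means flipped genes are enriched among C->D
    changes.
    """
    a = len(cd_genes & flipped)
    b = len(cd_genes - flipped)
    c = len(flipped - cd_genes)
    d = len(universe) - a - b - c
    log_odds = float(np.log((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))))
    return {"a": a, "b": b, "c": c, "d": d, "log_odds": log_odds}


@dataclass
class RecoveryResult:
    seed: int
    study: ExpressionStudy | None
    tokens: np.ndarray | None
    model: TrainedMLM | None
    loss_trace: pd.DataFrame
    eval_idx: np.ndarray
    balanced_accuracy: float
    classification: dis_mod.ClassificationResult
    contrast: pd.DataFrame | None = None
    flip_stats: dict | None = None
    clock_r: float | None = None
    clock_permuted_r: float | None = None
    clock_records: pd.DataFrame | None = None
    entropy_spearman: float | None = None
    entropy_disease_diff: float | None = None
    entropy_table: pd.DataFrame | None = None


def _gene_index(gene_ids: list[str]) -> dict[str, int]:
    return {g: i for i, g in enumerate(gene_ids)}


def recovery_run(seed: int,
                 sim: SimulationConfig | None = None,
                 model_cfg: ModelConfig | None = None,
                 n_bins: int = DEFAULT_BINS,
                 q: float = 80.0,
                 min_cells: int = 20,
                 holdout_fraction: float = 0.1,
                 do_clock: bool = True,
                 do_entropy: bool = True,
                 do_contrast: bool = True,
                 entropy_max_cells: int = 1800,
                 keep_artifacts: bool = True) -> RecoveryResult:
    """One full seeded recovery experiment at the default study conditions.

    The last ``holdout_fraction`` of cells (after the simulator's own row
    shuffle) is excluded from training and used to evaluate the clock.
    """
    sim = dataclasses.replace(sim or SimulationConfig(), seed=seed)
    study = simulate_corpus(sim)
    vocab = build_vocabulary(study, n_bins)
    tokens = encode_study(study, vocab)
    n_hold = int(round(holdout_fraction * study.n_cells))
    train_tokens = tokens[:-n_hold] if n_hold else tokens
    eval_idx = np.arange(study.n_cells - n_hold, study.n_cells)
    model_cfg = dataclasses.replace(model_cfg or ModelConfig(), seed=seed)
    model = init_model(vocab, tokens.shape[1], model_cfg)
    model, trace = train(model, train_tokens, model_cfg)

    meta = study.cell_meta
    gt = study.ground_truth
    age_bins = meta["age_bin"].to_numpy()
    gidx = _gene_index(study.gene_ids)

    # --- conservative/dissipative recovery --------------------------------
    trajs = gene_age_embeddings(model, tokens, age_bins, study.gene_ids,
                                min_cells=min_cells)
    profiles = [dis_mod.drift_profile(tr) for tr in trajs.values()]
    classification = dis_mod.classify_genes(profiles, q)
    predicted = {gidx[g] for g in classification.dissipative}
    ba = balanced_accuracy(predicted, gt.dissipative_genes,
                           set(range(study.n_genes)))
    result = RecoveryResult(seed=seed, study=study, tokens=tokens, model=model,
                            loss_trace=trace, eval_idx=eval_idx,
                            balanced_accuracy=ba, classification=classification)

    # --- disease contrast ---------------------------------------------------
    if do_contrast:
        ph = _stratum_profiles(model, tokens, meta, study.gene_ids, min_cells,
                               disease=0, stratum="healthy")
        pdz = _stratum_profiles(model, tokens, meta, study.gene_ids, min_cells,
                                disease=1, stratum="diseased")
        contrast = dis_mod.condition_contrast(ph, pdz, q)
        cd = {gidx[g] for g in contrast.loc[contrast["change"] == "C->D", "gene"]}
        result.contrast = contrast
        result.flip_stats = flip_enrichment(cd, gt.disease_flipped_genes,
                                            set(range(study.n_genes)))

    # --- aging clock on held-out cells -------------------------------------
    if do_clock and len(eval_idx):
        predicted_age = predict_age(model, tokens[eval_idx])
        records = build_age_gap_table(meta.iloc[eval_idx].reset_index(drop=True),
                                      predicted_age)
        true = records["true_age"].to_numpy()
        result.clock_r = float(stats.pearsonr(true, predicted_age).statistic)
        perm_rng = np.random.default_rng(seed + 10_000)
        result.clock_permuted_r = float(
            stats.pearsonr(perm_rng.permutation(true), predicted_age).statistic
        )
        result.clock_records = records

    # --- entropy in the noise-ramp tissue -----------------------------------
    if do_entropy:
        ramp = sorted(gt.noise_ramp_tissues)[0]
        rng = np.random.default_rng(seed + 20_000)
        sel = np.flatnonzero(meta["tissue"].to_numpy() == ramp)
        if len(sel) > entropy_max_cells:
            sel = np.sort(rng.choice(sel, size=entropy_max_cells, replace=False))
        records = reconstruction_entropy_profile(
            model, tokens[sel], meta.iloc[sel].reset_index(drop=True), rng,
            n_draws=2,
        )
        table = entropy_by_age(records)
        result.entropy_table = table
        result.entropy_spearman = table.attrs["spearman_pooled"]
        h = table[table["disease"] == 0].set_index("age_bin")["mean"]
        d = table[table["disease"] == 1].set_index("age_bin")["mean"]
        common = h.index.intersection(d.index)
        if len(common):
            result.entropy_disease_diff = float((d[common] - h[common]).mean())

    model.net.free_buffers()
    if not keep_artifacts:
        # keep only the scalar metrics and small tables (several runs are
        # often held in memory at once)
        result.study = None
        result.tokens = None
        result.model = None
    return result


def _stratum_profiles(model, tokens, meta, gene_ids, min_cells, disease, stratum):
    sel = select_stratum(meta, disease=disease)
    bins = meta["age_bin"].to_numpy()[sel]
    trajs = gene_age_embeddings(model, tokens[sel], bins, gene_ids,
                                stratum=stratum, min_cells=min_cells)
    return [dis_mod.drift_profile(tr) for tr in trajs.values()]
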