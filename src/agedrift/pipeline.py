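"""Deterministic pipeline: simulate -> tokenize -> train -> clock/embeddings/drift/entropy.

Each stage reads its inputs from the artifact directory, writes TSV/NPZ
outputs there, and records itself in ``manifest.json`` together with the
derived stage seed and output hashes.  A single global seed fans out to
per-stage seeds through a fixed hash derivation, so every stage is
independently reproducible; re-running a stage with unchanged inputs is a
no-op (hash match).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clock as clock_mod
from . import dissipation as dis_mod
from . import entropy as ent_mod
from .embeddings import (age_token_trajectory, binned_position_means,
                         gene_age_embeddings, gene_age_similarity_trajectory,
                         select_stratum, token_similarity_ranking,
                         trajectories_to_frame)
from .mlm import ModelConfig, init_model, load_model, save_model, train
from .synthetic_corpus import SimulationConfig, simulate_corpus, read_study, write_study
from .tokenizer import build_vocabulary, encode_study

logger = logging.getLogger("agedrift")

STAGES = ["simulate", "tokenize", "train", "clock", "embeddings", "dissipation", "entropy"]


@dataclass
class PipelineConfig:
    outdir: Path
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    n_expression_bins: int = 8
    q_percentile: float = 80.0
    min_cells: int = 20
    genes_per_cell_entropy: int = 24
    entropy_max_cells: int = 1800
    clock_eval_fraction: float = 0.2
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Fixed per-stage seed derivation (stage-name hashing), below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: PipelineConfig, stage: str) -> str:
    payload = json.dumps(
        {
            "sim": dataclasses.asdict(cfg.sim),
            "model": dataclasses.asdict(cfg.model),
            "analysis": [cfg.n_expression_bins, cfg.q_percentile, cfg.min_cells,
                         cfg.genes_per_cell_entropy, cfg.entropy_max_cells,
                         cfg.clock_eval_fraction],
            "seed": cfg.seed,
            "stage": stage,
        },
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


class Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = json.loads(path.read_text()) if path.exists() else {"stages": {}}

    def record(self, stage: str, cfg_hash: str, seed: int, outputs: list[Path]) -> None:
        self.data["stages"][stage] = {
            "config_hash": cfg_hash,
            "seed": seed,
            "outputs": {p.name: _hash_file(p) for p in outputs},
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))

    def up_to_date(self, stage: str, cfg_hash: str, outdir: Path) -> bool:
        rec = self.data["stages"].get(stage)
        if rec is None or rec["config_hash"] != cfg_hash:
            return False
        return all(
            (outdir / name).exists() and _hash_file(outdir / name) == h
            for name, h in rec["outputs"].items()
        )


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> Path:
    """Run the selected stages; returns the artifact directory.

    Raises ``FileNotFoundError`` when a selected stage's upstream artifact is
    missing (and its producing stage was not selected).
    """
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out / "manifest.json")
    runners = {
        "simulate": _run_simulate,
        "tokenize": _run_tokenize,
        "train": _run_train,
        "clock": _run_clock,
        "embeddings": _run_embeddings,
        "dissipation": _run_dissipation,
        "entropy": _run_entropy,
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        ch = _config_hash(cfg, stage)
        if not force and manifest.up_to_date(stage, ch, out):
            logger.info("stage %s up to date; skipping", stage)
            continue
        logger.info("running stage %s", stage)
        outputs = runners[stage](cfg, out)
        manifest.record(stage, ch, stage_seed(cfg.seed, stage), outputs)
    return out


# --------------------------------------------------------------------- stages

def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the '{producer}' stage first"
        )
    return path


def _load_study(out: Path):
    _require(out / "study" / "counts.mtx", "simulate")
    return read_study(out / "study")


def _load_tokens(out: Path):
    path = _require(out / "tokens.npz", "tokenize")
    with np.load(path) as data:
        return data["tokens"]


def _run_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    sim = dataclasses.replace(cfg.sim, seed=stage_seed(cfg.seed, "simulate"))
    study = simulate_corpus(sim)
    write_study(study, out / "study")
    return sorted((out / "study").glob("*"))


def _run_tokenize(cfg: PipelineConfig, out: Path) -> list[Path]:
    study = _load_study(out)
    vocab = build_vocabulary(study, cfg.n_expression_bins)
    tokens = encode_study(study, vocab)
    np.savez_compressed(out / "tokens.npz", tokens=tokens)
    vocab.to_tsv(out / "vocabulary.tsv")
    return [out / "tokens.npz", out / "vocabulary.tsv"]


def _run_train(cfg: PipelineConfig, out: Path) -> list[Path]:
    study = _load_study(out)
    tokens = _load_tokens(out)
    vocab = build_vocabulary(study, cfg.n_expression_bins)
    mcfg = dataclasses.replace(cfg.model, seed=stage_seed(cfg.seed, "train"))
    model = init_model(vocab, tokens.shape[1], mcfg)
    model, trace = train(model, tokens, mcfg)
    save_model(model, out / "checkpoint")
    trace.to_csv(out / "loss_trace.tsv", sep="\t", index=False)
    return [out / "checkpoint.npz", out / "checkpoint.json", out / "loss_trace.tsv"]


def _load_model(out: Path):
    _require(out / "checkpoint.npz", "train")
    return load_model(out / "checkpoint")


def _run_clock(cfg: PipelineConfig, out: Path) -> list[Path]:
    study = _load_study(out)
    tokens = _load_tokens(out)
    model = _load_model(out)
    rng = np.random.default_rng(stage_seed(cfg.seed, "clock"))
    n_eval = max(int(round(cfg.clock_eval_fraction * study.n_cells)), 10)
    eval_idx = rng.choice(study.n_cells, size=min(n_eval, study.n_cells), replace=False)
    predicted = clock_mod.predict_age(model, tokens[eval_idx])
    records = clock_mod.build_age_gap_table(
        study.cell_meta.iloc[eval_idx].reset_index(drop=True), predicted
    )
    records = clock_mod.age_gap_zscores(records)
    records.to_csv(out / "clock_records.tsv", sep="\t", index=False)
    groups = clock_mod.group_correlation(records, "tissue")
    groups.to_csv(out / "clock_by_tissue.tsv", sep="\t", index=False)
    profile = clock_mod.gap_by_age_profile(records)
    profile.to_csv(out / "clock_gap_profile.tsv", sep="\t", index=False)
    return [out / "clock_records.tsv", out / "clock_by_tissue.tsv",
            out / "clock_gap_profile.tsv"]


def _run_embeddings(cfg: PipelineConfig, out: Path) -> list[Path]:
    study = _load_study(out)
    tokens = _load_tokens(out)
    model = _load_model(out)
    meta = study.cell_meta
    age_bins = meta["age_bin"].to_numpy()
    pre = binned_position_means(model, tokens, age_bins)
    trajs = gene_age_embeddings(model, tokens, age_bins, study.gene_ids,
                                min_cells=cfg.min_cells, _precomputed=pre)
    ages = age_token_trajectory(model, tokens, age_bins, min_cells=cfg.min_cells,
                                _precomputed=pre)
    trajectories_to_frame(trajs).to_csv(out / "gene_trajectories.tsv", sep="\t",
                                        index=False, float_format="%.6g")
    sim_rows = []
    for gene, tr in trajs.items():
        curve = gene_age_similarity_trajectory(tr, ages)
        curve.insert(0, "gene", gene)
        sim_rows.append(curve)
    pd.concat(sim_rows, ignore_index=True).to_csv(
        out / "gene_age_similarity.tsv", sep="\t", index=False, float_format="%.6g"
    )
    token_similarity_ranking(model, "tissue").to_csv(
        out / "similarity_tissue.tsv", sep="\t", index=False
    )
    token_similarity_ranking(model, "cell_type").to_csv(
        out / "similarity_cell_type.tsv", sep="\t", index=False
    )
    return [out / "gene_trajectories.tsv", out / "gene_age_similarity.tsv",
            out / "similarity_tissue.tsv", out / "similarity_cell_type.tsv"]


def drift_profiles_for_stratum(model, tokens, meta, gene_ids, min_cells, sel,
                               stratum: str):
    """Trajectories -> drift profiles for the cells selected by ``sel``."""
    age_bins = meta["age_bin"].to_numpy()[sel]
    trajs = gene_age_embeddings(model, tokens[sel], age_bins, gene_ids,
                                stratum=stratum, min_cells=min_cells)
    return [dis_mod.drift_profile(tr) for tr in trajs.values()]


def _run_dissipation(cfg: PipelineConfig, out: Path) -> list[Path]:
    study = _load_study(out)
    tokens = _load_tokens(out)
    model = _load_model(out)
    meta = study.cell_meta
    profiles_all = drift_profiles_for_stratum(
        model, tokens, meta, study.gene_ids, cfg.min_cells,
        np.ones(len(meta), bool), "all")
    result = dis_mod.classify_genes(profiles_all, cfg.q_percentile)
    labels = result.labels.copy()
    labels["delta"] = result.delta
    labels["q"] = result.q
    labels.to_csv(out / "classification.tsv", sep="\t", index=False)
    healthy = select_stratum(meta, disease=0)
    diseased = select_stratum(meta, disease=1)
    files = [out / "classification.tsv"]
    if healthy.any() and diseased.any():
        ph = drift_profiles_for_stratum(model, tokens, meta, study.gene_ids,
                                        cfg.min_cells, healthy, "healthy")
        pdz = drift_profiles_for_stratum(model, tokens, meta, study.gene_ids,
                                         cfg.min_cells, diseased, "diseased")
        contrast = dis_mod.condition_contrast(ph, pdz, cfg.q_percentile)
        contrast.to_csv(out / "condition_contrast.tsv", sep="\t", index=False)
        files.append(out / "condition_contrast.tsv")
    rng = np.random.default_rng(stage_seed(cfg.seed, "dissipation"))
    lip = dis_mod.estimate_lipschitz(model, tokens, n_pairs=200, rng=rng)
    pd.DataFrame([{"l_max": lip.l_max, "l_min": lip.l_min, "n_pairs": lip.n_pairs}]
                 ).to_csv(out / "lipschitz.tsv", sep="\t", index=False)
    files.append(out / "lipschitz.tsv")
    return files


def _run_entropy(cfg: PipelineConfig, out: Path) -> list[Path]:
    study = _load_study(out)
    tokens = _load_tokens(out)
    model = _load_model(out)
    meta = study.cell_meta
    rng = np.random.default_rng(stage_seed(cfg.seed, "entropy"))
    gt = study.ground_truth
    ramp = sorted(gt.noise_ramp_tissues)[0] if gt and gt.noise_ramp_tissues else 0
    sel = np.flatnonzero(meta["tissue"].to_numpy() == ramp)
    if len(sel) > cfg.entropy_max_cells:
        sel = np.sort(rng.choice(sel, size=cfg.entropy_max_cells, replace=False))
    records = ent_mod.reconstruction_entropy_profile(
        model, tokens[sel], meta.iloc[sel].reset_index(drop=True), rng,
        n_draws=1,
    )
    records.to_csv(out / "entropy_records.tsv", sep="\t", index=False,
                   float_format="%.6g")
    table = ent_mod.entropy_by_age(records)
    table.to_csv(out / "entropy_summary.tsv", sep="\t", index=False)
    spearman = {str(k): v for k, v in table.attrs["spearman"].items()}
    spearman["pooled"] = table.attrs["spearman_pooled"]
    with open(out / "entropy_spearman.json", "w") as fh:
        json.dump(spearman, fh, indent=1)
    return [out / "entropy_records.tsv", out / "entropy_summary.tsv",
            out / "entropy_spearman.json"]
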