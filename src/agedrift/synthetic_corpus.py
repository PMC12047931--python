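"""Seeded synthetic single-cell corpora with planted conservative/dissipative gene dynamics.

The generator emulates the statistical structure that the embedding-drift
analysis exploits in real aging atlases:

* discrete age bins spanning a lifespan, several tissues and cell types,
  and a binary healthy/diseased flag;
* gene co-expression modules whose activities vary smoothly with age;
* *conservative* genes whose module loading is constant in age, versus
  *dissipative* genes whose loading rotates between two modules across one
  or two age breakpoints — their contextual role (and marginal log-mean)
  drifts with age;
* a subset of conservative genes that become dissipative only in diseased
  cells (disease-induced stability flips);
* designated "noise-ramp" tissues whose negative-binomial dispersion grows
  linearly with age, planting an age-increasing transcriptional noise
  signal.

Counts are negative binomial (gamma–Poisson); the latent log-mean matrix is
kept on the study object so tests can verify the planted signal directly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ExpressionStudy",
    "simulate_corpus",
    "write_study",
    "read_study",
]

LIFESPAN_YEARS = 80.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic corpus generator.

    All proportions are in [0, 1]; all counts at least 1; ``n_age_bins >= 3``
    (a baseline bin plus at least two later bins). Identical config + seed
    yields a bit-identical study.
    """

    n_genes: int = 200
    n_cells: int = 5000
    n_age_bins: int = 10
    n_tissues: int = 3
    n_cell_types: int = 4
    diseased_fraction: float = 0.25
    frac_dissipative: float = 0.2
    n_modules: int = 8
    effect_size: float = 1.0
    nb_dispersion_base: float = 0.15
    noise_age_slope: float = 0.3
    disease_flip_fraction: float = 0.25
    disease_dispersion_factor: float = 1.6
    # secondary shape parameters of the latent model (see docs/methods.md)
    activity_amplitude: float = 0.2
    module_offset_sd: float = 0.6
    module_noise_sd: float = 0.3
    tissue_offset_sd: float = 0.3
    cell_type_offset_sd: float = 0.3
    base_log_mean: float = 1.2
    base_log_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells", "n_tissues", "n_cell_types", "n_modules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_age_bins < 3:
            raise ValueError(f"n_age_bins must be >= 3, got {self.n_age_bins}")
        for name in ("diseased_fraction", "frac_dissipative", "disease_flip_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion_base <= 0:
            raise ValueError("nb_dispersion_base must be positive")

    @property
    def age_bin_width_years(self) -> float:
        return LIFESPAN_YEARS / self.n_age_bins

    def age_midpoints(self) -> np.ndarray:
        """Midpoint in years of each age bin (equal-width bins over the lifespan)."""
        w = self.age_bin_width_years
        return (np.arange(self.n_age_bins) + 0.5) * w


@dataclass
class GroundTruth:
    """Planted labels recorded by the simulator for recovery testing."""

    dissipative_genes: set[int]
    n_genes: int
    disease_flipped_genes: set[int]
    noise_ramp_tissues: set[int]
    module_of: np.ndarray  # primary module index per gene
    secondary_module: dict[int, int]  # dissipative/flipped gene -> rotation target
    breakpoints: dict[int, list[int]]  # gene -> age-bin breakpoints of the rotation

    @property
    def conservative_genes(self) -> set[int]:
        return set(range(self.n_genes)) - self.dissipative_genes

    def __post_init__(self) -> None:
        if not self.disease_flipped_genes <= self.conservative_genes:
            raise ValueError("disease_flipped_genes must be conservative genes")

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "dissipative_genes": sorted(self.dissipative_genes),
            "disease_flipped_genes": sorted(self.disease_flipped_genes),
            "noise_ramp_tissues": sorted(self.noise_ramp_tissues),
            "module_of": [int(m) for m in self.module_of],
            "secondary_module": {str(g): int(m) for g, m in sorted(self.secondary_module.items())},
            "breakpoints": {str(g): list(map(int, b)) for g, b in sorted(self.breakpoints.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            dissipative_genes=set(d["dissipative_genes"]),
            n_genes=int(d["n_genes"]),
            disease_flipped_genes=set(d["disease_flipped_genes"]),
            noise_ramp_tissues=set(d["noise_ramp_tissues"]),
            module_of=np.asarray(d["module_of"], dtype=int),
            secondary_module={int(g): int(m) for g, m in d["secondary_module"].items()},
            breakpoints={int(g): list(map(int, b)) for g, b in d["breakpoints"].items()},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return self.to_dict() == other.to_dict()


#: metadata columns of a study, in file order
META_COLUMNS = ["cell_id", "age_bin", "age_years", "tissue", "cell_type", "disease"]


@dataclass
class ExpressionStudy:
    """A cell x gene count matrix with per-cell metadata and optional planted truth.

    ``counts`` is sparse CSR with non-negative integer entries; ``cell_meta``
    has one row per cell with columns ``cell_id, age_bin, age_years, tissue,
    cell_type, disease``.  For synthetic studies ``log_mean`` carries the
    latent log-mean matrix used to generate the counts (not serialized).
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_ids: list[str]
    ground_truth: Optional[GroundTruth] = None
    log_mean: Optional[np.ndarray] = None
    config: Optional[SimulationConfig] = None

    def __post_init__(self) -> None:
        if self.counts.shape[0] != len(self.cell_meta):
            raise ValueError(
                f"counts has {self.counts.shape[0]} rows but cell_meta has "
                f"{len(self.cell_meta)} rows"
            )
        if self.counts.shape[1] != len(self.gene_ids):
            raise ValueError(
                f"counts has {self.counts.shape[1]} columns but {len(self.gene_ids)} gene ids"
            )
        if (self.counts.data < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_age_bins(self) -> int:
        return int(self.cell_meta["age_bin"].max()) + 1

    def age_midpoints(self) -> np.ndarray:
        """Midpoints in years of the age bins present in the study, by bin index."""
        out = np.zeros(self.n_age_bins)
        grouped = self.cell_meta.groupby("age_bin")["age_years"].first()
        out[grouped.index.to_numpy()] = grouped.to_numpy()
        return out


def _smooth_step(t: np.ndarray, breakpoint: float, width: float = 0.7) -> np.ndarray:
    """Logistic ramp 0 -> 1 centred on an age-bin breakpoint."""
    return 1.0 / (1.0 + np.exp(-(t - breakpoint) / width))


def simulate_corpus(config: SimulationConfig) -> ExpressionStudy:
    """Generate a seeded synthetic study with planted ground truth.

    Latent model: gene ``g`` carries loading ``lam_g`` on a primary module;
    module activities ``a_m(t) = o_m + A sin(2 pi f_m t/(T-1) + phi_m)`` vary
    smoothly over age bins around a static offset, plus per-cell module noise.
    Conservative genes keep their loading fixed; dissipative genes rotate
    their loading from the primary to a secondary module through
    ``theta_g(t) = effect_size * (pi/2) * ramp_g(t)`` where ``ramp_g`` is a sum
    of logistic steps at 1–2 breakpoints.  Counts are negative binomial with
    mean ``exp(mu)`` and dispersion ``alpha`` (variance ``m + alpha m^2``);
    dispersion ramps with age in noise-ramp tissues and is inflated in
    diseased cells.

    Raises
    ------
    ValueError
        If ``n_cells`` is smaller than the number of
        (age bin x tissue x disease) strata, naming the first stratum that
        cannot be populated.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_age_bins

    # ---- cell metadata with guaranteed stratum coverage -------------------
    n_disease_levels = 2 if 0.0 < cfg.diseased_fraction < 1.0 else 1
    strata = [
        (b, tis, dz)
        for b in range(T)
        for tis in range(cfg.n_tissues)
        for dz in ((0, 1) if n_disease_levels == 2 else (int(cfg.diseased_fraction >= 1.0),))
    ]
    if cfg.n_cells < len(strata):
        missing = strata[cfg.n_cells]
        raise ValueError(
            f"n_cells={cfg.n_cells} cannot populate the {len(strata)} "
            f"(age_bin x tissue x disease) strata; stratum "
            f"(age_bin={missing[0]}, tissue={missing[1]}, disease={missing[2]}) "
            "would be empty"
        )
    age_bin = rng.integers(0, T, size=cfg.n_cells)
    tissue = rng.integers(0, cfg.n_tissues, size=cfg.n_cells)
    disease = (rng.random(cfg.n_cells) < cfg.diseased_fraction).astype(np.int64)
    # overwrite the first len(strata) cells so every stratum is populated,
    # then shuffle the row order so position carries no information
    for i, (b, tis, dz) in enumerate(strata):
        age_bin[i], tissue[i], disease[i] = b, tis, dz
    order = rng.permutation(cfg.n_cells)
    age_bin, tissue, disease = age_bin[order], tissue[order], disease[order]
    cell_type = rng.integers(0, cfg.n_cell_types, size=cfg.n_cells)

    midpoints = cfg.age_midpoints()

    # ---- planted gene labels ---------------------------------------------
    n_dis = int(round(cfg.frac_dissipative * cfg.n_genes))
    dissipative = set(map(int, rng.choice(cfg.n_genes, size=n_dis, replace=False)))
    conservative = sorted(set(range(cfg.n_genes)) - dissipative)
    n_flip = int(round(cfg.disease_flip_fraction * len(conservative)))
    flipped = set(map(int, rng.choice(conservative, size=n_flip, replace=False))) if n_flip else set()
    noise_ramp_tissues = {0} if cfg.n_tissues >= 1 else set()

    module_of = rng.integers(0, cfg.n_modules, size=cfg.n_genes)
    lam = rng.lognormal(mean=0.0, sigma=0.3, size=cfg.n_genes)
    secondary: dict[int, int] = {}
    breakpoints: dict[int, list[int]] = {}
    for g in sorted(dissipative | flipped):
        if cfg.n_modules > 1:
            shift = int(rng.integers(1, cfg.n_modules))
            secondary[g] = int((module_of[g] + shift) % cfg.n_modules)
        else:
            secondary[g] = int(module_of[g])
        n_break = int(rng.integers(1, 3))
        lo, hi = 2, max(3, T - 1)
        bps = sorted(int(b) for b in rng.choice(np.arange(lo, hi), size=min(n_break, hi - lo), replace=False))
        breakpoints[g] = bps

    # ---- module activities ------------------------------------------------
    # module offsets are a deterministic, well-spread grid at the configured
    # scale: the offset gaps set the drift contrast of rotating genes, and
    # random draws would make that planted contrast fluctuate between
    # corpus realizations; activity frequencies/phases stay random
    if cfg.n_modules > 1:
        grid = np.linspace(-1.0, 1.0, cfg.n_modules)
        offsets = cfg.module_offset_sd * grid / grid.std()
    else:
        offsets = np.zeros(1)
    offsets = rng.permutation(offsets)
    freqs = rng.uniform(0.5, 1.0, size=cfg.n_modules)
    phases = rng.uniform(0.0, 2 * np.pi, size=cfg.n_modules)
    tgrid = np.arange(T)
    # (n_modules, T) activity at each bin
    act = offsets[:, None] + cfg.activity_amplitude * np.sin(
        2 * np.pi * freqs[:, None] * tgrid[None, :] / max(T - 1, 1) + phases[:, None]
    )
    cell_act = act[:, age_bin].T + rng.normal(
        0.0, cfg.module_noise_sd, size=(cfg.n_cells, cfg.n_modules)
    )  # (n_cells, n_modules)

    # ---- rotation angles per gene per bin ---------------------------------
    theta = np.zeros((cfg.n_genes, T))
    for g, bps in breakpoints.items():
        ramp = np.zeros(T)
        for b in bps:
            ramp += _smooth_step(tgrid.astype(float), b)
        theta[g] = cfg.effect_size * (np.pi / 2) * ramp

    # ---- latent log-mean ---------------------------------------------------
    base = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_genes)
    tissue_off = rng.normal(0.0, cfg.tissue_offset_sd, size=(cfg.n_tissues, cfg.n_genes))
    ct_off = rng.normal(0.0, cfg.cell_type_offset_sd, size=(cfg.n_cell_types, cfg.n_genes))

    a_primary = cell_act[:, module_of]  # (n_cells, n_genes)
    sec_idx = module_of.copy()
    for g, m2 in secondary.items():
        sec_idx[g] = m2
    a_secondary = cell_act[:, sec_idx]

    theta_cell = theta[:, :].T[age_bin, :]  # (n_cells, n_genes)
    # genes rotating only under disease: zero the angle in healthy cells;
    # genes planted dissipative rotate everywhere
    rotating = np.zeros(cfg.n_genes, dtype=bool)
    rotating[sorted(dissipative)] = True
    flip_mask = np.zeros(cfg.n_genes, dtype=bool)
    flip_mask[sorted(flipped)] = True
    active = rotating[None, :] | (flip_mask[None, :] & (disease[:, None] == 1))
    theta_eff = np.where(active, theta_cell, 0.0)

    contribution = lam[None, :] * (
        np.cos(theta_eff) * a_primary + np.sin(theta_eff) * a_secondary
    )
    log_mean = (
        base[None, :] + tissue_off[tissue, :] + ct_off[cell_type, :] + contribution
    ).astype(np.float64)

    # ---- negative-binomial sampling (gamma–Poisson) ------------------------
    alpha = np.full(cfg.n_cells, cfg.nb_dispersion_base)
    is_ramp = np.isin(tissue, sorted(noise_ramp_tissues))
    alpha = alpha * np.where(is_ramp, 1.0 + cfg.noise_age_slope * age_bin, 1.0)
    alpha = alpha * np.where(disease == 1, cfg.disease_dispersion_factor, 1.0)
    mean = np.exp(log_mean)
    shape = 1.0 / alpha[:, None]
    lam_pois = rng.gamma(shape=np.broadcast_to(shape, mean.shape), scale=mean * alpha[:, None])
    counts = rng.poisson(lam_pois).astype(np.int64)

    meta = pd.DataFrame(
        {
            "cell_id": [f"cell_{i:05d}" for i in range(cfg.n_cells)],
            "age_bin": age_bin,
            "age_years": midpoints[age_bin],
            "tissue": tissue,
            "cell_type": cell_type,
            "disease": disease,
        }
    )
    gt = GroundTruth(
        dissipative_genes=dissipative,
        n_genes=cfg.n_genes,
        disease_flipped_genes=flipped,
        noise_ramp_tissues=noise_ramp_tissues,
        module_of=module_of,
        secondary_module=secondary,
        breakpoints=breakpoints,
    )
    return ExpressionStudy(
        counts=sp.csr_matrix(counts),
        cell_meta=meta,
        gene_ids=[f"gene_{g:04d}" for g in range(cfg.n_genes)],
        ground_truth=gt,
        log_mean=log_mean.astype(np.float32),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# on-disk format: MTX counts (cells as rows) + TSV metadata + JSON ground truth
# ---------------------------------------------------------------------------

def write_study(study: ExpressionStudy, path: str | Path) -> None:
    """Write a study to a directory: counts.mtx, cell_meta.tsv, genes.tsv, ground_truth.json.

    The latent log-mean matrix, if present, is not serialized.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(str(path / "counts.mtx"), sp.coo_matrix(study.counts), field="integer")
    study.cell_meta.to_csv(path / "cell_meta.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": study.gene_ids}).to_csv(path / "genes.tsv", sep="\t", index=False)
    if study.ground_truth is not None:
        with open(path / "ground_truth.json", "w") as fh:
            json.dump(study.ground_truth.to_dict(), fh, indent=1)
    if study.config is not None:
        with open(path / "sim_config.json", "w") as fh:
            json.dump(dataclasses.asdict(study.config), fh, indent=1)


def read_study(path: str | Path) -> ExpressionStudy:
    """Read a study written by :func:`write_study`.

    Raises ``ValueError`` if the metadata row count does not match the matrix.
    """
    path = Path(path)
    counts = sp.csr_matrix(mmread(str(path / "counts.mtx")))
    meta = pd.read_csv(path / "cell_meta.tsv", sep="\t")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"cell_meta.tsv is missing columns: {missing}")
    if len(meta) != counts.shape[0]:
        raise ValueError(
            f"cell_meta.tsv has {len(meta)} rows but counts.mtx has "
            f"{counts.shape[0]} rows (cells)"
        )
    genes = pd.read_csv(path / "genes.tsv", sep="\t")["gene_id"].tolist()
    gt = None
    gt_path = path / "ground_truth.json"
    if gt_path.exists():
        with open(gt_path) as fh:
            gt = GroundTruth.from_dict(json.load(fh))
    config = None
    cfg_path = path / "sim_config.json"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            config = SimulationConfig(**json.load(fh))
    return ExpressionStudy(
        counts=counts, cell_meta=meta, gene_ids=genes, ground_truth=gt, config=config
    )
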