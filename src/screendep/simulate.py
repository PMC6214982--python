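"""Synthetic screen generation with known ground truth.

Data are drawn from the model's own generative process: parameters are
sampled from configurable effect-size distributions (with the mean-one
constraints on the scale parameters enforced at draw time), the noiseless
LFC tensor is computed from the model equation, and independent Gaussian
screen noise is added.  A designated fraction of genes is made common
essential (strongly negative across-cell-line effect); those genes double as
the positive control set, with negatives sampled from the near-zero
background genes.

The default scenario — 40 cell lines x 400 genes x 5 shRNAs/gene in one
dataset, 10% common essential, screen signal q ~ Uniform[0.5, 1.5] — is a
desk-scale stand-in for a genome-scale library that fits in minutes.
Simulation enters at the LFC level; read-count sampling is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import ControlGeneSets, ScreenDataset, TargetingMaps
from .inference import FitResult
from .model import ModelParams, gauge_rescale, predict_lfc

__all__ = ["SimConfig", "SimTruth", "RecoveryReport", "build_library",
           "draw_parameters", "simulate_screen", "simulate", "evaluate_recovery"]


@dataclass
class SimConfig:
    """Study design and effect-size distributions for the simulator.

    Effect scales are in LFC units.  ``seed`` drives every random draw.
    """

    n_cell_lines: int = 40
    n_genes: int = 400
    shrnas_per_gene: int = 5
    n_seeds: int = 150
    n_datasets: int = 1
    fraction_common_essential: float = 0.10
    essential_mean: float = -2.0
    essential_sd: float = 0.3
    background_sd: float = 0.2
    gene_dev_sd: float = 0.2
    seed_avg_sd: float = 0.3
    seed_dev_sd: float = 0.1
    batch_offset_sd: float = 0.1
    shrna_offset_sd: float = 0.1
    screen_offset_sd: float = 0.1
    q_range: tuple[float, float] = (0.5, 1.5)
    gamma_range: tuple[float, float] = (0.7, 1.3)
    noise_sd_range: tuple[float, float] = (0.3, 0.6)
    gene_efficacy_beta: tuple[float, float] = (5.0, 2.0)
    seed_efficacy_beta: tuple[float, float] = (2.0, 2.0)
    n_negative_controls: int = 80
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cell_lines", "n_genes", "shrnas_per_gene", "n_seeds", "n_datasets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.fraction_common_essential <= 1.0:
            raise ValueError("fraction_common_essential must lie in [0, 1]")
        for name in ("q_range", "gamma_range", "noise_sd_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValueError(f"{name} must be a positive, ordered range")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground-truth parameters paired with the data simulated from them."""

    config: SimConfig
    params: ModelParams
    data: ScreenDataset
    maps: TargetingMaps
    controls: ControlGeneSets
    essential_genes: tuple[str, ...]


def build_library(config: SimConfig, rng: np.random.Generator) -> TargetingMaps:
    """Synthetic shRNA library: one gene per shRNA, seeds from a shared pool.

    Each gene gets ``shrnas_per_gene`` dedicated shRNAs; each shRNA draws its
    two seed-window seeds independently from a finite pool, so seeds collide
    across shRNAs the way real 7-mers do (and the two windows occasionally
    coincide, giving a row sum of 1).
    """
    L, per = config.n_genes, config.shrnas_per_gene
    I = L * per
    gene_ids = [f"G{g:04d}" for g in range(L)]
    shrna_ids = [f"sh{i:05d}" for i in range(I)]
    seed_ids = [f"seed{s:03d}" for s in range(config.n_seeds)]
    G = sparse.csr_matrix(
        (np.ones(I), (np.arange(I), np.repeat(np.arange(L), per))), shape=(I, L)
    )
    picks = rng.integers(0, config.n_seeds, size=(I, 2))
    rows = np.repeat(np.arange(I), 2)
    B = sparse.csr_matrix(
        (np.ones(2 * I), (rows, picks.ravel())), shape=(I, config.n_seeds)
    )
    B.data = np.minimum(B.data, 1.0)  # coinciding windows collapse to one seed
    return TargetingMaps(
        gene_matrix=G, seed_matrix=B, shrna_ids=shrna_ids,
        gene_ids=gene_ids, seed_ids=seed_ids,
    )


def draw_parameters(
    config: SimConfig, maps: TargetingMaps, rng: np.random.Generator
) -> tuple[ModelParams, np.ndarray]:
    """Sample ground-truth parameters; returns (params, essential gene mask)."""
    L, J, K = config.n_genes, config.n_cell_lines, config.n_datasets
    I, S = maps.n_shrnas, maps.n_seeds
    C = J * K

    n_ess = int(round(config.fraction_common_essential * L))
    essential = np.zeros(L, dtype=bool)
    essential[rng.choice(L, size=n_ess, replace=False)] = True
    gene_avg = rng.normal(0.0, config.background_sd, size=L)
    gene_avg[essential] = rng.normal(config.essential_mean, config.essential_sd, size=n_ess)

    q = rng.uniform(*config.q_range, size=J)
    q = q / q.mean()
    gamma = rng.uniform(*config.gamma_range, size=C)
    gamma = gamma / gamma.mean()
    noise_sd = rng.uniform(*config.noise_sd_range, size=C)

    # Efficacy is identified only relative to the gene effect (their product
    # enters the likelihood), so it is drawn in the model's identified gauge:
    # per gene, relative to the most effective targeting reagent.
    alpha = np.clip(rng.beta(*config.gene_efficacy_beta, size=I), 0.0, 1.0)
    Gd = maps.gene_matrix.tocsc()
    for gi in range(L):
        rows = Gd.indices[Gd.indptr[gi] : Gd.indptr[gi + 1]]
        peak = alpha[rows].max()
        if peak > 0:
            alpha[rows] = alpha[rows] / peak

    params = ModelParams(
        gene_avg=gene_avg,
        gene_dev=rng.normal(0.0, config.gene_dev_sd, size=(L, J)),
        seed_avg=rng.normal(0.0, config.seed_avg_sd, size=S),
        seed_dev=rng.normal(0.0, config.seed_dev_sd, size=(S, J)),
        batch_offset=rng.normal(0.0, config.batch_offset_sd, size=(I, K)),
        shrna_offset=rng.normal(0.0, config.shrna_offset_sd, size=I),
        screen_offset=rng.normal(0.0, config.screen_offset_sd, size=C),
        screen_scale=gamma,
        screen_signal=q,
        gene_efficacy=alpha,
        seed_efficacy=np.clip(rng.beta(*config.seed_efficacy_beta, size=I), 0.0, 1.0),
        noise_var=noise_sd**2,
    )
    return params, essential


def _screen_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for k in range(config.n_datasets):
        for j in range(config.n_cell_lines):
            rows.append({"cell_line": f"CL{j:03d}", "dataset": f"DS{k}"})
    return pd.DataFrame(rows)


def simulate_screen(
    params: ModelParams,
    maps: TargetingMaps,
    config: SimConfig,
    rng: np.random.Generator,
) -> ScreenDataset:
    """Noiseless model prediction plus independent per-screen Gaussian noise."""
    screens = _screen_table(config)
    skeleton = ScreenDataset(
        lfc=np.zeros((maps.n_shrnas, len(screens))),
        mask=np.ones((maps.n_shrnas, len(screens)), dtype=bool),
        shrna_ids=list(maps.shrna_ids),
        screens=screens,
    )
    clean = predict_lfc(params, maps, skeleton)
    noise = rng.normal(0.0, np.sqrt(params.noise_var)[None, :], size=clean.shape)
    mask = np.ones_like(clean, dtype=bool)
    if config.missing_fraction > 0:
        mask &= rng.random(clean.shape) >= config.missing_fraction
    return ScreenDataset(
        lfc=clean + noise, mask=mask,
        shrna_ids=list(maps.shrna_ids), screens=screens,
    )


def simulate(config: SimConfig) -> SimTruth:
    """Full generative draw: library, parameters, data and control sets."""
    rng = np.random.default_rng(config.seed)
    maps = build_library(config, rng)
    params, essential = draw_parameters(config, maps, rng)
    data = simulate_screen(params, maps, config, rng)
    ess_ids = tuple(g for g, e in zip(maps.gene_ids, essential) if e)
    background = [g for g, e in zip(maps.gene_ids, essential) if not e]
    n_neg = min(config.n_negative_controls, len(background))
    if not ess_ids or n_neg == 0:
        raise ValueError("control sets require both essential and background genes")
    neg_ids = tuple(rng.choice(background, size=n_neg, replace=False))
    return SimTruth(
        config=config,
        params=params,
        data=data,
        maps=maps,
        controls=ControlGeneSets(positive=ess_ids, negative=neg_ids),
        essential_genes=ess_ids,
    )


@dataclass
class RecoveryReport:
    """Truth-vs-estimate summaries per parameter family."""

    bias: dict[str, float] = field(default_factory=dict)
    rmse: dict[str, float] = field(default_factory=dict)
    pearson_r: dict[str, float] = field(default_factory=dict)
    calibration_z_sd: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        fams = sorted(self.bias)
        return pd.DataFrame(
            {
                "bias": [self.bias[f] for f in fams],
                "rmse": [self.rmse[f] for f in fams],
                "pearson_r": [self.pearson_r[f] for f in fams],
            },
            index=fams,
        )


def _gauge_fix(params: ModelParams) -> ModelParams:
    """Resolve the rescaling gauges: mean(q) = 1 and mean(gamma) = 1."""
    out = gauge_rescale(params, float(params.screen_signal.mean()), which="signal")
    out = gauge_rescale(out, float(out.screen_scale.mean()), which="scale")
    return out


def evaluate_recovery(truth: SimTruth, fit: FitResult) -> RecoveryReport:
    """Bias, RMSE, Pearson r and posterior calibration of a fit on sim data.

    Both parameter sets are gauge-fixed to mean(q) = mean(gamma) = 1 before
    comparison; the calibration statistic is the SD of
    (estimate - truth) / posterior SD over the total gene effects.
    """
    t = _gauge_fix(truth.params)
    e = _gauge_fix(fit.params)
    if t.gene_dev.shape != e.gene_dev.shape:
        raise ValueError("truth and fit dimensions differ")
    report = RecoveryReport()

    pairs = {
        "gene_total": (t.gene_effect_matrix().ravel(), e.gene_effect_matrix().ravel()),
        "gene_avg": (t.gene_avg, e.gene_avg),
        "seed_total": (t.seed_effect_matrix().ravel(), e.seed_effect_matrix().ravel()),
        "screen_signal": (t.screen_signal, e.screen_signal),
        "screen_scale": (t.screen_scale, e.screen_scale),
    }
    for fam, (tv, ev) in pairs.items():
        err = ev - tv
        report.bias[fam] = float(err.mean())
        report.rmse[fam] = float(np.sqrt((err**2).mean()))
        report.pearson_r[fam] = float(np.corrcoef(tv, ev)[0, 1]) if tv.size > 1 else 1.0

    post_var = (
        fit.posterior.variances["gene_avg"][:, None] + fit.posterior.variances["gene_dev"]
    )
    z = (e.gene_effect_matrix() - t.gene_effect_matrix()) / np.sqrt(post_var)
    report.calibration_z_sd = float(z.std())
    return report
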