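"""Generative model for pooled RNAi screen depletion scores.

The observed LFC of shRNA ``i`` in screen (cell line ``j``, dataset ``k``) is
modeled as

    D[ijk] = a[jk] + theta[ik]
             + gamma[jk] * ( q[j] * alpha[i] * sum_l G[il] (gbar[l] + g[lj])
                             + beta[i] * sum_s B[is] (bbar[s] + b[sj])
                             + c[i] )
             + eps[ijk],        eps ~ Normal(0, sigma2[jk])

where ``gbar``/``g`` are across-cell-line average and cell-line specific gene
knockdown effects, ``bbar``/``b`` the analogous seed (off-target) effects,
``alpha``/``beta`` per-shRNA on-/off-target efficacies in [0, 1], ``q`` the
per-cell-line screen signal (scaling only the gene term), ``gamma``/``a``
per-screen scale and offset, ``theta`` a per-(shRNA, dataset) offset for
reference-measurement error, and ``c`` a per-shRNA offset for unmodeled
off-target effects.

The model is invariant to the joint rescaling ``q -> q/f`` with
``(gbar + g) -> f (gbar + g)`` (and analogously ``gamma`` against the whole
bracket), so both scale-parameter sets are constrained to average one.

Zero-mean Gaussian priors are placed on the hierarchically-modeled set
``Theta = {gbar, g, bbar, b, theta, c, a}`` (posterior-approximated); the
point-estimated set ``Psi = {q, gamma, alpha, beta, sigma2}`` carries flat
priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .containers import ScreenDataset, TargetingMaps

__all__ = [
    "ModelParams",
    "Hyperparams",
    "PosteriorApprox",
    "THETA_FIELDS",
    "predict_lfc",
    "predict_entry",
    "log_posterior",
    "gauge_rescale",
]

#: names of the posterior-approximated parameter families, in packing order
THETA_FIELDS = (
    "gene_avg",
    "gene_dev",
    "seed_avg",
    "seed_dev",
    "batch_offset",
    "shrna_offset",
    "screen_offset",
)

NOISE_FLOOR = 1e-6  # keeps the objective finite on degenerate perfect-fit data


@dataclass
class Hyperparams:
    """Prior variances for the Gaussian-prior parameter families.

    Defaults reflect the typical scale of LFC effects in genome-scale RNAi
    screens: across-cell-line gene effects span a few LFC units, per-line
    deviations and seed effects are substantially smaller, and per-screen
    offsets get an effectively uninformative prior.  The per-cell-line gene
    deviation prior is deliberately weak (several times the typical
    deviation scale): strong regularization of ``g_lj`` predicts little
    variation across cell lines and, because shrinkage strength then differs
    between screens of different quality, distorts cross-line comparisons —
    the quantity this model exists to get right.  The per-cell-line *seed*
    deviation prior is tight, by contrast: seed-mediated off-target effects
    are predominantly shared across cell lines, and that shared component is
    what statistically separates the per-screen scale ``gamma`` from the
    screen signal ``q``.
    """

    gene_avg_var: float = 2.0
    gene_dev_var: float = 0.25
    seed_avg_var: float = 0.2
    seed_dev_var: float = 0.01
    batch_offset_var: float = 0.02
    shrna_offset_var: float = 0.02
    screen_offset_var: float = 100.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    def prior_var(self, name: str) -> float:
        return getattr(self, f"{name}_var")


@dataclass
class ModelParams:
    """All model parameters for a given (data, maps) geometry.

    Array shapes: ``gene_avg (L,)``, ``gene_dev (L, J)``, ``seed_avg (S,)``,
    ``seed_dev (S, J)``, ``batch_offset (I, K)``, ``shrna_offset (I,)``,
    ``screen_offset (C,)``, ``screen_scale (C,)``, ``screen_signal (J,)``,
    ``gene_efficacy (I,)``, ``seed_efficacy (I,)``, ``noise_var (C,)`` with
    I shRNAs, L genes, S seeds, J cell lines, K datasets, C screens.
    """

    gene_avg: np.ndarray
    gene_dev: np.ndarray
    seed_avg: np.ndarray
    seed_dev: np.ndarray
    batch_offset: np.ndarray
    shrna_offset: np.ndarray
    screen_offset: np.ndarray
    screen_scale: np.ndarray
    screen_signal: np.ndarray
    gene_efficacy: np.ndarray
    seed_efficacy: np.ndarray
    noise_var: np.ndarray

    def __post_init__(self) -> None:
        for f in fields(self):
            setattr(self, f.name, np.asarray(getattr(self, f.name), dtype=float))
        if ((self.gene_efficacy < 0) | (self.gene_efficacy > 1)).any():
            raise ValueError("gene_efficacy must lie in [0, 1]")
        if ((self.seed_efficacy < 0) | (self.seed_efficacy > 1)).any():
            raise ValueError("seed_efficacy must lie in [0, 1]")
        if (self.noise_var <= 0).any():
            raise ValueError("noise variances must be positive")
        if (self.screen_scale <= 0).any():
            raise ValueError("screen scales must be positive")

    @classmethod
    def initial(cls, data: ScreenDataset, maps: TargetingMaps) -> "ModelParams":
        """All-zero Theta with unit efficacies, signals, scales and noise."""
        I, C = data.n_shrnas, data.n_screens
        L, S = maps.n_genes, maps.n_seeds
        J, K = data.n_cell_lines, data.n_datasets
        return cls(
            gene_avg=np.zeros(L),
            gene_dev=np.zeros((L, J)),
            seed_avg=np.zeros(S),
            seed_dev=np.zeros((S, J)),
            batch_offset=np.zeros((I, K)),
            shrna_offset=np.zeros(I),
            screen_offset=np.zeros(C),
            screen_scale=np.ones(C),
            screen_signal=np.ones(J),
            gene_efficacy=np.ones(I),
            seed_efficacy=np.ones(I),
            noise_var=np.ones(C),
        )

    def copy(self) -> "ModelParams":
        return replace(self, **{f.name: getattr(self, f.name).copy() for f in fields(self)})

    def gene_effect_matrix(self) -> np.ndarray:
        """Total gene effects ``gbar[l] + g[lj]`` (genes x cell lines)."""
        return self.gene_avg[:, None] + self.gene_dev

    def seed_effect_matrix(self) -> np.ndarray:
        return self.seed_avg[:, None] + self.seed_dev


def _bracket(params: ModelParams, maps: TargetingMaps, data: ScreenDataset) -> np.ndarray:
    """The gamma-scaled inner term, per (shRNA, screen)."""
    x = maps.gene_matrix @ params.gene_effect_matrix()  # I x J
    y = maps.seed_matrix @ params.seed_effect_matrix()  # I x J
    j = data.jidx
    return (
        params.gene_efficacy[:, None] * params.screen_signal[j][None, :] * x[:, j]
        + params.seed_efficacy[:, None] * y[:, j]
        + params.shrna_offset[:, None]
    )


def predict_lfc(params: ModelParams, maps: TargetingMaps, data: ScreenDataset) -> np.ndarray:
    """Model-predicted LFC for every (shRNA, screen) entry."""
    return (
        params.screen_offset[None, :]
        + params.batch_offset[:, data.kidx]
        + params.screen_scale[None, :] * _bracket(params, maps, data)
    )


def predict_entry(
    params: ModelParams,
    maps: TargetingMaps,
    data: ScreenDataset,
    shrna: str,
    cell_line: str,
    dataset: str,
) -> float:
    """Single-entry prediction addressed by (shRNA, cell line, dataset) ids."""
    try:
        i = data.shrna_ids.index(shrna)
    except ValueError:
        raise KeyError(f"unknown shRNA {shrna!r}") from None
    sel = (data.screens["cell_line"] == cell_line) & (data.screens["dataset"] == dataset)
    if not sel.any():
        raise KeyError(f"unknown screen ({cell_line!r}, {dataset!r})")
    col = int(np.flatnonzero(sel.to_numpy())[0])
    return float(predict_lfc(params, maps, data)[i, col])


def log_posterior(
    params: ModelParams,
    data: ScreenDataset,
    maps: TargetingMaps,
    hypers: Hyperparams,
) -> float:
    """Joint log density: Gaussian likelihood over unmasked entries plus
    zero-mean Gaussian log-priors on Theta (flat priors on Psi)."""
    if (params.noise_var <= 0).any():
        raise ValueError("noise variances must be positive")
    resid = predict_lfc(params, maps, data) - data.lfc
    s2 = params.noise_var
    n_col = data.mask.sum(axis=0)
    sq = np.where(data.mask, resid**2, 0.0).sum(axis=0)
    ll = -0.5 * float(np.sum(n_col * np.log(2.0 * np.pi * s2) + sq / s2))
    lp = ll
    for name in THETA_FIELDS:
        v = getattr(hypers, f"{name}_var")
        arr = getattr(params, name)
        lp += -0.5 * (arr.size * np.log(2.0 * np.pi * v) + float(np.sum(arr**2)) / v)
    return lp


def gauge_rescale(params: ModelParams, factor: float, which: str = "signal") -> ModelParams:
    """Apply the prediction-invariant rescaling by ``factor`` > 0.

    ``which="signal"``: ``q -> q/factor`` with gene effects multiplied by
    ``factor``.  ``which="scale"``: ``gamma -> gamma/factor`` with the whole
    bracketed term (gene, seed and shRNA-offset effects) multiplied by
    ``factor``.  Predictions are unchanged for any positive factor.
    """
    if factor <= 0:
        raise ValueError("gauge factor must be positive")
    out = params.copy()
    if which == "signal":
        out.screen_signal = out.screen_signal / factor
        out.gene_avg = out.gene_avg * factor
        out.gene_dev = out.gene_dev * factor
    elif which == "scale":
        out.screen_scale = out.screen_scale / factor
        for name in ("gene_avg", "gene_dev", "seed_avg", "seed_dev", "shrna_offset"):
            setattr(out, name, getattr(out, name) * factor)
    else:
        raise ValueError("which must be 'signal' or 'scale'")
    return out


@dataclass
class PosteriorApprox:
    """Fully factorized Gaussian posterior over Theta.

    ``means`` and ``variances`` are dicts keyed by the Theta family names,
    each holding an array of that family's shape.
    """

    means: dict[str, np.ndarray]
    variances: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name in THETA_FIELDS:
            if name not in self.means or name not in self.variances:
                raise ValueError(f"posterior approximation missing family {name!r}")
            if (self.variances[name] <= 0).any():
                raise ValueError(f"non-positive posterior variance in {name!r}")
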