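"""Model fitting: block-coordinate MAP/EM ascent plus a variational stage.

The procedure follows the hybrid estimation scheme the model was designed
around:

1.  initialize efficacies and screen signal to 1, Theta to 0;
2.  initialize per-screen scales ``gamma`` by regressing each screen's LFC on
    the across-cell-line mean LFC of its batch;
3.  conditional MAP of Theta (L-BFGS-B with analytic gradients);
4.  conditional update of the efficacies ``alpha, beta`` under [0, 1] bounds;
5.  control-separation update of the screen signal ``q``, with a
    conditional-MAP variant available;
6.  conditional update of ``gamma`` against predictions with the cell-line
    specific gene/seed deviations set to zero, followed by a per-line
    refinement of the q/gamma scale split;
7.  repeat 3-6, re-estimating the per-screen noise variances each pass,
    until the log-posterior converges;
8.  (re)estimate noise variances from the model residuals;
9.  variational approximation of the Theta posterior jointly with the noise
    variances.

Because the model is linear in Theta, the conditional posterior over Theta is
exactly Gaussian, so the variational stage admits a deterministic EM: the
mean-field fixed point has means equal to the conditional MAP and variances
equal to the inverse diagonal of the conditional precision, and the noise
variance M-step is the expected squared residual (residual^2 plus predictive
variance under the factorized posterior).  The point-estimated parameters
(``alpha``, ``beta``, ``gamma``) are likewise updated in EM form — their
normal equations use the expected products of the Theta terms, which adds
the posterior variance of the regressors to the denominators.  This corrects
the inflation a plain point-estimate regression suffers when its regressor
(the shrunk bracket) systematically underestimates the true effect scale,
an inflation that otherwise differs between screens and biases the scale
parameters.  Every such update is projected onto the region where the exact
conditional quadratic of the log-posterior does not decrease, preserving the
ascent property of the MAP steps.  No stochastic gradients are needed and
the whole fit is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .containers import ControlGeneSets, ScreenDataset, TargetingMaps
from .model import (
    NOISE_FLOOR,
    THETA_FIELDS,
    Hyperparams,
    ModelParams,
    PosteriorApprox,
    log_posterior,
    predict_lfc,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "initialize",
    "update_theta_block",
    "update_efficacies",
    "update_screen_signal",
    "update_overall_scale",
    "update_noise_em",
    "project_scale_constraint",
    "outer_loop",
    "init_noise_variance",
    "variational_stage",
    "fit_model",
]

log = logging.getLogger(__name__)

GAMMA_FLOOR = 1e-3  # positivity clamp for scale-type parameters
SIGNAL_FLOOR = 1e-3


@dataclass
class FitConfig:
    """Tuning knobs for the fitting procedure.

    The MAP stage and the closed-form variational stage are both
    deterministic; ``seed`` is accepted for interface stability but does not
    influence the fit.
    """

    max_outer_iters: int = 50
    tol: float = 1e-5  # relative log-posterior change per outer iteration
    lbfgs_maxiter: int = 100
    lbfgs_ftol: float = 1e-11
    vi_max_rounds: int = 50
    vi_tol: float = 1e-6  # relative noise-variance change per VI round
    noise_floor: float = NOISE_FLOOR
    gamma_floor: float = GAMMA_FLOOR
    signal_update: str = "controls"  # or "map"
    separation_source: str = "wls"  # or "posterior" (Eq.-style shrunk effects)
    scale_split: bool = True  # per-line q/gamma split refinement in step 6
    noise_in_loop: bool = True  # re-estimate sigma^2 each outer iteration
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_outer_iters", "tol", "lbfgs_maxiter", "lbfgs_ftol",
                     "vi_max_rounds", "vi_tol", "noise_floor", "gamma_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.signal_update not in ("controls", "map"):
            raise ValueError("signal_update must be 'controls' or 'map'")
        if self.separation_source not in ("wls", "posterior"):
            raise ValueError("separation_source must be 'wls' or 'posterior'")


@dataclass
class FitResult:
    """Outcome of a full fit: point estimates, posterior and diagnostics."""

    params: ModelParams
    posterior: PosteriorApprox
    trace: pd.DataFrame  # columns: iteration, step, log_posterior
    converged: bool
    n_iterations: int
    vi_converged: bool = True
    vi_rounds: int = 0


# ---------------------------------------------------------------------------
# geometry helpers

def _aggregators(data: ScreenDataset) -> tuple[np.ndarray, np.ndarray]:
    """Screen-to-cell-line (C x J) and screen-to-dataset (C x K) indicators."""
    C = data.n_screens
    Aj = np.zeros((C, data.n_cell_lines))
    Aj[np.arange(C), data.jidx] = 1.0
    Ak = np.zeros((C, data.n_datasets))
    Ak[np.arange(C), data.kidx] = 1.0
    return Aj, Ak


def _pack_theta(p: ModelParams) -> np.ndarray:
    return np.concatenate([getattr(p, name).ravel() for name in THETA_FIELDS])


def _unpack_theta(vec: np.ndarray, template: ModelParams) -> dict[str, np.ndarray]:
    out = {}
    pos = 0
    for name in THETA_FIELDS:
        shape = getattr(template, name).shape
        size = int(np.prod(shape)) if shape else 1
        out[name] = vec[pos : pos + size].reshape(shape)
        pos += size
    return out


# ---------------------------------------------------------------------------
# step 2: initialization

def initialize(data: ScreenDataset, maps: TargetingMaps,
               config: FitConfig | None = None) -> ModelParams:
    """Unit efficacies/signals/noise, zero Theta, regression-based gamma.

    Each screen's scale is initialized as the OLS slope (with intercept) of
    its LFC values on the across-cell-line mean LFC profile of its batch.
    """
    config = config or FitConfig()
    params = ModelParams.initial(data, maps)
    gamma = np.ones(data.n_screens)
    for k in range(data.n_datasets):
        cols = np.flatnonzero(data.kidx == k)
        if cols.size < 2:
            log.warning("dataset %r has a single screen; gamma initialized to 1",
                        data.datasets[k])
            continue
        with np.errstate(invalid="ignore"):
            profile = np.nanmean(
                np.where(data.mask[:, cols], data.lfc[:, cols], np.nan), axis=1
            )
        for col in cols:
            m = data.mask[:, col] & np.isfinite(profile)
            if m.sum() < 2:
                continue
            xs, ys = profile[m], data.lfc[m, col]
            xc = xs - xs.mean()
            denom = float(xc @ xc)
            slope = float(xc @ (ys - ys.mean())) / denom if denom > 0 else 1.0
            gamma[col] = max(slope, config.gamma_floor)
    params.screen_scale = gamma
    return params


# ---------------------------------------------------------------------------
# step 3: conditional MAP of Theta

def _theta_objective(vec, params, data, maps, hypers, Aj, Ak, consts):
    th = _unpack_theta(vec, params)
    G, B = maps.gene_matrix, maps.seed_matrix
    j = data.jidx
    geneline = th["gene_avg"][:, None] + th["gene_dev"]
    seedline = th["seed_avg"][:, None] + th["seed_dev"]
    x = G @ geneline
    y = B @ seedline
    alpha, beta = params.gene_efficacy, params.seed_efficacy
    q, gamma = params.screen_signal, params.screen_scale
    bracket = (
        alpha[:, None] * q[j][None, :] * x[:, j]
        + beta[:, None] * y[:, j]
        + th["shrna_offset"][:, None]
    )
    pred = th["screen_offset"][None, :] + th["batch_offset"][:, data.kidx] + gamma[None, :] * bracket
    R = np.where(data.mask, pred - data.lfc, 0.0)
    W = R / params.noise_var[None, :]
    value = 0.5 * float(np.sum(R * W)) + consts
    for name in THETA_FIELDS:
        value += 0.5 * float(np.sum(th[name] ** 2)) / hypers.prior_var(name)

    U = W * gamma[None, :]
    grad_a = W.sum(axis=0) + th["screen_offset"] / hypers.screen_offset_var
    grad_th = W @ Ak + th["batch_offset"] / hypers.batch_offset_var
    grad_c = U.sum(axis=1) + th["shrna_offset"] / hypers.shrna_offset_var
    Vg = (U * q[j][None, :]) @ Aj  # I x J
    Gg = G.T @ (alpha[:, None] * Vg)  # L x J
    grad_gd = Gg + th["gene_dev"] / hypers.gene_dev_var
    grad_ga = Gg.sum(axis=1) + th["gene_avg"] / hypers.gene_avg_var
    Vb = U @ Aj
    Bb = B.T @ (beta[:, None] * Vb)
    grad_bd = Bb + th["seed_dev"] / hypers.seed_dev_var
    grad_ba = Bb.sum(axis=1) + th["seed_avg"] / hypers.seed_avg_var

    grad = np.concatenate([
        grad_ga.ravel(), grad_gd.ravel(), grad_ba.ravel(), grad_bd.ravel(),
        grad_th.ravel(), grad_c.ravel(), grad_a.ravel(),
    ])
    return value, grad


def _neg_logpost_consts(params: ModelParams, data: ScreenDataset,
                        hypers: Hyperparams) -> float:
    """Theta-independent terms so that objective == -log_posterior exactly."""
    n_col = data.mask.sum(axis=0)
    consts = 0.5 * float(np.sum(n_col * np.log(2.0 * np.pi * params.noise_var)))
    for name in THETA_FIELDS:
        size = getattr(params, name).size
        consts += 0.5 * size * np.log(2.0 * np.pi * hypers.prior_var(name))
    return consts


def update_theta_block(
    params: ModelParams,
    data: ScreenDataset,
    maps: TargetingMaps,
    hypers: Hyperparams,
    config: FitConfig | None = None,
) -> ModelParams:
    """Maximize the conditional posterior over Theta (quadratic; L-BFGS-B).

    Warm-started from the current Theta; if the optimizer returns a worse
    point (line-search failure) the previous values are kept.
    """
    config = config or FitConfig()
    Aj, Ak = _aggregators(data)
    consts = _neg_logpost_consts(params, data, hypers)
    x0 = _pack_theta(params)
    f0, _ = _theta_objective(x0, params, data, maps, hypers, Aj, Ak, consts)
    res = minimize(
        _theta_objective,
        x0,
        args=(params, data, maps, hypers, Aj, Ak, consts),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": config.lbfgs_maxiter, "ftol": config.lbfgs_ftol},
    )
    if res.fun > f0:
        log.warning("Theta update did not improve the objective; keeping previous values")
        return params
    out = params.copy()
    for name, arr in _unpack_theta(res.x, params).items():
        setattr(out, name, arr.copy())
    return out


# ---------------------------------------------------------------------------
# mean-field variances of Theta (exact for the Gaussian conditional)

def _theta_precision_diag(
    params: ModelParams,
    data: ScreenDataset,
    maps: TargetingMaps,
    hypers: Hyperparams,
) -> dict[str, np.ndarray]:
    """Diagonal of the conditional (Gaussian) posterior precision over Theta."""
    Aj, Ak = _aggregators(data)
    G, B = maps.gene_matrix, maps.seed_matrix
    j = data.jidx
    w = 1.0 / params.noise_var  # per screen
    gamma2 = params.screen_scale**2
    q2 = params.screen_signal**2
    mw = data.mask * w[None, :]  # I x C
    alpha2 = params.gene_efficacy**2
    beta2 = params.seed_efficacy**2

    prec = {}
    prec["screen_offset"] = mw.sum(axis=0) + 1.0 / hypers.screen_offset_var
    prec["batch_offset"] = mw @ Ak + 1.0 / hypers.batch_offset_var
    prec["shrna_offset"] = (mw * gamma2[None, :]).sum(axis=1) + 1.0 / hypers.shrna_offset_var
    Wg = mw * (gamma2 * q2[j])[None, :]
    Vg = Wg @ Aj  # I x J
    gene_pre = G.T @ (alpha2[:, None] * Vg)  # L x J
    prec["gene_dev"] = gene_pre + 1.0 / hypers.gene_dev_var
    prec["gene_avg"] = gene_pre.sum(axis=1) + 1.0 / hypers.gene_avg_var
    Wb = mw * gamma2[None, :]
    Vb = Wb @ Aj
    seed_pre = B.T @ (beta2[:, None] * Vb)
    prec["seed_dev"] = seed_pre + 1.0 / hypers.seed_dev_var
    prec["seed_avg"] = seed_pre.sum(axis=1) + 1.0 / hypers.seed_avg_var
    return prec


def _theta_variances(params, data, maps, hypers) -> dict[str, np.ndarray]:
    return {k: 1.0 / v for k, v in _theta_precision_diag(params, data, maps, hypers).items()}


# ---------------------------------------------------------------------------
# step 4: shRNA efficacies

def update_efficacies(
    params: ModelParams,
    data: ScreenDataset,
    maps: TargetingMaps,
    hypers: Hyperparams,
    config: FitConfig | None = None,
) -> ModelParams:
    """Bound-constrained conditional update of alpha, beta in [0, 1].

    Solves, per shRNA, the 2-D box-constrained quadratic whose normal
    equations use the expected products of the gene/seed terms under the
    current Theta uncertainty (EM form); the move is then projected onto the
    segment of the exact conditional quadratic that does not decrease the
    log-posterior.
    """
    config = config or FitConfig()
    j = data.jidx
    sv = _theta_variances(params, data, maps, hypers)
    G, B = maps.gene_matrix, maps.seed_matrix
    x = G @ params.gene_effect_matrix()
    y = B @ params.seed_effect_matrix()
    vx = G @ (sv["gene_avg"][:, None] + sv["gene_dev"])  # I x J (binary incidence)
    vy = B @ (sv["seed_avg"][:, None] + sv["seed_dev"])
    gamma = params.screen_scale
    q = params.screen_signal
    P1 = gamma[None, :] * q[j][None, :] * x[:, j]
    P2 = gamma[None, :] * y[:, j]
    V1 = (gamma**2)[None, :] * (q**2)[j][None, :] * vx[:, j]
    V2 = (gamma**2)[None, :] * vy[:, j]
    r = (
        data.lfc
        - params.screen_offset[None, :]
        - params.batch_offset[:, data.kidx]
        - gamma[None, :] * params.shrna_offset[:, None]
    )
    w = (data.mask / params.noise_var[None, :])
    A11 = (w * (P1**2 + V1)).sum(axis=1)
    A22 = (w * (P2**2 + V2)).sum(axis=1)
    A12 = (w * P1 * P2).sum(axis=1)
    b1 = (w * P1 * r).sum(axis=1)
    b2 = (w * P2 * r).sum(axis=1)

    def solve_box(A11, A22, A12, b1, b2):
        det = A11 * A22 - A12**2
        with np.errstate(divide="ignore", invalid="ignore"):
            a_u = np.where(det > 0, (b1 * A22 - b2 * A12) / np.where(det > 0, det, 1.0), np.nan)
            b_u = np.where(det > 0, (b2 * A11 - b1 * A12) / np.where(det > 0, det, 1.0), np.nan)
            e_b0 = np.where(A11 > 0, b1 / np.where(A11 > 0, A11, 1.0), np.nan)
            e_b1 = np.where(A11 > 0, (b1 - A12) / np.where(A11 > 0, A11, 1.0), np.nan)
            e_a0 = np.where(A22 > 0, b2 / np.where(A22 > 0, A22, 1.0), np.nan)
            e_a1 = np.where(A22 > 0, (b2 - A12) / np.where(A22 > 0, A22, 1.0), np.nan)
        cand_a = np.stack([
            a_u, np.clip(e_b0, 0, 1), np.clip(e_b1, 0, 1),
            np.zeros_like(b1), np.ones_like(b1),
            np.zeros_like(b1), np.zeros_like(b1), np.ones_like(b1), np.ones_like(b1),
        ])
        cand_b = np.stack([
            b_u, np.zeros_like(b2), np.ones_like(b2),
            np.clip(e_a0, 0, 1), np.clip(e_a1, 0, 1),
            np.zeros_like(b2), np.ones_like(b2), np.zeros_like(b2), np.ones_like(b2),
        ])
        inside = (
            np.isfinite(cand_a) & np.isfinite(cand_b)
            & (cand_a >= 0) & (cand_a <= 1) & (cand_b >= 0) & (cand_b <= 1)
        )
        qval = (
            0.5 * (A11[None] * cand_a**2 + 2 * A12[None] * cand_a * cand_b + A22[None] * cand_b**2)
            - b1[None] * cand_a - b2[None] * cand_b
        )
        qval = np.where(inside, qval, np.inf)
        best = np.argmin(qval, axis=0)
        idx = np.arange(b1.size)
        return cand_a[best, idx], cand_b[best, idx]

    a_new, b_new = solve_box(A11, A22, A12, b1, b2)

    # ascent projection against the exact (point) conditional quadratic
    A11p = (w * P1**2).sum(axis=1)
    A22p = (w * P2**2).sum(axis=1)
    da = a_new - params.gene_efficacy
    db = b_new - params.seed_efficacy
    g0a = A11p * params.gene_efficacy + A12 * params.seed_efficacy - b1
    g0b = A22p * params.seed_efficacy + A12 * params.gene_efficacy - b2
    num = -(da * g0a + db * g0b)
    den = A11p * da**2 + 2 * A12 * da * db + A22p * db**2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_opt = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.where(num > 0, np.inf, 0.0))
    t = np.clip(np.minimum(1.0, 2.0 * t_opt), 0.0, 1.0)
    out = params.copy()
    out.gene_efficacy = np.clip(params.gene_efficacy + t * da, 0.0, 1.0)
    out.seed_efficacy = np.clip(params.seed_efficacy + t * db, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# step 5: screen signal

def _per_line_gene_effects_wls(
    params: ModelParams, data: ScreenDataset, maps: TargetingMaps
) -> np.ndarray:
    """Unshrunk per-(gene, cell line) weighted least-squares effect estimates.

    The seed, offset and scale components are removed at their current
    estimates, and each gene's per-line effect is estimated from its own
    shRNAs only, without hierarchical pooling.  Because no prior shrinkage is
    applied, these "measured" effects track each screen's depletion scale
    fully, regardless of how much information the screen carries — which is
    what makes them suitable for estimating relative screen signals.
    """
    j = data.jidx
    y = maps.seed_matrix @ params.seed_effect_matrix()
    resid = (
        data.lfc
        - params.screen_offset[None, :]
        - params.batch_offset[:, data.kidx]
        - params.screen_scale[None, :]
        * (params.seed_efficacy[:, None] * y[:, j] + params.shrna_offset[:, None])
    )
    coef = (
        params.screen_scale[None, :]
        * params.screen_signal[j][None, :]
        * params.gene_efficacy[:, None]
    )
    w = 1.0 / params.noise_var
    num = np.where(data.mask, coef * resid, 0.0) * w[None, :]
    den = np.where(data.mask, coef * coef, 0.0) * w[None, :]
    G = maps.gene_matrix
    Aj, _ = _aggregators(data)
    num_l = (G.T @ num) @ Aj  # L x J
    den_l = (G.T @ den) @ Aj
    return np.where(den_l > 0, num_l / np.maximum(den_l, 1e-300), 0.0)


def update_screen_signal(
    params: ModelParams,
    data: ScreenDataset,
    maps: TargetingMaps,
    controls: ControlGeneSets,
    method: str = "controls",
    config: FitConfig | None = None,
) -> ModelParams:
    """Update the per-cell-line screen signal ``q``.

    Default ("controls"): each line's measured gene-effect separation is the
    difference between its median negative-control and median positive-
    control gene effect.  The separation is taken on the depletion scale
    (i.e. including the current ``q_j`` factor), making the update a direct
    re-estimate whose fixed point equalizes control separation across lines;
    the ``q`` vector is then normalized to average 1.  The per-line effects
    entering the medians are, by default, unshrunk weighted least-squares
    estimates (``separation_source="wls"``); the hierarchically shrunk
    posterior effects can be used instead (``"posterior"``), at the cost of a
    screen-information-dependent compression of the separations.

    "map": conditional MAP of ``q`` (closed-form weighted least squares),
    normalized to mean 1.
    """
    config = config or FitConfig()
    out = params.copy()
    q_old = params.screen_signal
    if method == "controls":
        pos, neg = controls.resolve(maps.gene_ids)
        if config.separation_source == "wls":
            effects = _per_line_gene_effects_wls(params, data, maps)
        else:
            effects = params.gene_effect_matrix()
        sep = np.median(effects[neg], axis=0) - np.median(effects[pos], axis=0)
        q_hat = q_old * sep
        mean_q = q_hat.mean()
        if mean_q <= 0:
            raise ValueError("degenerate controls: mean screen signal is non-positive")
        q_new = q_hat / mean_q
        if (q_new < SIGNAL_FLOOR).any():
            log.warning("screen signal clamped at positivity floor for some lines")
            q_new = np.maximum(q_new, SIGNAL_FLOOR)
            q_new = q_new / q_new.mean()
        out.screen_signal = q_new
    elif method == "map":
        j = data.jidx
        x = maps.gene_matrix @ params.gene_effect_matrix()
        y = maps.seed_matrix @ params.seed_effect_matrix()
        U = params.screen_scale[None, :] * params.gene_efficacy[:, None] * x[:, j]
        resid0 = data.lfc - (
            params.screen_offset[None, :]
            + params.batch_offset[:, data.kidx]
            + params.screen_scale[None, :]
            * (params.seed_efficacy[:, None] * y[:, j] + params.shrna_offset[:, None])
        )
        w = 1.0 / params.noise_var
        num = np.zeros(data.n_cell_lines)
        den = np.zeros(data.n_cell_lines)
        Um = np.where(data.mask, U, 0.0)
        Rm = np.where(data.mask, resid0, 0.0)
        np.add.at(num, j, (Um * Rm * w[None, :]).sum(axis=0))
        np.add.at(den, j, (Um * Um * w[None, :]).sum(axis=0))
        q_new = np.where(den > 0, num / np.maximum(den, 1e-300), q_old)
        q_new = np.maximum(q_new, SIGNAL_FLOOR)
        mean_q = q_new.mean()
        if mean_q <= 0:
            raise ValueError("degenerate MAP screen-signal update")
        out.screen_signal = q_new / mean_q
    else:
        raise ValueError("method must be 'controls' or 'map'")
    return out


# ---------------------------------------------------------------------------
# step 6: overall scale (and the q/gamma split)

def update_overall_scale(
    params: ModelParams,
    data: ScreenDataset,
    maps: TargetingMaps,
    hypers: Hyperparams,
    config: FitConfig | None = None,
) -> ModelParams:
    """Conditional update of per-screen scales ``gamma``.

    Two sub-moves, both exact ascent:

    1. Per-screen scale against predictions with the cell-line specific
       deviations ``g_lj``/``b_sj`` set to zero (so scale differences are
       absorbed by ``gamma``, not the deviations).  The normal equation uses
       expected squared regressors under the Theta uncertainty (EM form),
       and the result is projected onto the interval around the exact
       conditional optimum on which the (concave quadratic) log-posterior
       does not decrease.

    2. A per-line refinement of the scale *split*: jointly rescaling
       ``gamma -> f*gamma`` and ``q -> q/f`` leaves the gene term invariant,
       so the optimal ``f`` is determined entirely by the seed/offset
       channel — the component of the model through which ``gamma`` is
       identified separately from the screen signal.  The 1-D conditional
       quadratic in ``f`` is solved exactly (again in EM form with an ascent
       projection).  Without this move, block updates barely search the
       near-flat valley in which only the product ``q*gamma`` is pinned.
    """
    config = config or FitConfig()
    j = data.jidx
    sv = _theta_variances(params, data, maps, hypers)
    w = data.mask / params.noise_var[None, :]

    # --- sub-move 1: dev-zeroed gamma regression (EM form) ---
    x0 = np.asarray(maps.gene_matrix @ params.gene_avg).ravel()
    y0 = np.asarray(maps.seed_matrix @ params.seed_avg).ravel()
    vx0 = np.asarray(maps.gene_matrix @ sv["gene_avg"]).ravel()
    vy0 = np.asarray(maps.seed_matrix @ sv["seed_avg"]).ravel()
    u = (
        (params.gene_efficacy * x0)[:, None] * params.screen_signal[j][None, :]
        + (params.seed_efficacy * y0 + params.shrna_offset)[:, None]
    )
    var_u = (
        (params.gene_efficacy**2 * vx0)[:, None] * (params.screen_signal**2)[j][None, :]
        + (params.seed_efficacy**2 * vy0 + sv["shrna_offset"])[:, None]
        * np.ones((1, data.n_screens))
    )
    resid0 = data.lfc - params.screen_offset[None, :] - params.batch_offset[:, data.kidx]
    num_sur = (w * u * resid0).sum(axis=0)
    den_sur = (w * (u**2 + var_u)).sum(axis=0)
    gamma_old = params.screen_scale
    gamma_tgt = np.where(den_sur > 0, num_sur / np.maximum(den_sur, 1e-300), gamma_old)
    gamma_tgt = np.maximum(gamma_tgt, config.gamma_floor)

    # exact conditional optimum (full bracket) bounds the ascent region
    from .model import _bracket

    v = _bracket(params, maps, data)
    num_full = (w * v * resid0).sum(axis=0)
    den_full = (w * v * v).sum(axis=0)
    gamma_full = np.where(den_full > 0, num_full / np.maximum(den_full, 1e-300), gamma_old)
    lo = np.minimum(gamma_old, 2.0 * gamma_full - gamma_old)
    hi = np.maximum(gamma_old, 2.0 * gamma_full - gamma_old)
    gamma_new = np.clip(gamma_tgt, lo, hi)
    gamma_new = np.where(den_full > 0, gamma_new, gamma_old)
    gamma_new = np.maximum(gamma_new, config.gamma_floor)

    out = params.copy()
    out.screen_scale = gamma_new

    # --- sub-move 2: per-line q/gamma split refinement ---
    if config.scale_split:
        out = _refine_scale_split(out, data, maps, sv, config)
    return out


def _refine_scale_split(
    params: ModelParams,
    data: ScreenDataset,
    maps: TargetingMaps,
    sv: dict[str, np.ndarray],
    config: FitConfig,
) -> ModelParams:
    j = data.jidx
    x = maps.gene_matrix @ params.gene_effect_matrix()
    gene_part = (
        params.screen_scale[None, :]
        * params.screen_signal[j][None, :]
        * params.gene_efficacy[:, None]
        * x[:, j]
    )
    # dev-zeroed seed/offset regressor: the per-line seed deviations absorb
    # per-line scale errors and would neutralize the very signal the split
    # estimates, so only the across-cell-line seed component enters
    y0 = np.asarray(maps.seed_matrix @ params.seed_avg).ravel()
    vy0 = np.asarray(maps.seed_matrix @ sv["seed_avg"]).ravel()
    sc0 = (
        params.screen_scale[None, :]
        * (params.seed_efficacy * y0 + params.shrna_offset)[:, None]
    )
    var_sc0 = (params.screen_scale**2)[None, :] * (
        params.seed_efficacy**2 * vy0 + sv["shrna_offset"]
    )[:, None]
    r = (
        data.lfc
        - params.screen_offset[None, :]
        - params.batch_offset[:, data.kidx]
        - gene_part
    )
    w = data.mask / params.noise_var[None, :]
    num0_col = (w * sc0 * r).sum(axis=0)
    den0_col = (w * (sc0**2 + var_sc0)).sum(axis=0)
    # exact conditional quadratic (full seed effects) bounds the ascent
    y_full = maps.seed_matrix @ params.seed_effect_matrix()
    sc_full = params.screen_scale[None, :] * (
        params.seed_efficacy[:, None] * y_full[:, j] + params.shrna_offset[:, None]
    )
    numf_col = (w * sc_full * r).sum(axis=0)
    denf_col = (w * sc_full**2).sum(axis=0)
    J = data.n_cell_lines
    num0 = np.zeros(J)
    den0 = np.zeros(J)
    numf = np.zeros(J)
    denf = np.zeros(J)
    np.add.at(num0, j, num0_col)
    np.add.at(den0, j, den0_col)
    np.add.at(numf, j, numf_col)
    np.add.at(denf, j, denf_col)
    f_em = np.where(den0 > 0, num0 / np.maximum(den0, 1e-300), 1.0)
    f_full = np.where(denf > 0, numf / np.maximum(denf, 1e-300), 1.0)
    lo = np.minimum(1.0, 2.0 * f_full - 1.0)
    hi = np.maximum(1.0, 2.0 * f_full - 1.0)
    f = np.clip(f_em, lo, hi)
    f = np.where(denf > 0, f, 1.0)
    f = np.clip(f, 0.2, 5.0)  # keeps both scales well away from degeneracy
    out = params.copy()
    out.screen_scale = np.maximum(params.screen_scale * f[j], config.gamma_floor)
    out.screen_signal = np.maximum(params.screen_signal / f, SIGNAL_FLOOR)
    return out


def project_scale_constraint(params: ModelParams) -> ModelParams:
    """Restore the mean-one constraints on ``gamma`` and ``q``.

    Both are flat-prior scale parameters, so the normalization is a plain
    rescaling; the small resulting misfit is re-absorbed by the next Theta
    update.
    """
    m_gamma = float(params.screen_scale.mean())
    m_q = float(params.screen_signal.mean())
    if m_gamma <= 0 or m_q <= 0:
        raise ValueError("mean scale parameters must be positive")
    out = params.copy()
    out.screen_scale = params.screen_scale / m_gamma
    out.screen_signal = params.screen_signal / m_q
    return out


# ---------------------------------------------------------------------------
# noise variances

def init_noise_variance(
    params: ModelParams,
    data: ScreenDataset,
    maps: TargetingMaps,
    config: FitConfig | None = None,
) -> ModelParams:
    """Per-screen mean squared residual, floored; sparse screens fall back to
    the global mean residual variance."""
    config = config or FitConfig()
    resid = predict_lfc(params, maps, data) - data.lfc
    sq = np.where(data.mask, resid**2, 0.0)
    n_col = data.mask.sum(axis=0)
    global_var = sq.sum() / max(n_col.sum(), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_col = np.where(n_col >= 2, sq.sum(axis=0) / np.maximum(n_col, 1), global_var)
    if (n_col < 2).any():
        log.warning("screens with <2 observations use the global residual variance")
    out = params.copy()
    out.noise_var = np.maximum(per_col, config.noise_floor)
    return out


def _predictive_variance(
    svars: dict[str, np.ndarray],
    params: ModelParams,
    data: ScreenDataset,
    maps: TargetingMaps,
) -> np.ndarray:
    """Per-entry prediction variance under the factorized Theta posterior."""
    G, B = maps.gene_matrix, maps.seed_matrix
    j = data.jidx
    gene_line_var = svars["gene_avg"][:, None] + svars["gene_dev"]  # L x J
    seed_line_var = svars["seed_avg"][:, None] + svars["seed_dev"]
    xs = G @ gene_line_var  # binary incidence: squared coefficients == entries
    ys = B @ seed_line_var
    gamma2 = params.screen_scale**2
    q2 = params.screen_signal**2
    alpha2 = params.gene_efficacy**2
    beta2 = params.seed_efficacy**2
    return (
        svars["screen_offset"][None, :]
        + svars["batch_offset"][:, data.kidx]
        + gamma2[None, :]
        * (
            svars["shrna_offset"][:, None]
            + q2[j][None, :] * alpha2[:, None] * xs[:, j]
            + beta2[:, None] * ys[:, j]
        )
    )


def update_noise_em(
    params: ModelParams,
    data: ScreenDataset,
    maps: TargetingMaps,
    hypers: Hyperparams,
    config: FitConfig | None = None,
) -> ModelParams:
    """Expected-residual noise update: sigma^2 = mean(resid^2 + pred. var.).

    The predictive-variance term (from the factorized Theta posterior)
    prevents the collapse feedback a plain residual-variance update exhibits
    on screens the model can partially overfit.
    """
    config = config or FitConfig()
    svars = _theta_variances(params, data, maps, hypers)
    resid = predict_lfc(params, maps, data) - data.lfc
    vpred = _predictive_variance(svars, params, data, maps)
    expected = np.where(data.mask, resid**2 + vpred, 0.0)
    n_col = data.mask.sum(axis=0)
    global_var = expected.sum() / max(n_col.sum(), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_col = np.where(n_col >= 2, expected.sum(axis=0) / np.maximum(n_col, 1), global_var)
    out = params.copy()
    out.noise_var = np.maximum(per_col, config.noise_floor)
    return out


# ---------------------------------------------------------------------------
# step 7: outer loop

def outer_loop(
    params: ModelParams,
    data: ScreenDataset,
    maps: TargetingMaps,
    controls: ControlGeneSets,
    hypers: Hyperparams,
    config: FitConfig | None = None,
) -> tuple[ModelParams, list[tuple[int, str, float]], bool, int]:
    """Iterate steps 3-6 until the log-posterior converges.

    Returns (params, trace, converged, iterations).  Trace entries are
    (iteration, step label, log-posterior after the step); the ascent steps
    (theta, efficacy, scale) are non-decreasing by construction, while the
    control-based signal step, the constraint projection and the noise
    update are re-estimates rather than ascent moves.
    """
    config = config or FitConfig()
    trace: list[tuple[int, str, float]] = []
    lp = log_posterior(params, data, maps, hypers)
    trace.append((0, "init", lp))
    converged = False
    it = 0
    for it in range(1, config.max_outer_iters + 1):
        lp_prev = lp
        params = update_theta_block(params, data, maps, hypers, config)
        trace.append((it, "theta", log_posterior(params, data, maps, hypers)))
        params = update_efficacies(params, data, maps, hypers, config)
        trace.append((it, "efficacy", log_posterior(params, data, maps, hypers)))
        params = update_screen_signal(params, data, maps, controls,
                                      method=config.signal_update, config=config)
        trace.append((it, "signal", log_posterior(params, data, maps, hypers)))
        params = update_overall_scale(params, data, maps, hypers, config)
        trace.append((it, "scale", log_posterior(params, data, maps, hypers)))
        params = project_scale_constraint(params)
        trace.append((it, "normalize", log_posterior(params, data, maps, hypers)))
        if config.noise_in_loop:
            params = update_noise_em(params, data, maps, hypers, config)
        lp = log_posterior(params, data, maps, hypers)
        trace.append((it, "noise", lp))
        if abs(lp - lp_prev) <= config.tol * (abs(lp_prev) + 1.0):
            converged = True
            break
    if not converged:
        log.warning("outer loop did not converge within %d iterations", config.max_outer_iters)
    return params, trace, converged, it


# ---------------------------------------------------------------------------
# step 9: variational stage

def variational_stage(
    params: ModelParams,
    data: ScreenDataset,
    maps: TargetingMaps,
    hypers: Hyperparams,
    config: FitConfig | None = None,
) -> tuple[PosteriorApprox, ModelParams, bool, int]:
    """Mean-field Gaussian posterior over Theta, alternated with sigma^2.

    Exploits the Gaussianity of the conditional posterior: the mean-field
    KL-optimal means coincide with the conditional MAP and the variances with
    the inverse precision diagonal, so each round is exact.  The noise
    variance M-step maximizes the expected complete-data log density.
    """
    config = config or FitConfig()
    svars = {name: np.full_like(getattr(params, name), np.nan) for name in THETA_FIELDS}
    converged = False
    rounds = 0
    for rounds in range(1, config.vi_max_rounds + 1):
        params = update_theta_block(params, data, maps, hypers, config)
        svars = _theta_variances(params, data, maps, hypers)
        s2_old = params.noise_var
        params = update_noise_em(params, data, maps, hypers, config)
        delta = float(np.max(np.abs(params.noise_var - s2_old) / s2_old))
        if delta < config.vi_tol:
            converged = True
            break
    if not converged:
        log.warning("variational stage did not converge within %d rounds", config.vi_max_rounds)
    svars = _theta_variances(params, data, maps, hypers)
    means = {name: getattr(params, name).copy() for name in THETA_FIELDS}
    posterior = PosteriorApprox(means=means, variances=svars)
    return posterior, params, converged, rounds


# ---------------------------------------------------------------------------
# full procedure

def fit_model(
    data: ScreenDataset,
    maps: TargetingMaps,
    controls: ControlGeneSets,
    hypers: Hyperparams | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Run the complete fitting procedure (steps 1-9)."""
    hypers = hypers or Hyperparams()
    config = config or FitConfig()
    params = initialize(data, maps, config)
    params, trace, converged, iters = outer_loop(params, data, maps, controls, hypers, config)
    params = init_noise_variance(params, data, maps, config)
    posterior, params, vi_converged, vi_rounds = variational_stage(
        params, data, maps, hypers, config
    )
    trace_df = pd.DataFrame(trace, columns=["iteration", "step", "log_posterior"])
    return FitResult(
        params=params,
        posterior=posterior,
        trace=trace_df,
        converged=converged,
        n_iterations=iters,
        vi_converged=vi_converged,
        vi_rounds=vi_rounds,
    )
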