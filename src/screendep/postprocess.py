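"""Turning fitted parameters into released gene-dependency scores.

The released score for gene ``l`` in cell line ``j`` is the posterior mean of
``gbar_l + g_lj``; under the mean-field family the two terms are independent,
so the entry variance is the sum of the two marginal variances.  Scores are
put on an absolute scale by a single affine map anchoring the median
across-cell-line average score of positive controls at -1 and of negative
controls at 0, and genes with unreliable reagent support are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ControlGeneSets, TargetingMaps
from .inference import FitResult
from .model import ModelParams

__all__ = [
    "DependencyMatrix",
    "scores_from_fit",
    "normalize_scores",
    "filter_unreliable_genes",
    "weighted_pearson",
    "zscore_relative_scores",
    "release_scores",
]

MIN_SHRNAS_PER_GENE = 3
MIN_MEAN_EFFICACY = 0.2
MIN_TOTAL_EFFICACY = 1.5


@dataclass
class DependencyMatrix:
    """Gene x cell-line dependency scores with optional per-entry variances."""

    scores: pd.DataFrame
    variances: pd.DataFrame | None = None
    excluded: pd.DataFrame | None = None  # columns: gene_id, reason

    def __post_init__(self) -> None:
        if self.variances is not None:
            if self.variances.shape != self.scores.shape:
                raise ValueError("variances shape must match scores")
            vals = self.variances.to_numpy()
            if (vals[np.isfinite(vals)] <= 0).any():
                raise ValueError("posterior variances must be positive")


def scores_from_fit(fit: FitResult, maps: TargetingMaps, cell_lines: list[str]) -> DependencyMatrix:
    """Posterior mean and variance of total gene effects, as a matrix."""
    mean = fit.posterior.means["gene_avg"][:, None] + fit.posterior.means["gene_dev"]
    var = fit.posterior.variances["gene_avg"][:, None] + fit.posterior.variances["gene_dev"]
    return DependencyMatrix(
        scores=pd.DataFrame(mean, index=maps.gene_ids, columns=cell_lines),
        variances=pd.DataFrame(var, index=maps.gene_ids, columns=cell_lines),
    )


def normalize_scores(raw: DependencyMatrix, controls: ControlGeneSets) -> DependencyMatrix:
    """Uniform affine map putting control medians at -1 (positive) and 0.

    A single slope/offset pair ``m x + b`` is applied to every entry (and
    ``m^2`` to the variances) such that the median across-cell-line average
    score is exactly -1 for the positive controls and 0 for the negatives.
    Being affine with positive slope, the map preserves all rank orders.
    """
    gene_ids = list(raw.scores.index)
    pos, neg = controls.resolve(gene_ids)
    row_means = raw.scores.to_numpy().mean(axis=1)
    med_pos = float(np.median(row_means[pos]))
    med_neg = float(np.median(row_means[neg]))
    if med_pos == med_neg:
        raise ValueError("control medians coincide; cannot anchor the scale")
    m = 1.0 / (med_neg - med_pos)
    b = -m * med_neg
    scores = raw.scores * m + b
    variances = raw.variances * (m * m) if raw.variances is not None else None
    return DependencyMatrix(scores=scores, variances=variances, excluded=raw.excluded)


def filter_unreliable_genes(
    params: ModelParams,
    maps: TargetingMaps,
    min_shrnas: int = MIN_SHRNAS_PER_GENE,
    min_mean_efficacy: float = MIN_MEAN_EFFICACY,
    min_total_efficacy: float = MIN_TOTAL_EFFICACY,
) -> pd.DataFrame:
    """Exclusion table (gene_id, reason) for unreliable gene estimates.

    A gene is excluded when it has fewer than ``min_shrnas`` targeting
    shRNAs, when the mean knockdown efficacy of its shRNAs is below
    ``min_mean_efficacy``, when the summed efficacy is below
    ``min_total_efficacy``, or when it is a merged gene-family entity.
    Decreasing any efficacy can only add exclusions, never remove them.
    """
    G = maps.gene_matrix
    counts = np.asarray(G.sum(axis=0)).ravel()
    alpha_sum = np.asarray(G.T @ params.gene_efficacy).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mean = np.where(counts > 0, alpha_sum / np.maximum(counts, 1), 0.0)
    rows = []
    for gi, gene in enumerate(maps.gene_ids):
        reasons = []
        if counts[gi] < min_shrnas:
            reasons.append("few_shrnas")
        if alpha_mean[gi] < min_mean_efficacy:
            reasons.append("low_mean_efficacy")
        if alpha_sum[gi] < min_total_efficacy:
            reasons.append("low_total_efficacy")
        if maps.is_family[gi]:
            reasons.append("gene_family")
        for reason in reasons:
            rows.append({"gene_id": gene, "reason": reason})
    return pd.DataFrame(rows, columns=["gene_id", "reason"])


def weighted_pearson(x, y, weights) -> tuple[float, float]:
    """Precision-weighted Pearson correlation with a t-based p-value.

    Weighted means/covariances with weights ``w`` (typically the inverse
    posterior variance); the two-sided p-value uses a t approximation with
    the effective sample size ``(sum w)^2 / sum w^2``.  With equal weights
    this reduces exactly to the ordinary Pearson estimator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != y.shape or x.shape != w.shape:
        raise ValueError("x, y and weights must have the same shape")
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(w)
    x, y, w = x[ok], y[ok], w[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    wsum = w.sum()
    xm = (w * x).sum() / wsum
    ym = (w * y).sum() / wsum
    cov = (w * (x - xm) * (y - ym)).sum() / wsum
    vx = (w * (x - xm) ** 2).sum() / wsum
    vy = (w * (y - ym) ** 2).sum() / wsum
    if vx <= 0 or vy <= 0:
        raise ValueError("zero weighted variance")
    r = cov / np.sqrt(vx * vy)
    ess = wsum**2 / (w**2).sum()
    df = max(ess - 2.0, 1e-8)
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(r), float(p)


def zscore_relative_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Global z-scoring for relative-scale methods.

    Each gene row is mean-subtracted, then the whole matrix is divided by one
    global standard deviation.
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 cell lines")
    centered = scores.sub(scores.mean(axis=1), axis=0)
    sd = float(np.nanstd(centered.to_numpy(), ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero global standard deviation")
    return centered / sd


def release_scores(
    fit: FitResult,
    maps: TargetingMaps,
    controls: ControlGeneSets,
    cell_lines: list[str],
) -> DependencyMatrix:
    """Full release path: posterior scores, -1/0 anchoring, exclusions applied."""
    raw = scores_from_fit(fit, maps, cell_lines)
    normalized = normalize_scores(raw, controls)
    exclusions = filter_unreliable_genes(fit.params, maps)
    keep = ~normalized.scores.index.isin(set(exclusions["gene_id"]))
    return DependencyMatrix(
        scores=normalized.scores.loc[keep],
        variances=normalized.variances.loc[keep] if normalized.variances is not None else None,
        excluded=exclusions,
    )
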