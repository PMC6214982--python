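"""Quality metrics and the gene-averaging baseline.

Screen quality is summarized by the strictly standardized mean difference
(SSMD) between positive-control (common-essential) and negative-control gene
scores in each cell line; the gene-averaging (GA) baseline scores a gene by
the mean z-scored LFC of its targeting shRNAs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ControlGeneSets, ScreenDataset, TargetingMaps
from .postprocess import DependencyMatrix, weighted_pearson

__all__ = [
    "gene_average",
    "ssmd",
    "screen_quality_report",
    "essential_signal_correlation",
]

log = logging.getLogger(__name__)


def gene_average(
    zlfc: np.ndarray,
    maps: TargetingMaps,
    data: ScreenDataset,
) -> DependencyMatrix:
    """Gene-averaging baseline: per (gene, screen) mean z-scored LFC.

    ``zlfc`` is the output of :func:`screendep.preprocess.zscore_per_screen`
    (NaN at masked entries).  Genes with no retained shRNA in a screen come
    back as NaN.
    """
    vals = np.asarray(zlfc, dtype=float)
    obs = np.isfinite(vals)
    filled = np.where(obs, vals, 0.0)
    G = maps.gene_matrix
    totals = G.T @ filled  # L x C
    counts = G.T @ obs.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
    frame = pd.DataFrame(means, index=maps.gene_ids, columns=data.screen_labels())
    return DependencyMatrix(scores=frame)


def ssmd(pos_scores, neg_scores) -> float:
    """Strictly standardized mean difference between control groups.

    Independent-groups form with sample variances (n-1):
    ``(mean(neg) - mean(pos)) / sqrt(var(pos) + var(neg))``; positive when
    essential genes deplete more strongly than non-essentials, and invariant
    to any common positive-slope affine rescaling of the scores.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 values in each control group")
    denom = pos.var(ddof=1) + neg.var(ddof=1)
    if denom <= 0:
        raise ValueError("zero pooled variance")
    return float((neg.mean() - pos.mean()) / np.sqrt(denom))


def screen_quality_report(
    dep: DependencyMatrix,
    controls: ControlGeneSets,
    unexpressed_per_line: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Per-cell-line SSMD of dependency scores over the control gene sets.

    When per-line unexpressed gene sets are supplied they override the global
    negative control list for that line.  Lines where either control group
    resolves to fewer than 2 scored genes are reported with NaN.
    """
    gene_index = pd.Index(dep.scores.index)
    pos_genes = [g for g in controls.positive if g in gene_index]
    rows = []
    for line in dep.scores.columns:
        neg_source = (
            unexpressed_per_line.get(line, controls.negative)
            if unexpressed_per_line
            else controls.negative
        )
        neg_genes = [g for g in neg_source if g in gene_index]
        pos_vals = dep.scores.loc[pos_genes, line].to_numpy()
        neg_vals = dep.scores.loc[neg_genes, line].to_numpy()
        try:
            value = ssmd(pos_vals, neg_vals)
        except ValueError:
            log.warning("cell line %r lacks resolvable controls; SSMD omitted", line)
            value = np.nan
        rows.append(
            {
                "cell_line": line,
                "ssmd": value,
                "n_pos": int(np.isfinite(pos_vals).sum()),
                "n_neg": int(np.isfinite(neg_vals).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("cell_line")


def essential_signal_correlation(
    dep: DependencyMatrix,
    essential_genes,
    covariate,
    use_precision: bool = False,
) -> float:
    """Correlation between per-line mean essential-gene score and a per-line
    covariate (e.g. the true screen signal in a simulation).

    An unbiased estimator shows no such correlation; scores that leak screen
    quality correlate strongly.  With ``use_precision`` the per-line means
    and the correlation are precision-weighted (inverse posterior variance).
    """
    genes = [g for g in essential_genes if g in dep.scores.index]
    if not genes:
        raise ValueError("no essential genes present in the score matrix")
    sub = dep.scores.loc[genes]
    cov = np.asarray(covariate, dtype=float)
    if cov.shape[0] != sub.shape[1]:
        raise ValueError("covariate length must match the number of cell lines")
    if use_precision and dep.variances is not None:
        prec = 1.0 / dep.variances.loc[genes].to_numpy()
        num = (sub.to_numpy() * prec).sum(axis=0)
        line_prec = prec.sum(axis=0)
        line_means = num / line_prec
        r, _ = weighted_pearson(line_means, cov, line_prec)
    else:
        line_means = np.nanmean(sub.to_numpy(), axis=0)
        r, _ = weighted_pearson(line_means, cov, np.ones_like(cov))
    return r
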