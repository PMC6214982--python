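"""Independent brute-force reference implementations used as test oracles.

Deliberately written as explicit loops over scipy.stats densities, sharing no
code with the package's vectorized implementations.
"""

import numpy as np
from scipy import stats


def naive_log_posterior(params, data, maps, hypers):
    G = maps.gene_matrix.toarray()
    B = maps.seed_matrix.toarray()
    total = 0.0
    for i in range(data.n_shrnas):
        for col in range(data.n_screens):
            if not data.mask[i, col]:
                continue
            j = data.jidx[col]
            k = data.kidx[col]
            gene_term = 0.0
            for l in range(maps.n_genes):
                if G[i, l]:
                    gene_term += params.gene_avg[l] + params.gene_dev[l, j]
            seed_term = 0.0
            for s in range(maps.n_seeds):
                if B[i, s]:
                    seed_term += params.seed_avg[s] + params.seed_dev[s, j]
            mu = (
                params.screen_offset[col]
                + params.batch_offset[i, k]
                + params.screen_scale[col]
                * (
                    params.screen_signal[j] * params.gene_efficacy[i] * gene_term
                    + params.seed_efficacy[i] * seed_term
                    + params.shrna_offset[i]
                )
            )
            total += stats.norm.logpdf(
                data.lfc[i, col], loc=mu, scale=np.sqrt(params.noise_var[col])
            )
    priors = {
        "gene_avg": hypers.gene_avg_var,
        "gene_dev": hypers.gene_dev_var,
        "seed_avg": hypers.seed_avg_var,
        "seed_dev": hypers.seed_dev_var,
        "batch_offset": hypers.batch_offset_var,
        "shrna_offset": hypers.shrna_offset_var,
        "screen_offset": hypers.screen_offset_var,
    }
    for name, var in priors.items():
        for value in np.atleast_1d(getattr(params, name)).ravel():
            total += stats.norm.logpdf(value, loc=0.0, scale=np.sqrt(var))
    return total


def naive_gene_average(zlfc, gene_matrix):
    """Per (gene, screen) mean of finite z-scores over targeting shRNAs."""
    G = gene_matrix.toarray()
    n_genes = G.shape[1]
    n_screens = zlfc.shape[1]
    out = np.full((n_genes, n_screens), np.nan)
    for l in range(n_genes):
        for col in range(n_screens):
            vals = [
                zlfc[i, col]
                for i in range(G.shape[0])
                if G[i, l] and np.isfinite(zlfc[i, col])
            ]
            if vals:
                out[l, col] = float(np.mean(vals))
    return out


def naive_weighted_pearson(x, y, w):
    x, y, w = map(np.asarray, (x, y, w))
    xm = np.sum(w * x) / np.sum(w)
    ym = np.sum(w * y) / np.sum(w)
    cov = np.sum(w * (x - xm) * (y - ym)) / np.sum(w)
    vx = np.sum(w * (x - xm) ** 2) / np.sum(w)
    vy = np.sum(w * (y - ym) ** 2) / np.sum(w)
    return cov / np.sqrt(vx * vy)
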