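"""Count normalization and LFC preprocessing for pooled shRNA screens.

Pipeline: raw read counts -> log2 counts-per-million (with a library-size
scaled pseudocount) -> removal of shRNAs under-represented in the plasmid
reference -> per-sample LFC against the matched reference profile ->
median collapse across replicates to one column per (cell line, dataset).
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import REFERENCE_ROLES, CountMatrix, ScreenDataset

__all__ = [
    "counts_to_logcpm",
    "filter_low_plasmid",
    "compute_lfc",
    "make_virtual_reference",
    "collapse_reference_replicates",
    "impute_missing_reference",
    "zscore_per_screen",
]

log = logging.getLogger(__name__)


def counts_to_logcpm(counts, prior_count: float = 10.0) -> pd.DataFrame:
    """log2 counts-per-million with a library-size scaled pseudocount.

    For sample ``s`` with library size ``L_s`` the pseudocount is
    ``p_s = prior_count * L_s / mean(L)`` and

        logCPM = log2( (c + p_s) / (L_s + 2 p_s) * 1e6 )

    which matches the standard ``cpm(log=TRUE, prior.count=...)`` convention.

    Parameters
    ----------
    counts:
        :class:`~screendep.containers.CountMatrix` or a non-negative
        DataFrame (shRNA x sample).
    prior_count:
        Average pseudocount across samples; 10 by default.
    """
    frame = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = frame.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    lib = vals.sum(axis=0)
    if (lib <= 0).any():
        bad = [c for c, sz in zip(frame.columns, lib) if sz <= 0]
        raise ValueError(f"zero library size for samples: {bad}")
    pseudo = prior_count * lib / lib.mean()
    cpm = (vals + pseudo) / (lib + 2.0 * pseudo) * 1e6
    return pd.DataFrame(np.log2(cpm), index=frame.index, columns=frame.columns)


def filter_low_plasmid(
    logcpm: pd.DataFrame,
    plasmid_columns: Mapping[str, str | Sequence[str]],
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-batch keep mask: shRNA retained iff plasmid logCPM >= threshold.

    ``plasmid_columns`` maps each batch/dataset id to the column (or columns,
    median-collapsed first) holding its plasmid reference profile.  The
    boundary is inclusive ("at least" the threshold).
    """
    keep = {}
    for batch, cols in plasmid_columns.items():
        if isinstance(cols, str):
            cols = [cols]
        cols = list(cols)
        if not cols:
            raise ValueError(f"no plasmid column for batch {batch!r}")
        missing = [c for c in cols if c not in logcpm.columns]
        if missing:
            raise ValueError(f"plasmid columns absent for batch {batch!r}: {missing}")
        profile = logcpm[cols].median(axis=1)
        keep[batch] = profile >= threshold
    return pd.DataFrame(keep)


def collapse_reference_replicates(
    logcpm: pd.DataFrame, sample_meta: pd.DataFrame
) -> pd.DataFrame:
    """Median-collapse reference-role samples to one profile per dataset."""
    meta = sample_meta.loc[[c for c in logcpm.columns if c in sample_meta.index]]
    refs = meta[meta["role"].str.lower().isin(REFERENCE_ROLES)]
    if refs.empty:
        raise ValueError("no reference-role samples found")
    out = {}
    for dataset, grp in refs.groupby("dataset", sort=False):
        out[dataset] = logcpm[list(grp.index)].median(axis=1)
    return pd.DataFrame(out)


def make_virtual_reference(
    reference_logcpm: pd.DataFrame,
    insufficient_reference_ids: Sequence[str] = (),
) -> pd.Series:
    """Synthesize a reference profile from the valid references of a pool.

    The virtual library is the per-shRNA median logCPM across all reference
    profiles not flagged as insufficient.  The returned Series carries
    ``attrs["virtual"] = True`` so downstream metadata can record provenance.
    """
    valid = [c for c in reference_logcpm.columns if c not in set(insufficient_reference_ids)]
    if not valid:
        raise ValueError("no valid reference profile available in the pool")
    if len(valid) < 2:
        warnings.warn("virtual reference built from a single valid profile", stacklevel=2)
    virtual = reference_logcpm[valid].median(axis=1)
    virtual.name = "virtual_reference"
    virtual.attrs["virtual"] = True
    return virtual


def impute_missing_reference(reference_logcpm: pd.DataFrame) -> pd.DataFrame:
    """Fill missing reference measurements with the across-profile mean.

    Optional per-dataset rule for libraries where some reference (t0)
    measurements are absent for individual screens: a missing entry is
    replaced by the mean reference value of that shRNA across all profiles
    where it was measured.
    """
    vals = reference_logcpm.to_numpy(dtype=float)
    row_mean = np.nanmean(vals, axis=1, keepdims=True)
    filled = np.where(np.isnan(vals), row_mean, vals)
    return pd.DataFrame(filled, index=reference_logcpm.index, columns=reference_logcpm.columns)


def compute_lfc(
    endpoint_logcpm: pd.DataFrame,
    reference_logcpm: pd.DataFrame,
    sample_meta: pd.DataFrame,
    keep: pd.DataFrame | None = None,
) -> ScreenDataset:
    """Reference-normalize and replicate-collapse logCPM into a ScreenDataset.

    Each endpoint sample's LFC is its logCPM minus the matched reference
    profile; the reference is resolved through the ``reference`` column of
    ``sample_meta`` when present, else through the sample's ``dataset``.
    Replicates of the same (cell line, dataset) are median-collapsed, as are
    duplicated shRNA rows within a dataset.  ``keep`` is an optional per
    (shRNA, dataset) boolean mask from :func:`filter_low_plasmid`; entries
    failing it are masked rather than dropped globally.
    """
    meta = sample_meta.loc[[c for c in endpoint_logcpm.columns if c in sample_meta.index]]
    if len(meta) != endpoint_logcpm.shape[1]:
        missing = set(endpoint_logcpm.columns) - set(sample_meta.index)
        raise ValueError(f"endpoint samples missing from sample_meta: {sorted(missing)}")
    ref_key = (
        meta["reference"] if "reference" in meta.columns else meta["dataset"]
    )
    bad = sorted(set(ref_key) - set(reference_logcpm.columns))
    if bad:
        raise ValueError(f"unresolved reference profiles: {bad}")

    per_sample = {}
    for sample in endpoint_logcpm.columns:
        per_sample[sample] = endpoint_logcpm[sample] - reference_logcpm[ref_key[sample]]
    lfc_samples = pd.DataFrame(per_sample)

    columns: dict[tuple[str, str], pd.Series] = {}
    for (cell, dataset), grp in meta.groupby(["cell_line", "dataset"], sort=False):
        block = lfc_samples[list(grp.index)]
        if block.shape[1] == 0 or block.isna().all(axis=None):
            log.warning("empty replicate group for (%s, %s); masking", cell, dataset)
            columns[(cell, dataset)] = pd.Series(np.nan, index=block.index)
            continue
        collapsed = block.median(axis=1)  # even count: mean of middle two
        if collapsed.index.has_duplicates:
            collapsed = collapsed.groupby(level=0, sort=False).median()
        if keep is not None and dataset in keep.columns:
            drop = ~keep[dataset].reindex(collapsed.index).fillna(False)
            collapsed = collapsed.mask(drop)
        columns[(cell, dataset)] = collapsed

    frame = pd.DataFrame(columns)
    screens = pd.DataFrame(
        [{"cell_line": c, "dataset": d} for c, d in frame.columns]
    )
    vals = frame.to_numpy(dtype=float)
    mask = np.isfinite(vals)
    return ScreenDataset(
        lfc=np.where(mask, vals, 0.0),
        mask=mask,
        shrna_ids=list(frame.index),
        screens=screens,
    )


def zscore_per_screen(data: ScreenDataset) -> np.ndarray:
    """Z-score each screen column over its unmasked entries (sample SD, n-1).

    Used only for the gene-averaging baseline and the relative-scale methods,
    never for the hierarchical-model fit itself.  Masked entries come back as
    NaN.
    """
    out = np.full_like(data.lfc, np.nan, dtype=float)
    for col in range(data.n_screens):
        m = data.mask[:, col]
        vals = data.lfc[m, col]
        if vals.size < 2:
            raise ValueError(f"screen column {col} has fewer than 2 observations")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"screen column {col} has zero variance")
        out[m, col] = (vals - vals.mean()) / sd
    return out
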