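"""Core data containers shared across the package.

The observed data for the model are log-fold-change (LFC) depletion scores
``D[i, (j, k)]`` for shRNA ``i`` measured in a *screen*: one (cell line ``j``,
dataset/batch ``k``) combination after replicate collapse.  Alongside the LFC
tensor the model consumes two fixed binary incidence structures: the
shRNA-to-gene map ``G`` and the shRNA-to-seed map ``B``, plus positive /
negative control gene lists used to anchor the screen-signal parameters and
the absolute dependency scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "CountMatrix",
    "ScreenDataset",
    "TargetingMaps",
    "ControlGeneSets",
    "REFERENCE_ROLES",
]

#: sample roles accepted as a reference (pre-selection) measurement
REFERENCE_ROLES = frozenset({"plasmid", "reference", "pdna", "t0"})


@dataclass
class CountMatrix:
    """Raw shRNA read counts with per-sample metadata.

    Parameters
    ----------
    counts:
        Non-negative integer matrix, shRNAs in rows, samples in columns.
    sample_meta:
        One row per sample (indexed by sample id) with columns
        ``cell_line``, ``dataset``, ``replicate`` and ``role``
        (``endpoint`` or one of the reference roles).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from sample_meta: {sorted(missing)}")
        required = {"cell_line", "dataset", "replicate", "role"}
        absent = required - set(self.sample_meta.columns)
        if absent:
            raise ValueError(f"sample_meta lacks required columns: {sorted(absent)}")
        roles = set(self.sample_meta["role"].str.lower())
        unknown = roles - ({"endpoint"} | set(REFERENCE_ROLES))
        if unknown:
            raise ValueError(f"unknown sample roles: {sorted(unknown)}")

    @property
    def library_size(self) -> pd.Series:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def endpoint_samples(self) -> list[str]:
        meta = self.sample_meta.loc[list(self.counts.columns)]
        return list(meta.index[meta["role"].str.lower() == "endpoint"])

    def reference_samples(self) -> list[str]:
        meta = self.sample_meta.loc[list(self.counts.columns)]
        return list(meta.index[meta["role"].str.lower().isin(REFERENCE_ROLES)])


@dataclass
class ScreenDataset:
    """Replicate-collapsed LFC matrix with screen metadata and missingness mask.

    ``lfc`` has one row per shRNA and one column per screen, where a screen is
    a unique (cell line, dataset) pair.  ``mask`` is ``True`` for observed
    entries; masked entries are excluded from every likelihood sum.
    """

    lfc: np.ndarray
    mask: np.ndarray
    shrna_ids: list[str]
    screens: pd.DataFrame  # columns: cell_line, dataset

    cell_lines: list[str] = field(init=False)
    datasets: list[str] = field(init=False)
    jidx: np.ndarray = field(init=False)
    kidx: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.lfc = np.asarray(self.lfc, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.lfc.shape != self.mask.shape:
            raise ValueError("lfc and mask shapes differ")
        if self.lfc.shape[0] != len(self.shrna_ids):
            raise ValueError("row count does not match shrna_ids")
        if self.lfc.shape[1] != len(self.screens):
            raise ValueError("column count does not match screens table")
        pairs = self.screens[["cell_line", "dataset"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise ValueError("screens must be unique (cell_line, dataset) pairs")
        self.cell_lines = list(pd.unique(self.screens["cell_line"]))
        self.datasets = list(pd.unique(self.screens["dataset"]))
        jmap = {c: j for j, c in enumerate(self.cell_lines)}
        kmap = {d: k for k, d in enumerate(self.datasets)}
        self.jidx = self.screens["cell_line"].map(jmap).to_numpy()
        self.kidx = self.screens["dataset"].map(kmap).to_numpy()

    @property
    def n_shrnas(self) -> int:
        return self.lfc.shape[0]

    @property
    def n_screens(self) -> int:
        return self.lfc.shape[1]

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_lines)

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    def screen_labels(self) -> list[str]:
        return [
            f"{c}::{d}"
            for c, d in zip(self.screens["cell_line"], self.screens["dataset"])
        ]

    def to_frame(self) -> pd.DataFrame:
        """LFC as a DataFrame with NaN at masked entries."""
        vals = np.where(self.mask, self.lfc, np.nan)
        return pd.DataFrame(vals, index=self.shrna_ids, columns=self.screen_labels())


def _as_binary_csr(mat) -> sparse.csr_matrix:
    m = sparse.csr_matrix(mat, dtype=float)
    m.eliminate_zeros()
    if m.nnz and not np.all(np.isin(m.data, [0.0, 1.0])):
        raise ValueError("incidence matrices must be binary")
    return m


@dataclass
class TargetingMaps:
    """Binary shRNA-to-gene (``G``) and shRNA-to-seed (``B``) incidence maps.

    Gene-family entities (groups of genes targeted by identical shRNA sets,
    merged because they are statistically indistinguishable) are flagged with
    ``is_family`` and their member lists kept in ``gene_families``.
    """

    gene_matrix: sparse.csr_matrix
    seed_matrix: sparse.csr_matrix
    shrna_ids: list[str]
    gene_ids: list[str]
    seed_ids: list[str]
    is_family: np.ndarray = None
    gene_families: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_matrix = _as_binary_csr(self.gene_matrix)
        self.seed_matrix = _as_binary_csr(self.seed_matrix)
        if self.gene_matrix.shape[0] != len(self.shrna_ids):
            raise ValueError("gene_matrix rows do not match shrna_ids")
        if self.seed_matrix.shape[0] != len(self.shrna_ids):
            raise ValueError("seed_matrix rows do not match shrna_ids")
        if self.gene_matrix.shape[1] != len(self.gene_ids):
            raise ValueError("gene_matrix columns do not match gene_ids")
        if self.seed_matrix.shape[1] != len(self.seed_ids):
            raise ValueError("seed_matrix columns do not match seed_ids")
        if self.is_family is None:
            self.is_family = np.zeros(len(self.gene_ids), dtype=bool)
        self.is_family = np.asarray(self.is_family, dtype=bool)

    @property
    def n_shrnas(self) -> int:
        return self.gene_matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.gene_matrix.shape[1]

    @property
    def n_seeds(self) -> int:
        return self.seed_matrix.shape[1]

    def genes_per_shrna(self) -> np.ndarray:
        return np.asarray(self.gene_matrix.sum(axis=1)).ravel()

    def shrnas_per_gene(self) -> np.ndarray:
        return np.asarray(self.gene_matrix.sum(axis=0)).ravel()


@dataclass(frozen=True)
class ControlGeneSets:
    """Positive (common-essential) and negative control gene id sets."""

    positive: tuple[str, ...]
    negative: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive", tuple(dict.fromkeys(self.positive)))
        object.__setattr__(self, "negative", tuple(dict.fromkeys(self.negative)))
        if not self.positive or not self.negative:
            raise ValueError("control gene sets must be non-empty")
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(f"control sets overlap: {sorted(overlap)}")

    def resolve(self, gene_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Indices of each control set within ``gene_ids`` (missing ids skipped)."""
        lookup = {g: i for i, g in enumerate(gene_ids)}
        pos = np.array([lookup[g] for g in self.positive if g in lookup], dtype=int)
        neg = np.array([lookup[g] for g in self.negative if g in lookup], dtype=int)
        if pos.size == 0 or neg.size == 0:
            raise ValueError("control sets do not resolve against the gene index")
        return pos, neg
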