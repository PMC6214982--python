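"""Readers and writers for the plain-text interchange formats.

Matrices travel as TSV with an id column; GCT 1.2 is supported for score
matrices.  Model parameters are serialized as one TSV per parameter family
with index labels, so a fit is fully reconstructable from text artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ControlGeneSets, ScreenDataset, TargetingMaps
from .mapping import maps_from_tables
from .model import ModelParams, PosteriorApprox, THETA_FIELDS

__all__ = [
    "read_matrix_tsv", "write_matrix_tsv", "read_gct", "write_gct",
    "read_sample_meta", "read_gene_list",
    "read_screen_dataset", "write_screen_dataset",
    "read_targeting_maps", "save_params", "load_params",
    "save_posterior", "load_posterior",
]


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(frame: pd.DataFrame, path, index_label: str = "id") -> None:
    frame.to_csv(path, sep="\t", index_label=index_label)


def read_gct(path) -> pd.DataFrame:
    """GCT 1.2: two header lines, then rows with Name/Description columns."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"unsupported GCT version line: {version!r}")
        fh.readline()  # dimensions; inferred from the table instead
        frame = pd.read_csv(fh, sep="\t")
    frame = frame.set_index("Name").drop(columns=["Description"])
    return frame


def write_gct(frame: pd.DataFrame, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{frame.shape[0]}\t{frame.shape[1]}\n")
        out = frame.copy()
        out.insert(0, "Description", description)
        out.to_csv(fh, sep="\t", index_label="Name")


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    required = {"cell_line", "dataset", "replicate", "role"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata lacks columns: {sorted(missing)}")
    return meta


def read_gene_list(path) -> tuple[str, ...]:
    lines = Path(path).read_text().split()
    return tuple(dict.fromkeys(lines))


def read_control_sets(positive_path, negative_path) -> ControlGeneSets:
    return ControlGeneSets(
        positive=read_gene_list(positive_path),
        negative=read_gene_list(negative_path),
    )


def write_screen_dataset(data: ScreenDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(data.to_frame(), outdir / "lfc.tsv", index_label="shrna_id")
    screens = data.screens.copy()
    screens.insert(0, "screen_id", data.screen_labels())
    screens.to_csv(outdir / "screens.tsv", sep="\t", index=False)


def read_screen_dataset(lfc_path, screens_path=None) -> ScreenDataset:
    frame = read_matrix_tsv(lfc_path)
    if screens_path is not None:
        screens = pd.read_csv(screens_path, sep="\t", dtype=str)[["cell_line", "dataset"]]
    else:  # columns encoded as "cell_line::dataset"
        parts = [c.split("::", 1) for c in frame.columns]
        if not all(len(p) == 2 for p in parts):
            raise ValueError("columns are not 'cell_line::dataset' labels; pass screens_path")
        screens = pd.DataFrame(parts, columns=["cell_line", "dataset"])
    vals = frame.to_numpy(dtype=float)
    mask = np.isfinite(vals)
    return ScreenDataset(
        lfc=np.where(mask, vals, 0.0), mask=mask,
        shrna_ids=[str(i) for i in frame.index], screens=screens,
    )


def read_targeting_maps(gene_map_path, seed_map_path=None, sequences_path=None) -> TargetingMaps:
    gene_map = pd.read_csv(gene_map_path, sep="\t", dtype=str)
    seed_map = pd.read_csv(seed_map_path, sep="\t", dtype=str) if seed_map_path else None
    sequences = pd.read_csv(sequences_path, sep="\t", dtype=str) if sequences_path else None
    return maps_from_tables(gene_map, seed_map=seed_map, sequences=sequences)


def _family_fields(params: ModelParams, data: ScreenDataset, maps: TargetingMaps):
    lines = [str(c) for c in data.cell_lines]
    screens = data.screen_labels()
    return {
        "gene_avg": (maps.gene_ids, ["value"]),
        "gene_dev": (maps.gene_ids, lines),
        "seed_avg": (maps.seed_ids, ["value"]),
        "seed_dev": (maps.seed_ids, lines),
        "batch_offset": (maps.shrna_ids, [str(d) for d in data.datasets]),
        "shrna_offset": (maps.shrna_ids, ["value"]),
        "screen_offset": (screens, ["value"]),
        "screen_scale": (screens, ["value"]),
        "screen_signal": (lines, ["value"]),
        "gene_efficacy": (maps.shrna_ids, ["value"]),
        "seed_efficacy": (maps.shrna_ids, ["value"]),
        "noise_var": (screens, ["value"]),
    }


def save_params(params: ModelParams, data: ScreenDataset, maps: TargetingMaps, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = _family_fields(params, data, maps)
    for name, (index, columns) in layout.items():
        arr = getattr(params, name)
        frame = pd.DataFrame(arr.reshape(len(index), -1), index=index, columns=columns)
        write_matrix_tsv(frame, outdir / f"{name}.tsv", index_label="id")
    (outdir / "shapes.json").write_text(
        json.dumps({name: list(getattr(params, name).shape) for name in layout})
    )


def load_params(indir) -> ModelParams:
    indir = Path(indir)
    shapes = json.loads((indir / "shapes.json").read_text())
    arrays = {}
    for name, shape in shapes.items():
        frame = read_matrix_tsv(indir / f"{name}.tsv")
        arrays[name] = frame.to_numpy(dtype=float).reshape(shape)
    return ModelParams(**arrays)


def save_posterior(post: PosteriorApprox, data: ScreenDataset, maps: TargetingMaps, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for kind, table in (("mean", post.means), ("var", post.variances)):
        for name in THETA_FIELDS:
            arr = np.asarray(table[name])
            frame = pd.DataFrame(arr.reshape(arr.shape[0], -1))
            frame.to_csv(outdir / f"{name}.{kind}.tsv", sep="\t", index=False)
    (outdir / "shapes.json").write_text(
        json.dumps({name: list(np.asarray(post.means[name]).shape) for name in THETA_FIELDS})
    )


def load_posterior(indir) -> PosteriorApprox:
    indir = Path(indir)
    shapes = json.loads((indir / "shapes.json").read_text())
    means, variances = {}, {}
    for name, shape in shapes.items():
        means[name] = pd.read_csv(indir / f"{name}.mean.tsv", sep="\t").to_numpy(float).reshape(shape)
        variances[name] = pd.read_csv(indir / f"{name}.var.tsv", sep="\t").to_numpy(float).reshape(shape)
    return PosteriorApprox(means=means, variances=variances)
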