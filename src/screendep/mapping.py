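"""shRNA-to-gene and shRNA-to-seed incidence construction.

A 21-mer shRNA target sequence maps to a gene when its *initial 19-mer* is an
exact substring of any of the gene's transcripts (the final 1-2 bases are
cleaved during processing and do not contribute to targeting specificity).
Off-target seed effects are driven by two 7-mers on the antisense strand,
positions 1-7 and 2-8 (1-based, inclusive).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import TargetingMaps

__all__ = [
    "reverse_complement",
    "map_shrnas_to_genes",
    "extract_seeds",
    "build_targeting_maps",
    "apply_structural_filters",
    "maps_from_tables",
]

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MAX_GENES_PER_SHRNA = 10  # shRNAs targeting more than this are "promiscuous"


def _check_dna(seq: str, min_len: int, what: str) -> str:
    seq = seq.upper()
    if len(seq) < min_len:
        raise ValueError(f"{what} shorter than {min_len} nt: {seq!r}")
    if set(seq) - _DNA:
        raise ValueError(f"{what} contains non-DNA characters: {seq!r}")
    return seq


def reverse_complement(seq: str) -> str:
    return _check_dna(seq, 1, "sequence").translate(_COMPLEMENT)[::-1]


def map_shrnas_to_genes(
    target_sequences: Mapping[str, str],
    transcripts: Mapping[str, str | Sequence[str]],
) -> pd.DataFrame:
    """Boolean shRNA x gene incidence from exact 19-mer transcript matches.

    Parameters
    ----------
    target_sequences:
        shRNA id -> 21-mer target (sense-strand) sequence.
    transcripts:
        gene id -> transcript sequence or list of transcript sequences.
    """
    gene_ids = list(transcripts)
    gene_seqs = {
        g: [s.upper()] if isinstance(s, str) else [t.upper() for t in s]
        for g, s in transcripts.items()
    }
    rows = {}
    for shrna, seq in target_sequences.items():
        query = _check_dna(seq, 19, "target sequence")[:19]
        rows[shrna] = [any(query in t for t in gene_seqs[g]) for g in gene_ids]
    return pd.DataFrame.from_dict(rows, orient="index", columns=gene_ids)


def extract_seeds(antisense_sequences: Mapping[str, str]) -> pd.DataFrame:
    """Boolean shRNA x seed incidence from antisense positions 1-7 and 2-8.

    Both 7-mer windows are recorded; when they coincide (e.g. homopolymers)
    the row sum is 1.
    """
    pairs = {}
    seeds_seen: dict[str, int] = {}
    for shrna, seq in antisense_sequences.items():
        s = _check_dna(seq, 8, "antisense sequence")
        w1, w2 = s[0:7], s[1:8]
        for w in (w1, w2):
            seeds_seen.setdefault(w, len(seeds_seen))
        pairs[shrna] = (w1, w2)
    seed_ids = sorted(seeds_seen, key=seeds_seen.get)
    frame = pd.DataFrame(False, index=list(pairs), columns=seed_ids)
    for shrna, (w1, w2) in pairs.items():
        frame.loc[shrna, w1] = True
        frame.loc[shrna, w2] = True
    return frame


def build_targeting_maps(gene_incidence: pd.DataFrame, seed_incidence: pd.DataFrame) -> TargetingMaps:
    """Assemble a :class:`TargetingMaps` from boolean incidence frames."""
    if list(gene_incidence.index) != list(seed_incidence.index):
        seed_incidence = seed_incidence.reindex(gene_incidence.index, fill_value=False)
    return TargetingMaps(
        gene_matrix=sparse.csr_matrix(gene_incidence.to_numpy(dtype=float)),
        seed_matrix=sparse.csr_matrix(seed_incidence.to_numpy(dtype=float)),
        shrna_ids=list(gene_incidence.index),
        gene_ids=list(gene_incidence.columns),
        seed_ids=list(seed_incidence.columns),
    )


def apply_structural_filters(
    maps: TargetingMaps, max_genes: int = MAX_GENES_PER_SHRNA
) -> tuple[TargetingMaps, list[str]]:
    """Drop promiscuous/untargeted shRNAs and merge identical-column genes.

    Returns the filtered maps and the list of dropped shRNA ids.  An shRNA is
    retained when it targets between 1 and ``max_genes`` genes and has at
    least one seed.  Genes whose retained-shRNA sets are identical are merged
    into a single "gene family" entity (flagged ``is_family``); families are
    kept in the fit but excluded from released scores.
    """
    genes_per = maps.genes_per_shrna()
    seeds_per = np.asarray(maps.seed_matrix.sum(axis=1)).ravel()
    keep = (genes_per >= 1) & (genes_per <= max_genes) & (seeds_per >= 1)
    dropped = [s for s, k in zip(maps.shrna_ids, keep) if not k]

    G = maps.gene_matrix[keep].toarray()
    B = maps.seed_matrix[keep]
    shrna_ids = [s for s, k in zip(maps.shrna_ids, keep) if k]

    # partition genes by identical targeting columns (over retained shRNAs)
    col_keys: dict[bytes, list[int]] = {}
    for gi in range(G.shape[1]):
        col_keys.setdefault(G[:, gi].tobytes(), []).append(gi)

    new_cols = []
    new_ids: list[str] = []
    is_family: list[bool] = []
    families: dict[str, tuple[str, ...]] = {}
    for members in col_keys.values():
        col = G[:, members[0]]
        if not col.any():  # gene lost all shRNAs after filtering
            continue
        if len(members) == 1:
            new_ids.append(maps.gene_ids[members[0]])
            is_family.append(False)
        else:
            member_ids = tuple(sorted(maps.gene_ids[m] for m in members))
            fam_id = "FAM:" + "|".join(member_ids)
            families[fam_id] = member_ids
            new_ids.append(fam_id)
            is_family.append(True)
        new_cols.append(col)

    Gnew = np.column_stack(new_cols) if new_cols else np.zeros((len(shrna_ids), 0))
    # drop seeds that no longer touch any retained shRNA
    seed_counts = np.asarray(B.sum(axis=0)).ravel()
    seed_keep = seed_counts > 0
    Bnew = B[:, seed_keep]
    seed_ids = [s for s, k in zip(maps.seed_ids, seed_keep) if k]

    return (
        TargetingMaps(
            gene_matrix=sparse.csr_matrix(Gnew),
            seed_matrix=sparse.csr_matrix(Bnew),
            shrna_ids=shrna_ids,
            gene_ids=new_ids,
            seed_ids=seed_ids,
            is_family=np.array(is_family, dtype=bool),
            gene_families=families,
        ),
        dropped,
    )


def maps_from_tables(
    gene_map: pd.DataFrame,
    seed_map: pd.DataFrame | None = None,
    sequences: pd.DataFrame | None = None,
) -> TargetingMaps:
    """Build raw targeting maps from long-format mapping tables.

    ``gene_map`` needs columns ``shrna_id``/``gene_id`` (one row per pair).
    Seeds come either from ``seed_map`` (``shrna_id``/``seed_id``) or are
    derived from a ``sequences`` table with ``shrna_id`` plus an
    ``antisense_seq`` column (or a sense-strand ``target_seq`` 21-mer, which
    is reverse-complemented first).
    """
    gene_inc = (
        gene_map.assign(v=True)
        .pivot_table(index="shrna_id", columns="gene_id", values="v", fill_value=False, aggfunc="any")
        .astype(bool)
    )
    if seed_map is not None:
        seed_inc = (
            seed_map.assign(v=True)
            .pivot_table(index="shrna_id", columns="seed_id", values="v", fill_value=False, aggfunc="any")
            .astype(bool)
        )
    elif sequences is not None:
        seqs = sequences.set_index("shrna_id")
        if "antisense_seq" in seqs.columns:
            anti = seqs["antisense_seq"].to_dict()
        elif "target_seq" in seqs.columns:
            anti = {s: reverse_complement(q) for s, q in seqs["target_seq"].items()}
        else:
            raise ValueError("sequences table needs antisense_seq or target_seq")
        seed_inc = extract_seeds(anti)
    else:
        raise ValueError("either seed_map or sequences must be provided")
    seed_inc = seed_inc.reindex(gene_inc.index, fill_value=False)
    return build_targeting_maps(gene_inc, seed_inc)
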