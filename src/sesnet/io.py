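"""Readers and writers for the pipeline's plain-text formats.

Counts travel as TSV (genes x samples) or MatrixMarket coordinate MTX with
sidecar gene/sample lists; gene sets as GMT; pathway parent-child relations
and scored edge lists as TSV. PPI score columns in either the [0,1] float
dialect or the 0-1000 integer dialect are auto-detected (integer scores are
divided by 1000). Every writer round-trips through its reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_counts", "write_counts", "read_counts_mtx", "write_counts_mtx",
    "read_metadata", "write_metadata", "read_gmt", "write_gmt",
    "read_edge_list", "write_edge_list", "read_hierarchy", "write_hierarchy",
]

_CATEGORICAL_META = ["sex", "race", "plate", "batch"]
_ORDERED_META = {"alcohol": ["0", "1-2", "3-5", ">5"]}


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    df.index.name = "gene"
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """MatrixMarket coordinate file plus .genes.txt / .samples.txt sidecars."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.coo_matrix(counts.to_numpy()))
    prefix.with_suffix(".genes.txt").write_text("\n".join(counts.index) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(counts.columns) + "\n")


def read_counts_mtx(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray().astype(np.int64)
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    samples = prefix.with_suffix(".samples.txt").read_text().splitlines()
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene id in MTX sidecar")
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in _CATEGORICAL_META:
        if col in df:
            df[col] = df[col].astype("category")
    for col, levels in _ORDERED_META.items():
        if col in df:
            df[col] = pd.Categorical(df[col].astype(str), categories=levels, ordered=True)
    return df


def write_metadata(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path) -> dict[str, set]:
    """GMT: one gene set per line — name, description, genes...."""
    sets: dict[str, set] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(annotations: dict[str, set], path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sorted(annotations):
            desc = descriptions.get(name, name)
            genes = "\t".join(sorted(annotations[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def _detect_ppi_dialect(scores: pd.Series) -> pd.Series:
    """[0,1] floats pass through; 0-1000 integer scores are divided by 1000."""
    s = scores.astype(float)
    if s.max() > 1.0:
        if s.max() > 1000 or (s < 0).any():
            raise ValueError("PPI scores must be in [0,1] or integer [0,1000]")
        return s / 1000.0
    return s


def read_edge_list(path, kind: str = "grn") -> pd.DataFrame:
    """Scored edge list TSV: (tf, target, confidence) or (protein_a, protein_b, score)."""
    df = pd.read_csv(path, sep="\t")
    if kind == "grn":
        expected = ["tf", "target", "confidence"]
    elif kind == "ppi":
        expected = ["protein_a", "protein_b", "score"]
    else:
        raise ValueError(f"unknown edge-list kind {kind!r}")
    if list(df.columns[:3]) != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    if kind == "ppi":
        df["score"] = _detect_ppi_dialect(df["score"])
    else:
        if ((df["confidence"] < 0) | (df["confidence"] > 1)).any():
            raise ValueError(f"{path}: GRN confidence outside [0,1]")
    return df


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_hierarchy(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["parent", "child"]:
        raise ValueError(f"{path}: expected columns (parent, child)")
    return df


def write_hierarchy(hierarchy: pd.DataFrame, path) -> None:
    hierarchy.to_csv(path, sep="\t", index=False)
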