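"""Shared numerics: FDR correction, correlation distances, Newick export."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import false_discovery_control


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return false_discovery_control(p, method="bh")


def uncentered_pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - uncentered (non-mean-subtracted) Pearson correlation.

    Ranges over [0, 2]; undefined (raises) when either vector has zero norm.
    """
    nx = float(np.linalg.norm(x))
    ny = float(np.linalg.norm(y))
    if nx == 0.0 or ny == 0.0:
        raise ValueError("uncentered correlation undefined for an all-zero vector")
    return 1.0 - float(np.dot(x, y)) / (nx * ny)


def uncentered_distance_matrix(columns: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - uncentered Pearson across DataFrame columns."""
    v = columns.to_numpy(dtype=float)
    norms = np.linalg.norm(v, axis=0)
    if np.any(norms == 0.0):
        bad = [str(c) for c, n in zip(columns.columns, norms) if n == 0.0]
        raise ValueError(f"all-zero sample vector(s): {', '.join(bad)}")
    corr = (v.T @ v) / np.outer(norms, norms)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def pearson_distance_matrix(rows: np.ndarray, constant_distance: float = 2.0) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between rows.

    Rows with zero variance have no defined correlation; pairs involving them
    are assigned ``constant_distance`` (the maximum) so they merge last and
    fall out as singletons under any sub-maximal cut.
    """
    r = np.asarray(rows, dtype=float)
    n = r.shape[0]
    sd = r.std(axis=1)
    d = np.full((n, n), constant_distance, dtype=float)
    ok = sd > 0
    if ok.sum() >= 2:
        c = np.corrcoef(r[ok])
        d[np.ix_(ok, ok)] = 1.0 - c
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def complete_linkage(dist: np.ndarray):
    """Complete-linkage merge tree from a square distance matrix."""
    return linkage(squareform(dist, checks=False), method="complete")


def leaf_order(linkage_matrix: np.ndarray, labels: list[str]) -> list[str]:
    return [labels[i] for i in leaves_list(linkage_matrix)]


def linkage_to_newick(linkage_matrix: np.ndarray, labels: list[str]) -> str:
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage_matrix, labels)
    return str(tree).strip()


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
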