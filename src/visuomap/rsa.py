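"""Representational similarity of back-projection maps.

Quantifies each participant's influence on the pooled searchlight map:
leave-one-subject-out (LOSO) back-projections, pairwise dissimilarity
(1 - Spearman rank correlation, with cells based on a single vertex or
none removed from both maps), and a classical (Torgerson) metric MDS
ordination of the dissimilarity structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from matplotlib import pyplot as plt
from scipy import stats
from sklearn.base import BaseEstimator

from .backprojection import BackProjectionMap, backproject

__all__ = [
    "loso_maps",
    "map_dissimilarity",
    "dissimilarity_matrix",
    "ClassicalMDS",
    "cmds",
    "ordination_plot",
]


def loso_maps(
    vertex_tables: dict[str, pd.DataFrame],
    value_column: str = "dbeta",
    **bp_params,
) -> dict[str, BackProjectionMap]:
    """All-in, individual, and leave-one-out back-projections.

    With P participants this returns 2P + 1 maps keyed ``pooled``,
    each participant id, and ``LOSO-<id>`` (pooled over everyone
    else). A left-out participant with no vertices leaves the LOSO
    map identical to the pooled one.
    """
    if len(vertex_tables) < 3:
        raise ValueError("LOSO analysis needs at least 3 participants")
    maps: dict[str, BackProjectionMap] = {}
    maps["pooled"] = backproject(vertex_tables, value_column, **bp_params)
    for pid, table in vertex_tables.items():
        maps[pid] = backproject(table, value_column, **bp_params)
    for pid in vertex_tables:
        rest = {k: v for k, v in vertex_tables.items() if k != pid}
        maps[f"LOSO-{pid}"] = backproject(rest, value_column, **bp_params)
    return maps


def map_dissimilarity(a: BackProjectionMap, b: BackProjectionMap) -> float:
    """1 - Spearman correlation between two maps' t-statistics.

    Cells invalid in either map (based on a single vertex or none) and
    untraversed cells are removed from both maps before correlating;
    ties get average ranks. Requires at least 3 shared valid cells.
    """
    if a.grid != b.grid:
        raise ValueError("maps are defined on different grids")
    mask = a.valid & b.valid & a.traversed & b.traversed
    if mask.sum() < 3:
        raise ValueError("fewer than 3 shared valid cells")
    rho = stats.spearmanr(a.t[mask], b.t[mask]).statistic
    return float(1.0 - rho)


def dissimilarity_matrix(
    maps: dict[str, BackProjectionMap],
    order: list[str] | None = None,
) -> pd.DataFrame:
    """Square symmetric matrix of pairwise map dissimilarities."""
    labels = order or list(maps)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = map_dissimilarity(maps[labels[i]],
                                                  maps[labels[j]])
    return pd.DataFrame(D, index=labels, columns=labels)


class ClassicalMDS(BaseEstimator):
    """Classical (metric) multidimensional scaling, Torgerson form.

    Double-centers the squared dissimilarities,
    ``B = -1/2 J D^2 J``, eigendecomposes, and returns the top-k
    coordinates scaled by the square root of the eigenvalues (negative
    eigenvalues truncated at 0). Axes are ordered by decreasing
    eigenvalue and sign-canonicalized so the first point has
    non-negative coordinates.

    Attributes
    ----------
    embedding_ : ndarray, (n_points, n_components)
    eigenvalues_ : ndarray, all eigenvalues in decreasing order
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit_transform(self, D: np.ndarray | pd.DataFrame, y=None) -> np.ndarray:
        labels = list(D.index) if isinstance(D, pd.DataFrame) else None
        D = np.asarray(D, float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be square")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("D must be symmetric")
        n = D.shape[0]
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        B = -0.5 * J @ (D ** 2) @ J
        evals, evecs = np.linalg.eigh(B)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        self.eigenvalues_ = evals
        k = self.n_components
        lam = np.clip(evals[:k], 0.0, None)
        # numerically-zero eigenvalues carry no structure; zero them so
        # duplicate points coincide exactly
        lam[lam < 1e-12 * max(float(evals.max()), 1.0)] = 0.0
        coords = evecs[:, :k] * np.sqrt(lam)
        # reproducible orientation: first nonzero coordinate of each axis
        # is made positive
        for j in range(coords.shape[1]):
            col = coords[:, j]
            nz = np.flatnonzero(np.abs(col) > 1e-12)
            if nz.size and col[nz[0]] < 0:
                coords[:, j] = -col
        self.embedding_ = coords
        self.labels_ = labels
        return coords

    def fit(self, D, y=None) -> "ClassicalMDS":
        self.fit_transform(D)
        return self


def cmds(D: np.ndarray | pd.DataFrame, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper: returns (coordinates, eigenvalues)."""
    est = ClassicalMDS(n_components=k)
    coords = est.fit_transform(D)
    return coords, est.eigenvalues_


def ordination_plot(coords: np.ndarray, labels: list[str], ax=None):
    """Scatter the 2D ordination with text labels."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(coords[:, 0], coords[:, 1], s=18, color="tab:blue")
    for (cx, cy), lab in zip(coords, labels):
        ax.annotate(lab, (cx, cy), fontsize=8,
                    textcoords="offset points", xytext=(3, 3))
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    return ax
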