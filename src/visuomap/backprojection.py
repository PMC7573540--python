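"""Visual-space searchlight back-projection.

Per-vertex differential betas are projected into visual space by
passing a circular searchlight (radius 1 dva) across a 17 x 17 dva
mesh grid (0.1 dva spacing, centers restricted to eccentricity
<= 8.6 dva). At each grid point, the betas of all vertices whose pRF
center falls inside the searchlight are summarized as a one-sample
t-statistic against 0; cells with a single vertex or none are set to
0. Alongside, each member vertex contributes a distance weight
``1 - d/r``; the searchlight-wise sums are normalized by the 25th
percentile of their distribution (clipped at 1), yielding the
saturation weights used for rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib import colors as mcolors
from matplotlib import pyplot as plt
from scipy import spatial
from sklearn.base import BaseEstimator

from .grid import VisualFieldGrid

__all__ = [
    "BackProjectionMap",
    "SearchlightBackProjection",
    "vertices_in_searchlight",
    "cell_t_statistic",
    "cell_weight",
    "normalize_weights",
    "backproject",
    "render_heatmap",
]

#: Default searchlight radius, dva.
SEARCHLIGHT_RADIUS = 1.0
#: Maximal searchlight-center eccentricity during traversal, dva
#: (grid extent 8.5 plus one step, so no border vertex is missed).
TRAVERSAL_ECC_MAX = 8.6
#: Finite stand-in for an infinite t (zero variance, n >= 2); only
#: degenerate noise-free synthetic input can produce it.
T_DEGENERATE_SENTINEL = 1e6


@dataclass
class BackProjectionMap:
    """Searchlight summary statistics over a visual-field grid.

    All arrays have the grid's (ny, nx) shape. ``t`` is the per-cell
    one-sample t-statistic (0 where n <= 1), ``n`` the vertex count,
    ``w_raw`` the summed distance weights, ``w`` the normalized weight
    in [0, 1], ``valid`` flags cells with n >= 2 and ``traversed``
    flags centers within the traversal eccentricity cap (cells outside
    were never visited, which is distinct from a zero).
    """

    grid: VisualFieldGrid
    t: np.ndarray
    n: np.ndarray
    w_raw: np.ndarray
    w: np.ndarray
    valid: np.ndarray
    traversed: np.ndarray
    meta: dict = field(default_factory=dict)


def vertices_in_searchlight(
    center: tuple[float, float],
    vertex_table: pd.DataFrame,
    radius: float = SEARCHLIGHT_RADIUS,
) -> pd.DataFrame:
    """Vertices whose pRF center lies strictly inside the searchlight."""
    d = np.hypot(vertex_table["x"] - center[0], vertex_table["y"] - center[1])
    return vertex_table.loc[d < radius]


def cell_t_statistic(betas: np.ndarray) -> float:
    """One-sample t against 0 of the betas inside one searchlight.

    ``t = mean / (sd / sqrt(n))`` with the sample sd (n-1 denominator).
    Cells based on a single vertex or none return 0. A zero sd with
    n >= 2 returns a signed finite sentinel instead of +-inf.
    """
    betas = np.asarray(betas, float)
    n = betas.size
    if n <= 1:
        return 0.0
    sd = betas.std(ddof=1)
    m = betas.mean()
    if sd == 0:
        return float(np.sign(m) * T_DEGENERATE_SENTINEL)
    return float(m / (sd / np.sqrt(n)))


def cell_weight(vertex_distances: np.ndarray,
                radius: float = SEARCHLIGHT_RADIUS,
                scheme: str = "linear") -> float:
    """Summed distance weights of the vertices inside one searchlight.

    Each vertex contributes its radius-normalized inverse distance
    from the searchlight center; with the default ``linear`` scheme
    this is ``1 - d/r`` (1 at the center, 0 at the rim). The
    ``reciprocal`` scheme uses ``r/d`` instead (unbounded at d -> 0).
    Summary weights based on a single vertex (or none) are set to 0.
    """
    d = np.asarray(vertex_distances, float)
    if d.size <= 1:
        return 0.0
    if scheme == "linear":
        w = 1.0 - d / radius
    elif scheme == "reciprocal":
        with np.errstate(divide="ignore"):
            w = radius / d
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    return float(w.sum())


def normalize_weights(raw: np.ndarray,
                      traversed: np.ndarray | None = None,
                      include_zeros: bool = True) -> np.ndarray:
    """Normalize summary weights by the 25th percentile, clipped at 1.

    The percentile is taken over the traversed cells (including
    zero-weight cells unless ``include_zeros`` is False). If the 25th
    percentile is 0, all nonzero cells map to 1 (degenerate rule).
    Untraversed cells stay 0.
    """
    raw = np.asarray(raw, float)
    if traversed is None:
        traversed = np.ones(raw.shape, dtype=bool)
    pool = raw[traversed]
    if not include_zeros:
        pool = pool[pool > 0]
    p25 = np.percentile(pool, 25) if pool.size else 0.0
    out = np.zeros_like(raw)
    if p25 > 0:
        out[traversed] = np.minimum(raw[traversed] / p25, 1.0)
    else:
        out[traversed] = (raw[traversed] > 0).astype(float)
    return out


class SearchlightBackProjection(BaseEstimator):
    """Searchlight back-projection of per-vertex values into visual space.

    Parameters
    ----------
    radius : float
        Searchlight radius, dva.
    extent, step : float
        Grid half-width and spacing, dva (defaults give 171 centers
        per axis spanning -8.5..8.5).
    ecc_max : float
        Traversal cap on searchlight-center eccentricity, dva.
    value_column : str
        Column of the vertex table holding the per-vertex values.
    weight_scheme : str
        ``linear`` (1 - d/r) or ``reciprocal`` (r/d).
    p25_include_zeros : bool
        Whether zero-weight traversed cells enter the normalization
        percentile.

    After :meth:`fit`, the summary arrays are available as ``t_``,
    ``n_``, ``w_raw_``, ``w_``, ``valid_``, ``traversed_`` and bundled
    in ``map_``.
    """

    def __init__(self, radius: float = SEARCHLIGHT_RADIUS,
                 extent: float = 8.5, step: float = 0.1,
                 ecc_max: float = TRAVERSAL_ECC_MAX,
                 value_column: str = "dbeta",
                 weight_scheme: str = "linear",
                 p25_include_zeros: bool = True):
        self.radius = radius
        self.extent = extent
        self.step = step
        self.ecc_max = ecc_max
        self.value_column = value_column
        self.weight_scheme = weight_scheme
        self.p25_include_zeros = p25_include_zeros

    def _grid(self) -> VisualFieldGrid:
        return VisualFieldGrid(-self.extent, self.extent,
                               -self.extent, self.extent, self.step)

    def fit(self, X: pd.DataFrame, y=None) -> "SearchlightBackProjection":
        """Run the searchlight pass over a (pooled) vertex table.

        ``X`` must carry columns ``x, y`` (pRF centers, dva) and the
        configured value column. The table is expected to be smoothed
        and filtered already.
        """
        if len(X) == 0:
            raise ValueError("empty vertex table")
        grid = self._grid()
        gx, gy = grid.meshgrid()
        centers = np.column_stack([gx.ravel(), gy.ravel()])
        traversed_flat = np.hypot(centers[:, 0], centers[:, 1]) <= self.ecc_max

        pts = X[["x", "y"]].to_numpy(float)
        vals = X[self.value_column].to_numpy(float)
        tree = spatial.cKDTree(pts)
        # strict d < r membership: query at r then drop boundary ties
        neighbors = tree.query_ball_point(centers[traversed_flat], self.radius)

        shape = grid.shape
        t = np.zeros(shape).ravel()
        n = np.zeros(shape, dtype=int).ravel()
        w_raw = np.zeros(shape).ravel()
        idx_traversed = np.flatnonzero(traversed_flat)
        for ci, members in zip(idx_traversed, neighbors):
            if not members:
                continue
            m = np.asarray(members)
            d = np.hypot(pts[m, 0] - centers[ci, 0],
                         pts[m, 1] - centers[ci, 1])
            inside = d < self.radius
            m, d = m[inside], d[inside]
            n[ci] = m.size
            if m.size == 0:
                continue
            t[ci] = cell_t_statistic(vals[m])
            w_raw[ci] = cell_weight(d, self.radius, self.weight_scheme)

        t = t.reshape(shape)
        n = n.reshape(shape)
        w_raw = w_raw.reshape(shape)
        traversed = traversed_flat.reshape(shape)
        w = normalize_weights(w_raw, traversed, self.p25_include_zeros)
        valid = traversed & (n >= 2)
        self.t_, self.n_, self.w_raw_, self.w_ = t, n, w_raw, w
        self.valid_, self.traversed_ = valid, traversed
        self.map_ = BackProjectionMap(
            grid, t, n, w_raw, w, valid, traversed,
            meta={"radius": self.radius, "ecc_max": self.ecc_max,
                  "value_column": self.value_column,
                  "weight_scheme": self.weight_scheme,
                  "n_vertices": int(len(X))})
        return self

    def transform(self, X: pd.DataFrame) -> BackProjectionMap:
        """Fit on ``X`` and return the resulting map."""
        return self.fit(X).map_


def backproject(
    vertex_tables: pd.DataFrame | list[pd.DataFrame] | dict[str, pd.DataFrame],
    value_column: str = "dbeta",
    **params,
) -> BackProjectionMap:
    """Pool vertex tables across participants and back-project.

    Accepts a single table, a list, or a mapping of participant ->
    table; tables are concatenated (each participant's table should be
    smoothed and filtered beforehand) and passed through the
    searchlight.
    """
    if isinstance(vertex_tables, dict):
        tables = list(vertex_tables.values())
    elif isinstance(vertex_tables, pd.DataFrame):
        tables = [vertex_tables]
    else:
        tables = list(vertex_tables)
    pooled = pd.concat(tables, ignore_index=True) if len(tables) != 1 else tables[0]
    est = SearchlightBackProjection(value_column=value_column, **params)
    return est.fit(pooled).map_


def render_heatmap(
    bp_map: BackProjectionMap,
    cap: float = 25.0,
    cmap: str = "RdBu_r",
    background: tuple[float, float, float] = (1.0, 1.0, 1.0),
    outline: np.ndarray | None = None,
    ax=None,
):
    """Render a back-projection map as a saturation-weighted heatmap.

    t-statistics beyond ``+-cap`` are set to the cap, mapped through a
    diverging colormap, and each cell's color saturation is scaled by
    its normalized summary weight (w = 0 renders as background).
    Returns the RGB image array of the grid's shape; if ``ax`` is
    given, also draws it (with an optional stimulus outline overlay).
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    t = np.clip(bp_map.t, -cap, cap)
    norm = mcolors.Normalize(vmin=-cap, vmax=cap)
    rgba = plt.get_cmap(cmap)(norm(t))
    rgb = rgba[..., :3]
    hsv = mcolors.rgb_to_hsv(rgb)
    hsv[..., 1] *= np.clip(bp_map.w, 0.0, 1.0)
    rgb = mcolors.hsv_to_rgb(hsv)
    bg = np.asarray(background, float)
    mask = ~bp_map.traversed | (bp_map.w <= 0)
    rgb[mask] = bg
    if ax is not None:
        g = bp_map.grid
        ax.imshow(rgb, origin="lower",
                  extent=(g.x_min, g.x_max, g.y_min, g.y_max))
        if outline is not None:
            ax.contour(g.x, g.y, outline.astype(float), levels=[0.5],
                       colors="white", linewidths=0.8)
        ax.set_xlabel("x (dva)")
        ax.set_ylabel("y (dva)")
    return rgb
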