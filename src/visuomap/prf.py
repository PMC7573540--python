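"""Population receptive field (pRF) model.

Each vertex's pRF is a 2D isotropic Gaussian in visual space with four
free parameters: center ``(x, y)`` in dva, size ``sigma`` in dva, and
response amplitude ``beta``. The forward model predicts a BOLD series
as the HRF-convolved overlap between the Gaussian and the stimulus
aperture at each time step; fitting is a coarse grid search over
``(x, y, sigma)`` with ``beta`` solved by least squares, followed by
local derivative-free refinement.

The Gaussian is peak-normalized (value 1 at its center, not unit
integral); ``beta`` therefore absorbs all scale, which changes its
interpretation but not the fit quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal, spatial
from sklearn.base import BaseEstimator

from .grid import VisualFieldGrid
from .hrf import double_gamma_hrf
from .stimuli import ApertureSequence

__all__ = [
    "PRFParams",
    "gaussian_field",
    "predict_timeseries",
    "predict_timeseries_matrix",
    "PRFEstimator",
    "fit_prf",
    "filter_vertices",
    "smooth_vertex_values",
]

#: Goodness-of-fit floor below which a pRF estimate is unusable at all.
R2_FLOOR_SMOOTHING = 0.01
#: Stricter floor applied before back-projection.
R2_FLOOR_BACKPROJECTION = 0.05
#: Maximum eccentricity of the stimulated mapping area (dva).
ECC_MAX_BACKPROJECTION = 8.5
#: FWHM-to-sigma conversion for Gaussian kernels.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class PRFParams:
    """The four pRF parameters: center (dva), size (dva), amplitude."""

    x: float
    y: float
    sigma: float
    beta: float = 1.0

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x, self.y))


def gaussian_field(prf: PRFParams, grid: VisualFieldGrid) -> np.ndarray:
    """Evaluate the peak-normalized pRF Gaussian on a grid.

    ``w(gx, gy) = exp(-((gx-x)^2 + (gy-y)^2) / (2 sigma^2))``.
    """
    if prf.sigma <= 0:
        raise ValueError(f"sigma must be positive, got {prf.sigma}")
    X, Y = grid.meshgrid()
    return np.exp(-((X - prf.x) ** 2 + (Y - prf.y) ** 2)
                  / (2.0 * prf.sigma ** 2))


def _convolved_apertures(apertures: ApertureSequence,
                         hrf: np.ndarray,
                         tr: float) -> np.ndarray:
    """HRF-convolve the aperture stack frame-wise, resampled to TR.

    Convolution commutes with the spatial sum, so convolving the
    aperture pixels once lets any pRF prediction be a single dot
    product. Returns (n_volumes, n_pixels).
    """
    frames = apertures.frames.reshape(apertures.n_frames, -1).astype(float)
    conv = signal.fftconvolve(frames, hrf[:, None], axes=0)[:apertures.n_frames]
    d = apertures.frame_duration
    duration = apertures.n_frames * d
    n_vol = int(round(duration / tr))
    if abs(d - tr) < 1e-12:
        return conv
    frame_t = np.arange(apertures.n_frames) * d
    vol_t = np.arange(n_vol) * tr
    out = np.empty((n_vol, conv.shape[1]))
    for j in range(conv.shape[1]):
        out[:, j] = np.interp(vol_t, frame_t, conv[:, j])
    return out


def predict_timeseries(
    prf: PRFParams,
    apertures: ApertureSequence,
    hrf: np.ndarray | None = None,
    tr: float = 1.0,
) -> np.ndarray:
    """Forward-model the BOLD series of a single pRF.

    Per frame the aperture-pRF overlap is summed over the grid, the
    overlap series is convolved with the HRF, resampled to the TR, and
    scaled by ``beta``. Linear in ``beta`` by construction.
    """
    if apertures.n_frames == 0:
        raise ValueError("empty aperture sequence")
    if hrf is None:
        hrf = double_gamma_hrf(apertures.frame_duration)
    return predict_timeseries_matrix(
        np.array([prf.x]), np.array([prf.y]), np.array([prf.sigma]),
        np.array([prf.beta]), apertures, hrf, tr)[0]


def predict_timeseries_matrix(
    x: np.ndarray, y: np.ndarray, sigma: np.ndarray, beta: np.ndarray,
    apertures: ApertureSequence, hrf: np.ndarray, tr: float = 1.0,
) -> np.ndarray:
    """Vectorized forward model; returns (n_prfs, n_volumes)."""
    aconv = _convolved_apertures(apertures, hrf, tr)
    X, Y = apertures.grid.meshgrid()
    px, py = X.ravel(), Y.ravel()
    g = np.exp(-((px[:, None] - x) ** 2 + (py[:, None] - y) ** 2)
               / (2.0 * sigma ** 2))
    return (aconv @ g).T * beta[:, None]


class PRFEstimator(BaseEstimator):
    """Coarse-to-fine pRF fitting for a matrix of vertex time series.

    Parameters
    ----------
    apertures : ApertureSequence
        The mapping stimulus driving the forward model.
    tr : float
        Repetition time of the series, seconds.
    hrf : ndarray, optional
        HRF kernel sampled at the aperture frame rate; canonical
        double-gamma by default.
    coarse_step : float
        Lattice spacing of the (x, y) grid search, dva.
    extent : float
        Half-width of the search lattice, dva.
    sigma_min, sigma_max, n_sigma : float, float, int
        Logarithmic sigma search range.
    refine : bool
        Run Nelder-Mead refinement of (x, y, log sigma) from the best
        coarse candidate; never returns a worse r2 than the coarse fit.
    r2_floor : float
        Fits at or below this r2, or with ``beta <= 0``, are flagged as
        not accepted (artifacts).

    Attributes
    ----------
    params_ : DataFrame
        Per-vertex ``x, y, sigma, beta, r2, eccentricity, accepted``.
    """

    def __init__(self, apertures: ApertureSequence, tr: float = 1.0,
                 hrf: np.ndarray | None = None, coarse_step: float = 0.5,
                 extent: float = 9.0, sigma_min: float = 0.1,
                 sigma_max: float = 8.0, n_sigma: int = 20,
                 refine: bool = True, r2_floor: float = R2_FLOOR_SMOOTHING):
        self.apertures = apertures
        self.tr = tr
        self.hrf = hrf
        self.coarse_step = coarse_step
        self.extent = extent
        self.sigma_min = sigma_min
        self.sigma_max = sigma_max
        self.n_sigma = n_sigma
        self.refine = refine
        self.r2_floor = r2_floor

    # -- internals ---------------------------------------------------------

    def _prepare(self):
        hrf = (self.hrf if self.hrf is not None
               else double_gamma_hrf(self.apertures.frame_duration))
        aconv = _convolved_apertures(self.apertures, hrf, self.tr)
        # the data are linearly detrended in preprocessing; detrending is a
        # linear projection that commutes with the spatial sum, so applying
        # it to the convolved apertures detrends every candidate prediction
        aconv = signal.detrend(aconv, axis=0, type="linear")
        X, Y = self.apertures.grid.meshgrid()
        return aconv, X.ravel(), Y.ravel()

    @staticmethod
    def _score(aconv, px, py, x, y, sigma, yv):
        """(r2, beta) of a single candidate against a centered series."""
        g = np.exp(-((px - x) ** 2 + (py - y) ** 2) / (2.0 * sigma ** 2))
        p = aconv @ g
        p = p - p.mean()
        pp = p @ p
        if pp <= 0:
            return 0.0, 0.0
        py_ = p @ yv
        yy = yv @ yv
        if yy <= 0:
            return 0.0, 0.0
        return float(py_ ** 2 / (pp * yy)), float(py_ / pp)

    def fit(self, X: np.ndarray, y=None) -> "PRFEstimator":
        """Fit pRFs to each row of ``X`` (vertices x volumes)."""
        Y = np.atleast_2d(np.asarray(X, float))
        aconv, px, py = self._prepare()
        if Y.shape[1] != aconv.shape[0]:
            raise ValueError(
                f"series length {Y.shape[1]} does not match the aperture "
                f"sequence ({aconv.shape[0]} volumes)")
        Yc = Y - Y.mean(axis=1, keepdims=True)
        ynorm = np.linalg.norm(Yc, axis=1)
        degenerate = ynorm == 0

        xs = np.arange(-self.extent, self.extent + 1e-9, self.coarse_step)
        ys = xs
        sigmas = np.geomspace(self.sigma_min, self.sigma_max, self.n_sigma)
        XX, YY = np.meshgrid(xs, ys)
        cx, cy = XX.ravel(), YY.ravel()

        n_v = Y.shape[0]
        best_r2 = np.zeros(n_v)
        best_idx = np.zeros(n_v, dtype=int)
        best_sig = np.zeros(n_v, dtype=int)
        best_sgn = np.ones(n_v)
        yn = np.where(degenerate, 1.0, ynorm)
        Yn = Yc / yn[:, None]
        for si, s in enumerate(sigmas):
            g = np.exp(-((px[:, None] - cx) ** 2 + (py[:, None] - cy) ** 2)
                       / (2.0 * s * s))
            pred = aconv @ g
            pred -= pred.mean(axis=0)
            norms = np.linalg.norm(pred, axis=0)
            norms[norms == 0] = np.inf
            corr = (Yn @ pred) / norms             # (n_v, n_cand)
            idx = np.argmax(np.abs(corr), axis=1)
            r2 = corr[np.arange(n_v), idx] ** 2
            upd = r2 > best_r2
            best_r2[upd] = r2[upd]
            best_idx[upd] = idx[upd]
            best_sig[upd] = si
            best_sgn[upd] = np.sign(corr[np.arange(n_v), idx][upd])

        out = np.empty((n_v, 5))  # x, y, sigma, beta, r2
        for i in range(n_v):
            if degenerate[i]:
                out[i] = (0.0, 0.0, sigmas[0], 0.0, 0.0)
                continue
            x0, y0 = cx[best_idx[i]], cy[best_idx[i]]
            s0 = sigmas[best_sig[i]]
            r2_c, beta_c = self._score(aconv, px, py, x0, y0, s0, Yc[i])
            xf, yf, sf, bf, r2f = x0, y0, s0, beta_c, r2_c
            if self.refine:
                yv = Yc[i]

                def neg_r2(q):
                    return -self._score(aconv, px, py, q[0], q[1],
                                        np.exp(q[2]), yv)[0]

                res = optimize.minimize(
                    neg_r2, [x0, y0, np.log(s0)], method="Nelder-Mead",
                    options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400})
                r2_r = -res.fun
                if r2_r >= r2_c:  # refinement never degrades the fit
                    xf, yf, sf = res.x[0], res.x[1], np.exp(res.x[2])
                    r2f, bf = self._score(aconv, px, py, xf, yf, sf, yv)
            out[i] = (xf, yf, sf, bf, r2f)

        params = pd.DataFrame(out, columns=["x", "y", "sigma", "beta", "r2"])
        params["eccentricity"] = np.hypot(params["x"], params["y"])
        params["accepted"] = ((params["r2"] > self.r2_floor)
                              & (params["beta"] > 0)
                              & (params["sigma"] > 0)
                              & ~degenerate)
        self.params_ = params
        return self

    def predict(self, X=None) -> np.ndarray:
        """Forward-model series for the fitted parameters."""
        p = self.params_
        hrf = (self.hrf if self.hrf is not None
               else double_gamma_hrf(self.apertures.frame_duration))
        return predict_timeseries_matrix(
            p["x"].to_numpy(), p["y"].to_numpy(), p["sigma"].to_numpy(),
            p["beta"].to_numpy(), self.apertures, hrf, self.tr)


def fit_prf(series: np.ndarray, apertures: ApertureSequence,
            **kwargs) -> pd.Series:
    """Fit a single vertex series; returns one row of fit results."""
    est = PRFEstimator(apertures, **kwargs).fit(np.atleast_2d(series))
    return est.params_.iloc[0]


def filter_vertices(table: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Apply the staged vertex exclusion cascade.

    ``pre_smoothing`` removes artifacts and unusable fits
    (``r2 <= 0.01``, ``sigma <= 0`` or ``beta <= 0``);
    ``pre_backprojection`` additionally removes poor fits
    (``r2 <= 0.05``) and pRF centers outside the stimulated mapping
    area (eccentricity ``>= 8.5`` dva). Both thresholds are inclusive
    on the removal side.
    """
    if stage not in ("pre_smoothing", "pre_backprojection"):
        raise ValueError(f"unknown filter stage {stage!r}")
    keep = ((table["r2"] > R2_FLOOR_SMOOTHING)
            & (table["sigma"] > 0) & (table["beta"] > 0))
    if stage == "pre_backprojection":
        ecc = np.hypot(table["x"], table["y"])
        keep &= (table["r2"] > R2_FLOOR_BACKPROJECTION)
        keep &= ecc < ECC_MAX_BACKPROJECTION
    return table.loc[keep].copy()


def smooth_vertex_values(
    values: np.ndarray,
    coords_mm: np.ndarray,
    fwhm: float = 3.0,
    mask: np.ndarray | None = None,
    cutoff_sigmas: float = 4.0,
) -> np.ndarray:
    """Surface smoothing with a Gaussian kernel of given FWHM (mm).

    ``coords_mm`` are 2D positions on a flattened cortical sheet used
    as the geodesic-distance proxy. Vertices where ``mask`` is False
    are excluded: they contribute no weight and receive NaN. The kernel
    sigma is ``fwhm / 2.3548``; weights are truncated at
    ``cutoff_sigmas`` sigmas. Weight normalization makes a constant
    field a fixed point.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    values = np.asarray(values, float)
    coords = np.asarray(coords_mm, float)
    if mask is None:
        mask = np.ones(len(values), dtype=bool)
    if fwhm == 0:
        out = np.where(mask, values, np.nan)
        return out
    sig = fwhm * FWHM_TO_SIGMA
    idx = np.flatnonzero(mask)
    pts = coords[idx]
    tree = spatial.cKDTree(pts)
    pairs = tree.sparse_distance_matrix(tree, cutoff_sigmas * sig,
                                        output_type="coo_matrix")
    w = np.exp(-pairs.data ** 2 / (2.0 * sig * sig))
    num = np.zeros(len(idx))
    den = np.zeros(len(idx))
    np.add.at(num, pairs.row, w * values[idx][pairs.col])
    np.add.at(den, pairs.row, w)
    out = np.full(len(values), np.nan)
    out[idx] = num / den
    return out
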