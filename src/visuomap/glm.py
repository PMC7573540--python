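"""Percept-state and block GLMs.

Builds boxcar design matrices from event tables (including
variable-epoch percept regressors parsed from key-press streams),
convolves them with the canonical HRF, removes slow drifts with a
discrete-cosine high-pass projection applied identically to data and
design, fits the linear model (OLS or two-pass AR(1) prewhitening),
and forms contrasts of differential betas. Fixation intervals are
modeled implicitly (no baseline regressor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .hrf import double_gamma_hrf
from .synth import PerceptStream

__all__ = [
    "parse_percept_stream",
    "dct_drift_basis",
    "n_drift_columns",
    "DesignMatrix",
    "build_design",
    "FMRIGLM",
    "fit_glm",
    "ContrastResult",
]

PERCEPT_CONDITIONS = ("global", "local", "pre_first_press")


def parse_percept_stream(stream: PerceptStream) -> pd.DataFrame:
    """Convert a key-press stream into a variable-epoch event table.

    The interval from display onset to the first press is labeled
    ``pre_first_press``; each subsequent inter-press interval carries
    the state of the press that opened it, and the final epoch ends at
    display offset. Repeated presses of the state already being
    reported (observers who lost track were allowed to press again)
    are merged into the ongoing epoch. An empty stream yields a single
    ``pre_first_press`` epoch covering the whole window.
    """
    rows = []
    onset, offset = stream.display_onset, stream.display_offset
    if offset <= onset:
        return pd.DataFrame(columns=["onset", "duration", "condition"])
    if not stream.events:
        return pd.DataFrame(
            [{"onset": onset, "duration": offset - onset,
              "condition": "pre_first_press"}])
    t_first = stream.events[0][0]
    rows.append({"onset": onset, "duration": t_first - onset,
                 "condition": "pre_first_press"})
    current_state = None
    current_start = t_first
    for t, key in stream.events:
        if key == current_state:
            continue  # duplicate press of the ongoing percept
        if current_state is not None:
            rows.append({"onset": current_start,
                         "duration": t - current_start,
                         "condition": current_state})
        current_state, current_start = key, t
    rows.append({"onset": current_start, "duration": offset - current_start,
                 "condition": current_state})
    return pd.DataFrame(rows)


def n_drift_columns(duration_s: float, cutoff_s: float) -> int:
    """Number of discrete-cosine drift regressors for a run.

    ``floor(2 * duration / cutoff)`` non-constant cosines have period
    longer than the cutoff.
    """
    return int(np.floor(2.0 * duration_s / cutoff_s))


def dct_drift_basis(n_volumes: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Orthonormal DCT-II basis of slow drifts (constant term excluded)."""
    k = n_drift_columns(n_volumes * tr, cutoff_s)
    t = np.arange(n_volumes)
    basis = np.empty((n_volumes, k))
    for j in range(1, k + 1):
        basis[:, j - 1] = np.sqrt(2.0 / n_volumes) * np.cos(
            np.pi * j * (2 * t + 1) / (2.0 * n_volumes))
    return basis


@dataclass
class DesignMatrix:
    """A convolved, high-pass-filtered fMRI design.

    ``matrix`` holds the filtered regressors (volumes x regressors);
    ``drift_basis`` the orthonormal DCT columns whose span has been
    projected out of both the design and (via :meth:`apply_hpf`) the
    data.
    """

    matrix: np.ndarray
    names: list[str]
    tr: float
    drift_basis: np.ndarray = field(
        default_factory=lambda: np.empty((0, 0)))

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def apply_hpf(self, Y: np.ndarray) -> np.ndarray:
        """Residual-forming high-pass projection, ``Y - C (C^T Y)``.

        Idempotent because the basis is orthonormal.
        """
        C = self.drift_basis
        if C.size == 0:
            return np.asarray(Y, float)
        Y = np.asarray(Y, float)
        return Y - C @ (C.T @ Y)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def build_design(
    events: pd.DataFrame,
    tr: float,
    n_volumes: int,
    hpf_cutoff: float | None = None,
    hrf: np.ndarray | None = None,
    nuisance: np.ndarray | None = None,
    oversample: int = 10,
    add_constant: bool = True,
) -> DesignMatrix:
    """Build an HRF-convolved boxcar design from an event table.

    Events (columns ``onset, duration, condition``, seconds) become one
    boxcar regressor per condition, sampled on an oversampled time
    grid, convolved with the HRF and downsampled to volume onsets.
    Zero-duration events enter as unit impulses. Optional nuisance
    columns (e.g. 6 motion parameters) and a constant are appended and
    are not convolved. When ``hpf_cutoff`` is given, the DCT drift
    subspace is projected out of every regressor; apply the same
    projection to the data with :meth:`DesignMatrix.apply_hpf`.
    """
    if hpf_cutoff is not None and hpf_cutoff <= 2 * tr:
        raise ValueError("hpf cutoff must exceed 2*TR")
    run_end = n_volumes * tr
    if len(events) and (events["onset"] + events["duration"]).max() > run_end + 1e-9:
        raise ValueError("events extend past the end of the run")

    dt = tr / oversample
    n_hi = n_volumes * oversample
    if hrf is None:
        hrf = double_gamma_hrf(dt)
    conditions = list(dict.fromkeys(events["condition"])) if len(events) else []
    cols, names = [], []
    for cond in conditions:
        hi = np.zeros(n_hi)
        for _, ev in events[events["condition"] == cond].iterrows():
            i0 = int(round(ev["onset"] / dt))
            if ev["duration"] > 0:
                i1 = int(round((ev["onset"] + ev["duration"]) / dt))
                hi[i0:max(i1, i0 + 1)] = 1.0
            elif i0 < n_hi:
                hi[i0] = 1.0  # impulse event
        conv = np.convolve(hi, hrf)[:n_hi]
        cols.append(conv[::oversample])
        names.append(cond)
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, float))
        if nuisance.shape[0] != n_volumes:
            nuisance = nuisance.T
        for j in range(nuisance.shape[1]):
            cols.append(nuisance[:, j])
            names.append(f"nuisance_{j}")
    if add_constant:
        cols.append(np.ones(n_volumes))
        names.append("constant")
    X = np.column_stack(cols) if cols else np.empty((n_volumes, 0))

    drift = np.empty((0, 0))
    if hpf_cutoff is not None:
        drift = dct_drift_basis(n_volumes, tr, hpf_cutoff)
        if drift.size:
            keep = [i for i, nm in enumerate(names) if nm != "constant"]
            X[:, keep] = X[:, keep] - drift @ (drift.T @ X[:, keep])
    design = DesignMatrix(X, names, tr, drift)
    if X.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient after filtering")
    return design


@dataclass
class ContrastResult:
    """A contrast of GLM betas per vertex."""

    effect: np.ndarray        # contrast-weighted beta per vertex
    se: np.ndarray
    dof: float
    weights: np.ndarray

    @property
    def t(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, self.effect / self.se, 0.0)


class FMRIGLM(BaseEstimator):
    """Mass-univariate linear model over vertices.

    ``fit(design, Y)`` takes a :class:`DesignMatrix` (or raw matrix)
    and data ``Y`` of shape (volumes, vertices). With
    ``ar_model='ar1'`` a two-pass prewhitening is used: OLS residuals
    give a single lag-1 autocorrelation pooled over vertices, both
    sides are prewhitened and the model refit (a pragmatic stand-in
    for full restricted-maximum-likelihood AR(1) estimation).

    Attributes
    ----------
    coef_ : ndarray, (regressors, vertices)
    resid_var_ : ndarray, (vertices,)
    dof_ : float
    rho_ : float, the pooled AR(1) coefficient (0 under OLS)
    """

    def __init__(self, ar_model: str = "none"):
        if ar_model not in ("none", "ar1"):
            raise ValueError("ar_model must be 'none' or 'ar1'")
        self.ar_model = ar_model

    def fit(self, design: DesignMatrix | np.ndarray, Y: np.ndarray) -> "FMRIGLM":
        if isinstance(design, DesignMatrix):
            X = design.matrix
            Y = design.apply_hpf(Y)
            n_drift = design.drift_basis.shape[1] if design.drift_basis.size else 0
            self.names_ = list(design.names)
        else:
            X = np.asarray(design, float)
            Y = np.asarray(Y, float)
            n_drift = 0
            self.names_ = [f"x{i}" for i in range(X.shape[1])]
        Y = np.atleast_2d(Y)
        if Y.shape[0] != X.shape[0]:
            raise ValueError("Y and design disagree on the number of volumes")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError("design matrix is rank-deficient")

        beta, resid = self._ols(X, Y)
        self.rho_ = 0.0
        dof = X.shape[0] - rank - n_drift
        if self.ar_model == "ar1":
            num = float(np.sum(resid[1:] * resid[:-1]))
            den = float(np.sum(resid * resid))
            rho = num / den if den > 0 else 0.0
            Xw = X[1:] - rho * X[:-1]
            Yw = Y[1:] - rho * Y[:-1]
            beta, resid = self._ols(Xw, Yw)
            self.rho_ = rho
            dof = Xw.shape[0] - rank - n_drift
            X = Xw
        self.coef_ = beta
        self.dof_ = float(max(dof, 1))
        self.resid_var_ = (resid ** 2).sum(axis=0) / self.dof_
        self.xtx_inv_ = np.linalg.inv(X.T @ X)
        self.resid_ = resid
        self.design_cols_ = X.shape[1]
        return self

    @staticmethod
    def _ols(X, Y):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        return beta, Y - X @ beta

    def contrast(self, weights) -> ContrastResult:
        """Weighted combination of betas per vertex, with its SE.

        For differential contrasts the weights sum to zero over the
        condition regressors.
        """
        w = np.zeros(self.design_cols_)
        if isinstance(weights, dict):
            for name, val in weights.items():
                w[self.names_.index(name)] = val
        else:
            weights = np.asarray(weights, float)
            if len(weights) > self.design_cols_:
                raise ValueError(
                    f"{len(weights)} weights for {self.design_cols_} regressors")
            w[:len(weights)] = weights
        effect = w @ self.coef_
        var_scale = float(w @ self.xtx_inv_ @ w)
        se = np.sqrt(var_scale * self.resid_var_)
        return ContrastResult(np.asarray(effect), se, self.dof_, w)


def fit_glm(Y: np.ndarray, X: DesignMatrix | np.ndarray,
            ar_model: str = "none") -> FMRIGLM:
    """Thin wrapper: fit an :class:`FMRIGLM` and return it."""
    return FMRIGLM(ar_model=ar_model).fit(X, Y)
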