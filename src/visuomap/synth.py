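"""Synthetic data with known ground truth.

Emulates the inputs of the back-projection pipeline: pRF populations
per visual area, bistable percept report streams, per-vertex
differential response amplitudes carrying a known topographic pattern,
and forward-modeled BOLD time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .hrf import double_gamma_hrf
from .prf import predict_timeseries_matrix
from .stimuli import ApertureSequence, RegionMasks

__all__ = [
    "AreaProfile",
    "DEFAULT_AREA_PROFILES",
    "PerceptStream",
    "sample_vertex_population",
    "generate_percept_stream",
    "simulate_differential_betas",
    "simulate_timeseries",
]


# ---------------------------------------------------------------------------
# pRF populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AreaProfile:
    """Statistical profile of a visual area's pRF population.

    pRF size grows linearly with eccentricity,
    ``sigma = intercept + slope * ecc`` (dva), with lognormal scatter.
    ``density_exponent`` shapes the radial density: eccentricities are
    drawn as ``ecc_max * u**density_exponent`` for uniform ``u``, so
    exponents > 0.5 concentrate coverage foveally and larger exponents
    thin out the periphery (the object-sensitive VLOC complex gets the
    sparsest peripheral coverage and the largest pRFs).
    """

    name: str
    sigma_intercept: float
    sigma_slope: float
    ecc_max: float = 9.0
    density_exponent: float = 0.7
    sigma_scatter: float = 0.1      # lognormal sd of multiplicative scatter
    beta_mean: float = 1.0
    r2_mean: float = 0.55
    r2_sd: float = 0.18


DEFAULT_AREA_PROFILES: dict[str, AreaProfile] = {
    "V1": AreaProfile("V1", 0.5, 0.15, density_exponent=0.7),
    "V2": AreaProfile("V2", 0.7, 0.20, density_exponent=0.75),
    "V3": AreaProfile("V3", 0.9, 0.25, density_exponent=0.8),
    "VLOC": AreaProfile("VLOC", 1.5, 0.40, density_exponent=1.0),
}

#: Cortical magnification scale (mm) for the synthetic flattened sheet.
_CORTEX_MAG_MM = 15.0


def _cortical_coordinates(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Complex-log retinotopic map onto a flattened sheet (mm): radial
    # distance ~ log(1 + ecc), polar angle preserved. Keeps visual-field
    # neighbours adjacent on the sheet, which is all surface smoothing needs.
    ecc = np.hypot(x, y)
    theta = np.arctan2(y, x)
    r_mm = _CORTEX_MAG_MM * np.log1p(ecc)
    return r_mm * np.cos(theta), r_mm * np.sin(theta)


def sample_vertex_population(
    area_profile: AreaProfile | dict[str, AreaProfile],
    n: int,
    seed: int,
    participant: str = "P1",
) -> pd.DataFrame:
    """Draw a synthetic pRF population.

    Parameters
    ----------
    area_profile : AreaProfile or mapping of name -> AreaProfile
        With a mapping, ``n`` vertices are drawn *per area*.
    n : int
        Number of vertices (per area). Must be >= 1.
    seed : int
        Seed for the random generator; identical seeds give identical
        tables.

    Returns
    -------
    DataFrame
        Columns ``vertex_id, participant, area, x, y, sigma, beta, r2``
        plus flattened-cortex coordinates ``cx, cy`` (mm) used for
        surface smoothing.
    """
    if n < 1:
        raise ValueError(f"need at least one vertex, got n={n}")
    if isinstance(area_profile, dict):
        if not area_profile:
            raise ValueError("empty area profile mapping")
        parts = []
        for i, (name, prof) in enumerate(area_profile.items()):
            t = sample_vertex_population(prof, n, seed + i, participant)
            parts.append(t)
        out = pd.concat(parts, ignore_index=True)
        out["vertex_id"] = np.arange(len(out))
        return out

    prof = area_profile
    rng = np.random.default_rng(seed)
    ecc = prof.ecc_max * rng.random(n) ** prof.density_exponent
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    x = ecc * np.cos(theta)
    y = ecc * np.sin(theta)
    sigma = (prof.sigma_intercept + prof.sigma_slope * ecc) * np.exp(
        rng.normal(0.0, prof.sigma_scatter, n))
    sigma = np.maximum(sigma, 0.05)
    beta = prof.beta_mean * np.exp(rng.normal(0.0, 0.3, n))
    r2 = np.clip(rng.normal(prof.r2_mean, prof.r2_sd, n), 0.0, 0.999)
    cx, cy = _cortical_coordinates(x, y)
    return pd.DataFrame({
        "vertex_id": np.arange(n),
        "participant": participant,
        "area": prof.name,
        "x": x, "y": y, "sigma": sigma, "beta": beta, "r2": r2,
        "cx": cx, "cy": cy,
    })


# ---------------------------------------------------------------------------
# Percept report streams
# ---------------------------------------------------------------------------

@dataclass
class PerceptStream:
    """Key presses reporting the current percept of a bistable display.

    ``events`` is a list of ``(time_s, key)`` with ``key`` in
    ``{"global", "local"}``; times are strictly increasing and lie
    within ``[display_onset, display_offset]``.
    """

    events: list[tuple[float, str]]
    display_onset: float
    display_offset: float

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("press times must be strictly increasing")
        if times and (times[0] < self.display_onset
                      or times[-1] > self.display_offset):
            raise ValueError("press times outside the display window")


def generate_percept_stream(
    mean_durations: tuple[float, float] = (8.0, 8.0),
    display_window: tuple[float, float] = (0.0, 400.0),
    seed: int = 0,
    gamma_shape: float = 2.0,
) -> PerceptStream:
    """Simulate alternating percept reports over a display window.

    Percept dwell times are gamma-distributed (shape ``gamma_shape``,
    the right-skewed form characteristic of bistable alternation) with
    per-state means ``mean_durations = (mean_global, mean_local)``.
    The stream starts with a pre-report latency drawn like a dwell time
    of the first state, so the first press falls strictly after display
    onset; thereafter each press toggles the reported state.
    """
    m_global, m_local = mean_durations
    if m_global <= 0 or m_local <= 0:
        raise ValueError("mean durations must be positive")
    onset, offset = display_window
    window = offset - onset
    if window < 0:
        raise ValueError("display window ends before it starts")
    if 0 < window < max(m_global, m_local):
        warnings.warn("display window shorter than one mean percept "
                      "duration; stream may be empty", stacklevel=2)
    rng = np.random.default_rng(seed)
    means = {"global": m_global, "local": m_local}
    state = "global" if rng.random() < 0.5 else "local"
    events: list[tuple[float, str]] = []
    t = onset + rng.gamma(gamma_shape, means[state] / gamma_shape)
    while t < offset:
        events.append((t, state))
        t += rng.gamma(gamma_shape, means[state] / gamma_shape)
        state = "local" if state == "global" else "global"
    return PerceptStream(events, onset, offset)


# ---------------------------------------------------------------------------
# Differential betas with known regional ground truth
# ---------------------------------------------------------------------------

#: Ground-truth regional pattern for the diamond display: suppression of
#: the stimulated figure region, enhancement of the unstimulated ground.
DEFAULT_DIAMOND_EFFECTS = {
    "segments": -0.5, "corners": -0.25, "center": 0.25, "background": 0.5,
}


def simulate_differential_betas(
    vertex_table: pd.DataFrame,
    region_masks: RegionMasks,
    effects: dict[str, float],
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Inject a known regional effect pattern into a vertex table.

    Each vertex receives the signed amplitude of the region containing
    its pRF center plus i.i.d. Gaussian noise. Returns a copy of the
    table with columns ``dbeta`` (noisy differential beta),
    ``true_effect`` and ``region`` (the ground-truth assignment, kept
    for recovery tests). pRF centers falling outside every mask are
    assigned to ``background``.
    """
    rng = np.random.default_rng(seed)
    out = vertex_table.copy()
    region = region_masks.region_of(out["x"].to_numpy(), out["y"].to_numpy())
    true = np.array([effects.get(r, 0.0) for r in region])
    out["region"] = region
    out["true_effect"] = true
    out["dbeta"] = true + rng.normal(0.0, noise_sd, len(out))
    return out


# ---------------------------------------------------------------------------
# Forward-modeled time series
# ---------------------------------------------------------------------------

def simulate_timeseries(
    vertex_table: pd.DataFrame,
    apertures: ApertureSequence,
    hrf: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    tr: float = 1.0,
) -> np.ndarray:
    """Forward-model BOLD series for each vertex under a mapping stimulus.

    Per vertex: the pRF-aperture overlap series convolved with the HRF
    and scaled by beta, plus white noise, then linearly detrended and
    z-standardized row-wise (mirroring the preprocessing the analysis
    assumes).

    Returns an array of shape ``(n_vertices, n_frames)``.
    """
    if apertures.n_frames == 0:
        raise ValueError("empty aperture sequence")
    if hrf is None:
        hrf = double_gamma_hrf(apertures.frame_duration)
    pred = predict_timeseries_matrix(
        vertex_table["x"].to_numpy(),
        vertex_table["y"].to_numpy(),
        vertex_table["sigma"].to_numpy(),
        vertex_table["beta"].to_numpy(),
        apertures, hrf, tr=tr)
    rng = np.random.default_rng(seed)
    y = pred + rng.normal(0.0, noise_sd, pred.shape)
    y = signal.detrend(y, axis=1, type="linear")
    sd = y.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    return (y - y.mean(axis=1, keepdims=True)) / sd[:, None]
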