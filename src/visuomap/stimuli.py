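"""Stimulus apertures and region geometry.

Generates (a) the combined wedge-and-ring retinotopic mapping aperture
as a binary frame stack, (b) the partition of the visual field induced
by the occluded-diamond display (visible-segment sweep, occluded
corners, interior, background), and (c) the circular dot-field
apertures of the motion-grouping displays.

All geometry is specified in degrees of visual angle (dva).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import VisualFieldGrid

__all__ = [
    "ApertureSequence",
    "RegionMasks",
    "WedgeRingParams",
    "wedge_positions_per_cycle",
    "wedge_ring_apertures",
    "DiamondGeometry",
    "diamond_region_masks",
    "dots_aperture_masks",
]


@dataclass
class ApertureSequence:
    """Time-ordered binary masks on a visual-field grid.

    ``frames`` has shape (n_frames, ny, nx); ``frame_duration`` is the
    presentation time of one frame in seconds.
    """

    frames: np.ndarray
    grid: VisualFieldGrid
    frame_duration: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=bool)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, ny, nx)")
        if self.frames.shape[1:] != self.grid.shape:
            raise ValueError(
                f"frame shape {self.frames.shape[1:]} does not match "
                f"grid shape {self.grid.shape}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class RegionMasks:
    """Named binary masks over a common grid."""

    grid: VisualFieldGrid
    masks: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self) -> list[str]:
        return list(self.masks)

    def region_of(self, x, y, default: str = "background") -> np.ndarray:
        """Label the region containing each (x, y) point.

        Points are snapped to the nearest grid cell; points outside the
        grid get ``default``.
        """
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        g = self.grid
        ix = np.round((x - g.x_min) / g.step).astype(int)
        iy = np.round((y - g.y_min) / g.step).astype(int)
        ny, nx = g.shape
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        labels = np.full(x.shape, default, dtype=object)
        for name, m in self.masks.items():
            if name == default:
                continue
            hit = np.zeros_like(inside)
            hit[inside] = m[iy[inside], ix[inside]]
            labels[hit] = name
        return labels


# ---------------------------------------------------------------------------
# Wedge-and-ring mapping aperture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WedgeRingParams:
    """Parameters of the combined wedge-and-ring mapping stimulus.

    Defaults reproduce the mapping display: a 12 deg-wide wedge sector
    of a 17.03 dva disk stepping once per second with 50% overlap
    between consecutive positions (60 positions per rotation), plus an
    annulus whose inner/outer diameters follow a 36-step logarithmic
    progression from a 0.48 dva minimum inner diameter to a 40.38 dva
    maximum outer diameter, the inner diameter being 57% of the outer.
    A block lasts 90 s: 1.5 wedge rotations and 2.5 ring cycles.
    """

    wedge_width_deg: float = 12.0
    wedge_overlap: float = 0.5
    disk_diameter: float = 17.03
    ring_inner_min: float = 0.48
    ring_outer_max: float = 40.38
    ring_inner_outer_ratio: float = 0.57
    ring_steps: int = 36
    step_rate_hz: float = 1.0
    block_length_s: float = 90.0
    wedge_direction: int = 1          # +1 clockwise, -1 counterclockwise
    ring_expanding: bool = True


def wedge_positions_per_cycle(width_deg: float, overlap: float) -> int:
    """Number of distinct wedge positions in one full rotation.

    The wedge advances by ``width * (1 - overlap)`` per step, so a 12 deg
    wedge with 50% overlap visits 360 / 6 = 60 positions.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if width_deg <= 0:
        raise ValueError("wedge width must be positive")
    return int(round(360.0 / (width_deg * (1.0 - overlap))))


def _ring_diameters(p: WedgeRingParams) -> tuple[np.ndarray, np.ndarray]:
    # Geometric (log-spaced) progression of the outer diameter across the
    # ring steps, pinned to the printed endpoints; inner = ratio * outer.
    outer_min = p.ring_inner_min / p.ring_inner_outer_ratio
    outer = np.geomspace(outer_min, p.ring_outer_max, p.ring_steps)
    inner = p.ring_inner_outer_ratio * outer
    return inner, outer


def wedge_ring_apertures(
    params: WedgeRingParams | None = None,
    grid: VisualFieldGrid | None = None,
) -> ApertureSequence:
    """Generate one block of the wedge-and-ring mapping aperture.

    Returns one binary mask per step (1 s at the default step rate);
    each mask is the union of the wedge sector and the ring annulus at
    that step.
    """
    p = params or WedgeRingParams()
    if not 0 <= p.wedge_overlap < 1:
        raise ValueError("wedge overlap must be in [0, 1)")
    if p.disk_diameter <= 0 or p.ring_inner_min <= 0 or p.ring_outer_max <= 0:
        raise ValueError("diameters must be positive")
    if grid is None:
        grid = VisualFieldGrid(-8.5, 8.5, -8.5, 8.5, 0.25)

    n_frames = int(round(p.block_length_s * p.step_rate_hz))
    wedge_step_deg = p.wedge_width_deg * (1.0 - p.wedge_overlap)
    X, Y = grid.meshgrid()
    ecc = np.hypot(X, Y)
    # polar angle measured clockwise from vertical (12 o'clock), deg
    ang = np.degrees(np.arctan2(X, Y)) % 360.0

    inner_d, outer_d = _ring_diameters(p)
    half_width = p.wedge_width_deg / 2.0
    disk_r = p.disk_diameter / 2.0

    frames = np.empty((n_frames,) + grid.shape, dtype=bool)
    for t in range(n_frames):
        center = (p.wedge_direction * t * wedge_step_deg) % 360.0
        dang = np.abs((ang - center + 180.0) % 360.0 - 180.0)
        wedge = (dang <= half_width) & (ecc <= disk_r)
        k = t % p.ring_steps
        if not p.ring_expanding:
            k = p.ring_steps - 1 - k
        ring = (ecc >= inner_d[k] / 2.0) & (ecc <= outer_d[k] / 2.0)
        frames[t] = wedge | ring

    meta = {
        "wedge_positions_per_cycle":
            wedge_positions_per_cycle(p.wedge_width_deg, p.wedge_overlap),
        "wedge_cycles_per_block":
            n_frames * wedge_step_deg / 360.0,
        "ring_cycles_per_block": n_frames / p.ring_steps,
        "ring_growth_factor": float(outer_d[1] / outer_d[0]),
    }
    return ApertureSequence(frames, grid, 1.0 / p.step_rate_hz, meta)


# ---------------------------------------------------------------------------
# Occluded-diamond region partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiamondGeometry:
    """Geometry of the occluded, horizontally oscillating diamond display.

    The diamond is a square frame of side ``side`` rotated 45 deg
    (corners on the meridians at ``side / sqrt(2)`` eccentricity).
    Three screen-colored rectangles occlude it: a central one of width
    ``mid_occluder_width`` and two lateral ones of width
    ``side_occluder_width`` whose vertical symmetry axes sit at the
    screen edges (``+-screen_half_width``). The diamond center
    oscillates horizontally with amplitude ``oscillation_amplitude``.
    """

    side: float = 7.92
    mid_occluder_width: float = 3.75
    side_occluder_width: float = 22.84
    screen_half_width: float = 15.14
    oscillation_amplitude: float = 1.29

    @property
    def corner_eccentricity(self) -> float:
        """Distance from fixation to a corner of the centered diamond."""
        return self.side / math.sqrt(2.0)

    @property
    def visible_window(self) -> tuple[float, float]:
        """|x| interval within which the diamond contour is unoccluded."""
        lo = self.mid_occluder_width / 2.0
        hi = self.screen_half_width - self.side_occluder_width / 2.0
        return lo, hi

    @property
    def segment_length(self) -> float:
        """Length of one visible diamond segment (centered diamond)."""
        lo, hi = self.visible_window
        return (hi - lo) * math.sqrt(2.0)


def diamond_region_masks(
    grid: VisualFieldGrid,
    geometry: DiamondGeometry | None = None,
) -> RegionMasks:
    """Partition a grid into the diamond display's visual-field regions.

    Regions (pairwise disjoint, covering the grid):

    - ``segments``: area swept by the visible diamond segments over the
      full horizontal oscillation,
    - ``corners``: swept contour area hidden behind the occluders,
    - ``center``: interior of the diamond for every oscillation phase,
    - ``background``: exterior of the diamond for every phase.

    A point is on the contour for center offset ``c`` iff
    ``|x - c| + |y| = e`` with ``e`` the corner eccentricity; sweeping
    ``c`` over ``[-A, A]`` makes the three-way split exact.
    """
    g = geometry or DiamondGeometry()
    e = g.corner_eccentricity
    a = g.oscillation_amplitude
    lo, hi = g.visible_window
    if not grid.contains_disk(e + a):
        raise ValueError("grid too small to contain the oscillating diamond")

    X, Y = grid.meshgrid()
    ax, ay = np.abs(X), np.abs(Y)
    lo_dist = ay + np.maximum(ax - a, 0.0)   # min over c of |x-c| + |y|
    hi_dist = ay + ax + a                    # max over c

    center = hi_dist < e
    background = lo_dist > e
    swept = ~center & ~background
    visible = (ax > lo) & (ax < hi)
    segments = swept & visible
    corners = swept & ~visible
    return RegionMasks(
        grid,
        {"segments": segments, "corners": corners,
         "center": center, "background": background},
        meta={"corner_eccentricity": g.corner_eccentricity,
              "segment_length": g.segment_length},
    )


# ---------------------------------------------------------------------------
# Dot-field apertures
# ---------------------------------------------------------------------------

_DOTS_VARIANTS = {
    # diameter, square size, square midpoint, dot density (per dva^2)
    "central": (2.85, 5.69, (0.0, 0.0), 12.33),
    "quadrant": (0.58, 2.27, (3.41, 3.41), 60.31),
}


def dots_aperture_masks(variant: str, grid: VisualFieldGrid) -> RegionMasks:
    """Circular aperture masks of the moving-dots displays.

    ``central``: four apertures of diameter 2.85 dva centered on the
    corners of a 5.69 dva square around fixation. ``quadrant``: four
    apertures of diameter 0.58 dva on the corners of a 2.27 dva square
    whose midpoint lies at (3.41, 3.41) dva, i.e. wholly within the
    upper-right quadrant.

    Dot density and lifetime are recorded as metadata only; individual
    dots are not simulated (only the aperture masks enter the
    back-projection geometry).
    """
    if variant not in _DOTS_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of "
            f"{sorted(_DOTS_VARIANTS)}")
    diameter, square, (mx, my), density = _DOTS_VARIANTS[variant]
    half = square / 2.0
    centers = [(mx + sx * half, my + sy * half)
               for sy in (1, -1) for sx in (-1, 1)]
    X, Y = grid.meshgrid()
    masks: dict[str, np.ndarray] = {}
    union = np.zeros(grid.shape, dtype=bool)
    for i, (cx, cy) in enumerate(centers, start=1):
        m = np.hypot(X - cx, Y - cy) <= diameter / 2.0
        masks[f"aperture_{i}"] = m
        union |= m
    masks["background"] = ~union
    return RegionMasks(
        grid, masks,
        meta={"variant": variant, "aperture_diameter": diameter,
              "centers": centers, "dot_density_per_dva2": density,
              "dot_lifetime_frames": 9},
    )
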