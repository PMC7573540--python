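"""Visual-field grids.

All spatial quantities are in degrees of visual angle (dva), with the
origin at fixation, x increasing rightward and y increasing upward.
Arrays over a grid are indexed ``[iy, ix]`` with row 0 at ``y_min``
(render with ``origin='lower'``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VisualFieldGrid", "default_backprojection_grid"]


@dataclass(frozen=True)
class VisualFieldGrid:
    """A regular rectangular lattice of points in the visual field.

    Parameters
    ----------
    x_min, x_max, y_min, y_max : float
        Extent of the lattice in dva (inclusive at both ends).
    step : float
        Spacing between neighbouring points, dva. Must be positive.
    """

    x_min: float = -8.5
    x_max: float = 8.5
    y_min: float = -8.5
    y_max: float = 8.5
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("grid extent is empty")

    @property
    def x(self) -> np.ndarray:
        n = int(round((self.x_max - self.x_min) / self.step)) + 1
        return self.x_min + self.step * np.arange(n)

    @property
    def y(self) -> np.ndarray:
        n = int(round((self.y_max - self.y_min) / self.step)) + 1
        return self.y_min + self.step * np.arange(n)

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx)."""
        return len(self.y), len(self.x)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) coordinate arrays of shape ``(ny, nx)``."""
        return np.meshgrid(self.x, self.y)

    def eccentricity(self) -> np.ndarray:
        X, Y = self.meshgrid()
        return np.hypot(X, Y)

    def polar_angle(self) -> np.ndarray:
        """Angle in radians, counterclockwise from the positive x axis."""
        X, Y = self.meshgrid()
        return np.arctan2(Y, X)

    def contains_disk(self, radius: float) -> bool:
        return (self.x_min <= -radius and self.x_max >= radius
                and self.y_min <= -radius and self.y_max >= radius)


def default_backprojection_grid() -> VisualFieldGrid:
    """The 17 x 17 dva mesh used for searchlight back-projection.

    Grid points span -8.5..8.5 dva in both dimensions at 0.1 dva
    spacing, i.e. 171 points per axis.
    """
    return VisualFieldGrid(-8.5, 8.5, -8.5, 8.5, 0.1)
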