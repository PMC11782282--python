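"""Screen geometry and the pixel <-> degree-of-visual-angle contract.

Coordinate convention: pixel origin at the top-left of the screen, x
rightward, y downward, 0-based, with pixel centers at integer coordinates.
Degrees of visual angle are measured from the screen center along each axis,
rightward/downward positive, using the exact per-axis arctangent for a
viewer positioned on the screen's central normal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ScreenGeometry", "px_to_deg", "deg_to_px"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical monitor and viewing distance.

    Parameters
    ----------
    width_px, height_px : int
        Display resolution in pixels.
    width_cm, height_cm : float
        Physical panel size in centimetres.
    distance_cm : float
        Eye-to-screen distance in centimetres.
    """

    width_px: int
    height_px: int
    width_cm: float
    height_cm: float
    distance_cm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm", "distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be strictly positive")
        aspect_px = self.width_px / self.height_px
        aspect_cm = self.width_cm / self.height_cm
        if abs(aspect_px - aspect_cm) / aspect_cm > 0.05:
            warnings.warn(
                "pixel and physical aspect ratios disagree by more than 5% "
                f"({aspect_px:.3f} vs {aspect_cm:.3f}); pixels are anisotropic",
                stacklevel=2,
            )

    @property
    def cm_per_px_x(self) -> float:
        return self.width_cm / self.width_px

    @property
    def cm_per_px_y(self) -> float:
        return self.height_cm / self.height_px

    @property
    def center_px(self) -> tuple[float, float]:
        """Screen center in pixel coordinates (pixel centers at integers)."""
        return ((self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0)

    def px_per_deg(self) -> tuple[float, float]:
        """Approximate pixels per degree at the screen center (small-angle)."""
        cm_per_deg = self.distance_cm * math.tan(math.radians(1.0))
        return (cm_per_deg / self.cm_per_px_x, cm_per_deg / self.cm_per_px_y)


def px_to_deg(x_px, y_px, geometry: ScreenGeometry):
    """Convert screen pixel coordinates to degrees of visual angle.

    Exact per-axis arctangent: ``angle = atan(offset_cm / distance_cm)``
    where ``offset_cm`` is the pixel offset from the screen center scaled by
    the per-axis centimetre-per-pixel factor. Off-screen points are allowed.

    Parameters
    ----------
    x_px, y_px : array_like
        Pixel coordinates (scalars or arrays).
    geometry : ScreenGeometry

    Returns
    -------
    (x_deg, y_deg) : tuple of ndarray or float
    """
    cx, cy = geometry.center_px
    x_cm = (np.asarray(x_px, dtype=float) - cx) * geometry.cm_per_px_x
    y_cm = (np.asarray(y_px, dtype=float) - cy) * geometry.cm_per_px_y
    x_deg = np.degrees(np.arctan(x_cm / geometry.distance_cm))
    y_deg = np.degrees(np.arctan(y_cm / geometry.distance_cm))
    if np.isscalar(x_px) and np.isscalar(y_px):
        return float(x_deg), float(y_deg)
    return x_deg, y_deg


def deg_to_px(x_deg, y_deg, geometry: ScreenGeometry):
    """Inverse of :func:`px_to_deg`; exact to floating precision."""
    cx, cy = geometry.center_px
    x_cm = np.tan(np.radians(np.asarray(x_deg, dtype=float))) * geometry.distance_cm
    y_cm = np.tan(np.radians(np.asarray(y_deg, dtype=float))) * geometry.distance_cm
    x_px = x_cm / geometry.cm_per_px_x + cx
    y_px = y_cm / geometry.cm_per_px_y + cy
    if np.isscalar(x_deg) and np.isscalar(y_deg):
        return float(x_px), float(y_px)
    return x_px, y_px
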