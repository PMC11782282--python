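"""Spatial-frequency analysis of stimulus images in cycles per degree.

Supports the acuity-threshold rationale for stimulus selection: if nearly
all of an image's (non-DC) spectral power lies above a viewer's grating
acuity, the image content is effectively invisible to viewers below that
acuity. Frequencies are expressed in cycles per degree (cpd) using the
exact angular subtense of the stimulus rectangle at the viewing distance;
anisotropic pixels are handled by separate per-axis cpd scales combined
radially.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .geometry import ScreenGeometry, px_to_deg

__all__ = ["SpectrumReport", "cpd_per_cycle", "high_freq_energy_fraction", "analyze_image"]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class SpectrumReport:
    image_id: str
    threshold_cpd: float
    energy_fraction_above: float
    total_power: float

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "threshold_cpd": self.threshold_cpd,
            "energy_fraction_above": self.energy_fraction_above,
            "total_power": self.total_power,
        }


def cpd_per_cycle(
    geometry: ScreenGeometry,
    image_rect: tuple[float, float, float, float],
) -> tuple[float, float]:
    """Per-axis conversion from image cycles to cycles per degree.

    ``k`` cycles across the image along an axis correspond to
    ``k * cpd_per_cycle`` cpd, where the scale is the reciprocal of the
    image's angular subtense along that axis (exact trigonometry via the
    screen geometry).
    """
    x, y, w, h = image_rect
    if w <= 0 or h <= 0:
        raise ValueError(f"degenerate image_rect {image_rect}")
    cy = y + h / 2.0
    cx = x + w / 2.0
    left, _ = px_to_deg(x, cy, geometry)
    right, _ = px_to_deg(x + w, cy, geometry)
    _, top = px_to_deg(cx, y, geometry)
    _, bottom = px_to_deg(cx, y + h, geometry)
    subtense_x = abs(right - left)
    subtense_y = abs(bottom - top)
    return 1.0 / subtense_x, 1.0 / subtense_y


def high_freq_energy_fraction(
    image: np.ndarray,
    geometry: ScreenGeometry,
    image_rect: tuple[float, float, float, float],
    threshold_cpd: float,
) -> float:
    """Fraction of non-DC spectral power at radial frequency >= threshold.

    Power is the squared magnitude of the 2-D DFT; the DC bin is excluded;
    the radial frequency of bin (kx, ky) combines the per-axis cpd scales.
    A constant image has no non-DC power and returns 0 with a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    h, w = img.shape
    if img.min() == img.max():
        warnings.warn("constant image has no spatial structure; fraction defined as 0", stacklevel=2)
        return 0.0
    scale_x, scale_y = cpd_per_cycle(geometry, image_rect)
    power = np.abs(np.fft.fft2(img)) ** 2
    fx = np.fft.fftfreq(w) * w * scale_x  # cpd
    fy = np.fft.fftfreq(h) * h * scale_y
    radial = np.hypot(*np.meshgrid(fx, fy))
    power[0, 0] = 0.0  # exclude DC
    total = power.sum()
    if total == 0:
        return 0.0
    return float(power[radial >= threshold_cpd].sum() / total)


def analyze_image(
    image: np.ndarray,
    geometry: ScreenGeometry,
    image_rect,
    threshold_cpd: float = 3.0,
    image_id: str = "",
) -> SpectrumReport:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    power = np.abs(np.fft.fft2(img)) ** 2
    total = float(power.sum() - power[0, 0])
    frac = high_freq_energy_fraction(img, geometry, image_rect, threshold_cpd)
    return SpectrumReport(
        image_id=image_id,
        threshold_cpd=threshold_cpd,
        energy_fraction_above=frac,
        total_power=total,
    )
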