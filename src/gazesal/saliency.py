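"""Feature saliency maps: smoothing, 0-255 normalization, differencing, PNG I/O.

A saliency map is a grayscale grid, one per (stimulus image, feature)
pair, in which pixel intensity predicts visual attention drawn by that
feature. Maps arrive as raw real-valued grids from an external generator
backend (any program that, given a stimulus image and a prompt, writes a
grayscale PNG); this module smooths them with a Gaussian filter and
min-max normalizes to integer intensities 0-255. Differential maps are
formed by subtracting the raw maps of two opposite prompts before
normalization, retaining the signed range (no clipping).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "SaliencyMap",
    "MapDataError",
    "FEATURE_LABELS",
    "smooth_and_normalize",
    "differential_map",
    "load_map_png",
    "write_map_png",
    "read_manifest",
    "write_manifest",
    "DEFAULT_SIGMA_FRAC",
]

# Canonical feature vocabulary: four colors, visual-field maps, low-level
# image statistics, and higher-order semantic features.
FEATURE_LABELS = [
    "color_red",
    "color_yellow",
    "color_green",
    "color_blue",
    "field_central_peripheral",
    "field_upper_lower",
    "field_right_left",
    "luminance",
    "contrast",
    "orientation",
    "background",
    "depth",
    "animals",
    "human_faces",
    "human_bodies",
    "movement",
    "complexity",
]

# Default Gaussian sigma as a fraction of map width: scale-free default.
DEFAULT_SIGMA_FRAC = 0.02

# ITU-R BT.601 luminance weights for collapsing RGB input.
_LUMA = np.array([0.299, 0.587, 0.114])


class MapDataError(ValueError):
    """Raised for malformed or incompatible saliency-map data."""


@dataclass
class SaliencyMap:
    """Normalized grayscale saliency map.

    ``intensities`` is a uint8 array (height, width); when the map is
    normalized every value is in [0, 255] with min 0 and max 255 unless
    the map is constant (then all zeros and ``constant`` is True).
    """

    feature_label: str
    intensities: np.ndarray
    normalized: bool = True
    constant: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def width_px(self) -> int:
        return self.intensities.shape[1]

    @property
    def height_px(self) -> int:
        return self.intensities.shape[0]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def smooth_and_normalize(
    raw: np.ndarray,
    sigma_px: float | None = None,
    feature_label: str = "",
) -> SaliencyMap:
    """Gaussian-smooth a raw map and min-max rescale to integers 0-255.

    Smoothing uses a reflective boundary (mass-conserving); ``sigma_px=0``
    skips it; ``sigma_px=None`` uses ``DEFAULT_SIGMA_FRAC`` of the map
    width. Rescaling maps the minimum to 0 and the maximum to 255 with
    round-half-away-from-zero; a constant input (no signal) maps to all
    zeros and is flagged constant.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise MapDataError(f"raw map must be 2-D, got shape {raw.shape}")
    if not np.all(np.isfinite(raw)):
        raise MapDataError("raw map contains non-finite values")
    if sigma_px is None:
        sigma_px = DEFAULT_SIGMA_FRAC * raw.shape[1]
    if sigma_px < 0:
        raise MapDataError("sigma_px must be >= 0")
    smoothed = gaussian_filter(raw, sigma=sigma_px, mode="reflect") if sigma_px > 0 else raw
    lo, hi = float(smoothed.min()), float(smoothed.max())
    if hi == lo:
        return SaliencyMap(
            feature_label=feature_label,
            intensities=np.zeros(raw.shape, dtype=np.uint8),
            normalized=True,
            constant=True,
            meta={"sigma_px": sigma_px},
        )
    scaled = (smoothed - lo) / (hi - lo) * 255.0
    return SaliencyMap(
        feature_label=feature_label,
        intensities=_round_half_away(scaled).astype(np.uint8),
        normalized=True,
        constant=False,
        meta={"sigma_px": sigma_px},
    )


def differential_map(
    map_a: np.ndarray,
    map_b: np.ndarray,
    sigma_px: float | None = None,
    feature_label: str = "",
) -> SaliencyMap:
    """Subtract two raw maps (target minus opposite) and normalize.

    The element-wise difference is taken on the raw, pre-normalization
    values; negatives are retained and the full signed range is min-max
    rescaled (no clipping).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise MapDataError(f"map shapes differ: {a.shape} vs {b.shape}")
    return smooth_and_normalize(a - b, sigma_px=sigma_px, feature_label=feature_label)


def load_map_png(path, feature_label: str = "") -> SaliencyMap:
    """Load a saliency map from PNG.

    8-bit grayscale loads losslessly; 16-bit is rescaled to 8-bit with a
    warning; RGB is collapsed to luminance (BT.601 weights).
    """
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
        arr = _round_half_away(arr)
    elif arr.dtype.kind in "iu" and arr.dtype.itemsize > 1:
        warnings.warn(f"{path}: 16-bit map rescaled to 8-bit", stacklevel=2)
        arr = _round_half_away(arr.astype(float) * 255.0 / 65535.0)
    arr = np.clip(arr, 0, 255).astype(np.uint8)
    const = bool(arr.min() == arr.max())
    return SaliencyMap(feature_label=feature_label, intensities=arr, normalized=True, constant=const)


def write_map_png(smap: SaliencyMap, path) -> None:
    Image.fromarray(smap.intensities.astype(np.uint8), mode="L").save(path)


def read_manifest(path) -> pd.DataFrame:
    """Read the map manifest CSV: ``image_id,feature_label,map_path``."""
    df = pd.read_csv(path)
    required = {"image_id", "feature_label", "map_path"}
    missing = required - set(df.columns)
    if missing:
        raise MapDataError(f"manifest missing columns: {sorted(missing)}")
    df["image_id"] = df["image_id"].astype(str)
    return df


def write_manifest(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, index=False)
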