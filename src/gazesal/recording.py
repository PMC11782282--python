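"""Gaze recording data model, CSV I/O and binocular compositing.

A recording holds timestamped binocular gaze samples (pixels, one row per
sample at the tracker rate, typically 500 Hz), a trial segmentation table
mapping time intervals to stimulus images, and the viewing geometry.

Native CSV dialects
-------------------
Gaze CSV header: ``t_ms,lx,ly,rx,ry,lvalid,rvalid``; missing coordinates are
empty fields; validity flags are 0/1.
Trial CSV header: ``image_id,onset_ms,offset_ms,rect_x,rect_y,rect_w,rect_h``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry

__all__ = [
    "GazeDataError",
    "GazeFormatError",
    "TrialSegment",
    "GazeRecording",
    "CompositeStream",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_trials_csv",
    "write_trials_csv",
    "binocular_composite",
]

GAZE_COLUMNS = ["t_ms", "lx", "ly", "rx", "ry", "lvalid", "rvalid"]
TRIAL_COLUMNS = ["image_id", "onset_ms", "offset_ms", "rect_x", "rect_y", "rect_w", "rect_h"]


class GazeFormatError(ValueError):
    """Raised when a gaze or trial file does not conform to the CSV dialect."""


class GazeDataError(ValueError):
    """Raised when file contents violate recording invariants."""


@dataclass(frozen=True)
class TrialSegment:
    """One stimulus presentation interval.

    ``image_rect`` is (x, y, width, height) of the stimulus in screen pixels.
    """

    image_id: str
    onset_ms: float
    offset_ms: float
    image_rect: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise GazeDataError(
                f"trial {self.image_id!r}: offset {self.offset_ms} <= onset {self.onset_ms}"
            )
        x, y, w, h = self.image_rect
        if w <= 0 or h <= 0:
            raise GazeDataError(f"trial {self.image_id!r}: degenerate image_rect")


@dataclass
class GazeRecording:
    """Binocular gaze samples plus trial segmentation for one session.

    ``samples`` is a DataFrame with columns ``t_ms, lx, ly, rx, ry, lvalid,
    rvalid``; coordinates are NaN where missing, validity flags boolean.
    """

    participant_id: str
    group_label: str
    sample_rate_hz: float
    geometry: ScreenGeometry
    samples: pd.DataFrame
    trials: list[TrialSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise GazeDataError("sample_rate_hz must be positive")
        t = self.samples["t_ms"].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0)) + 1
                raise GazeDataError(f"timestamps not strictly increasing at row {bad}")
            expected = 1000.0 / self.sample_rate_hz
            med = float(np.median(dt))
            if abs(med - expected) / expected > 0.10:
                raise GazeDataError(
                    f"median inter-sample interval {med:.3f} ms inconsistent with "
                    f"declared rate {self.sample_rate_hz} Hz (expected {expected:.3f} ms)"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class CompositeStream:
    """Cyclopean (single-position) gaze stream derived from two eyes."""

    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.t_ms)


def read_gaze_csv(
    path,
    geometry: ScreenGeometry,
    sample_rate_hz: float,
    participant_id: str = "unknown",
    group_label: str = "unknown",
    trials: list[TrialSegment] | None = None,
) -> GazeRecording:
    """Read a gaze sample CSV into a :class:`GazeRecording`.

    Raises :class:`GazeFormatError` naming any missing column and
    :class:`GazeDataError` for non-monotone timestamps or a sample interval
    inconsistent with the declared rate.
    """
    df = pd.read_csv(path)
    for col in GAZE_COLUMNS:
        if col not in df.columns:
            raise GazeFormatError(f"gaze CSV {path} is missing required column {col!r}")
    df = df[GAZE_COLUMNS].copy()
    df["t_ms"] = df["t_ms"].astype(float)
    for c in ("lx", "ly", "rx", "ry"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in ("lvalid", "rvalid"):
        df[c] = df[c].astype(int).astype(bool)
    # an eye with missing coordinates cannot be valid
    df.loc[df["lx"].isna() | df["ly"].isna(), "lvalid"] = False
    df.loc[df["rx"].isna() | df["ry"].isna(), "rvalid"] = False
    return GazeRecording(
        participant_id=participant_id,
        group_label=group_label,
        sample_rate_hz=sample_rate_hz,
        geometry=geometry,
        samples=df,
        trials=list(trials) if trials else [],
    )


def write_gaze_csv(recording: GazeRecording, path) -> None:
    """Write samples in the native dialect; round-trips bit-exactly."""
    df = recording.samples.copy()
    df["lvalid"] = df["lvalid"].astype(int)
    df["rvalid"] = df["rvalid"].astype(int)
    df.to_csv(path, index=False, float_format="%.17g")


def read_trials_csv(path) -> list[TrialSegment]:
    df = pd.read_csv(path)
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise GazeFormatError(f"trial CSV {path} is missing required column {col!r}")
    return [
        TrialSegment(
            image_id=str(r.image_id),
            onset_ms=float(r.onset_ms),
            offset_ms=float(r.offset_ms),
            image_rect=(float(r.rect_x), float(r.rect_y), float(r.rect_w), float(r.rect_h)),
        )
        for r in df.itertuples()
    ]


def write_trials_csv(trials: list[TrialSegment], path) -> None:
    rows = [
        {
            "image_id": tr.image_id,
            "onset_ms": tr.onset_ms,
            "offset_ms": tr.offset_ms,
            "rect_x": tr.image_rect[0],
            "rect_y": tr.image_rect[1],
            "rect_w": tr.image_rect[2],
            "rect_h": tr.image_rect[3],
        }
        for tr in trials
    ]
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def binocular_composite(samples: pd.DataFrame) -> CompositeStream:
    """Reduce binocular samples to a single composite gaze position.

    Both eyes valid: arithmetic mean per axis. Exactly one eye valid: that
    eye's position (monocular recordings are first-class; strabismic viewers
    may be tracked from the fixating eye only). Neither valid: the sample is
    kept in the stream but flagged invalid.
    """
    lx = samples["lx"].to_numpy(dtype=float)
    ly = samples["ly"].to_numpy(dtype=float)
    rx = samples["rx"].to_numpy(dtype=float)
    ry = samples["ry"].to_numpy(dtype=float)
    lv = samples["lvalid"].to_numpy(dtype=bool)
    rv = samples["rvalid"].to_numpy(dtype=bool)

    x = np.full(len(samples), np.nan)
    y = np.full(len(samples), np.nan)
    both = lv & rv
    x[both] = (lx[both] + rx[both]) / 2.0
    y[both] = (ly[both] + ry[both]) / 2.0
    only_l = lv & ~rv
    x[only_l], y[only_l] = lx[only_l], ly[only_l]
    only_r = rv & ~lv
    x[only_r], y[only_r] = rx[only_r], ry[only_r]
    return CompositeStream(
        t_ms=samples["t_ms"].to_numpy(dtype=float),
        x_px=x,
        y_px=y,
        valid=lv | rv,
    )
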