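"""Fixation and saccade detection from composite gaze streams.

The detector mirrors the event definitions used by research-grade video
eye trackers: a fixation is a period in which gaze stays within 0.1 degree
of its centroid for at least 100 ms; a saccade is a rapid shift whose peak
velocity exceeds 30 deg/s, peak acceleration exceeds 8000 deg/s^2 and
amplitude exceeds 0.1 degree. Composition of the two definitions: saccades
are detected first as maximal supra-velocity-threshold runs (kept only if
the peak-acceleration and amplitude criteria also hold for the run);
fixations are then carved from the inter-saccade gaps by greedy
left-to-right dispersion clustering (I-DT style), dispersion being the
maximum sample distance from the running centroid.

Velocity and acceleration are estimated by central differences on the
degree-space trace; endpoints of each uninterrupted run use one-sided
differences. Invalid samples and timestamp gaps longer than two nominal
inter-sample intervals break differentiation windows and events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry, px_to_deg
from .recording import CompositeStream

__all__ = [
    "DetectionParams",
    "FixationEvent",
    "SaccadeEvent",
    "heuristic_denoise",
    "compute_kinematics",
    "detect_events",
    "events_to_frame",
    "write_events_csv",
    "read_events_csv",
]


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds governing event detection (all strictly positive).

    Defaults are the standard video-oculography parameters: 0.1 deg
    dispersion radius, 100 ms minimum fixation duration, 30 deg/s velocity,
    8000 deg/s^2 acceleration and 0.1 deg amplitude for saccades, and a
    3-sample median denoising window.
    """

    dispersion_deg: float = 0.1
    min_fix_duration_ms: float = 100.0
    saccade_velocity_deg_s: float = 30.0
    saccade_accel_deg_s2: float = 8000.0
    saccade_amplitude_deg: float = 0.1
    denoise_window_samples: int = 3

    def __post_init__(self) -> None:
        for name in (
            "dispersion_deg",
            "min_fix_duration_ms",
            "saccade_velocity_deg_s",
            "saccade_accel_deg_s2",
            "saccade_amplitude_deg",
            "denoise_window_samples",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"DetectionParams.{name} must be strictly positive")


@dataclass(frozen=True)
class FixationEvent:
    onset_ms: float
    offset_ms: float
    centroid_px: tuple[float, float]
    centroid_deg: tuple[float, float]
    duration_ms: float
    dispersion_deg: float
    n_samples: int


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    peak_velocity_deg_s: float
    peak_accel_deg_s2: float


def heuristic_denoise(stream: CompositeStream, window: int = 3) -> CompositeStream:
    """Sliding per-axis median filter over valid samples.

    The window is centred and counted in samples; only valid samples inside
    it contribute to the median. Invalid samples pass through unchanged and
    do not contribute. Output length equals input length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"denoise window must be odd and >= 1, got {window}")
    if window == 1 or len(stream) == 0:
        return CompositeStream(stream.t_ms.copy(), stream.x_px.copy(), stream.y_px.copy(), stream.valid.copy())
    hw = window // 2
    n = len(stream)
    x = stream.x_px.copy()
    y = stream.y_px.copy()
    valid = stream.valid
    for i in range(n):
        if not valid[i]:
            continue
        lo, hi = max(0, i - hw), min(n, i + hw + 1)
        m = valid[lo:hi]
        x[i] = float(np.median(stream.x_px[lo:hi][m]))
        y[i] = float(np.median(stream.y_px[lo:hi][m]))
    return CompositeStream(stream.t_ms.copy(), x, y, valid.copy())


def _nominal_dt_ms(t: np.ndarray) -> float:
    if len(t) < 2:
        return np.inf
    return float(np.median(np.diff(t)))


def _contiguous_runs(stream: CompositeStream, max_gap_ms: float):
    """Indices of maximal runs of valid samples with gaps <= max_gap_ms."""
    idx = np.flatnonzero(stream.valid)
    if len(idx) == 0:
        return []
    gaps = np.diff(stream.t_ms[idx])
    breaks = np.flatnonzero(gaps > max_gap_ms)
    runs = []
    start = 0
    for b in breaks:
        runs.append(idx[start : b + 1])
        start = b + 1
    runs.append(idx[start:])
    return runs


def compute_kinematics(stream: CompositeStream, geometry: ScreenGeometry):
    """Per-sample speed (deg/s) and acceleration (deg/s^2).

    Returns ``(speed, accel)`` arrays aligned with the stream; entries are
    NaN where undefined (invalid samples, isolated samples, or positions
    separated by a gap longer than two nominal inter-sample intervals).
    Speed is the norm of the central-difference velocity of the
    degree-space position; acceleration is the central difference of speed.
    """
    n = len(stream)
    speed = np.full(n, np.nan)
    accel = np.full(n, np.nan)
    if n == 0:
        return speed, accel
    dt_nom = _nominal_dt_ms(stream.t_ms[stream.valid]) if stream.valid.any() else np.inf
    max_gap = 2.0 * dt_nom * (1 + 1e-9)
    xdeg, ydeg = px_to_deg(stream.x_px, stream.y_px, geometry)
    for run in _contiguous_runs(stream, max_gap):
        if len(run) < 2:
            continue
        t = stream.t_ms[run] / 1000.0  # seconds
        vx = np.gradient(xdeg[run], t)
        vy = np.gradient(ydeg[run], t)
        sp = np.hypot(vx, vy)
        speed[run] = sp
        if len(run) >= 3:
            accel[run] = np.gradient(sp, t)
        else:
            accel[run] = (sp[1] - sp[0]) / (t[1] - t[0]) if t[1] > t[0] else 0.0
    return speed, accel


def _carve_fixations(
    run: np.ndarray,
    stream: CompositeStream,
    xdeg: np.ndarray,
    ydeg: np.ndarray,
    params: DetectionParams,
) -> list[FixationEvent]:
    """Greedy left-to-right dispersion clustering over one candidate range."""
    out: list[FixationEvent] = []
    i = 0
    n = len(run)
    while i < n:
        j = i + 1
        while j <= n:
            if j < n:
                seg = run[i : j + 1]
                cx, cy = xdeg[seg].mean(), ydeg[seg].mean()
                disp = float(np.hypot(xdeg[seg] - cx, ydeg[seg] - cy).max())
                if disp <= params.dispersion_deg:
                    j += 1
                    continue
            break
        seg = run[i:j]
        t0, t1 = stream.t_ms[seg[0]], stream.t_ms[seg[-1]]
        if t1 - t0 >= params.min_fix_duration_ms:
            cx, cy = xdeg[seg].mean(), ydeg[seg].mean()
            disp = float(np.hypot(xdeg[seg] - cx, ydeg[seg] - cy).max())
            out.append(
                FixationEvent(
                    onset_ms=float(t0),
                    offset_ms=float(t1),
                    centroid_px=(float(stream.x_px[seg].mean()), float(stream.y_px[seg].mean())),
                    centroid_deg=(float(cx), float(cy)),
                    duration_ms=float(t1 - t0),
                    dispersion_deg=disp,
                    n_samples=len(seg),
                )
            )
        i = j
    return out


def detect_events(
    stream: CompositeStream,
    geometry: ScreenGeometry,
    params: DetectionParams | None = None,
) -> list[FixationEvent | SaccadeEvent]:
    """Detect saccades then fixations; returns events ordered by onset.

    Saccade candidates are maximal runs of samples whose speed exceeds the
    velocity threshold; a candidate becomes a saccade only if its peak
    absolute acceleration exceeds the acceleration threshold and its
    start-to-end angular amplitude exceeds the amplitude threshold.
    Fixations are carved from the remaining samples by greedy dispersion
    clustering and kept if they last at least the minimum duration.
    """
    params = params or DetectionParams()
    if len(stream) == 0:
        return []
    speed, accel = compute_kinematics(stream, geometry)
    xdeg, ydeg = px_to_deg(stream.x_px, stream.y_px, geometry)
    dt_nom = _nominal_dt_ms(stream.t_ms[stream.valid]) if stream.valid.any() else np.inf
    max_gap = 2.0 * dt_nom * (1 + 1e-9)

    events: list[FixationEvent | SaccadeEvent] = []
    for run in _contiguous_runs(stream, max_gap):
        if len(run) < 2:
            continue
        fast = speed[run] > params.saccade_velocity_deg_s
        # maximal supra-threshold runs within this contiguous segment
        edges = np.flatnonzero(np.diff(fast.astype(int)))
        starts = [0] if fast[0] else []
        starts += [int(e) + 1 for e in edges if not fast[e]]
        sacc_ranges: list[tuple[int, int]] = []  # local [i0, i1] inclusive
        for s in starts:
            e = s
            while e + 1 < len(run) and fast[e + 1]:
                e += 1
            amp = float(np.hypot(xdeg[run[e]] - xdeg[run[s]], ydeg[run[e]] - ydeg[run[s]]))
            pk_v = float(np.nanmax(speed[run[s : e + 1]]))
            acc_seg = np.abs(accel[run[s : e + 1]])
            pk_a = float(np.nanmax(acc_seg)) if np.any(np.isfinite(acc_seg)) else 0.0
            if (
                amp > params.saccade_amplitude_deg
                and pk_a > params.saccade_accel_deg_s2
                and pk_v > params.saccade_velocity_deg_s
            ):
                sacc_ranges.append((s, e))
                events.append(
                    SaccadeEvent(
                        onset_ms=float(stream.t_ms[run[s]]),
                        offset_ms=float(stream.t_ms[run[e]]),
                        amplitude_deg=amp,
                        peak_velocity_deg_s=pk_v,
                        peak_accel_deg_s2=pk_a,
                    )
                )
        # inter-saccade gaps are fixation candidates
        cursor = 0
        for s, e in sacc_ranges + [(len(run), len(run))]:
            if s > cursor:
                events.extend(_carve_fixations(run[cursor:s], stream, xdeg, ydeg, params))
            cursor = e + 1
    events.sort(key=lambda ev: ev.onset_ms)
    return events


def events_to_frame(events) -> pd.DataFrame:
    """Tabulate events; fixation rows leave saccade columns empty and vice versa."""
    rows = []
    for ev in events:
        if isinstance(ev, FixationEvent):
            rows.append(
                {
                    "type": "fixation",
                    "onset_ms": ev.onset_ms,
                    "offset_ms": ev.offset_ms,
                    "x_px": ev.centroid_px[0],
                    "y_px": ev.centroid_px[1],
                    "duration_ms": ev.duration_ms,
                    "dispersion_deg": ev.dispersion_deg,
                    "amplitude_deg": np.nan,
                    "peak_vel": np.nan,
                    "peak_acc": np.nan,
                }
            )
        else:
            rows.append(
                {
                    "type": "saccade",
                    "onset_ms": ev.onset_ms,
                    "offset_ms": ev.offset_ms,
                    "x_px": np.nan,
                    "y_px": np.nan,
                    "duration_ms": ev.offset_ms - ev.onset_ms,
                    "dispersion_deg": np.nan,
                    "amplitude_deg": ev.amplitude_deg,
                    "peak_vel": ev.peak_velocity_deg_s,
                    "peak_acc": ev.peak_accel_deg_s2,
                }
            )
    cols = [
        "type",
        "onset_ms",
        "offset_ms",
        "x_px",
        "y_px",
        "duration_ms",
        "dispersion_deg",
        "amplitude_deg",
        "peak_vel",
        "peak_acc",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_events_csv(events, path) -> None:
    events_to_frame(events).to_csv(path, index=False, float_format="%.9g")


def read_events_csv(path) -> list[FixationEvent | SaccadeEvent]:
    df = pd.read_csv(path)
    out: list[FixationEvent | SaccadeEvent] = []
    for r in df.itertuples():
        if r.type == "fixation":
            out.append(
                FixationEvent(
                    onset_ms=float(r.onset_ms),
                    offset_ms=float(r.offset_ms),
                    centroid_px=(float(r.x_px), float(r.y_px)),
                    centroid_deg=(np.nan, np.nan),
                    duration_ms=float(r.duration_ms),
                    dispersion_deg=float(r.dispersion_deg),
                    n_samples=0,
                )
            )
        else:
            out.append(
                SaccadeEvent(
                    onset_ms=float(r.onset_ms),
                    offset_ms=float(r.offset_ms),
                    amplitude_deg=float(r.amplitude_deg),
                    peak_velocity_deg_s=float(r.peak_vel),
                    peak_accel_deg_s2=float(r.peak_acc),
                )
            )
    return out
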