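"""Synthetic viewers, feature maps, and 500 Hz gaze recordings with ground truth.

The simulator stands in for a clinical cohort: each synthetic viewer
carries attention weights over feature saliency maps, and fixation targets
are drawn with probability proportional to the weighted mixture of
normalized map intensities plus a uniform exploration remainder. Fixation
durations follow a truncated normal; saccades are rendered as smooth
minimum-jerk transitions whose duration follows the oculomotor main
sequence (so that amplitude, peak velocity and peak acceleration all clear
the detector's thresholds for saccades of a degree or more); optional
per-sample Gaussian jitter models tracker noise. Every recording is
accompanied by a :class:`SimulationScript` holding the ground truth, which
the detection and scoring tests check recovery against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ScreenGeometry
from .recording import GazeRecording, TrialSegment
from .saliency import SaliencyMap, smooth_and_normalize

__all__ = [
    "ViewerProfile",
    "ScriptedFixation",
    "ScriptedSaccade",
    "SimulationScript",
    "make_feature_maps",
    "simulate_recording",
    "simulate_cohort",
    "expected_mean_value",
    "CVI_LIKE",
    "CONTROL_LIKE",
]


@dataclass(frozen=True)
class ViewerProfile:
    """Generative description of one synthetic viewer.

    ``attention_weights`` maps feature labels to non-negative weights
    summing to at most 1; the remainder is uniform exploration over the
    image. Durations are in ms; ``gaze_noise_deg`` is the SD of per-sample
    isotropic Gaussian jitter in degrees.
    """

    label: str = "custom"
    attention_weights: dict[str, float] = field(default_factory=dict)
    fixation_duration_mean_ms: float = 250.0
    fixation_duration_sd_ms: float = 60.0
    min_fixation_ms: float = 80.0
    saccade_duration_ms: float = 40.0
    min_saccade_amplitude_deg: float = 1.0
    gaze_noise_deg: float = 0.0
    binocular_offset_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.attention_weights.values()):
            raise ValueError("attention weights must be non-negative")
        if sum(self.attention_weights.values()) > 1 + 1e-9:
            raise ValueError("attention weights must sum to at most 1")
        if self.fixation_duration_mean_ms < self.min_fixation_ms:
            raise ValueError("mean fixation duration below the minimum")
        if self.gaze_noise_deg < 0:
            raise ValueError("gaze noise must be non-negative")


# Default group profiles: the clinical-like viewer weights lower-order
# features (color, luminance, background); the control-like viewer weights
# higher-order features (faces, depth, complexity). Fixtures, not claims.
CVI_LIKE = ViewerProfile(
    label="cvi_like",
    attention_weights={"color_red": 0.25, "luminance": 0.25, "background": 0.25},
)
CONTROL_LIKE = ViewerProfile(
    label="control_like",
    attention_weights={"human_faces": 0.25, "depth": 0.25, "complexity": 0.25},
)


@dataclass(frozen=True)
class ScriptedFixation:
    image_id: str
    target_px: tuple[float, float]
    onset_ms: float
    duration_ms: float


@dataclass(frozen=True)
class ScriptedSaccade:
    onset_ms: float
    duration_ms: float
    from_px: tuple[float, float]
    to_px: tuple[float, float]


@dataclass
class SimulationScript:
    """Ground truth for one simulated recording."""

    participant_id: str
    fixations: list[ScriptedFixation] = field(default_factory=list)
    saccades: list[ScriptedSaccade] = field(default_factory=list)

    def n_fixations(self, min_duration_ms: float | None = None) -> int:
        if min_duration_ms is None:
            return len(self.fixations)
        return sum(1 for f in self.fixations if f.duration_ms >= min_duration_ms)

    def to_json(self, path) -> None:
        obj = {
            "participant_id": self.participant_id,
            "fixations": [
                {
                    "image_id": f.image_id,
                    "x_px": f.target_px[0],
                    "y_px": f.target_px[1],
                    "onset_ms": f.onset_ms,
                    "duration_ms": f.duration_ms,
                }
                for f in self.fixations
            ],
            "saccades": [
                {
                    "onset_ms": s.onset_ms,
                    "duration_ms": s.duration_ms,
                    "from": list(s.from_px),
                    "to": list(s.to_px),
                }
                for s in self.saccades
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def make_feature_maps(
    kind: str,
    size: tuple[int, int],
    params: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Construct a raw feature map grid with values in [0, 1].

    Kinds
    -----
    blob
        Sum of Gaussian bumps; ``params``: ``centers`` (list of (x, y)),
        ``sigma_px``. Random centers if omitted.
    grating
        Oriented sinusoid; ``params``: ``cycles`` (cycles across the map
        width), ``orientation_deg``.
    field_half
        Indicator over a screen region; ``params``: ``side`` in
        left/right/upper/lower/center/periphery (center = middle half
        annulus boundary at half the min dimension).
    background
        Complement of a blob map (same params as blob).
    """
    params = dict(params or {})
    h, w = size
    if h <= 0 or w <= 0:
        raise ValueError("map size must be positive")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]

    if kind in ("blob", "background"):
        sigma = float(params.get("sigma_px", 0.08 * min(h, w)))
        centers = params.get("centers")
        if centers is None:
            k = int(params.get("n_blobs", 3))
            centers = [(rng.uniform(0.15 * w, 0.85 * w), rng.uniform(0.15 * h, 0.85 * h)) for _ in range(k)]
        grid = np.zeros((h, w))
        for cx, cy in centers:
            grid += np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
        grid = grid / grid.max() if grid.max() > 0 else grid
        return 1.0 - grid if kind == "background" else grid

    if kind == "grating":
        cycles = float(params.get("cycles", 10.0))
        theta = np.radians(float(params.get("orientation_deg", 0.0)))
        phase = 2 * np.pi * cycles * (xx * np.cos(theta) + yy * np.sin(theta)) / w
        return 0.5 + 0.5 * np.sin(phase)

    if kind == "field_half":
        side = params.get("side", "left")
        if side == "left":
            return (xx < w / 2).astype(float)
        if side == "right":
            return (xx >= w / 2).astype(float)
        if side == "upper":
            return (yy < h / 2).astype(float)
        if side == "lower":
            return (yy >= h / 2).astype(float)
        r = np.hypot(xx - (w - 1) / 2, yy - (h - 1) / 2)
        if side == "center":
            return (r <= min(h, w) / 4).astype(float)
        if side == "periphery":
            return (r > min(h, w) / 4).astype(float)
        raise ValueError(f"unknown field side {side!r}")

    raise ValueError(f"unknown map kind {kind!r}")


def _as_normalized(m) -> SaliencyMap:
    if isinstance(m, SaliencyMap):
        return m
    return smooth_and_normalize(np.asarray(m, dtype=float), sigma_px=0)


def expected_mean_value(smap, weight: float) -> float:
    """Expected fixation saliency value of a viewer with weight w on this map.

    Targets drawn with probability w * I/sum(I) + (1-w)/N give expected
    intensity w * sum(I^2)/sum(I) + (1-w) * mean(I); strictly increasing
    in w for any non-constant map.
    """
    I = _as_normalized(smap).intensities.astype(float)
    s = I.sum()
    if s == 0:
        return 0.0
    return float(weight * (I**2).sum() / s + (1 - weight) * I.mean())


def _mixture_probs(maps: dict[str, SaliencyMap], weights: dict[str, float], shape) -> np.ndarray:
    h, w = shape
    p = np.zeros(h * w)
    total_w = 0.0
    for feat, wt in weights.items():
        if wt == 0 or feat not in maps:
            continue
        total_w += wt  # attention committed to this feature, signal or not
        I = maps[feat].intensities.astype(float).ravel()
        if I.sum() > 0:
            p += wt * I / I.sum()
    p += (1.0 - total_w) / (h * w)
    s = p.sum()
    if s <= 0:
        raise ValueError("all-zero target mixture: no map signal and no uniform remainder")
    return p / s


def _truncnorm_duration(rng, mean, sd, minimum, dt) -> float:
    """Truncated-normal duration snapped to the sample grid."""
    for _ in range(1000):
        d = rng.normal(mean, sd)
        if d >= minimum:
            break
    else:
        d = minimum
    return max(round(d / dt), round(minimum / dt)) * dt


def _minjerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_recording(
    viewer: ViewerProfile,
    maps: dict[str, dict[str, object]],
    geometry: ScreenGeometry,
    trials: list[TrialSegment],
    sample_rate_hz: float = 500.0,
    participant_id: str = "sim",
    group_label: str = "custom",
) -> tuple[GazeRecording, SimulationScript]:
    """Simulate one session; returns the recording and its ground truth.

    ``maps`` is keyed by image id, then feature label; values may be raw
    arrays or :class:`SaliencyMap` objects (raw arrays are normalized
    first so target sampling matches downstream scoring intensities).
    """
    import pandas as pd

    rng = np.random.default_rng(viewer.seed)
    dt = 1000.0 / sample_rate_hz
    ppd_x, ppd_y = geometry.px_per_deg()

    script = SimulationScript(participant_id=participant_id)
    seg_times: list[np.ndarray] = []
    seg_x: list[np.ndarray] = []
    seg_y: list[np.ndarray] = []
    prev_target: tuple[float, float] | None = None

    for trial in trials:
        if trial.image_id not in maps or not maps[trial.image_id]:
            raise ValueError(f"no maps for trial image {trial.image_id!r}")
        norm_maps = {f: _as_normalized(m) for f, m in maps[trial.image_id].items()}
        any_map = next(iter(norm_maps.values()))
        mh, mw = any_map.intensities.shape
        probs = _mixture_probs(norm_maps, viewer.attention_weights, (mh, mw))
        rx, ry, rw, rh = trial.image_rect

        def to_screen(flat_idx: int) -> tuple[float, float]:
            row, col = divmod(flat_idx, mw)
            sx = rx + (col + 0.5) * rw / mw - 0.5
            sy = ry + (row + 0.5) * rh / mh - 0.5
            return sx, sy

        def draw_target(prev: tuple[float, float] | None) -> tuple[float, float]:
            cand = to_screen(int(rng.choice(len(probs), p=probs)))
            if prev is None:
                return cand
            for _ in range(50):
                amp = np.hypot((cand[0] - prev[0]) / ppd_x, (cand[1] - prev[1]) / ppd_y)
                if amp >= viewer.min_saccade_amplitude_deg:
                    break
                cand = to_screen(int(rng.choice(len(probs), p=probs)))
            return cand

        def saccade_duration_ms(amp_deg: float) -> float:
            # oculomotor main sequence, capped by the profile transition time
            d = min(viewer.saccade_duration_ms, 2.2 * amp_deg + 21.0)
            return max(round(d / dt), 3) * dt

        # scripted timeline for this trial
        t = trial.onset_ms
        target = draw_target(prev_target)
        entries: list[tuple[float, float, str, tuple, tuple]] = []  # (t0, t1, kind, A, B)
        if prev_target is not None:
            amp = float(
                np.hypot((target[0] - prev_target[0]) / ppd_x, (target[1] - prev_target[1]) / ppd_y)
            )
            if amp >= viewer.min_saccade_amplitude_deg:
                sac_dur = saccade_duration_ms(amp)
                script.saccades.append(ScriptedSaccade(t, sac_dur, prev_target, target))
                entries.append((t, t + sac_dur, "sac", prev_target, target))
                t += sac_dur
            # a sub-amplitude jump is rendered as an instantaneous step; it
            # falls below the detector's amplitude criterion by construction
        # a new fixation+saccade pair only fits if this much time remains
        tail_margin = viewer.min_fixation_ms + viewer.saccade_duration_ms + 2 * dt
        while t < trial.offset_ms - 1e-9:
            dur = _truncnorm_duration(
                rng, viewer.fixation_duration_mean_ms, viewer.fixation_duration_sd_ms,
                viewer.min_fixation_ms, dt,
            )
            if trial.offset_ms - (t + dur) < tail_margin:
                dur = trial.offset_ms - t  # absorb the trial tail

            script.fixations.append(
                ScriptedFixation(trial.image_id, target, onset_ms=t, duration_ms=dur)
            )
            entries.append((t, t + dur, "fix", target, target))
            t += dur
            if t >= trial.offset_ms - 1e-9:
                break
            nxt = draw_target(target)
            amp_deg = float(np.hypot((nxt[0] - target[0]) / ppd_x, (nxt[1] - target[1]) / ppd_y))
            sac_dur = min(saccade_duration_ms(amp_deg), trial.offset_ms - t)
            script.saccades.append(ScriptedSaccade(t, sac_dur, target, nxt))
            entries.append((t, t + sac_dur, "sac", target, nxt))
            t += sac_dur
            target = nxt

        tt = np.arange(trial.onset_ms, trial.offset_ms - 1e-9, dt)
        px = np.empty_like(tt)
        py = np.empty_like(tt)
        for t0, t1, kind, A, B in entries:
            m = (tt >= t0 - 1e-9) & (tt < t1 - 1e-9)
            if kind == "fix":
                px[m], py[m] = A[0], A[1]
            else:
                tau = (tt[m] - t0) / (t1 - t0)
                s = _minjerk(tau)
                px[m] = A[0] + (B[0] - A[0]) * s
                py[m] = A[1] + (B[1] - A[1]) * s
        seg_times.append(tt)
        seg_x.append(px)
        seg_y.append(py)
        prev_target = target

    t_all = np.concatenate(seg_times)
    x_all = np.concatenate(seg_x)
    y_all = np.concatenate(seg_y)
    if viewer.gaze_noise_deg > 0:
        x_all = x_all + rng.normal(0, viewer.gaze_noise_deg * ppd_x, size=len(x_all))
        y_all = y_all + rng.normal(0, viewer.gaze_noise_deg * ppd_y, size=len(y_all))

    off = viewer.binocular_offset_px
    samples = pd.DataFrame(
        {
            "t_ms": t_all,
            "lx": x_all - off,
            "ly": y_all,
            "rx": x_all + off,
            "ry": y_all,
            "lvalid": True,
            "rvalid": True,
        }
    )
    rec = GazeRecording(
        participant_id=participant_id,
        group_label=group_label,
        sample_rate_hz=sample_rate_hz,
        geometry=geometry,
        samples=samples,
        trials=list(trials),
    )
    return rec, script


def simulate_cohort(
    n_per_group: int,
    profiles: dict[str, ViewerProfile],
    maps: dict[str, dict[str, object]],
    geometry: ScreenGeometry,
    trials: list[TrialSegment],
    seed: int = 0,
    sample_rate_hz: float = 500.0,
) -> list[tuple[GazeRecording, SimulationScript]]:
    """Simulate ``n_per_group`` viewers per group with derived seeds.

    Per-participant seeds are derived deterministically from the master
    seed, so the same master seed reproduces the cohort bit-for-bit.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    out = []
    for g_idx, (group, profile) in enumerate(sorted(profiles.items())):
        for i in range(n_per_group):
            child = int(
                np.random.SeedSequence(entropy=[seed, g_idx, i]).generate_state(1)[0] & 0x7FFFFFFF
            )
            pid = f"{group}_{i:03d}"
            viewer = replace(profile, seed=child)
            rec, script = simulate_recording(
                viewer, maps, geometry, trials, sample_rate_hz,
                participant_id=pid, group_label=group,
            )
            out.append((rec, script))
    return out
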