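"""Fixation saliency scoring: map fixation centers to map pixels and aggregate.

The outcome measure of the analysis is the *fixation saliency value*: the
intensity (0-255) of the saliency-map pixel under a fixation's center.
Fixations are discarded when their centroid lies more than a margin
fraction (default 20%) of the image dimension outside the stimulus image
on either axis; fixations off the image but within the margin are scored
at the nearest in-image pixel (clamping). Trials without any surviving
fixation are discarded. Per participant and feature, the values are
averaged per image, then across images, giving one scalar per participant
per feature — the unit of the group analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import FixationEvent
from .recording import GazeRecording, TrialSegment
from .saliency import SaliencyMap

__all__ = [
    "ScoringError",
    "FixationSaliencyRecord",
    "ParticipantFeatureSummary",
    "filter_fixations",
    "fixation_value",
    "score_session",
    "records_to_frame",
    "summaries_to_frame",
]

logger = logging.getLogger(__name__)


class ScoringError(ValueError):
    """Raised for scoring configuration or data errors."""


@dataclass(frozen=True)
class FixationSaliencyRecord:
    """One fixation's value on one feature map: the unit observation."""

    participant_id: str
    group_label: str
    image_id: str
    feature_label: str
    fixation_index: int
    value: int


@dataclass
class ParticipantFeatureSummary:
    """Per-participant aggregate: mean of per-image mean values."""

    participant_id: str
    group_label: str
    feature_label: str
    per_image_means: dict[str, float]
    overall_mean: float
    n_valid_trials: int
    n_fixations: int


def filter_fixations(
    fixations: list[FixationEvent],
    image_rect: tuple[float, float, float, float],
    margin_frac: float = 0.20,
) -> list[FixationEvent]:
    """Keep fixations whose centroid is within the expanded image rectangle.

    A fixation is discarded iff its centroid lies farther outside the image
    than ``margin_frac`` of the corresponding image dimension on either
    axis: the acceptance region is the image rect expanded by
    ``margin_frac * width`` horizontally and ``margin_frac * height``
    vertically on each side.
    """
    if not 0 <= margin_frac <= 1:
        raise ScoringError(f"margin_frac must be in [0, 1], got {margin_frac}")
    x, y, w, h = image_rect
    if w <= 0 or h <= 0:
        raise ScoringError(f"degenerate image_rect {image_rect}")
    x_lo, x_hi = x - margin_frac * w, x + w + margin_frac * w
    y_lo, y_hi = y - margin_frac * h, y + h + margin_frac * h
    kept = []
    for fx in fixations:
        cx, cy = fx.centroid_px
        if x_lo <= cx <= x_hi and y_lo <= cy <= y_hi:
            kept.append(fx)
        else:
            logger.debug("discarding fixation at (%.1f, %.1f): outside 20%% margin", cx, cy)
    return kept


def fixation_value(
    fixation: FixationEvent,
    smap: SaliencyMap,
    image_rect: tuple[float, float, float, float],
    *,
    allow_constant: bool = False,
) -> int:
    """Intensity of the map pixel under the fixation center.

    The centroid is translated from screen into map coordinates via
    ``image_rect`` (scaling if the map resolution differs from the rect),
    rounded to the nearest pixel, and clamped to the map bounds for
    in-margin but off-image centroids. Constant maps carry no feature
    signal and are refused unless ``allow_constant`` is set.
    """
    if smap.constant and not allow_constant:
        raise ScoringError(
            f"saliency map {smap.feature_label!r} is constant and carries no signal"
        )
    x, y, w, h = image_rect
    cx, cy = fixation.centroid_px
    # pixel centers at integer map coordinates; scale if resolution differs
    mx = (cx - x + 0.5) * smap.width_px / w - 0.5
    my = (cy - y + 0.5) * smap.height_px / h - 0.5
    col = int(np.clip(np.floor(mx + 0.5), 0, smap.width_px - 1))
    row = int(np.clip(np.floor(my + 0.5), 0, smap.height_px - 1))
    return int(smap.intensities[row, col])


def _trial_for_fixation(fx: FixationEvent, trials: list[TrialSegment]) -> TrialSegment | None:
    """Assign a fixation to the trial containing its temporal midpoint."""
    mid = (fx.onset_ms + fx.offset_ms) / 2.0
    for tr in trials:
        if tr.onset_ms <= mid < tr.offset_ms:
            return tr
    return None


def score_session(
    recording: GazeRecording,
    events,
    maps: dict[tuple[str, str], SaliencyMap],
    margin_frac: float = 0.20,
) -> tuple[list[FixationSaliencyRecord], list[ParticipantFeatureSummary]]:
    """Score one participant session against every available feature map.

    ``maps`` is keyed by ``(image_id, feature_label)``; (image, feature)
    pairs absent from it are skipped with a warning. Per trial, fixations
    assigned to the trial (by temporal midpoint) are filtered by the
    margin rule and scored; trials with zero surviving fixations are
    excluded from averaging. Returns the per-fixation records and the
    per-participant per-feature summaries (mean of per-image means).
    """
    if not recording.trials:
        raise ScoringError(f"recording {recording.participant_id!r} has no trials")
    fixations = [ev for ev in events if isinstance(ev, FixationEvent)]
    features = sorted({feat for (_, feat) in maps})

    records: list[FixationSaliencyRecord] = []
    # feature -> image -> list of values
    per_feature: dict[str, dict[str, list[int]]] = {f: {} for f in features}

    for trial in recording.trials:
        in_trial = [fx for fx in fixations if _trial_for_fixation(fx, recording.trials) is trial]
        kept = filter_fixations(in_trial, trial.image_rect, margin_frac)
        if not kept:
            continue  # trial without valid fixations is discarded
        for feat in features:
            key = (trial.image_id, feat)
            if key not in maps:
                logger.warning("no map for image %r feature %r; pair skipped", trial.image_id, feat)
                continue
            smap = maps[key]
            vals = per_feature[feat].setdefault(trial.image_id, [])
            for k, fx in enumerate(kept):
                v = fixation_value(fx, smap, trial.image_rect)
                vals.append(v)
                records.append(
                    FixationSaliencyRecord(
                        participant_id=recording.participant_id,
                        group_label=recording.group_label,
                        image_id=trial.image_id,
                        feature_label=feat,
                        fixation_index=k,
                        value=v,
                    )
                )

    summaries: list[ParticipantFeatureSummary] = []
    for feat in features:
        image_means = {img: float(np.mean(vs)) for img, vs in per_feature[feat].items() if vs}
        if not image_means:
            continue  # participant excluded for this feature
        summaries.append(
            ParticipantFeatureSummary(
                participant_id=recording.participant_id,
                group_label=recording.group_label,
                feature_label=feat,
                per_image_means=image_means,
                overall_mean=float(np.mean(list(image_means.values()))),
                n_valid_trials=len(image_means),
                n_fixations=sum(len(vs) for vs in per_feature[feat].values()),
            )
        )
    return records, summaries


def records_to_frame(records: list[FixationSaliencyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "group": r.group_label,
                "image_id": r.image_id,
                "feature": r.feature_label,
                "fixation_index": r.fixation_index,
                "value": r.value,
            }
            for r in records
        ],
        columns=["participant_id", "group", "image_id", "feature", "fixation_index", "value"],
    )


def summaries_to_frame(summaries: list[ParticipantFeatureSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "group": s.group_label,
                "feature": s.feature_label,
                "overall_mean": s.overall_mean,
                "n_trials": s.n_valid_trials,
                "n_fixations": s.n_fixations,
            }
            for s in summaries
        ],
        columns=["participant_id", "group", "feature", "overall_mean", "n_trials", "n_fixations"],
    )
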