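"""Subtask segmentation of scored streams and exposure-feature extraction.

Features per segment (a subtask group, or the whole session):

* mean and SD of the grand score per side,
* mean and SD of each local anatomical-area score,
* percentage of scored time spent in each grand-score band
  (1-2 / 3-4 / 5-6 / 7),
* percentage of scored time at a *risky level* per area: frames whose
  local score is at or above a predefined per-area threshold (inclusive).

The wrist area uses the combined wrist-and-hand score (wrist posture +
wrist twist, range 2-6).  Percentages always use the segment's scored
frames as denominator; frames dropped for missing angles never appear in
any numerator or denominator.

Cross-participant summaries average participant means (each participant
contributes equally regardless of how long a subtask lasted) with the
sample SD across participants.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SubtaskAnnotation
from .rula_engine import SessionScores
from .taxonomy import UNASSIGNED

logger = logging.getLogger(__name__)

#: grand-score bands, label -> (lo, hi) inclusive
BANDS: dict[str, tuple[int, int]] = {
    "1-2": (1, 2),
    "3-4": (3, 4),
    "5-6": (5, 6),
    "7": (7, 7),
}

#: anatomical areas per side: area -> (score column template, score range)
_SIDED_AREAS = {
    "shoulder_upper_arm": ("upper_arm_{s}", (1, 6)),
    "elbow_lower_arm": ("lower_arm_{s}", (1, 3)),
    "wrist_hand": ("wrist_hand_{s}", (2, 6)),
}
_CENTRAL_AREAS = {
    "neck_head": ("neck", (1, 6)),
    "pelvis_trunk": ("trunk", (1, 6)),
}


class EmptySegmentError(ValueError):
    """Feature extraction requested on a segment with no scored frames."""


@dataclasses.dataclass(frozen=True)
class RiskThresholds:
    """Per-area local-score cutoffs defining time at a risky level.

    A frame is at risk for an area when its local score is >= the
    threshold.  Defaults (of the area's maximum): shoulder/upper arm 5
    of 6, elbow/lower arm 2 of 3, wrist/hand 5 of 6 (combined score),
    neck/head 4 of 6, pelvis/trunk 4 of 6.
    """

    shoulder_upper_arm: int = 5
    elbow_lower_arm: int = 2
    wrist_hand: int = 5
    neck_head: int = 4
    pelvis_trunk: int = 4

    def __post_init__(self) -> None:
        ranges = {**{k: v[1] for k, v in _SIDED_AREAS.items()},
                  **{k: v[1] for k, v in _CENTRAL_AREAS.items()}}
        for area, (lo, hi) in ranges.items():
            v = getattr(self, area)
            if not lo <= v <= hi:
                raise ValueError(f"threshold {area}={v} outside score range [{lo}, {hi}]")


@dataclasses.dataclass(frozen=True)
class SubtaskFeatures:
    """Exposure features of one segment for one side (right/left/central).

    ``mean_global``/``sd_global``/``pct_range`` are ``None`` for the
    central side, which has no grand score of its own.
    """

    group: str
    side: str  # "right" | "left" | "central"
    n_frames: int
    mean_global: float | None
    sd_global: float | None
    mean_local: dict[str, float]
    sd_local: dict[str, float]
    pct_range: dict[str, float] | None
    pct_at_risk: dict[str, float]


def segment_scores(
    scores: SessionScores,
    annotations: Sequence[SubtaskAnnotation],
) -> dict[str, SessionScores]:
    """Cut a scored stream into per-group segments.

    Each scored frame lands in at most one group (annotations are
    non-overlapping, intervals half-open); subtasks pool into their
    taxonomy group; uncovered frames collect under ``"(unassigned)"``.
    Annotations extending beyond the scored span are truncated with a
    warning.
    """
    t = scores.frame["t_s"].to_numpy()
    labels = np.full(len(t), UNASSIGNED, dtype=object)
    if len(t):
        span_lo, span_hi = t[0], t[-1]
        for a in annotations:
            if a.start_s < span_lo or a.end_s > span_hi:
                logger.warning(
                    "annotation %r [%g, %g) extends beyond scored span [%g, %g]; truncated",
                    a.label, a.start_s, a.end_s, span_lo, span_hi,
                )
            labels[(t >= a.start_s) & (t < a.end_s)] = a.group
    out: dict[str, SessionScores] = {}
    for group in pd.unique(labels):
        sub = scores.frame.loc[labels == group]
        out[str(group)] = SessionScores(sub, participant_id=scores.participant_id)
    return out


def _segment_side(
    frame: pd.DataFrame, group: str, side: str, thresholds: RiskThresholds
) -> SubtaskFeatures:
    n = len(frame)
    if side in ("right", "left"):
        s = side[0]
        grand = frame[f"grand_{s}"].to_numpy()
        pct_range = {
            band: 100.0 * np.mean((grand >= lo) & (grand <= hi))
            for band, (lo, hi) in BANDS.items()
        }
        areas = {a: frame[col.format(s=s)].to_numpy() for a, (col, _) in _SIDED_AREAS.items()}
        mean_global, sd_global = float(grand.mean()), float(grand.std(ddof=0))
    else:
        pct_range = None
        mean_global = sd_global = None
        areas = {a: frame[col].to_numpy() for a, (col, _) in _CENTRAL_AREAS.items()}
    return SubtaskFeatures(
        group=group,
        side=side,
        n_frames=n,
        mean_global=mean_global,
        sd_global=sd_global,
        mean_local={a: float(v.mean()) for a, v in areas.items()},
        sd_local={a: float(v.std(ddof=0)) for a, v in areas.items()},
        pct_range=pct_range,
        pct_at_risk={
            a: 100.0 * float(np.mean(v >= getattr(thresholds, a))) for a, v in areas.items()
        },
    )


def compute_features(
    scores: SessionScores,
    thresholds: RiskThresholds = RiskThresholds(),
    group: str = "(session)",
) -> dict[str, SubtaskFeatures]:
    """Features of one segment, keyed by side (``right``/``left``/``central``)."""
    if len(scores) == 0:
        raise EmptySegmentError(f"segment {group!r} has no scored frames")
    return {
        side: _segment_side(scores.frame, group, side, thresholds)
        for side in ("right", "left", "central")
    }


ParticipantFeatures = Mapping[str, Mapping[str, SubtaskFeatures]]
"""Per-participant features: group -> side -> SubtaskFeatures."""


def features_to_long(features: ParticipantFeatures) -> pd.DataFrame:
    """Flatten group -> side -> SubtaskFeatures into a tidy long table
    with columns (group, side, stat, value)."""
    rows = []
    for group, sides in features.items():
        for side, f in sides.items():
            stats: dict[str, float] = {}
            if f.mean_global is not None:
                stats["mean_global"] = f.mean_global
                stats["sd_global"] = f.sd_global
            for a, v in f.mean_local.items():
                stats[f"mean_local_{a}"] = v
            for a, v in f.sd_local.items():
                stats[f"sd_local_{a}"] = v
            if f.pct_range is not None:
                for band, v in f.pct_range.items():
                    stats[f"pct_range_{band}"] = v
            for a, v in f.pct_at_risk.items():
                stats[f"pct_at_risk_{a}"] = v
            rows.extend(
                {"group": group, "side": side, "stat": k, "value": v}
                for k, v in stats.items()
            )
    return pd.DataFrame(rows, columns=["group", "side", "stat", "value"])


def summarize_participants(
    per_participant: Sequence[ParticipantFeatures],
) -> pd.DataFrame:
    """Grand means +/- SD across participants, per group, side and stat.

    Each participant's segment mean contributes one equally weighted
    observation (a participant who spent longer on a subtask does not
    weigh more).  SD is the sample SD (ddof=1) across participants; a
    single participant yields SD 0 by convention.  Output columns:
    group, side, stat, mean, sd, n_participants.
    """
    if not per_participant:
        raise ValueError("no participant features given")
    long = pd.concat(
        [features_to_long(f).assign(participant=i) for i, f in enumerate(per_participant)],
        ignore_index=True,
    )
    def _agg(v: pd.Series) -> pd.Series:
        return pd.Series({
            "mean": v.mean(),
            "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
            "n_participants": len(v),
        })
    out = (
        long.groupby(["group", "side", "stat"], sort=False)["value"]
        .apply(_agg)
        .unstack()
        .reset_index()
    )
    out["n_participants"] = out["n_participants"].astype(int)
    return out
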