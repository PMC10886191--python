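"""Reading, writing and clock-synchronisation of session artifacts.

A recording session is represented by three plain-text CSV artifacts:

* a joint-angle stream (one row per frame, one column per angle channel),
* subtask annotations (label, start, end in seconds on the video clock),
* load events (intervals during which a weight was handled).

All files are comma-separated with a mandatory header and decimal-point
floats.  Intervals are half-open ``[start_s, end_s)`` everywhere: a frame
at time ``t`` belongs to an interval iff ``start <= t < end``, so interval
partitions never double-count frames.

Angle gaps are explicit ``NaN`` markers, never silent zeros; a frame with
any missing channel is later dropped from scoring and from all feature
denominators.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .taxonomy import TaxonomyError, group_of

logger = logging.getLogger(__name__)

#: Angle channels required for per-frame scoring, in canonical column order.
#: Bilateral angles carry an ``_r`` / ``_l`` suffix; head and trunk angles
#: are central.  All values are degrees, signed per anatomical convention
#: (flexion positive, extension negative).
CHANNELS: tuple[str, ...] = (
    "upper_arm_flexion_r",
    "upper_arm_flexion_l",
    "upper_arm_rotation_r",
    "upper_arm_rotation_l",
    "lower_arm_flexion_r",
    "lower_arm_flexion_l",
    "wrist_flexion_r",
    "wrist_flexion_l",
    "wrist_deviation_r",
    "wrist_deviation_l",
    "wrist_pronosupination_r",
    "wrist_pronosupination_l",
    "head_flexion",
    "head_inclination",
    "head_rotation",
    "trunk_flexion",
    "trunk_inclination",
    "trunk_rotation",
)


class SchemaError(ValueError):
    """A required column is absent from a tabular artifact."""


class FormatError(ValueError):
    """A structurally malformed artifact (e.g. non-monotone frame index)."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant."""


class SyncError(ValueError):
    """Annotation and kinematics clocks disagree beyond plausible drift."""


@dataclasses.dataclass(frozen=True)
class KinematicsRecord:
    """Uniformly sampled joint-angle channels for one participant session.

    Parameters
    ----------
    participant_id : str
        Free-form participant identifier.
    sample_rate_hz : float
        Sampling rate of the angle stream (60 Hz for the wearable system
        this pipeline targets).
    data : pandas.DataFrame
        One row per frame, exactly the :data:`CHANNELS` columns, degrees.
        Missing angles are ``NaN``.
    t0 : float
        Time of the first frame on the kinematics clock, seconds.
    """

    participant_id: str
    sample_rate_hz: float
    data: pd.DataFrame
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.sample_rate_hz > 0:
            raise ValidationError("sample_rate_hz must be positive")
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing required channel(s): {missing}")
        object.__setattr__(
            self, "data", self.data.loc[:, list(CHANNELS)].astype(float)
        )
        with np.errstate(invalid="ignore"):
            if np.isinf(self.data.to_numpy()).any():
                raise ValidationError("angle channels contain infinities")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps on the kinematics clock, seconds."""
        return self.t0 + np.arange(self.n_frames) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sample_rate_hz

    def complete_frames(self) -> np.ndarray:
        """Boolean mask of frames with all channels present."""
        return ~self.data.isna().any(axis=1).to_numpy()


@dataclasses.dataclass(frozen=True, order=True)
class SubtaskAnnotation:
    """A labelled work interval ``[start_s, end_s)`` on some clock."""

    start_s: float
    end_s: float
    label: str
    group: str = ""

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"annotation {self.label!r}: start_s ({self.start_s}) must be "
                f"< end_s ({self.end_s})"
            )
        expected = group_of(self.label)  # raises TaxonomyError if unknown
        if self.group == "":
            object.__setattr__(self, "group", expected)
        elif self.group != expected:
            raise TaxonomyError(
                f"subtask {self.label!r} belongs to group {expected!r}, "
                f"not {self.group!r}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclasses.dataclass(frozen=True, order=True)
class LoadEvent:
    """An interval during which a weight was handled.

    ``static_or_repeated`` marks loads held statically or lifted
    repeatedly (raises the force/load adder from 1 to 2 in the 2-10 kg
    band); ``shock_or_rapid_buildup`` marks shock or rapid force build-up
    (forces the adder to 3 regardless of mass).
    """

    start_s: float
    end_s: float
    mass_kg: float
    static_or_repeated: bool = False
    shock_or_rapid_buildup: bool = False

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"load event: start_s ({self.start_s}) must be < end_s "
                f"({self.end_s})"
            )
        if self.mass_kg < 0:
            raise ValidationError(f"mass_kg must be >= 0, got {self.mass_kg}")


@dataclasses.dataclass(frozen=True)
class SyncOffset:
    """Affine map from the annotation clock to the kinematics clock.

    ``t_kin = offset_s + scale * t_ann``.  ``scale`` is 1 for pure-offset
    synchronisation; a scale outside [0.99, 1.01] is rejected as
    implausible clock drift.
    """

    offset_s: float
    scale: float = 1.0

    def apply(self, t: float | np.ndarray) -> float | np.ndarray:
        return self.offset_s + self.scale * t

    def inverse(self) -> "SyncOffset":
        return SyncOffset(offset_s=-self.offset_s / self.scale, scale=1.0 / self.scale)


# ---------------------------------------------------------------------------
# readers / writers


def read_kinematics(
    path: str | Path,
    sample_rate_hz: float,
    participant_id: str | None = None,
    t0: float = 0.0,
) -> KinematicsRecord:
    """Read a joint-angle CSV into a validated :class:`KinematicsRecord`.

    Cells that do not parse as numbers become explicit ``NaN`` markers.
    An optional leading ``frame`` column, when present, must be strictly
    increasing (duplicates or reordering indicate a corrupted export).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in CHANNELS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required channel(s): {', '.join(missing)}"
        )
    if "frame" in raw.columns:
        idx = pd.to_numeric(raw["frame"], errors="raise").to_numpy()
        if len(idx) and not np.all(np.diff(idx) > 0):
            raise FormatError(
                f"{path.name}: frame index is not strictly increasing"
            )
    data = raw.loc[:, list(CHANNELS)].apply(pd.to_numeric, errors="coerce")
    n_bad = int(data.isna().any(axis=1).sum())
    if n_bad:
        logger.info("%s: %d frame(s) with missing/unparseable angles", path.name, n_bad)
    return KinematicsRecord(
        participant_id=participant_id if participant_id is not None else path.stem,
        sample_rate_hz=sample_rate_hz,
        data=data,
        t0=t0,
    )


def write_kinematics(record: KinematicsRecord, path: str | Path) -> None:
    record.data.to_csv(path, index=False, float_format="%.6f")


def read_annotations(path: str | Path) -> list[SubtaskAnnotation]:
    """Read subtask annotations; validate labels and non-overlap.

    The group is inferred from the subtask label; annotations are returned
    sorted by ``start_s``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        return []
    for col in ("label", "start_s", "end_s"):
        if col not in raw.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    anns = [
        SubtaskAnnotation(
            start_s=float(r.start_s), end_s=float(r.end_s), label=str(r.label)
        )
        for r in raw.itertuples()
    ]
    anns.sort()
    _check_non_overlapping(anns)
    return anns


def _check_non_overlapping(anns: Sequence[SubtaskAnnotation]) -> None:
    for a, b in zip(anns, anns[1:]):
        if b.start_s < a.end_s:  # half-open: touching intervals are fine
            raise ValidationError(
                f"overlapping annotations: {a.label!r} [{a.start_s}, {a.end_s}) "
                f"and {b.label!r} [{b.start_s}, {b.end_s})"
            )


def write_annotations(anns: Iterable[SubtaskAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [{"label": a.label, "start_s": a.start_s, "end_s": a.end_s} for a in anns]
    ).to_csv(path, index=False)


_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(x: object) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    try:
        return _BOOL[str(x).strip().lower()]
    except KeyError:
        raise ValidationError(f"cannot parse boolean value {x!r}") from None


def read_load_events(path: str | Path) -> list[LoadEvent]:
    """Read load events; an empty file yields an empty list."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        return []
    for col in ("start_s", "end_s", "mass_kg"):
        if col not in raw.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    events = [
        LoadEvent(
            start_s=float(r.start_s),
            end_s=float(r.end_s),
            mass_kg=float(r.mass_kg),
            static_or_repeated=_parse_bool(getattr(r, "static_or_repeated", False)),
            shock_or_rapid_buildup=_parse_bool(
                getattr(r, "shock_or_rapid_buildup", False)
            ),
        )
        for r in raw.itertuples()
    ]
    events.sort()
    return events


def write_load_events(events: Iterable[LoadEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "start_s": e.start_s,
                "end_s": e.end_s,
                "mass_kg": e.mass_kg,
                "static_or_repeated": e.static_or_repeated,
                "shock_or_rapid_buildup": e.shock_or_rapid_buildup,
            }
            for e in events
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# clock synchronisation


def sync_offset(
    clap_annotation_s: tuple[float, float],
    clap_kinematic_s: tuple[float, float],
    max_drift: float = 0.01,
) -> SyncOffset:
    """Fit the affine annotation->kinematics clock map from the two claps.

    The participant claps at the start and end of the recording; both
    clocks observe both claps.  A pure offset is the degenerate case
    (scale exactly 1).  A rescale factor outside ``1 +/- max_drift`` is
    rejected: real video/IMU clock drift over an hour is far below 1%.
    """
    a1, a2 = clap_annotation_s
    k1, k2 = clap_kinematic_s
    if not (a1 < a2 and k1 < k2):
        raise SyncError("clap instants must be increasing on both clocks")
    scale = (k2 - k1) / (a2 - a1)
    if not (1 - max_drift <= scale <= 1 + max_drift):
        raise SyncError(
            f"clock rescale factor {scale:.4f} outside plausible drift band "
            f"[{1 - max_drift}, {1 + max_drift}]"
        )
    return SyncOffset(offset_s=k1 - scale * a1, scale=scale)


def synchronize(
    annotations: Sequence[SubtaskAnnotation],
    clap_annotation_s: tuple[float, float],
    clap_kinematic_s: tuple[float, float],
) -> list[SubtaskAnnotation]:
    """Map annotation intervals onto the kinematics clock via the claps."""
    m = sync_offset(clap_annotation_s, clap_kinematic_s)
    return [
        dataclasses.replace(
            a, start_s=float(m.apply(a.start_s)), end_s=float(m.apply(a.end_s))
        )
        for a in annotations
    ]
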