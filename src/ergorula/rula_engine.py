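"""Per-frame RULA scoring of joint-angle streams.

The rapid upper limb assessment (RULA) turns a posture into a 1-7 grand
score per body side in three stages:

1. *Local scores* bin each joint angle: upper arm (1-6), lower arm (1-3),
   wrist posture (1-4), wrist twist (1-2), neck (1-6), trunk (1-6),
   legs (1-2).
2. Two look-up tables combine them: Table A (upper arm x lower arm x
   wrist x twist) for each arm-wrist chain, Table B (neck x trunk x legs)
   for the central chain.  A muscle-use adder (0-1, static or highly
   repetitive work) and a force/load adder (0-3, handled mass) are added
   to both, giving score C (per side) and score D (shared).
3. Table C maps (score C, score D) to the grand score 1-7; inputs of 8 or
   more collapse onto the 8+ row/column.

The numeric bins and the three tables follow the original published RULA
worksheet and ship as versioned CSV fixtures under ``ergorula/data``.

Angle sign conventions: flexion positive, extension negative, degrees.
Bin boundaries are half-open and lower-inclusive ([20, 45) etc.): a value
exactly on a boundary takes the higher bin.  Scoring a continuous stream
is therefore reproducible bit-for-bit.

All scalar scorers also accept numpy arrays; :func:`score_session` scores
a whole 40-60 min session vectorised.
"""

from __future__ import annotations

import dataclasses
import logging
from importlib.resources import files
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import KinematicsRecord, LoadEvent

logger = logging.getLogger(__name__)


class DomainError(ValueError):
    """A look-up table argument outside its declared range."""


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass(frozen=True)
class RulaDefaults:
    """Session-level scoring context that angle streams cannot provide.

    Defaults reflect an observational protocol where shoulders were never
    raised, legs and feet were always supported, and posture was neither
    held static beyond the method's criterion nor repeated four or more
    times per minute; all three are overridable per session.
    """

    shoulders_raised: bool = False
    legs_supported: bool = True
    posture_static_or_repeated: bool = False


@dataclasses.dataclass(frozen=True)
class ScoringAdjustments:
    """Thresholds for the worksheet's posture adjustments.

    The wearable's minimal angle set does not measure shoulder abduction
    or hand position directly, so two adjustments are driven by proxy
    predicates on upper-arm internal/external rotation:

    * ``abduction_from_rotation`` (default off) approximates "upper arm
      abducted" as ``|rotation| > abduction_rotation_deg``;
    * the lower-arm "working across the midline or out to one side" +1 is
      applied when ``|rotation| > midline_rotation_deg`` (default on; a
      cross-body or out-turned forearm shows up as large humeral
      rotation).
    """

    wrist_neutral_eps_deg: float = 1.0
    trunk_neutral_eps_deg: float = 1.0
    wrist_deviation_deg: float = 10.0
    wrist_twist_endrange_deg: float = 60.0
    neck_rotation_deg: float = 20.0
    neck_inclination_deg: float = 20.0
    trunk_rotation_deg: float = 20.0
    trunk_inclination_deg: float = 20.0
    abduction_from_rotation: bool = False
    abduction_rotation_deg: float = 30.0
    lower_arm_midline_from_rotation: bool = True
    midline_rotation_deg: float = 45.0


DEFAULT_ADJUSTMENTS = ScoringAdjustments()


# ---------------------------------------------------------------------------
# look-up tables (packaged fixtures)


def _load_table(name: str, index_cols: tuple[str, ...], shape: tuple[int, ...]) -> np.ndarray:
    df = pd.read_csv(files("ergorula.data") / name)
    arr = np.zeros(shape, dtype=np.int64)
    idx = tuple(df[c].to_numpy() - 1 for c in index_cols)
    arr[idx] = df["score"].to_numpy()
    return arr


_TABLE_A = _load_table("table_a.csv", ("upper_arm", "lower_arm", "wrist", "wrist_twist"), (6, 3, 4, 2))
_TABLE_B = _load_table("table_b.csv", ("neck", "trunk", "legs"), (6, 6, 2))
_TABLE_C = _load_table("table_c.csv", ("score_c", "score_d"), (8, 7))


def _check_range(name: str, value, lo: int, hi: int) -> np.ndarray:
    arr = np.asarray(value)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise DomainError(f"{name} must be integer, got {value!r}")
        arr = arr.astype(np.int64)
    if arr.size and (arr.min() < lo or arr.max() > hi):
        raise DomainError(f"{name} must be in [{lo}, {hi}], got {value!r}")
    return arr


def table_a(upper, lower, wrist, twist):
    """Posture score A for one arm-wrist chain (max 9)."""
    u = _check_range("upper_arm", upper, 1, 6)
    l = _check_range("lower_arm", lower, 1, 3)
    w = _check_range("wrist", wrist, 1, 4)
    t = _check_range("wrist_twist", twist, 1, 2)
    out = _TABLE_A[u - 1, l - 1, w - 1, t - 1]
    return out if out.ndim else int(out)


def table_b(neck, trunk, legs):
    """Posture score B for the neck-trunk-legs chain (max 9)."""
    n = _check_range("neck", neck, 1, 6)
    t = _check_range("trunk", trunk, 1, 6)
    g = _check_range("legs", legs, 1, 2)
    out = _TABLE_B[n - 1, t - 1, g - 1]
    return out if out.ndim else int(out)


def table_c(score_c, score_d):
    """Grand score 1-7 from the modified intermediary scores.

    Inputs of 8 or more collapse onto the table's 8+ row/column, so the
    function is total (and saturating) for any scores >= 1.
    """
    c = _check_range("score_c", score_c, 1, 10**9)
    d = _check_range("score_d", score_d, 1, 10**9)
    out = _TABLE_C[np.minimum(c, 8) - 1, np.minimum(d, 7) - 1]
    return out if out.ndim else int(out)


# ---------------------------------------------------------------------------
# local scorers (array-capable; scalars in -> python int out)


def _ret(out: np.ndarray):
    return out if out.ndim else int(out)


def score_upper_arm(flexion_deg, shoulder_raised=False, abducted=False, arm_supported=False):
    """Upper-arm score 1-6 from shoulder flexion/extension.

    Bins: [-20, 20) -> 1; extension beyond -20 or [20, 45) -> 2;
    [45, 90) -> 3; >= 90 -> 4.  +1 shoulder raised, +1 abducted,
    -1 arm supported or person leaning; clamped to 1-6.
    """
    f = np.asarray(flexion_deg, dtype=float)
    base = np.select(
        [f >= 90, f >= 45, f >= 20, f > -20],
        [4, 3, 2, 1],
        default=2,  # extension beyond -20
    )
    score = base + np.asarray(shoulder_raised, int) + np.asarray(abducted, int) - np.asarray(arm_supported, int)
    return _ret(np.clip(score, 1, 6))


def score_lower_arm(flexion_deg, across_midline_or_out=False):
    """Lower-arm score 1-3: 1 when elbow flexion in [60, 100), else 2;
    +1 when the forearm works across the midline or out to the side."""
    f = np.asarray(flexion_deg, dtype=float)
    base = np.where((f >= 60) & (f < 100), 1, 2)
    return _ret(np.clip(base + np.asarray(across_midline_or_out, int), 1, 3))


def score_wrist(flexion_deg, deviation_deg, adjustments: ScoringAdjustments = DEFAULT_ADJUSTMENTS):
    """Wrist posture score 1-4 from flexion/extension and radioulnar deviation.

    1 if |flexion| is within the neutral tolerance, 2 up to 15 degrees
    either way, 3 beyond; +1 when |deviation| exceeds the deviation
    threshold (wrist bent from the midline).
    """
    f = np.abs(np.asarray(flexion_deg, dtype=float))
    base = np.select([f < adjustments.wrist_neutral_eps_deg, f <= 15], [1, 2], default=3)
    dev = np.abs(np.asarray(deviation_deg, dtype=float)) > adjustments.wrist_deviation_deg
    return _ret(np.clip(base + dev.astype(int), 1, 4))


def score_wrist_twist(pronosupination_deg, adjustments: ScoringAdjustments = DEFAULT_ADJUSTMENTS):
    """Wrist twist score: 1 in mid pronation/supination range, 2 near end of range."""
    p = np.abs(np.asarray(pronosupination_deg, dtype=float))
    return _ret(np.where(p >= adjustments.wrist_twist_endrange_deg, 2, 1))


def score_neck(flexion_deg, rotation_deg=0.0, inclination_deg=0.0,
               adjustments: ScoringAdjustments = DEFAULT_ADJUSTMENTS):
    """Neck score 1-6: flexion [0, 10) -> 1, [10, 20) -> 2, >= 20 -> 3,
    extension -> 4; +1 twisted, +1 side-bent."""
    f = np.asarray(flexion_deg, dtype=float)
    base = np.select([f < 0, f >= 20, f >= 10], [4, 3, 2], default=1)
    adj = (np.abs(np.asarray(rotation_deg, float)) > adjustments.neck_rotation_deg).astype(int) \
        + (np.abs(np.asarray(inclination_deg, float)) > adjustments.neck_inclination_deg).astype(int)
    return _ret(np.clip(base + adj, 1, 6))


def score_trunk(flexion_deg, rotation_deg=0.0, inclination_deg=0.0, standing=True,
                adjustments: ScoringAdjustments = DEFAULT_ADJUSTMENTS):
    """Trunk score 1-6: upright (|flexion| within tolerance) -> 1, then
    magnitude bins [eps, 20) -> 2, [20, 60) -> 3, >= 60 -> 4 (forward and
    backward lean score alike); +1 twisted, +1 side-bent.

    ``standing`` is accepted for symmetry with the worksheet (a seated,
    well-supported trunk also scores 1); it does not alter the bins.
    """
    del standing
    a = np.abs(np.asarray(flexion_deg, dtype=float))
    base = np.select([a < adjustments.trunk_neutral_eps_deg, a < 20, a < 60], [1, 2, 3], default=4)
    adj = (np.abs(np.asarray(rotation_deg, float)) > adjustments.trunk_rotation_deg).astype(int) \
        + (np.abs(np.asarray(inclination_deg, float)) > adjustments.trunk_inclination_deg).astype(int)
    return _ret(np.clip(base + adj, 1, 6))


def score_legs(legs_supported=True):
    """Legs score: 1 if legs and feet are supported and balanced, else 2."""
    return _ret(np.where(np.asarray(legs_supported, bool), 1, 2))


def muscle_use_score(static_or_repeated=False):
    """Muscle-use adder: 1 for mainly static posture or action repeated
    4+ times per minute, else 0."""
    return _ret(np.asarray(static_or_repeated, bool).astype(int))


def force_load_score(active_loads: Sequence[LoadEvent]):
    """Force/load adder 0-3 from the loads active at one instant.

    With ``m`` the maximum active mass (0 with no active event): 0 for
    m < 2 kg intermittent; 1 for 2-10 kg intermittent; 2 for 2-10 kg
    static or repeated; 3 for m > 10 kg or any shock / rapid build-up.
    """
    if not active_loads:
        return 0
    m = max(e.mass_kg for e in active_loads)
    shock = any(e.shock_or_rapid_buildup for e in active_loads)
    static = any(e.static_or_repeated for e in active_loads if e.mass_kg >= 2)
    if shock or m > 10:
        return 3
    if m >= 2:
        return 2 if static else 1
    return 0


def force_load_series(times_s: np.ndarray, loads: Sequence[LoadEvent]) -> np.ndarray:
    """Vectorised force/load adder over a whole frame-time vector."""
    t = np.asarray(times_s, dtype=float)
    mass = np.zeros_like(t)
    shock = np.zeros(t.shape, dtype=bool)
    static = np.zeros(t.shape, dtype=bool)
    for e in loads:
        active = (t >= e.start_s) & (t < e.end_s)
        mass[active] = np.maximum(mass[active], e.mass_kg)
        if e.shock_or_rapid_buildup:
            shock |= active
        if e.static_or_repeated and e.mass_kg >= 2:
            static |= active
    out = np.zeros(t.shape, dtype=np.int64)
    out[(mass >= 2)] = 1
    out[(mass >= 2) & static] = 2
    out[(mass > 10) | shock] = 3
    return out


# ---------------------------------------------------------------------------
# per-frame containers


@dataclasses.dataclass(frozen=True)
class LocalScores:
    upper_arm_r: int
    upper_arm_l: int
    lower_arm_r: int
    lower_arm_l: int
    wrist_posture_r: int
    wrist_posture_l: int
    wrist_twist_r: int
    wrist_twist_l: int
    neck: int
    trunk: int
    legs: int

    @property
    def wrist_hand_r(self) -> int:
        """Combined wrist-and-hand reporting score (2-6)."""
        return self.wrist_posture_r + self.wrist_twist_r

    @property
    def wrist_hand_l(self) -> int:
        return self.wrist_posture_l + self.wrist_twist_l


@dataclasses.dataclass(frozen=True)
class FrameScores:
    """All RULA scores for one frame: local, intermediary and grand."""

    t_s: float
    locals: LocalScores
    posture_a_r: int
    posture_a_l: int
    posture_b: int
    muscle_use: int
    force_load: int
    score_c_r: int
    score_c_l: int
    score_d: int
    grand_r: int
    grand_l: int


#: SessionScores column order (t_s plus every score component)
SCORE_COLUMNS: tuple[str, ...] = (
    "t_s",
    "upper_arm_r", "upper_arm_l", "lower_arm_r", "lower_arm_l",
    "wrist_posture_r", "wrist_posture_l", "wrist_twist_r", "wrist_twist_l",
    "wrist_hand_r", "wrist_hand_l",
    "neck", "trunk", "legs",
    "posture_a_r", "posture_a_l", "posture_b",
    "muscle_use", "force_load",
    "score_c_r", "score_c_l", "score_d",
    "grand_r", "grand_l",
)


class SessionScores:
    """Per-frame scores for one session, DataFrame-backed.

    Behaves as a sequence of :class:`FrameScores` (len / index /
    iteration) while keeping the columnar frame for vectorised feature
    extraction.  ``n_dropped`` counts frames excluded for missing angles.
    """

    def __init__(self, frame: pd.DataFrame, n_dropped: int = 0, participant_id: str = ""):
        missing = [c for c in SCORE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"score frame missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)
        self.n_dropped = int(n_dropped)
        self.participant_id = participant_id

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, i: int) -> FrameScores:
        r = self.frame.iloc[i]
        loc = LocalScores(
            upper_arm_r=int(r.upper_arm_r), upper_arm_l=int(r.upper_arm_l),
            lower_arm_r=int(r.lower_arm_r), lower_arm_l=int(r.lower_arm_l),
            wrist_posture_r=int(r.wrist_posture_r), wrist_posture_l=int(r.wrist_posture_l),
            wrist_twist_r=int(r.wrist_twist_r), wrist_twist_l=int(r.wrist_twist_l),
            neck=int(r.neck), trunk=int(r.trunk), legs=int(r.legs),
        )
        return FrameScores(
            t_s=float(r.t_s), locals=loc,
            posture_a_r=int(r.posture_a_r), posture_a_l=int(r.posture_a_l),
            posture_b=int(r.posture_b),
            muscle_use=int(r.muscle_use), force_load=int(r.force_load),
            score_c_r=int(r.score_c_r), score_c_l=int(r.score_c_l),
            score_d=int(r.score_d),
            grand_r=int(r.grand_r), grand_l=int(r.grand_l),
        )

    def __iter__(self) -> Iterator[FrameScores]:
        for i in range(len(self)):
            yield self[i]


# ---------------------------------------------------------------------------
# frame and session scoring


def _score_arrays(
    ch: Mapping[str, np.ndarray],
    t_s: np.ndarray,
    force_load: np.ndarray,
    defaults: RulaDefaults,
    adjustments: ScoringAdjustments,
) -> pd.DataFrame:
    """Vectorised scoring core over channel arrays (no missing values)."""
    adj = adjustments
    out: dict[str, np.ndarray] = {"t_s": t_s}
    for side in ("r", "l"):
        rot = np.abs(ch[f"upper_arm_rotation_{side}"])
        abducted = (rot > adj.abduction_rotation_deg) if adj.abduction_from_rotation else False
        across = (rot > adj.midline_rotation_deg) if adj.lower_arm_midline_from_rotation else False
        out[f"upper_arm_{side}"] = np.asarray(score_upper_arm(
            ch[f"upper_arm_flexion_{side}"], defaults.shoulders_raised, abducted, False))
        out[f"lower_arm_{side}"] = np.asarray(score_lower_arm(
            ch[f"lower_arm_flexion_{side}"], across))
        out[f"wrist_posture_{side}"] = np.asarray(score_wrist(
            ch[f"wrist_flexion_{side}"], ch[f"wrist_deviation_{side}"], adj))
        out[f"wrist_twist_{side}"] = np.asarray(score_wrist_twist(
            ch[f"wrist_pronosupination_{side}"], adj))
        out[f"wrist_hand_{side}"] = out[f"wrist_posture_{side}"] + out[f"wrist_twist_{side}"]
    out["neck"] = np.asarray(score_neck(
        ch["head_flexion"], ch["head_rotation"], ch["head_inclination"], adj))
    out["trunk"] = np.asarray(score_trunk(
        ch["trunk_flexion"], ch["trunk_rotation"], ch["trunk_inclination"], True, adj))
    out["legs"] = np.full(t_s.shape, score_legs(defaults.legs_supported), dtype=np.int64)

    out["muscle_use"] = np.full(
        t_s.shape, muscle_use_score(defaults.posture_static_or_repeated), dtype=np.int64)
    out["force_load"] = np.asarray(force_load, dtype=np.int64)

    out["posture_b"] = _TABLE_B[out["neck"] - 1, out["trunk"] - 1, out["legs"] - 1]
    out["score_d"] = out["posture_b"] + out["muscle_use"] + out["force_load"]
    for side in ("r", "l"):
        out[f"posture_a_{side}"] = _TABLE_A[
            out[f"upper_arm_{side}"] - 1,
            out[f"lower_arm_{side}"] - 1,
            out[f"wrist_posture_{side}"] - 1,
            out[f"wrist_twist_{side}"] - 1,
        ]
        out[f"score_c_{side}"] = out[f"posture_a_{side}"] + out["muscle_use"] + out["force_load"]
        out[f"grand_{side}"] = _TABLE_C[
            np.minimum(out[f"score_c_{side}"], 8) - 1,
            np.minimum(out["score_d"], 7) - 1,
        ]
    return pd.DataFrame(out, columns=list(SCORE_COLUMNS))


def score_frame(
    angles: Mapping[str, float],
    loads: Sequence[LoadEvent] = (),
    defaults: RulaDefaults = RulaDefaults(),
    adjustments: ScoringAdjustments = DEFAULT_ADJUSTMENTS,
    t_s: float = 0.0,
) -> FrameScores:
    """Score a single posture (all channels present) into :class:`FrameScores`.

    Left and right sides are composed independently through Table A and
    Table C; posture score B and the two adders are shared.
    """
    from .io_formats import CHANNELS

    missing = [c for c in CHANNELS if c not in angles or not np.isfinite(angles[c])]
    if missing:
        raise ValueError(f"frame is missing channel(s): {missing}")
    ch = {c: np.asarray([float(angles[c])]) for c in CHANNELS}
    active = [e for e in loads if e.start_s <= t_s < e.end_s]
    fl = np.asarray([force_load_score(active)])
    frame = _score_arrays(ch, np.asarray([t_s]), fl, defaults, adjustments)
    return SessionScores(frame)[0]


def score_session(
    record: KinematicsRecord,
    loads: Sequence[LoadEvent] = (),
    defaults: RulaDefaults = RulaDefaults(),
    adjustments: ScoringAdjustments = DEFAULT_ADJUSTMENTS,
) -> SessionScores:
    """Score every complete frame of a session, order preserved.

    Frames with any missing channel are dropped from scoring (and later
    from every feature denominator); the drop count is logged and kept on
    the returned :class:`SessionScores`.
    """
    mask = record.complete_frames()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d/%d frame(s) with missing angles",
            record.participant_id, n_dropped, record.n_frames,
        )
    t = record.times[mask]
    ch = {c: record.data[c].to_numpy()[mask] for c in record.data.columns}
    fl = force_load_series(t, loads)
    frame = _score_arrays(ch, t, fl, defaults, adjustments)
    return SessionScores(frame, n_dropped=n_dropped, participant_id=record.participant_id)
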