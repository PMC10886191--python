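"""Synthetic multi-subtask cleaning sessions for end-to-end testing.

No recordings of the original study are deposited, so the generator
emulates what the analysis assumes about them: 40-60 min sessions at
60 Hz, one interval per subtask group with subtask labels drawn from the
group's coding scheme, brief unassigned transitions, participant-level
posture offsets, and load episodes for the handling tasks.

Each archetype draws every angle channel as

    mean + participant offset + slow sinusoidal drift + Gaussian noise,

clipped to +/-180 degrees.  This produces realistic bin-crossing in the
scored stream without modelling true human dynamics — the scoring only
consumes angles through bins.

Risk is *designed*: three "mover" groups (operating table, stretcher,
trolley) carry heavy (> 10 kg) near-continuous loads and flexed trunks,
two handling groups carry intermittent heavy loads with large
between-participant variation, and the remaining twelve groups are
ordinary cleaning postures whose grand scores sit in the 3-4 band.
:func:`ground_truth` exposes the designed tier ordering for recovery
tests.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CHANNELS,
    KinematicsRecord,
    LoadEvent,
    SubtaskAnnotation,
    write_annotations,
    write_kinematics,
    write_load_events,
)
from .taxonomy import GROUPS


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclasses.dataclass(frozen=True)
class ChannelMotion:
    """Stationary motion model for one angle channel, degrees."""

    mean: float
    sd: float = 3.0
    drift_amp: float = 4.0
    drift_period_s: float = 20.0

    def __post_init__(self) -> None:
        if self.sd < 0 or self.drift_amp < 0 or self.drift_period_s <= 0:
            raise ConfigError("channel SDs/amplitudes must be >= 0, period > 0")


@dataclasses.dataclass(frozen=True)
class LoadProfile:
    """One load episode per interval: mass and the fraction of the
    interval during which it is active (jittered per participant)."""

    mass_kg: float
    fraction: float
    fraction_jitter: float = 0.0
    static_or_repeated: bool = False
    shock_or_rapid_buildup: bool = False

    def __post_init__(self) -> None:
        if self.mass_kg < 0 or not 0 < self.fraction <= 1:
            raise ConfigError("load mass must be >= 0 and fraction in (0, 1]")


#: neutral-ish working posture used for channels an archetype leaves
#: unspecified and for unassigned transition frames
BASE_POSTURE: dict[str, ChannelMotion] = {
    "upper_arm_flexion": ChannelMotion(25, 6),
    "upper_arm_rotation": ChannelMotion(20, 8),
    "lower_arm_flexion": ChannelMotion(45, 8),
    "wrist_flexion": ChannelMotion(12, 6),
    "wrist_deviation": ChannelMotion(5, 4),
    "wrist_pronosupination": ChannelMotion(30, 10),
    "head_flexion": ChannelMotion(8, 4),
    "head_inclination": ChannelMotion(3, 3),
    "head_rotation": ChannelMotion(5, 5),
    "trunk_flexion": ChannelMotion(10, 5),
    "trunk_inclination": ChannelMotion(3, 3),
    "trunk_rotation": ChannelMotion(5, 4),
}


@dataclasses.dataclass(frozen=True)
class SubtaskArchetype:
    """Generative description of one subtask group's interval."""

    group: str
    duration_s: float
    duration_jitter_s: float = 0.0
    channels: Mapping[str, ChannelMotion] = dataclasses.field(default_factory=dict)
    load: LoadProfile | None = None
    target_risk_tier: str = "low"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigError(f"unknown subtask group {self.group!r}")
        if self.duration_s <= 0 or self.duration_jitter_s < 0:
            raise ConfigError("durations must be positive, jitter >= 0")
        if self.target_risk_tier not in ("low", "medium", "high"):
            raise ConfigError(f"unknown risk tier {self.target_risk_tier!r}")
        if self.target_risk_tier == "high":
            heavy = self.load is not None and self.load.mass_kg > 10
            extreme = any(
                abs(m.mean) >= 90 if name.startswith("upper_arm_flexion")
                else abs(m.mean) >= 60
                for name, m in self.channels.items()
                if name.startswith(("upper_arm_flexion", "trunk_flexion"))
            )
            if not (heavy or extreme):
                raise ConfigError(
                    f"high-tier archetype {self.group!r} needs a > 10 kg load "
                    "or an extreme posture mean"
                )

    def motion(self, channel_base: str) -> ChannelMotion:
        return self.channels.get(channel_base, BASE_POSTURE[channel_base])


def _arch(group, duration, tier="low", load=None, **over):
    channels = {k: ChannelMotion(*v) if isinstance(v, tuple) else v for k, v in over.items()}
    return SubtaskArchetype(
        group=group,
        duration_s=duration,
        duration_jitter_s=0.15 * duration,
        channels=channels,
        load=load,
        target_risk_tier=tier,
    )


#: the three designed high-risk "mover" groups
HIGH_TIER_GROUPS: tuple[str, ...] = (
    "Operating table moving",
    "Stretcher moving",
    "Trolley moving",
)

DEFAULT_ARCHETYPES: tuple[SubtaskArchetype, ...] = (
    # Twelve "low" groups: ordinary cleaning postures in the 3-4 grand
    # band.  Their channel profiles differ (reaching up, mopping,
    # wrist-heavy scrubbing, ...) but are balanced so the designed grand
    # means stay close: between-participant posture variation, not the
    # designed profile, decides their pairwise ordering.
    _arch("Waste disposal", 170, trunk_flexion=(13, 5)),
    _arch("Handling of lighting", 170, upper_arm_flexion=(32, 7), head_flexion=(4, 3)),
    _arch("Handling around the patient", 170, trunk_flexion=(12, 5), wrist_flexion=(14, 6)),
    _arch("Cables and pipes handling", 170, trunk_flexion=(14, 5), trunk_rotation=(8, 4)),
    # Two "medium" groups: intermittent heavy lifts whose active fraction
    # varies strongly between participants, mirroring occasional
    # high-exposure handling work.
    _arch(
        "Patient transfer", 120, tier="medium",
        load=LoadProfile(12.0, fraction=0.12, fraction_jitter=0.15),
        trunk_flexion=(14, 5),
    ),
    _arch("Surfaces and tools cleaning", 170, wrist_flexion=(14, 6), wrist_deviation=(7, 4)),
    _arch(
        "Various objects moving", 170,
        load=LoadProfile(4.0, fraction=0.3, fraction_jitter=0.1),
        trunk_flexion=(12, 5),
    ),
    _arch(
        "Floor cleaning", 170,
        wrist_flexion=(16, 6), wrist_deviation=(8, 4), trunk_flexion=(16, 6),
    ),
    _arch(
        "Box lifting", 120, tier="medium",
        load=LoadProfile(12.0, fraction=0.12, fraction_jitter=0.15),
        trunk_flexion=(15, 5),
    ),
    _arch(
        "Water tanks handling", 170,
        load=LoadProfile(5.0, fraction=0.2, fraction_jitter=0.1),
        wrist_flexion=(15, 6), wrist_deviation=(9, 4),
    ),
    _arch("Pressure washing", 170, upper_arm_flexion=(33, 8), wrist_flexion=(15, 6)),
    # Three "high" movers: rolling heavy equipment, near-continuous
    # > 10 kg effective loads with flexed trunk.  The tiered load
    # fractions separate the movers from each other as well as from
    # everything else.
    _arch(
        "Operating table moving", 60, tier="high",
        load=LoadProfile(15.0, fraction=0.95, fraction_jitter=0.03),
        trunk_flexion=(28, 5), head_flexion=(14, 4), upper_arm_flexion=(30, 6),
    ),
    _arch(
        "Stretcher moving", 60, tier="high",
        load=LoadProfile(15.0, fraction=0.80, fraction_jitter=0.03),
        trunk_flexion=(26, 5), head_flexion=(12, 4), upper_arm_flexion=(30, 6),
    ),
    _arch("Operating table cleaning", 170, trunk_flexion=(17, 6), wrist_flexion=(15, 6)),
    _arch(
        "Operating table disassembly", 120,
        load=LoadProfile(5.0, fraction=0.3, fraction_jitter=0.1),
        trunk_flexion=(14, 5),
    ),
    _arch("Sheets moving", 170, trunk_flexion=(11, 4), wrist_flexion=(12, 5)),
    _arch(
        "Trolley moving", 60, tier="high",
        load=LoadProfile(15.0, fraction=0.65, fraction_jitter=0.03),
        trunk_flexion=(24, 5), head_flexion=(10, 4), upper_arm_flexion=(30, 6),
    ),
)


@dataclasses.dataclass(frozen=True)
class SessionConfig:
    """Study-generation configuration.

    The default study matches the emulated protocol: 8 participants, one
    interval per subtask group, 60 Hz, sessions whose archetype durations
    sum to the 40-60 min window.  ``duration_scale`` shrinks (or
    stretches) every archetype interval and transition by a common
    factor, preserving the study's structure at a smaller problem size.
    ``session_length_s``, when given, must accommodate the archetypes;
    remaining time becomes trailing unassigned frames.
    """

    n_participants: int = 8
    sample_rate_hz: float = 60.0
    archetypes: tuple[SubtaskArchetype, ...] = DEFAULT_ARCHETYPES
    session_length_s: float | None = None
    duration_scale: float = 1.0
    participant_offset_sd_deg: float = 6.0
    transition_s: tuple[float, float] = (2.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("need at least one participant")
        if self.sample_rate_hz <= 0 or self.duration_scale <= 0:
            raise ConfigError("sample_rate_hz and duration_scale must be positive")
        if not self.archetypes:
            raise ConfigError("need at least one archetype")
        if self.session_length_s is not None:
            worst = self.duration_scale * sum(
                a.duration_s + 2 * a.duration_jitter_s + self.transition_s[1]
                for a in self.archetypes
            )
            if worst > self.session_length_s:
                raise ConfigError(
                    f"archetypes may need up to {worst:.0f} s but session_length_s "
                    f"is {self.session_length_s:.0f} s"
                )


def ground_truth(config: SessionConfig) -> list[str]:
    """Designed risk ordering of groups, riskiest tier first.

    Groups are listed high tier first, then medium, then low, preserving
    archetype order within a tier.  If every archetype shares one tier
    there is no designed ordering and the list is empty.  The ordering
    depends only on the configuration, never on the seed.
    """
    tiers = {a.group: a.target_risk_tier for a in config.archetypes}
    if len(set(tiers.values())) == 1:
        return []
    rank = {"high": 0, "medium": 1, "low": 2}
    return sorted(tiers, key=lambda g: rank[tiers[g]])


def _sided(base: str) -> list[str]:
    """Expand a base channel name to its concrete column names."""
    if f"{base}_r" in CHANNELS:
        return [f"{base}_r", f"{base}_l"]
    return [base]


def _synth_block(
    rng: np.random.Generator,
    arch_motion,
    n: int,
    fs: float,
    offsets: Mapping[str, float],
) -> dict[str, np.ndarray]:
    t = np.arange(n) / fs
    cols: dict[str, np.ndarray] = {}
    for base in BASE_POSTURE:
        m = arch_motion(base)
        for col in _sided(base):
            phase = rng.uniform(0, 2 * np.pi)
            series = (
                m.mean
                + offsets.get(col, 0.0)
                + m.drift_amp * np.sin(2 * np.pi * t / m.drift_period_s + phase)
                + rng.normal(0.0, m.sd, size=n)
            )
            cols[col] = np.clip(series, -180.0, 180.0)
    return cols


def generate_participant(
    config: SessionConfig, participant_index: int
) -> tuple[KinematicsRecord, list[SubtaskAnnotation], list[LoadEvent]]:
    """Generate one complete session (angles, annotations, load events).

    Archetype intervals are concatenated in randomised order, separated
    by brief unassigned transitions at the neutral working posture.
    Participant-level Gaussian channel offsets — one draw per channel per
    archetype per participant, i.e. each worker's own way of holding each
    subtask — create between-subject variability in every subtask's
    posture.  Output times are on the kinematics clock starting at 0.
    """
    if not 0 <= participant_index < config.n_participants:
        raise ConfigError(
            f"participant_index {participant_index} outside 0..{config.n_participants - 1}"
        )
    master = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(master.spawn(config.n_participants)[participant_index])
    fs = config.sample_rate_hz
    scale = config.duration_scale
    def draw_offsets() -> dict[str, float]:
        return {
            col: rng.normal(0.0, config.participant_offset_sd_deg)
            for base in BASE_POSTURE
            for col in _sided(base)
        }

    order = rng.permutation(len(config.archetypes))

    blocks: list[dict[str, np.ndarray]] = []
    annotations: list[SubtaskAnnotation] = []
    loads: list[LoadEvent] = []
    t_cursor = 0.0

    def emit(arch_motion, duration: float, offsets: Mapping[str, float]) -> int:
        n = max(1, int(round(duration * fs)))
        blocks.append(_synth_block(rng, arch_motion, n, fs, offsets))
        return n

    base_motion = lambda ch: BASE_POSTURE[ch]  # noqa: E731 - tiny closure
    no_offsets: dict[str, float] = {}
    for idx in order:
        arch = config.archetypes[idx]
        gap = scale * rng.uniform(*config.transition_s)
        t_cursor += emit(base_motion, gap, no_offsets) / fs
        dur = scale * max(
            1.0 / fs, rng.normal(arch.duration_s, arch.duration_jitter_s)
        )
        n = emit(arch.motion, dur, draw_offsets())
        start, end = t_cursor, t_cursor + n / fs
        label = rng.choice(GROUPS[arch.group])
        annotations.append(SubtaskAnnotation(start_s=start, end_s=end, label=str(label)))
        if arch.load is not None:
            frac = float(np.clip(
                rng.normal(arch.load.fraction, arch.load.fraction_jitter), 0.05, 0.95,
            ))
            span = frac * (end - start)
            l_start = start + rng.uniform(0.0, (end - start) - span)
            loads.append(LoadEvent(
                start_s=l_start, end_s=l_start + span, mass_kg=arch.load.mass_kg,
                static_or_repeated=arch.load.static_or_repeated,
                shock_or_rapid_buildup=arch.load.shock_or_rapid_buildup,
            ))
        t_cursor = end
    # trailing unassigned tail, padding to session_length_s when requested
    tail = scale * rng.uniform(*config.transition_s)
    if config.session_length_s is not None:
        tail = max(tail, config.session_length_s - t_cursor)
    emit(base_motion, tail, no_offsets)

    data = pd.DataFrame({
        col: np.concatenate([b[col] for b in blocks]) for col in CHANNELS
    })
    record = KinematicsRecord(
        participant_id=f"P{participant_index + 1:02d}",
        sample_rate_hz=fs,
        data=data,
    )
    annotations.sort()
    loads.sort()
    return record, annotations, loads


def generate_study(config: SessionConfig, out_dir: str | Path) -> list[Path]:
    """Write a complete study to disk: one folder per participant with
    ``kinematics.csv``, ``annotations.csv``, ``load_events.csv``, plus a
    study-level ``manifest.json``.  Per-participant randomness derives
    reproducibly from the master seed, so a fixed seed yields
    byte-identical files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    folders = []
    for i in range(config.n_participants):
        record, anns, loads = generate_participant(config, i)
        folder = out_dir / record.participant_id
        folder.mkdir(exist_ok=True)
        write_kinematics(record, folder / "kinematics.csv")
        write_annotations(anns, folder / "annotations.csv")
        write_load_events(loads, folder / "load_events.csv")
        folders.append(folder)
    manifest = {
        "n_participants": config.n_participants,
        "sample_rate_hz": config.sample_rate_hz,
        "duration_scale": config.duration_scale,
        "seed": config.seed,
        "designed_risk_ordering": ground_truth(config),
        "participants": [f.name for f in folders],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return folders
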