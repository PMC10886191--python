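"""End-to-end pipeline: load (or reuse) a study, score every session,
segment, extract features, run group statistics, and write report tables.

Report bundle written to the output directory:

* ``frame_scores/<participant>.csv`` — per-frame scores (optional),
* ``local_scores_session.csv`` — session-level local-score means across
  participants (anatomical-area table),
* ``band_occupancy_session.csv`` — session grand-score band occupancy and
  per-area time-at-risk, across participants,
* ``subtask_global_scores.csv`` — per-subtask global and local means,
* ``subtask_band_occupancy.csv`` — per-subtask band occupancy,
* ``subtask_time_at_risk.csv`` — per-subtask time at a risky level,
* ``stats_omnibus.csv``, ``stats_pairwise_right.csv``,
  ``stats_pairwise_left.csv``, ``stats_sig_counts.csv`` — Friedman
  omnibus per side, pairwise signed-rank p matrices, and per-group
  significance counts,
* ``run_manifest.json`` — configuration, seeds and package version.

Any stage failure aborts with a stage-named error and non-zero exit when
run through the CLI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
import numpy as np

from .group_stats import (
    GroupStatsResult,
    friedman_test,
    score_matrix_from_means,
    wilcoxon_posthoc,
)
from .io_formats import (
    read_annotations,
    read_kinematics,
    read_load_events,
    synchronize,
)
from .rula_engine import DEFAULT_ADJUSTMENTS, RulaDefaults, ScoringAdjustments, score_session
from .segmentation_features import (
    RiskThresholds,
    compute_features,
    segment_scores,
    summarize_participants,
)
from .taxonomy import SESSION, UNASSIGNED

logger = logging.getLogger(__name__)

#: grand-score band -> action recommendation
INTERPRETATIONS: dict[str, str] = {
    "1-2": "acceptable posture",
    "3-4": "further investigation, change may be needed",
    "5-6": "further investigation, change soon",
    "7": "investigate and implement change",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def interpret_band(grand: int) -> str:
    """Action recommendation for a grand score 1-7."""
    if not (isinstance(grand, (int, np.integer)) and 1 <= grand <= 7):
        raise ValueError(f"grand score must be an integer in 1..7, got {grand!r}")
    if grand <= 2:
        return INTERPRETATIONS["1-2"]
    if grand <= 4:
        return INTERPRETATIONS["3-4"]
    if grand <= 6:
        return INTERPRETATIONS["5-6"]
    return INTERPRETATIONS["7"]


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs, file-backed via YAML."""

    study_dir: Path
    out_dir: Path
    sample_rate_hz: float = 60.0
    defaults: RulaDefaults = RulaDefaults()
    adjustments: ScoringAdjustments = DEFAULT_ADJUSTMENTS
    thresholds: RiskThresholds = RiskThresholds()
    alpha: float = 0.05
    holm: bool = False
    clap_annotation_s: tuple[float, float] | None = None
    clap_kinematic_s: tuple[float, float] | None = None
    write_frame_scores: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "study_dir", Path(self.study_dir))
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load config from YAML with keys ``paths.study_dir``,
        ``paths.out_dir``, ``io.sample_rate_hz``, ``rula.defaults.*``,
        ``rula.adjustments.*``, ``features.thresholds.*``,
        ``stats.alpha``, ``stats.holm``, ``sync.clap_*``."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        paths = raw.get("paths", {})
        kw: dict = {}
        if "study_dir" in paths:
            kw["study_dir"] = paths["study_dir"]
        if "out_dir" in paths:
            kw["out_dir"] = paths["out_dir"]
        if "sample_rate_hz" in raw.get("io", {}):
            kw["sample_rate_hz"] = raw["io"]["sample_rate_hz"]
        rula = raw.get("rula", {})
        if rula.get("defaults"):
            kw["defaults"] = RulaDefaults(**rula["defaults"])
        if rula.get("adjustments"):
            kw["adjustments"] = ScoringAdjustments(**rula["adjustments"])
        if raw.get("features", {}).get("thresholds"):
            kw["thresholds"] = RiskThresholds(**raw["features"]["thresholds"])
        stats_cfg = raw.get("stats", {})
        for key in ("alpha", "holm"):
            if key in stats_cfg:
                kw[key] = stats_cfg[key]
        sync = raw.get("sync", {})
        for key in ("clap_annotation_s", "clap_kinematic_s"):
            if key in sync:
                kw[key] = tuple(sync[key])
        kw.update(overrides)
        return cls(**kw)


#: report files a complete run always writes (besides optional frame scores)
REPORT_FILES: tuple[str, ...] = (
    "local_scores_session.csv",
    "band_occupancy_session.csv",
    "subtask_global_scores.csv",
    "subtask_band_occupancy.csv",
    "subtask_time_at_risk.csv",
    "stats_omnibus.csv",
    "stats_sig_counts.csv",
)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("score")
def _score_study(config: PipelineConfig):
    folders = sorted(p for p in config.study_dir.iterdir() if p.is_dir())
    if not folders:
        raise FileNotFoundError(f"no participant folders under {config.study_dir}")
    sessions = []
    for folder in folders:
        record = read_kinematics(
            folder / "kinematics.csv", config.sample_rate_hz, participant_id=folder.name
        )
        anns = read_annotations(folder / "annotations.csv")
        if config.clap_annotation_s and config.clap_kinematic_s:
            anns = synchronize(anns, config.clap_annotation_s, config.clap_kinematic_s)
        loads = read_load_events(folder / "load_events.csv")
        scores = score_session(record, loads, config.defaults, config.adjustments)
        logger.info(
            "%s: scored %d frames (%d dropped)", folder.name, len(scores), scores.n_dropped
        )
        sessions.append((folder.name, scores, anns))
    return sessions


@_stage("features")
def _extract_features(config: PipelineConfig, sessions):
    per_participant = []
    for name, scores, anns in sessions:
        segments = segment_scores(scores, anns)
        feats = {SESSION: compute_features(scores, config.thresholds, group=SESSION)}
        for group, seg in segments.items():
            if len(seg):
                feats[group] = compute_features(seg, config.thresholds, group=group)
        per_participant.append(feats)
    return per_participant


@_stage("stats")
def _run_stats(config: PipelineConfig, per_participant, participant_ids) -> dict[str, GroupStatsResult]:
    results = {}
    for side in ("right", "left"):
        rows = []
        for pid, feats in zip(participant_ids, per_participant):
            for group, sides in feats.items():
                if group in (SESSION, UNASSIGNED):
                    continue
                rows.append({
                    "participant": pid, "group": group,
                    "value": sides[side].mean_global,
                })
        matrix = score_matrix_from_means(pd.DataFrame(rows))
        fr = friedman_test(matrix)
        if fr.p_value < config.alpha:
            results[side] = wilcoxon_posthoc(matrix, alpha=config.alpha, holm=config.holm)
        else:
            # post hocs are only run after a significant omnibus; report
            # the omnibus with an empty pairwise surface
            logger.info(
                "%s side: Friedman omnibus not significant (p = %.4g); "
                "skipping pairwise post hocs", side, fr.p_value,
            )
            k = matrix.k
            empty = pd.DataFrame(
                np.full((k, k), np.nan),
                index=list(matrix.group_labels), columns=list(matrix.group_labels),
            )
            results[side] = GroupStatsResult(
                chi2=fr.chi2, df=fr.df, p_value=fr.p_value,
                pairwise_p=empty, degenerate=empty.isna() & False,
                alpha=config.alpha,
                sig_counts=pd.Series(0, index=list(matrix.group_labels), name="sig_count"),
            )
    return results


def _wide(summary: pd.DataFrame, stats_prefixes: tuple[str, ...], groups=None) -> pd.DataFrame:
    sel = summary[summary["stat"].str.startswith(stats_prefixes)]
    if groups is not None:
        sel = sel[sel["group"].isin(groups)]
    wide = sel.pivot_table(
        index="group", columns=["stat", "side"], values=["mean", "sd"], sort=False
    )
    wide.columns = [f"{stat}_{side}_{agg}" for agg, stat, side in wide.columns]
    return wide.sort_index(axis=1)


@_stage("report")
def _write_reports(config: PipelineConfig, sessions, per_participant, stats) -> dict[str, Path]:
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if config.write_frame_scores:
        fs_dir = out / "frame_scores"
        fs_dir.mkdir(exist_ok=True)
        for name, scores, _ in sessions:
            path = fs_dir / f"{name}.csv"
            scores.frame.to_csv(path, index=False, float_format="%.6f")
            written[f"frame_scores/{name}"] = path

    summary = summarize_participants(per_participant)
    session_summary = summary[summary["group"] == SESSION]
    subtask_groups = [
        g for g in summary["group"].unique() if g not in (SESSION, UNASSIGNED)
    ]

    tables = {
        "local_scores_session.csv": _wide(session_summary, ("mean_local",)),
        "band_occupancy_session.csv": _wide(session_summary, ("pct_range", "pct_at_risk")),
        "subtask_global_scores.csv": _wide(summary, ("mean_global", "mean_local"), subtask_groups),
        "subtask_band_occupancy.csv": _wide(summary, ("pct_range",), subtask_groups),
        "subtask_time_at_risk.csv": _wide(summary, ("pct_at_risk",), subtask_groups),
    }
    omnibus = pd.DataFrame(
        [
            {"side": side, "chi2": r.chi2, "df": r.df, "p_value": r.p_value, "alpha": r.alpha}
            for side, r in stats.items()
        ]
    )
    sig = pd.DataFrame({side: r.sig_counts for side, r in stats.items()})
    sig.index.name = "group"
    tables["stats_omnibus.csv"] = omnibus.set_index("side")
    tables["stats_sig_counts.csv"] = sig
    for side, r in stats.items():
        tables[f"stats_pairwise_{side}.csv"] = r.pairwise_p

    for name, df in tables.items():
        path = out / name
        df.to_csv(path, float_format="%.6f")
        written[name] = path

    manifest = {
        "version": __version__,
        "config": {
            "study_dir": str(config.study_dir),
            "out_dir": str(config.out_dir),
            "sample_rate_hz": config.sample_rate_hz,
            "defaults": dataclasses.asdict(config.defaults),
            "adjustments": dataclasses.asdict(config.adjustments),
            "thresholds": dataclasses.asdict(config.thresholds),
            "alpha": config.alpha,
            "holm": config.holm,
        },
        "participants": [name for name, _, _ in sessions],
        "frames_scored": {name: len(s) for name, s, _ in sessions},
        "frames_dropped": {name: s.n_dropped for name, s, _ in sessions},
    }
    path = out / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["run_manifest.json"] = path
    return written


def run_pipeline(config: PipelineConfig) -> Mapping[str, object]:
    """Run score -> segment -> features -> stats -> report on a study.

    Returns the report bundle: written paths plus the in-memory summary
    frame and per-side statistics.
    """
    if not config.study_dir.is_dir():
        raise PipelineError(f"stage 'load' failed: study dir {config.study_dir} not found")
    sessions = _score_study(config)
    per_participant = _extract_features(config, sessions)
    stats = _run_stats(config, per_participant, [name for name, _, _ in sessions])
    written = _write_reports(config, sessions, per_participant, stats)
    return {
        "written": written,
        "summary": summarize_participants(per_participant),
        "stats": stats,
        "per_participant": per_participant,
    }
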