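"""Segmentation, exposure features and cross-participant summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergorula.io_formats import SubtaskAnnotation
from ergorula.rula_engine import SCORE_COLUMNS, SessionScores, score_session
from ergorula.segmentation_features import (
    BANDS,
    EmptySegmentError,
    RiskThresholds,
    compute_features,
    segment_scores,
    summarize_participants,
)
from ergorula.taxonomy import UNASSIGNED

from .conftest import make_record


def synthetic_scores(
    grand_r, grand_l=None, upper=1, lower=1, wrist_posture=1, wrist_twist=1,
    neck=1, trunk=1, fs=60.0,
) -> SessionScores:
    """Hand-built SessionScores with prescribed score columns (synthetic
    stand-in for engine output; only the columns features read matter)."""
    grand_r = np.asarray(grand_r)
    grand_l = grand_r if grand_l is None else np.asarray(grand_l)
    n = len(grand_r)

    def col(v):
        return np.broadcast_to(np.asarray(v), (n,)).astype(int)

    frame = pd.DataFrame({
        "t_s": np.arange(n) / fs,
        "upper_arm_r": col(upper), "upper_arm_l": col(upper),
        "lower_arm_r": col(lower), "lower_arm_l": col(lower),
        "wrist_posture_r": col(wrist_posture), "wrist_posture_l": col(wrist_posture),
        "wrist_twist_r": col(wrist_twist), "wrist_twist_l": col(wrist_twist),
        "wrist_hand_r": col(wrist_posture) + col(wrist_twist),
        "wrist_hand_l": col(wrist_posture) + col(wrist_twist),
        "neck": col(neck), "trunk": col(trunk), "legs": col(1),
        "posture_a_r": col(1), "posture_a_l": col(1), "posture_b": col(1),
        "muscle_use": col(0), "force_load": col(0),
        "score_c_r": col(1), "score_c_l": col(1), "score_d": col(1),
        "grand_r": grand_r.astype(int), "grand_l": grand_l.astype(int),
    }, columns=list(SCORE_COLUMNS))
    return SessionScores(frame)


class TestSegmentScores:
    def test_one_second_annotation_holds_60_frames(self):
        scores = score_session(make_record(120))
        segs = segment_scores(
            scores, [SubtaskAnnotation(start_s=0.0, end_s=1.0, label="Floor cleaning")]
        )
        assert len(segs["Floor cleaning"]) == 60
        assert len(segs[UNASSIGNED]) == 60

    def test_subtasks_pool_into_their_group(self):
        scores = score_session(make_record(120))
        segs = segment_scores(scores, [
            SubtaskAnnotation(start_s=0.0, end_s=0.5, label="Waste pickup"),
            SubtaskAnnotation(start_s=1.0, end_s=1.5, label="Garbage disposal"),
        ])
        assert len(segs["Waste disposal"]) == 60

    def test_no_annotations_all_unassigned(self):
        scores = score_session(make_record(30))
        segs = segment_scores(scores, [])
        assert set(segs) == {UNASSIGNED}
        assert len(segs[UNASSIGNED]) == 30

    def test_annotation_beyond_span_truncates_with_warning(self, caplog):
        scores = score_session(make_record(60))
        with caplog.at_level("WARNING"):
            segs = segment_scores(
                scores,
                [SubtaskAnnotation(start_s=0.5, end_s=5.0, label="Box lifting")],
            )
        assert "truncated" in caplog.text
        assert len(segs["Box lifting"]) == 30  # frames in [0.5, 1.0)

    def test_frame_conservation(self, rng):
        scores = score_session(make_record(600))
        anns = [
            SubtaskAnnotation(start_s=1.0, end_s=3.5, label="Floor cleaning"),
            SubtaskAnnotation(start_s=4.0, end_s=7.25, label="Patient transfer"),
        ]
        segs = segment_scores(scores, anns)
        assert sum(len(s) for s in segs.values()) == len(scores)


class TestComputeFeatures:
    def test_all_frames_in_top_band(self):
        feats = compute_features(synthetic_scores(np.full(50, 7)))
        assert feats["right"].pct_range == {"1-2": 0.0, "3-4": 0.0, "5-6": 0.0, "7": 100.0}

    def test_half_three_half_five(self):
        feats = compute_features(synthetic_scores(np.array([3] * 25 + [5] * 25)))
        r = feats["right"]
        assert r.mean_global == pytest.approx(4.0)
        assert r.pct_range["3-4"] == pytest.approx(50.0)
        assert r.pct_range["5-6"] == pytest.approx(50.0)

    def test_empty_segment_is_explicit_error(self):
        with pytest.raises(EmptySegmentError):
            compute_features(synthetic_scores(np.array([], dtype=int)))

    def test_threshold_at_minimum_gives_100(self):
        thr = RiskThresholds(shoulder_upper_arm=1, elbow_lower_arm=1,
                             wrist_hand=2, neck_head=1, pelvis_trunk=1)
        feats = compute_features(synthetic_scores(np.full(10, 3)), thr)
        for side in ("right", "left", "central"):
            assert all(v == 100.0 for v in feats[side].pct_at_risk.values())

    def test_threshold_above_maximum_gives_0(self):
        thr = RiskThresholds(shoulder_upper_arm=6, elbow_lower_arm=3,
                             wrist_hand=6, neck_head=6, pelvis_trunk=6)
        feats = compute_features(synthetic_scores(np.full(10, 3)), thr)
        for side in ("right", "left", "central"):
            assert all(v == 0.0 for v in feats[side].pct_at_risk.values())

    def test_risk_threshold_is_inclusive(self):
        feats = compute_features(synthetic_scores(np.full(10, 3), lower=2))
        assert feats["right"].pct_at_risk["elbow_lower_arm"] == 100.0

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            RiskThresholds(elbow_lower_arm=4)

    @given(st.lists(st.integers(1, 7), min_size=1, max_size=300))
    @settings(max_examples=100, derandomize=True)
    def test_band_occupancies_partition_scored_time(self, grands):
        feats = compute_features(synthetic_scores(np.array(grands)))
        for side in ("right", "left"):
            pct = feats[side].pct_range
            assert sum(pct.values()) == pytest.approx(100.0, abs=1e-6)
            assert all(0.0 <= v <= 100.0 for v in pct.values())

    @given(st.lists(st.integers(1, 7), min_size=1, max_size=200))
    @settings(max_examples=100, derandomize=True)
    def test_risky_band_aggregation_identity(self, grands):
        """pct(5-6) + pct(7) equals the share of frames with grand >= 5."""
        g = np.array(grands)
        feats = compute_features(synthetic_scores(g))
        r = feats["right"]
        assert r.pct_range["5-6"] + r.pct_range["7"] == pytest.approx(
            100.0 * np.mean(g >= 5), abs=1e-9
        )

    def test_matches_naive_per_frame_recount(self, rng):
        """Exact agreement with a brute-force per-frame recount."""
        n = 1000
        scores = synthetic_scores(
            rng.integers(1, 8, n),
            grand_l=rng.integers(1, 8, n),
            upper=rng.integers(1, 7, n),
            lower=rng.integers(1, 4, n),
            wrist_posture=rng.integers(1, 5, n),
            wrist_twist=rng.integers(1, 3, n),
            neck=rng.integers(1, 7, n),
            trunk=rng.integers(1, 7, n),
        )
        thr = RiskThresholds()
        feats = compute_features(scores, thr)
        # naive recount, one frame at a time
        counts = {band: 0 for band in BANDS}
        risky_upper = risky_lower = risky_wrist = 0
        grand_sum = 0
        for fs in scores:
            grand_sum += fs.grand_r
            for band, (lo, hi) in BANDS.items():
                if lo <= fs.grand_r <= hi:
                    counts[band] += 1
            risky_upper += fs.locals.upper_arm_r >= thr.shoulder_upper_arm
            risky_lower += fs.locals.lower_arm_r >= thr.elbow_lower_arm
            risky_wrist += fs.locals.wrist_hand_r >= thr.wrist_hand
        r = feats["right"]
        assert r.mean_global == pytest.approx(grand_sum / n)
        for band in BANDS:
            assert r.pct_range[band] == pytest.approx(100.0 * counts[band] / n)
        assert r.pct_at_risk["shoulder_upper_arm"] == pytest.approx(100.0 * risky_upper / n)
        assert r.pct_at_risk["elbow_lower_arm"] == pytest.approx(100.0 * risky_lower / n)
        assert r.pct_at_risk["wrist_hand"] == pytest.approx(100.0 * risky_wrist / n)


class TestSummarizeParticipants:
    def _features(self, grand_value, n=20):
        return {"Floor cleaning": compute_features(
            synthetic_scores(np.full(n, grand_value)), group="Floor cleaning"
        )}

    def test_single_participant_sd_zero(self):
        out = summarize_participants([self._features(3)])
        row = out[(out.group == "Floor cleaning") & (out.side == "right")
                  & (out.stat == "mean_global")].iloc[0]
        assert row["mean"] == pytest.approx(3.0)
        assert row["sd"] == 0.0
        assert row["n_participants"] == 1

    def test_two_participants_average_equally(self):
        out = summarize_participants([self._features(3), self._features(5)])
        row = out[(out.group == "Floor cleaning") & (out.side == "right")
                  & (out.stat == "mean_global")].iloc[0]
        assert row["mean"] == pytest.approx(4.0)
        assert row["sd"] == pytest.approx(np.std([3, 5], ddof=1))

    def test_unequal_segment_lengths_weigh_equally(self):
        out = summarize_participants(
            [self._features(3, n=1000), self._features(5, n=10)]
        )
        row = out[(out.stat == "mean_global") & (out.side == "left")].iloc[0]
        assert row["mean"] == pytest.approx(4.0)

    def test_participant_order_irrelevant(self):
        a = [self._features(3), self._features(5), self._features(6)]
        out1 = summarize_participants(a)
        out2 = summarize_participants(list(reversed(a)))
        pd.testing.assert_frame_equal(
            out1.sort_values(["group", "side", "stat"]).reset_index(drop=True),
            out2.sort_values(["group", "side", "stat"]).reset_index(drop=True),
        )
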