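"""RULA scoring: local bins, look-up tables, adders and frame composition."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergorula.io_formats import CHANNELS, LoadEvent
from ergorula.rula_engine import (
    DomainError,
    RulaDefaults,
    ScoringAdjustments,
    force_load_score,
    force_load_series,
    muscle_use_score,
    score_frame,
    score_legs,
    score_lower_arm,
    score_neck,
    score_session,
    score_trunk,
    score_upper_arm,
    score_wrist,
    score_wrist_twist,
    table_a,
    table_b,
    table_c,
)

from .conftest import make_record, neutral_angles, random_record

angles = st.floats(-180, 180, allow_nan=False)


class TestLocalScorers:
    @pytest.mark.parametrize(
        "flexion,raised,abducted,supported,expected",
        [
            (0, False, False, False, 1),
            (100, True, False, False, 5),
            (30, False, False, True, 1),
            (-30, False, False, False, 2),
            (20, False, False, False, 2),   # boundary takes the higher bin
            (45, False, False, False, 3),
            (90, False, False, False, 4),
            (120, True, True, False, 6),
        ],
    )
    def test_upper_arm(self, flexion, raised, abducted, supported, expected):
        assert score_upper_arm(flexion, raised, abducted, supported) == expected

    @pytest.mark.parametrize(
        "flexion,across,expected",
        [(80, False, 1), (30, True, 3), (60, False, 1), (100, False, 2), (110, True, 3)],
    )
    def test_lower_arm(self, flexion, across, expected):
        assert score_lower_arm(flexion, across) == expected

    @pytest.mark.parametrize(
        "flexion,deviation,expected",
        [(0, 0, 1), (20, 0, 3), (10, 20, 3), (-20, 0, 3), (15, 0, 2), (25, 25, 4)],
    )
    def test_wrist(self, flexion, deviation, expected):
        assert score_wrist(flexion, deviation) == expected

    @pytest.mark.parametrize("prono,expected", [(0, 1), (80, 2), (-80, 2), (30, 1)])
    def test_wrist_twist(self, prono, expected):
        assert score_wrist_twist(prono) == expected

    @pytest.mark.parametrize(
        "flexion,rotation,inclination,expected",
        [(5, 0, 0, 1), (25, 30, 0, 4), (-10, 0, 0, 4), (15, 0, 0, 2), (25, 30, 30, 5)],
    )
    def test_neck(self, flexion, rotation, inclination, expected):
        assert score_neck(flexion, rotation, inclination) == expected

    @pytest.mark.parametrize(
        "flexion,rotation,inclination,expected",
        [(0, 0, 0, 1), (30, 0, 25, 4), (70, 30, 30, 6), (10, 0, 0, 2), (-30, 0, 0, 3)],
    )
    def test_trunk(self, flexion, rotation, inclination, expected):
        assert score_trunk(flexion, rotation, inclination) == expected

    def test_legs(self):
        assert score_legs(True) == 1
        assert score_legs(False) == 2

    @given(f=angles, r=angles, i=angles)
    @settings(max_examples=200, derandomize=True)
    def test_local_ranges_on_random_angles(self, f, r, i):
        assert 1 <= score_upper_arm(f, True, True, False) <= 6
        assert 1 <= score_lower_arm(f, True) <= 3
        assert 1 <= score_wrist(f, r) <= 4
        assert 1 <= score_wrist_twist(f) <= 2
        assert 1 <= score_neck(f, r, i) <= 6
        assert 1 <= score_trunk(f, r, i) <= 6


class TestAdders:
    def test_muscle_use(self):
        assert muscle_use_score(False) == 0
        assert muscle_use_score(True) == 1
        assert muscle_use_score(RulaDefaults().posture_static_or_repeated) == 0

    @pytest.mark.parametrize(
        "events,expected",
        [
            ([], 0),
            ([LoadEvent(0, 1, 1.0)], 0),
            ([LoadEvent(0, 1, 5.0)], 1),
            ([LoadEvent(0, 1, 2.0)], 1),
            ([LoadEvent(0, 1, 5.0, static_or_repeated=True)], 2),
            ([LoadEvent(0, 1, 12.0)], 3),
            ([LoadEvent(0, 1, 1.0, shock_or_rapid_buildup=True)], 3),
            ([LoadEvent(0, 1, 5.0), LoadEvent(0, 1, 12.0)], 3),
        ],
    )
    def test_force_load_bands(self, events, expected):
        assert force_load_score(events) == expected

    def test_force_load_series_matches_scalar(self):
        loads = [
            LoadEvent(1.0, 2.0, 5.0),
            LoadEvent(1.5, 3.0, 12.0),
            LoadEvent(4.0, 5.0, 3.0, static_or_repeated=True),
        ]
        t = np.arange(0, 6, 0.25)
        series = force_load_series(t, loads)
        scalar = [
            force_load_score([e for e in loads if e.start_s <= ti < e.end_s]) for ti in t
        ]
        assert series.tolist() == scalar


class TestTables:
    def test_table_a_extremes(self):
        assert table_a(1, 1, 1, 1) == 1
        assert table_a(6, 3, 4, 2) == 9

    def test_table_b_extremes(self):
        assert table_b(1, 1, 1) == 1
        assert table_b(6, 6, 2) == 9

    def test_table_c_extremes_and_saturation(self):
        assert table_c(1, 1) == 1
        assert table_c(8, 7) == 7
        assert table_c(12, 12) == 7

    @pytest.mark.parametrize(
        "fn,args",
        [
            (table_a, (1, 1, 1, 3)),
            (table_a, (0, 1, 1, 1)),
            (table_b, (0, 1, 1)),
            (table_b, (1, 7, 1)),
            (table_c, (0, 1)),
            (table_c, (1, 1.5)),
        ],
    )
    def test_out_of_range_is_domain_error(self, fn, args):
        with pytest.raises(DomainError):
            fn(*args)

    def test_table_a_monotone_in_every_argument(self):
        for u, l, w, t in itertools.product(range(1, 7), range(1, 4), range(1, 5), range(1, 3)):
            here = table_a(u, l, w, t)
            assert 1 <= here <= 9
            if u < 6:
                assert table_a(u + 1, l, w, t) >= here
            if l < 3:
                assert table_a(u, l + 1, w, t) >= here
            if w < 4:
                assert table_a(u, l, w + 1, t) >= here
            if t < 2:
                assert table_a(u, l, w, t + 1) >= here

    def test_table_b_monotone_in_every_argument(self):
        for n, t, g in itertools.product(range(1, 7), range(1, 7), range(1, 3)):
            here = table_b(n, t, g)
            assert 1 <= here <= 9
            if n < 6:
                assert table_b(n + 1, t, g) >= here
            if t < 6:
                assert table_b(n, t + 1, g) >= here
            if g < 2:
                assert table_b(n, t, g + 1) >= here

    def test_table_c_monotone_and_saturating(self):
        for c, d in itertools.product(range(1, 13), range(1, 13)):
            here = table_c(c, d)
            assert 1 <= here <= 7
            assert table_c(c + 1, d) >= here
            assert table_c(c, d + 1) >= here
        assert table_c(100, 100) == 7


class TestScoreFrame:
    def test_neutral_frame_scores_one(self, neutral_frame):
        fs = score_frame(neutral_frame)
        assert fs.grand_r == fs.grand_l == 1
        assert fs.posture_a_r == fs.posture_a_l == 1
        assert fs.posture_b == 1

    def test_saturated_frame_with_heavy_load(self):
        worst = {c: 180.0 for c in CHANNELS}
        worst["head_flexion"] = -45.0  # extension is the worst neck base
        fs = score_frame(
            worst,
            loads=[LoadEvent(0, 1, 12.0)],
            defaults=RulaDefaults(shoulders_raised=True, legs_supported=False),
            adjustments=ScoringAdjustments(abduction_from_rotation=True),
            t_s=0.5,
        )
        assert fs.grand_r == fs.grand_l == 7
        assert fs.locals.upper_arm_r == 6
        assert fs.posture_a_r == fs.posture_a_l == 9

    def test_one_sided_elevation_raises_that_side_only(self, neutral_frame):
        neutral_frame["upper_arm_flexion_r"] = 100.0
        fs = score_frame(neutral_frame)
        assert fs.grand_r > fs.grand_l
        assert fs.grand_l == 1

    def test_missing_channel_rejected(self, neutral_frame):
        del neutral_frame["trunk_rotation"]
        with pytest.raises(ValueError, match="trunk_rotation"):
            score_frame(neutral_frame)

    @given(st.data())
    @settings(max_examples=100, derandomize=True)
    def test_mirroring_sides_swaps_grand_scores(self, data):
        frame = {c: data.draw(angles, label=c) for c in CHANNELS}
        mirrored = dict(frame)
        for c in CHANNELS:
            if c.endswith("_r"):
                mirrored[c] = frame[c[:-2] + "_l"]
                mirrored[c[:-2] + "_l"] = frame[c]
        a, b = score_frame(frame), score_frame(mirrored)
        assert (a.grand_r, a.grand_l) == (b.grand_l, b.grand_r)

    @given(st.data())
    @settings(max_examples=100, derandomize=True)
    def test_grand_in_range_and_deterministic(self, data):
        frame = {c: data.draw(angles, label=c) for c in CHANNELS}
        a, b = score_frame(frame), score_frame(frame)
        assert 1 <= a.grand_r <= 7 and 1 <= a.grand_l <= 7
        assert a == b

    def test_wrist_hand_combined_range(self, neutral_frame):
        fs = score_frame(neutral_frame)
        assert fs.locals.wrist_hand_r == 2
        neutral_frame["wrist_flexion_r"] = 30.0
        neutral_frame["wrist_deviation_r"] = 30.0
        neutral_frame["wrist_pronosupination_r"] = 90.0
        assert score_frame(neutral_frame).locals.wrist_hand_r == 6


@given(st.data())
@settings(max_examples=150, derandomize=True)
def test_grand_monotone_in_locals_and_adders(data):
    """Increasing any single local score or adder never lowers the grand."""
    u = data.draw(st.integers(1, 6))
    l = data.draw(st.integers(1, 3))
    w = data.draw(st.integers(1, 4))
    t = data.draw(st.integers(1, 2))
    n = data.draw(st.integers(1, 6))
    tr = data.draw(st.integers(1, 6))
    g = data.draw(st.integers(1, 2))
    add = data.draw(st.integers(0, 4))

    def grand(u=u, l=l, w=w, t=t, n=n, tr=tr, g=g, add=add):
        return table_c(table_a(u, l, w, t) + add, table_b(n, tr, g) + add)

    base = grand()
    for bump in (
        dict(u=min(u + 1, 6)), dict(l=min(l + 1, 3)), dict(w=min(w + 1, 4)),
        dict(t=min(t + 1, 2)), dict(n=min(n + 1, 6)), dict(tr=min(tr + 1, 6)),
        dict(g=min(g + 1, 2)), dict(add=add + 1),
    ):
        assert grand(**bump) >= base


class TestScoreSession:
    def test_clean_record_scores_every_frame(self):
        rec = make_record(120)
        scores = score_session(rec)
        assert len(scores) == 120
        assert scores.n_dropped == 0

    def test_missing_frames_are_dropped_and_counted(self):
        rec = make_record(120)
        data = rec.data.copy()
        data.loc[[3, 10, 50, 51, 99], "wrist_flexion_l"] = np.nan
        rec = type(rec)("P01", 60.0, data)
        scores = score_session(rec)
        assert len(scores) == 115
        assert scores.n_dropped == 5

    def test_empty_record_yields_empty_scores(self):
        scores = score_session(make_record(0))
        assert len(scores) == 0

    def test_vectorised_session_matches_per_frame_scoring(self, rng):
        rec = random_record(rng, 40)
        loads = [LoadEvent(0.2, 0.5, 12.0), LoadEvent(0.5, 0.6, 5.0)]
        scores = score_session(rec, loads)
        for i in [0, 7, 19, 39]:
            frame_angles = {c: float(rec.data.loc[i, c]) for c in CHANNELS}
            expected = score_frame(frame_angles, loads, t_s=float(rec.times[i]))
            assert scores[i] == expected

    def test_default_context_yields_legs_one_and_no_muscle_adder(self):
        scores = score_session(make_record(10))
        assert set(scores.frame["legs"]) == {1}
        assert set(scores.frame["muscle_use"]) == {0}
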