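"""Stroke segmentation, the 21 biomarkers, and their exact identities."""

import math

import numpy as np
import pytest

import graphomark as gm
from graphomark.biomarkers import EmptySessionError, count_within_stroke_pauses
from oracles import oracle_biomarkers, oracle_segment

NUMERIC = [c for c in gm.BIOMARKER_COLUMNS if c != "EFDB_1"]


class TestSegmentation:
    def test_two_stroke_decomposition(self, toy_session):
        seg = gm.segment_strokes(toy_session)
        assert seg.n_strokes == 2
        assert seg.initial_pause == pytest.approx(2.0)
        assert list(seg.inter_stroke_gaps) == pytest.approx([2.0])
        assert seg.total_time == pytest.approx(7.0)

    def test_single_stroke_at_origin(self):
        ses = gm.WritingSession.from_events(
            "s", [(0, 0, 0, "down"), (100, 5, 5, "up")])
        seg = gm.segment_strokes(ses)
        assert seg.initial_pause == 0.0
        assert seg.inter_stroke_gaps.size == 0

    def test_empty_session_raises(self):
        with pytest.raises(EmptySessionError):
            gm.segment_strokes(gm.WritingSession.from_events("e", []))

    def test_matches_event_scan_oracle(self, params):
        ses = gm.simulate_session(params, "MCI", seed=7)
        seg = gm.segment_strokes(ses)
        j, initial, gaps, total = oracle_segment(list(ses.events))
        assert seg.n_strokes == j
        assert seg.initial_pause == pytest.approx(initial)
        np.testing.assert_allclose(seg.inter_stroke_gaps, gaps, rtol=1e-12)
        assert seg.total_time == pytest.approx(total)

    def test_pause_decomposition_is_exact(self, mci_session):
        seg = gm.segment_strokes(mci_session)
        lhs = seg.total_time
        rhs = seg.initial_pause + seg.durations.sum() + \
            seg.inter_stroke_gaps.sum()
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestToyValues:
    def test_ipsdb_on_two_stroke_session(self, toy_session):
        b = gm.compute_ipsdb(gm.segment_strokes(toy_session))
        assert b["IPSDB_1"] == pytest.approx(7.0)
        assert b["IPSDB_2"] == pytest.approx(5.0)
        assert b["IPSDB_3"] == pytest.approx(3.0)
        assert b["IPSDB_4"] == pytest.approx(4.0)
        assert b["IPSDB_5"] == pytest.approx(2.0)
        assert b["IPSDB_6"] == pytest.approx(2.0)
        assert b["IPSDB_7"] == pytest.approx(2.0)
        assert b["IPSDB_8"] == pytest.approx(2.0)
        assert b["IPSDB_9"] == 0.0  # single gap: zero variance

    def test_efdb_direct_arithmetic(self):
        # strokes of length 100 px and 300 px, 1 s each, total time 10 s
        events = [
            (0, 0.0, 0.0, "down"), (1000, 100.0, 0.0, "up"),
            (8000, 0.0, 50.0, "down"), (9000, 300.0, 50.0, "up"),
        ]
        ses = gm.WritingSession.from_events("s", events)
        seg = gm.segment_strokes(ses)
        b = gm.compute_efdb(seg)
        assert b["EFDB_2"] == 2
        assert b["EFDB_3"] == pytest.approx(2 / 9.0 * 60)
        assert b["EFDB_5"] == pytest.approx(400.0)
        assert b["EFDB_6"] == pytest.approx(300.0)
        assert b["EFDB_7"] == pytest.approx(200.0)
        assert b["EFDB_9"] == pytest.approx(300.0)
        assert b["EFDB_10"] == pytest.approx(200.0)
        assert b["EFDB_11"] == pytest.approx(100.0 / 200.0)  # population SD
        assert b["EFDB_8"] == pytest.approx(100.0 / 200.0)

    def test_equal_gaps_zero_cv(self):
        events = []
        for k in range(4):  # strokes at 0-1, 2-3, 4-5, 6-7 s
            events += [(k * 2000, 0.0, 0.0, "down"),
                       (k * 2000 + 1000, 50.0, 0.0, "up")]
        b = gm.compute_ipsdb(gm.segment_strokes(
            gm.WritingSession.from_events("s", events)))
        assert b["IPSDB_9"] == 0.0

    def test_single_stroke_gap_stats_are_missing_not_zero(self):
        ses = gm.WritingSession.from_events(
            "s", [(0, 0, 0, "down"), (500, 9, 9, "up")])
        b = gm.compute_ipsdb(gm.segment_strokes(ses))
        assert math.isnan(b["IPSDB_7"])
        assert math.isnan(b["IPSDB_8"])
        assert math.isnan(b["IPSDB_9"])
        assert b["IPSDB_6"] == 0.0


class TestWithinStrokePauses:
    def test_one_duplicate_pair(self):
        ses = gm.WritingSession.from_events(
            "s", [(0, 5, 5, "down"), (16, 5, 5, "move"), (33, 6, 5, "up")])
        assert count_within_stroke_pauses(gm.segment_strokes(ses), 0) == 1

    def test_strictly_moving_stroke_counts_zero(self):
        ses = gm.WritingSession.from_events(
            "s", [(0, 5, 5, "down"), (16, 6, 5, "move"), (33, 7, 5, "up")])
        assert count_within_stroke_pauses(gm.segment_strokes(ses), 0) == 0

    def test_duration_threshold_filters_short_runs(self):
        # two runs: 32 ms (2 repeats) and 96 ms (3 repeats)
        pts = [(0, 1.0), (16, 1.0), (32, 1.0), (48, 2.0), (80, 3.0),
               (112, 3.0), (144, 3.0), (176, 3.0), (192, 4.0)]
        events = [(t, x, 0.0, "down" if i == 0 else
                   ("up" if i == len(pts) - 1 else "move"))
                  for i, (t, x) in enumerate(pts)]
        seg = gm.segment_strokes(gm.WritingSession.from_events("s", events))
        assert count_within_stroke_pauses(seg, 50) == 1
        assert count_within_stroke_pauses(seg, 0) == 5  # duplicate pairs

    def test_injected_runs_match_oracle_scan(self, params):
        for seed in range(10):
            ses = gm.simulate_session(params, "MCI", seed=seed)
            seg = gm.segment_strokes(ses)
            assert count_within_stroke_pauses(seg, 50) == \
                oracle_biomarkers(list(ses.events), 50)["IPSDB_10"]

    def test_negative_threshold_rejected(self, toy_session):
        with pytest.raises(ValueError):
            count_within_stroke_pauses(gm.segment_strokes(toy_session), -1)


class TestOracleEquivalence:
    def test_all_numeric_markers_match_event_scan(self, params):
        """Every kinematic biomarker equals an independent single-pass
        recomputation from raw events on random simulated sessions."""
        rng = np.random.SeedSequence(42).spawn(40)
        for i, ch in enumerate(rng):
            group = "MCI" if i % 2 else "HC"
            ses = gm.simulate_session(params, group, ch)
            ours = gm.extract_biomarkers(ses)
            ref = oracle_biomarkers(list(ses.events))
            for key, expected in ref.items():
                if math.isnan(expected):
                    assert math.isnan(ours[key])
                else:
                    assert ours[key] == pytest.approx(expected, rel=1e-9), key


class TestInvariants:
    def test_exact_identities_on_simulated_sessions(self, params):
        for seed in range(25):
            ses = gm.simulate_session(params, "HC" if seed % 2 else "MCI",
                                      seed=seed)
            b = gm.extract_biomarkers(ses)
            assert b["IPSDB_1"] == pytest.approx(b["IPSDB_5"] + b["IPSDB_2"],
                                                 rel=1e-12)
            assert b["IPSDB_4"] == pytest.approx(b["IPSDB_5"] + b["IPSDB_6"],
                                                 rel=1e-12)
            assert b["IPSDB_2"] == pytest.approx(b["IPSDB_3"] + b["IPSDB_6"],
                                                 rel=1e-12)
            assert b["EFDB_5"] == pytest.approx(b["EFDB_2"] * b["EFDB_7"],
                                                rel=1e-12)
            assert b["EFDB_6"] >= b["EFDB_7"]
            assert b["EFDB_9"] >= b["EFDB_10"]
            assert 0 < b["EFDB_4"] <= 1

    def test_time_shift_moves_only_pause_markers(self, mci_session):
        """Translating the stream by +c changes the initial pause (and the
        totals containing it) by exactly c and nothing else."""
        c = 1.5
        shifted = mci_session.shifted(1500)
        b0 = gm.extract_biomarkers(mci_session)
        b1 = gm.extract_biomarkers(shifted)
        affected = {"IPSDB_1", "IPSDB_2", "IPSDB_4", "IPSDB_5",
                    "EFDB_3", "EFDB_4"}
        assert b1["IPSDB_1"] == pytest.approx(b0["IPSDB_1"] + c)
        assert b1["IPSDB_4"] == pytest.approx(b0["IPSDB_4"] + c)
        assert b1["IPSDB_5"] == pytest.approx(b0["IPSDB_5"] + c)
        assert b1["IPSDB_2"] == pytest.approx(b0["IPSDB_2"])
        for key in NUMERIC:
            if key not in affected:
                assert b1[key] == pytest.approx(b0[key], rel=1e-9), key

    def test_spatial_isometry_preserves_lengths_and_speeds(self, hc_session):
        theta = 0.31
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        xy = np.column_stack([hc_session.x, hc_session.y]) @ rot.T
        xy -= xy.min(axis=0) - 5.0  # keep coordinates non-negative
        import dataclasses
        moved = dataclasses.replace(hc_session, x=xy[:, 0], y=xy[:, 1])
        b0 = gm.extract_biomarkers(hc_session)
        b1 = gm.extract_biomarkers(moved)
        for key in ("EFDB_5", "EFDB_6", "EFDB_7", "EFDB_8", "EFDB_9",
                    "EFDB_10", "EFDB_11", "IPSDB_3"):
            assert b1[key] == pytest.approx(b0[key], rel=1e-9), key


class TestTaskScore:
    def _perfect_session(self, params, n_chars=10):
        clean = params.model_copy(deep=True)
        for gp in (clean.mci, clean.hc):
            gp.stroke_merge_rate = 0.0
            gp.stroke_split_rate = 0.0
            gp.stroke_drop_rate = 0.0
            gp.order_scramble_rate = 0.0
            gp.char_count_error_rate = 0.0
        clean.n_chars = n_chars
        return gm.simulate_session(clean, "HC", seed=3)

    def test_perfect_performance_scores_two(self, params):
        ses = self._perfect_session(params)
        res = gm.score_task(gm.segment_strokes(ses))
        assert res.n_characters == 10
        assert (res.order_component, res.count_component) == (1, 1)
        assert res.score == 2

    def test_wrong_character_count_loses_count_point(self, params):
        ses = self._perfect_session(params, n_chars=9)
        res = gm.score_task(gm.segment_strokes(ses), task_char_count=10)
        assert res.n_characters == 9
        assert res.count_component == 0
        assert res.order_component == 1
        assert res.score == 1

    def test_scrambled_order_loses_order_point(self, params):
        scrambled = params.model_copy(deep=True)
        scrambled.mci.order_scramble_rate = 1.0
        scrambled.mci.stroke_merge_rate = 0.0
        scrambled.mci.stroke_split_rate = 0.0
        scrambled.mci.stroke_drop_rate = 0.0
        scrambled.mci.char_count_error_rate = 0.0
        ses = gm.simulate_session(scrambled, "MCI", seed=5)
        res = gm.score_task(gm.segment_strokes(ses))
        assert res.order_component == 0

    def test_score_bounds_on_random_sessions(self, params):
        for seed in range(8):
            ses = gm.simulate_session(params, "MCI", seed=seed)
            res = gm.score_task(gm.segment_strokes(ses))
            assert 0 <= res.score <= 2
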