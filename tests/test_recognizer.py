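"""Readiness gating, throw recognition, streams and accuracy aggregation."""

import numpy as np
import pytest

from throwsense import (
    RecognizerConfig,
    ThrowProfile,
    ThrowSequencePair,
    aggregate_accuracy,
    check_ready,
    generate_session,
    generate_throw,
    process_stream,
    recognize_throw,
)
from throwsense.preprocess import FOREARM, UPPERARM, Trace
from tests.conftest import TABLE4_COUNTS

STAND = (0, -1, 0)


def triples(seq):
    return np.array(seq, dtype=np.int8)


class TestCheckReady:
    def test_stable_standing_posture_is_ready(self, rec_cfg):
        w = triples([STAND] * 40)
        st = check_ready(w, w, min_hold=30, config=rec_cfg)
        assert st.ok and st.reason == "ready"

    def test_stable_wrong_posture_reports_worn_incorrectly(self, rec_cfg):
        w = triples([STAND] * 40)
        rotated = triples([(1, 0, 0)] * 40)
        st = check_ready(rotated, w, min_hold=30, config=rec_cfg)
        assert not st.ok and st.reason == "Worn too inside or outside"

    def test_alternating_posture_is_unstable(self, rec_cfg):
        w = triples([STAND, (1, 0, 0)] * 20)
        st = check_ready(w, w, min_hold=30, config=rec_cfg)
        assert not st.ok and st.reason == "unstable"

    def test_short_window_rejected(self, rec_cfg):
        w = triples([STAND] * 10)
        with pytest.raises(ValueError):
            check_ready(w, w, min_hold=30, config=rec_cfg)


class TestRecognizeThrow:
    def test_noiseless_throw_passes_all_six_steps(self, run_throw):
        f, u, _ = generate_throw(ThrowProfile(seed=1))
        res = run_throw(f, u)
        assert res.all_ok
        assert res.display_lines() == [f"S{k}: OK!!" for k in range(1, 7)]
        assert res.report_lines() == [f"STEP{k}: OK!!" for k in range(1, 7)]

    def test_low_elbow_fails_step4_only(self, run_throw):
        f, u, _ = generate_throw(ThrowProfile(seed=2), error_id="Elbow is not high enough")
        res = run_throw(f, u)
        assert res.steps[4].status == "error"
        assert res.steps[4].message == "Elbow is not high enough"
        assert "S4: Elbow is not enough high!!" in res.display_lines()
        for k in (1, 2, 3, 5, 6):
            assert res.steps[k].ok, f"step {k} should stay OK"

    def test_rest_only_pair_passes_no_step(self, db, rec_cfg):
        pair = ThrowSequencePair("1" * 120, "2" * 120)
        res = recognize_throw(pair, db, rec_cfg)
        assert not any(v.ok for v in res.steps.values())

    def test_empty_pair_rejected(self, db, rec_cfg):
        with pytest.raises(ValueError):
            recognize_throw(ThrowSequencePair("", ""), db, rec_cfg)

    def test_deterministic(self, run_throw):
        f, u, _ = generate_throw(ThrowProfile(seed=3, noise_sigma=0.05))
        a = run_throw(f, u)
        b = run_throw(f, u)
        assert [v for v in a.steps.values()] == [v for v in b.steps.values()]

    def test_left_hand_mirrors_to_identical_verdicts(self, run_throw):
        right = generate_throw(ThrowProfile(seed=4, handedness="right"))
        left = generate_throw(ThrowProfile(seed=4, handedness="left"))
        res_r = run_throw(right[0], right[1], handedness="right")
        res_l = run_throw(left[0], left[1], handedness="left")
        assert [v.status for v in res_r.steps.values()] == [
            v.status for v in res_l.steps.values()
        ]
        assert res_r.all_ok


class TestProcessStream:
    def test_three_throw_session(self, db, sensor_cfg, rec_cfg):
        f, u, gt = generate_session(3, ThrowProfile(seed=11))
        rep = process_stream(f, u, db, sensor_cfg, rec_cfg)
        assert len(rep.throws) == 3
        assert all(t.all_ok for t in rep.throws)

    def test_interrupted_throw_marked_incomplete(self, db, sensor_cfg, rec_cfg):
        f1, u1, _ = generate_throw(ThrowProfile(seed=12))
        f2, u2, g2 = generate_throw(ThrowProfile(seed=13))
        cut = g2.step_bounds[3][1]  # throw 2 stops right after arm cocking
        rest = np.tile(f2.counts[0], (150, 1))
        fc = np.concatenate([f1.counts, f2.counts[:cut], rest, f1.counts])
        uc = np.concatenate([u1.counts, u2.counts[:cut], rest, u1.counts])
        t = np.arange(len(fc)) / 100.0
        rep = process_stream(
            Trace(t, fc, FOREARM), Trace(t, uc, UPPERARM), db, sensor_cfg, rec_cfg
        )
        assert len(rep.throws) == 3
        assert rep.throws[0].all_ok and rep.throws[2].all_ok
        middle = rep.throws[1]
        assert [middle.steps[k].status for k in range(1, 7)] == [
            "ok", "ok", "ok", "incomplete", "incomplete", "incomplete",
        ]

    def test_silent_phase_error_is_not_split_by_windowing(self, db, sensor_cfg, rec_cfg):
        """A throw whose erroneous step is pure rest must stay one window:
        the rest hold bridges the silent phase and the later steps still pass."""
        f, u, _ = generate_session(
            2, ThrowProfile(seed=15), error_ids=["Elbow is not high enough", None]
        )
        rep = process_stream(f, u, db, sensor_cfg, rec_cfg)
        assert len(rep.throws) == 2
        first = rep.throws[0]
        assert first.steps[4].message == "Elbow is not high enough"
        assert first.steps[5].ok and first.steps[6].ok
        assert rep.throws[1].all_ok

    def test_gate_never_passes_means_no_throws(self, db, sensor_cfg, rec_cfg):
        f, u, _ = generate_throw(
            ThrowProfile(seed=14), error_id="Worn too inside or outside"
        )
        rep = process_stream(f, u, db, sensor_cfg, rec_cfg)
        assert rep.throws == []
        assert rep.ready_checks and not rep.ready_checks[0].ok
        assert rep.ready_checks[0].reason == "Worn too inside or outside"


class TestAggregateAccuracy:
    def test_three_user_evaluation_aggregates(self):
        acc = aggregate_accuracy(TABLE4_COUNTS)
        assert acc.user_average == {
            "User 1": 95.14,
            "User 2": 91.42,
            "User 3": 95.14,
        }
        assert acc.overall == 93.90
        assert acc.step_average[0] == 99.33
        assert min(acc.step_average) == 85.33

    def test_zero_identifications_report_zero(self):
        acc = aggregate_accuracy({"u": [(0, 50)]})
        assert acc.per_step_pct["u"] == [0.0]

    def test_truncation_toward_zero(self):
        # 2/3 of 100% = 66.666..% -> 66.66, not 66.67
        acc = aggregate_accuracy({"u": [(2, 3)]})
        assert acc.per_step_pct["u"] == [66.66]

    def test_zero_attempts_rejected(self):
        with pytest.raises(ValueError):
            aggregate_accuracy({"u": [(0, 0)]})

    def test_text_table_contains_averages(self):
        text = aggregate_accuracy(TABLE4_COUNTS).to_text()
        assert "95.14" in text and "91.42" in text and "93.90" in text
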