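"""AUC epochs, bout detection, the Δ back-reference, and 50% gating."""

import numpy as np
import pytest

from uemasim import sensors
from uemasim.sensors import (AccelTrace, ActivityInterval, AucSeries,
                             BoutEvent, auc_epochs, calibrate_thresholds,
                             delta_minutes, detect_bouts, maybe_trigger,
                             synth_accel)
from uemasim.selection import QuestionSpec

CORE_Q = QuestionSpec("int01", "Feeling stressed?", "internal",
                      ("Yes", "Sort of", "No"))


def flat_auc(pattern):
    """Build an AucSeries from (value, n_epochs) runs."""
    vals = np.concatenate([np.full(n, v, dtype=float) for v, n in pattern])
    return AucSeries(10.0, vals)


class TestAucEpochs:
    def test_pure_gravity_gives_zero_auc(self):
        samples = np.zeros((3000, 3))
        samples[:, 2] = 1.0  # constant 1 g on z
        auc = auc_epochs(AccelTrace(50.0, samples))
        assert auc.values.shape == (6,)
        assert np.all(auc.values < 1e-6)

    def test_sinusoid_auc_matches_closed_form(self):
        # mean |sin| is 2/pi, so a unit 2 Hz sinusoid integrates to
        # 10 * 2/pi ~ 6.37 per 10-s epoch
        t = np.arange(3000) / 50.0
        samples = np.zeros((3000, 3))
        samples[:, 0] = np.sin(2 * np.pi * 2.0 * t)
        auc = auc_epochs(AccelTrace(50.0, samples))
        # interior epochs avoid the filtfilt edge transient
        assert auc.values[2] == pytest.approx(10.0 * 2 / np.pi, rel=0.05)

    def test_auc_is_linear_in_amplitude(self, rng):
        samples = rng.normal(0, 0.1, size=(6000, 3))
        a1 = auc_epochs(AccelTrace(50.0, samples)).values
        a2 = auc_epochs(AccelTrace(50.0, 2.0 * samples)).values
        np.testing.assert_allclose(a2, 2.0 * a1, rtol=1e-9)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            auc_epochs(AccelTrace(50.0, np.zeros((100, 3))))


class TestDeltaRule:
    def test_pa_bout_detected_at_end(self):
        assert delta_minutes(0.0, 600.0, 600.0) == pytest.approx(2.5)

    def test_sb_bout_detected_at_end(self):
        assert delta_minutes(0.0, 3600.0, 3600.0) == pytest.approx(15.0)

    def test_gap_plus_quarter_bout(self):
        # 20-minute bout that ended 4 minutes ago
        assert delta_minutes(0.0, 1200.0, 1440.0) == pytest.approx(9.0)


class TestDetectBouts:
    def test_ten_minute_run_is_a_pa_bout(self):
        auc = flat_auc([(1.0, 30), (5.0, 60), (1.0, 30)])
        bouts = detect_bouts(auc, now_s=1200.0, pa_threshold=3.0,
                             sb_threshold=0.5)
        assert [b.kind for b in bouts] == ["PA"]
        b = bouts[0]
        assert (b.start_s, b.end_s) == (300.0, 900.0)
        assert b.delta_min == pytest.approx((1200 - 900) / 60 + 2.5)

    def test_nine_minute_run_is_not_a_bout(self):
        auc = flat_auc([(1.0, 30), (5.0, 54), (1.0, 30)])
        assert detect_bouts(auc, now_s=1140.0, pa_threshold=3.0,
                            sb_threshold=0.5) == []

    def test_sixty_minute_low_run_is_an_sb_bout(self):
        auc = flat_auc([(5.0, 60), (0.1, 360)])
        bouts = detect_bouts(auc, now_s=4200.0, pa_threshold=3.0,
                             sb_threshold=0.5)
        kinds = {b.kind for b in bouts}
        assert kinds == {"PA", "SB"}
        sb = next(b for b in bouts if b.kind == "SB")
        assert sb.delta_min == pytest.approx(15.0)

    def test_thresholds_validated(self):
        auc = flat_auc([(1.0, 10)])
        with pytest.raises(ValueError):
            detect_bouts(auc, 100.0, pa_threshold=-1.0)
        with pytest.raises(ValueError, match="sb_threshold"):
            detect_bouts(auc, 100.0, pa_threshold=1.0, sb_threshold=2.0)

    def test_pa_and_sb_bouts_never_overlap(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 6, size=500)
            vals[rng.random(500) < 0.5] = 0.05  # long low stretches
            bouts = detect_bouts(AucSeries(10.0, vals), now_s=5000.0)
            for a in bouts:
                for b in bouts:
                    if a is not b:
                        assert a.end_s <= b.start_s or b.end_s <= a.start_s

    def test_delta_nonnegative_for_past_bouts(self, rng):
        vals = rng.uniform(0, 6, size=1000)
        bouts = detect_bouts(AucSeries(10.0, vals), now_s=10_000.0)
        assert all(b.delta_min >= 0 for b in bouts)


class TestSynthAccel:
    def script(self):
        i = sensors.DEFAULT_INTENSITIES
        return [ActivityInterval("sedentary", 1800, i["sedentary"]),
                ActivityInterval("active", 720, i["active"]),
                ActivityInterval("sedentary", 1800, i["sedentary"])]

    def test_identical_seeds_identical_traces(self):
        t1 = synth_accel(self.script(), np.random.default_rng(5))
        t2 = synth_accel(self.script(), np.random.default_rng(5))
        np.testing.assert_array_equal(t1.samples, t2.samples)

    def test_twelve_minute_active_block_is_recovered(self, rng):
        trace = synth_accel(self.script(), rng)
        bouts = detect_bouts(auc_epochs(trace), now_s=trace.duration_s)
        pa = [b for b in bouts if b.kind == "PA"]
        assert len(pa) >= 1
        assert pa[0].start_s == pytest.approx(1800, abs=30)
        assert pa[0].end_s == pytest.approx(2520, abs=30)

    def test_calibration_separates_labels(self, rng):
        trace = synth_accel(self.script(), rng)
        pa_thr, sb_thr = calibrate_thresholds(trace)
        assert 0.3 < sb_thr <= pa_thr < 5.0

    def test_scripted_bouts_recovered_with_95pct_overlap(self):
        # parameter-recovery property over random scripts at the default
        # thresholds: detected bouts cover >= 95% of each scripted episode
        master = np.random.default_rng(99)
        i = sensors.DEFAULT_INTENSITIES
        for _ in range(100):
            script, truth_pa, truth_sb = [], [], []
            t = 0.0
            for k in range(3):
                sed = float(master.integers(390, 450)) * 10.0  # 65-75 min
                act = float(master.integers(72, 120)) * 10.0   # 12-20 min
                script.append(ActivityInterval("sedentary", sed,
                                               i["sedentary"]))
                truth_sb.append((t, t + sed)); t += sed
                script.append(ActivityInterval("active", act, i["active"]))
                truth_pa.append((t, t + act)); t += act
            trace = synth_accel(script, master)
            bouts = detect_bouts(auc_epochs(trace), now_s=trace.duration_s)
            for kind, truths in (("PA", truth_pa), ("SB", truth_sb)):
                dets = [b for b in bouts if b.kind == kind]
                for s, e in truths:
                    cover = sum(max(0.0, min(e, b.end_s) - max(s, b.start_s))
                                for b in dets)
                    assert cover / (e - s) >= 0.95


class TestMaybeTrigger:
    def test_no_bouts_leaves_slot_question(self, rng):
        q, bout = maybe_trigger([], CORE_Q, rng)
        assert q is CORE_Q and bout is None

    def test_most_recent_bout_wins(self):
        pa = BoutEvent("PA", 0.0, 600.0, 2.5)
        sb = BoutEvent("SB", 1000.0, 4600.0, 15.0)

        class Always:
            def random(self):
                return 0.0
        q, bout = maybe_trigger([pa, sb], CORE_Q, Always())
        assert bout is sb and q.category == "sensor_sb"
        assert "Sedentary" in q.text

    def test_tie_prefers_pa(self):
        pa = BoutEvent("PA", 0.0, 600.0, 2.5)
        sb = BoutEvent("SB", -3000.0, 600.0, 15.0)

        class Always:
            def random(self):
                return 0.0
        q, bout = maybe_trigger([sb, pa], CORE_Q, Always())
        assert bout is pa and q.category == "sensor_pa"

    def test_trigger_fraction_is_half(self, rng):
        pa = BoutEvent("PA", 0.0, 600.0, 2.5)
        n = 40_000
        hits = sum(maybe_trigger([pa], CORE_Q, rng)[1] is not None
                   for _ in range(n))
        assert hits / n == pytest.approx(0.5, abs=0.01)
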