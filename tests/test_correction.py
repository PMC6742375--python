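"""Envelope construction, correction-latency detection and path-offset measures."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from doublestep import (build_envelope, build_envelopes, correction_frequency,
                        detect_correction, mpo_latency, path_linearity,
                        trial_path_linearity, Trial)
from doublestep.simulate import TrialParams, generate_trial
from doublestep import GeneratorConfig

from conftest import quiet_groups

FS = 240.0


def make_trial(x, cond=None, direction="none", latency_s=0.3):
    """A trial on the 240 Hz grid with a fully controlled horizontal trace."""
    x = np.asarray(x, float)
    n = len(x)
    t_rel = np.arange(n) / FS
    reach_onset = latency_s
    pert = None if cond is None else reach_onset + cond / 1000.0
    return Trial(
        participant="p", group="younger", block=1, trial=1,
        condition_ms=cond, direction=direction,
        target_onset_s=0.0, reach_onset_s=reach_onset, perturbation_s=pert,
        touch_s=reach_onset + t_rel[-1], touch_x_cm=float(x[-1]), touch_y_cm=0.0,
        t_s=reach_onset + t_rel, x_cm=x,
        y_cm=np.zeros(n), z_cm=np.linspace(40.0, 0.0, n),
    )


def static_envelope(offsets, n=160, k=1.5, min_support=2):
    """Envelope from constant-offset static traces."""
    trials = [make_trial(np.full(n, c)) for c in offsets]
    return build_envelope(trials, FS, k=k, min_support=min_support)


class TestBuildEnvelope:
    def test_identical_trials_collapse_to_mean(self):
        env = static_envelope([0.0] * 10, min_support=10)
        np.testing.assert_allclose(env.sd, 0.0, atol=1e-12)
        lo, hi = env.bounds()
        np.testing.assert_allclose(lo, hi, atol=1e-12)

    def test_two_trial_bounds(self):
        """x = {1, 3}: mean 2, sample SD sqrt(2), bounds 2 +/- 1.5*sqrt(2)."""
        env = static_envelope([1.0, 3.0])
        np.testing.assert_allclose(env.mean, 2.0)
        np.testing.assert_allclose(env.sd, math.sqrt(2.0))
        lo, hi = env.bounds()
        np.testing.assert_allclose(lo, 2 - 1.5 * math.sqrt(2), atol=1e-9)
        np.testing.assert_allclose(hi, 2 + 1.5 * math.sqrt(2), atol=1e-9)

    def test_support_non_increasing_in_flight(self):
        trials = [make_trial(np.zeros(n)) for n in (100, 130, 160, 190)]
        env = build_envelope(trials, FS, min_support=4)
        movement = env.n[-env.start_index:]   # samples from reach onset on
        assert np.all(np.diff(movement) <= 0)

    def test_insufficient_support_raises(self):
        with pytest.raises(ValueError, match="minimum support"):
            static_envelope([0.0] * 5, min_support=10)


class TestDetectCorrection:
    def test_trial_on_envelope_mean_not_detected(self):
        env = static_envelope([0.0] * 12, min_support=10)
        trial = make_trial(np.zeros(160), cond=200, direction="right")
        res = detect_correction(trial, env)
        assert not res.detected
        assert math.isnan(res.correction_latency_ms)

    def test_large_deviation_at_150ms_post_perturbation(self):
        """Brute-force check: onset at the first sample of the sustained
        excursion, 150 ms after the perturbation."""
        env = static_envelope([-0.2, 0.2] * 6, min_support=10)
        sigma = env.sd[0]
        x = np.zeros(200)
        pert_idx = 48                      # 200 ms condition
        onset_idx = pert_idx + 36          # +150 ms
        x[onset_idx:] = 10.0 * sigma
        trial = make_trial(x, cond=200, direction="right")
        res = detect_correction(trial, env)
        assert res.detected
        assert res.correction_latency_ms == pytest.approx(150.0, abs=1000.0 / FS)
        # independent per-sample scan
        lo, hi = env.bounds(len(x))
        outside = x > hi
        first = next(i for i in range(len(x)) if outside[i])
        assert first == onset_idx

    def test_continuously_outside_from_perturbation_floors_at_80ms(self):
        env = static_envelope([0.0] * 20, min_support=10)
        x = np.zeros(200)
        x[48:] = 5.0                       # outside from perturbation onset
        trial = make_trial(x, cond=200, direction="right")
        res = detect_correction(trial, env)
        assert res.detected
        assert res.correction_latency_ms == 80.0

    def test_pre_existing_deviation_not_counted(self):
        env = static_envelope([-0.2, 0.2] * 6, min_support=10)
        x = np.full(200, 10.0 * env.sd[0])  # outside the whole trial
        trial = make_trial(x, cond=200, direction="right")
        res = detect_correction(trial, env)
        assert not res.detected
        assert res.pre_deviated

    def test_opposite_side_crossing_flagged_not_counted(self):
        env = static_envelope([-0.2, 0.2] * 6, min_support=10)
        x = np.zeros(200)
        x[100:] = -10.0 * env.sd[0]        # away from the rightward target
        trial = make_trial(x, cond=200, direction="right")
        res = detect_correction(trial, env)
        assert not res.detected
        assert res.opposite_crossing

    def test_sustain_rejects_short_blips(self):
        env = static_envelope([-0.2, 0.2] * 6, min_support=10)
        x = np.zeros(200)
        x[90:92] = 10.0 * env.sd[0]        # 2-sample blip
        trial = make_trial(x, cond=0, direction="right")
        assert not detect_correction(trial, env, sustain=3).detected
        assert detect_correction(trial, env, sustain=1).detected

    def test_scan_window_beyond_trace_raises(self):
        env = static_envelope([0.0] * 12, min_support=10)
        trial = make_trial(np.zeros(55), cond=200, direction="right")
        with pytest.raises(ValueError, match="scan window"):
            detect_correction(trial, env)

    def test_detected_latency_bounds_on_noisy_session(self):
        """Detected latency is never below the 80 ms floor nor past touch."""
        from doublestep.simulate import generate_session

        cfg = GeneratorConfig(participants=(("p1", "younger"),),
                              groups=quiet_groups(), blocks=2,
                              artifact_rate=0.0, behavioral_outlier_rate=0.0)
        session, _ = generate_session(cfg, seed=21)
        envs = build_envelopes(session)
        checked = 0
        for tr in session:
            if not tr.perturbed:
                continue
            res = detect_correction(tr, envs[(tr.participant, tr.block)])
            if res.detected:
                dur_ms = (tr.touch_s - tr.perturbation_s) * 1000.0
                assert 80.0 <= res.correction_latency_ms <= dur_ms
                checked += 1
        assert checked > 20


class TestPathLinearity:
    def test_collinear_path_is_perfectly_straight(self):
        s = np.linspace(0.0, 1.0, 50)
        L, A, B, _ = path_linearity(0 * s, 3.15 * s, 40.0 * (1 - s))
        assert L == pytest.approx(0.0, abs=1e-12)
        assert A == pytest.approx(0.0, abs=1e-10)

    def test_isoceles_apex(self):
        L, A, B, idx = path_linearity([0, 5, 10], [0, 5, 0])
        assert (L, A, B) == pytest.approx((0.5, 5.0, 10.0))
        assert idx == 1

    def test_semicircle_approaches_half(self):
        theta = np.linspace(0, np.pi, 10_000)
        r = 3.0
        L, A, B, _ = path_linearity(r * np.cos(theta), r * np.sin(theta))
        assert L == pytest.approx(0.5, abs=1e-4)
        assert A == pytest.approx(r, abs=1e-3)
        assert B == pytest.approx(2 * r, abs=1e-9)

    def test_degenerate_closed_path_flagged(self):
        L, A, B, idx = path_linearity([0, 1, 0], [0, 1, 0])
        assert math.isnan(L) and idx == -1

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="3 samples"):
            path_linearity([0, 1], [0, 1])

    @given(st.floats(0, 2 * math.pi), st.floats(-50, 50), st.floats(-50, 50),
           st.floats(0.1, 10))
    def test_rigid_motion_and_scale_invariance(self, angle, tx, ty, scale):
        x = np.array([0.0, 2.0, 5.0, 7.0, 10.0])
        y = np.array([0.0, 3.0, 4.0, 2.5, 0.0])
        L0, *_ = path_linearity(x, y)
        c, s = math.cos(angle), math.sin(angle)
        xr = scale * (c * x - s * y) + tx
        yr = scale * (s * x + c * y) + ty
        L1, *_ = path_linearity(xr, yr)
        assert L1 == pytest.approx(L0, rel=1e-9, abs=1e-9)

    def test_horizontal_plane_mode_ignores_vertical(self):
        x = np.array([0.0, 1.0, 0.0])
        y = np.array([0.0, 50.0, 100.0])   # large vertical excursion
        z = np.array([40.0, 20.0, 0.0])
        L3, *_ = path_linearity(x, y, z)
        Lh, *_ = path_linearity(x, y, z, plane="horizontal")
        assert Lh > L3                     # vertical leg no longer dilutes B


class TestMpoLatency:
    def test_direct_subtraction(self):
        x = np.zeros(200)
        x[100] = 2.0
        trial = make_trial(x, cond=0, direction="right")
        # argmax sample at index 100 = 416.7 ms after reach onset = perturbation
        _, _, _, idx = trial_path_linearity(trial)
        assert mpo_latency(trial, idx) == pytest.approx(100 / FS * 1000.0, abs=1e-6)

    def test_unperturbed_trial_rejected(self):
        trial = make_trial(np.zeros(120))
        with pytest.raises(ValueError, match="unperturbed"):
            mpo_latency(trial, 10)

    def test_submovement_mpo_peaks_after_detected_onset(self, rng):
        """The offset maximum lies inside the correction, after its onset."""
        cfg = GeneratorConfig(participants=(("p1", "younger"),),
                              groups=quiet_groups(), noise_sd=0.0,
                              start_offset_sd=0.0, artifact_rate=0.0,
                              behavioral_outlier_rate=0.0)
        p = TrialParams("p1", "younger", 1, 1, 0, "right", 600.0, 300.0, 500.0,
                        correction=True, correction_latency_ms=160.0,
                        submovement_duration_ms=260.0)
        trial, _ = generate_trial(cfg, p, rng)
        L, A, B, idx = trial_path_linearity(trial)
        lat = mpo_latency(trial, idx)
        assert lat > 160.0
        assert 0.0 <= lat <= (trial.touch_s - trial.perturbation_s) * 1000.0
        # brute-force perpendicular-distance maximum over the movement path
        sel = trial.t_s >= trial.reach_onset_s - 1e-9
        pts = np.column_stack([trial.x_cm[sel], trial.y_cm[sel], trial.z_cm[sel]])
        chord = pts[-1] - pts[0]
        u = chord / np.linalg.norm(chord)
        dists = [np.linalg.norm(np.cross(q - pts[0], u)) for q in pts]
        assert idx == int(np.argmax(dists))
        assert A == pytest.approx(max(dists), rel=1e-9)


class TestCorrectionFrequency:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["group", "condition_ms", "direction",
                                           "detected"])

    def test_all_detected_gives_100_everywhere(self):
        rows = [("younger", c, d, True) for c in (0, 200)
                for d in ("left", "right") for _ in range(5)]
        table = correction_frequency(self._frame(rows))
        assert (table.to_numpy() == 100.0).all()

    def test_mixed_cell_percentage(self):
        rows = [("younger", 0, "left", True)] * 3 + [("younger", 0, "left", False)]
        table = correction_frequency(self._frame(rows))
        assert table.loc["younger", (0, "left")] == pytest.approx(75.0)

    def test_empty_cell_is_missing_not_zero(self):
        rows = [("younger", 0, "left", True), ("older", 200, "right", False)]
        table = correction_frequency(self._frame(rows))
        assert math.isnan(table.loc["younger", (200, "right")])
        assert table.loc["older", (200, "right")] == 0.0
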