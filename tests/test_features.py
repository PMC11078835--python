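"""Outcome variables: lift delay, max lift velocity, peak grip force rate."""

import numpy as np
import pytest

from handover.calibration import liftoff_detection_lag
from handover.events import EventSet, PhaseSegmentation, segment_trial
from handover.features import (
    extract_features,
    lift_delay,
    max_lift_velocity,
    peak_grip_force_rate,
)
from handover.pipeline import PipelineSettings, process_trial
from handover.preprocessing import preprocess_recording
from handover.schedule import Weight
from handover.simulate import SimulatorConfig, simulate_trial

from conftest import make_condition


def _min_jerk_pos(d, T, fs=100.0, pad=1.0):
    """3-D midpoint series (mm): rest, a minimum-jerk move of d metres in
    T seconds along x, rest."""
    n_pad = int(pad * fs)
    s = np.arange(int(T * fs) + 1) / (T * fs)
    move = d * (10 * s**3 - 15 * s**4 + 6 * s**5)
    x = np.concatenate([np.zeros(n_pad), move, np.full(n_pad, d)])
    pos = np.zeros((x.size, 3))
    pos[:, 0] = x * 1000.0
    return pos, (n_pad, n_pad + s.size)


class TestLiftDelay:
    def test_frame_arithmetic(self):
        ev = EventSet(100, 138, 200, 300)
        assert lift_delay(ev, fs=100.0) == pytest.approx(380.0)

    def test_zero_delay_impossible_by_invariant(self):
        with pytest.raises(ValueError, match="A < B"):
            EventSet(100, 100, 200, 300)


class TestMaxLiftVelocity:
    def test_minimum_jerk_peak_speed(self):
        """0.4 m in 1.5 s -> peak 1.875 * 0.4 / 1.5 = 0.5 m/s."""
        pos, (b, c) = _min_jerk_pos(0.4, 1.5)
        assert max_lift_velocity(pos, (b, c), 100.0) == pytest.approx(0.5, rel=5e-3)

    def test_stationary_wrist_zero(self):
        pos = np.zeros((300, 3))
        assert max_lift_velocity(pos, (50, 250), 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_constant_velocity_line(self):
        t = np.arange(400) / 100.0
        pos = np.zeros((400, 3))
        pos[:, 1] = 0.3 * t * 1000.0  # 0.3 m/s along y, in mm
        assert max_lift_velocity(pos, (100, 300), 100.0) == pytest.approx(0.3)

    def test_invariant_to_rigid_translation(self, rng):
        pos, (b, c) = _min_jerk_pos(0.4, 1.5)
        shifted = pos + np.array([123.0, -456.0, 789.0])
        assert max_lift_velocity(pos, (b, c), 100.0) == pytest.approx(
            max_lift_velocity(shifted, (b, c), 100.0)
        )

    def test_interval_too_short_rejected(self):
        pos = np.zeros((100, 3))
        with pytest.raises(ValueError, match="shorter than 3"):
            max_lift_velocity(pos, (10, 12), 100.0)


def _bump(center, width, height, n=500):
    """Smooth bump in a rate series."""
    i = np.arange(n)
    return height * np.exp(-0.5 * ((i - center) / width) ** 2)


class TestPeakGripForceRate:
    def test_first_supra_threshold_peak_wins(self):
        rate = _bump(100, 8, 40) + _bump(200, 8, 80)
        value, fallback = peak_grip_force_rate(rate, (0, 500), min_peak=30)
        assert value == pytest.approx(40, rel=1e-6)
        assert not fallback

    def test_sub_threshold_first_peak_skipped(self):
        rate = _bump(100, 8, 20) + _bump(200, 8, 80)
        value, fallback = peak_grip_force_rate(rate, (0, 500), min_peak=30)
        assert value == pytest.approx(80, rel=1e-6)
        assert not fallback

    def test_fallback_to_absolute_maximum(self):
        rate = _bump(250, 10, 12)
        value, fallback = peak_grip_force_rate(rate, (0, 500), min_peak=30)
        assert value == pytest.approx(12, rel=1e-6)
        assert fallback

    def test_plateau_resolves_to_first_sample(self):
        rate = np.zeros(50)
        rate[10:15] = 35.0  # flat-topped peak
        value, fallback = peak_grip_force_rate(rate, (0, 50), min_peak=30)
        assert value == 35.0 and not fallback

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            peak_grip_force_rate(np.zeros(10), (5, 5), 30)

    def test_agrees_with_brute_force_oracle(self, rng):
        """The picker equals an exhaustive scan of all local maxima (strict
        neighbours, plateau -> first sample) on 1000 random series."""

        def oracle(w, min_peak):
            maxima = []
            for i in range(1, len(w) - 1):
                left = i - 1
                right = i + 1
                while right < len(w) and w[right] == w[i]:
                    right += 1
                if (
                    w[i] > w[left]
                    and right < len(w)
                    and w[right] < w[i]
                    and w[i - 1] < w[i]  # first sample of a plateau only
                ):
                    maxima.append(i)
            for i in maxima:
                if w[i] >= min_peak:
                    return w[i], False
            return w.max(), True

        for _ in range(1000):
            n = int(rng.integers(5, 60))
            w = rng.integers(-5, 50, size=n).astype(float)  # ties are common
            min_peak = float(rng.uniform(5, 45))
            got = peak_grip_force_rate(w, (0, n), min_peak)
            expected = oracle(w, min_peak)
            assert got[0] == pytest.approx(expected[0])
            assert got[1] == expected[1]


class TestExtractFeatures:
    @pytest.mark.parametrize("weight", list(Weight))
    def test_noise_free_recovery_of_ground_truth(self, noise_free_trials, weight):
        """Noise-free simulation: detected delay equals the true delay plus
        the closed-form 2 mm lag within 1 frame; peak speed and both peak
        rates recover the drawn values within 2%."""
        _, rec, filtered, gt = noise_free_trials[weight]
        ev, ph = segment_trial(filtered)
        f = extract_features(filtered, ev, ph)
        lag = liftoff_detection_lag(gt.mass_kg, gt.load_force_rate)
        expected_delay_ms = (gt.true_lift_delay + lag) * 1000
        assert abs(f.lift_delay - expected_delay_ms) <= 2 * 10.0 + 1e-9  # 2 frames: A and B each quantize
        assert f.max_lift_velocity == pytest.approx(gt.true_peak_speed, rel=0.02)
        assert f.giver_pgfr == pytest.approx(gt.true_giver_pgfr, rel=0.02)
        assert f.receiver_pgfr == pytest.approx(gt.true_receiver_pgfr, rel=0.02)
        assert not f.receiver_pgfr_fallback_used

    def test_velocity_invariant_to_marker_label_swap(self, noise_free_trials):
        _, rec, filtered, _ = noise_free_trials[Weight.MEDIUM]
        import copy

        swapped = copy.deepcopy(filtered)
        swapped.radius_marker, swapped.ulna_marker = (
            filtered.ulna_marker.copy(),
            filtered.radius_marker.copy(),
        )
        ev, ph = segment_trial(filtered)
        f1 = extract_features(filtered, ev, ph)
        f2 = extract_features(swapped, ev, ph)
        assert f1.max_lift_velocity == pytest.approx(f2.max_lift_velocity)

    def test_receiver_collision_bump_ignored(self, noise_free_trials):
        """A small collision when the receiver first reaches the object
        (sub-threshold rate bump before the real grasp) must not become the
        receiver's peak grip force rate."""
        _, rec, _, gt = noise_free_trials[Weight.MEDIUM]
        import copy

        bumped = copy.deepcopy(rec)
        fs = rec.fs
        c_frame = int(gt.t_contact_receiver * fs)
        # 10 N/s triangle lasting 80 ms, well before the grasp pulse peak
        i = np.arange(bumped.n_samples)
        tri = np.maximum(0, 1 - np.abs(i - (c_frame + 4)) / 4) * 0.4
        bumped.receiver_force = bumped.receiver_force + tri
        filtered = preprocess_recording(bumped)
        ev, ph = segment_trial(filtered)
        f = extract_features(filtered, ev, ph)
        assert f.receiver_pgfr == pytest.approx(gt.true_receiver_pgfr, rel=0.05)

    def test_fallback_rate_below_5_percent(self, experiment_20_dyads):
        features, _ = experiment_20_dyads
        assert len(features) >= 600
        assert features["receiver_pgfr_fallback_used"].mean() < 0.05

    def test_noisy_batch_recovers_ground_truth_rates(self, experiment_20_dyads):
        """Across the default-noise experiment, detected receiver peak rates
        track the drawn ground-truth values closely."""
        features, gts = experiment_20_dyads
        truth = {
            (c.dyad_id, c.block, c.trial_in_block): g.true_receiver_pgfr
            for c, g in gts
        }
        det = features.set_index(["dyad_id", "block", "trial_in_block"])[
            "receiver_pgfr"
        ]
        errs = [
            det.loc[k] - v for k, v in truth.items() if k in det.index
        ]
        assert np.median(np.abs(errs)) < 2.0  # N/s
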