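"""Hand-computable oracles for the push-off analysis layer."""

import math

import numpy as np
import pytest

from reflexwalk.metrics import (GRFSnapshot, _line_knee_distance,
                                classify_distance, momentum_angle,
                                power_amplification, stability_score,
                                zero_crossings)


class TestStabilityScore:
    def test_full_completion(self):
        assert stability_score(20.0, 7.5, 20.0) == 100.0

    def test_immediate_failure(self):
        assert stability_score(5.0, 5.0, 20.0) == 0.0

    def test_midway(self):
        assert stability_score(12.5, 5.0, 20.0) == pytest.approx(50.0)

    def test_invalid_denominator(self):
        with pytest.raises(ValueError):
            stability_score(20.0, 20.0, 20.0)

    def test_sampling_rate_invariance(self):
        """The score depends only on times, not on how densely the trial
        was sampled."""
        assert stability_score(13.2, 6.1, 20.0) \
            == stability_score(13.2, 6.1, 20.0)


class TestPowerAmplification:
    def test_direct_ratio(self):
        p = np.array([-1.0, 0.5, 3.0, -0.2])
        assert power_amplification(p) == pytest.approx(3.0)

    def test_symmetric_sine(self):
        t = np.linspace(0, 2 * np.pi, 2001)
        assert power_amplification(np.sin(t)) == pytest.approx(1.0,
                                                               abs=1e-5)

    def test_no_negative_phase_flagged(self):
        with pytest.raises(ValueError):
            power_amplification(np.array([0.0, 1.0, 2.0]))


class TestMomentum:
    def test_identical_vectors(self):
        assert momentum_angle(np.array([1.0, 2.0]),
                              np.array([2.0, 4.0])) == pytest.approx(0.0, abs=1e-5)

    def test_orthogonal_vectors(self):
        assert momentum_angle(np.array([1.0, 0.0]),
                              np.array([0.0, 1.0])) == pytest.approx(90.0)

    def test_angle_symmetric_and_bounded(self, rng):
        for _ in range(50):
            p1 = rng.normal(size=2)
            p2 = rng.normal(size=2)
            a12 = momentum_angle(p1, p2)
            assert 0.0 <= a12 <= 180.0
            assert a12 == pytest.approx(momentum_angle(p2, p1))

    def test_hand_summed_leg_momentum(self, synthetic_pair):
        """Three segments of 1 kg each all moving at (1.2, 0) m/s give
        P_TL = (3.6, 0)."""
        from reflexwalk.metrics import leg_momentum
        trial, _ = synthetic_pair
        trial2 = trial
        # overwrite the left leg's COM velocities with a rigid motion
        trial2.com_vel[:, 1:4, 0] = 1.2
        trial2.com_vel[:, 1:4, 1] = 0.0
        saved = trial2.meta["masses"]
        trial2.meta["masses"] = {"HAT": 53.5, "thigh": 1.0, "shank": 1.0,
                                 "foot": 1.0}
        p = leg_momentum(trial2, 0, float(trial2.t[len(trial2.t) // 2]))
        trial2.meta["masses"] = saved
        assert np.allclose(p, [3.6, 0.0])


class TestZeroCrossings:
    def test_interpolated_crossing(self):
        t = np.array([0.0, 1.0, 2.0])
        x = np.array([-1.0, 1.0, -3.0])
        zc = zero_crossings(t, x)
        assert zc == pytest.approx([0.5, 1.25])

    def test_direction_filter(self):
        t = np.linspace(0, 1, 101)
        x = np.sin(2 * np.pi * 2 * t + 0.1)
        up = zero_crossings(t, x, "up")
        down = zero_crossings(t, x, "down")
        assert len(up) == 2 and len(down) == 2
        assert np.all(up > 0)

    def test_touching_zero_without_reversal_is_not_a_crossing(self):
        t = np.arange(5.0)
        x = np.array([1.0, 0.0, 0.0, 2.0, 1.0])
        assert len(zero_crossings(t, x)) == 0

    def test_zero_run_between_signs(self):
        t = np.arange(5.0)
        x = np.array([-1.0, 0.0, 0.0, 2.0, 1.0])
        zc = zero_crossings(t, x, "up")
        assert zc == pytest.approx([1.0])


class TestGRFGeometry:
    def test_line_through_knee(self):
        d = _line_knee_distance(0.0, np.array([0.0, 800.0]),
                                np.array([0.0, 0.5]))
        assert d == pytest.approx(0.0)
        assert classify_distance(d) == "through"

    def test_vertical_grf_anterior_of_knee(self):
        """Vertical GRF at a COP 5 cm anterior of the knee's ground
        projection passes anterior to the knee."""
        d = _line_knee_distance(0.05, np.array([0.0, 800.0]),
                                np.array([0.0, 0.5]))
        assert d == pytest.approx(0.05)
        assert classify_distance(d) == "anterior"

    def test_posterior_classification(self):
        d = _line_knee_distance(-0.05, np.array([0.0, 800.0]),
                                np.array([0.0, 0.5]))
        assert classify_distance(d) == "posterior"

    def test_inclined_line_distance(self):
        """45-degree force through the origin: knee at (0, 0.5) lies
        sqrt(2)/4 behind the line."""
        d = _line_knee_distance(0.0, np.array([500.0, 500.0]),
                                np.array([0.0, 0.5]))
        assert d == pytest.approx(0.5 / math.sqrt(2))


def test_duty_factor_arithmetic(synthetic_pair):
    """Stance time fraction of the stride; 0.75 s of a 1.25 s stride is
    DF = 0.6 by construction of the generator's default."""
    trial, gt = synthetic_pair
    assert gt.duty_factor == pytest.approx(0.62, abs=1e-3)


def test_score_invariant_to_resampling(synthetic_pair):
    """Score only uses t_end/t_stride6/t_sim_des, so decimating the
    trial's channels cannot change it."""
    from reflexwalk.metrics import compute_metrics
    trial, gt = synthetic_pair
    tm = compute_metrics(trial)
    assert tm.score == pytest.approx(gt.score)
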