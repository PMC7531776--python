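import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyforage import kinematics as kin
from flyforage.kinematics import Trajectory


class TestPreprocess:
    def test_constant_trace_unchanged(self, traj_factory):
        traj = traj_factory(np.full(200, 10.0))
        out = kin.preprocess_trajectory(traj)
        np.testing.assert_allclose(out.x, 10.0, atol=1e-9)

    def test_nan_linear_interpolation(self):
        # (t=1, x=0) .. NaN at t=2 .. (t=3, x=2) -> x=1 at t=2
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        x = np.array([-1.0, 0.0, np.nan, 2.0, 3.0])
        traj = Trajectory(time=t, x=x, y=np.zeros(5))
        out = kin.preprocess_trajectory(traj, cutoff=None)
        assert out.x[2] == pytest.approx(1.0)

    def test_jump_removed(self):
        t = np.arange(50) * 0.05
        x = np.linspace(0, 5, 50)
        x[25] += 30.0  # tracking glitch
        traj = Trajectory(time=t, x=x, y=np.zeros(50))
        out = kin.preprocess_trajectory(traj, cutoff=None, jump_threshold=5.0)
        assert abs(out.x[25] - np.linspace(0, 5, 50)[25]) < 0.2

    def test_butterworth_attenuates_fast_sinusoid(self):
        # 25 Hz sinusoid vs 5 Hz cutoff (order 2, zero phase):
        # |H|^2 = (1 + 5^4)^-1 ~ 0.0016 << 0.05
        fs, cutoff = 200.0, 5.0
        t = np.arange(0, 10, 1 / fs)
        x = 25.0 + np.sin(2 * np.pi * 5 * cutoff * t)
        traj = Trajectory(time=t, x=x, y=np.zeros_like(t))
        out = kin.preprocess_trajectory(traj, cutoff=cutoff, order=2,
                                        jump_threshold=None)
        amp = (out.x[400:-400] - 25.0).max()
        assert amp < 0.05

    def test_all_missing_rejected(self):
        traj = Trajectory(time=np.arange(5.0), x=np.full(5, np.nan),
                          y=np.zeros(5))
        with pytest.raises(ValueError):
            kin.preprocess_trajectory(traj)

    def test_too_short_rejected(self):
        traj = Trajectory(time=np.array([0.0]), x=np.array([1.0]),
                          y=np.array([0.0]))
        with pytest.raises(ValueError):
            kin.preprocess_trajectory(traj)


class TestStops:
    def test_constant_position_one_stop(self, traj_factory):
        traj = traj_factory(np.full(100, 5.0))
        stops = kin.detect_stops(traj)
        assert len(stops) == 1
        assert stops[0].t_start == traj.time[0]
        assert stops[0].t_end == traj.time[-1]
        assert stops[0].mean_x == pytest.approx(5.0)

    def test_constant_speed_no_stops(self, traj_factory):
        traj = traj_factory(np.arange(100) * 0.05)  # 1 mm/s at dt=0.05
        assert kin.detect_stops(traj) == []

    def test_default_threshold_value(self):
        assert kin.STOP_SPEED_THRESHOLD == 0.01


class TestTurns:
    def test_monotone_no_turns(self, traj_factory):
        assert kin.detect_turns(traj_factory(np.linspace(0, 40, 200))) == []

    def test_triangle_wave_seven_reversals(self, traj_factory):
        # 8 alternating linear legs -> 7 reversals of the generating wave
        legs = []
        pos = 5.0
        for i in range(8):
            step = 1.0 if i % 2 == 0 else -1.0
            legs.append(pos + step * np.arange(1, 21) * 0.5)
            pos = legs[-1][-1]
        x = np.concatenate([[5.0], *legs])
        assert len(kin.detect_turns(traj_factory(x))) == 7

    def test_constant_position_no_turns(self, traj_factory):
        assert kin.detect_turns(traj_factory(np.full(50, 3.0))) == []

    def test_zero_run_between_opposite_signs_is_one_turn(self):
        x = np.concatenate([np.arange(10.0), np.full(10, 9.0),
                            9.0 - np.arange(1, 11)])
        t = np.arange(len(x)) * 1.0
        traj = Trajectory(time=t, x=x, y=np.zeros_like(x))
        assert len(kin.detect_turns(traj)) == 1

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(-3, 3), min_size=3, max_size=100))
    def test_brute_force_sign_alternation_oracle(self, steps):
        x = np.concatenate([[0.0], np.cumsum(steps, dtype=float)])
        t = np.arange(len(x), dtype=float)
        # oracle: count sign alternations in the displacement sequence
        signs = [s for s in np.sign(np.diff(x)) if s != 0]
        expected = sum(1 for a, b in zip(signs, signs[1:]) if a != b)
        traj = Trajectory(time=t, x=x, y=np.zeros_like(x))
        assert len(kin.detect_turns(traj)) == expected


class TestOccupancy:
    def test_fixed_position_single_bin(self, traj_factory):
        traj = traj_factory(np.full(100, 25.2))
        hist, edges = kin.occupancy_distribution(traj, n_bins=50, length=50.0)
        assert hist.sum() == pytest.approx(1.0)
        k = np.searchsorted(edges, 25.2) - 1
        assert hist[k] == pytest.approx(1.0)

    def test_uniform_sweep_near_uniform(self, traj_factory):
        x = np.linspace(0, 50, 20001)[:-1]
        hist, _ = kin.occupancy_distribution(traj_factory(x, dt=0.001),
                                             n_bins=50, length=50.0)
        assert hist.max() / hist.min() < 1.1

    def test_normalization_random_walk(self, traj_factory):
        rng = np.random.default_rng(0)
        x = np.clip(np.cumsum(rng.normal(0, 0.5, 1000)) + 25, 0, 50)
        hist, _ = kin.occupancy_distribution(traj_factory(x), n_bins=50,
                                             length=50.0)
        assert hist.sum() == pytest.approx(1.0)

    def test_invalid_bins(self, traj_factory):
        with pytest.raises(ValueError):
            kin.occupancy_distribution(traj_factory(np.arange(10.0)), n_bins=0)


class TestPreferenceIndex:
    @pytest.mark.parametrize("z1,z2,expected", [
        (10.0, 10.0, 0.0),
        (10.0, 0.0, 1.0),
        (0.0, 10.0, -1.0),
        (3.0, 1.0, 0.5),
    ])
    def test_values(self, z1, z2, expected):
        assert kin.preference_index(z1, z2) == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            kin.preference_index(0.0, 0.0)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_bounds(self, z1, z2):
        if z1 + z2 <= 0:
            return
        assert -1.0 <= kin.preference_index(z1, z2) <= 1.0


class TestAngularEntropy:
    def test_straight_path_zero(self):
        x = np.linspace(0, 10, 100)
        y = np.full(100, 2.5)
        assert kin.angular_distribution_entropy(x, y) == pytest.approx(0.0)

    def test_uniform_headings_max_entropy(self):
        # a uniform heading histogram attains the maximum S = log(n_bins)
        n_bins = 36
        ang = (np.arange(n_bins) + 0.5) / n_bins * 2 * np.pi - np.pi
        s = kin.entropy_of_angles(ang, n_angle_bins=n_bins)
        assert s == pytest.approx(np.log(n_bins), rel=1e-9)
        bits = kin.entropy_of_angles(ang, n_angle_bins=n_bins, units="bits")
        assert bits == pytest.approx(np.log2(n_bins), rel=1e-9)

    def test_weaving_exceeds_straight(self):
        t = np.linspace(0, 10, 500)
        straight = kin.angular_distribution_entropy(t, np.zeros_like(t))
        weave = kin.angular_distribution_entropy(t, np.sin(4 * np.pi * t))
        assert straight < weave

    def test_entropy_bounds_and_units(self):
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.normal(0, 1, 400))
        y = np.cumsum(rng.normal(0, 1, 400))
        nats = kin.angular_distribution_entropy(x, y, n_angle_bins=36)
        bits = kin.angular_distribution_entropy(x, y, n_angle_bins=36, units="bits")
        assert 0.0 <= nats <= np.log(36)
        assert bits == pytest.approx(nats / np.log(2))

    def test_monotone_in_heading_noise(self):
        rng = np.random.default_rng(2)
        base = np.linspace(0, 50, 600)
        noise = np.cumsum(rng.normal(0, 1, 600)) * 0.05
        entropies = []
        for amp in (0.0, 0.05, 0.2, 0.8, 2.0):
            entropies.append(kin.angular_distribution_entropy(base, amp * noise))
        assert all(a <= b + 1e-9 for a, b in zip(entropies, entropies[1:]))

    def test_no_displacement_rejected(self):
        with pytest.raises(ValueError):
            kin.angular_distribution_entropy(np.zeros(10), np.zeros(10))
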