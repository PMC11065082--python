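"""Unit and property tests for the full-network firing-rate dynamics."""

import numpy as np
import pytest

from ringrecal.angles import TWO_PI, wrap_difference
from ringrecal.network_core import (
    NetworkParams,
    NetworkState,
    NoBumpError,
    RingGrid,
    VisualDrive,
    WeightKernel,
    bump_emergence_time,
    build_recurrent_kernel,
    circular_convolve,
    converge_bump,
    count_local_maxima,
    decode_bump_location,
    default_network,
    make_visual_drive,
    simulate_central_ring,
    simulate_full,
    step_central_ring,
    step_full_network,
)


class TestRingGrid:
    def test_angles_uniform_and_in_range(self):
        grid = RingGrid(64)
        a = grid.angles
        assert a[0] == 0.0 and a[-1] < TWO_PI
        assert np.allclose(np.diff(a), grid.spacing)

    def test_rejects_tiny_grids(self):
        with pytest.raises(ValueError):
            RingGrid(8)


class TestRecurrentKernel:
    def test_even_symmetry(self):
        k = build_recurrent_kernel(64)
        v = k.values
        assert np.allclose(v[1:], v[1:][::-1])  # kernel[j] == kernel[n-j]

    def test_zero_excitation_gives_pure_inhibition(self):
        k = build_recurrent_kernel(64, excit_amp=0.0, inhib_amp=0.7, normalize=False)
        assert np.allclose(k.values, -0.7)

    @pytest.mark.parametrize(
        "kwargs", [{"excit_width": 0.0}, {"excit_width": 4.0}, {"inhib_amp": -1.0}]
    )
    def test_rejects_bad_parameters(self, kwargs):
        with pytest.raises(ValueError):
            build_recurrent_kernel(64, **kwargs)

    def test_normalization_makes_bump_a_fixed_point(self):
        """The converged bump of the rectified map is neutral in amplitude."""
        k = build_recurrent_kernel(128)
        r = np.maximum(np.cos(TWO_PI * np.arange(128) / 128), 0.0)
        for _ in range(3000):
            r = np.maximum(circular_convolve(k, r), 0.0)
            r /= np.linalg.norm(r)
        growth = np.linalg.norm(np.maximum(circular_convolve(k, r), 0.0))
        assert growth == pytest.approx(1.0, abs=1e-9)


class TestCircularConvolve:
    def test_delta_input_returns_rotated_kernel(self):
        k = build_recurrent_kernel(64, normalize=False)
        delta = np.zeros(64)
        delta[5] = 1.0
        out = circular_convolve(k, delta)
        assert np.allclose(out, np.roll(k.values, 5) * (TWO_PI / 64), atol=1e-12)

    def test_rotation_equivariance(self, rng):
        k = build_recurrent_kernel(64)
        r = rng.uniform(0, 10, 64)
        assert np.allclose(
            circular_convolve(k, np.roll(r, 7)), np.roll(circular_convolve(k, r), 7)
        )

    def test_matches_double_loop_reference(self, rng):
        """FFT convolution agrees with the O(n^2) definition to 1e-12."""
        n = 48
        k = WeightKernel(values=rng.standard_normal(n))
        r = rng.uniform(0, 5, n)
        ref = np.zeros(n)
        for i in range(n):
            for j in range(n):
                ref[i] += k.values[(i - j) % n] * r[j]
        ref *= TWO_PI / n
        out = circular_convolve(k, r)
        assert np.max(np.abs(out - ref)) / np.max(np.abs(ref)) < 1e-12

    def test_grid_mismatch_rejected(self):
        k = build_recurrent_kernel(64)
        with pytest.raises(ValueError, match="grid mismatch"):
            circular_convolve(k, np.zeros(32))


class TestCentralRing:
    def test_zero_state_is_fixed_point(self):
        params = NetworkParams(grid=RingGrid(64))
        state = NetworkState(r_c=np.zeros(64), r_cw=np.zeros(64), r_ccw=np.zeros(64))
        out = step_central_ring(state, np.zeros(64), 1e-3, params)
        assert np.all(out.r_c == 0.0)

    @pytest.mark.parametrize("dt", [0.0, -1e-3, 0.02])
    def test_invalid_dt_rejected(self, dt):
        params = NetworkParams(grid=RingGrid(64))
        state = NetworkState(r_c=np.zeros(64), r_cw=np.zeros(64), r_ccw=np.zeros(64))
        with pytest.raises(ValueError):
            step_central_ring(state, np.zeros(64), dt, params)

    def test_bump_emerges_from_random_rates_within_100ms(self):
        """Single activity bump forms in under 100 ms of simulated time."""
        params = NetworkParams(grid=RingGrid(256))  # tau_c = 10 ms
        times, rates = simulate_central_ring(
            params, duration=0.1, dt=5e-4, seed=3, record_every=4
        )
        assert bump_emergence_time(times, rates) <= 0.1

    def test_converged_bump_fixed_point_residual(self):
        params = NetworkParams(grid=RingGrid(256))
        _, rates = simulate_central_ring(params, duration=20.0, seed=1, record_every=200)
        r = rates[-1]
        residual = np.linalg.norm(
            r - np.maximum(circular_convolve(params.kernel_cc, r), 0.0)
        ) / np.linalg.norm(r)
        assert residual < 1e-6

    def test_rates_stay_nonnegative(self, rng):
        params = NetworkParams(grid=RingGrid(64))
        state = NetworkState(
            r_c=rng.uniform(0, 30, 64), r_cw=np.zeros(64), r_ccw=np.zeros(64)
        )
        for _ in range(200):
            state = step_central_ring(state, rng.normal(0, 5, 64), 5e-4, params)
            assert np.all(state.r_c >= 0.0)


class TestDecode:
    def test_cosine_bump_decodes_to_its_center(self):
        angles = TWO_PI * np.arange(256) / 256
        rates = np.maximum(np.cos(angles - np.pi / 2), 0.0)
        assert decode_bump_location(rates) == pytest.approx(np.pi / 2, abs=1e-9)

    def test_rotation_shifts_decode_by_bin_multiples(self, rng):
        rates = np.maximum(np.cos(TWO_PI * np.arange(64) / 64), 0.0)
        for m in (1, 5, 33):
            got = decode_bump_location(np.roll(rates, m))
            assert wrap_difference(got - TWO_PI * m / 64) == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_rates_signal_no_bump(self):
        with pytest.raises(NoBumpError):
            decode_bump_location(np.zeros(64))

    def test_decode_robust_to_uniform_noise(self):
        """5% uniform noise moves the decode < 0.02 rad (100 seeded draws)."""
        n = 256
        angles = TWO_PI * np.arange(n) / n
        bump = np.maximum(np.cos(angles - 1.0), 0.0) * 40.0
        rng = np.random.default_rng(7)
        errs = [
            abs(wrap_difference(decode_bump_location(bump + rng.uniform(0, 2.0, n)) - 1.0))
            for _ in range(100)
        ]
        assert max(errs) < 0.02


class TestFullNetwork:
    def test_immobile_bump_does_not_drift(self, full_net):
        """Balanced rotation-ring input keeps theta invariant at v=0."""
        params, template, _ = full_net
        traj = simulate_full(params, 0.0, 5.0, template=template)
        theta = np.unwrap(traj.frame["theta"].to_numpy())
        assert abs(theta[-1] - theta[0]) < 0.01

    def test_bump_speed_tracks_calibrated_gain(self, full_net):
        params, template, _ = full_net
        v = 0.3
        traj = simulate_full(params, v, 3.0, template=template)
        theta = np.unwrap(traj.frame["theta"].to_numpy())
        t = traj.frame["t"].to_numpy()
        k = (theta[-1] - theta[0]) / (v * (t[-1] - t[0]))
        assert k == pytest.approx(1.0, rel=0.05)

    def test_visual_drive_pulls_bump_to_landmark(self, full_net):
        params, template, _ = full_net
        vis = make_visual_drive(params, amplitude=3.0, theta_star=1.0, template=template)
        traj = simulate_full(params, 0.0, 3.0, visual=vis, template=template)
        final = traj.frame["theta"].iloc[-1]
        assert abs(wrap_difference(final - 1.0)) < 0.05

    def test_rotation_equivariance_of_trajectory(self, full_net):
        """Rotating the initial bump by whole bins rotates the decoded path."""
        params, template, _ = full_net
        m = 32
        t1 = simulate_full(params, 0.4, 0.5, template=template)
        t2 = simulate_full(
            params, 0.4, 0.5, template=np.roll(template, m),
            initial_theta=m * params.grid.spacing,
        )
        d = wrap_difference(
            t2.frame["theta"].to_numpy() - t1.frame["theta"].to_numpy()
            - m * params.grid.spacing
        )
        assert np.max(np.abs(d)) < 1e-9

    def test_bump_shape_invariance_under_motion(self, full_net):
        """Moving bump stays a shifted copy of the template within 2% RMS."""
        params, template, _ = full_net
        state = NetworkState(
            r_c=template.copy(),
            r_cw=np.zeros(params.grid.n_neurons),
            r_ccw=np.zeros(params.grid.n_neurons),
        )
        dt = params.tau_c / 20.0
        for _ in range(int(2.0 / dt)):
            state = step_full_network(state, 0.5, None, dt, params)
        shift = params.grid.bin_of(decode_bump_location(state.r_c))
        aligned = np.roll(state.r_c, -shift)
        assert np.linalg.norm(aligned - template) / np.linalg.norm(template) < 0.02

    def test_out_of_range_velocity_warns(self, full_net):
        params, template, _ = full_net
        state = NetworkState(
            r_c=template.copy(),
            r_cw=np.zeros(params.grid.n_neurons),
            r_ccw=np.zeros(params.grid.n_neurons),
        )
        with pytest.warns(RuntimeWarning, match="linear range"):
            step_full_network(state, 2.0 * params.v_max, None, 1e-4, params)


class TestVisualDrive:
    def test_profile_is_unimodal_with_peak_at_offset_zero(self, full_net):
        params, template, _ = full_net
        vis = make_visual_drive(params, amplitude=2.0, template=template)
        assert np.argmax(vis.rho_vis) == 0
        assert count_local_maxima(vis.rho_vis) == 1

    def test_inactive_drive_injects_no_current(self, full_net):
        params, template, _ = full_net
        vis = make_visual_drive(params, amplitude=2.0, template=template)
        vis.active = False
        assert np.all(vis.current(params.grid) == 0.0)
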