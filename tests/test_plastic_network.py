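"""Tests for the plastic (recalibrating) ring attractor."""

import numpy as np
import pytest
from scipy import stats

from ringrecal.angles import TWO_PI, wrap_difference, wrap_position
from ringrecal.network_core import decode_bump_location
from ringrecal.plastic_network import (
    HebbianParams,
    build_error_code_wiring,
    error_code_response,
    error_tuning_sweep,
    estimate_pi_gain,
    hebbian_update_visual_association,
    run_error_correction_protocol,
)


def _bump(n, center_bin, width=20, amp=30.0):
    offs = np.minimum(
        np.abs(np.arange(n) - center_bin), n - np.abs(np.arange(n) - center_bin)
    )
    return amp * np.maximum(1.0 - offs / width, 0.0)


class TestErrorCodeWiring:
    """Standalone three-population motif: X3 rate encodes the X1/X2 bump offset."""

    def setup_method(self):
        self.n = 128
        self.wiring_ccw = build_error_code_wiring(0.8, "ccw", inhib_gain=0.5)
        self.wiring_cw = build_error_code_wiring(0.8, "cw", inhib_gain=0.5)

    def _mean_rate(self, wiring, diff_bins):
        x1 = _bump(self.n, 40)
        x2 = _bump(self.n, 40 + diff_bins)
        return float(error_code_response(wiring, x1, x2).mean())

    def test_monotonic_increase_with_ccw_difference(self):
        diffs = range(-8, 9, 2)
        rates = [self._mean_rate(self.wiring_ccw, d) for d in diffs]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_baseline_rate_strictly_between_extremes(self):
        base = self._mean_rate(self.wiring_ccw, 0)
        lo = self._mean_rate(self.wiring_ccw, -8)
        hi = self._mean_rate(self.wiring_ccw, 8)
        assert lo < base < hi

    def test_reversing_offset_direction_reverses_tuning(self):
        diffs = range(-8, 9, 2)
        slope_ccw = np.polyfit(list(diffs), [self._mean_rate(self.wiring_ccw, d) for d in diffs], 1)[0]
        slope_cw = np.polyfit(list(diffs), [self._mean_rate(self.wiring_cw, d) for d in diffs], 1)[0]
        assert slope_ccw > 0 > slope_cw

    def test_offset_bounds_enforced(self):
        with pytest.raises(ValueError):
            build_error_code_wiring(0.0, "ccw")
        with pytest.raises(ValueError):
            build_error_code_wiring(2.0, "ccw")


class TestVisualAssociationPlasticity:
    def test_silent_visual_ring_leaves_only_decay(self, trained_plastic_net):
        net = trained_plastic_net.snapshot()
        s = net.state
        s.r_vis = np.zeros_like(s.r_vis)
        before = s.W_vis_assoc.copy()
        hebbian_update_visual_association(s, net.hebb, dt=0.01)
        expected = np.clip(
            before * (1.0 - 0.01 * net.hebb.assoc_decay), 0.0, net.hebb.w_max_assoc
        )
        assert np.allclose(s.W_vis_assoc, expected)

    def test_training_builds_diagonal_band(self, trained_plastic_net):
        W = trained_plastic_net.state.W_vis_assoc
        n = W.shape[0]
        offs = (np.arange(n)[None, :] - np.arange(n)[:, None]) % n
        band = np.minimum(offs, n - offs) <= 8
        assert W[band].mean() > 2.0 * W[~band].mean()

    def test_association_bump_tracks_landmark_when_central_weakened(
        self, trained_plastic_net
    ):
        probe = trained_plastic_net.snapshot()
        probe.w_c_assoc *= 0.05
        theta = probe.decode()
        target = wrap_position(theta + 0.9)
        r_c_clamp = probe.state.r_c.copy()
        dt = probe.params.tau_c / 10.0
        for _ in range(int(0.3 / dt)):
            probe.step(0.0, target, landmarks_on=True, dt=dt)
            probe.state.r_c = r_c_clamp.copy()
        assoc_loc = decode_bump_location(probe.state.r_assoc)
        assert abs(wrap_difference(assoc_loc - target)) < 0.05

    def test_weights_stay_bounded(self, trained_plastic_net):
        W = trained_plastic_net.state.W_vis_assoc
        assert W.min() >= 0.0
        assert W.max() <= trained_plastic_net.hebb.w_max_assoc + 1e-12


class TestVelocityWeightPlasticity:
    def test_no_drift_at_rest_with_zero_error(self, trained_plastic_net):
        net = trained_plastic_net.snapshot()
        theta_star = net.decode()
        before_cw = net.state.W_v_cw.copy()
        before_ccw = net.state.W_v_ccw.copy()
        dt = net.params.tau_c / 10.0
        for _ in range(200):
            net.step(0.0, theta_star, landmarks_on=True, dt=dt, plastic_velocity=True)
        assert np.mean(net.state.W_v_cw) == pytest.approx(np.mean(before_cw), rel=1e-4)
        assert np.mean(net.state.W_v_ccw) == pytest.approx(np.mean(before_ccw), rel=1e-4)

    def test_positive_error_times_velocity_potentiates_both_weights(
        self, trained_plastic_net
    ):
        """Sustained theta~ * v > 0 raises the mean of both CW and CCW weights."""
        net = trained_plastic_net.snapshot()
        before = np.mean(net.state.W_v_cw) + np.mean(net.state.W_v_ccw)
        dt = net.params.tau_c / 10.0
        v = 0.5
        theta_star = net.decode()
        for _ in range(int(5.0 / dt)):
            # landmarks move faster than the bump: persistent positive error
            theta_star = wrap_position(theta_star + 1.5 * v * dt)
            net.step(v, theta_star, landmarks_on=True, dt=dt, plastic_velocity=True)
        after = np.mean(net.state.W_v_cw) + np.mean(net.state.W_v_ccw)
        assert after > before


class TestErrorRateCode:
    def test_rotation_ring_tuning_is_monotone_in_error(self, trained_plastic_net):
        """CCW ring rate rises and CW falls with imposed error (17-point sweep)."""
        df = error_tuning_sweep(trained_plastic_net, np.linspace(-0.4, 0.4, 17))
        rho_ccw = stats.spearmanr(df.theta_tilde, df.mean_rate_ccw).statistic
        rho_cw = stats.spearmanr(df.theta_tilde, df.mean_rate_cw).statistic
        assert rho_ccw > 0.95
        assert rho_cw < -0.95


class TestErrorCorrection:
    def test_landmark_jump_is_corrected(self, trained_plastic_net):
        traj = run_error_correction_protocol(
            0.5, net=trained_plastic_net, duration=4.0
        )
        assert abs(traj.meta["final_error"]) < 0.12
        fr = traj.frame
        # early differential rotation-ring response pushes the bump CCW
        early = fr[(fr.t > 0.05) & (fr.t < 0.5)]
        assert (early.mean_rate_ccw - early.mean_rate_cw).mean() > 0.0

    def test_zero_offset_leaves_rates_balanced(self, trained_plastic_net):
        traj = run_error_correction_protocol(
            0.0, net=trained_plastic_net, duration=1.0
        )
        fr = traj.frame
        drift = abs(wrap_difference(fr.theta.iloc[-1] - fr.theta.iloc[0]))
        assert drift < 0.12


class TestGainProbe:
    def test_reduced_closed_form_recovery(self):
        """Unwrapped displacement over v*T recovers a known constant gain."""
        from ringrecal.plastic_network import pi_gain_from_theta

        t = np.linspace(0, 10, 2001)
        theta = wrap_position(0.3 + 1.27 * 0.4 * t)
        assert pi_gain_from_theta(t, theta, 0.4) == pytest.approx(1.27, abs=1e-6)

    def test_probe_rejects_zero_velocity(self, trained_plastic_net):
        with pytest.raises(ValueError):
            estimate_pi_gain(trained_plastic_net, probe_v=0.0)

    def test_trained_network_probe_reads_unit_gain(self, trained_plastic_net):
        gain = estimate_pi_gain(trained_plastic_net, probe_v=0.5)
        assert gain == pytest.approx(1.0, abs=0.02)

    def test_full_network_probe_matches_analytic_average(self, full_net):
        """Landmark-extinction probe agrees with the analytic spatial average."""
        from ringrecal.reduced_model import compute_pi_gain_profile, spatial_average

        params, template, rot = full_net
        k0_pred = spatial_average(compute_pi_gain_profile(params, template, rot))
        k0_meas = estimate_pi_gain(params, probe_v=0.3, n_laps=1.0)
        assert k0_meas == pytest.approx(k0_pred, rel=0.05)


class TestStability:
    def test_rates_and_weights_bounded_under_plasticity(self, trained_plastic_net):
        net = trained_plastic_net.snapshot()
        dt = net.params.tau_c / 10.0
        theta_star = net.decode()
        v = 0.5
        peak0 = net.state.r_c.max()
        for _ in range(int(20.0 / dt)):
            theta_star = wrap_position(theta_star + 1.3 * v * dt)
            net.step(v, theta_star, landmarks_on=True, dt=dt, plastic_velocity=True)
        assert np.isfinite(net.state.r_c).all()
        assert net.state.r_c.max() < 5.0 * peak0
        hi = net.hebb.w_v_max_frac * net.w_v_init
        assert net.state.W_v_cw.max() <= hi + 1e-9
        assert net.state.W_v_ccw.max() <= hi + 1e-9


class TestMechanisticProbe:
    def test_probe_report_detects_instantaneous_error_code(
        self, trained_plastic_net
    ):
        """During error correction the CCW (CW) mean rate co-varies positively
        (negatively) with the instantaneous positional error."""
        from ringrecal.gain_adaptation import mechanistic_probe_report

        traj = run_error_correction_protocol(
            0.5, net=trained_plastic_net, duration=4.0
        )
        rep = mechanistic_probe_report(traj, seed=1)
        inst = rep["instantaneous_error_code"]
        assert inst["ccw"]["spearman_vs_error"] > 0.5
        assert inst["cw"]["spearman_vs_error"] < -0.5
        assert abs(inst["ccw"]["shuffled_control"]) < 0.3

    def test_short_probe_flags_local_bias(self, trained_plastic_net):
        with pytest.warns(RuntimeWarning, match="less than one lap"):
            estimate_pi_gain(trained_plastic_net, probe_v=0.5, n_laps=0.5)
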