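"""Modified ring attractor with an explicit error-rate code and Hebbian plasticity.

Three modifications turn the classical three-ring attractor into a network
that recalibrates its own path-integration gain:

1. an *association ring* between the visual ring and the attractor: weak,
   hardwired topographic input from the central ring plus plastic input from
   the visual ring, so Hebbian potentiation learns a flexible landmark-to-
   position mapping and the association ring becomes a visually driven proxy
   of the animal's true position;
2. *offset inhibitory* connections from the association ring onto the
   rotation rings (CCW offset to the CCW ring, CW offset to the CW ring):
   combined with the topographic excitatory central-ring input, each rotation
   ring fires as a monotonic function of the positional error
   ``theta~ = theta* - theta`` -- the CCW ring increases and the CW ring
   decreases with it.  This same differential modulation acts like a virtual
   velocity signal, re-aligning the bump with the landmarks (error
   correction);
3. *plastic velocity-to-rotation weights*: covariance-style Hebbian updates
   driven by the baseline-subtracted velocity-neuron rate (pre) and rotation
   ring rate (post).  Because pre encodes ``+/-v`` and post encodes
   ``+/-theta~``, the mean weight -- and with it the PI gain -- moves in the
   direction of ``theta~ * v``, satisfying the recalibration sign condition.
   The residual velocity modulation of the rotation rings adds a ``v^2`` bias
   term, so recalibration is stable but slightly imperfect, settling between
   the initial gain and the visual gain ``k*``.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import TWO_PI, wrap_difference, wrap_position
from .network_core import (
    NetworkParams,
    NetworkState,
    _relu,
    _velocity_rates,
    circular_convolve,
    converge_bump,
    decode_bump_location,
    default_network,
    rotation_feedback,
    rotation_ring_rates,
)

__all__ = [
    "ErrorCodeWiring",
    "HebbianParams",
    "PlasticNetworkState",
    "PlasticNetwork",
    "build_error_code_wiring",
    "error_code_response",
    "build_plastic_network",
    "train_association",
    "hebbian_update_visual_association",
    "hebbian_update_velocity_weights",
    "run_recalibration_protocol",
    "run_error_correction_protocol",
    "estimate_pi_gain",
    "error_tuning_sweep",
    "pi_gain_from_theta",
]


@dataclass
class ErrorCodeWiring:
    """Excitatory topographic + inhibitory offset wiring onto a readout ring.

    The readout population (X3) receives zero-offset excitation from X1 and
    inhibition from X2 through connections offset by ``offset`` radians in
    the given direction.  Its mean rate then grows (ccw offset) or falls
    (cw offset) monotonically with the bump-location difference ``x2 - x1``.
    """

    offset: float
    direction: str
    excit_gain: float = 1.0
    inhib_gain: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.offset < np.pi / 2):
            raise ValueError("offset must lie in (0, pi/2)")
        if self.direction not in ("cw", "ccw"):
            raise ValueError("direction must be 'cw' or 'ccw'")

    def offset_bins(self, n: int) -> int:
        bins = max(1, int(round(self.offset / (TWO_PI / n))))
        return bins if self.direction == "ccw" else -bins

    def inhibitory_current(self, r_x2: np.ndarray) -> np.ndarray:
        """Inhibition delivered to X3 at each angle (offset-shifted X2 activity)."""
        n = r_x2.shape[0]
        return self.inhib_gain * np.roll(r_x2, self.offset_bins(n))


def build_error_code_wiring(
    offset: float, direction: str, excit_gain: float = 1.0, inhib_gain: float = 1.0
) -> ErrorCodeWiring:
    """Wiring whose readout rate varies monotonically with a bump-location difference."""
    return ErrorCodeWiring(
        offset=offset, direction=direction, excit_gain=excit_gain, inhib_gain=inhib_gain
    )


def error_code_response(
    wiring: ErrorCodeWiring,
    r_x1: np.ndarray,
    r_x2: np.ndarray,
    threshold: float = 0.0,
) -> np.ndarray:
    """Rectified X3 rates: ``relu(excit * x1 - offset-shifted inhib * x2 - threshold)``."""
    return _relu(
        wiring.excit_gain * r_x1 - wiring.inhibitory_current(r_x2) - threshold
    )


@dataclass
class HebbianParams:
    """Learning rates and bounds of the two plastic pathways."""

    lr_assoc: float = 0.3  # visual->association potentiation (1/s, normalized pre/post)
    lr_velocity: float = 5e-5  # velocity-weight learning rate (1/s per Hz^2)
    assoc_decay: float = 0.05  # weight decay of the association matrix (1/s)
    w_max_assoc: float = 1.5
    w_v_min_frac: float = 0.2  # velocity-weight bounds, fractions of initial value
    w_v_max_frac: float = 4.0
    v_baseline_gamma: float = 1.0  # velocity weighting of the plasticity baseline

    def __post_init__(self):
        if self.lr_assoc < 0 or self.lr_velocity < 0 or self.assoc_decay < 0:
            raise ValueError("learning/decay rates must be nonnegative")


@dataclass
class PlasticNetworkState:
    """Network state extended with the visual/association rings and plastic weights."""

    r_c: np.ndarray
    r_cw: np.ndarray
    r_ccw: np.ndarray
    r_vis: np.ndarray
    r_assoc: np.ndarray
    W_vis_assoc: np.ndarray  # (n_assoc, n_vis) plastic matrix, bounded >= 0
    W_v_cw: np.ndarray  # plastic velocity-sensitivity vectors
    W_v_ccw: np.ndarray
    t: float = 0.0


class PlasticNetwork:
    """Bundle of parameters, wiring, templates and state; integrates the model.

    ``params.w_v_cw`` / ``params.w_v_ccw`` alias the plastic weight vectors in
    the state, so weight updates take effect immediately in the dynamics.
    """

    def __init__(
        self,
        params: NetworkParams,
        wiring_ccw: ErrorCodeWiring,
        wiring_cw: ErrorCodeWiring,
        hebb: HebbianParams,
        tau_assoc: float = 0.005,
        w_c_assoc: float = 0.35,
        vis_amplitude: float = 30.0,
        I_assoc: float = 16.0,
        seed: int = 0,
    ):
        self.params = params
        self.wiring_ccw = wiring_ccw
        self.wiring_cw = wiring_cw
        self.hebb = hebb
        self.tau_assoc = tau_assoc
        self.w_c_assoc = w_c_assoc
        self.I_assoc = I_assoc
        n = params.grid.n_neurons
        rng = np.random.default_rng(seed)

        # visual ring template: cosine bump, peak `vis_amplitude`, width ~ central bump
        angles = params.grid.angles
        prof = np.cos(angles) - np.cos(1.0)
        self.vis_template = vis_amplitude * _relu(prof) / max(float(np.max(prof)), 1e-12)

        bump = converge_bump(params, theta=0.0)
        self.bump_template = bump
        self.w_v_init = float(np.mean(params.w_v_cw))

        self.state = PlasticNetworkState(
            r_c=bump.copy(),
            r_cw=np.zeros(n),
            r_ccw=np.zeros(n),
            r_vis=np.zeros(n),
            r_assoc=np.zeros(n),
            W_vis_assoc=rng.uniform(0.0, 0.04 * hebb.w_max_assoc, size=(n, n)),
            W_v_cw=params.w_v_cw.copy(),
            W_v_ccw=params.w_v_ccw.copy(),
            t=0.0,
        )
        # dynamics read the plastic vectors directly
        self.params.w_v_cw = self.state.W_v_cw
        self.params.w_v_ccw = self.state.W_v_ccw
        self.rot_base_cw = None
        self.rot_base_ccw = None
        self.motion_ref_v = 0.5  # reference speed of the motion-offset calibration
        self.motion_ref_offset = (0.0, 0.0)  # (d at -v_ref, d at +v_ref)
        self.refresh_baselines()

    # -- construction ------------------------------------------------------

    def refresh_baselines(self, settle: float = 0.3):
        """Recompute the zero-error baseline templates (landmarks on, v=0).

        Stores the settled central-bump and association-ring profiles aligned
        to bin 0; :meth:`velocity_baselines` evaluates from them the
        rotation-ring rates expected at any velocity with zero positional
        error, which is what the covariance plasticity rule subtracts.
        """
        saved = copy.deepcopy(self.state)
        theta0 = decode_bump_location(self.state.r_c)
        for _ in range(int(round(settle / (self.params.tau_c / 10.0)))):
            self.step(0.0, theta0, landmarks_on=True, dt=self.params.tau_c / 10.0)
        shift = -self.params.grid.bin_of(decode_bump_location(self.state.r_c))
        self.bump_base = np.roll(self.state.r_c, shift)
        self.assoc_base = np.roll(self.state.r_assoc, shift)
        self.rot_base_cw = np.roll(self.state.r_cw, shift)
        self.rot_base_ccw = np.roll(self.state.r_ccw, shift)
        self.state = saved
        self.params.w_v_cw = self.state.W_v_cw
        self.params.w_v_ccw = self.state.W_v_ccw

    def velocity_baselines(self, v: float, theta: float) -> tuple[np.ndarray, np.ndarray]:
        """Expected (CW, CCW) rotation rates at zero positional error.

        Evaluated algebraically from the *current* central-ring activity with
        the zero-error association profile rotated to the bump location, so
        the moving bump's shape distortion cancels between the actual rates
        and the baseline and the residual covariance isolates the error-code
        response.  ``v_baseline_gamma`` slightly over-weights the velocity
        term, leaving a small negative velocity bias: recalibration is then
        stable but settles short of the visual gain, matching the partial
        recalibration seen experimentally.
        """
        assoc = self.state.r_assoc
        if float(assoc.sum()) > 1e-9:
            # translate the *actual* association profile to the zero-error
            # position: amplitude and shape then cancel exactly and only the
            # positional displacement -- the error -- drives the covariance.
            # The zero-error reference includes the velocity-dependent
            # alignment offset measured under veridical motion (a moving bump
            # is tilted, displacing the population-vector decode).
            d_m, d_p = self.motion_ref_offset
            d_v = (v / self.motion_ref_v) * d_p if v >= 0 else (-v / self.motion_ref_v) * d_m
            shift = self.params.grid.bin_of(theta + d_v) - self.params.grid.bin_of(
                decode_bump_location(assoc)
            )
            assoc = np.roll(assoc, shift)
        return rotation_ring_rates(
            self.state.r_c,
            self.hebb.v_baseline_gamma * v,
            self.params,
            inhib_cw=self.wiring_cw.inhibitory_current(assoc),
            inhib_ccw=self.wiring_ccw.inhibitory_current(assoc),
        )

    def calibrate_motion_reference(self, v_ref: float = 0.5, duration: float = 6.0):
        """Measure the veridical-motion alignment offset of the association decode.

        Runs the network with landmarks moving veridically (k* = 1) at
        ``+/-v_ref`` and records the mean displacement between the
        association-ring and central-ring decodes once transients settle.
        The covariance plasticity treats this displacement as "zero error",
        so only genuine landmark conflicts drive recalibration.
        """
        offsets = []
        for sign in (-1.0, 1.0):
            probe = self.snapshot()
            v = sign * v_ref
            theta_star = probe.decode()
            dt = probe.params.tau_c / 10.0
            ds = []
            n_steps = int(round(duration / dt))
            for i in range(n_steps):
                theta_star = wrap_position(theta_star + v * dt)
                probe.step(v, theta_star, landmarks_on=True, dt=dt)
                if i > n_steps // 3 and i % 20 == 0:
                    ds.append(
                        wrap_difference(
                            decode_bump_location(probe.state.r_assoc)
                            - decode_bump_location(probe.state.r_c)
                        )
                    )
            offsets.append(float(np.mean(ds)))
        self.motion_ref_v = v_ref
        self.motion_ref_offset = (offsets[0], offsets[1])
        return self.motion_ref_offset

    # -- dynamics ----------------------------------------------------------

    def visual_rates(self, theta_star: float, landmarks_on: bool) -> np.ndarray:
        if not landmarks_on:
            return np.zeros(self.params.grid.n_neurons)
        return np.roll(self.vis_template, self.params.grid.bin_of(theta_star))

    def step(
        self,
        v: float,
        theta_star: float,
        landmarks_on: bool,
        dt: float,
        plastic_assoc: bool = False,
        plastic_velocity: bool = False,
    ):
        """One Euler step of all rings, optionally applying plasticity."""
        p, s = self.params, self.state
        dpsi = p.grid.spacing
        s.r_vis = self.visual_rates(theta_star, landmarks_on)

        # association ring: weak hardwired central input + plastic visual input
        I_assoc_in = (
            self.w_c_assoc * s.r_c
            + (s.W_vis_assoc @ s.r_vis) * dpsi
            - self.I_assoc
        )
        r_assoc_inf = _relu(I_assoc_in)
        s.r_assoc = s.r_assoc + (dt / self.tau_assoc) * (r_assoc_inf - s.r_assoc)

        # rotation rings with offset inhibition from the association ring
        inhib_ccw = self.wiring_ccw.inhibitory_current(s.r_assoc)
        inhib_cw = self.wiring_cw.inhibitory_current(s.r_assoc)
        r_cw, r_ccw = rotation_ring_rates(
            s.r_c, v, p, inhib_cw=inhib_cw, inhib_ccw=inhib_ccw
        )
        s.r_cw, s.r_ccw = r_cw, r_ccw

        # plasticity baseline from the same pre-update central rates the
        # rotation rings saw, so the moving-bump distortion cancels exactly
        if plastic_velocity:
            baselines = self.velocity_baselines(v, decode_bump_location(s.r_c))

        # central ring: recurrent + offset rotation feedback (no direct visual input)
        I_ext = rotation_feedback(r_cw, r_ccw, p)
        drive = _relu(circular_convolve(p.kernel_cc, s.r_c) + I_ext)
        s.r_c = s.r_c + (dt / p.tau_c) * (drive - s.r_c)
        s.t += dt

        if plastic_assoc and landmarks_on:
            hebbian_update_visual_association(s, self.hebb, dt)
        if plastic_velocity:
            hebbian_update_velocity_weights(
                s, v, self.hebb, dt, net_params=p, baselines=baselines
            )

    def decode(self) -> float:
        return decode_bump_location(self.state.r_c)

    def mean_gain_weights(self) -> tuple[float, float]:
        return float(np.mean(self.state.W_v_cw)), float(np.mean(self.state.W_v_ccw))

    def snapshot(self) -> "PlasticNetwork":
        """Deep copy whose aliased weight views are re-established."""
        clone = copy.copy(self)
        clone.params = self.params.copy()
        clone.state = copy.deepcopy(self.state)
        clone.params.w_v_cw = clone.state.W_v_cw
        clone.params.w_v_ccw = clone.state.W_v_ccw
        return clone


def hebbian_update_visual_association(
    state: PlasticNetworkState, params: HebbianParams, dt: float
) -> PlasticNetworkState:
    """Hebbian potentiation of the visual-to-association matrix, with decay and bounds.

    ``dW[i, j] ∝ r_assoc[i] * r_vis[j] * dt`` (rates normalized by their
    maxima so the learning rate is dimensionless), then decay toward 0 and
    clipping to ``[0, w_max_assoc]`` keep the matrix bounded.
    """
    pre_peak = float(np.max(state.r_vis))
    if pre_peak > 0.0:
        post_peak = max(float(np.max(state.r_assoc)), 1e-9)
        outer = np.outer(state.r_assoc / post_peak, state.r_vis / pre_peak)
        state.W_vis_assoc += dt * params.lr_assoc * params.w_max_assoc * outer
    state.W_vis_assoc -= dt * params.assoc_decay * state.W_vis_assoc
    np.clip(state.W_vis_assoc, 0.0, params.w_max_assoc, out=state.W_vis_assoc)
    return state


def hebbian_update_velocity_weights(
    state: PlasticNetworkState,
    v: float,
    params: HebbianParams,
    dt: float,
    *,
    net_params: NetworkParams = None,
    baselines=None,
) -> PlasticNetworkState:
    """Covariance-style Hebbian update of the plastic velocity weights.

    ``dW_v_cw[j] ∝ (u_cw(v) - u_cw0) * (r_cw[j] - baseline_cw[j]) * dt`` and
    analogously for CCW.  ``baselines`` are the zero-error rotation-ring
    rates expected at the current velocity and bump location (see
    :meth:`PlasticNetwork.velocity_baselines`), so immobility -- and motion
    with zero positional error -- produces (almost) no drift.  Weights are
    clipped to ``[w_v_min_frac, w_v_max_frac]`` times their initial mean.
    """
    p = net_params
    if p is None or baselines is None:
        raise ValueError("network params and baseline templates are required")
    b_cw, b_ccw = baselines
    u_cw, u_ccw = _velocity_rates(v, p)
    w0 = max(float(np.mean(p.w_v_cw) + np.mean(p.w_v_ccw)) / 2.0, 1e-12)
    lo, hi = params.w_v_min_frac * w0, params.w_v_max_frac * w0
    state.W_v_cw += dt * params.lr_velocity * (u_cw - p.u_cw0) * (state.r_cw - b_cw)
    state.W_v_ccw += dt * params.lr_velocity * (u_ccw - p.u_ccw0) * (state.r_ccw - b_ccw)
    np.clip(state.W_v_cw, lo, hi, out=state.W_v_cw)
    np.clip(state.W_v_ccw, lo, hi, out=state.W_v_ccw)
    return state


# ---------------------------------------------------------------------------
# Construction and protocols


def build_plastic_network(
    n: int = 128,
    offset: float | None = None,
    inhib_gain: float = 0.2,
    hebb: HebbianParams | None = None,
    seed: int = 0,
    calibrate_probe: bool = True,
    **network_overrides,
) -> PlasticNetwork:
    """Plastic ring attractor with unit PI gain and default error-code wiring.

    ``offset`` is the association-to-rotation connection offset in radians
    (default: 3 grid bins at n=128), setting the steepness of the error-rate
    code.  With ``calibrate_probe`` the velocity weights are trimmed so the
    landmark-extinction probe reads gain 1 at the network's actual operating
    point (the association-ring inhibition shifts the rotation rings relative
    to the bare network, which the analytic calibration alone cannot see).
    """
    network_overrides.setdefault("b_bins", -max(1, round(6 * n / 256)))
    network_overrides.setdefault("w_cw_c", -0.2)
    network_overrides.setdefault("w_ccw_c", -0.2)
    network_overrides.setdefault("I_bar", 45.0)
    network_overrides.setdefault("recurrent_gain", 1.16)
    params = default_network(n=n, calibrate_gain=1.0, **network_overrides)
    if offset is None:
        offset = 1.0
    wiring_ccw = build_error_code_wiring(offset, "ccw", inhib_gain=inhib_gain)
    wiring_cw = build_error_code_wiring(offset, "cw", inhib_gain=inhib_gain)
    net = PlasticNetwork(
        params=params,
        wiring_ccw=wiring_ccw,
        wiring_cw=wiring_cw,
        hebb=hebb or HebbianParams(),
        seed=seed,
    )
    if calibrate_probe:
        for _ in range(2):  # second pass absorbs mild nonlinearity of the probe
            gain = estimate_pi_gain(net, probe_v=0.5)
            if gain <= 0:
                raise RuntimeError("probe gain non-positive; cannot calibrate")
            net.state.W_v_cw /= gain
            net.state.W_v_ccw /= gain
        net.w_v_init = float(np.mean(net.state.W_v_cw))
        net.refresh_baselines()
    return net


def train_association(
    net: PlasticNetwork,
    duration: float = 120.0,
    v: float = 0.5,
    dt: float | None = None,
    lap_time: float | None = None,
) -> PlasticNetwork:
    """Novel-environment phase: learn the landmark-to-position mapping.

    The animal explores with veridical landmarks (``k* = 1``), alternating
    running direction every lap so the learned association is symmetric (a
    moving bump is slightly tilted, and unidirectional exposure would imprint
    that tilt into the map as a systematic positional bias).  Only the
    visual-to-association pathway is plastic.  Rotation-ring baselines are
    refreshed afterwards (the association ring's drive changes as it becomes
    visually dominated).
    """
    dt = net.params.tau_c / 10.0 if dt is None else dt
    if lap_time is None:
        lap_time = TWO_PI / abs(v) if v else duration
    theta_star = decode_bump_location(net.state.r_c)
    n_steps = int(round(duration / dt))
    steps_per_lap = max(1, int(round(lap_time / dt)))
    for i in range(n_steps):
        v_t = v if (i // steps_per_lap) % 2 == 0 else -v
        theta_star = wrap_position(theta_star + v_t * dt)
        net.step(v_t, theta_star, landmarks_on=True, dt=dt, plastic_assoc=True)
    net.refresh_baselines()
    # trim the velocity weights so the landmark-extinction probe reads unit
    # gain at the trained operating point (the now visually driven
    # association ring shifts the rotation rings' working range slightly)
    gain = estimate_pi_gain(net, probe_v=abs(v) if v else 0.5)
    net.state.W_v_cw /= gain
    net.state.W_v_ccw /= gain
    net.w_v_init = float(np.mean(net.state.W_v_cw))
    net.refresh_baselines()
    net.calibrate_motion_reference(v_ref=abs(v) if v else 0.5)
    return net


def pi_gain_from_theta(t: np.ndarray, theta: np.ndarray, v: float) -> float:
    """PI gain from a decoded bump trajectory at constant probe velocity."""
    theta_unwrapped = np.unwrap(np.asarray(theta, float))
    return float((theta_unwrapped[-1] - theta_unwrapped[0]) / (v * (t[-1] - t[0])))


def estimate_pi_gain(
    network,
    probe_v: float = 0.5,
    probe_T: float | None = None,
    dt: float | None = None,
    n_laps: float = 1.0,
) -> float:
    """Landmark-extinction probe of the PI gain.

    Runs a copy of the network with landmarks off and plasticity frozen at
    constant ``probe_v``, and returns decoded ``delta theta / (v * T)``.  By
    default the probe covers one nominal lap so spatial gain inhomogeneity
    averages out; a shorter probe on an inhomogeneous network yields a biased
    (local) estimate.
    """
    if probe_v == 0.0:
        raise ValueError("probe velocity must be nonzero")
    if probe_T is None:
        probe_T = abs(n_laps * TWO_PI / probe_v)
    if abs(probe_T * probe_v) < TWO_PI:
        warnings.warn(
            "gain probe covers less than one lap: the estimate is local and "
            "biased if the gain profile is spatially inhomogeneous",
            RuntimeWarning,
            stacklevel=2,
        )
    if isinstance(network, PlasticNetwork):
        net = network.snapshot()
        dt = net.params.tau_c / 10.0 if dt is None else dt
        n_steps = int(round(probe_T / dt))
        times = [net.state.t]
        thetas = [net.decode()]
        for i in range(n_steps):
            net.step(probe_v, 0.0, landmarks_on=False, dt=dt)
            if (i + 1) % 10 == 0:
                times.append(net.state.t)
                thetas.append(net.decode())
        return pi_gain_from_theta(np.asarray(times), np.asarray(thetas), probe_v)
    # plain NetworkParams: probe the unconstrained network
    from .network_core import simulate_full

    traj = simulate_full(network, probe_v, probe_T, visual=None, dt=dt, record_dt=0.01)
    return pi_gain_from_theta(
        traj.frame["t"].to_numpy(), traj.frame["theta"].to_numpy(), probe_v
    )


def run_recalibration_protocol(
    k_star: float,
    duration: float = 480.0,
    velocity: float = 0.5,
    net: PlasticNetwork | None = None,
    seed: int = 0,
    dt: float | None = None,
    probe_interval: float = 120.0,
    probe_laps: float = 1.0,
    record_dt: float = 0.5,
    train_duration: float = 120.0,
):
    """Gain-recalibration session: landmarks move at ``k* * v``; weights adapt.

    If ``net`` is None a fresh network is built and association-trained first.
    The PI gain is probed (landmarks off, plasticity frozen, on a copy of the
    network) at ``probe_interval`` spacing and once more at the end.  Returns
    a :class:`~ringrecal.analysis_io.Trajectory` whose metadata includes
    ``gain_initial`` and ``gain_final``.
    """
    from .analysis_io import Trajectory

    if net is None:
        net = build_plastic_network(seed=seed)
        train_association(net, duration=train_duration, v=velocity)
    dt = net.params.tau_c / 10.0 if dt is None else dt
    v_of_t = velocity if callable(velocity) else (lambda t, _v=float(velocity): _v)

    gain_initial = estimate_pi_gain(net, probe_v=0.5, n_laps=probe_laps)
    theta_star = net.decode()
    t0 = net.state.t  # report session-relative times
    n_steps = int(round(duration / dt))
    record_every = max(1, int(round(record_dt / dt)))
    probe_every = int(round(probe_interval / dt)) if probe_interval else 0
    rows = []
    probes = [(0.0, gain_initial)]

    def _record(t, v, gain=np.nan):
        theta = net.decode()
        rows.append(
            (
                t,
                v,
                theta,
                wrap_position(theta_star),
                wrap_difference(theta_star - theta),
                gain,
                float(net.state.r_cw.mean()),
                float(net.state.r_ccw.mean()),
                *net.mean_gain_weights(),
            )
        )

    _record(0.0, float(v_of_t(0.0)), gain_initial)
    for i in range(n_steps):
        t = i * dt
        v = float(v_of_t(t))
        theta_star = wrap_position(theta_star + k_star * v * dt)
        net.step(
            v, theta_star, landmarks_on=True, dt=dt,
            plastic_assoc=False, plastic_velocity=True,
        )
        if probe_every and (i + 1) % probe_every == 0:
            probes.append(
                (net.state.t - t0, estimate_pi_gain(net, probe_v=0.5, n_laps=probe_laps))
            )
            _record(net.state.t - t0, v, probes[-1][1])
        elif (i + 1) % record_every == 0:
            _record(net.state.t - t0, v)

    gain_final = estimate_pi_gain(net, probe_v=0.5, n_laps=probe_laps)
    probes.append((net.state.t - t0, gain_final))
    df = pd.DataFrame(
        rows,
        columns=[
            "t", "v", "theta", "theta_star", "theta_tilde", "gain_estimate",
            "mean_rate_cw", "mean_rate_ccw", "mean_w_v_cw", "mean_w_v_ccw",
        ],
    )
    meta = {
        "kind": "plastic_recalibration",
        "k_star": k_star,
        "seed": seed,
        "gain_initial": gain_initial,
        "gain_final": gain_final,
        "probes": probes,
        "duration": duration,
    }
    return Trajectory(frame=df, meta=meta)


def run_error_correction_protocol(
    initial_offset: float,
    net: PlasticNetwork | None = None,
    seed: int = 0,
    duration: float = 4.0,
    dt: float | None = None,
    record_dt: float = 0.01,
    train_duration: float = 120.0,
):
    """Abrupt landmark jump with plasticity frozen: landmarks re-align the bump.

    The landmark position is displaced by ``initial_offset`` from the bump;
    the offset association-ring inhibition turns the resulting error into a
    differential rotation-ring signal (a virtual velocity) that drives
    ``theta`` back to ``theta*``.
    """
    from .analysis_io import Trajectory

    if net is None:
        net = build_plastic_network(seed=seed)
        train_association(net, duration=train_duration)
    else:
        net = net.snapshot()
    dt = net.params.tau_c / 10.0 if dt is None else dt
    theta_star = wrap_position(net.decode() + initial_offset)
    t0 = net.state.t  # report protocol-relative times
    n_steps = int(round(duration / dt))
    record_every = max(1, int(round(record_dt / dt)))
    rows = []

    def _record(t):
        theta = net.decode()
        rows.append(
            (
                t, 0.0, theta, theta_star,
                wrap_difference(theta_star - theta),
                float(net.state.r_cw.mean()),
                float(net.state.r_ccw.mean()),
            )
        )

    _record(0.0)
    for i in range(n_steps):
        net.step(0.0, theta_star, landmarks_on=True, dt=dt)
        if (i + 1) % record_every == 0:
            _record(net.state.t - t0)
    df = pd.DataFrame(
        rows,
        columns=["t", "v", "theta", "theta_star", "theta_tilde",
                 "mean_rate_cw", "mean_rate_ccw"],
    )
    meta = {
        "kind": "error_correction",
        "initial_offset": initial_offset,
        "seed": seed,
        "final_error": rows[-1][4],
    }
    return Trajectory(frame=df, meta=meta)


def error_tuning_sweep(
    net: PlasticNetwork,
    errors: np.ndarray,
    settle: float = 0.2,
    dt: float | None = None,
) -> pd.DataFrame:
    """Rotation-ring mean rates as a function of an imposed positional error.

    The central bump is clamped while the landmark bump is held at
    ``theta + error``; the association and rotation rings settle to their
    quasi-static response.  Returns a frame with columns
    ``theta_tilde, mean_rate_cw, mean_rate_ccw``.
    """
    dt = net.params.tau_c / 10.0 if dt is None else dt
    n_settle = int(round(settle / dt))
    records = []
    for err in np.atleast_1d(errors):
        probe = net.snapshot()
        theta = probe.decode()
        r_c_clamp = probe.state.r_c.copy()
        theta_star = wrap_position(theta + err)
        for _ in range(n_settle):
            probe.step(0.0, theta_star, landmarks_on=True, dt=dt)
            probe.state.r_c = r_c_clamp.copy()
        records.append(
            (
                float(err),
                float(probe.state.r_cw.mean()),
                float(probe.state.r_ccw.mean()),
            )
        )
    return pd.DataFrame(records, columns=["theta_tilde", "mean_rate_cw", "mean_rate_ccw"])
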