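"""Firing-rate dynamics of the unconstrained ring attractor network.

The network has a central ring whose recurrent connectivity (local excitation,
global inhibition) sustains a persistent activity bump, plus clockwise (CW)
and counter-clockwise (CCW) rotation rings that conjoin the bump position with
velocity-neuron input and push-pull the bump through one-to-one feedback
connections offset by ``+/-b``.  A visual ring can inject a bump-shaped
current at the landmark-defined position ``theta_star``, pulling the bump
toward it.

Central ring dynamics (explicit Euler, rectified-linear activation)::

    tau_c * dr_c/dt = -r_c + relu(W_cc (*) r_c + I_ext)

where ``(*)`` is circular convolution scaled by the grid spacing ``2*pi/n``.
Rotation-ring rates are algebraic (quasi-static) functions of the current
central-ring activity and the velocity-neuron rates, mirroring the invariant
bump-shape assumption used for the reduced model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .angles import TWO_PI, wrap_difference, wrap_position

__all__ = [
    "RingGrid",
    "WeightKernel",
    "NetworkParams",
    "NetworkState",
    "VisualDrive",
    "NoBumpError",
    "build_recurrent_kernel",
    "circular_convolve",
    "step_central_ring",
    "step_full_network",
    "rotation_ring_rates",
    "decode_bump_location",
    "default_network",
    "converge_bump",
    "make_visual_drive",
    "simulate_central_ring",
    "simulate_full",
    "bump_emergence_time",
    "count_local_maxima",
    "measure_gain_profile",
]


class NoBumpError(ValueError):
    """Raised when a bump location is requested from an all-zero rate vector."""


@dataclass(frozen=True)
class RingGrid:
    """Uniform discretization of the circular neural space ``psi in [0, 2*pi)``."""

    n_neurons: int

    def __post_init__(self):
        if self.n_neurons < 16:
            raise ValueError("RingGrid requires at least 16 neurons")

    @property
    def angles(self) -> np.ndarray:
        return TWO_PI * np.arange(self.n_neurons) / self.n_neurons

    @property
    def spacing(self) -> float:
        return TWO_PI / self.n_neurons

    def bin_of(self, angle: float) -> int:
        """Index of the grid bin nearest to ``angle``."""
        return int(np.round(wrap_position(angle) / self.spacing)) % self.n_neurons


@dataclass(frozen=True)
class WeightKernel:
    """Synaptic weight as a function of angular offset on a :class:`RingGrid`.

    ``values[j]`` is the weight at offset ``psi_j = 2*pi*j/n`` (offsets wrap).
    """

    values: np.ndarray
    is_rotation_invariant: bool = True

    @property
    def n(self) -> int:
        return self.values.shape[0]


def build_recurrent_kernel(
    n: int,
    excit_width: float = 0.5,
    excit_amp: float = 6.0,
    inhib_amp: float = 0.5,
    normalize: bool = True,
) -> WeightKernel:
    """Local-excitation / global-inhibition recurrent kernel for the central ring.

    A Gaussian excitatory lobe of angular s.d. ``excit_width`` (radians) rides
    on a constant inhibitory floor ``-inhib_amp``.  ``excit_amp = 0`` yields
    pure global inhibition.

    With ``normalize=True`` (default) the kernel is rescaled so the rectified
    recurrent map ``r -> relu(W (*) r)`` has its persistent bump as an exact
    fixed point: with a rectified-linear activation the map is positively
    homogeneous, so the bump family is neutral in amplitude and persists
    indefinitely without external input.  The rescaling divides the kernel by
    the nonlinear principal eigenvalue, found by power-type iteration.
    """
    if n < 16:
        raise ValueError("kernel requires n >= 16")
    if not (0.0 < excit_width < np.pi):
        raise ValueError("excit_width must lie in (0, pi)")
    if excit_amp < 0.0 or inhib_amp <= 0.0:
        raise ValueError("amplitudes must be positive (excit_amp may be zero)")
    offs = wrap_difference(TWO_PI * np.arange(n) / n)
    values = excit_amp * np.exp(-0.5 * (offs / excit_width) ** 2) - inhib_amp
    kernel = WeightKernel(values=values)
    if normalize and excit_amp > 0.0:
        lam = _bump_eigenvalue(kernel)
        if lam > 0.0:
            kernel = WeightKernel(values=values / lam)
    return kernel


def _bump_eigenvalue(kernel: WeightKernel, max_iter: int = 4000, tol: float = 1e-14) -> float:
    """Principal eigenvalue of the rectified recurrent map on its bump shape.

    Iterates ``r <- relu(W (*) r) / ||.||`` until the shape is stationary; the
    returned norm ratio is the amplitude growth factor of the converged bump.
    """
    n = kernel.n
    r = _relu(np.cos(TWO_PI * np.arange(n) / n))
    lam = 0.0
    for _ in range(max_iter):
        g = _relu(circular_convolve(kernel, r))
        norm = float(np.linalg.norm(g))
        if norm == 0.0:
            return 0.0
        r_new = g / norm
        if float(np.max(np.abs(r_new - r))) < tol:
            return norm  # r is unit-norm, so the norm ratio is just ||g||
        r = r_new
    return norm


def circular_convolve(kernel: WeightKernel, rates: np.ndarray) -> np.ndarray:
    """Discrete circular convolution scaled by the grid spacing ``2*pi/n``.

    ``out[i] = (2*pi/n) * sum_j kernel[(i - j) mod n] * rates[j]``.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape[0] != kernel.n:
        raise ValueError(
            f"grid mismatch: kernel has n={kernel.n}, rates has n={rates.shape[0]}"
        )
    n = kernel.n
    out = np.fft.irfft(np.fft.rfft(kernel.values) * np.fft.rfft(rates), n)
    return out * (TWO_PI / n)


@dataclass
class NetworkParams:
    """Structural parameters of the three-ring attractor.

    Velocity input convention: velocity neurons fire at
    ``u_cw(v) = relu(u_cw0 - alpha_cw * v)`` and
    ``u_ccw(v) = relu(u_ccw0 + alpha_ccw * v)``.  Their *baseline* component
    ``u_i0`` reaches each rotation ring through the uniform weight ``w_v0``,
    while the velocity-modulated component ``u_i(v) - u_i0`` is weighted by
    the per-neuron velocity-sensitivity profile ``w_v_cw(psi)`` /
    ``w_v_ccw(psi)``.  Splitting the pathway this way keeps the bump exactly
    stationary during immobility even when the sensitivity profiles are
    spatially nonuniform, which is what makes the spatially distributed PI
    gain well defined (see docs/methods.md).
    """

    grid: RingGrid
    tau_c: float = 0.01  # synaptic time constant (s)
    alpha_cw: float = 50.0  # |tuning slope| of CW velocity neuron (Hz per rad/s)
    alpha_ccw: float = 50.0
    u_cw0: float = 50.0  # velocity-neuron baseline rates (Hz)
    u_ccw0: float = 50.0
    I_bar: float = 30.0  # global inhibition onto rotation rings (Hz)
    b_bins: int = -6  # signed offset of rotation-to-central feedback, whole bins
    recurrent_gain: float = 1.0  # scaling of the (normalized) recurrent kernel
    kernel_cc: WeightKernel = None  # recurrent kernel W_c-c
    w_c_cw: np.ndarray = None  # topographic central->CW ring weights
    w_c_ccw: np.ndarray = None
    w_cw_c: np.ndarray = None  # offset CW->central feedback weights (inhibitory)
    w_ccw_c: np.ndarray = None
    w_v0: float = 0.3  # uniform weight of the velocity-neuron baseline drive
    w_v_cw: np.ndarray = None  # velocity-sensitivity profiles W_v-i(psi)
    w_v_ccw: np.ndarray = None
    rectify_mode: str = "warn"  # {"warn", "raise", "clip"} for out-of-range |v|

    def __post_init__(self):
        n = self.grid.n_neurons
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if self.alpha_cw <= 0 or self.alpha_ccw <= 0:
            raise ValueError("velocity tuning slopes must be positive")
        if self.u_cw0 < 0 or self.u_ccw0 < 0:
            raise ValueError("velocity-neuron baselines must be nonnegative")
        if self.kernel_cc is None:
            base = build_recurrent_kernel(n)
            self.kernel_cc = WeightKernel(values=self.recurrent_gain * base.values)
        for name, default in [
            ("w_c_cw", 0.8),
            ("w_c_ccw", 0.8),
            ("w_cw_c", -0.1),
            ("w_ccw_c", -0.1),
            ("w_v_cw", 1.0),
            ("w_v_ccw", 1.0),
        ]:
            val = getattr(self, name)
            if val is None:
                val = default
            setattr(self, name, np.broadcast_to(np.asarray(val, float), (n,)).copy())

    @property
    def b(self) -> float:
        """Feedback offset in radians (whole-bin multiples of the grid spacing)."""
        return self.b_bins * self.grid.spacing

    @property
    def v_max(self) -> float:
        """Largest |v| keeping both velocity neurons in their linear range."""
        return min(self.u_cw0 / self.alpha_cw, self.u_ccw0 / self.alpha_ccw)

    def copy(self) -> "NetworkParams":
        out = replace(self)
        for name in ("w_c_cw", "w_c_ccw", "w_cw_c", "w_ccw_c", "w_v_cw", "w_v_ccw"):
            setattr(out, name, getattr(self, name).copy())
        return out


@dataclass
class NetworkState:
    """Firing rates (Hz) of all ring populations at time ``t`` (s)."""

    r_c: np.ndarray
    r_cw: np.ndarray
    r_ccw: np.ndarray
    t: float = 0.0


@dataclass
class VisualDrive:
    """Bump-shaped synaptic current from the visual ring.

    ``rho_vis[j]`` is the current profile at angular offset ``psi_j`` from the
    peak; when active the central ring receives ``rho_vis(psi - theta_star)``.
    """

    rho_vis: np.ndarray
    theta_star: float = 0.0
    active: bool = True

    def current(self, grid: RingGrid) -> np.ndarray:
        if not self.active:
            return np.zeros(grid.n_neurons)
        shift = grid.bin_of(self.theta_star)
        return np.roll(self.rho_vis, shift)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _velocity_rates(v: float, params: NetworkParams) -> tuple[float, float]:
    """Rectified CW/CCW velocity-neuron rates, honoring the rectify policy."""
    cw = params.u_cw0 - params.alpha_cw * v
    ccw = params.u_ccw0 + params.alpha_ccw * v
    if cw < 0.0 or ccw < 0.0:
        msg = f"|v|={abs(v):.3g} rad/s exceeds the linear range (v_max={params.v_max:.3g})"
        if params.rectify_mode == "raise":
            raise ValueError(msg)
        if params.rectify_mode == "warn":
            warnings.warn(msg, RuntimeWarning, stacklevel=3)
    return max(cw, 0.0), max(ccw, 0.0)


def rotation_ring_rates(
    r_c: np.ndarray,
    v: float,
    params: NetworkParams,
    inhib_cw: np.ndarray | float = 0.0,
    inhib_ccw: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-static CW/CCW rotation-ring rates given central activity and velocity.

    ``inhib_cw``/``inhib_ccw`` are optional extra inhibitory currents (used by
    the plastic network's offset association-ring connections).
    """
    u_cw, u_ccw = _velocity_rates(v, params)
    base_cw = params.w_v0 * params.u_cw0 - params.I_bar
    base_ccw = params.w_v0 * params.u_ccw0 - params.I_bar
    r_cw = _relu(
        params.w_c_cw * r_c
        + params.w_v_cw * (u_cw - params.u_cw0)
        + base_cw
        - inhib_cw
    )
    r_ccw = _relu(
        params.w_c_ccw * r_c
        + params.w_v_ccw * (u_ccw - params.u_ccw0)
        + base_ccw
        - inhib_ccw
    )
    return r_cw, r_ccw


def rotation_feedback(
    r_cw: np.ndarray, r_ccw: np.ndarray, params: NetworkParams
) -> np.ndarray:
    """Offset one-to-one feedback current from the rotation rings onto the central ring.

    The central neuron at ``psi`` receives the CCW-ring neuron at ``psi - b``
    and the CW-ring neuron at ``psi + b``; the push-pull asymmetry of these two
    terms under nonzero velocity is what shifts the bump.
    """
    b = params.b_bins
    return params.w_ccw_c * np.roll(r_ccw, b) + params.w_cw_c * np.roll(r_cw, -b)


def _validate_dt(dt: float, tau_c: float):
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    if dt > tau_c:
        raise ValueError(f"dt={dt} exceeds the synaptic time constant tau_c={tau_c}")


def step_central_ring(
    state: NetworkState, I_ext: np.ndarray, dt: float, params: NetworkParams
) -> NetworkState:
    """One explicit-Euler step of the central ring alone.

    ``tau_c * dr/dt = -r + relu(W_cc (*) r + I_ext)``; rates stay >= 0.
    """
    _validate_dt(dt, params.tau_c)
    drive = _relu(circular_convolve(params.kernel_cc, state.r_c) + I_ext)
    r_c = state.r_c + (dt / params.tau_c) * (drive - state.r_c)
    return NetworkState(r_c=r_c, r_cw=state.r_cw, r_ccw=state.r_ccw, t=state.t + dt)


def step_full_network(
    state: NetworkState,
    v: float,
    visual: VisualDrive | None,
    dt: float,
    params: NetworkParams,
) -> NetworkState:
    """One Euler step of the full three-ring network with velocity and visual input."""
    _validate_dt(dt, params.tau_c)
    r_cw, r_ccw = rotation_ring_rates(state.r_c, v, params)
    I_ext = rotation_feedback(r_cw, r_ccw, params)
    if visual is not None and visual.active:
        I_ext = I_ext + visual.current(params.grid)
    drive = _relu(circular_convolve(params.kernel_cc, state.r_c) + I_ext)
    r_c = state.r_c + (dt / params.tau_c) * (drive - state.r_c)
    return NetworkState(r_c=r_c, r_cw=r_cw, r_ccw=r_ccw, t=state.t + dt)


def decode_bump_location(rates: np.ndarray) -> float:
    """Population-vector decode of the bump peak, in ``[0, 2*pi)``."""
    rates = np.asarray(rates, dtype=float)
    n = rates.shape[0]
    angles = TWO_PI * np.arange(n) / n
    s = float(np.dot(rates, np.sin(angles)))
    c = float(np.dot(rates, np.cos(angles)))
    if s == 0.0 and c == 0.0:
        raise NoBumpError("cannot decode bump location from all-zero rates")
    return float(np.mod(np.arctan2(s, c), TWO_PI))


# ---------------------------------------------------------------------------
# Construction helpers


def default_network(
    n: int = 256,
    calibrate_gain: float | None = 1.0,
    w_v_modulation: np.ndarray | None = None,
    recurrent_gain: float = 1.08,
    tau_c: float = 0.005,
    **overrides,
) -> NetworkParams:
    """Default full three-ring network with the PI gain calibrated analytically.

    The recurrent kernel is slightly supercritical (``recurrent_gain`` times
    the neutral normalization); the inhibitory offset feedback from the
    rotation rings then pins the bump at a stable, finite amplitude with the
    rotation rings robustly active.  ``calibrate_gain`` rescales the
    velocity-sensitivity profiles so the spatial average of the predicted
    gain profile equals the requested value (typically 1, i.e. the bump
    tracks the animal veridically).  ``w_v_modulation`` multiplies both
    profiles (e.g. ``1 + 0.4*sin(psi)``) *before* calibration, producing a
    spatially inhomogeneous gain.
    """
    grid = RingGrid(n)
    params = NetworkParams(
        grid=grid, recurrent_gain=recurrent_gain, tau_c=tau_c, **overrides
    )
    if w_v_modulation is not None:
        mod = np.broadcast_to(np.asarray(w_v_modulation, float), (n,))
        params.w_v_cw = params.w_v_cw * mod
        params.w_v_ccw = params.w_v_ccw * mod
    if calibrate_gain is not None:
        from .reduced_model import compute_pi_gain_profile, spatial_average

        template = converge_bump(params)
        r_cw, r_ccw = rotation_ring_rates(template, 0.0, params)
        k0_raw = spatial_average(
            compute_pi_gain_profile(params, template, (r_cw, r_ccw))
        )
        if abs(k0_raw) < 1e-12:
            raise RuntimeError("cannot calibrate: predicted gain is zero")
        scale = calibrate_gain / k0_raw
        params.w_v_cw = params.w_v_cw * scale
        params.w_v_ccw = params.w_v_ccw * scale
    return params


def converge_bump(
    params: NetworkParams,
    theta: float = 0.0,
    duration: float = 1.0,
    dt: float | None = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """Converged central-ring bump template centered at ``theta`` (v=0, no visual).

    Integrates the full network from a cosine-bump seed until the rate vector
    stops changing, then recenters the result exactly on ``theta``.
    """
    n = params.grid.n_neurons
    dt = params.tau_c / 20.0 if dt is None else dt
    angles = params.grid.angles
    seed_bump = 30.0 * _relu(np.cos(angles - theta))
    state = NetworkState(r_c=seed_bump, r_cw=np.zeros(n), r_ccw=np.zeros(n))
    n_steps = int(round(duration / dt))
    for i in range(n_steps):
        prev = state.r_c
        state = step_full_network(state, 0.0, None, dt, params)
        if i % 50 == 49:
            denom = max(float(np.max(np.abs(state.r_c))), 1e-12)
            if float(np.max(np.abs(state.r_c - prev))) / denom < tol:
                break
    # recenter on the requested angle (decode may be off-grid by < one bin)
    shift = params.grid.bin_of(theta) - params.grid.bin_of(
        decode_bump_location(state.r_c)
    )
    return np.roll(state.r_c, shift)


def make_visual_drive(
    params: NetworkParams,
    amplitude: float = 3.0,
    theta_star: float = 0.0,
    template: np.ndarray | None = None,
) -> VisualDrive:
    """Visual current shaped like the converged bump, scaled to ``amplitude`` Hz peak."""
    if template is None:
        template = converge_bump(params, theta=0.0)
    peak = float(np.max(template))
    if peak <= 0:
        raise NoBumpError("flat template cannot define a visual drive")
    return VisualDrive(
        rho_vis=amplitude * template / peak, theta_star=theta_star, active=True
    )


# ---------------------------------------------------------------------------
# Simulation and measurement utilities


def simulate_central_ring(
    params: NetworkParams,
    duration: float = 0.2,
    dt: float | None = None,
    seed: int = 0,
    record_every: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the isolated central ring from pseudo-random nonnegative initial rates.

    Returns ``(times, rates)`` with ``rates[i]`` the rate vector at
    ``times[i]``.
    """
    n = params.grid.n_neurons
    dt = params.tau_c / 20.0 if dt is None else dt
    rng = np.random.default_rng(seed)
    state = NetworkState(
        r_c=rng.uniform(0.0, 20.0, size=n), r_cw=np.zeros(n), r_ccw=np.zeros(n)
    )
    n_steps = int(round(duration / dt))
    times, rates = [0.0], [state.r_c.copy()]
    zero = np.zeros(n)
    for i in range(n_steps):
        state = step_central_ring(state, zero, dt, params)
        if (i + 1) % record_every == 0:
            times.append(state.t)
            rates.append(state.r_c.copy())
    return np.asarray(times), np.asarray(rates)


def _smooth_circular(rates: np.ndarray, sigma_bins: float = 3.0) -> np.ndarray:
    n = rates.shape[-1]
    offs = wrap_difference(TWO_PI * np.arange(n) / n) / (TWO_PI / n)
    g = np.exp(-0.5 * (offs / sigma_bins) ** 2)
    g /= g.sum()
    return np.fft.irfft(np.fft.rfft(rates, axis=-1) * np.fft.rfft(g), n, axis=-1)


def count_local_maxima(
    rates: np.ndarray, sigma_bins: float = 3.0, rel_height: float = 0.02
) -> int:
    """Number of local maxima of the circularly smoothed rate vector.

    Maxima below ``rel_height`` times the global peak are ignored (numerical
    ripple in silent regions of a rectified network is not a bump).
    """
    sm = _smooth_circular(np.asarray(rates, float), sigma_bins)
    left, right = np.roll(sm, 1), np.roll(sm, -1)
    peaks = (sm > left) & (sm >= right) & (sm > rel_height * sm.max())
    return int(np.sum(peaks))


def bump_emergence_time(
    times: np.ndarray,
    rates: np.ndarray,
    sigma_bins: float = 3.0,
    contrast: float = 0.5,
) -> float:
    """First time the smoothed rate vector is a single bump.

    Criteria: exactly one local maximum on the circle and a peak-to-trough
    contrast ``(max - min) / max >= contrast``.  Returns ``inf`` if a bump
    never forms within the recorded window.
    """
    for t, r in zip(times, rates):
        sm = _smooth_circular(r, sigma_bins)
        peak = float(sm.max())
        if peak <= 0:
            continue
        if (peak - float(sm.min())) / peak < contrast:
            continue
        if count_local_maxima(r, sigma_bins) == 1:
            return float(t)
    return float("inf")


def simulate_full(
    params: NetworkParams,
    velocity,
    duration: float,
    visual: VisualDrive | None = None,
    k_star: float = 1.0,
    dt: float | None = None,
    record_dt: float = 0.01,
    initial_theta: float = 0.0,
    template: np.ndarray | None = None,
):
    """Simulate the full network under a velocity profile and optional landmarks.

    ``velocity`` may be a scalar, a callable ``v(t)`` or a
    :class:`~ringrecal.synthetic_inputs.VelocityProfile`.  When ``visual`` is
    given, its peak advances as ``dtheta*/dt = k_star * v`` (landmark motion
    controlled by the visual gain).  Returns a
    :class:`~ringrecal.analysis_io.Trajectory`.
    """
    from .analysis_io import Trajectory

    n = params.grid.n_neurons
    dt = params.tau_c / 20.0 if dt is None else dt
    v_of_t = velocity if callable(velocity) else (lambda t, _v=float(velocity): _v)
    if template is None:
        template = converge_bump(params, theta=initial_theta)
    else:
        template = np.roll(
            template,
            params.grid.bin_of(initial_theta)
            - params.grid.bin_of(decode_bump_location(template)),
        )
    r_cw, r_ccw = rotation_ring_rates(template, v_of_t(0.0), params)
    state = NetworkState(r_c=template.copy(), r_cw=r_cw, r_ccw=r_ccw)
    theta_star = visual.theta_star if visual is not None else initial_theta

    n_steps = int(round(duration / dt))
    record_every = max(1, int(round(record_dt / dt)))
    rows = []

    def _record(t, v):
        theta = decode_bump_location(state.r_c)
        rows.append(
            (
                t,
                v,
                theta,
                wrap_position(theta_star),
                wrap_difference(theta_star - theta),
                float(state.r_c.mean()),
                float(state.r_cw.mean()),
                float(state.r_ccw.mean()),
            )
        )

    _record(0.0, v_of_t(0.0))
    for i in range(n_steps):
        t = i * dt
        v = float(v_of_t(t))
        if visual is not None:
            theta_star += k_star * v * dt
            visual.theta_star = wrap_position(theta_star)
        state = step_full_network(state, v, visual, dt, params)
        if (i + 1) % record_every == 0:
            _record(state.t, v)

    frame_cols = [
        "t",
        "v",
        "theta",
        "theta_star",
        "theta_tilde",
        "mean_rate_c",
        "mean_rate_cw",
        "mean_rate_ccw",
    ]
    import pandas as pd

    df = pd.DataFrame(rows, columns=frame_cols)
    meta = {
        "kind": "full_network",
        "n": n,
        "dt": dt,
        "k_star": k_star,
        "landmarks": visual is not None,
    }
    return Trajectory(frame=df, meta=meta)


def measure_gain_profile(
    params: NetworkParams,
    v: float,
    n_laps: float = 1.0,
    dt: float | None = None,
    n_theta: int = 64,
    template: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Measure the PI gain ``k(theta) = bump speed / v`` from a full simulation.

    Runs the network at constant velocity for ``n_laps`` bump laps, computes
    the instantaneous decoded bump speed by central differences, and bin-
    averages ``speed / v`` on a ``theta`` grid.  Returns ``(theta_grid, k)``.
    """
    if v == 0.0:
        raise ValueError("probe velocity must be nonzero")
    duration = abs(n_laps * TWO_PI / v)  # nominal (gain ~ 1) lap time
    traj = simulate_full(
        params, v, duration, visual=None, dt=dt, record_dt=0.005, template=template
    )
    t = traj.frame["t"].to_numpy()
    theta = np.unwrap(traj.frame["theta"].to_numpy())
    speed = np.gradient(theta, t)
    k_samples = speed / v
    centers = wrap_position(theta)
    edges = np.linspace(0.0, TWO_PI, n_theta + 1)
    idx = np.clip(np.digitize(centers, edges) - 1, 0, n_theta - 1)
    k = np.full(n_theta, np.nan)
    for j in range(n_theta):
        m = idx == j
        if m.sum() >= 2:
            k[j] = float(np.mean(k_samples[m]))
    grid = 0.5 * (edges[:-1] + edges[1:])
    return grid, k
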