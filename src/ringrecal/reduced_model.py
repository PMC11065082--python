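"""Reduced-order models of the bump location and the spatially distributed PI gain.

Projecting the full ring-attractor dynamics onto the bump's translation mode
reduces the network to a one-dimensional ODE for the bump location ``theta``::

    dtheta*/dt = k_star * v                      (landmark position)
    dtheta/dt  = beta(theta* - theta) + k(theta) * v

where ``k(theta)`` is the path-integration gain profile, ``k0`` its spatial
average, ``kac(theta) = k(theta) - k0`` the zero-mean deviation, and ``beta``
the landmark feedback (sign-matching its argument near 0, e.g.
``0.66 * sin``).  An optional gain-update rule ``dk0/dt = g0(k0, theta~, v)``
models recalibration (see :mod:`ringrecal.gain_adaptation`).

The gain profile is evaluated from network structure as

    k(theta) = -b / (tau_c * ||dr*/dpsi||^2)
               * Int d2r*(psi - theta)/dpsi^2
                 * sum_i alpha_i W_i-c(psi) W_v-i(psi) sign(r_i*(psi, theta, 0)) dpsi

with the squared L2 norm of the bump-template gradient in the denominator,
central differences on the circular grid, and the rectified rotation-ring
templates supplying the ``sign`` indicator (0 or 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .angles import TWO_PI, wrap_difference, wrap_position
from .network_core import NetworkParams, NoBumpError

__all__ = [
    "GainProfile",
    "FeedbackFunction",
    "ReducedState",
    "compute_pi_gain_profile",
    "spatial_average",
    "beta_sinusoidal",
    "simulate_reduced",
    "uniform_gain_profile",
]


@dataclass
class GainProfile:
    """PI gain ``k(theta)`` sampled on a uniform theta grid."""

    theta: np.ndarray
    k_values: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.k_values = np.asarray(self.k_values, dtype=float)
        if self.theta.shape != self.k_values.shape:
            raise ValueError("theta and k_values must have the same shape")

    @property
    def k0(self) -> float:
        """Spatial average of the gain (trapezoid on the circle = plain mean)."""
        return float(np.mean(self.k_values))

    @property
    def kac_values(self) -> np.ndarray:
        """Zero-mean deviation ``k(theta) - k0``."""
        return self.k_values - self.k0

    def kac_at(self, theta) -> np.ndarray | float:
        """Deviation ``kac`` linearly interpolated (circularly) at ``theta``."""
        th = wrap_position(theta)
        grid = np.concatenate([self.theta, [self.theta[0] + TWO_PI]])
        vals = np.concatenate([self.kac_values, [self.kac_values[0]]])
        out = np.interp(th, grid, vals)
        return float(out) if np.isscalar(theta) else out


def uniform_gain_profile(k0: float, n: int = 64) -> GainProfile:
    """Spatially homogeneous gain profile of value ``k0``."""
    theta = TWO_PI * np.arange(n) / n
    return GainProfile(theta=theta, k_values=np.full(n, float(k0)))


@dataclass
class FeedbackFunction:
    """Landmark feedback ``beta`` mapping wrapped positional error to rad/s.

    Must vanish at 0 and share the sign of its argument near 0 (negative
    feedback pulling ``theta`` toward ``theta*``).
    """

    func: Callable[[float], float]
    params: dict = field(default_factory=dict)
    label: str = "beta"

    def __call__(self, x):
        return self.func(x)


def beta_sinusoidal(amplitude: float = 0.66) -> FeedbackFunction:
    """Sinusoidal landmark feedback ``beta(x) = amplitude * sin(x)``."""
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    return FeedbackFunction(
        func=lambda x: amplitude * np.sin(x),
        params={"amplitude": amplitude},
        label=f"{amplitude}*sin",
    )


@dataclass
class ReducedState:
    """Bump location, landmark location and average gain of the reduced model."""

    theta: float = 0.0
    theta_star: float = 0.0
    k0: float = 1.0
    t: float = 0.0

    def __post_init__(self):
        self.theta = float(wrap_position(self.theta))
        self.theta_star = float(wrap_position(self.theta_star))

    @property
    def theta_tilde(self) -> float:
        """Wrapped positional error ``theta* - theta``."""
        return float(wrap_difference(self.theta_star - self.theta))


# ---------------------------------------------------------------------------
# Analytic gain profile


def _d1_circular(r: np.ndarray, dpsi: float) -> np.ndarray:
    return (np.roll(r, -1) - np.roll(r, 1)) / (2.0 * dpsi)


def _d2_circular(r: np.ndarray, dpsi: float) -> np.ndarray:
    return (np.roll(r, -1) - 2.0 * r + np.roll(r, 1)) / dpsi**2


def compute_pi_gain_profile(
    params: NetworkParams,
    bump_template: np.ndarray,
    rotation_templates: tuple[np.ndarray, np.ndarray],
) -> GainProfile:
    """Analytic PI gain profile of the network, evaluated on the neural grid.

    ``bump_template`` is the converged central-ring bump at immobility and
    ``rotation_templates = (r_cw*, r_ccw*)`` the matching rotation-ring bumps;
    all centered at the same location.  The gain at each ``theta`` is obtained
    by rotating the templates and evaluating the projection integral by
    quadrature on the grid.
    """
    grid = params.grid
    n = grid.n_neurons
    dpsi = grid.spacing
    r = np.asarray(bump_template, dtype=float)
    if r.shape[0] != n:
        raise ValueError("bump template does not match the parameter grid")
    d1 = _d1_circular(r, dpsi)
    grad_norm_sq = float(np.sum(d1**2) * dpsi)
    if grad_norm_sq < 1e-12:
        raise NoBumpError("flat bump template: gradient norm is zero")
    d2 = _d2_circular(r, dpsi)
    r_cw0, r_ccw0 = rotation_templates
    s_cw0 = (np.asarray(r_cw0, float) > 0.0).astype(float)
    s_ccw0 = (np.asarray(r_ccw0, float) > 0.0).astype(float)

    w_cw = params.alpha_cw * params.w_cw_c * params.w_v_cw
    w_ccw = params.alpha_ccw * params.w_ccw_c * params.w_v_ccw

    k = np.empty(n)
    pref = -params.b / (params.tau_c * grad_norm_sq)
    for j in range(n):
        d2_shift = np.roll(d2, j)  # d2 r*(psi - theta_j)
        integrand = d2_shift * (
            w_cw * np.roll(s_cw0, j) + w_ccw * np.roll(s_ccw0, j)
        )
        k[j] = pref * float(np.sum(integrand) * dpsi)
    return GainProfile(theta=grid.angles.copy(), k_values=k)


def spatial_average(profile: GainProfile) -> float:
    """Spatial average ``k0`` of a gain profile (mean of uniform samples)."""
    return profile.k0


# ---------------------------------------------------------------------------
# Reduced-model simulation


def simulate_reduced(
    initial: ReducedState,
    velocity,
    k_star: float,
    beta: FeedbackFunction,
    rule=None,
    kac: GainProfile | None = None,
    dt: float = 0.01,
    duration: float | None = None,
    landmarks_off_after: float | None = None,
    record_dt: float = 0.1,
    method: str = "rk4",
):
    """Integrate the reduced bump-location model, optionally with gain updates.

    ``velocity`` is a scalar, callable ``v(t)`` or ``VelocityProfile`` (whose
    duration is used when ``duration`` is None).  ``rule`` is an optional
    :class:`~ringrecal.gain_adaptation.GainRule` driving ``dk0/dt``.  ``kac``
    supplies a frozen spatial gain deviation; the instantaneous gain is
    ``k0(t) + kac(theta)``.  The landmark feedback term is dropped after
    ``landmarks_off_after`` seconds (never, if None).  Returns a
    :class:`~ringrecal.analysis_io.Trajectory`.
    """
    from .analysis_io import Trajectory
    import pandas as pd

    if callable(velocity):
        v_of_t = velocity
    else:
        v_of_t = lambda t, _v=float(velocity): _v
    if duration is None:
        dur = getattr(velocity, "duration", None)
        if dur is None:
            raise ValueError("duration must be given when velocity has none")
        duration = float(dur)
    if method not in ("rk4", "euler"):
        raise ValueError("method must be 'rk4' or 'euler'")

    kac_at = (lambda th: 0.0) if kac is None else kac.kac_at
    g0 = (lambda k0, err, v: 0.0) if rule is None else rule.g0

    def deriv(t, y):
        th_star, th, k0 = y
        v = float(v_of_t(t))
        landmarks_on = landmarks_off_after is None or t < landmarks_off_after
        err = wrap_difference(th_star - th)
        dth_star = k_star * v
        dth = (beta(err) if landmarks_on else 0.0) + (k0 + kac_at(th)) * v
        dk0 = g0(k0, err, v) if landmarks_on else 0.0
        return np.array([dth_star, dth, dk0])

    y = np.array([initial.theta_star, initial.theta, initial.k0])
    n_steps = int(round(duration / dt))
    record_every = max(1, int(round(record_dt / dt)))
    rows = [
        (
            0.0,
            float(v_of_t(0.0)),
            wrap_position(y[1]),
            wrap_position(y[0]),
            wrap_difference(y[0] - y[1]),
            y[2],
        )
    ]
    for i in range(n_steps):
        t = i * dt
        if method == "rk4":
            k1 = deriv(t, y)
            k2 = deriv(t + 0.5 * dt, y + 0.5 * dt * k1)
            k3 = deriv(t + 0.5 * dt, y + 0.5 * dt * k2)
            k4 = deriv(t + dt, y + dt * k3)
            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        else:
            y = y + dt * deriv(t, y)
        if (i + 1) % record_every == 0:
            tnew = t + dt
            rows.append(
                (
                    tnew,
                    float(v_of_t(tnew)),
                    wrap_position(y[1]),
                    wrap_position(y[0]),
                    wrap_difference(y[0] - y[1]),
                    y[2],
                )
            )

    df = pd.DataFrame(
        rows, columns=["t", "v", "theta", "theta_star", "theta_tilde", "k0"]
    )
    meta = {
        "kind": "reduced",
        "k_star": k_star,
        "dt": dt,
        "method": method,
        "rule": getattr(rule, "label", None),
        "landmarks_off_after": landmarks_off_after,
    }
    return Trajectory(frame=df, meta=meta)
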